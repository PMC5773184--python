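"""Four-level variance decomposition of phase output with resampling inference.

The decomposition separates, for each network level (CPG interneurons,
motor neurons, heart constrictions) and coordination state:

* cycle-to-cycle variance: angular variance of per-cycle phase
  differences within one coordination episode;
* population variance: angular variance of per-animal mean phase
  differences (one switch cycle per animal), with a bootstrap CI;
* repetition variance: angular variance of the per-animal circular
  difference between two consecutive switch cycles (Delta-Delta-phi),
  tested against a null built by scrambling switch cycles across animals;
* bilateral variance: the same construction for left-vs-right phase
  differences within a coordination.

Scrambling tests report a p-value from the z score of the observed
variance under a normal fit to the scrambled-variance distribution,
one-sided toward "observed smaller than scrambled".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import (
    FOUR_PI_SQ,
    CircularSummary,
    angular_variance,
    center_phase,
    circular_mean,
    circular_mean_difference,
    circular_summary,
)
from .episodes import Episode

__all__ = [
    "PopulationVariance",
    "ScramblingResult",
    "TTestResult",
    "abs_ddphi_summary",
    "bilateral_test",
    "compare_levels",
    "cycle_to_cycle_variance",
    "estimate_variance_components",
    "outlier_screen",
    "phase_period_correlation",
    "population_variance",
    "repetition_test",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def cycle_to_cycle_variance(episode: Episode, min_cycles: int = 7) -> CircularSummary | None:
    """Circular summary of one episode's per-cycle phase differences.

    Episodes shorter than ``min_cycles`` (default 7, the smallest
    per-switch-cycle count retained in the source datasets) are excluded
    with a warning and return ``None``.
    """
    if episode.n_cycles < min_cycles:
        warnings.warn(
            f"episode {episode.side}/{episode.coordination} has "
            f"{episode.n_cycles} < {min_cycles} cycles; excluded",
            stacklevel=2,
        )
        return None
    return circular_summary(episode.dphi)


@dataclass(frozen=True)
class PopulationVariance:
    """Angular variance of per-animal mean phase differences, with CI."""

    n: int
    mean_dphi: float  # centered mean vector phase across animals
    var_phase: float  # point estimate, phase units squared
    ci_lo: float
    ci_hi: float
    ci_level: float
    n_boot: int
    method: str


def _angvar_and_se(phases_2d: np.ndarray):
    """Angular variance (phase^2) and linearized SE for each row.

    The angular variance is, to first order, the sample mean of the
    per-observation contributions ``2(1 - cos(theta_i - mean))``; its
    standard error is estimated from the spread of those contributions.
    """
    ang = 2.0 * np.pi * phases_2d
    c = np.mean(np.cos(ang), axis=1, keepdims=True)
    s = np.mean(np.sin(ang), axis=1, keepdims=True)
    r = np.minimum(np.hypot(c, s), 1.0)
    mu = np.arctan2(s, c)
    v = (2.0 * (1.0 - r) / FOUR_PI_SQ)[:, 0]
    contrib = 2.0 * (1.0 - np.cos(ang - mu)) / FOUR_PI_SQ
    n = phases_2d.shape[1]
    se = np.std(contrib, axis=1, ddof=1) / np.sqrt(n)
    return v, se


def population_variance(
    per_animal_means,
    n_boot: int = 10_000,
    ci: float = 0.95,
    rng=None,
    method: str = "studentized",
) -> PopulationVariance:
    """Population variance of per-animal mean phase differences.

    The point estimate is the angular variance of the per-animal means;
    the CI comes from ``n_boot`` bootstrap resamples (with replacement).
    ``method='studentized'`` (default) uses the bootstrap-t construction
    with a linearized standard error, which holds close to nominal
    coverage for variance-type statistics at small n; ``'percentile'``
    gives the plain percentile interval.
    """
    means = np.asarray(per_animal_means, dtype=float)
    n = means.size
    if n < 3:
        raise ValueError("population variance requires at least 3 animals")
    if method not in ("studentized", "percentile"):
        raise ValueError(f"unknown CI method: {method!r}")
    rng = _as_rng(rng)
    point, se = _angvar_and_se(means[None, :])
    point, se = float(point[0]), float(se[0])
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_v, boot_se = _angvar_and_se(means[idx])
    alpha = 1.0 - ci
    if method == "percentile":
        lo, hi = np.percentile(boot_v, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        ok = boot_se > 0
        if se == 0.0 or not np.any(ok):
            lo = hi = point  # degenerate sample (all means identical)
        else:
            t_stat = (boot_v[ok] - point) / boot_se[ok]
            q_lo, q_hi = np.percentile(t_stat, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            lo, hi = point - q_hi * se, point - q_lo * se
    lo = max(float(lo), 0.0)
    hi = max(float(hi), lo)
    return PopulationVariance(
        n=n,
        mean_dphi=center_phase(circular_mean(means)),
        var_phase=point,
        ci_lo=min(lo, point),
        ci_hi=max(hi, point),
        ci_level=ci,
        n_boot=n_boot,
        method=method,
    )


@dataclass(frozen=True)
class ScramblingResult:
    """Observed Delta-Delta-phi variance against a scrambled-pairing null."""

    n_pairs: int
    observed: float  # angular variance of Delta-Delta-phi, phase^2
    mean_ddphi: float
    mean_abs_ddphi: float
    null_mean: float
    null_sd: float
    z: float
    p_lower: float  # one-sided: observed smaller than scrambled
    p_two_sided: float
    n_scramble: int
    pairing: str


def _derangement_rows(n: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-point-free partner matchings, one row per iteration.

    Each row is a random permutation composed with a nonzero cyclic
    shift, so every animal is matched to a different animal and each
    partner is used exactly once per iteration.
    """
    perm = np.argsort(rng.random((n_iter, n)), axis=1)
    inv = np.argsort(perm, axis=1)
    shift = rng.integers(1, n, size=(n_iter, 1))
    return np.take_along_axis(perm, (inv + shift) % n, axis=1)


def _independent_rows(n: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Partner j != i drawn independently for every animal and iteration."""
    u = rng.integers(0, n - 1, size=(n_iter, n))
    return (np.arange(n)[None, :] + 1 + u) % n


def _scramble_test(
    a, b, n_scramble: int, rng, pairing: str, min_pairs: int
) -> ScramblingResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be 1-D arrays of equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    n_drop = int(np.sum(~keep))
    if n_drop:
        warnings.warn(f"dropped {n_drop} animals with a missing value", stacklevel=3)
    a, b = a[keep], b[keep]
    n = a.size
    if n < min_pairs:
        raise ValueError(f"scrambling test requires >= {min_pairs} complete pairs, got {n}")
    rng = _as_rng(rng)
    dd = circular_mean_difference(a, b)
    observed = float(angular_variance(dd))
    za = np.exp(2j * np.pi * a)
    zb = np.exp(-2j * np.pi * b)
    if pairing == "derangement":
        J = _derangement_rows(n, n_scramble, rng)
    elif pairing == "independent":
        J = _independent_rows(n, n_scramble, rng)
    else:
        raise ValueError(f"unknown pairing scheme: {pairing!r}")
    null = 2.0 * (1.0 - np.abs(np.mean(za[None, :] * zb[J], axis=1))) / FOUR_PI_SQ
    mu, sd = float(np.mean(null)), float(np.std(null))
    if sd <= 1e-30:
        z = 0.0
        near = np.isclose(observed, mu, atol=1e-15)
        p_lower = 0.5 if near else (0.0 if observed < mu else 1.0)
    else:
        z = (observed - mu) / sd
        p_lower = float(stats.norm.cdf(z))
    p_two = float(min(1.0, 2.0 * min(p_lower, 1.0 - p_lower)))
    return ScramblingResult(
        n_pairs=n,
        observed=observed,
        mean_ddphi=float(center_phase(circular_mean(dd))),
        mean_abs_ddphi=float(np.mean(np.abs(dd))),
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p_lower=p_lower,
        p_two_sided=p_two,
        n_scramble=n_scramble,
        pairing=pairing,
    )


def repetition_test(
    dphi_cycle1,
    dphi_cycle2,
    n_scramble: int = 10_000,
    rng=None,
    pairing: str = "derangement",
) -> ScramblingResult:
    """Is a repeated coordination tighter than expected from the population?

    ``dphi_cycle1``/``dphi_cycle2`` are per-animal mean phase differences
    of two consecutive switch cycles.  The observed statistic is the
    angular variance of their circular differences; the null re-pairs
    switch cycle 1 of each animal with switch cycle 2 of a different
    animal, ``n_scramble`` times.  Animals missing a cycle are dropped.
    """
    return _scramble_test(dphi_cycle1, dphi_cycle2, n_scramble, rng, pairing, min_pairs=5)


def bilateral_test(
    dphi_left,
    dphi_right,
    n_scramble: int = 10_000,
    rng=None,
    pairing: str = "derangement",
) -> ScramblingResult:
    """Are bilaterally homologous elements tighter than the population?

    Same construction as :func:`repetition_test` with per-animal left and
    right mean phase differences within one coordination.
    """
    return _scramble_test(dphi_left, dphi_right, n_scramble, rng, pairing, min_pairs=5)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float
    paired: bool


def _linearize(phases, anchor: float) -> np.ndarray:
    """Unwrap phases into the window centered on ``anchor``."""
    return anchor + center_phase(np.asarray(phases, dtype=float) - anchor)


def compare_levels(a, b, paired: bool = False) -> TTestResult:
    """t-test of mean phase difference between two groups (e.g. two levels).

    Phases are first unwrapped around the pooled circular mean so the
    test operates on linear values free of wrap artifacts; this is exact
    for the small dispersions the system exhibits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    anchor = center_phase(circular_mean(np.concatenate([a, b])))
    la, lb = _linearize(a, anchor), _linearize(b, anchor)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length samples")
        d = la - lb
        if np.allclose(d, 0.0):
            res_t, res_p, df = 0.0, 1.0, a.size - 1
        else:
            res = stats.ttest_rel(la, lb)
            res_t, res_p, df = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        if np.allclose(la - la.mean(), 0.0) and np.allclose(lb - lb.mean(), 0.0):
            same = np.isclose(la.mean(), lb.mean())
            res_t, res_p, df = 0.0 if same else np.inf, 1.0 if same else 0.0, a.size + b.size - 2
        else:
            res = stats.ttest_ind(la, lb)
            res_t, res_p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TTestResult(
        t=res_t,
        p=res_p,
        df=float(df),
        mean_a=float(np.mean(la)),
        mean_b=float(np.mean(lb)),
        paired=paired,
    )


def abs_ddphi_summary(ddphis) -> float:
    """Mean of absolute centered circular differences |Delta-Delta-phi|."""
    dd = center_phase(np.asarray(ddphis, dtype=float))
    if dd.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(dd)))


def outlier_screen(values) -> np.ndarray:
    """Flag values outside 1.5 * IQR beyond the quartiles (Tukey fences)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("outlier screen requires at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def phase_period_correlation(dphi, periods) -> tuple[float, float]:
    """Pearson correlation of phase difference with cycle period.

    Plain utility; phases are unwrapped around their circular mean first.
    """
    dphi = np.asarray(dphi, dtype=float)
    anchor = center_phase(circular_mean(dphi))
    res = stats.pearsonr(_linearize(dphi, anchor), np.asarray(periods, dtype=float))
    return float(res.statistic), float(res.pvalue)


def estimate_variance_components(
    cycle_means: pd.DataFrame,
    level: str,
    coordination: str,
    side: str = "L",
    correct: bool = True,
) -> dict[str, float]:
    """Method-of-moments estimates of the four variance components.

    ``cycle_means`` is the tidy per-episode table with columns
    ``animal, side, level, coordination, switch_cycle, mean_dphi,
    cycle_var, n_cycles`` (one row per episode).  Estimators:

    * ``var_cycle``: mean within-episode angular variance;
    * ``var_repetition``: angular variance of per-animal differences
      between switch cycles 1 and 2 (one side);
    * ``var_bilateral``: angular variance of per-animal left-right
      differences (switch cycle 1) minus the repetition estimate, since
      the two sides' episodes carry independent repetition draws;
    * ``var_population``: angular variance of per-animal means (switch
      cycle 1, one side).

    With ``correct=True`` the finite-cycle noise of episode means
    (``cycle_var / n_cycles``) is subtracted where it enters, making the
    estimators asymptotically unbiased for the generating components.
    Estimates are clipped at zero.
    """
    sub = cycle_means[
        (cycle_means["level"] == level) & (cycle_means["coordination"] == coordination)
    ]
    if sub.empty:
        raise ValueError(f"no rows for level={level!r}, coordination={coordination!r}")

    out: dict[str, float] = {}
    out["var_cycle"] = float(sub["cycle_var"].mean())
    mean_noise = (sub["cycle_var"] / sub["n_cycles"]).mean() if correct else 0.0

    one_side = sub[sub["side"] == side]
    piv = one_side.pivot_table(index="animal", columns="switch_cycle", values="mean_dphi")
    if 1 in piv.columns and 2 in piv.columns:
        both = piv[[1, 2]].dropna()
        dd = circular_mean_difference(both[1].to_numpy(), both[2].to_numpy())
        out["var_repetition"] = max(float(angular_variance(dd)) - 2 * mean_noise, 0.0)
        out["n_repetition"] = len(both)
    else:
        out["var_repetition"] = np.nan
        out["n_repetition"] = 0

    sc1 = sub[sub["switch_cycle"] == 1]
    pivlr = sc1.pivot_table(index="animal", columns="side", values="mean_dphi")
    if "L" in pivlr.columns and "R" in pivlr.columns:
        both = pivlr[["L", "R"]].dropna()
        dd = circular_mean_difference(both["L"].to_numpy(), both["R"].to_numpy())
        raw = float(angular_variance(dd)) - 2 * mean_noise
        rep = out["var_repetition"] if np.isfinite(out["var_repetition"]) else 0.0
        out["var_bilateral"] = max(raw - rep, 0.0)
        out["n_bilateral"] = len(both)
    else:
        out["var_bilateral"] = np.nan
        out["n_bilateral"] = 0

    pop = one_side[one_side["switch_cycle"] == 1]["mean_dphi"].to_numpy()
    if pop.size >= 3:
        out["var_population"] = max(float(angular_variance(pop)) - mean_noise, 0.0)
        out["n_population"] = int(pop.size)
    else:
        out["var_population"] = np.nan
        out["n_population"] = int(pop.size)
    return out
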