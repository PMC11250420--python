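"""MR-PRESSO: pleiotropy residual sum and outlier framework.

Three seeded Monte-Carlo tests on harmonized pairs:

* **global** — observed residual sum of squares, each SNP's residual taken
  about its leave-one-out IVW prediction, compared against RSS from
  datasets simulated under the no-pleiotropy model;
* **outlier** — each SNP's observed weighted squared residual against its
  own simulated distribution, Bonferroni-adjusted across SNPs;
* **distortion** — whether removing the flagged outliers changes the IVW
  estimate more than removing random SNP subsets of the same size.

``run_presso_and_refit`` orchestrates the three tests and, when outliers
are found, reruns the full estimator battery on the reduced set — the
workflow the forest-plot analyses use when heterogeneity is detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CismrError, DataError
from .estimators import (
    HeterogeneityResult,
    MrResult,
    PleiotropyResult,
    cochran_q,
    egger,
    ivw,
    weighted_median,
)
from .harmonize import HarmonizedPair

logger = logging.getLogger(__name__)

MIN_SNPS = 4


@dataclass
class PressoResult:
    """Global / outlier / distortion test outputs plus the corrected estimate."""

    rss_obs: float
    global_p: float
    n_sim: int
    seed: int
    per_snp_p: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)
    distortion_p: float | None = None
    corrected: MrResult | None = None


@dataclass
class PressoReport:
    """PRESSO plus the post-outlier-removal second pass of MR estimators."""

    presso: PressoResult
    second_pass: dict[str, object] | None = None
    notes: list[str] = field(default_factory=list)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, one per SNP (vectorized)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _core(pairs, n_sim: int, seed: int):
    """Observed per-SNP residuals and their simulated null distributions."""
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    obs_resid = (by - theta_loo * bx) ** 2 / sy**2
    rss_obs = float(obs_resid.sum())

    rng = np.random.default_rng(seed)
    expected = theta_loo * bx
    by_sim = rng.normal(expected, sy, size=(n_sim, len(pairs)))
    bx_sim = rng.normal(bx, sx, size=(n_sim, len(pairs)))

    sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    theta_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim * bx_sim)
    sim_resid = (by_sim - theta_sim * bx_sim) ** 2 / sy**2

    return rss_obs, obs_resid, sim_resid


def _check(pairs):
    if len(pairs) < MIN_SNPS:
        raise CismrError(
            f"MR-PRESSO requires at least {MIN_SNPS} instruments (got {len(pairs)})"
        )


def presso_global(
    pairs: list[HarmonizedPair], n_sim: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Global pleiotropy test. Returns (rss_obs, empirical p).

    The empirical p is (1 + #{RSS* ≥ RSS_obs}) / (n_sim + 1), floored at
    1/(n_sim+1); deterministic given the seed.
    """
    _check(pairs)
    if seed is None:
        raise CismrError("presso_global requires an explicit seed")
    rss_obs, _, sim_resid = _core(pairs, n_sim, seed)
    rss_sim = sim_resid.sum(axis=1)
    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    return rss_obs, global_p


def presso_outlier(
    pairs: list[HarmonizedPair],
    n_sim: int = 1000,
    seed: int | None = None,
    significance: float = 0.05,
) -> tuple[dict[str, float], list[str]]:
    """Per-SNP outlier test with Bonferroni adjustment across SNPs."""
    _check(pairs)
    if seed is None:
        raise CismrError("presso_outlier requires an explicit seed")
    _, obs_resid, sim_resid = _core(pairs, n_sim, seed)
    j = len(pairs)
    per_snp_p: dict[str, float] = {}
    outliers: list[str] = []
    for i, pair in enumerate(pairs):
        p_raw = (1.0 + float(np.sum(sim_resid[:, i] >= obs_resid[i]))) / (n_sim + 1.0)
        per_snp_p[pair.rsid] = p_raw
        if p_raw * j < significance:
            outliers.append(pair.rsid)
    return per_snp_p, outliers


def presso_distortion(
    pairs: list[HarmonizedPair],
    outliers: list[str],
    n_boot: int = 1000,
    seed: int | None = None,
    ivw_model: str = "multiplicative_random",
) -> tuple[float, MrResult]:
    """Distortion test: is the outlier-corrected estimate meaningfully shifted?

    Statistic D = (θ̂_all − θ̂_corrected)/|θ̂_corrected|, referenced against
    the same statistic under removal of random subsets of equal size.
    """
    if not outliers:
        raise CismrError("distortion test requires a non-empty outlier set")
    if seed is None:
        raise CismrError("presso_distortion requires an explicit seed")
    keep = [p for p in pairs if p.rsid not in set(outliers)]
    if len(keep) < 2:
        raise DataError("cannot correct: fewer than 2 non-outlier instruments remain")
    theta_all = ivw(pairs, model=ivw_model).estimate
    corrected = ivw(keep, model=ivw_model)
    if corrected.estimate == 0:
        raise DataError("corrected estimate is exactly 0; distortion undefined")
    d_obs = (theta_all - corrected.estimate) / abs(corrected.estimate)

    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    w = 1.0 / sy**2
    j, k = len(pairs), len(set(outliers) & {p.rsid for p in pairs})
    rng = np.random.default_rng(seed)
    d_null = np.empty(n_boot)
    for b in range(n_boot):
        drop = rng.choice(j, size=k, replace=False)
        mask = np.ones(j, dtype=bool)
        mask[drop] = False
        th = float(np.sum((w * bx * by)[mask]) / np.sum((w * bx * bx)[mask]))
        d_null[b] = (theta_all - th) / abs(th) if th != 0 else np.inf
    distortion_p = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_boot + 1.0)
    return distortion_p, corrected


def run_presso_and_refit(
    pairs: list[HarmonizedPair],
    n_sim: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    significance: float = 0.05,
    ivw_model: str = "multiplicative_random",
    wm_n_boot: int = 1000,
) -> PressoReport:
    """Global -> outlier -> distortion, then rerun the estimator battery.

    The outlier test runs only when the global test is significant; the
    second pass (IVW, Egger, weighted median, Q) runs only when outliers
    were flagged, on the reduced set, with methods below their minimum SNP
    count skipped and the reason recorded.
    """
    _check(pairs)
    if seed is None:
        raise CismrError("run_presso_and_refit requires an explicit seed")
    rss_obs, global_p = presso_global(pairs, n_sim=n_sim, seed=seed)
    result = PressoResult(
        rss_obs=rss_obs, global_p=global_p, n_sim=n_sim, seed=seed
    )
    report = PressoReport(presso=result)
    if global_p >= significance:
        report.notes.append("global test not significant; no outlier search")
        return report

    per_snp_p, outliers = presso_outlier(
        pairs, n_sim=n_sim, seed=seed, significance=significance
    )
    result.per_snp_p = per_snp_p
    result.outliers = outliers
    if not outliers:
        report.notes.append("global test significant but no individual outlier flagged")
        return report

    try:
        distortion_p, corrected = presso_distortion(
            pairs, outliers, n_boot=n_boot, seed=seed + 1, ivw_model=ivw_model
        )
        result.distortion_p = distortion_p
        result.corrected = corrected
    except DataError as exc:
        report.notes.append(f"distortion test unavailable: {exc}")
        return report

    keep = [p for p in pairs if p.rsid not in set(outliers)]
    second: dict[str, object] = {"ivw": ivw(keep, model=ivw_model)}
    second["heterogeneity"] = (
        cochran_q(keep, second["ivw"].estimate) if len(keep) >= 2 else None
    )
    if len(keep) >= 3:
        slope, intercept = egger(keep)
        second["egger"] = slope
        second["egger_intercept"] = intercept
        second["weighted_median"] = weighted_median(keep, n_boot=wm_n_boot, seed=seed + 2)
    else:
        report.notes.append(
            f"second pass: only {len(keep)} instruments remain; "
            "MR-Egger and weighted median skipped (minimum 3)"
        )
    report.second_pass = second
    return report
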