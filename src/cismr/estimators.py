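"""Causal-effect estimators and sensitivity statistics for two-sample MR.

All estimators consume harmonized pairs (per-SNP exposure and outcome
effects on a shared allele) and return estimates on the log-odds scale per
unit of exposure, with 95% CIs and the exponentiated odds-ratio scale.

* Wald ratio — beta_out / beta_exp per SNP, first-order delta-method SE.
* IVW — weighted regression of beta_out on beta_exp through the origin
  with weights 1/se_out²; the default multiplicative random-effects model
  inflates the SE by max(1, sqrt(Q/(J−1))).
* MR-Egger — the same weighted regression with an unconstrained intercept,
  after orienting every pair to beta_exp ≥ 0; a non-zero intercept signals
  directional pleiotropy. SEs use a residual scale floored at 1 and t(J−2)
  reference.
* Weighted median — consistent when valid instruments carry more than half
  the weight; SE by parametric bootstrap.
* Cochran's Q — heterogeneity of the per-SNP ratios about an estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import CismrError, DataError
from .harmonize import HarmonizedPair

DEFAULT_LEVEL = 0.95


@dataclass
class MrResult:
    """One method's causal estimate, on log-odds and odds-ratio scales."""

    method: str
    nsnp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_: float
    or_ci_low: float
    or_ci_high: float


@dataclass
class HeterogeneityResult:
    method: str
    Q: float
    df: int
    pvalue: float


@dataclass
class PleiotropyResult:
    """MR-Egger intercept: average directional pleiotropic effect."""

    intercept: float
    se: float
    pvalue: float


def to_odds_ratio(estimate: float, se: float, level: float = DEFAULT_LEVEL):
    """Exponentiate a log-odds estimate and its normal-theory CI."""
    if not (0.0 < level < 1.0):
        raise CismrError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        math.exp(estimate),
        math.exp(estimate - z * se),
        math.exp(estimate + z * se),
    )


def _result(method, nsnp, estimate, se, pvalue, level=DEFAULT_LEVEL) -> MrResult:
    z = stats.norm.ppf(0.5 + level / 2.0)
    or_, lo, hi = to_odds_ratio(estimate, se, level)
    return MrResult(
        method=method,
        nsnp=nsnp,
        estimate=estimate,
        se=se,
        ci_low=estimate - z * se,
        ci_high=estimate + z * se,
        pvalue=pvalue,
        or_=or_,
        or_ci_low=lo,
        or_ci_high=hi,
    )


def _arrays(pairs):
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, by, sx, sy


def wald_ratio(pair: HarmonizedPair) -> MrResult:
    """Single-SNP causal estimate: beta_out/beta_exp with first-order SE."""
    if pair.beta_exp == 0:
        raise DataError(f"{pair.rsid}: beta_exp = 0, Wald ratio undefined")
    est = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    p = 2.0 * stats.norm.sf(abs(est / se))
    return _result("wald_ratio", 1, est, se, p)


def ivw(pairs: list[HarmonizedPair], model: str = "multiplicative_random") -> MrResult:
    """Inverse-variance-weighted estimate (primary method).

    Weighted regression through the origin with weights 1/se_out². The
    single-pair case reduces exactly to the Wald ratio.
    """
    if not pairs:
        raise CismrError("ivw requires at least 1 pair")
    if model not in ("fixed", "multiplicative_random"):
        raise CismrError(f"unknown IVW model {model!r}")
    bx, by, _, sy = _arrays(pairs)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by)) / sxx
    se = math.sqrt(1.0 / sxx)
    if model == "multiplicative_random" and len(pairs) >= 2:
        q = float(np.sum(w * (by - est * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (len(pairs) - 1)))
    p = 2.0 * stats.norm.sf(abs(est / se))
    return _result("ivw", len(pairs), est, se, p)


def egger(pairs: list[HarmonizedPair]) -> tuple[MrResult, PleiotropyResult]:
    """MR-Egger: weighted regression with intercept, pairs oriented beta_exp ≥ 0.

    Slope is the pleiotropy-adjusted causal estimate (valid under InSIDE);
    intercept estimates the mean directional pleiotropic effect. Residual
    scale max(1, sqrt(RSS/(J−2))) multiplies both SEs; p-values use t(J−2).
    """
    j = len(pairs)
    if j < 3:
        raise CismrError("MR-Egger requires at least 3 instruments")
    bx, by, _, sy = _arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    # closed-form WLS for [intercept, slope]
    sw = w.sum()
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx * swx
    if det <= 0:
        raise DataError("degenerate design: no variation in exposure effects")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss / (j - 2)))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(swxx / det) * scale
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df=j - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df=j - 2)
    slope_res = _result("egger", j, slope, se_slope, p_slope)
    return slope_res, PleiotropyResult(intercept=intercept, se=se_int, pvalue=p_int)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, r))


def weighted_median(
    pairs: list[HarmonizedPair], n_boot: int = 1000, seed: int | None = None
) -> MrResult:
    """Weighted median of per-SNP Wald ratios.

    Weights are inverse first-order ratio variances (beta_exp²/se_out²);
    the point estimate interpolates where the cumulative standardized
    weight crosses 0.5. SE from a seeded parametric bootstrap.
    """
    j = len(pairs)
    if j < 3:
        raise CismrError("weighted median requires at least 3 instruments")
    if seed is None:
        raise CismrError("weighted_median requires an explicit seed")
    bx, by, sx, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise DataError("beta_exp = 0 among pairs; ratio undefined")
    ratios = by / bx
    weights = bx**2 / sy**2
    est = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(est / se))
    else:  # degenerate bootstrap (all replicates identical)
        p = 1.0 if est == 0.0 else float(np.finfo(float).tiny)
    return _result("weighted_median", j, est, se, p)


def cochran_q(
    pairs: list[HarmonizedPair],
    estimate: float,
    intercept: float = 0.0,
    method: str = "ivw",
) -> HeterogeneityResult:
    """Cochran's Q about an estimate; p > .05 indicates no heterogeneity.

    Q = Σ w_j (ratio_j − estimate)² with w_j = (beta_exp,j / se_out,j)²,
    df = J−1 for IVW. With ``method="egger"`` the residual includes the
    intercept (pairs oriented beta_exp ≥ 0) and df = J−2 (Rücker's Q').
    """
    j = len(pairs)
    min_n = 2 if method == "ivw" else 3
    if j < min_n:
        raise CismrError(f"cochran_q ({method}) requires at least {min_n} pairs")
    bx, by, _, sy = _arrays(pairs)
    if method == "egger":
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        df = j - 2
    elif method == "ivw":
        df = j - 1
    else:
        raise CismrError(f"unknown heterogeneity context {method!r}")
    q = float(np.sum((by - intercept - estimate * bx) ** 2 / sy**2))
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(method=method, Q=q, df=df, pvalue=max(p, np.finfo(float).tiny))


def leave_one_out(
    pairs: list[HarmonizedPair], model: str = "multiplicative_random"
) -> list[tuple[str, MrResult]]:
    """IVW re-estimated with each SNP omitted in turn, to spot driving SNPs."""
    if len(pairs) < 2:
        raise CismrError("leave-one-out requires at least 2 pairs")
    out = []
    for i, p in enumerate(pairs):
        rest = pairs[:i] + pairs[i + 1 :]
        out.append((p.rsid, ivw(rest, model=model)))
    return out


def flip_exposure_direction(res: MrResult) -> MrResult:
    """Negate an estimate (reciprocate ORs, swap CI bounds).

    Used to report effects in the exposure-lowering (inhibitor) direction.
    An involution: applying twice restores the original.
    """
    return replace(
        res,
        estimate=-res.estimate,
        ci_low=-res.ci_high,
        ci_high=-res.ci_low,
        or_=1.0 / res.or_,
        or_ci_low=1.0 / res.or_ci_high,
        or_ci_high=1.0 / res.or_ci_low,
    )
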