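"""Two-sample GWAS summary-statistic generator with known ground truth.

The generator emulates the statistical structure the estimators assume:
per-SNP true exposure effects gamma_j, a single causal effect theta on the
log-odds scale, optional pleiotropic effects alpha_j (balanced or
directional), planted outlier SNPs, and sampling noise consistent with the
standard-error formula se = 1/sqrt(2·maf·(1−maf)·N) for a standardized
trait. Exposure and outcome samples are independent (two-sample design).

Everything is a deterministic function of one master seed; sub-streams are
derived from it. Ground truth (gamma, alpha, theta, outliers, planted
allele orientations) is returned alongside the datasets so recovery and
detection tests can score against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import CismrError, DataError
from .sumstats import LdMatrix, SnpAssociation, SummaryDataset

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Knobs of the two-sample generator; defaults are the study conditions.

    Sample sizes default to the scale of the real exposure GWAS (~344k for
    HbA1c) and a large biobank outcome. ``gamma_sd`` sets the spread of
    true exposure effects; with ``orient_gamma_positive`` (default) effects
    are half-normal, matching the convention that the effect allele is the
    exposure-raising allele. Pleiotropy is none/balanced/directional with
    mean ``mu_alpha`` and SD ``sigma_alpha``; ``pleiotropy_frac`` < 1
    confines pleiotropy to a random subset whose weight share (gamma²) is
    kept below half, so the weighted-median breakdown condition holds.
    Outliers get alpha = ``outlier_scale`` × their outcome SE unless
    explicit ``outlier_alpha`` values are given.
    """

    n_snps: int = 15
    theta: float = 0.0
    n_exp: int = 300_000
    n_out: int = 200_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.05
    gamma_min: float = 0.0
    pleiotropy: str = "none"  # none | balanced | directional
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    pleiotropy_frac: float = 1.0
    outlier_idx: tuple[int, ...] = ()
    outlier_alpha: tuple[float, ...] | None = None
    outlier_scale: float = 10.0
    palindromic_rate: float = 0.2
    eaf_noise_sd: float = 0.0
    outcome_flip_rate: float = 0.0
    orient_gamma_positive: bool = True
    chrom: str = "16"
    pos_start: int = 30_600_000
    pos_step: int = 120_000
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise CismrError("n_snps must be >= 1")
        if self.gamma_sd < 0 or self.sigma_alpha < 0:
            raise CismrError("sd parameters must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise CismrError("maf_range must lie inside (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise CismrError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if not (0.0 < self.pleiotropy_frac <= 1.0):
            raise CismrError("pleiotropy_frac must be in (0, 1]")
        if any(i < 0 or i >= self.n_snps for i in self.outlier_idx):
            raise CismrError("outlier_idx out of range")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset pair."""

    gamma: np.ndarray
    alpha: np.ndarray
    theta: float
    outlier_idx: tuple[int, ...]
    pleiotropic_idx: tuple[int, ...] = ()
    flipped_outcome_idx: tuple[int, ...] = ()


def _pleiotropy_subset(rng, gamma: np.ndarray, frac: float) -> np.ndarray:
    """Random subset of ceil(frac·J) SNPs whose gamma² share stays below 0.5.

    Rejection-sampled (up to 200 tries, then the smallest-share draw) so a
    'minority of weight invalid' regime really is one.
    """
    j = len(gamma)
    k = math.ceil(frac * j)
    if k >= j:
        return np.arange(j)
    total = float(np.sum(gamma**2)) or 1.0
    best, best_share = None, np.inf
    for _ in range(200):
        idx = rng.choice(j, size=k, replace=False)
        share = float(np.sum(gamma[idx] ** 2)) / total
        if share < best_share:
            best, best_share = idx, share
        if share < 0.5:
            return np.sort(idx)
    return np.sort(best)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, SimulationTruth]:
    """Generate exposure and outcome summary datasets plus ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    j = config.n_snps

    maf = rng.uniform(*config.maf_range, size=j)
    if config.gamma_min > 0:
        # half-normal truncated below gamma_min: the analyzed instruments
        # of a real study have already passed a significance filter, so
        # near-null exposure effects never reach the estimators
        from scipy import stats as _st

        if config.gamma_sd <= 0:
            raise CismrError("gamma_min > 0 requires gamma_sd > 0")
        fmin = min(
            2.0 * _st.norm.cdf(config.gamma_min / config.gamma_sd) - 1.0,
            1.0 - 1e-12,  # keep the inverse CDF finite when gamma_min >> gamma_sd
        )
        u = rng.random(j)
        gamma = config.gamma_sd * _st.norm.ppf((1.0 + fmin + u * (1.0 - fmin)) / 2.0)
        if not config.orient_gamma_positive:
            gamma *= rng.choice([-1.0, 1.0], size=j)
    else:
        gamma = rng.normal(0.0, config.gamma_sd, size=j)
        if config.orient_gamma_positive:
            gamma = np.abs(gamma)

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out)

    alpha = np.zeros(j)
    pleio_idx: tuple[int, ...] = ()
    if config.pleiotropy != "none":
        idx = _pleiotropy_subset(rng, gamma, config.pleiotropy_frac)
        mean = 0.0 if config.pleiotropy == "balanced" else config.mu_alpha
        alpha[idx] = rng.normal(mean, config.sigma_alpha, size=len(idx))
        pleio_idx = tuple(int(i) for i in idx)
    if config.outlier_idx:
        if config.outlier_alpha is not None:
            if len(config.outlier_alpha) != len(config.outlier_idx):
                raise CismrError("outlier_alpha length must match outlier_idx")
            for i, a in zip(config.outlier_idx, config.outlier_alpha):
                alpha[i] = a
        else:
            for i in config.outlier_idx:
                alpha[i] = config.outlier_scale * se_out[i]

    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(config.theta * gamma + alpha, se_out)

    # allele assignment, shared between samples; outcome may be reported
    # with swapped alleles at outcome_flip_rate to exercise harmonization
    n_pal = int(round(config.palindromic_rate * j))
    is_pal = np.zeros(j, dtype=bool)
    if n_pal:
        is_pal[rng.choice(j, size=n_pal, replace=False)] = True
    alleles = [
        _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
        if is_pal[i]
        else _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        for i in range(j)
    ]
    flip = rng.random(j) < config.outcome_flip_rate
    flipped_idx = tuple(int(i) for i in np.where(flip)[0])

    eaf_out = maf.copy()
    if config.eaf_noise_sd > 0:
        eaf_out = np.clip(
            eaf_out + rng.normal(0.0, config.eaf_noise_sd, size=j), 1e-4, 1 - 1e-4
        )

    def pvalue(beta, se):
        from scipy import stats

        return float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))

    exp_records: dict[str, SnpAssociation] = {}
    out_records: dict[str, SnpAssociation] = {}
    for i in range(j):
        rsid = f"rs{1000 + i}"
        pos = config.pos_start + i * config.pos_step
        ea, oa = alleles[i]
        exp_records[rsid] = SnpAssociation(
            rsid=rsid, chrom=config.chrom, pos=pos,
            effect_allele=ea, other_allele=oa,
            eaf=float(maf[i]), beta=float(beta_exp[i]), se=float(se_exp[i]),
            pvalue=pvalue(beta_exp[i], se_exp[i]), n=config.n_exp,
        )
        if flip[i]:
            o_ea, o_oa = oa, ea
            o_beta, o_eaf = -float(beta_out[i]), 1.0 - float(eaf_out[i])
        else:
            o_ea, o_oa = ea, oa
            o_beta, o_eaf = float(beta_out[i]), float(eaf_out[i])
        out_records[rsid] = SnpAssociation(
            rsid=rsid, chrom=config.chrom, pos=pos,
            effect_allele=o_ea, other_allele=o_oa,
            eaf=o_eaf, beta=o_beta, se=float(se_out[i]),
            pvalue=pvalue(beta_out[i], se_out[i]), n=config.n_out,
        )

    exposure = SummaryDataset(trait="exposure", genome_build="GRCh37",
                              ancestry="EUR", records=exp_records)
    outcome = SummaryDataset(trait="outcome", genome_build="GRCh37",
                             ancestry="EUR", records=out_records)
    truth = SimulationTruth(
        gamma=gamma, alpha=alpha, theta=config.theta,
        outlier_idx=tuple(config.outlier_idx),
        pleiotropic_idx=pleio_idx, flipped_outcome_idx=flipped_idx,
    )
    return exposure, outcome, truth


def simulate_ld_block(
    rsids: list[str], block_size: int, rho: float
) -> LdMatrix:
    """Block-diagonal LD with within-block r² = rho^|i−j|; identity if rho=0."""
    if not (0.0 <= rho < 1.0):
        raise DataError("rho must be in [0, 1)")
    if block_size < 1:
        raise DataError("block_size must be >= 1")
    n = len(rsids)
    r2 = np.eye(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        for a in range(start, stop):
            for b in range(start, stop):
                r2[a, b] = rho ** abs(a - b)
    return LdMatrix(rsids=list(rsids), r2=r2)


#: Named regimes mirroring the analysis situations the pipeline must face.
_PRESETS: dict[str, SimulationConfig] = {
    # null causal effect, strong instruments, no pleiotropy
    "null": SimulationConfig(n_snps=15, theta=0.0, seed=0),
    # clear positive causal effect at the SGLT2-instrument scale (J=18)
    "causal_clean": SimulationConfig(n_snps=18, theta=0.5, seed=0),
    # directional pleiotropy on every SNP, InSIDE satisfied; instruments
    # carry a strength floor as a significance-filtered set would
    "directional_pleiotropy": SimulationConfig(
        n_snps=20, theta=0.5, pleiotropy="directional",
        mu_alpha=0.02, sigma_alpha=0.01, gamma_min=0.02, seed=0,
    ),
    # one heavily pleiotropic SNP among 10 (the outlier-removal workflow);
    # uniformly strong instruments and no palindromic loss, so the scenario
    # isolates outlier detection from harmonization attrition
    "single_outlier": SimulationConfig(
        n_snps=10, theta=0.5, outlier_idx=(4,), outlier_scale=10.0,
        gamma_min=0.05, gamma_sd=0.03, n_exp=344_182,
        palindromic_rate=0.0, seed=0,
    ),
    # small effects in a modest sample: F mostly below 10
    "weak_instruments": SimulationConfig(
        n_snps=10, theta=0.5, gamma_sd=0.004, n_exp=50_000, seed=0,
    ),
    # cis drug-target instrument scale: protective exposure-raising effect,
    # J inside the 8-18 range of real cis instrument sets, positions inside
    # a gene window on chr16
    # outcome sample size reflects a disease GWAS (tens of thousands
    # effective), so genuinely causal instruments are not wiped out by the
    # outcome-association exclusion rule
    "drug_target_cis": SimulationConfig(
        n_snps=12, theta=-0.5, gamma_sd=0.08, palindromic_rate=0.15,
        n_out=20_000, chrom="16", pos_start=30_600_000, pos_step=120_000,
        seed=0,
    ),
}


def scenario_preset(name: str, seed: int = 0) -> SimulationConfig:
    """A documented SimulationConfig for a named scenario."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise CismrError(
            f"unknown scenario {name!r}; known: {sorted(_PRESETS)}"
        ) from None
    return replace(base, seed=seed)


def preset_names() -> list[str]:
    return sorted(_PRESETS)
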