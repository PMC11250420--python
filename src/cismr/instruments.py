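"""Genetic instrument construction for drug-target and trait exposures.

Two modes mirror the study design:

* **cis** — SNPs within a flanked window around the drug target's encoding
  gene (e.g. SLC5A1 ± 500 kb, SLC5A2 ± 1000 kb), associated with the
  exposure biomarker below a significance threshold, LD-clumped at a
  permissive r² (default: discard when r² > 0.3 *and* within 100 kb).
* **genome_wide** — trait instruments anywhere in the genome except inside
  the drug-target windows, clumped far more strictly (r² > 0.001 within
  10,000 kb) because variants are drawn genome-wide rather than from one
  locus.

After window/significance/clump selection, candidates pass an exclusion
chain: MAF ≥ maf_min, instrument-strength F ≥ f_min, presence in the
outcome GWAS, and outcome p-value ≥ outcome_p_exclude (a SNP strongly
associated with the outcome itself would violate the exclusion
restriction). All thresholds use strict inequality on the *exclusion* side:
a SNP is removed when MAF < 0.01, F < 10, or outcome p < 5e-5.

Per-SNP variance explained uses
R² = (2·eaf·(1−eaf)·beta²) / (2·eaf·(1−eaf)·beta² + 2·eaf·(1−eaf)·N·se²),
which simplifies to beta²/(beta² + N·se²), and F = R²·(N−2)/(1−R²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigurationError, DataError, NoInstrumentsError
from .sumstats import LdMatrix, SnpAssociation, SummaryDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A gene span plus flank, defining a cis window on one chromosome.

    Coordinates are build-specific; they ship as editable config, not code.
    The window is closed: [start − flank, end + flank].
    """

    gene: str
    chrom: str
    start: int
    end: int
    flank_kb: int
    genome_build: str = "GRCh37"

    def __post_init__(self):
        if self.start >= self.end:
            raise ConfigurationError(f"{self.gene}: start must be < end")
        if self.flank_kb < 0:
            raise ConfigurationError(f"{self.gene}: flank_kb must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start - self.flank_kb * 1000, self.end + self.flank_kb * 1000)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return str(chrom) == str(self.chrom) and lo <= pos <= hi


@dataclass
class SelectionConfig:
    """All instrument-selection thresholds in one place.

    Defaults are the SGLT2/genome-wide-significance settings; cis analyses
    override per target (e.g. p 5e-7 for SLC5A1). ``clump_r2`` may be
    tightened to 0.1 as a sensitivity setting.
    """

    mode: str = "cis"  # "cis" | "genome_wide"
    p_threshold: float = 5e-8
    clump_r2: float = 0.3
    clump_window_kb: int = 100
    maf_min: float = 0.01
    f_min: float = 10.0
    outcome_p_exclude: float = 5e-5
    excluded_regions: tuple[GeneRegion, ...] = ()

    def __post_init__(self):
        if self.mode not in ("cis", "genome_wide"):
            raise ConfigurationError(f"unknown selection mode {self.mode!r}")
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ConfigurationError("clump_r2 must be in (0, 1]")
        if self.clump_window_kb <= 0 or self.maf_min < 0 or self.f_min < 0:
            raise ConfigurationError("thresholds must be positive")


@dataclass
class InstrumentSet:
    """Selected, strength-annotated exposure instruments.

    ``provenance`` is an ordered list of (filter_name, n_before, n_after)
    recording the whole chain; counts are non-increasing.
    """

    exposure: str
    snps: list[SnpAssociation]
    per_snp_r2: dict[str, float]
    per_snp_f: dict[str, float]
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]


def snp_variance_explained(eaf: float, beta: float, se: float, n: float) -> float:
    """Proportion of exposure variance explained by one SNP.

    Computes the allele-frequency form; the common factor 2·eaf·(1−eaf)
    cancels so the result equals beta²/(beta² + N·se²), in [0, 1).
    """
    if not (0.0 < eaf < 1.0):
        raise DataError("eaf must be strictly inside (0, 1)")
    if se <= 0:
        raise DataError("se must be > 0")
    if n <= 2:
        raise DataError("n must be > 2")
    het = 2.0 * eaf * (1.0 - eaf)
    num = het * beta * beta
    den = num + het * n * se * se
    return num / den


def snp_f_statistic(r2: float, n: float) -> float:
    """Single-instrument F statistic: F = R²·(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise DataError("r2 must be in [0, 1)")
    if n <= 2:
        raise DataError("n must be > 2")
    return r2 * (n - 2.0) / (1.0 - r2)


def select_cis_candidates(
    dataset: SummaryDataset, region: GeneRegion, p_threshold: float
) -> list[SnpAssociation]:
    """SNPs inside the (closed) cis window with p below threshold, by position."""
    if dataset.genome_build != region.genome_build:
        raise ConfigurationError(
            f"dataset build {dataset.genome_build} != region build {region.genome_build}"
        )
    hits = [
        s
        for s in dataset
        if region.contains(s.chrom, s.pos) and s.pvalue < p_threshold
    ]
    hits.sort(key=lambda s: (s.pos, s.rsid))
    return hits


def clump(
    candidates: list[SnpAssociation],
    ld: LdMatrix,
    r2_thresh: float,
    window_kb: int,
) -> list[SnpAssociation]:
    """Greedy LD clumping of candidates.

    Repeatedly keep the smallest-p remaining SNP (ties: smaller position,
    then rsid) and discard remaining SNPs that are BOTH in LD with it
    (r² > r2_thresh) and within window_kb on the same chromosome. Pairs
    absent from the LD matrix count as r² = 0, with a warning. Output is
    sorted by position. Idempotent and order-invariant.
    """
    if not candidates:
        return []
    missing = sorted({s.rsid for s in candidates if s.rsid not in ld})
    if missing:
        logger.warning(
            "clump: %d candidate SNP(s) absent from LD matrix, treated as unlinked: %s",
            len(missing),
            ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )
    remaining = sorted(candidates, key=lambda s: (s.pvalue, s.pos, s.rsid))
    kept: list[SnpAssociation] = []
    window_bp = window_kb * 1000
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for s in remaining:
            r2 = ld.r2_between(index.rsid, s.rsid)
            linked = (
                r2 is not None
                and r2 > r2_thresh
                and str(s.chrom) == str(index.chrom)
                and abs(s.pos - index.pos) <= window_bp
            )
            if not linked:
                survivors.append(s)
        remaining = survivors
    kept.sort(key=lambda s: (s.pos, s.rsid))
    return kept


def _annotate_strength(snp: SnpAssociation) -> tuple[float | None, float | None]:
    if snp.eaf is None or not (0.0 < snp.eaf < 1.0):
        return None, None
    r2 = snp_variance_explained(snp.eaf, snp.beta, snp.se, snp.n)
    return r2, snp_f_statistic(r2, snp.n)


def apply_exclusions(
    candidates: list[SnpAssociation],
    outcome: SummaryDataset,
    config: SelectionConfig,
    *,
    exposure: str = "exposure",
    provenance: list[tuple[str, int, int]] | None = None,
) -> InstrumentSet:
    """Apply the MAF / F / outcome-presence / outcome-p exclusion chain.

    A SNP without a usable exposure frequency cannot be MAF- or F-checked
    and is removed at the MAF step. Raises :class:`NoInstrumentsError`
    naming the first filter that emptied the set.
    """
    prov = list(provenance) if provenance else []
    current = list(candidates)
    r2_map: dict[str, float] = {}
    f_map: dict[str, float] = {}
    for s in current:
        r2, f = _annotate_strength(s)
        if r2 is not None:
            r2_map[s.rsid] = r2
            f_map[s.rsid] = f

    def step(name: str, predicate) -> None:
        nonlocal current
        before = len(current)
        current = [s for s in current if predicate(s)]
        prov.append((name, before, len(current)))
        if before > 0 and not current:
            raise NoInstrumentsError(
                f"{exposure}: no valid instruments (filter {name!r} removed all "
                f"{before} candidate(s))",
                filter_name=name,
            )

    step("maf", lambda s: s.maf is not None and not (s.maf < config.maf_min))
    step("f_stat", lambda s: not (f_map.get(s.rsid, 0.0) < config.f_min))
    step("in_outcome", lambda s: s.rsid in outcome)
    step(
        "outcome_p",
        lambda s: not (outcome.get(s.rsid).pvalue < config.outcome_p_exclude),
    )
    if not current:
        raise NoInstrumentsError(f"{exposure}: no candidate instruments supplied",
                                 filter_name=prov[0][0] if prov else None)
    return InstrumentSet(
        exposure=exposure,
        snps=current,
        per_snp_r2={s.rsid: r2_map[s.rsid] for s in current},
        per_snp_f={s.rsid: f_map[s.rsid] for s in current},
        provenance=prov,
    )


def select_cis(
    dataset: SummaryDataset,
    region: GeneRegion,
    outcome: SummaryDataset,
    config: SelectionConfig,
    ld: LdMatrix,
    *,
    exposure: str | None = None,
) -> InstrumentSet:
    """Full cis pipeline: window+significance -> clump -> exclusion chain."""
    name = exposure or region.gene
    prov: list[tuple[str, int, int]] = []
    cands = select_cis_candidates(dataset, region, config.p_threshold)
    prov.append(("window_and_p", len(dataset), len(cands)))
    if not cands:
        raise NoInstrumentsError(
            f"{name}: no SNPs in the cis window below p={config.p_threshold}",
            filter_name="window_and_p",
        )
    clumped = clump(cands, ld, config.clump_r2, config.clump_window_kb)
    prov.append(("clump", len(cands), len(clumped)))
    return apply_exclusions(clumped, outcome, config, exposure=name, provenance=prov)


def select_genome_wide(
    dataset: SummaryDataset,
    config: SelectionConfig,
    ld: LdMatrix,
    outcome: SummaryDataset,
    *,
    exposure: str = "genome_wide",
) -> InstrumentSet:
    """Genome-wide trait instruments excluding the drug-target cis windows."""
    if not config.excluded_regions:
        raise ConfigurationError(
            "genome-wide selection requires non-empty excluded_regions"
        )
    prov: list[tuple[str, int, int]] = []
    sig = [s for s in dataset if s.pvalue < config.p_threshold]
    sig.sort(key=lambda s: (s.chrom, s.pos, s.rsid))
    prov.append(("p_threshold", len(dataset), len(sig)))
    if not sig:
        raise NoInstrumentsError(
            f"{exposure}: no genome-wide significant SNPs", filter_name="p_threshold"
        )
    outside = [
        s
        for s in sig
        if not any(reg.contains(s.chrom, s.pos) for reg in config.excluded_regions)
    ]
    prov.append(("region_exclusion", len(sig), len(outside)))
    if not outside:
        raise NoInstrumentsError(
            f"{exposure}: all significant SNPs fall in excluded regions",
            filter_name="region_exclusion",
        )
    clumped = clump(outside, ld, config.clump_r2, config.clump_window_kb)
    prov.append(("clump", len(outside), len(clumped)))
    return apply_exclusions(clumped, outcome, config, exposure=exposure, provenance=prov)


def instrument_table(instruments: InstrumentSet):
    """Instrument report rows (rsid, alleles, eaf, beta, se, p, n, r2, F)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "rsid": s.rsid,
                "chrom": s.chrom,
                "pos": s.pos,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "eaf": s.eaf,
                "beta": s.beta,
                "se": s.se,
                "pvalue": s.pvalue,
                "n": s.n,
                "r2": instruments.per_snp_r2.get(s.rsid),
                "F": instruments.per_snp_f.get(s.rsid),
            }
            for s in instruments.snps
        ]
    )
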