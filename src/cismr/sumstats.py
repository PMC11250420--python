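"""Reading, validating and writing GWAS summary statistics and LD matrices.

Summary statistics arrive as delimited text with one row per SNP. Different
providers name their columns differently (IEU OpenGWAS, FinnGen, GWAS
Catalog); a *dialect* maps the canonical semantic columns onto a provider's
header. Everything downstream works on the normalized in-memory model:
:class:`SnpAssociation` rows collected in a :class:`SummaryDataset`.

LD is an input artifact here — a labelled square matrix of pairwise r²
(e.g. computed once from the 1000 Genomes European panel) — not something
this package derives from genotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Canonical column order for written summary statistics.
CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

#: Semantic columns that must be present. EAF is optional: some outcome GWAS
#: omit allele frequencies; affected palindromic SNPs are then dropped during
#: harmonization (conservative mode).
REQUIRED_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "BETA", "SE", "P", "N"]

#: Named dialect presets for the three source families used in this study
#: design, plus the package's own canonical layout. A user mapping
#: (dict canonical -> source column) is accepted anywhere a name is.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "ieu": {
        "SNP": "SNP",
        "CHR": "chr",
        "BP": "position",
        "EA": "effect_allele",
        "NEA": "other_allele",
        "EAF": "eaf",
        "BETA": "beta",
        "SE": "standard_error",
        "P": "p",
        "N": "n",
    },
    "finngen": {
        "SNP": "rsids",
        "CHR": "#chrom",
        "BP": "pos",
        "EA": "alt",
        "NEA": "ref",
        "EAF": "af_alt",
        "BETA": "beta",
        "SE": "sebeta",
        "P": "pval",
        "N": "n",
    },
    "gwas_catalog": {
        "SNP": "variant_id",
        "CHR": "chromosome",
        "BP": "base_pair_location",
        "EA": "effect_allele",
        "NEA": "other_allele",
        "EAF": "effect_allele_frequency",
        "BETA": "beta",
        "SE": "standard_error",
        "P": "p_value",
        "N": "n",
    },
}

_DNA = set("ACGT")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association for one trait.

    ``beta`` is the per-effect-allele effect: phenotype units for a
    quantitative trait (e.g. HbA1c), log-odds for a binary outcome.
    ``eaf`` may be ``None`` when the source GWAS does not report frequencies.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> None:
        if not self.rsid:
            raise DataError("empty rsid")
        if self.pos <= 0:
            raise DataError(f"{self.rsid}: pos must be > 0")
        for a in (self.effect_allele, self.other_allele):
            if not a or not set(a) <= _DNA:
                raise DataError(f"{self.rsid}: allele {a!r} is not a DNA string")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: identical alleles")
        if self.se <= 0 or not math.isfinite(self.se):
            raise DataError(f"{self.rsid}: se must be > 0")
        if not math.isfinite(self.beta):
            raise DataError(f"{self.rsid}: non-finite beta")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise DataError(f"{self.rsid}: eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise DataError(f"{self.rsid}: pvalue outside (0, 1]")
        if self.n <= 0:
            raise DataError(f"{self.rsid}: n must be > 0")

    @property
    def maf(self) -> float | None:
        """Minor allele frequency, min(eaf, 1-eaf); None when eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return (
            len(self.effect_allele) == 1
            and len(self.other_allele) == 1
            and comp.get(self.effect_allele) == self.other_allele
        )

    @property
    def is_snv(self) -> bool:
        """Single-nucleotide biallelic variant (not an indel / multi-char allele)."""
        return len(self.effect_allele) == 1 and len(self.other_allele) == 1


@dataclass
class SummaryDataset:
    """A validated GWAS summary-statistics dataset keyed by rsID.

    SNP matching across datasets is by rsID only, never by position, so a
    build mismatch between sources (e.g. FinnGen GRCh38 vs IEU GRCh37) is
    harmless; the build tag matters only for cis-window coordinates.
    """

    trait: str
    genome_build: str
    ancestry: str
    records: dict[str, SnpAssociation] = field(default_factory=dict)

    def __post_init__(self):
        if self.genome_build not in ("GRCh37", "GRCh38"):
            raise ConfigurationError(
                f"unknown genome build {self.genome_build!r} (GRCh37 or GRCh38)"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __iter__(self):
        return iter(self.records.values())

    def get(self, rsid: str) -> SnpAssociation | None:
        return self.records.get(rsid)


@dataclass
class LdMatrix:
    """Pairwise r² between SNPs, symmetric with unit diagonal.

    A plain-text stand-in for reference-panel LD. Pairs absent from the
    matrix are treated as unlinked (r² = 0) by consumers, with a warning.
    """

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise DataError("LD matrix shape does not match label count")
        if len(set(self.rsids)) != n:
            raise DataError("duplicate rsids in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise DataError("LD matrix is not symmetric (tolerance 1e-8)")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal is not 1")
        if self.r2.min() < -1e-9 or self.r2.max() > 1.0 + 1e-9:
            raise DataError("LD r² entries outside [0, 1]")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r2_between(self, a: str, b: str) -> float | None:
        """r² for a pair, or None when either SNP is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def _resolve_dialect(dialect: str | dict[str, str]) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    missing = [c for c in REQUIRED_COLUMNS if c not in dialect]
    if missing:
        raise ConfigurationError(f"dialect mapping lacks semantic columns {missing}")
    return dict(dialect)


def read_sumstats(
    path,
    dialect: str | dict[str, str] = "canonical",
    *,
    trait: str = "trait",
    genome_build: str = "GRCh37",
    ancestry: str = "EUR",
) -> SummaryDataset:
    """Read delimited summary statistics into a validated :class:`SummaryDataset`.

    Rows failing type coercion or the per-SNP invariants are dropped with a
    logged count; duplicate rsIDs keep the first occurrence. Raises
    :class:`ConfigurationError` if a required column is absent and
    :class:`DataError` if no valid rows remain.
    """
    mapping = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if mapping[c] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {[mapping[c] for c in missing]}"
        )
    has_eaf = "EAF" in mapping and mapping["EAF"] in df.columns

    records: dict[str, SnpAssociation] = {}
    n_dropped = 0
    n_dup = 0
    for d in df.to_dict("records"):
        try:
            eaf_raw = d[mapping["EAF"]] if has_eaf else None
            eaf = None if eaf_raw in (None, "", "NA") or pd.isna(eaf_raw) else float(eaf_raw)
            rec = SnpAssociation(
                rsid=str(d[mapping["SNP"]]),
                chrom=str(d[mapping["CHR"]]),
                pos=int(float(d[mapping["BP"]])),
                effect_allele=str(d[mapping["EA"]]).upper(),
                other_allele=str(d[mapping["NEA"]]).upper(),
                eaf=eaf,
                beta=float(d[mapping["BETA"]]),
                se=float(d[mapping["SE"]]),
                pvalue=float(d[mapping["P"]]),
                n=int(float(d[mapping["N"]])),
            )
            rec.validate()
        except (DataError, ValueError, TypeError):
            n_dropped += 1
            continue
        if rec.rsid in records:
            n_dup += 1
            continue
        records[rec.rsid] = rec

    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    if n_dup:
        logger.warning("%s: dropped %d duplicate rsid row(s)", path, n_dup)
    if not records:
        raise DataError(f"{path}: no valid summary-statistic rows")
    return SummaryDataset(trait=trait, genome_build=genome_build, ancestry=ancestry, records=records)


def write_sumstats(dataset: SummaryDataset, path) -> str:
    """Write a dataset in canonical column order, tab-delimited.

    Refuses to write an empty dataset. ``read_sumstats(write_sumstats(d))``
    reproduces ``d``'s records exactly (floats round-trip via repr).
    """
    if len(dataset) == 0:
        raise DataError("refusing to write a dataset with no records")
    rows = [
        {
            "SNP": r.rsid,
            "CHR": r.chrom,
            "BP": r.pos,
            "EA": r.effect_allele,
            "NEA": r.other_allele,
            "EAF": "NA" if r.eaf is None else repr(r.eaf),
            "BETA": repr(r.beta),
            "SE": repr(r.se),
            "P": repr(r.pvalue),
            "N": r.n,
        }
        for r in dataset
    ]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)
    return str(path)


def read_ld_matrix(path) -> LdMatrix:
    """Read a labelled square r² matrix (rsID row and column labels)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if list(df.index) != list(df.columns):
        raise DataError(f"{path}: LD row and column labels differ")
    return LdMatrix(rsids=[str(r) for r in df.index], r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path) -> str:
    df = pd.DataFrame(ld.r2, index=ld.rsids, columns=ld.rsids)
    df.to_csv(path, sep="\t", float_format="%.12g")
    return str(path)


def subset_dataset(dataset: SummaryDataset, rsids) -> SummaryDataset:
    """A copy of the dataset restricted to the given rsIDs (order-preserving)."""
    recs = {r: dataset.records[r] for r in rsids if r in dataset.records}
    return replace(dataset, records=recs)
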