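"""Two-sample harmonization: align exposure and outcome effects on one allele.

The exposure and outcome GWAS may report a SNP with respect to different
effect alleles, or on opposite strands. Harmonization puts the outcome
effect on the exposure's effect allele:

* identical allele pair -> keep as-is;
* swapped alleles -> negate the outcome beta and complement its frequency;
* strand-complement alleles -> relabel to the exposure strand, then align;
* palindromic SNPs (A/T, C/G) are strand-ambiguous: in conservative mode
  orientation is inferred from allele frequencies when both sides sit
  outside the ambiguity band (default EAF in [0.42, 0.58] -> drop);
  permissive mode assumes both GWAS report the same strand;
* indels / multi-character alleles and irreconcilable pairs are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import CismrError, NoInstrumentsError
from .instruments import InstrumentSet
from .sumstats import SnpAssociation, SummaryDataset

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: action_taken values
NONE = "none"
FLIP = "flip"
STRAND_FLIP = "strand_flip"
DROPPED_AMBIGUOUS = "dropped_ambiguous"
DROPPED_INCOMPATIBLE = "dropped_incompatible"

DEFAULT_AMBIGUITY_BAND = (0.42, 0.58)


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    palindromic: bool
    action: str

    @property
    def dropped(self) -> bool:
        return self.action in (DROPPED_AMBIGUOUS, DROPPED_INCOMPATIBLE)


def _dropped(exp: SnpAssociation, out: SnpAssociation, action: str) -> HarmonizedPair:
    return HarmonizedPair(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=out.beta,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=out.eaf,
        palindromic=exp.is_palindromic,
        action=action,
    )


def harmonize_pair(
    exp: SnpAssociation,
    out: SnpAssociation,
    mode: str = "conservative",
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
) -> HarmonizedPair:
    """Align one outcome record onto the exposure record's effect allele."""
    if exp.rsid != out.rsid:
        raise CismrError(f"rsid mismatch: {exp.rsid} vs {out.rsid}")
    if mode not in ("conservative", "permissive"):
        raise CismrError(f"unknown harmonization mode {mode!r}")
    if not exp.is_snv or not out.is_snv:
        return _dropped(exp, out, DROPPED_INCOMPATIBLE)

    a1, a2 = exp.effect_allele, exp.other_allele
    b1, b2 = out.effect_allele, out.other_allele
    beta_out, eaf_out = out.beta, out.eaf
    palindromic = exp.is_palindromic

    if (b1, b2) == (a1, a2):
        action = NONE
    elif (b1, b2) == (a2, a1):
        action = FLIP
        beta_out = -beta_out
        eaf_out = None if eaf_out is None else 1.0 - eaf_out
    else:
        c1, c2 = _COMPLEMENT[b1], _COMPLEMENT[b2]
        if (c1, c2) == (a1, a2):
            action = STRAND_FLIP
        elif (c1, c2) == (a2, a1):
            action = STRAND_FLIP
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        else:
            return _dropped(exp, out, DROPPED_INCOMPATIBLE)

    if palindromic and mode == "conservative":
        # Allele labels cannot distinguish a swapped report from an
        # opposite-strand report; fall back to frequency agreement.
        lo, hi = ambiguity_band
        if exp.eaf is None or eaf_out is None:
            return _dropped(exp, out, DROPPED_AMBIGUOUS)
        if lo <= exp.eaf <= hi or lo <= eaf_out <= hi:
            return _dropped(exp, out, DROPPED_AMBIGUOUS)
        if (exp.eaf < 0.5) != (eaf_out < 0.5):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = NONE if action == FLIP else FLIP

    return HarmonizedPair(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        palindromic=palindromic,
        action=action,
    )


def harmonize_set(
    instruments: InstrumentSet,
    outcome: SummaryDataset,
    mode: str = "conservative",
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
) -> tuple[list[HarmonizedPair], list[dict]]:
    """Harmonize every instrument against the outcome dataset.

    Returns surviving pairs in instrument order plus a per-SNP log
    (rsid, action, reason). Instruments absent from the outcome are logged
    and skipped (selection normally guarantees presence). Raises
    :class:`NoInstrumentsError` when nothing survives.
    """
    if len(instruments) == 0:
        raise NoInstrumentsError("empty instrument set")
    pairs: list[HarmonizedPair] = []
    log: list[dict] = []
    for snp in instruments.snps:
        out = outcome.get(snp.rsid)
        if out is None:
            log.append({"rsid": snp.rsid, "action": "absent", "reason": "not in outcome GWAS"})
            continue
        pair = harmonize_pair(snp, out, mode=mode, ambiguity_band=ambiguity_band)
        if pair.dropped:
            reason = (
                "palindromic, frequency uninformative"
                if pair.action == DROPPED_AMBIGUOUS
                else "incompatible alleles or indel"
            )
            log.append({"rsid": snp.rsid, "action": pair.action, "reason": reason})
            continue
        log.append({"rsid": snp.rsid, "action": pair.action, "reason": ""})
        pairs.append(pair)
    n_dropped = len(instruments) - len(pairs)
    if n_dropped:
        logger.info("harmonize_set: dropped %d of %d instruments", n_dropped, len(instruments))
    if not pairs:
        raise NoInstrumentsError("no valid instruments after harmonization")
    return pairs, log
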