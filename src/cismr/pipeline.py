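"""Study orchestration: selection -> harmonization -> estimation -> sensitivity.

One :class:`StudyConfig` describes every exposure (cis drug-target proxy or
genome-wide trait instrument) and every outcome; :func:`run_study` runs the
full battery for each exposure × outcome pair and collects an
:class:`AnalysisReport`. A failure in one pair (e.g. no surviving
instruments) is recorded as a structured reason and never aborts the rest.

Reported odds ratios follow a sign convention: effects are estimated
natively in the exposure-raising direction and flipped at reporting time
when the convention is ``lowering``, so that a drug-target analysis reads
in the inhibitor (biomarker-lowering) direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CismrError, ConfigurationError, DataError, NoInstrumentsError
from .estimators import (
    HeterogeneityResult,
    MrResult,
    PleiotropyResult,
    cochran_q,
    egger,
    flip_exposure_direction,
    ivw,
    leave_one_out,
    weighted_median,
)
from .harmonize import harmonize_set
from .instruments import (
    GeneRegion,
    InstrumentSet,
    SelectionConfig,
    select_cis,
    select_genome_wide,
)
from .presso import MIN_SNPS as PRESSO_MIN_SNPS
from .presso import PressoReport, run_presso_and_refit
from .sumstats import LdMatrix, SummaryDataset, read_ld_matrix, read_sumstats

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure", "outcome", "pass", "method", "nsnp", "estimate", "se",
    "ci_low", "ci_high", "pvalue", "or", "or_ci_low", "or_ci_high",
]


@dataclass
class SignConvention:
    """Direction in which exposure effects are reported."""

    exposure_direction: str = "lowering"  # "raising" | "lowering"

    def __post_init__(self):
        if self.exposure_direction not in ("raising", "lowering"):
            raise ConfigurationError(
                f"unknown exposure_direction {self.exposure_direction!r}"
            )


@dataclass
class ExposureSpec:
    name: str
    sumstats: object  # path or SummaryDataset
    selection: SelectionConfig
    region: GeneRegion | None = None
    dialect: str | dict = "canonical"

    def __post_init__(self):
        if self.selection.mode == "cis" and self.region is None:
            raise ConfigurationError(f"exposure {self.name}: cis mode needs a region")
        if self.selection.mode == "genome_wide" and not self.selection.excluded_regions:
            raise ConfigurationError(
                f"exposure {self.name}: genome-wide mode needs excluded_regions"
            )


@dataclass
class OutcomeSpec:
    name: str
    sumstats: object
    dialect: str | dict = "canonical"
    positive_control: bool = False


@dataclass
class StudyConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    ld_matrix: object  # path or LdMatrix
    seed: int = 0
    ivw_model: str = "multiplicative_random"
    wm_n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_n_boot: int = 1000
    presso_significance: float = 0.05
    harmonize_mode: str = "conservative"
    sign_convention: SignConvention = field(default_factory=SignConvention)

    def __post_init__(self):
        names = [e.name for e in self.exposures]
        if len(set(names)) != len(names):
            raise ConfigurationError("exposure names must be unique")
        names = [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("outcome names must be unique")
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")


@dataclass
class PairAnalysis:
    """Everything computed for one exposure × outcome pair."""

    exposure: str
    outcome: str
    status: str = "ok"  # "ok" | "failed"
    reason: str = ""
    positive_control: bool = False
    instruments: InstrumentSet | None = None
    harmonization_log: list[dict] = field(default_factory=list)
    results: list[MrResult] = field(default_factory=list)
    heterogeneity: HeterogeneityResult | None = None
    pleiotropy: PleiotropyResult | None = None
    presso: PressoReport | None = None
    leave_one_out: list[tuple[str, MrResult]] = field(default_factory=list)
    second_pass: list[MrResult] = field(default_factory=list)
    second_pass_heterogeneity: HeterogeneityResult | None = None
    second_pass_pleiotropy: PleiotropyResult | None = None


@dataclass
class AnalysisReport:
    pairs: list[PairAnalysis]
    seed: int
    convention: SignConvention

    def get(self, exposure: str, outcome: str) -> PairAnalysis | None:
        for p in self.pairs:
            if p.exposure == exposure and p.outcome == outcome:
                return p
        return None


def apply_sign_convention(
    results: list[MrResult], convention: SignConvention
) -> list[MrResult]:
    """Flip estimates into the reported direction (no-op for 'raising')."""
    if convention.exposure_direction == "raising":
        return list(results)
    return [flip_exposure_direction(r) for r in results]


def _subseed(master: int, k: int) -> int:
    # stable derived seed, kept below 2**31
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


def _load_dataset(source, dialect, trait) -> SummaryDataset:
    if isinstance(source, SummaryDataset):
        return source
    return read_sumstats(source, dialect, trait=trait)


def _analyze_pair(
    exp_spec: ExposureSpec,
    out_spec: OutcomeSpec,
    exposure_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    ld: LdMatrix,
    config: StudyConfig,
    seed: int,
) -> PairAnalysis:
    pa = PairAnalysis(
        exposure=exp_spec.name,
        outcome=out_spec.name,
        positive_control=out_spec.positive_control,
    )
    sel = exp_spec.selection
    if sel.mode == "cis":
        inst = select_cis(exposure_ds, exp_spec.region, outcome_ds, sel, ld,
                          exposure=exp_spec.name)
    else:
        inst = select_genome_wide(exposure_ds, sel, ld, outcome_ds,
                                  exposure=exp_spec.name)
    pa.instruments = inst
    pairs, log = harmonize_set(inst, outcome_ds, mode=config.harmonize_mode)
    pa.harmonization_log = log

    raw: list[MrResult] = [ivw(pairs, model=config.ivw_model)]
    ivw_est = raw[0].estimate
    if len(pairs) >= 3:
        slope, intercept = egger(pairs)
        raw.append(slope)
        raw.append(weighted_median(pairs, n_boot=config.wm_n_boot, seed=seed))
        pa.pleiotropy = intercept
    if len(pairs) >= 2:
        pa.heterogeneity = cochran_q(pairs, ivw_est)
        pa.leave_one_out = [
            (rsid, r) for rsid, r in leave_one_out(pairs, model=config.ivw_model)
        ]
    if len(pairs) >= PRESSO_MIN_SNPS:
        pa.presso = run_presso_and_refit(
            pairs,
            n_sim=config.presso_n_sim,
            n_boot=config.presso_n_boot,
            seed=seed + 1,
            significance=config.presso_significance,
            ivw_model=config.ivw_model,
            wm_n_boot=config.wm_n_boot,
        )

    conv = config.sign_convention
    pa.results = apply_sign_convention(raw, conv)
    pa.leave_one_out = [
        (rsid, apply_sign_convention([r], conv)[0]) for rsid, r in pa.leave_one_out
    ]
    if conv.exposure_direction == "lowering" and pa.pleiotropy is not None:
        pa.pleiotropy = replace(pa.pleiotropy, intercept=-pa.pleiotropy.intercept)
    if pa.presso is not None and pa.presso.second_pass:
        sp = pa.presso.second_pass
        methods = [sp[k] for k in ("ivw", "egger", "weighted_median") if k in sp]
        pa.second_pass = apply_sign_convention(methods, conv)
        pa.second_pass_heterogeneity = sp.get("heterogeneity")
        ip = sp.get("egger_intercept")
        if ip is not None and conv.exposure_direction == "lowering":
            ip = replace(ip, intercept=-ip.intercept)
        pa.second_pass_pleiotropy = ip
        if pa.presso.presso.corrected is not None:
            pa.presso.presso.corrected = apply_sign_convention(
                [pa.presso.presso.corrected], conv
            )[0]
    return pa


def run_study(config: StudyConfig) -> AnalysisReport:
    """Run every exposure × outcome pair; failures are recorded, not fatal."""
    ld = (
        config.ld_matrix
        if isinstance(config.ld_matrix, LdMatrix)
        else read_ld_matrix(config.ld_matrix)
    )
    exposures = {
        e.name: _load_dataset(e.sumstats, e.dialect, e.name) for e in config.exposures
    }
    outcomes = {
        o.name: _load_dataset(o.sumstats, o.dialect, o.name) for o in config.outcomes
    }
    report = AnalysisReport(pairs=[], seed=config.seed, convention=config.sign_convention)
    k = 0
    for exp_spec in config.exposures:
        for out_spec in config.outcomes:
            seed = _subseed(config.seed, k)
            k += 1
            try:
                pa = _analyze_pair(
                    exp_spec, out_spec, exposures[exp_spec.name],
                    outcomes[out_spec.name], ld, config, seed,
                )
            except (NoInstrumentsError, DataError, CismrError) as exc:
                logger.warning("%s x %s failed: %s", exp_spec.name, out_spec.name, exc)
                pa = PairAnalysis(
                    exposure=exp_spec.name, outcome=out_spec.name,
                    status="failed", reason=str(exc),
                    positive_control=out_spec.positive_control,
                )
            report.pairs.append(pa)
    return report


# ---------------------------------------------------------------------------
# report rendering


def _result_row(pa: PairAnalysis, passno: int, r: MrResult) -> dict:
    return {
        "exposure": pa.exposure, "outcome": pa.outcome, "pass": passno,
        "method": r.method, "nsnp": r.nsnp,
        "estimate": r.estimate, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "pvalue": r.pvalue,
        "or": r.or_, "or_ci_low": r.or_ci_low, "or_ci_high": r.or_ci_high,
    }


def report_frames(report: AnalysisReport) -> dict[str, pd.DataFrame]:
    """The report as a dict of tidy DataFrames (one per output table)."""
    results, sensitivity, presso_rows, loo_rows, failures = [], [], [], [], []
    for pa in report.pairs:
        if pa.status != "ok":
            failures.append(
                {"exposure": pa.exposure, "outcome": pa.outcome, "reason": pa.reason}
            )
            continue
        for r in pa.results:
            results.append(_result_row(pa, 1, r))
        for r in pa.second_pass:
            results.append(_result_row(pa, 2, r))
        sens = {
            "exposure": pa.exposure, "outcome": pa.outcome,
            "q": pa.heterogeneity.Q if pa.heterogeneity else np.nan,
            "q_df": pa.heterogeneity.df if pa.heterogeneity else np.nan,
            "q_pvalue": pa.heterogeneity.pvalue if pa.heterogeneity else np.nan,
            "egger_intercept": pa.pleiotropy.intercept if pa.pleiotropy else np.nan,
            "egger_intercept_se": pa.pleiotropy.se if pa.pleiotropy else np.nan,
            "egger_intercept_pvalue": pa.pleiotropy.pvalue if pa.pleiotropy else np.nan,
            "positive_control": pa.positive_control,
        }
        sensitivity.append(sens)
        if pa.presso is not None:
            pr = pa.presso.presso
            presso_rows.append({
                "exposure": pa.exposure, "outcome": pa.outcome,
                "rss_obs": pr.rss_obs, "global_p": pr.global_p,
                "n_sim": pr.n_sim,
                "outliers": ";".join(pr.outliers),
                "distortion_p": pr.distortion_p if pr.distortion_p is not None else np.nan,
                "corrected_estimate": pr.corrected.estimate if pr.corrected else np.nan,
                "corrected_or": pr.corrected.or_ if pr.corrected else np.nan,
                "notes": "; ".join(pa.presso.notes),
            })
        for rsid, r in pa.leave_one_out:
            row = _result_row(pa, 1, r)
            row["omitted"] = rsid
            loo_rows.append(row)
    sens_cols = ["exposure", "outcome", "q", "q_df", "q_pvalue",
                 "egger_intercept", "egger_intercept_se",
                 "egger_intercept_pvalue", "positive_control"]
    presso_cols = ["exposure", "outcome", "rss_obs", "global_p", "n_sim",
                   "outliers", "distortion_p", "corrected_estimate",
                   "corrected_or", "notes"]
    return {
        "results": pd.DataFrame(results, columns=RESULT_COLUMNS),
        "sensitivity": pd.DataFrame(sensitivity, columns=sens_cols),
        "presso": pd.DataFrame(presso_rows, columns=presso_cols),
        "leave_one_out": pd.DataFrame(loo_rows, columns=RESULT_COLUMNS + ["omitted"]),
        "failures": pd.DataFrame(failures, columns=["exposure", "outcome", "reason"]),
    }


def render_report(report: AnalysisReport, outdir) -> dict[str, str]:
    """Write results/sensitivity/presso/leave-one-out TSVs plus a run log.

    Output is deterministic: identical report -> byte-identical files.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    frames = report_frames(report)
    paths = {}
    for name, df in frames.items():
        path = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name] = path
    logpath = os.path.join(outdir, "run.log")
    with open(logpath, "w") as fh:
        fh.write(f"cismr {__version__}\n")
        fh.write(f"numpy {np.__version__}\npandas {pd.__version__}\n")
        fh.write(f"seed {report.seed}\n")
        fh.write(f"sign_convention {report.convention.exposure_direction}\n")
    paths["log"] = logpath
    return paths


def load_report_frames(outdir) -> dict[str, pd.DataFrame]:
    """Read back the tables written by :func:`render_report`."""
    import os

    frames = {}
    for name in ("results", "sensitivity", "presso", "leave_one_out", "failures"):
        path = os.path.join(outdir, f"{name}.tsv")
        if os.path.exists(path):
            frames[name] = pd.read_csv(path, sep="\t")
    return frames


# ---------------------------------------------------------------------------
# YAML study config


def _region_from_dict(d: dict) -> GeneRegion:
    try:
        return GeneRegion(
            gene=d["gene"], chrom=str(d["chrom"]), start=int(d["start"]),
            end=int(d["end"]), flank_kb=int(d["flank_kb"]),
            genome_build=d.get("genome_build", "GRCh37"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"region config missing key {exc}") from None


def _selection_from_dict(d: dict, regions: list[GeneRegion]) -> SelectionConfig:
    return SelectionConfig(
        mode=d.get("mode", "cis"),
        p_threshold=float(d.get("p_threshold", 5e-8)),
        clump_r2=float(d.get("clump_r2", 0.3)),
        clump_window_kb=int(d.get("clump_window_kb", 100)),
        maf_min=float(d.get("maf_min", 0.01)),
        f_min=float(d.get("f_min", 10.0)),
        outcome_p_exclude=float(d.get("outcome_p_exclude", 5e-5)),
        excluded_regions=tuple(regions),
    )


def load_study_config(path) -> StudyConfig:
    """Parse a YAML study config; schema violations raise before any compute."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: study config must be a mapping")
    try:
        exposures = []
        for e in raw["exposures"]:
            region = _region_from_dict(e["region"]) if "region" in e else None
            excluded = [_region_from_dict(r) for r in e.get("excluded_regions", [])]
            sel = _selection_from_dict(e.get("selection", {}), excluded)
            exposures.append(
                ExposureSpec(
                    name=e["name"], sumstats=e["sumstats"],
                    selection=sel, region=region,
                    dialect=e.get("dialect", "canonical"),
                )
            )
        outcomes = [
            OutcomeSpec(
                name=o["name"], sumstats=o["sumstats"],
                dialect=o.get("dialect", "canonical"),
                positive_control=bool(o.get("positive_control", False)),
            )
            for o in raw["outcomes"]
        ]
        return StudyConfig(
            exposures=exposures,
            outcomes=outcomes,
            ld_matrix=raw["ld_matrix"],
            seed=int(raw.get("seed", 0)),
            ivw_model=raw.get("ivw_model", "multiplicative_random"),
            wm_n_boot=int(raw.get("wm_n_boot", 1000)),
            presso_n_sim=int(raw.get("presso_n_sim", 1000)),
            presso_n_boot=int(raw.get("presso_n_boot", 1000)),
            presso_significance=float(raw.get("presso_significance", 0.05)),
            harmonize_mode=raw.get("harmonize_mode", "conservative"),
            sign_convention=SignConvention(raw.get("sign_convention", "lowering")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: invalid study config ({exc})") from exc
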