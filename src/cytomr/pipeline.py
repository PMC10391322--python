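"""Orchestration of the full exposure-by-outcome MR grid.

For every exposure the pipeline selects instruments (genome-wide threshold
with a relaxed fallback, LD clumping), and for every outcome it extracts the
instrument associations (substituting high-LD proxies for variants the
outcome GWAS lacks), harmonises alleles, and runs the estimator battery:
Wald ratio or IVW always; MR-Egger, weighted median, Cochran's Q and
leave-one-out when at least three variants survive. A cis variant of the
grid restricts each exposure's instruments to the locus of its encoding
gene first. Every relaxation, proxy substitution, drop and infeasible
method is recorded as a machine-readable flag.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .gwas_io import (
    HarmonisedSet,
    SummaryStatRecord,
    harmonise,
    read_summary_stats,
    write_results_table,
)
from .instruments import (
    DEFAULT_CIS_FLANK_KB,
    DEFAULT_CLUMP_KB,
    DEFAULT_CLUMP_R2,
    DEFAULT_PROXY_R2,
    GENOME_WIDE_P,
    RELAXED_P,
    GeneAnnotation,
    InstrumentSet,
    LDMatrix,
    cis_filter,
    find_proxy,
    select_instruments,
)

logger = logging.getLogger(__name__)

#: outcome scales; "score" outcomes are linear but reported both ways
OUTCOME_TYPES = ("binary", "continuous", "score")


@dataclass
class GridOptions:
    """All thresholds and switches of the grid analysis, with field defaults."""

    primary_p: float = GENOME_WIDE_P
    fallback_p: float = RELAXED_P
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_kb: float = DEFAULT_CLUMP_KB
    proxy_r2: float = DEFAULT_PROXY_R2
    cis_flank_kb: float = DEFAULT_CIS_FLANK_KB
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)
    drop_palindromic_ambiguous: bool = True
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0


SourceT = Sequence[SummaryStatRecord] | str | Path


@dataclass
class AnalysisGrid:
    """Named exposure and outcome sources plus shared LD and options.

    Sources may be in-memory record sequences or paths to summary tables;
    outcome sources are (source, outcome_type) with outcome_type one of
    ``binary``, ``continuous``, ``score``.
    """

    exposures: Mapping[str, SourceT]
    outcomes: Mapping[str, tuple[SourceT, str]]
    ld: LDMatrix | str | Path
    options: GridOptions = field(default_factory=GridOptions)
    cis_annotations: Mapping[str, GeneAnnotation] | None = None

    def __post_init__(self) -> None:
        for name, (_, otype) in self.outcomes.items():
            if otype not in OUTCOME_TYPES:
                raise ValueError(f"outcome {name!r}: unknown outcome_type {otype!r}")
        for name, src in self.exposures.items():
            if isinstance(src, (str, Path)) and not Path(src).exists():
                raise FileNotFoundError(f"exposure {name!r}: no such file {src}")
        for name, (src, _) in self.outcomes.items():
            if isinstance(src, (str, Path)) and not Path(src).exists():
                raise FileNotFoundError(f"outcome {name!r}: no such file {src}")

    @classmethod
    def from_config(cls, path: str | Path) -> "AnalysisGrid":
        """Build a grid from a YAML config (paths resolved relative to it)."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        exposures = {name: resolve(src) for name, src in raw["exposures"].items()}
        outcomes = {
            name: (resolve(spec["path"]), spec.get("outcome_type", "binary"))
            for name, spec in raw["outcomes"].items()
        }
        options = GridOptions(**raw.get("options", {}))
        cis = None
        if "cis_annotations" in raw:
            cis = {
                name: GeneAnnotation(
                    gene_symbol=spec.get("gene_symbol", name),
                    chrom=str(spec["chrom"]),
                    start=int(spec["start"]),
                    end=int(spec["end"]),
                )
                for name, spec in raw["cis_annotations"].items()
            }
        return cls(
            exposures=exposures,
            outcomes=outcomes,
            ld=resolve(raw["ld"]),
            options=options,
            cis_annotations=cis,
        )


@dataclass
class GridResult:
    """Estimates, per-pair flags and leave-one-out traces for a whole grid."""

    rows: list[est.MREstimate] = field(default_factory=list)
    flags: list[dict] = field(default_factory=list)
    leave_one_out: dict[tuple[str, str], list[est.LeaveOneOutResult]] = field(
        default_factory=dict
    )

    def flag(self, exposure: str, outcome: str | None, kind: str, detail: str = "") -> None:
        self.flags.append(
            {"exposure": exposure, "outcome": outcome or "", "flag": kind, "detail": detail}
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])

    def flags_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, columns=["exposure", "outcome", "flag", "detail"])

    def write(self, path: str | Path) -> Path:
        return write_results_table(self.rows, path)


def _load_records(src: SourceT) -> list[SummaryStatRecord]:
    if isinstance(src, (str, Path)):
        return read_summary_stats(src)
    return list(src)


def _load_ld(ld: LDMatrix | str | Path) -> LDMatrix:
    if isinstance(ld, LDMatrix):
        return ld
    return LDMatrix.from_square_file(ld)


def _pair_seed(exposure: str, outcome: str, base_seed: int) -> int:
    """Deterministic per-pair bootstrap seed, independent of grid order."""
    return (zlib.crc32(f"{exposure}|{outcome}|{base_seed}".encode()) & 0x7FFFFFFF) or 1


def run_grid(grid: AnalysisGrid, cis: bool = False) -> GridResult:
    """Run every exposure-outcome pair of the grid.

    With ``cis=True`` instruments are first restricted to each exposure's
    annotated gene locus (requires ``grid.cis_annotations``). A failure to
    read one source only flags the affected pairs; the rest of the grid
    proceeds.
    """
    if cis and not grid.cis_annotations:
        raise ValueError("cis analysis requested but the grid has no cis_annotations")
    ld = _load_ld(grid.ld)
    opts = grid.options
    result = GridResult()

    outcome_cache: dict[str, list[SummaryStatRecord] | None] = {}
    for oname, (src, _) in grid.outcomes.items():
        try:
            outcome_cache[oname] = _load_records(src)
        except Exception as exc:  # noqa: BLE001 - per-pair isolation
            logger.error("outcome %s unreadable: %s", oname, exc)
            outcome_cache[oname] = None
            result.flag("", oname, "load_error", str(exc))

    for ename, src in grid.exposures.items():
        try:
            stats = _load_records(src)
        except Exception as exc:  # noqa: BLE001 - per-pair isolation
            logger.error("exposure %s unreadable: %s", ename, exc)
            result.flag(ename, None, "load_error", str(exc))
            continue
        inst = select_instruments(
            stats,
            ld,
            primary_p=opts.primary_p,
            fallback_p=opts.fallback_p,
            r2_max=opts.clump_r2,
            window_kb=opts.clump_kb,
            exposure_name=ename,
        )
        if inst.uninstrumentable:
            result.flag(ename, None, "uninstrumentable")
            continue
        if inst.threshold_used == opts.fallback_p:
            result.flag(ename, None, "threshold_relaxed", f"p<{opts.fallback_p:g}")
        if cis:
            gene = grid.cis_annotations.get(ename)
            if gene is None:
                result.flag(ename, None, "no_cis_annotation")
                continue
            inst = cis_filter(inst, gene, flank_kb=opts.cis_flank_kb)
            if inst.uninstrumentable:
                result.flag(ename, None, "uninstrumentable_cis", gene.gene_symbol)
                continue
        exposure_by_id = {r.variant_id: r for r in stats}
        for oname, (osrc, otype) in grid.outcomes.items():
            orecords = outcome_cache[oname]
            if orecords is None:
                result.flag(ename, oname, "outcome_unreadable")
                continue
            _analyse_pair(
                ename, oname, otype, inst, exposure_by_id, orecords, ld, opts, result
            )
    return result


def _analyse_pair(
    ename: str,
    oname: str,
    otype: str,
    inst: InstrumentSet,
    exposure_by_id: Mapping[str, SummaryStatRecord],
    orecords: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    opts: GridOptions,
    result: GridResult,
) -> None:
    available = {r.variant_id for r in orecords}
    used: list[SummaryStatRecord] = []
    for rec in inst.records:
        if rec.variant_id in available:
            used.append(rec)
            continue
        proxy = find_proxy(rec.variant_id, available, ld, r2_min=opts.proxy_r2)
        if proxy is not None and proxy in exposure_by_id:
            used.append(exposure_by_id[proxy])
            result.flag(ename, oname, "proxy_used", f"{rec.variant_id}->{proxy}")
        else:
            result.flag(ename, oname, "instrument_missing_in_outcome", rec.variant_id)
    if not used:
        result.flag(ename, oname, "no_shared_variants")
        return
    hs = harmonise(
        used,
        orecords,
        palindromic_eaf_window=opts.palindromic_eaf_window,
        drop_palindromic_ambiguous=opts.drop_palindromic_ambiguous,
    )
    for _, drop in hs.dropped.iterrows():
        result.flag(ename, oname, drop["action"], drop["variant_id"])
    k = hs.n_snps
    if k == 0:
        result.flag(ename, oname, "no_harmonisable_variants")
        return

    def add(estimate: est.MREstimate) -> None:
        estimate.exposure = ename
        estimate.outcome = oname
        result.rows.append(estimate)

    if k == 1:
        add(est.ivw(hs))  # collapses to the Wald ratio, labelled wald_ratio
        result.flag(ename, oname, "methods_not_feasible", "egger,weighted_median,loo (n_snps<3)")
        return
    add(est.ivw(hs, effects_model=opts.effects_model))
    other = "fixed" if opts.effects_model == "multiplicative_random" else "multiplicative_random"
    add(est.ivw(hs, effects_model=other))
    if k < 3:
        result.flag(ename, oname, "methods_not_feasible", "egger,weighted_median,loo (n_snps<3)")
        return
    add(est.mr_egger(hs))
    add(est.weighted_median(hs, n_boot=opts.n_boot, seed=_pair_seed(ename, oname, opts.seed)))
    result.leave_one_out[(ename, oname)] = est.leave_one_out(
        hs, effects_model=opts.effects_model
    )


def run_cis_grid(grid: AnalysisGrid) -> GridResult:
    """Grid analysis restricted to cis instruments (see :func:`run_grid`)."""
    return run_grid(grid, cis=True)


def sensitivity_report(result: GridResult) -> pd.DataFrame:
    """Side-by-side estimator comparison per exposure-outcome pair.

    Reports the default IVW, MR-Egger and weighted-median betas, whether all
    available estimates agree in sign (the concordance reading under which
    results are considered more likely valid), Cochran's Q p-value, the
    Egger intercept p (directional pleiotropy), and the largest
    leave-one-out deviation. A Bonferroni column (0.05 over the number of
    pairs) is provided as a reader aid; the primary p-values are unadjusted.
    """
    by_pair: dict[tuple[str, str], dict[str, est.MREstimate]] = {}
    for row in result.rows:
        by_pair.setdefault((row.exposure, row.outcome), {})[row.method] = row
    n_pairs = max(len(by_pair), 1)
    records = []
    for (ename, oname), methods in sorted(by_pair.items()):
        primary = (
            methods.get(est.IVW_MRE)
            or methods.get(est.IVW_FIXED)
            or methods.get(est.WALD_RATIO)
        )
        egger = methods.get(est.EGGER)
        wm = methods.get(est.WEIGHTED_MEDIAN)
        betas = [m.beta for m in (primary, egger, wm) if m is not None]
        loo = result.leave_one_out.get((ename, oname))
        records.append(
            {
                "exposure": ename,
                "outcome": oname,
                "n_snps": primary.n_snps,
                "beta_ivw": primary.beta,
                "p_ivw": primary.pvalue,
                "beta_egger": egger.beta if egger else np.nan,
                "beta_weighted_median": wm.beta if wm else np.nan,
                "sign_agreement": bool(
                    all(np.sign(b) == np.sign(betas[0]) for b in betas)
                ),
                "q_pvalue": primary.q_pvalue if primary.q_pvalue is not None else np.nan,
                "egger_intercept_p": egger.egger_intercept_p if egger else np.nan,
                "max_loo_deviation": (
                    est.max_loo_deviation(primary, loo) if loo else np.nan
                ),
                "bonferroni_alpha": 0.05 / n_pairs,
            }
        )
    columns = [
        "exposure", "outcome", "n_snps", "beta_ivw", "p_ivw", "beta_egger",
        "beta_weighted_median", "sign_agreement", "q_pvalue",
        "egger_intercept_p", "max_loo_deviation", "bonferroni_alpha",
    ]
    return pd.DataFrame(records, columns=columns)


def forest_table(result: GridResult) -> pd.DataFrame:
    """Plot-ready table of odds ratios with 95% intervals per estimate."""
    records = [
        {
            "exposure": r.exposure,
            "outcome": r.outcome,
            "method": r.method,
            "or": float(np.exp(r.beta)),
            "ci_low": float(np.exp(r.ci_low)),
            "ci_high": float(np.exp(r.ci_high)),
            "beta": r.beta,
            "pvalue": r.pvalue,
        }
        for r in result.rows
    ]
    return pd.DataFrame(
        records,
        columns=["exposure", "outcome", "method", "or", "ci_low", "ci_high", "beta", "pvalue"],
    )
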