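"""Genetic-instrument selection and strength diagnostics.

Instruments are approximately independent variants robustly associated with
the exposure: candidates below a genome-wide significance threshold
(5e-8, relaxed to 5e-7 for exposures with no genome-wide hit) are greedily
LD-clumped (r^2 < 0.01 within a 10,000 kb window by default). Per-variant
strength is summarised by the F-statistic (beta/se)^2 and variance explained;
a joint (cumulative) F over the clumped set flags weak-instrument bias when
below ~10. A cis filter restricts instruments to the locus of the gene
encoding the measured protein, where horizontal pleiotropy is less likely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import SummaryStatRecord

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
RELAXED_P = 5e-7
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_KB = 10_000.0
DEFAULT_PROXY_R2 = 0.8
DEFAULT_CIS_FLANK_KB = 100.0


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix over a set of variants."""

    variant_ids: list[str]
    r2: np.ndarray
    pos: np.ndarray | None = None
    chrom: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} does not match {k} variants")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=float)
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom, dtype=object)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def pairwise_r2(self, id1: str, id2: str) -> float:
        """r^2 between two variants; 0 (unlinked) if either is unknown."""
        i = self._index.get(id1)
        j = self._index.get(id2)
        if i is None or j is None:
            return 0.0
        return float(self.r2[i, j])

    @classmethod
    def from_square_file(cls, path: str | Path) -> "LDMatrix":
        """Square tab-delimited matrix with variant ids as header and index."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        return cls(variant_ids=ids, r2=df.to_numpy(dtype=float))

    @classmethod
    def from_long_file(cls, path: str | Path) -> "LDMatrix":
        """Triplet file (id1, id2, r2); unlisted pairs are unlinked."""
        df = pd.read_csv(path, sep="\t", header=None, names=["id1", "id2", "r2"], comment="#")
        ids = sorted(set(df["id1"].astype(str)) | set(df["id2"].astype(str)))
        index = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for id1, id2, r2 in df.itertuples(index=False):
            i, j = index[str(id1)], index[str(id2)]
            mat[i, j] = mat[j, i] = float(r2)
        return cls(variant_ids=ids, r2=mat)


@dataclass
class InstrumentSet:
    """Post-selection instruments with per-SNP and cumulative strength."""

    exposure_name: str
    records: list[SummaryStatRecord]
    threshold_used: float | None
    per_snp_f: list[float] = field(default_factory=list)
    per_snp_r2: list[float] = field(default_factory=list)
    cumulative_f: float | None = None
    uninstrumentable: bool = False

    @property
    def k(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic interval of the gene encoding a measured protein (1-based, inclusive)."""

    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start {self.start} > end {self.end}")


def read_gene_annotations(path: str | Path, zero_based_half_open: bool = False) -> list[GeneAnnotation]:
    """Read BED-like (chrom, start, end, gene_symbol) annotations.

    Coordinates are interpreted 1-based inclusive unless
    ``zero_based_half_open`` selects the BED dialect.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_symbol"])
    offset = 1 if zero_based_half_open else 0
    return [
        GeneAnnotation(
            gene_symbol=str(r.gene_symbol),
            chrom=str(r.chrom),
            start=int(r.start) + offset,
            end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def _sort_key(rec: SummaryStatRecord):
    # deterministic: p-value, then chromosome/position, then id
    return (
        rec.pvalue if rec.pvalue is not None else 1.0,
        rec.chrom or "",
        rec.pos if rec.pos is not None else 0,
        rec.variant_id,
    )


def clump(
    candidates: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
) -> list[SummaryStatRecord]:
    """Greedy p-value clumping.

    Repeatedly promote the smallest-p remaining variant to index status and
    discard remaining variants on the same chromosome within ``window_kb``
    of it whose r^2 with it is >= ``r2_max``. Variants absent from the LD
    matrix are treated as unlinked. Output order is selection order, and is
    invariant to the input row order.
    """
    remaining = sorted(candidates, key=_sort_key)
    for rec in remaining:
        if rec.variant_id not in ld:
            logger.warning("variant %s missing from LD matrix; treated as unlinked", rec.variant_id)
    window_bp = window_kb * 1000.0
    selected: list[SummaryStatRecord] = []
    while remaining:
        index_var = remaining.pop(0)
        selected.append(index_var)
        kept = []
        for rec in remaining:
            same_chrom = (
                index_var.chrom is not None
                and rec.chrom is not None
                and rec.chrom == index_var.chrom
            )
            within = (
                same_chrom
                and index_var.pos is not None
                and rec.pos is not None
                and abs(rec.pos - index_var.pos) <= window_bp
            )
            if within and ld.pairwise_r2(index_var.variant_id, rec.variant_id) >= r2_max:
                continue
            kept.append(rec)
        remaining = kept
    return selected


def select_instruments(
    stats: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    primary_p: float = GENOME_WIDE_P,
    fallback_p: float = RELAXED_P,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
    exposure_name: str = "exposure",
) -> InstrumentSet:
    """Threshold-and-clump instrument selection with a relaxed fallback.

    Variants with p < ``primary_p`` are clumped; if none pass, the procedure
    is repeated at ``fallback_p`` and the set records which threshold
    applied. An exposure with no variant below ``fallback_p`` is flagged
    uninstrumentable (not an error).
    """
    for threshold in (primary_p, fallback_p):
        passing = [r for r in stats if r.pvalue is not None and r.pvalue < threshold]
        if passing:
            records = clump(passing, ld, r2_max=r2_max, window_kb=window_kb)
            inst = InstrumentSet(
                exposure_name=exposure_name, records=records, threshold_used=threshold
            )
            _attach_strength(inst)
            return inst
    return InstrumentSet(
        exposure_name=exposure_name, records=[], threshold_used=None, uninstrumentable=True
    )


def _attach_strength(inst: InstrumentSet) -> None:
    strengths = [per_snp_strength(r) for r in inst.records]
    inst.per_snp_f = [f for f, _ in strengths]
    inst.per_snp_r2 = [r2 for _, r2 in strengths]
    ns = [r.n for r in inst.records if r.n is not None]
    n = float(np.median(ns)) if ns else None
    if n is not None and n > inst.k + 1 and all(r2 is not None for r2 in inst.per_snp_r2):
        inst.cumulative_f = cumulative_strength(inst, n=n)


def find_proxy(
    target: str,
    available: set[str] | Sequence[str],
    ld: LDMatrix,
    r2_min: float = DEFAULT_PROXY_R2,
) -> str | None:
    """Best available proxy for a variant missing from the outcome GWAS.

    Returns the available variant with the highest r^2 to the target,
    provided it reaches ``r2_min``; ties are broken by smaller base-pair
    distance, then lexicographic id.
    """
    if target not in ld:
        logger.warning("proxy search: target %s not in LD matrix", target)
        return None
    ti = ld._index[target]
    best: tuple[float, float, str] | None = None  # (-r2, distance, id)
    for vid in available:
        if vid == target or vid not in ld:
            continue
        r2 = ld.pairwise_r2(target, vid)
        if r2 < r2_min:
            continue
        if ld.pos is not None:
            dist = abs(float(ld.pos[ld._index[vid]]) - float(ld.pos[ti]))
        else:
            dist = 0.0
        key = (-r2, dist, vid)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def per_snp_strength(record: SummaryStatRecord) -> tuple[float, float | None]:
    """Per-variant F-statistic and variance in the exposure explained.

    F = (beta/se)^2. For an SD-scaled trait with known effect-allele
    frequency, r^2 = 2 beta^2 eaf (1 - eaf); with the frequency missing the
    fallback r^2 = F / (F + n - 2) is used, and r^2 is undefined (None) when
    n is also missing or <= 2.
    """
    f = (record.beta / record.se) ** 2
    if record.eaf is not None:
        r2 = 2.0 * record.beta**2 * record.eaf * (1.0 - record.eaf)
    elif record.n is not None and record.n > 2:
        r2 = f / (f + record.n - 2.0)
    else:
        logger.warning("variant %s: r2 undefined (no eaf, n <= 2)", record.variant_id)
        r2 = None
    return f, r2


def cumulative_strength(instruments: InstrumentSet, n: float) -> float:
    """Joint F-statistic over all instruments.

    Sums the per-SNP variances explained (valid after clumping, when
    instruments are approximately independent), caps the total at 0.99, and
    forms F = (R^2 / (1 - R^2)) * ((n - k - 1) / k).
    """
    k = instruments.k
    if n <= k + 1:
        raise ValueError(f"cumulative F undefined: n={n} <= k+1={k + 1}")
    r2s = [r2 for r2 in instruments.per_snp_r2 if r2 is not None]
    r2_total = min(float(np.sum(r2s)), 0.99)
    return (r2_total / (1.0 - r2_total)) * ((n - k - 1.0) / k)


def cis_filter(
    instruments: InstrumentSet,
    gene: GeneAnnotation,
    flank_kb: float = DEFAULT_CIS_FLANK_KB,
) -> InstrumentSet:
    """Restrict instruments to the cis window around the encoding gene.

    Retains variants on ``gene.chrom`` with position in
    [start - flank, end + flank] (inclusive). The result may be empty, in
    which case the exposure is uninstrumentable for cis analysis.
    """
    flank = flank_kb * 1000.0
    lo = gene.start - flank
    hi = gene.end + flank
    kept = [
        r
        for r in instruments.records
        if r.chrom == gene.chrom and r.pos is not None and lo <= r.pos <= hi
    ]
    out = InstrumentSet(
        exposure_name=instruments.exposure_name,
        records=kept,
        threshold_used=instruments.threshold_used if kept else None,
        uninstrumentable=not kept,
    )
    if kept:
        _attach_strength(out)
    return out
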