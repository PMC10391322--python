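"""Reading, validation and allele harmonization of GWAS summary statistics.

Summary-statistic tables are the exchange format of two-sample Mendelian
randomization: each row records one variant's association with one trait
(effect allele, other allele, effect-allele frequency, beta, SE, p, N).
Exposure betas are expected on the standard-deviation scale of the trait;
binary-outcome betas are log odds.

Harmonization expresses the exposure and outcome effects of each shared
variant with respect to the same effect allele, resolving allele swaps and
strand flips from the allele letters, and palindromic (A/T, C/G) variants
from allele frequencies where these are informative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: actions recorded per harmonised variant pair
ALIGNED = "aligned"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
STRAND_AND_SIGN_FLIPPED = "strand_flipped_and_sign_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"

RETAINED_ACTIONS = (ALIGNED, SIGN_FLIPPED, STRAND_FLIPPED, STRAND_AND_SIGN_FLIPPED)

#: accepted header aliases for each canonical column (lower-cased match)
COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "rs_id", "markername", "id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "position", "bp", "base_pair_location"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1"),
    "other_allele": ("other_allele", "oa", "a2", "allele2", "non_effect_allele"),
    "eaf": ("eaf", "effect_allele_frequency", "freq", "af", "maf"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "se": ("se", "standard_error", "stderr"),
    "pvalue": ("pvalue", "p", "pval", "p_value"),
    "n": ("n", "samplesize", "sample_size", "n_total"),
}

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")


class SchemaError(ValueError):
    """Raised when a summary-statistic file lacks resolvable required columns."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is per SD of a continuous trait or a log odds for a binary
    trait; ``eaf`` is the frequency of ``effect_allele`` and may be None.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    ``pairs`` holds only retained variants; ``dropped`` records the variant
    id and drop reason for every excluded shared variant. Array accessors
    (``beta_exposure`` ...) feed the estimators directly.
    """

    pairs: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "action"])
    )

    PAIR_COLUMNS = (
        "variant_id",
        "beta_exposure",
        "se_exposure",
        "beta_outcome",
        "se_outcome",
        "eaf_exposure",
        "eaf_outcome",
        "action",
    )

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != list(self.PAIR_COLUMNS):
            self.pairs = self.pairs.reindex(columns=list(self.PAIR_COLUMNS))

    @classmethod
    def from_arrays(
        cls,
        beta_exposure: Sequence[float],
        se_exposure: Sequence[float],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        variant_ids: Sequence[str] | None = None,
        eaf_exposure: Sequence[float] | None = None,
        eaf_outcome: Sequence[float] | None = None,
    ) -> "HarmonisedSet":
        bx = np.asarray(beta_exposure, dtype=float)
        k = bx.size
        ids = list(variant_ids) if variant_ids is not None else [f"snp{i + 1}" for i in range(k)]
        pairs = pd.DataFrame(
            {
                "variant_id": ids,
                "beta_exposure": bx,
                "se_exposure": np.asarray(se_exposure, dtype=float),
                "beta_outcome": np.asarray(beta_outcome, dtype=float),
                "se_outcome": np.asarray(se_outcome, dtype=float),
                "eaf_exposure": np.asarray(eaf_exposure, dtype=float) if eaf_exposure is not None else np.nan,
                "eaf_outcome": np.asarray(eaf_outcome, dtype=float) if eaf_outcome is not None else np.nan,
                "action": ALIGNED,
            }
        )
        return cls(pairs=pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.pairs["variant_id"].to_numpy()

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.pairs["beta_exposure"].to_numpy(dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.pairs["se_exposure"].to_numpy(dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.pairs["beta_outcome"].to_numpy(dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.pairs["se_outcome"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "HarmonisedSet":
        return HarmonisedSet(pairs=self.pairs.loc[mask].reset_index(drop=True))


def two_sided_p(beta: float | np.ndarray, se: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value for beta/se (the GWAS convention)."""
    z = np.abs(np.asarray(beta, dtype=float)) / np.asarray(se, dtype=float)
    p = 2.0 * stats.norm.sf(z)
    # clamp into (0, 1]; underflow to 0 would violate the record invariant
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return float(p) if np.isscalar(beta) or np.ndim(beta) == 0 else p


def _resolve_columns(header: Iterable[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    lower = {str(c).lower(): c for c in header}
    resolved: dict[str, str] = {}
    explicit = {k: v for k, v in (column_map or {}).items()}
    for canon, aliases in COLUMN_ALIASES.items():
        if canon in explicit:
            if explicit[canon] in lower.values() or explicit[canon] in lower:
                resolved[canon] = lower.get(explicit[canon].lower(), explicit[canon])
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a tab- or comma-delimited GWAS summary table into records.

    Rows violating record invariants (non-ACGT or identical alleles,
    se <= 0, eaf outside (0,1)) are dropped with a logged reason. Missing
    p-values are recomputed as two-sided normal from beta/se; p-values
    inconsistent with beta/se by more than a factor of two only trigger a
    warning. Duplicate variant ids keep the smallest-p row.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header_line = fh.readline()
        sep = "\t" if "\t" in header_line else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"cannot read summary-statistic file {path}: {exc}") from exc
    cols = _resolve_columns(df.columns, column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(
            f"{path}: required columns not resolvable: {missing}; found header {list(df.columns)}"
        )

    records: list[SummaryStatRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        vid = str(row[cols["variant_id"]])
        try:
            ea = str(row[cols["effect_allele"]]).upper().strip()
            oa = str(row[cols["other_allele"]]).upper().strip()
            beta = float(row[cols["beta"]])
            se = float(row[cols["se"]])
        except (TypeError, ValueError):
            logger.warning("dropping %s: unparseable numeric field", vid)
            n_dropped += 1
            continue
        if ea not in NUCLEOTIDES or oa not in NUCLEOTIDES or ea == oa:
            logger.warning("dropping %s: invalid allele pair %s/%s", vid, ea, oa)
            n_dropped += 1
            continue
        if not math.isfinite(beta) or not math.isfinite(se) or se <= 0:
            logger.warning("dropping %s: invalid beta/se (%s, %s)", vid, beta, se)
            n_dropped += 1
            continue
        eaf = _optional_float(row, cols.get("eaf"))
        if eaf is not None and not (0.0 < eaf < 1.0):
            logger.warning("dropping %s: eaf %s outside (0,1)", vid, eaf)
            n_dropped += 1
            continue
        pval = _optional_float(row, cols.get("pvalue"))
        if pval is None or not (0.0 < pval <= 1.0):
            pval = two_sided_p(beta, se)
        else:
            expected = two_sided_p(beta, se)
            ratio = pval / expected if expected > 0 else math.inf
            if not (0.5 <= ratio <= 2.0) and expected > 1e-300:
                logger.warning(
                    "%s: reported p=%.3g differs from normal-theory p=%.3g by >2x", vid, pval, expected
                )
        n = _optional_float(row, cols.get("n"))
        pos = _optional_float(row, cols.get("pos"))
        chrom = None
        if cols.get("chrom") is not None and not pd.isna(row[cols["chrom"]]):
            chrom = str(row[cols["chrom"]])
        records.append(
            SummaryStatRecord(
                variant_id=vid,
                chrom=chrom,
                pos=int(pos) if pos is not None else None,
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=se,
                pvalue=float(pval),
                n=n,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d invalid rows", path, n_dropped)
    return _deduplicate(records)


def _optional_float(row: pd.Series, col: str | None) -> float | None:
    if col is None:
        return None
    val = row[col]
    if pd.isna(val):
        return None
    return float(val)


def _deduplicate(records: list[SummaryStatRecord]) -> list[SummaryStatRecord]:
    """Keep the smallest-p row per variant id (deterministic strongest signal)."""
    best: dict[str, SummaryStatRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.variant_id not in best:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        else:
            logger.warning("duplicate variant %s: keeping smallest p-value", rec.variant_id)
            if (rec.pvalue or 1.0) < (best[rec.variant_id].pvalue or 1.0):
                best[rec.variant_id] = rec
    return [best[v] for v in order]


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def harmonise(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
    drop_palindromic_ambiguous: bool = True,
) -> HarmonisedSet:
    """Match exposure and outcome records by variant id and align alleles.

    Non-palindromic variants are resolved from allele letters alone:
    matching alleles keep the outcome beta; swapped alleles negate it and
    complement the frequency; a strand complement (A<->T, C<->G) is applied
    first when needed. Palindromic variants carry no strand information in
    their letters, so orientation is decided by comparing effect-allele
    frequencies: both frequencies must fall outside ``palindromic_eaf_window``,
    same side of 0.5 meaning same orientation, opposite sides meaning the
    outcome beta must be flipped. Otherwise the variant is dropped as
    ambiguous (always, when either frequency is missing).

    With ``drop_palindromic_ambiguous=False``, palindromic variants are
    instead aligned from allele letters under a same-strand assumption.
    """
    lo, hi = palindromic_eaf_window
    out_by_id = {r.variant_id: r for r in outcome}
    rows: list[dict] = []
    dropped: list[dict] = []
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue  # not a shared variant
        row = {
            "variant_id": exp.variant_id,
            "beta_exposure": exp.beta,
            "se_exposure": exp.se,
            "eaf_exposure": np.nan if exp.eaf is None else exp.eaf,
        }
        if exp.is_palindromic() or out.is_palindromic():
            if not (exp.is_palindromic() and out.is_palindromic()):
                dropped.append({"variant_id": exp.variant_id, "action": DROPPED_INCOMPATIBLE})
                continue
            if {exp.effect_allele, exp.other_allele} != {out.effect_allele, out.other_allele}:
                dropped.append({"variant_id": exp.variant_id, "action": DROPPED_INCOMPATIBLE})
                continue
            action = _resolve_palindromic(
                exp, out, lo, hi, drop_ambiguous=drop_palindromic_ambiguous
            )
            if action in (DROPPED_PALINDROMIC, DROPPED_INCOMPATIBLE):
                dropped.append({"variant_id": exp.variant_id, "action": action})
                continue
        else:
            action = _resolve_orientation(exp, out)
            if action == DROPPED_INCOMPATIBLE:
                dropped.append({"variant_id": exp.variant_id, "action": action})
                continue
        flip = action in (SIGN_FLIPPED, STRAND_AND_SIGN_FLIPPED)
        row["beta_outcome"] = -out.beta if flip else out.beta
        row["se_outcome"] = out.se
        if out.eaf is None:
            row["eaf_outcome"] = np.nan
        else:
            row["eaf_outcome"] = 1.0 - out.eaf if flip else out.eaf
        row["action"] = action
        rows.append(row)
    pairs = pd.DataFrame(rows, columns=list(HarmonisedSet.PAIR_COLUMNS))
    return HarmonisedSet(
        pairs=pairs, dropped=pd.DataFrame(dropped, columns=["variant_id", "action"])
    )


def _resolve_orientation(exp: SummaryStatRecord, out: SummaryStatRecord) -> str:
    """Orientation of a non-palindromic outcome record relative to the exposure."""
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return ALIGNED
    if o == e[::-1]:
        return SIGN_FLIPPED
    oc = _complement_pair(*o)
    if oc == e:
        return STRAND_FLIPPED
    if oc == e[::-1]:
        return STRAND_AND_SIGN_FLIPPED
    return DROPPED_INCOMPATIBLE


def _resolve_palindromic(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    lo: float,
    hi: float,
    drop_ambiguous: bool,
) -> str:
    """Orient a palindromic pair from allele frequencies.

    Letters are uninformative (strand complement maps the pair onto itself),
    so the decision is frequency-based: both eafs outside the ambiguity
    window and on the same side of 0.5 means the reported effect alleles are
    the same allele; opposite sides means they are complements on opposite
    strands and the outcome beta must be flipped.
    """
    if not drop_ambiguous:
        # letters-only fallback: assume same strand
        action = _resolve_orientation(exp, out)
        return ALIGNED if action == STRAND_FLIPPED else (
            SIGN_FLIPPED if action == STRAND_AND_SIGN_FLIPPED else action
        )
    if exp.eaf is None or out.eaf is None:
        return DROPPED_PALINDROMIC
    if lo < exp.eaf < hi or lo < out.eaf < hi:
        return DROPPED_PALINDROMIC
    # the two effect alleles are the same physical allele iff their
    # frequencies sit on the same side of 0.5; letters only label the action
    same_letters = out.effect_allele == exp.effect_allele
    same_allele = (exp.eaf < 0.5) == (out.eaf < 0.5)
    if same_allele:
        return ALIGNED if same_letters else STRAND_FLIPPED
    return STRAND_AND_SIGN_FLIPPED if same_letters else SIGN_FLIPPED


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> Path:
    """Write records as a tab-delimited summary table (canonical column names)."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in records
        ],
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


RESULT_COLUMNS = (
    "exposure",
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pvalue",
    "q",
    "q_pvalue",
    "egger_intercept",
    "egger_intercept_p",
)


def write_results_table(rows, path: str | Path) -> Path:
    """Serialize MR estimates to a tab-delimited table (>=10 significant digits).

    ``rows`` is a sequence of ``MREstimate`` (or dicts with the same keys);
    an ``or`` column (exp(beta)) is added so binary-outcome effects read as
    odds ratios. Rereading the file reproduces the numbers exactly.
    """
    path = Path(path)
    dicts = []
    for row in rows:
        d = dict(row.to_dict() if hasattr(row, "to_dict") else row)
        if "or" not in d and d.get("beta") is not None:
            d["or"] = math.exp(d["beta"])
        dicts.append(d)
    df = pd.DataFrame(dicts, columns=list(RESULT_COLUMNS))
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write results table {path}: {exc}") from exc
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
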