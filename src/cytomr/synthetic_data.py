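"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the data layout of a two-sample MR study of
circulating cytokines on Alzheimer's disease: an SD-scaled exposure GWAS of
a few thousand individuals, a much larger case-control outcome GWAS on the
log-odds scale, and a set of approximately independent instruments. The
generative model per variant j is

    beta_x_j ~ Normal(gamma_j, sigma_x_j)      (exposure association)
    beta_y_j ~ Normal(theta * gamma_j + alpha_j, sigma_y_j)

with gamma_j the true variant-exposure effect, theta the causal effect of
the exposure on the outcome, and alpha_j a direct (horizontally
pleiotropic) variant-outcome effect that is zero for valid instruments.
Standard errors follow the usual GWAS approximation from sample size and
allele frequency, sigma = 1/sqrt(2 N maf (1-maf)), inflated by
1/sqrt(p(1-p)) for a binary outcome with case fraction p.

An individual-level generator (genotypes, confounder, exposure, outcome,
per-variant regressions in two disjoint samples) backs the summary-level
shortcut; ``scramble_alleles`` corrupts allele coding (swaps, strand flips,
palindromic variants) to stress harmonization; ``make_ld_blocks`` builds
block-diagonal LD to exercise clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .gwas_io import COMPLEMENT, SummaryStatRecord, two_sided_p
from .instruments import LDMatrix

#: allele pairs assignable to non-palindromic variants
_NON_PALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

#: guard for the individual-level generator (total genotype draws)
MAX_GENOTYPE_DRAWS = 100_000_000


@dataclass(frozen=True)
class PleiotropyRegime:
    """Distribution of direct variant-outcome effects for invalid instruments.

    kinds: ``none``; ``balanced`` (zero-mean alpha, InSIDE holds);
    ``directional`` (non-zero mean alpha, independent of gamma, so InSIDE
    still holds and MR-Egger remains consistent); ``inside_violating``
    (alpha correlated with gamma, biasing every estimator including Egger).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if not (-1.0 <= self.correlation <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")

    @classmethod
    def none(cls) -> "PleiotropyRegime":
        return cls(kind="none")

    @classmethod
    def balanced(cls, sd: float) -> "PleiotropyRegime":
        return cls(kind="balanced", sd=sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "PleiotropyRegime":
        return cls(kind="directional", mean=mean, sd=sd)

    @classmethod
    def inside_violating(cls, correlation: float, sd: float) -> "PleiotropyRegime":
        return cls(kind="inside_violating", correlation=correlation, sd=sd)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic exposure-outcome dataset.

    Defaults mirror the study conditions this generator emulates: an
    exposure GWAS of 8,293 individuals (the largest cytokine cohort), a
    binary outcome GWAS of 79,145 with 24,087 cases, variant-exposure
    effects sized to give per-variant F-statistics well above 10, and a
    causal effect of 0.1 log odds per SD (odds ratio ~1.1, the effect the
    power analysis targets).
    """

    n_snps: int = 30
    n_exposure: int = 8_293
    n_outcome: int = 79_145
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta: float = 0.1
    gamma_dist: tuple[float, float] = (0.0, 0.15)  # (mean, sd) of true SNP-exposure effects
    pleiotropy: PleiotropyRegime = field(default_factory=PleiotropyRegime.none)
    invalid_fraction: float = 0.0
    outcome_type: str = "binary"  # or "continuous"
    case_fraction: float = 24_087 / 79_145
    confounder_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise ValueError("n_snps must be non-negative")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.gamma_dist[1] < 0:
            raise ValueError("gamma sd must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        """Load a config from a YAML file; the seed key is mandatory."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"{path}: simulation config must set an explicit seed")
        if "pleiotropy" in raw and isinstance(raw["pleiotropy"], dict):
            raw["pleiotropy"] = PleiotropyRegime(**raw["pleiotropy"])
        for key in ("maf_range", "gamma_dist"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset, for recovery checks."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    invalid_flags: np.ndarray

    @property
    def mean_pleiotropy(self) -> float:
        return float(np.mean(self.alpha)) if self.alpha.size else 0.0


def _draw_effects(rng: np.random.Generator, config: SimConfig):
    k = config.n_snps
    maf = rng.uniform(*config.maf_range, size=k)
    gamma = rng.normal(config.gamma_dist[0], config.gamma_dist[1], size=k)
    n_invalid = int(round(config.invalid_fraction * k))
    invalid = np.zeros(k, dtype=bool)
    if n_invalid:
        invalid[rng.choice(k, size=n_invalid, replace=False)] = True
    alpha = np.zeros(k)
    reg = config.pleiotropy
    if n_invalid and reg.kind != "none":
        if reg.kind == "balanced":
            alpha[invalid] = rng.normal(0.0, reg.sd, size=n_invalid)
        elif reg.kind == "directional":
            alpha[invalid] = rng.normal(reg.mean, reg.sd, size=n_invalid)
        else:  # inside_violating: alpha correlated with gamma
            g = gamma[invalid]
            g_sd = config.gamma_dist[1] if config.gamma_dist[1] > 0 else 1.0
            z = rng.normal(0.0, 1.0, size=n_invalid)
            rho = reg.correlation
            alpha[invalid] = reg.sd * (
                rho * (g - config.gamma_dist[0]) / g_sd + np.sqrt(max(0.0, 1 - rho**2)) * z
            )
    return maf, gamma, alpha, invalid


def _allele_pairs(rng: np.random.Generator, k: int) -> list[tuple[str, str]]:
    idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=k)
    return [_NON_PALINDROMIC_PAIRS[i] for i in idx]


def _build_records(
    ids: Sequence[str],
    alleles: Sequence[tuple[str, str]],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
) -> list[SummaryStatRecord]:
    pvals = two_sided_p(beta, se) if beta.size else np.empty(0)
    records = []
    for j, vid in enumerate(ids):
        chrom = str(j % 22 + 1)
        pos = 1_000_000 + (j // 22) * 50_000_000
        records.append(
            SummaryStatRecord(
                variant_id=vid,
                chrom=chrom,
                pos=pos,
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                eaf=float(maf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(np.atleast_1d(pvals)[j]),
                n=float(n),
            )
        )
    return records


def _se_scales(config: SimConfig, maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sigma_x = 1.0 / np.sqrt(2.0 * config.n_exposure * maf * (1.0 - maf))
    sigma_y = 1.0 / np.sqrt(2.0 * config.n_outcome * maf * (1.0 - maf))
    if config.outcome_type == "binary":
        p = config.case_fraction
        sigma_y = sigma_y / np.sqrt(p * (1.0 - p))
    return sigma_x, sigma_y


def simulate_summary_level(
    config: SimConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Draw exposure and outcome summary statistics directly.

    Estimated betas are sampled around their true values with the standard
    GWAS standard errors; exposure and outcome errors are independent (the
    two-sample design). Identical configs (including the seed) produce
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    maf, gamma, alpha, invalid = _draw_effects(rng, config)
    sigma_x, sigma_y = _se_scales(config, maf)
    beta_x = rng.normal(gamma, sigma_x)
    beta_y = rng.normal(config.theta * gamma + alpha, sigma_y)
    ids = [f"rs{j + 1:05d}" for j in range(k)]
    alleles = _allele_pairs(rng, k)
    exposure = _build_records(ids, alleles, maf, beta_x, sigma_x, config.n_exposure)
    outcome = _build_records(ids, alleles, maf, beta_y, sigma_y, config.n_outcome)
    truth = SimulationTruth(
        theta=config.theta, gamma=gamma, alpha=alpha, maf=maf, invalid_flags=invalid
    )
    return exposure, outcome, truth


def _simple_ols(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on each genotype column."""
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(Gc**2, axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = Gc.T @ yc / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    return beta, se


def _logistic_score(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column logistic score-test effect estimates (one-step, null model)."""
    ybar = y.mean()
    Gc = G - G.mean(axis=0)
    score = Gc.T @ (y - ybar)
    info = ybar * (1.0 - ybar) * np.sum(Gc**2, axis=0)
    info = np.where(info == 0, np.nan, info)
    return score / info, 1.0 / np.sqrt(info)


def simulate_individual_level(
    config: SimConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Simulate genotypes and phenotypes, then run per-variant GWAS.

    The exposure X = sum_j gamma_j G_j + c U + eps is normalised to unit
    variance (SD scaling); the outcome adds theta X, direct effects alpha_j
    and the shared confounder U in a disjoint sample, either as a continuous
    trait or as a Bernoulli draw through a logistic link whose intercept is
    solved to hit the target case fraction. Summary statistics come from
    per-variant least squares (continuous) or logistic score tests (binary).
    """
    k = config.n_snps
    if k * (config.n_exposure + config.n_outcome) > MAX_GENOTYPE_DRAWS:
        raise ValueError(
            "individual-level simulation too large "
            f"({k} x {config.n_exposure + config.n_outcome} genotype draws); "
            "use simulate_summary_level instead"
        )
    rng = np.random.default_rng(config.seed)
    maf, gamma, alpha, invalid = _draw_effects(rng, config)
    truth = SimulationTruth(
        theta=config.theta, gamma=gamma, alpha=alpha, maf=maf, invalid_flags=invalid
    )
    ids = [f"rs{j + 1:05d}" for j in range(k)]
    alleles = _allele_pairs(rng, k)
    if k == 0:
        return [], [], truth

    c = config.confounder_strength
    gvar = float(np.sum(gamma**2 * 2.0 * maf * (1.0 - maf)))
    resid_var = 1.0 - gvar - c**2
    if resid_var <= 0:
        raise ValueError(
            f"exposure variance over-allocated: genetic {gvar:.3f} + confounder {c**2:.3f} >= 1"
        )

    def draw_exposure(n: int):
        G = rng.binomial(2, maf, size=(n, k)).astype(float)
        U = rng.normal(size=n)
        X = G @ gamma + c * U + rng.normal(scale=np.sqrt(resid_var), size=n)
        return G, U, X

    # exposure sample
    G1, _, X1 = draw_exposure(config.n_exposure)
    bx, sx = _simple_ols(G1, X1)
    exposure = _build_records(ids, alleles, maf, bx, sx, config.n_exposure)

    # outcome sample (disjoint draw)
    G2, U2, X2 = draw_exposure(config.n_outcome)
    linpred = config.theta * X2 + G2 @ alpha + c * U2
    if config.outcome_type == "continuous":
        y = linpred + rng.normal(size=config.n_outcome)
        by, sy = _simple_ols(G2, y)
    else:
        b0 = brentq(
            lambda b: expit(b + linpred).mean() - config.case_fraction, -30.0, 30.0
        )
        y = rng.binomial(1, expit(b0 + linpred)).astype(float)
        by, sy = _logistic_score(G2, y)
    outcome = _build_records(ids, alleles, maf, by, sy, config.n_outcome)
    return exposure, outcome, truth


@dataclass
class ScrambleResult:
    """Output of :func:`scramble_alleles`.

    ``records`` is the corrupted copy; ``reference`` is the clean copy after
    palindromic designation (harmonising ``records`` against ``reference``
    should recover the reference numbers for every resolvable variant);
    ``log`` records, per variant, which corruptions were applied.
    """

    records: list[SummaryStatRecord]
    reference: list[SummaryStatRecord]
    log: list[dict]


def scramble_alleles(
    records: Sequence[SummaryStatRecord],
    swap_prob: float = 0.5,
    strand_prob: float = 0.5,
    palindromic_fraction: float = 0.0,
    seed: int = 0,
) -> ScrambleResult:
    """Corrupt allele coding to stress-test harmonization.

    A fraction of variants is first redesignated palindromic (allele pair
    A/T or C/G) in both the reference and the corrupted copy. Each record is
    then independently allele-swapped with probability ``swap_prob``
    (negating beta and complementing eaf) and strand-complemented with
    probability ``strand_prob`` (a labelling change only). All draws are
    governed by ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    n_palin = int(round(palindromic_fraction * n))
    palin_idx = set(rng.choice(n, size=n_palin, replace=False).tolist()) if n_palin else set()
    reference: list[SummaryStatRecord] = []
    corrupted: list[SummaryStatRecord] = []
    log: list[dict] = []
    for j, rec in enumerate(records):
        ref = rec
        if j in palin_idx:
            ea, oa = _PALINDROMIC_PAIRS[int(rng.integers(0, 2))]
            ref = replace(rec, effect_allele=ea, other_allele=oa)
        cor = ref
        swapped = bool(rng.random() < swap_prob)
        stranded = bool(rng.random() < strand_prob)
        if swapped:
            cor = replace(
                cor,
                effect_allele=cor.other_allele,
                other_allele=cor.effect_allele,
                beta=-cor.beta,
                eaf=None if cor.eaf is None else 1.0 - cor.eaf,
            )
        if stranded:
            cor = replace(
                cor,
                effect_allele=COMPLEMENT[cor.effect_allele],
                other_allele=COMPLEMENT[cor.other_allele],
            )
        reference.append(ref)
        corrupted.append(cor)
        log.append(
            {
                "variant_id": rec.variant_id,
                "palindromic": j in palin_idx,
                "swapped": swapped,
                "strand_flipped": stranded,
            }
        )
    return ScrambleResult(records=corrupted, reference=reference, log=log)


def make_ld_blocks(
    n_snps: int,
    block_sizes: Sequence[int],
    within_r2: float,
    seed: int = 0,
    variant_ids: Sequence[str] | None = None,
) -> LDMatrix:
    """Block-diagonal LD: ``within_r2`` inside each block, zero between.

    Positions are assigned so each block sits comfortably inside a clumping
    window (10 kb spacing within blocks) and blocks are far apart on the
    same chromosome (50 Mb gaps).
    """
    if sum(block_sizes) != n_snps:
        raise ValueError(f"block sizes {list(block_sizes)} do not sum to n_snps={n_snps}")
    if not (0.0 <= within_r2 < 1.0):
        raise ValueError("within_r2 must lie in [0, 1)")
    if variant_ids is None:
        variant_ids = [f"rs{j + 1:05d}" for j in range(n_snps)]
    elif len(variant_ids) != n_snps:
        raise ValueError("variant_ids length must equal n_snps")
    r2 = np.zeros((n_snps, n_snps))
    pos = np.zeros(n_snps)
    start = 0
    block_origin = 1_000_000
    for size in block_sizes:
        sl = slice(start, start + size)
        r2[sl, sl] = within_r2
        pos[sl] = block_origin + 10_000 * np.arange(size)
        block_origin += 50_000_000
        start += size
    np.fill_diagonal(r2, 1.0)
    chrom = np.array(["1"] * n_snps, dtype=object)
    return LDMatrix(variant_ids=list(variant_ids), r2=r2, pos=pos, chrom=chrom)


def apply_ld_layout(
    records: Sequence[SummaryStatRecord], ld: LDMatrix
) -> list[SummaryStatRecord]:
    """Overwrite record chrom/pos with the LD matrix layout (matched by id)."""
    out = []
    for rec in records:
        if rec.variant_id in ld:
            i = ld._index[rec.variant_id]
            out.append(
                replace(
                    rec,
                    chrom=str(ld.chrom[i]) if ld.chrom is not None else rec.chrom,
                    pos=int(ld.pos[i]) if ld.pos is not None else rec.pos,
                )
            )
        else:
            out.append(rec)
    return out
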