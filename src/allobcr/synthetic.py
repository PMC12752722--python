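"""Synthetic cohorts with the statistical structure of rejecting allografts.

The generator emulates the study conditions the analysis assumes, so every
downstream module is testable without any sequencing data and printed effect
sizes become parameter-recovery targets:

* a bulk cohort of 18 TCMR / 16 STA biopsies whose total clonotype abundance
  is expanded 38-fold in TCMR, with an isotype-specific IGHG1 fold of 51;
* a barcoded single-cell sample (993 naive B / 620 memory B / 76 plasma
  cells) whose pooled plasma:B read ratio is 182 and whose plasma heavy-chain
  reads are 68% IGHG, 91.9% of which is IGHG1;
* an expression matrix with genes implanted to hit target correlations with
  IGHG abundance (0.891) and IGHG CPK (-0.703) exactly in-sample;
* proportional-hazards survival data with a true per-unit hazard ratio of
  2.421 under calibrated uniform censoring.

All randomness flows through one integer seed; identical config + seed give
byte-identical outputs. CDR3 sequences are structurally valid in-frame
placeholders (no stop codons), not biological junctions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import write_airr
from .records import RepertoireSample
from .stats import RepertoireSummary

__all__ = [
    "SyntheticConfig", "SingleCellConfig", "ExpressionConfig",
    "ExpressionImplant", "SurvivalConfig", "ConfigError",
    "generate_repertoire_cohort", "generate_single_cell",
    "generate_expression", "generate_infiltration", "generate_survival",
    "write_fixture",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


# ---------------------------------------------------------------------------
# gene-name pools (IMGT-style names; weights loosely follow common usage with
# IGHV3-23 / IGHV3-30 / IGHV4-59 at the top, as in rejecting allografts)
# ---------------------------------------------------------------------------

IGHV_POOL = {
    "IGHV3-23": 0.14, "IGHV3-30": 0.11, "IGHV4-59": 0.09, "IGHV1-69": 0.06,
    "IGHV3-7": 0.06, "IGHV4-34": 0.06, "IGHV1-2": 0.05, "IGHV1-18": 0.05,
    "IGHV3-15": 0.05, "IGHV3-21": 0.05, "IGHV3-48": 0.05, "IGHV4-39": 0.05,
    "IGHV5-51": 0.04, "IGHV2-5": 0.04, "IGHV6-1": 0.03, "IGHV3-33": 0.03,
    "IGHV4-4": 0.03, "IGHV1-46": 0.03, "IGHV3-74": 0.02, "IGHV7-4-1": 0.02,
}
IGHJ_POOL = {
    "IGHJ4": 0.40, "IGHJ6": 0.20, "IGHJ3": 0.12, "IGHJ5": 0.12,
    "IGHJ1": 0.08, "IGHJ2": 0.08,
}
IGKV_POOL = {
    "IGKV1-39": 0.25, "IGKV3-20": 0.22, "IGKV1-5": 0.18, "IGKV4-1": 0.15,
    "IGKV2-28": 0.12, "IGKV3-11": 0.08,
}
IGKJ_POOL = {"IGKJ1": 0.3, "IGKJ2": 0.25, "IGKJ4": 0.25, "IGKJ3": 0.1, "IGKJ5": 0.1}
IGLV_POOL = {
    "IGLV1-44": 0.3, "IGLV2-14": 0.25, "IGLV3-21": 0.2, "IGLV1-40": 0.15,
    "IGLV2-23": 0.1,
}
IGLJ_POOL = {"IGLJ2": 0.4, "IGLJ3": 0.35, "IGLJ1": 0.25}

#: mixture categories: heavy subclasses/isotypes plus the two light loci
MIXTURE_CATEGORIES = (
    "IGHA1", "IGHA2", "IGHD", "IGHE", "IGHG1", "IGHG2", "IGHG3", "IGHG4",
    "IGHM", "IGK", "IGL",
)

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_NONSTOP = [(c, aa) for c, aa in zip(_CODONS, _AA) if aa != "*"]
_NT61 = np.array([c for c, _ in _NONSTOP], dtype="S3")
_AA61 = np.array([aa for _, aa in _NONSTOP], dtype="S1")


def _random_cdr3(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n random in-frame CDR3s: Cys + 4-12 non-stop codons + Trp."""
    nt = np.empty(n, dtype=object)
    aa = np.empty(n, dtype=object)
    lengths = rng.integers(4, 13, size=n)
    for length in np.unique(lengths):
        rows = np.flatnonzero(lengths == length)
        idx = rng.integers(0, len(_NT61), size=(len(rows), length))
        nt_mid = np.frombuffer(
            _NT61[idx].tobytes(), dtype=f"S{3 * length}"
        ).astype(str)
        aa_mid = np.frombuffer(
            _AA61[idx].tobytes(), dtype=f"S{length}"
        ).astype(str)
        nt[rows] = np.char.add(np.char.add("TGT", nt_mid), "TGG")
        aa[rows] = np.char.add(np.char.add("C", aa_mid), "W")
    return nt, aa


def _weighted_choice(rng, pool: dict[str, float], n: int) -> np.ndarray:
    names = np.array(list(pool), dtype=object)
    w = np.fromiter(pool.values(), dtype=float)
    return names[rng.choice(len(names), size=n, p=w / w.sum())]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_sta_mixture() -> dict[str, float]:
    # IGHG1 at 0.38 so that folds 38 (total) / 51 (IGHG1) put the TCMR IGHG1
    # share at 0.51 — more than half of all reads, the expansion signature;
    # the remaining STA mass stays IGHM/IGHD/light-weighted.
    return {
        "IGHA1": 0.05, "IGHA2": 0.02, "IGHD": 0.05, "IGHE": 0.005,
        "IGHG1": 0.38, "IGHG2": 0.04, "IGHG3": 0.02, "IGHG4": 0.015,
        "IGHM": 0.14, "IGK": 0.18, "IGL": 0.10,
    }


def _default_b_mixture() -> dict[str, float]:
    # naive/memory B cells: IgM/IgD-dominated surface repertoire
    return {
        "IGHA1": 0.03, "IGHA2": 0.0, "IGHD": 0.15, "IGHE": 0.01,
        "IGHG1": 0.04, "IGHG2": 0.0, "IGHG3": 0.0, "IGHG4": 0.0,
        "IGHM": 0.42, "IGK": 0.25, "IGL": 0.10,
    }


@dataclass
class SingleCellConfig:
    """Barcoded single-cell sample: cell counts and read concentration."""

    n_naive_b: int = 993
    n_memory_b: int = 620
    n_plasma: int = 76
    read_ratio: float = 182.0          # pooled plasma reads / pooled B reads
    b_extra_reads: float = 0.2         # B-cell reads = 1 + Poisson(this)
    plasma_clonotypes_per_cell: float = 10.0
    plasma_read_cv: float = 0.25       # gamma CV of per-plasma-cell read totals
    plasma_heavy_share: float = 0.89   # heavy-chain fraction of plasma reads
    plasma_ighg_share: float = 0.68    # IGHG fraction of plasma heavy reads
    plasma_ighg1_share: float = 0.919  # IGHG1 fraction of plasma IGHG reads
    b_mixture: dict = field(default_factory=_default_b_mixture)

    def plasma_mixture(self) -> dict[str, float]:
        """Full 11-category mixture implied by the share parameters."""
        heavy = self.plasma_heavy_share
        light = 1.0 - heavy
        ighg = heavy * self.plasma_ighg_share
        other = heavy - ighg
        g1 = ighg * self.plasma_ighg1_share
        g_rest = ighg - g1
        mix = {
            "IGK": light * 0.65, "IGL": light * 0.35,
            "IGHG1": g1, "IGHG2": g_rest * 0.6, "IGHG3": g_rest * 0.3,
            "IGHG4": g_rest * 0.1,
            "IGHA1": other * 0.28, "IGHA2": other * 0.07,
            "IGHM": other * 0.45, "IGHD": other * 0.17, "IGHE": other * 0.03,
        }
        return {cat: mix[cat] for cat in MIXTURE_CATEGORIES}


@dataclass
class ExpressionImplant:
    """One gene built to hit target correlations with the IGHG metrics."""

    gene: str
    r_abundance: float = 0.891
    r_cpk: float = -0.703
    group_effect: float = 0.0  # extra TCMR mean shift, in noise-SD units


@dataclass
class ExpressionConfig:
    n_genes: int = 200                 # null genes beside the implants
    noise_scale: float = 1.0
    implants: list = field(
        default_factory=lambda: [ExpressionImplant(gene="MEI1")]
    )


@dataclass
class SurvivalConfig:
    n: int = 282
    baseline_rate: float = 0.15        # exponential baseline hazard (1/month)
    hazard_ratios: dict = field(
        default_factory=lambda: {"gene": 2.421, "rejection": 1.8}
    )
    censoring_fraction: float = 0.4    # target fraction censored


@dataclass
class SyntheticConfig:
    """All generator effect sizes, mixtures and the master seed."""

    seed: int = 0
    n_tcmr: int = 18
    n_sta: int = 16
    sta_mean_clonotypes: float = 100.0    # Poisson mean per STA sample
    # clone-size model: reads per clonotype are 1 + NB. TCMR clones are
    # larger (lower CPK — the clonal-expansion signature), and the per-sample
    # mean varies lognormally so abundance and CPK are anticorrelated across
    # the cohort without being collinear with the group label.
    clone_size_mean_sta: float = 2.5
    clone_size_mean_tcmr: float = 5.0
    clone_size_sample_sigma: float = 0.35  # lognormal sd of per-sample mean
    clone_size_dispersion: float = 0.3     # NB shape of the heavy right tail
    total_abundance_fold: float = 38.0    # TCMR/STA expansion multiplier
    isotype_folds: dict = field(default_factory=lambda: {"IGHG1": 51.0})
    isotype_mixture_sta: dict = field(default_factory=_default_sta_mixture)
    infiltration_plasma_corr: float = 0.8
    single_cell: SingleCellConfig = field(default_factory=SingleCellConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, mix in [
            ("isotype_mixture_sta", self.isotype_mixture_sta),
            ("single_cell.b_mixture", self.single_cell.b_mixture),
            ("single_cell.plasma_mixture", self.single_cell.plasma_mixture()),
        ]:
            _check_mixture(mix, name)
        if self.total_abundance_fold <= 0:
            raise ConfigError("total_abundance_fold must be > 0")
        if any(f <= 0 for f in self.isotype_folds.values()):
            raise ConfigError("isotype folds must be > 0")
        _check_mixture(self.tcmr_mixture(), "derived TCMR mixture")
        if not 0 <= self.survival.censoring_fraction < 1:
            raise ConfigError("censoring_fraction must be in [0, 1)")
        for imp in self.expression.implants:
            for r in (imp.r_abundance, imp.r_cpk):
                if not -1 < r < 1:
                    raise ConfigError(
                        f"implant target correlation {r} outside (-1, 1)"
                    )

    def tcmr_mixture(self) -> dict[str, float]:
        """TCMR mixture implied by the STA mixture and the fold structure.

        A category with an explicit isotype fold f gets TCMR weight
        w_sta * f / F (F = total fold); the remaining mass is spread over the
        unspecified categories proportionally to their STA weights, so every
        category's effective fold is positive and the total fold is exactly F.
        """
        F = self.total_abundance_fold
        sta = self.isotype_mixture_sta
        spec_mass = 0.0
        tcmr = {}
        for cat, f in self.isotype_folds.items():
            tcmr[cat] = sta[cat] * f / F
            spec_mass += sta[cat]
        specified_total = sum(tcmr.values())
        if specified_total > 1.0:
            raise ConfigError(
                "isotype folds imply a TCMR mixture mass above 1; lower the "
                "per-isotype folds or raise the total fold"
            )
        rest_sta = 1.0 - spec_mass
        rest_tcmr = 1.0 - specified_total
        for cat in MIXTURE_CATEGORIES:
            if cat not in tcmr:
                tcmr[cat] = sta[cat] * rest_tcmr / rest_sta
        return {cat: tcmr[cat] for cat in MIXTURE_CATEGORIES}

    def effective_isotype_folds(self) -> dict[str, float]:
        """Per-category abundance fold implied by the mixtures and F."""
        tcmr = self.tcmr_mixture()
        sta = self.isotype_mixture_sta
        return {
            cat: self.total_abundance_fold * tcmr[cat] / sta[cat]
            for cat in MIXTURE_CATEGORIES if sta[cat] > 0
        }


def _check_mixture(mix: dict[str, float], name: str) -> None:
    missing = set(MIXTURE_CATEGORIES) - set(mix)
    if missing:
        raise ConfigError(f"{name}: missing categories {sorted(missing)}")
    vals = np.array([mix[c] for c in MIXTURE_CATEGORIES], dtype=float)
    if (vals < 0).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-8):
        raise ConfigError(f"{name}: weights must be >=0 and sum to 1")


# ---------------------------------------------------------------------------
# record assembly shared by bulk and single-cell generation
# ---------------------------------------------------------------------------

def _assemble_records(
    rng: np.random.Generator,
    categories: np.ndarray,
    read_counts: np.ndarray,
    barcodes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build a clonotype frame from mixture categories and read counts."""
    n = len(categories)
    cdr3_nt, cdr3_aa = _random_cdr3(rng, n)
    v_call = np.empty(n, dtype=object)
    j_call = np.empty(n, dtype=object)
    c_call = np.empty(n, dtype=object)
    is_k = categories == "IGK"
    is_l = categories == "IGL"
    heavy = ~(is_k | is_l)
    for mask, vpool, jpool, const in [
        (heavy, IGHV_POOL, IGHJ_POOL, None),
        (is_k, IGKV_POOL, IGKJ_POOL, "IGKC"),
        (is_l, IGLV_POOL, IGLJ_POOL, "IGLC"),
    ]:
        m = int(mask.sum())
        if not m:
            continue
        v_call[mask] = _weighted_choice(rng, vpool, m)
        j_call[mask] = _weighted_choice(rng, jpool, m)
        c_call[mask] = categories[mask] if const is None else const
    # random allele suffixes exercise allele trimming downstream
    alleles = np.where(rng.random(n) < 0.3, "*02", "*01")
    v_call = np.char.add(v_call.astype(str), alleles)
    return pd.DataFrame({
        "cdr3_nt": cdr3_nt, "cdr3_aa": cdr3_aa,
        "v_call": v_call, "d_call": "", "j_call": j_call.astype(str),
        "c_call": c_call.astype(str),
        "read_count": read_counts.astype(np.int64),
        "cell_barcode": "" if barcodes is None else barcodes,
    })


def _clone_sizes(rng, mean: float, dispersion: float, n: int) -> np.ndarray:
    """1 + negative binomial: heavy right tail so top bins are occupied."""
    extra_mean = max(mean - 1.0, 1e-6)
    p = dispersion / (dispersion + extra_mean)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_repertoire_cohort(
    config: SyntheticConfig,
) -> tuple[list[RepertoireSample], dict]:
    """Generate the bulk cohort (n_tcmr TCMR + n_sta STA samples).

    Per sample the clonotype count is Poisson with the group's mean (STA mean
    scaled by the expansion fold for TCMR), so the expected TCMR/STA ratio of
    clonotype counts — absolute abundance in the repertoire sense — equals
    ``total_abundance_fold``, with per-category deviations encoded by
    ``isotype_folds`` through the group mixtures. Clone sizes are
    negative-binomial around a per-sample lognormal mean that is larger in
    TCMR, so CPK drops where abundance rises. Returns the samples plus a
    ground-truth record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mixtures = {
        "TCMR": config.tcmr_mixture(), "STA": config.isotype_mixture_sta,
    }
    samples = []
    plan = [("TCMR", i + 1) for i in range(config.n_tcmr)]
    plan += [("STA", i + 1) for i in range(config.n_sta)]
    for group, i in plan:
        lam = config.sta_mean_clonotypes
        size_mean = config.clone_size_mean_sta
        if group == "TCMR":
            lam *= config.total_abundance_fold
            size_mean = config.clone_size_mean_tcmr
        n = int(rng.poisson(lam))
        mix = mixtures[group]
        p = np.array([mix[c] for c in MIXTURE_CATEGORIES])
        cats = np.array(MIXTURE_CATEGORIES, dtype=object)[
            rng.choice(len(MIXTURE_CATEGORIES), size=n, p=p)
        ]
        sample_mean = max(
            1.05,
            size_mean * math.exp(
                rng.normal(0.0, config.clone_size_sample_sigma)
            ),
        )
        sizes = _clone_sizes(rng, sample_mean, config.clone_size_dispersion, n)
        frame = _assemble_records(rng, cats, sizes)
        samples.append(RepertoireSample.from_frame(
            frame, sample_id=f"{group}{i:02d}", group=group, modality="bulk",
        ))
    truth = {
        "total_abundance_fold": config.total_abundance_fold,
        "isotype_folds": config.effective_isotype_folds(),
        "mixtures": mixtures,
        "sta_mean_clonotypes": config.sta_mean_clonotypes,
        "clone_size_means": {
            "TCMR": config.clone_size_mean_tcmr,
            "STA": config.clone_size_mean_sta,
        },
    }
    return samples, truth


def generate_single_cell(
    config: SyntheticConfig,
) -> tuple[RepertoireSample, "pd.DataFrame", dict]:
    """Generate one barcoded rejection sample plus its cell-type annotation.

    B cells carry one clonotype with ~1 read; each plasma cell carries
    several clonotypes whose summed reads are drawn so the expected pooled
    plasma:B read ratio equals ``read_ratio``, with isotypes from the plasma
    mixture. Returns (sample, annotation table, ground truth).
    """
    config.validate()
    sc = config.single_cell
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n_b = sc.n_naive_b + sc.n_memory_b
    cell_types = (
        ["naive B"] * sc.n_naive_b + ["memory B"] * sc.n_memory_b
        + ["plasma"] * sc.n_plasma
    )
    barcodes = [f"BC{i:06d}" for i in range(len(cell_types))]
    annotation = pd.DataFrame({
        "cell_id": barcodes, "cell_type": cell_types,
        "sample_id": "SC01", "group": "TCMR",
    })

    frames = []
    b_mix = np.array([sc.b_mixture[c] for c in MIXTURE_CATEGORIES])
    if n_b:
        b_reads = 1 + rng.poisson(sc.b_extra_reads, size=n_b)
        cats = np.array(MIXTURE_CATEGORIES, dtype=object)[
            rng.choice(len(MIXTURE_CATEGORIES), size=n_b, p=b_mix)
        ]
        frames.append(_assemble_records(
            rng, cats, b_reads, barcodes=np.array(barcodes[:n_b], dtype=object),
        ))

    if sc.n_plasma:
        expected_b_total = n_b * (1.0 + sc.b_extra_reads)
        mean_reads = sc.read_ratio * expected_b_total / sc.n_plasma
        cv = sc.plasma_read_cv
        shape = 1.0 / cv**2
        totals = np.maximum(
            1, rng.gamma(shape, mean_reads / shape, size=sc.n_plasma).round()
        ).astype(np.int64)
        p_mix = sc.plasma_mixture()
        p = np.array([p_mix[c] for c in MIXTURE_CATEGORIES])
        cell_frames = []
        for cell_i, total in enumerate(totals):
            k = 1 + int(rng.poisson(max(sc.plasma_clonotypes_per_cell - 1, 0)))
            k = min(k, int(total))
            # every clonotype gets >=1 read; the rest spread evenly
            sizes = 1 + rng.multinomial(int(total) - k, np.full(k, 1.0 / k))
            cats = np.array(MIXTURE_CATEGORIES, dtype=object)[
                rng.choice(len(MIXTURE_CATEGORIES), size=k, p=p)
            ]
            bc = np.full(k, barcodes[n_b + cell_i], dtype=object)
            cell_frames.append(_assemble_records(rng, cats, sizes, barcodes=bc))
        frames.extend(cell_frames)

    frame = (
        pd.concat(frames, ignore_index=True) if frames
        else pd.DataFrame(columns=[
            "cdr3_nt", "cdr3_aa", "v_call", "d_call", "j_call", "c_call",
            "read_count", "cell_barcode",
        ])
    )
    sample = RepertoireSample.from_frame(
        frame, sample_id="SC01", group="TCMR", modality="single_cell",
    )
    truth = {
        "read_ratio": sc.read_ratio,
        "plasma_mixture": sc.plasma_mixture(),
        "plasma_heavy_share": sc.plasma_heavy_share,
        "plasma_ighg_share": sc.plasma_ighg_share,
        "plasma_ighg1_share": sc.plasma_ighg1_share,
        "cell_counts": {
            "naive B": sc.n_naive_b, "memory B": sc.n_memory_b,
            "plasma": sc.n_plasma,
        },
    }
    return sample, annotation, truth


def _exact_implant(
    rng: np.random.Generator,
    targets: np.ndarray,    # target correlations with each metric column
    Z: np.ndarray,          # n x k standardized metric matrix
) -> np.ndarray:
    """Gene vector whose in-sample correlation with each column of Z equals
    the target exactly.

    Solves the k-metric linear construction y = Z b + sigma * eps with
    b = R^-1 t (R the empirical metric correlation matrix) and
    sigma^2 = 1 - t' R^-1 t, with eps residualized against [1, Z] and
    rescaled to unit sample variance; infeasible targets (sigma^2 <= 0,
    i.e. the implied correlation matrix is not positive definite) raise.
    """
    n, k = Z.shape
    R = (Z.T @ Z) / n
    b = np.linalg.solve(R, targets)
    sigma2 = 1.0 - float(targets @ b)
    if sigma2 <= 0:
        raise ConfigError(
            f"implant targets {targets.tolist()} infeasible given the metric "
            f"correlation structure (implied residual variance {sigma2:.4f})"
        )
    eps = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), Z])
    eps = eps - X @ np.linalg.lstsq(X, eps, rcond=None)[0]
    eps = eps / eps.std()
    return Z @ b + math.sqrt(sigma2) * eps


def _standardize(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ConfigError(f"{what} is constant; cannot implant correlations")
    return (x - x.mean()) / sd


def generate_expression(
    config: SyntheticConfig,
    summaries: list[RepertoireSummary],
) -> tuple[pd.DataFrame, dict]:
    """Expression matrix (genes x samples) with implanted candidate genes.

    Null genes are independent standard normals. Each implant is built with
    the two-metric linear construction against the per-sample IGHG clonotype
    abundance and IGHG CPK so its sample correlations equal the targets
    exactly; a requested ``group_effect`` adds a TCMR mean shift afterwards
    (at the cost of that exactness).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    ids = [s.sample_id for s in summaries]
    abundance = np.array([s.metric("IGHG", "abundance") for s in summaries])
    cpk = np.array([s.metric("IGHG", "cpk") for s in summaries])
    if np.isnan(cpk).any():
        raise ConfigError("IGHG CPK undefined for some samples")
    Z = np.column_stack([
        _standardize(abundance, "IGHG abundance"),
        _standardize(cpk, "IGHG CPK"),
    ])
    is_tcmr = np.array([s.group == "TCMR" for s in summaries], dtype=float)

    n = len(ids)
    ecfg = config.expression
    names = [f"GENE{i:04d}" for i in range(ecfg.n_genes)]
    values = rng.standard_normal((ecfg.n_genes, n)) * ecfg.noise_scale
    expr = pd.DataFrame(values, index=names, columns=ids)
    implant_truth = []
    for imp in ecfg.implants:
        t = np.array([imp.r_abundance, imp.r_cpk])
        y = _exact_implant(rng, t, Z)
        if imp.group_effect:
            y = y + imp.group_effect * is_tcmr
        expr.loc[imp.gene] = y * ecfg.noise_scale
        implant_truth.append({
            "gene": imp.gene, "r_abundance": imp.r_abundance,
            "r_cpk": imp.r_cpk, "group_effect": imp.group_effect,
        })
    truth = {
        "implants": implant_truth, "n_null_genes": ecfg.n_genes,
        "metric_correlation": float(np.mean(Z[:, 0] * Z[:, 1])),
    }
    return expr, truth


def generate_infiltration(
    config: SyntheticConfig,
    summaries: list[RepertoireSummary],
) -> tuple[pd.DataFrame, dict]:
    """Per-sample infiltration scores (samples x cell types, all >= 0).

    The plasma score is implanted to correlate with IGHG read abundance at
    ``infiltration_plasma_corr`` (exact in-sample); naive/memory B scores are
    independent noise. Scores are shifted to be non-negative, which leaves
    Pearson correlations untouched.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    ids = [s.sample_id for s in summaries]
    ighg_reads = np.array([s.metric("IGHG", "reads") for s in summaries])
    z = _standardize(ighg_reads, "IGHG reads")[:, None]
    target = config.infiltration_plasma_corr
    plasma = _exact_implant(rng, np.array([target]), z)
    scores = pd.DataFrame({
        "naive B": rng.standard_normal(len(ids)),
        "memory B": rng.standard_normal(len(ids)),
        "plasma": plasma,
    }, index=pd.Index(ids, name="sample_id"))
    scores = scores - scores.min(axis=0)
    return scores, {"plasma_ighg_corr": target}


def generate_survival(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Proportional-hazards survival data with calibrated uniform censoring.

    Exponential baseline; the hazard is multiplied by exp(beta.x) with one
    continuous standard-normal covariate ("gene") and one binary covariate
    ("rejection"), each with its configured true hazard ratio. Censoring
    times are Uniform(0, u) with u solved so the expected censored fraction
    matches the config; censoring_fraction = 0 observes every event.
    """
    config.validate()
    scfg = config.survival
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    n = scfg.n
    covs = {
        "gene": rng.standard_normal(n),
        "rejection": rng.binomial(1, 0.5, n).astype(float),
    }
    eta = np.zeros(n)
    for name, hr in scfg.hazard_ratios.items():
        eta += math.log(hr) * covs[name]
    theta = scfg.baseline_rate * np.exp(eta)
    T = rng.exponential(1.0 / theta)
    if scfg.censoring_fraction == 0:
        time, event, u = T, np.ones(n, dtype=int), math.inf
    else:
        def censored_fraction(u: float) -> float:
            tu = theta * u
            p_event = 1.0 - (1.0 - np.exp(-tu)) / tu
            return float(1.0 - p_event.mean())

        u = brentq(
            lambda x: censored_fraction(x) - scfg.censoring_fraction,
            1e-6, 1e8,
        )
        C = rng.uniform(0, u, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    records = pd.DataFrame({
        "sample_id": [f"KT{i + 1:03d}" for i in range(n)],
        "time": time, "event": event, **covs,
    })
    truth = {
        "hazard_ratios": dict(scfg.hazard_ratios),
        "baseline_rate": scfg.baseline_rate,
        "censoring_upper": u,
        "target_censoring_fraction": scfg.censoring_fraction,
    }
    return records, truth


# ---------------------------------------------------------------------------
# end-to-end fixture writer
# ---------------------------------------------------------------------------

def write_fixture(config: SyntheticConfig, outdir) -> dict:
    """Write a complete end-to-end fixture: per-sample AIRR TSVs, sample
    sheet, single-cell AIRR + annotation, expression, infiltration and
    survival tables, plus a machine-readable ground-truth manifest.

    Returns the manifest (also written to ``ground_truth.json``).
    """
    from .stats import summarize

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples, truth_bulk = generate_repertoire_cohort(config)
    sheet = []
    for s in samples:
        write_airr(s, outdir / f"{s.sample_id}.airr.tsv")
        sheet.append({
            "sample_id": s.sample_id, "group": s.group,
            "path": f"{s.sample_id}.airr.tsv",
        })
    pd.DataFrame(sheet).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)

    sc_sample, annotation, truth_sc = generate_single_cell(config)
    write_airr(sc_sample, outdir / "single_cell.airr.tsv")
    annotation.to_csv(outdir / "cell_annotation.tsv", sep="\t", index=False)

    summaries = [summarize(s) for s in samples]
    expr, truth_expr = generate_expression(config, summaries)
    expr.round(6).to_csv(outdir / "expression.tsv", sep="\t")
    scores, truth_inf = generate_infiltration(config, summaries)
    scores.round(6).to_csv(outdir / "infiltration.tsv", sep="\t")
    surv, truth_surv = generate_survival(config)
    surv.round(6).to_csv(outdir / "survival.csv", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "bulk": truth_bulk, "single_cell": truth_sc,
        "expression": truth_expr, "infiltration": truth_inf,
        "survival": truth_surv,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
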