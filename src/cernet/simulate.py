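"""Synthetic cohorts with planted ceRNA structure.

The generator emulates the statistical structure the inference pipeline
assumes, with a known answer key at every stage:

* a bipartite miRNA-target incidence in which planted lncRNA-mRNA pairs
  (or a whole planted biclique module) are forced to share a controlled
  fraction of their miRNA sets, while all other overlap is by chance;
* log2-scale Gaussian expression in which each planted pair (or module)
  loads on a shared latent per-sample factor calibrated so the expected
  Pearson correlation equals ``pair_correlation``;
* exponential proportional-hazards survival whose hazard depends on the
  standardized expression of planted risk genes, with independent
  censoring tuned to the requested censoring rate.

Every stage draws from a generator seeded by (config.seed, stage index),
so identical configs give byte-identical cohorts and toggling one stage
does not shift another's randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .interactions import InteractionSet, interaction_set_from_frame, load_interactions, write_interactions
from .coexpression import load_expression, write_expression
from .survival import check_clinical, load_clinical

_STAGE_INTERACTIONS = 1
_STAGE_EXPRESSION = 2
_STAGE_SURVIVAL = 3
_STAGE_SPLIT = 4

#: Baseline log2 expression level the array-like intensities fluctuate around.
_BASELINE_LOG2 = 6.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a mid-sized tumour expression cohort: 422 patients, a
    modest transcript panel, planted competing pairs sharing 80% of their
    miRNA sites with target co-expression r = 0.9, one planted risk gene
    with log hazard ratio 0.7 per SD of expression, exponential baseline
    hazard 0.055 per month (mean survival ~18 months) and ~12% censoring.
    """

    n_mirnas: int = 150
    n_lncrnas: int = 30
    n_mrnas: int = 100
    n_samples: int = 422
    mirnas_per_lncrna: tuple[int, int] = (8, 15)
    mirnas_per_mrna: tuple[int, int] = (8, 15)
    n_true_pairs: int = 6
    shared_fraction: float = 0.8
    pair_correlation: float = 0.9
    noise_sd: float = 1.0
    n_risk_genes: int = 1
    risk_log_hazards: tuple[float, ...] = (0.7,)
    censoring_rate: float = 0.12
    baseline_hazard: float = 0.055
    seed: int = 0
    #: Optional planted complete module (n lncRNAs, n mRNAs); its cross
    #: pairs count toward n_true_pairs.
    planted_biclique: tuple[int, int] | None = None
    #: Additive batch offset hook; defaults off (no batch structure).
    batch_offset: float = 0.0

    def __post_init__(self) -> None:
        counts = {
            "n_mirnas": self.n_mirnas,
            "n_lncrnas": self.n_lncrnas,
            "n_mrnas": self.n_mrnas,
            "n_samples": self.n_samples,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name, rng_ in (
            ("mirnas_per_lncrna", self.mirnas_per_lncrna),
            ("mirnas_per_mrna", self.mirnas_per_mrna),
        ):
            lo, hi = rng_
            if not 1 <= lo <= hi:
                raise ValueError(f"{name} range invalid: {rng_}")
            if hi > self.n_mirnas:
                raise ValueError(f"{name} upper bound exceeds n_mirnas")
        if self.n_true_pairs < 0 or self.n_true_pairs > self.n_lncrnas * self.n_mrnas:
            raise ValueError("n_true_pairs must be in [0, n_lncrnas * n_mrnas]")
        if not 0 < self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in (0, 1]")
        if not 0 < self.pair_correlation < 1:
            raise ValueError("pair_correlation must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_risk_genes < 0:
            raise ValueError("n_risk_genes must be >= 0")
        if len(self.risk_log_hazards) != self.n_risk_genes:
            raise ValueError("risk_log_hazards must have n_risk_genes entries")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.planted_biclique is not None:
            a, b = self.planted_biclique
            if a < 1 or b < 1 or a > self.n_lncrnas or b > self.n_mrnas:
                raise ValueError("planted_biclique sizes out of range")


@dataclass(frozen=True)
class SyntheticCohort:
    """Interactions, expression, clinical and truth tables for one cohort."""

    config: SimulationConfig
    interactions: InteractionSet
    lnc_expression: pd.DataFrame
    mrna_expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        samples = list(self.lnc_expression.columns)
        if list(self.mrna_expression.columns) != samples:
            raise ValueError("expression matrices disagree on sample ids/order")
        if list(self.clinical["sample_id"]) != samples:
            raise ValueError("clinical sample ids differ from expression columns")


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def planted_groups(config: SimulationConfig) -> list[tuple[list[str], list[str]]]:
    """Planted units: an optional biclique module plus singleton pairs.

    Each unit is (lncRNA ids, mRNA ids); every cross pair of a unit is a
    planted true ceRNA pair.  Singleton pairs use genes disjoint from the
    module and from each other.
    """
    lncs = _gene_ids("LNC", config.n_lncrnas)
    mrnas = _gene_ids("MRNA", config.n_mrnas)
    groups: list[tuple[list[str], list[str]]] = []
    li = mi = 0
    n_needed = config.n_true_pairs
    if config.planted_biclique is not None:
        a, b = config.planted_biclique
        groups.append((lncs[:a], mrnas[:b]))
        li, mi = a, b
        n_needed -= a * b
    while n_needed > 0:
        if li >= config.n_lncrnas or mi >= config.n_mrnas:
            raise ValueError("not enough genes to plant the requested pairs disjointly")
        groups.append(([lncs[li]], [mrnas[mi]]))
        li += 1
        mi += 1
        n_needed -= 1
    return groups


def true_pairs(config: SimulationConfig) -> list[tuple[str, str]]:
    """All planted (lncRNA, mRNA) pairs implied by the planted groups."""
    out = []
    for ls, ms in planted_groups(config):
        out.extend((l, m) for l in ls for m in ms)
    return out


def simulate_interactions(config: SimulationConfig) -> InteractionSet:
    """Bipartite miRNA-target sets with forced overlap in planted units.

    Every gene receives a miRNA set of uniformly drawn size within its class
    range; within each planted unit a common core of
    ceil(shared_fraction * smallest set size) miRNAs is forced into every
    member's set, so each planted pair shares at least that core.
    """
    rng = _rng(config, _STAGE_INTERACTIONS)
    mirnas = np.array(_gene_ids("MIR", config.n_mirnas))
    lncs = _gene_ids("LNC", config.n_lncrnas)
    mrnas = _gene_ids("MRNA", config.n_mrnas)
    sizes: dict[str, int] = {}
    for g in lncs:
        sizes[g] = int(rng.integers(config.mirnas_per_lncrna[0], config.mirnas_per_lncrna[1] + 1))
    for g in mrnas:
        sizes[g] = int(rng.integers(config.mirnas_per_mrna[0], config.mirnas_per_mrna[1] + 1))
    sets: dict[str, set] = {
        g: set(rng.choice(mirnas, size=sizes[g], replace=False)) for g in lncs + mrnas
    }
    for ls, ms in planted_groups(config):
        members = ls + ms
        core_size = math.ceil(config.shared_fraction * min(sizes[g] for g in members))
        if core_size > min(sizes[g] for g in members):
            raise ValueError("shared_fraction exceeds what the drawn set sizes allow")
        core = set(rng.choice(mirnas, size=core_size, replace=False))
        for g in members:
            extra = sizes[g] - core_size
            pool = np.array(sorted(set(mirnas) - core))
            others = set(rng.choice(pool, size=extra, replace=False)) if extra else set()
            sets[g] = core | others
    rows = []
    for g in lncs:
        rows.extend((m, g, "lncRNA", "supported") for m in sorted(sets[g]))
    for g in mrnas:
        rows.extend((m, g, "mRNA", "supported") for m in sorted(sets[g]))
    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "gene_class", "evidence"])
    return interaction_set_from_frame(table)


def simulate_expression(
    config: SimulationConfig, interactions: InteractionSet
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log2-scale Gaussian expression with planted positive co-expression.

    Genes of a planted unit share a latent per-sample factor z ~ N(0,1):

        expr = mu + z + noise_sd * sqrt((1-rho)/rho) * eps

    so at the default noise_sd = 1 the expected Pearson correlation of any
    two unit members is exactly ``pair_correlation`` (rho), and noise_sd = 0
    gives r = 1.  All other genes are independent with the same total
    variance.  Returns (lncRNA matrix, mRNA matrix, truth table).
    """
    rng = _rng(config, _STAGE_EXPRESSION)
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    lncs = interactions.genes("lncRNA")
    mrnas = interactions.genes("mRNA")
    rho = config.pair_correlation
    noise_scale = config.noise_sd * math.sqrt((1 - rho) / rho)
    total_sd = math.sqrt(1 + noise_scale**2)
    groups = planted_groups(config)
    for ls, ms in groups:
        for g in ls + ms:
            if g not in lncs and g not in mrnas:
                raise ValueError(f"planted gene {g!r} absent from interactions")

    def gene_matrix(genes: list[str], latent: dict[str, np.ndarray]) -> pd.DataFrame:
        data = np.empty((len(genes), config.n_samples))
        for i, g in enumerate(genes):
            mu = _BASELINE_LOG2 + rng.normal(0, 1)
            if g in latent:
                data[i] = mu + latent[g] + noise_scale * rng.normal(0, 1, config.n_samples)
            else:
                data[i] = mu + total_sd * rng.normal(0, 1, config.n_samples)
        out = pd.DataFrame(data, index=genes, columns=samples)
        out.index.name = "gene_id"
        return out

    latent: dict[str, np.ndarray] = {}
    for ls, ms in groups:
        z = rng.normal(0, 1, config.n_samples)
        for g in ls + ms:
            latent[g] = z
    lnc_expr = gene_matrix(lncs, latent)
    mrna_expr = gene_matrix(mrnas, latent)
    if config.batch_offset:
        half = config.n_samples // 2
        lnc_expr.iloc[:, half:] += config.batch_offset
        mrna_expr.iloc[:, half:] += config.batch_offset

    risk_genes = select_risk_genes(config)
    truth_rows = [
        (f"{l}|{m}", "cerna_pair", f"shared_fraction={config.shared_fraction};r={rho}")
        for l, m in true_pairs(config)
    ]
    truth_rows += [
        (g, "risk_gene", f"log_hazard={beta}")
        for g, beta in zip(risk_genes, config.risk_log_hazards)
    ]
    truth = pd.DataFrame(truth_rows, columns=["pair_or_gene", "role", "effect"])
    return lnc_expr, mrna_expr, truth


def select_risk_genes(config: SimulationConfig) -> list[str]:
    """Planted risk genes: module/pair mRNAs first, then remaining mRNAs."""
    mrnas = _gene_ids("MRNA", config.n_mrnas)
    preferred = []
    for _, ms in planted_groups(config):
        preferred.extend(m for m in ms if m not in preferred)
    pool = preferred + [m for m in mrnas if m not in preferred]
    return pool[: config.n_risk_genes]


def simulate_survival(
    config: SimulationConfig,
    lnc_expression: pd.DataFrame,
    mrna_expression: pd.DataFrame,
    risk_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival with planted gene effects.

    hazard_i = baseline_hazard * exp(sum_j beta_j * z_ij) with z the
    gene-wise standardized expression of the risk genes.  Censoring times
    are exponential with a rate calibrated (by bisection) so the expected
    fraction censored matches ``censoring_rate``.
    """
    rng = _rng(config, _STAGE_SURVIVAL)
    if risk_genes is None:
        risk_genes = select_risk_genes(config)
    expr = pd.concat([lnc_expression, mrna_expression])
    missing = [g for g in risk_genes if g not in expr.index]
    if missing:
        raise ValueError(f"risk genes absent from expression: {missing}")
    samples = list(lnc_expression.columns)
    lp = np.zeros(len(samples))
    for g, beta in zip(risk_genes, config.risk_log_hazards):
        v = expr.loc[g].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"risk gene {g!r} has zero expression variance")
        lp += beta * (v - v.mean()) / sd
    hazards = config.baseline_hazard * np.exp(lp)
    event_times = rng.exponential(1.0 / hazards)
    if config.censoring_rate == 0:
        time, event = event_times, np.ones(len(samples), dtype=int)
    else:
        c = _censoring_rate_for(hazards, config.censoring_rate)
        censor_times = rng.exponential(1.0 / c, size=len(samples))
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    clinical = pd.DataFrame(
        {"sample_id": samples, "time": np.maximum(time, 1e-9), "event": event}
    )
    return check_clinical(clinical)


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+lambda_i) = target."""
    lo, hi = 1e-12, hazards.max()
    while np.mean(hi / (hi + hazards)) < target:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if np.mean(mid / (mid + hazards)) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: interactions, expression, clinical and truth tables."""
    iset = simulate_interactions(config)
    lnc_expr, mrna_expr, truth = simulate_expression(config, iset)
    clinical = simulate_survival(config, lnc_expr, mrna_expr)
    return SyntheticCohort(config, iset, lnc_expr, mrna_expr, clinical, truth)


# ---------------------------------------------------------------------------
# Cohort I/O (TSV round trip)

_FILES = {
    "interactions": "interactions.tsv",
    "lnc": "lnc_expression.tsv",
    "mrna": "mrna_expression.tsv",
    "clinical": "clinical.tsv",
    "truth": "truth.tsv",
}


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the cohort tables as TSVs; round-trips through read_cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    try:
        write_interactions(cohort.interactions, paths["interactions"])
        write_expression(cohort.lnc_expression, paths["lnc"])
        write_expression(cohort.mrna_expression, paths["mrna"])
        cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.10g")
        cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing cohort to {directory}: {exc}") from exc
    return paths


def read_cohort(directory, config: SimulationConfig | None = None) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    if config is None:
        config = SimulationConfig()
    truth = pd.read_csv(directory / _FILES["truth"], sep="\t")
    if list(truth.columns) != ["pair_or_gene", "role", "effect"]:
        raise ValueError("malformed truth table")
    return SyntheticCohort(
        config,
        load_interactions(directory / _FILES["interactions"]),
        load_expression(directory / _FILES["lnc"]),
        load_expression(directory / _FILES["mrna"]),
        load_clinical(directory / _FILES["clinical"]),
        truth,
    )
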