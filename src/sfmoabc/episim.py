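"""Penetrance-model simulator for two-locus epistasis benchmarks.

Generates case-control genotype datasets in the EpiSIM style: genotype
combinations at the functional loci are drawn under Hardy-Weinberg
equilibrium (HWE), disease status is assigned with the penetrance
probability of the drawn combination, and sampling continues until the
case and control quotas fill.  Non-functional (noise) SNPs are drawn
independently under HWE with minor-allele frequencies sampled uniformly
from a configurable range.

Twelve standard two-order disease models are built in: models 1-8 carry a
marginal single-locus effect (DME), models 9-12 are designed to act only
through the interaction (DNME) under the original simulator's allele
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_data import GenotypeDataset

__all__ = [
    "PenetranceModel",
    "SimulationSpec",
    "builtin_models",
    "genotype_probabilities",
    "prevalence",
    "sample_population",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PenetranceModel:
    """A k-order penetrance table: P(disease | genotype combination).

    ``table`` holds 3**order probabilities in mixed-radix base-3 order with
    the first locus most significant; for k=2 that is AABB, AABb, AAbb,
    AaBB, AaBb, Aabb, aaBB, aaBb, aabb (0, 1, 2 copies of the minor allele
    at locus A, then at locus B).
    """

    order: int
    table: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "table", tuple(float(p) for p in self.table))
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if len(self.table) != 3**self.order:
            raise ValueError(
                f"penetrance table needs {3**self.order} entries for order "
                f"{self.order}, got {len(self.table)}"
            )
        if any(not (0.0 <= p <= 1.0) for p in self.table):
            raise ValueError("penetrances must lie in [0, 1]")


@dataclass
class SimulationSpec:
    """Everything needed to simulate one replicated dataset family."""

    model: PenetranceModel
    mafs: tuple[float, ...] = (0.25, 0.25)
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    n_cases: int = 2000
    n_controls: int = 2000
    n_snps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.mafs = tuple(float(m) for m in self.mafs)
        if len(self.mafs) != self.model.order:
            raise ValueError(
                f"{len(self.mafs)} MAFs for a model of order {self.model.order}"
            )
        if any(not (0.0 < m <= 0.5) for m in self.mafs):
            raise ValueError("functional MAFs must lie in (0, 0.5]")
        lo, hi = self.noise_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("noise MAF range must lie within (0, 0.5]")
        if self.n_snps < self.model.order:
            raise ValueError("n_snps must be at least the model order")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("sample sizes must be nonnegative")


# Two-order penetrance tables for the 12 standard epistasis benchmark models,
# row order AABB..aabb.  Models 1-8: marginal effects present; 9-12: none
# (under the original generator's MAFs).
_MODEL_TABLES: dict[str, tuple[float, ...]] = {
    "Model 1": (0.087, 0.087, 0.087, 0.087, 0.146, 0.190, 0.087, 0.190, 0.247),
    "Model 2": (0.078, 0.078, 0.078, 0.078, 0.105, 0.122, 0.078, 0.122, 0.142),
    "Model 3": (0.009, 0.009, 0.009, 0.013, 0.006, 0.006, 0.013, 0.006, 0.006),
    "Model 4": (0.092, 0.092, 0.092, 0.092, 0.319, 0.319, 0.092, 0.319, 0.319),
    "Model 5": (0.084, 0.084, 0.084, 0.084, 0.210, 0.210, 0.084, 0.210, 0.210),
    "Model 6": (0.052, 0.052, 0.052, 0.052, 0.137, 0.137, 0.052, 0.137, 0.137),
    "Model 7": (0.072, 0.164, 0.164, 0.164, 0.072, 0.072, 0.164, 0.072, 0.072),
    "Model 8": (0.067, 0.155, 0.155, 0.155, 0.067, 0.067, 0.155, 0.067, 0.067),
    "Model 9": (0.486, 0.960, 0.538, 0.947, 0.004, 0.811, 0.640, 0.606, 0.909),
    "Model 10": (0.103, 0.063, 0.124, 0.098, 0.086, 0.069, 0.021, 0.147, 0.059),
    "Model 11": (0.000, 0.000, 0.000, 0.000, 0.050, 0.000, 0.100, 0.000, 0.000),
    "Model 12": (0.000, 0.020, 0.000, 0.020, 0.000, 0.020, 0.000, 0.020, 0.000),
}


def builtin_models() -> dict[str, PenetranceModel]:
    """The 12 standard two-order disease models, keyed by label."""
    return {
        label: PenetranceModel(order=2, table=table, label=label)
        for label, table in _MODEL_TABLES.items()
    }


def genotype_probabilities(maf: float) -> tuple[float, float, float]:
    """HWE genotype probabilities (P(0), P(1), P(2)) for allele frequency q.

    P(0) = (1-q)^2, P(1) = 2q(1-q), P(2) = q^2.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
    q = float(maf)
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)


def _joint_genotype_probs(mafs: Sequence[float]) -> np.ndarray:
    """Joint HWE probabilities over all 3^k combinations (first locus most
    significant)."""
    per_locus = [genotype_probabilities(m) for m in mafs]
    probs = np.ones(1)
    for p in per_locus:
        probs = np.outer(probs, p).ravel()
    return probs


def prevalence(model: PenetranceModel, mafs: Sequence[float]) -> float:
    """Population disease prevalence: sum_g P(g | HWE) * penetrance(g)."""
    if len(mafs) != model.order:
        raise ValueError(f"{len(mafs)} MAFs for a model of order {model.order}")
    return float(_joint_genotype_probs(mafs) @ np.asarray(model.table))


def sample_population(
    model: PenetranceModel,
    mafs: Sequence[float],
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Prospectively sample ``n`` individuals at the functional loci.

    Returns ``(genotypes, is_case)`` where genotypes is (n, order) with
    entries in {0,1,2} and is_case is a boolean vector: each individual's
    genotype combination is drawn from the HWE joint distribution and
    disease status is Bernoulli with the combination's penetrance.
    """
    probs = _joint_genotype_probs(mafs)
    codes = rng.choice(3**model.order, size=n, p=probs)
    pen = np.asarray(model.table)[codes]
    is_case = rng.random(n) < pen
    genotypes = np.empty((n, model.order), dtype=np.int8)
    rem = codes
    for j in range(model.order - 1, -1, -1):
        genotypes[:, j] = rem % 3
        rem = rem // 3
    return genotypes, is_case


def simulate_dataset(spec: SimulationSpec) -> GenotypeDataset:
    """Simulate one case-control dataset with a single embedded functional
    SNP combination.

    Functional genotypes are drawn by rejection sampling until both the
    case and the control quota fill; controls are written first.  The
    functional loci are placed at random column positions, recorded in the
    returned dataset's ``truth``.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.model.order

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    need_cases, need_controls = spec.n_cases, spec.n_controls
    batch = max(1024, 2 * (need_cases + need_controls))
    max_draws = 2000 * max(need_cases + need_controls, 1) + 100_000
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"rejection sampling exhausted after {drawn} draws; the model "
                f"(prevalence={prevalence(spec.model, spec.mafs):.3g}) cannot "
                "fill the requested case/control quotas"
            )
        g, is_case = sample_population(spec.model, spec.mafs, batch, rng)
        drawn += batch
        if need_cases > 0:
            take = g[is_case][:need_cases]
            cases.append(take)
            need_cases -= len(take)
        if need_controls > 0:
            take = g[~is_case][:need_controls]
            controls.append(take)
            need_controls -= len(take)

    func = np.concatenate(
        [np.concatenate(controls) if controls else np.empty((0, k), np.int8),
         np.concatenate(cases) if cases else np.empty((0, k), np.int8)]
    )
    n_total = spec.n_cases + spec.n_controls
    phenotype = np.concatenate(
        [np.zeros(spec.n_controls, np.int8), np.ones(spec.n_cases, np.int8)]
    )

    genotypes = np.empty((n_total, spec.n_snps), dtype=np.int8)
    lo, hi = spec.noise_maf_range
    noise_mafs = rng.uniform(lo, hi, size=spec.n_snps - k)
    func_cols = np.sort(rng.choice(spec.n_snps, size=k, replace=False))
    noise_cols = np.setdiff1d(np.arange(spec.n_snps), func_cols)
    genotypes[:, func_cols] = func
    for col, maf in zip(noise_cols, noise_mafs):
        p0, p1, p2 = genotype_probabilities(maf)
        genotypes[:, col] = rng.choice(3, size=n_total, p=(p0, p1, p2))

    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        snp_names=[f"SNP{i + 1}" for i in range(spec.n_snps)],
        truth=[tuple(int(c) for c in func_cols)],
    )
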