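"""Seeded Monte-Carlo simulation of hybrid crosses.

Realizes the same generative process as the closed forms in
:mod:`mitonuclear.model` — Mendelian gamete draws per locus, per-locus
fitness multiplication — and serves as an independent stochastic check on
them.  Parental individuals are homozygous for their population's matched
allele (the fixed-population regime), so gamete draws are fair coin flips
for F1-derived gametes and deterministic for parental gametes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CrossKind, ModelParams

__all__ = ["SimConfig", "SimResult", "simulate_cross", "simulate_all_crosses"]


@dataclass(frozen=True)
class SimConfig:
    params: ModelParams
    cross: CrossKind
    replicates: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


@dataclass(frozen=True)
class SimResult:
    mean_fitness: float
    std_error: float
    replicates: int


def _replicate_fitness(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-replicate organismal fitness values, shape (replicates,).

    Allele coding per locus: 0 = allele matched to the zygote's mtDNA,
    1 = mismatched allele.  An F1 individual is heterozygous everywhere, so
    each of its gametes is a fair coin flip per locus.
    """
    p = config.params
    n, reps = p.n_loci, config.replicates
    if n == 0:
        return np.ones(reps)
    kind = config.cross
    if kind is CrossKind.F1:
        # mother's gamete all matched, father's all mismatched: fixed genotype
        mismatched_copies = np.ones((reps, n), dtype=np.int8)
    elif kind is CrossKind.F2:
        g1 = rng.integers(0, 2, size=(reps, n), dtype=np.int8)
        g2 = rng.integers(0, 2, size=(reps, n), dtype=np.int8)
        mismatched_copies = g1 + g2
    elif kind is CrossKind.BC_COMPATIBLE:
        # parental gamete carries the matched allele
        mismatched_copies = rng.integers(0, 2, size=(reps, n), dtype=np.int8)
    elif kind is CrossKind.BC_PATERNAL:
        # parental gamete carries the mismatched allele
        mismatched_copies = rng.integers(0, 2, size=(reps, n), dtype=np.int8) + 1
    else:
        raise ValueError(f"unknown cross kind {kind!r}")
    w = np.array([1.0, 1.0 - p.s1, 1.0 - p.s2])
    return np.prod(w[mismatched_copies], axis=1)


def simulate_cross(config: SimConfig) -> SimResult:
    """Mean hybrid fitness (with standard error) over seeded replicates."""
    rng = np.random.default_rng(config.seed)
    fitness = _replicate_fitness(config, rng)
    reps = config.replicates
    se = float(fitness.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    if np.ptp(fitness) == 0.0:  # constant replicates (e.g. F1): exactly zero SE
        se = 0.0
    return SimResult(mean_fitness=float(fitness.mean()), std_error=se, replicates=reps)


def simulate_all_crosses(
    params: ModelParams, replicates: int = 100_000, seed: int = 0
) -> pd.DataFrame:
    """One simulated mean per cross kind, single RNG stream.

    Returns a DataFrame with columns ``cross, mean, se, reps``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for kind in CrossKind:
        config = SimConfig(params=params, cross=kind, replicates=replicates, seed=seed)
        fitness = _replicate_fitness(config, rng)
        se = (
            float(fitness.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
        )
        if np.ptp(fitness) == 0.0:
            se = 0.0
        rows.append(
            {
                "cross": kind.value,
                "mean": float(fitness.mean()),
                "se": se,
                "reps": replicates,
            }
        )
    return pd.DataFrame(rows)
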