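"""Seeded generators for every input the pipeline consumes.

Three generators with recorded ground truth:

* two-population genotype tables — Hardy-Weinberg draws within each
  population at specified per-locus allele frequencies, emulating the
  genotyped-cohort regime (two mtDNA-defined groups, biallelic loci,
  ~35 samples per side);
* variant presence matrices — i.i.d. background presence plus planted
  differentiating variants with exact (n_in, n_out) patterns, emulating a
  ten-transcriptome variant-call matrix;
* protein MSA pairs — conservation-weighted background columns plus
  planted covarying column pairs with tunable coupling.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coevolution import ProteinMSA
from .io import GenotypeTable
from .popgen import GenotypeCounts
from .screen import VariantPresenceMatrix

__all__ = [
    "GenotypeSimSpec",
    "PresenceSimSpec",
    "MSASimSpec",
    "gen_genotypes",
    "gen_presence",
    "gen_msa_pair",
    "expected_genotype_counts",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Two-population Hardy-Weinberg genotype simulation settings.

    ``freq_north[i]`` / ``freq_south[i]`` give the allele-1 frequency at
    locus i in each population; genotypes are stored as copies of
    allele 2, matching the genotype-table convention.
    """

    n_north: int
    n_south: int
    freq_north: tuple[float, ...]
    freq_south: tuple[float, ...]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_north < 1 or self.n_south < 1:
            raise ValueError("each population needs at least one sample")
        if len(self.freq_north) != len(self.freq_south):
            raise ValueError("frequency vectors must have equal length")
        for f in (*self.freq_north, *self.freq_south):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency outside [0, 1]: {f}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def gen_genotypes(spec: GenotypeSimSpec) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw a genotype table; return it with the generating frequencies.

    Each sample's genotype at a locus is Binomial(2, 1 - freq) copies of
    allele 2 (Hardy-Weinberg within population); missing entries are
    inserted independently at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n_loci = len(spec.freq_north)
    loci = [f"locus{i + 1}" for i in range(n_loci)]
    samples = [f"N{i + 1:03d}" for i in range(spec.n_north)] + [
        f"S{i + 1:03d}" for i in range(spec.n_south)
    ]
    groups = pd.Series(
        ["north"] * spec.n_north + ["south"] * spec.n_south, index=samples
    )
    geno = np.empty((len(samples), n_loci))
    for j in range(n_loci):
        geno[: spec.n_north, j] = rng.binomial(2, 1 - spec.freq_north[j], spec.n_north)
        geno[spec.n_north :, j] = rng.binomial(2, 1 - spec.freq_south[j], spec.n_south)
    if spec.missing_rate > 0:
        geno[rng.random(geno.shape) < spec.missing_rate] = np.nan
    table = GenotypeTable(
        genotypes=pd.DataFrame(geno, index=samples, columns=loci), groups=groups
    )
    truth = pd.DataFrame(
        {
            "locus": loci,
            "freq_north": spec.freq_north,
            "freq_south": spec.freq_south,
        }
    )
    return table, truth


def expected_genotype_counts(
    freq_north: float, freq_south: float, n_north: int, n_south: int, locus: str = "L"
) -> GenotypeCounts:
    """Expected Hardy-Weinberg genotype class counts for one locus.

    Real-valued counts; plugging them into the Weir-Cockerham estimator
    gives the theta implied by the generating frequencies.
    """

    def hwe(p, n):
        return (n * p * p, n * 2 * p * (1 - p), n * (1 - p) * (1 - p))

    return GenotypeCounts(
        locus=locus, north=hwe(freq_north, n_north), south=hwe(freq_south, n_south)
    )


# ---------------------------------------------------------------------------
# presence matrices


@dataclass(frozen=True)
class PresenceSimSpec:
    """Variant-presence simulation: background noise plus planted patterns.

    ``planted`` is a sequence of (n_in, n_out, direction) patterns, with
    direction 'north' or 'south' naming the enriched group; each planted
    variant is realized with exactly those presence counts.
    """

    n_north: int = 5
    n_south: int = 5
    n_background: int = 0
    p_background: float = 0.5
    planted: tuple[tuple[int, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_north < 1 or self.n_south < 1:
            raise ValueError("each group needs at least one sample")
        if not 0.0 <= self.p_background <= 1.0:
            raise ValueError("p_background must lie in [0, 1]")
        for n_in, n_out, direction in self.planted:
            if direction not in ("north", "south"):
                raise ValueError(f"unknown direction {direction!r}")
            size_in = self.n_north if direction == "north" else self.n_south
            size_out = self.n_south if direction == "north" else self.n_north
            if not (0 <= n_in <= size_in and 0 <= n_out <= size_out):
                raise ValueError(
                    f"infeasible planted pattern ({n_in}, {n_out}) for "
                    f"group sizes ({self.n_north}, {self.n_south})"
                )


def gen_presence(spec: PresenceSimSpec) -> tuple[VariantPresenceMatrix, pd.DataFrame]:
    """Draw a presence matrix; return it with planted-variant ground truth."""
    rng = np.random.default_rng(spec.seed)
    north = [f"N{i + 1}" for i in range(spec.n_north)]
    south = [f"S{i + 1}" for i in range(spec.n_south)]
    samples = north + south
    groups = pd.Series(["north"] * len(north) + ["south"] * len(south), index=samples)
    rows, ids, truth_rows = [], [], []
    for k, (n_in, n_out, direction) in enumerate(spec.planted):
        in_group, out_group = (north, south) if direction == "north" else (south, north)
        row = dict.fromkeys(samples, False)
        for s in rng.permutation(in_group)[:n_in]:
            row[s] = True
        for s in rng.permutation(out_group)[:n_out]:
            row[s] = True
        ids.append(f"planted{k + 1}")
        rows.append(row)
        truth_rows.append(
            {"variant": ids[-1], "n_in": n_in, "n_out": n_out, "direction": direction}
        )
    background = rng.random((spec.n_background, len(samples))) < spec.p_background
    for k in range(spec.n_background):
        ids.append(f"bg{k + 1}")
        rows.append(dict(zip(samples, background[k])))
    presence = pd.DataFrame(rows, index=ids, columns=samples, dtype=bool)
    matrix = VariantPresenceMatrix(presence=presence, groups=groups)
    return matrix, pd.DataFrame(
        truth_rows, columns=["variant", "n_in", "n_out", "direction"]
    )


# ---------------------------------------------------------------------------
# MSA pairs


@dataclass(frozen=True)
class MSASimSpec:
    """Paired-alignment simulation with planted covarying column pairs.

    ``conservation`` in [0, 1] is the probability that a species carries
    its column's consensus residue (otherwise a uniform residue).
    ``planted`` holds (col_a, col_b, coupling) with 0-based column indices;
    coupling is the probability a species' residue in col_b is the
    deterministic image of its residue in col_a under a random bijection.
    """

    n_species: int = 50
    len_a: int = 20
    len_b: int = 20
    conservation: float = 0.5
    planted: tuple[tuple[int, int, float], ...] = ()
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conservation", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for col_a, col_b, coupling in self.planted:
            if not (0 <= col_a < self.len_a and 0 <= col_b < self.len_b):
                raise ValueError(f"planted pair ({col_a}, {col_b}) out of range")
            if not 0.0 <= coupling <= 1.0:
                raise ValueError(f"coupling must lie in [0, 1], got {coupling}")


def _background_column(
    n_species: int, conservation: float, rng: np.random.Generator
) -> np.ndarray:
    consensus = rng.choice(AMINO_ACIDS)
    col = rng.choice(AMINO_ACIDS, size=n_species)
    col[rng.random(n_species) < conservation] = consensus
    return col


def gen_msa_pair(
    spec: MSASimSpec,
) -> tuple[ProteinMSA, ProteinMSA, pd.DataFrame]:
    """Draw two alignments over one species set with planted covariation.

    At a planted pair, column A is split between two residues (balanced
    binary states, the regime where covariation scores are most
    informative) and column B copies A through a residue bijection with
    probability ``coupling`` per species, else draws from background.
    Gaps are inserted independently at ``gap_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"sp{i + 1:03d}" for i in range(spec.n_species)]
    mat_a = np.stack(
        [
            _background_column(spec.n_species, spec.conservation, rng)
            for _ in range(spec.len_a)
        ],
        axis=1,
    )
    mat_b = np.stack(
        [
            _background_column(spec.n_species, spec.conservation, rng)
            for _ in range(spec.len_b)
        ],
        axis=1,
    )
    truth_rows = []
    for col_a, col_b, coupling in spec.planted:
        res = rng.choice(AMINO_ACIDS, size=2, replace=False)
        images = rng.choice(np.setdiff1d(AMINO_ACIDS, res), size=2, replace=False)
        states = rng.integers(0, 2, size=spec.n_species)
        mat_a[:, col_a] = res[states]
        coupled = rng.random(spec.n_species) < coupling
        mat_b[coupled, col_b] = images[states[coupled]]
        mat_b[~coupled, col_b] = rng.choice(AMINO_ACIDS, size=(~coupled).sum())
        truth_rows.append({"col_a": col_a, "col_b": col_b, "coupling": coupling})
    if spec.gap_rate > 0:
        mat_a[rng.random(mat_a.shape) < spec.gap_rate] = "-"
        mat_b[rng.random(mat_b.shape) < spec.gap_rate] = "-"
    msa_a = ProteinMSA(ids=list(ids), matrix=mat_a.astype("<U1"))
    msa_b = ProteinMSA(ids=list(ids), matrix=mat_b.astype("<U1"))
    return msa_a, msa_b, pd.DataFrame(truth_rows, columns=["col_a", "col_b", "coupling"])
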