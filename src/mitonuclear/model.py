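"""Closed-form hybrid fitness under mito-nuclear incompatibility.

Two allopatric populations (north and south) carry divergent, maternally
inherited mitochondrial genomes ``m_N`` and ``m_S``.  ``n`` unlinked nuclear
loci interact with the mitochondria; each population is fixed for the allele
matched to its own mtDNA.  Per locus, a genotype homozygous for the allele
matched to the zygote's mtDNA has fitness 1, a heterozygote pays a cost
``s1`` and a homozygote mismatched to the mtDNA pays ``s2``.  Interactions
are independent, so organismal fitness is the product of per-locus fitness.

Under these rules each hybrid cross has an exchangeable per-locus genotype
distribution, so the expected fitness is a per-locus factor raised to the
power ``n``:

====================  =============================================
cross                 per-locus factor
====================  =============================================
F1                    ``1 - s1``
F2                    ``(1 - s2)/4 + (1 - s1)/2 + 1/4``
maternal backcross    ``1 - s1/2``
paternal backcross    ``(1 - s1)/2 + (1 - s2)/2``
====================  =============================================

"Maternal backcross" covers F1 males crossed to either population and F1
females crossed to their maternal population (no mismatched homozygote can
form); "paternal backcross" is an F1 female crossed to her paternal
population (no fully matched homozygote can form).

The literal multinomial/binomial sums over locus-state counts are also
implemented and used as an internal cross-check; they are algebraically
identical to the factorized forms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ModelParams",
    "CrossKind",
    "FitnessValue",
    "PopulationAlleleProfile",
    "f1_fitness",
    "f2_fitness",
    "backcross_compatible_fitness",
    "backcross_paternal_fitness",
    "cross_fitness",
    "fitness_curves",
    "polymorphic_fitness",
]


@dataclass(frozen=True)
class ModelParams:
    """Number of interacting nuclear loci and the two selection costs.

    Parameters
    ----------
    n_loci
        Number of nuclear loci interacting with the mitochondria (>= 0).
    s1
        Fitness cost paid by a heterozygote at one locus, in [0, 1].
    s2
        Fitness cost paid by a homozygote mismatched to the zygote's
        mtDNA, in [0, 1].
    """

    n_loci: int
    s1: float
    s2: float = 0.0

    def __post_init__(self) -> None:
        if int(self.n_loci) != self.n_loci or self.n_loci < 0:
            raise ValueError(f"n_loci must be a non-negative integer, got {self.n_loci}")
        for name in ("s1", "s2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


class CrossKind(enum.Enum):
    """Hybrid cross whose expected fitness is being evaluated."""

    F1 = "F1"
    F2 = "F2"
    #: F1 male x either population, or F1 female x her maternal population.
    BC_COMPATIBLE = "BC_COMPATIBLE"
    #: F1 female x her paternal population.
    BC_PATERNAL = "BC_PATERNAL"


@dataclass(frozen=True)
class FitnessValue:
    """Expected organismal fitness together with its per-locus factor."""

    value: float
    per_locus_factor: float
    method: str = "factorized"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"fitness must lie in [0, 1], got {self.value}")


# ---------------------------------------------------------------------------
# per-locus factors

def _factor(kind: CrossKind, s1: float, s2: float) -> float:
    if kind is CrossKind.F1:
        return 1.0 - s1
    if kind is CrossKind.F2:
        return 0.25 * (1.0 - s2) + 0.5 * (1.0 - s1) + 0.25
    if kind is CrossKind.BC_COMPATIBLE:
        return 1.0 - 0.5 * s1
    if kind is CrossKind.BC_PATERNAL:
        return 0.5 * (1.0 - s1) + 0.5 * (1.0 - s2)
    raise ValueError(f"unknown cross kind {kind!r}")


def _literal_sum(kind: CrossKind, params: ModelParams) -> float:
    """The multinomial/binomial sums over per-locus state counts.

    F2 sums over (x, y, z) = (mismatched homozygotes, heterozygotes,
    matched homozygotes) with multinomial weights at gamete-union
    probabilities (1/4, 1/2, 1/4); the backcrosses are binomial over the
    two states each allows.  Exact integer coefficients keep the sums
    stable at any n.
    """
    n, s1, s2 = params.n_loci, params.s1, params.s2
    if kind is CrossKind.F1:
        return (1.0 - s1) ** n
    if kind is CrossKind.F2:
        total = 0.0
        for i in range(n + 1):  # mismatched homozygotes
            for j in range(n - i + 1):  # heterozygotes
                coeff = math.comb(n, i) * math.comb(n - i, j)
                prob = coeff * 0.25**i * 0.5**j * 0.25 ** (n - i - j)
                total += prob * (1.0 - s2) ** i * (1.0 - s1) ** j
        return total
    if kind is CrossKind.BC_COMPATIBLE:
        return sum(
            math.comb(n, i) * 0.5**n * (1.0 - s1) ** i for i in range(n + 1)
        )
    if kind is CrossKind.BC_PATERNAL:
        return sum(
            math.comb(n, i) * 0.5**n * (1.0 - s1) ** i * (1.0 - s2) ** (n - i)
            for i in range(n + 1)
        )
    raise ValueError(f"unknown cross kind {kind!r}")


def cross_fitness(
    params: ModelParams, kind: CrossKind, method: str = "factorized"
) -> FitnessValue:
    """Expected fitness of a cross, by factorized form or literal sum.

    ``method="factorized"`` raises the per-locus factor to ``n_loci``;
    ``method="closed_form_sum"`` evaluates the literal state-count sum.
    The two agree to floating-point accuracy and the factorized form is
    the default.
    """
    factor = _factor(kind, params.s1, params.s2)
    if method == "factorized":
        value = factor**params.n_loci
    elif method == "closed_form_sum":
        value = _literal_sum(kind, params)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FitnessValue(value=min(value, 1.0), per_locus_factor=factor, method=method)


def f1_fitness(params: ModelParams, method: str = "factorized") -> FitnessValue:
    """W1 = (1 - s1)^n: every locus of an F1 is heterozygous."""
    return cross_fitness(params, CrossKind.F1, method)


def f2_fitness(params: ModelParams, method: str = "factorized") -> FitnessValue:
    """W2: each F2 locus unites two independent F1 gametes (1/4, 1/2, 1/4)."""
    return cross_fitness(params, CrossKind.F2, method)


def backcross_compatible_fitness(
    params: ModelParams, method: str = "factorized"
) -> FitnessValue:
    """W3 = (1 - s1/2)^n: no mismatched homozygote is possible."""
    return cross_fitness(params, CrossKind.BC_COMPATIBLE, method)


def backcross_paternal_fitness(
    params: ModelParams, method: str = "factorized"
) -> FitnessValue:
    """W4 = [(1-s1)/2 + (1-s2)/2]^n: no fully matched homozygote is possible."""
    return cross_fitness(params, CrossKind.BC_PATERNAL, method)


def fitness_curves(n_max: int, s1: float, s2: float) -> pd.DataFrame:
    """Expected-fitness curves of all four crosses for n = 1..n_max.

    Returns a DataFrame with columns ``n, W1, W2, W3, W4``.  With the
    reference costs s1 = 0.05, s2 = 0.5 the curves preserve the ordering
    W3 >= W1 >= W2 >= W4 at every n; the ordering holds for any costs with
    s2 >= 2*s1 > 0.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    rows = []
    for n in range(1, n_max + 1):
        p = ModelParams(n_loci=n, s1=s1, s2=s2)
        rows.append(
            {
                "n": n,
                "W1": f1_fitness(p).value,
                "W2": f2_fitness(p).value,
                "W3": backcross_compatible_fitness(p).value,
                "W4": backcross_paternal_fitness(p).value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# polymorphic extension


@dataclass(frozen=True)
class PopulationAlleleProfile:
    """Per-locus frequency of the locally adapted allele in each pool.

    ``north[i]`` is the frequency, in the north pool, of the allele matched
    to the north mtDNA at locus i; ``south[i]`` is the frequency, in the
    south pool, of the allele matched to the south mtDNA.  Frequencies of 1
    everywhere recover the fixed-population model.
    """

    north: tuple[float, ...]
    south: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.north) != len(self.south):
            raise ValueError("north and south profiles must have equal length")
        for freqs in (self.north, self.south):
            for f in freqs:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"allele frequency outside [0, 1]: {f}")

    @property
    def n_loci(self) -> int:
        return len(self.north)


def _genotype_dist(g_mother: float, g_father: float) -> tuple[float, float, float]:
    """(P matched hom, P het, P mismatched hom) from two gamete frequencies.

    Gamete frequencies are of the allele matched to the zygote's mtDNA.
    """
    return (
        g_mother * g_father,
        g_mother * (1.0 - g_father) + (1.0 - g_mother) * g_father,
        (1.0 - g_mother) * (1.0 - g_father),
    )


def polymorphic_fitness(
    profile: PopulationAlleleProfile,
    params: ModelParams,
    cross: CrossKind,
    maternal: str = "north",
) -> FitnessValue:
    """Expected cross fitness when parental pools are polymorphic.

    Parents are drawn under Hardy-Weinberg at the profile frequencies, so a
    parental gamete carries the locally adapted allele with the pool
    frequency itself; gametes propagate through the cross against the
    maternally inherited mtDNA (``maternal`` names the F1 mother's
    population and hence the zygote's mtDNA).  Per-locus expected fitness
    values are multiplied across loci.  At fixation (all frequencies 1)
    this reduces exactly to the fixed-population closed forms.
    """
    if profile.n_loci != params.n_loci:
        raise ValueError(
            f"profile has {profile.n_loci} loci but params.n_loci = {params.n_loci}"
        )
    if maternal not in ("north", "south"):
        raise ValueError(f"maternal must be 'north' or 'south', got {maternal!r}")
    s1, s2 = params.s1, params.s2
    value = 1.0
    for i in range(params.n_loci):
        # frequency of the mtDNA-matched allele in each parental pool
        if maternal == "north":
            g_mat, g_pat = profile.north[i], 1.0 - profile.south[i]
        else:
            g_mat, g_pat = profile.south[i], 1.0 - profile.north[i]
        g_f1 = 0.5 * (g_mat + g_pat)  # gamete of an F1 individual
        if cross is CrossKind.F1:
            dist = _genotype_dist(g_mat, g_pat)
        elif cross is CrossKind.F2:
            dist = _genotype_dist(g_f1, g_f1)
        elif cross is CrossKind.BC_COMPATIBLE:
            dist = _genotype_dist(g_f1, g_mat)
        elif cross is CrossKind.BC_PATERNAL:
            dist = _genotype_dist(g_f1, g_pat)
        else:
            raise ValueError(f"unknown cross kind {cross!r}")
        value *= dist[0] + dist[1] * (1.0 - s1) + dist[2] * (1.0 - s2)
    factor = value ** (1.0 / params.n_loci) if params.n_loci else 1.0
    return FitnessValue(value=value, per_locus_factor=factor, method="polymorphic")
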