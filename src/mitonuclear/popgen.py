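"""Genotype association statistics for two mtDNA-defined groups.

For each biallelic nuclear locus genotyped in the north and south samples,
the association with the mtDNA type is assessed with a Pearson chi-square
test of independence on the 2 x 3 genotype table (no continuity
correction; genotype classes empty in both groups are dropped before the
expecteds are formed), Bonferroni-corrected over the number of candidate
genes, and quantified with the Weir & Cockerham (1984) theta estimator of
Fst computed from genotype counts.  Multi-locus theta is the ratio of
summed variance components, the convention of standard Fst software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "FstComponents",
    "AssociationResult",
    "chi_square_independence",
    "bonferroni",
    "wc_fst_single",
    "wc_fst_multilocus",
    "association_report",
]

#: Qualitative interpretation bands for Fst (Wright/Hartl conventions):
#: 0-0.05 minute, 0.05-0.15 moderate, 0.15-0.25 high, >0.25 profound
#: genetic differentiation.
FST_BANDS = ((0.05, "minute"), (0.15, "moderate"), (0.25, "high"), (1.0, "profound"))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts (hom-1, het, hom-2) per population at one locus.

    Counts may be real-valued so that expected Hardy-Weinberg class counts
    can be pushed through the estimator.
    """

    locus: str
    north: tuple[float, float, float]
    south: tuple[float, float, float]
    gene: str = ""
    alleles: tuple[str, str] = ("A1", "A2")

    def __post_init__(self) -> None:
        for pop in (self.north, self.south):
            if len(pop) != 3 or any(c < 0 for c in pop):
                raise ValueError(f"{self.locus}: counts must be 3 non-negative values")

    def table(self) -> np.ndarray:
        return np.array([self.north, self.south], dtype=float)


@dataclass(frozen=True)
class FstComponents:
    """Weir-Cockerham per-locus variance components and theta.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals; ``theta = a / (a + b + c)``.
    ``theta`` is None for a monomorphic locus (undefined, not zero) and is
    reported unclamped otherwise (small negative estimates are valid).
    """

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float | None:
        denom = self.a + self.b + self.c
        if denom == 0.0:
            return None
        return self.a / denom


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    n_samples: int
    n_loci: int
    chi2: float
    df: int
    p_value: float
    p_bonferroni: float
    theta: float | None


def chi_square_independence(counts: GenotypeCounts) -> tuple[float, int, float]:
    """Pearson chi-square of genotype distribution vs population.

    Genotype classes with zero total count across both populations are
    dropped before expecteds are computed; no continuity correction is
    applied.  Returns ``(chi2, df, p)``.
    """
    table = counts.table()
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"degenerate table for locus {counts.locus}")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def bonferroni(p: float, m_tests: int) -> float:
    """Bonferroni-corrected p-value, min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    return min(1.0, m_tests * p)


def wc_fst_single(counts: GenotypeCounts) -> FstComponents:
    """Weir & Cockerham (1984) variance components for one biallelic locus.

    With r = 2 populations of sizes ``n_i``, allele-1 frequencies ``p_i``
    and observed heterozygote proportions ``h_i``:

    .. math::

        a &= \\frac{\\bar n}{n_c}\\Big[s^2 - \\frac{1}{\\bar n - 1}\\Big(
             \\bar p(1-\\bar p) - \\frac{r-1}{r}s^2 - \\frac{\\bar h}{4}
             \\Big)\\Big] \\\\
        b &= \\frac{\\bar n}{\\bar n - 1}\\Big[\\bar p(1-\\bar p)
             - \\frac{r-1}{r}s^2
             - \\frac{2\\bar n - 1}{4\\bar n}\\bar h\\Big] \\\\
        c &= \\bar h / 2

    where ``n_bar`` is the mean sample size, ``n_c`` the variance-corrected
    size, ``p_bar``/``h_bar`` weighted means and ``s^2`` the sample variance
    of allele frequencies.
    """
    pops = [counts.north, counts.south]
    n_i, p_i, h_i = [], [], []
    for h1, het, h2 in pops:
        n = h1 + het + h2
        if n <= 0:
            raise ValueError(f"{counts.locus}: empty population sample")
        n_i.append(n)
        p_i.append((2 * h1 + het) / (2 * n))
        h_i.append(het / n)
    r = 2
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    inner = pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4
    a = (nbar / nc) * (s2 - inner / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return FstComponents(a=float(a), b=float(b), c=float(c))


def wc_fst_multilocus(loci: Iterable[GenotypeCounts]) -> float:
    """Multilocus theta as the ratio of summed components over loci.

    Loci whose components are all zero (monomorphic) are skipped; raises if
    every locus is undefined.
    """
    num = den = 0.0
    any_defined = False
    for counts in loci:
        comp = wc_fst_single(counts)
        denom = comp.a + comp.b + comp.c
        if denom == 0.0:
            continue
        any_defined = True
        num += comp.a
        den += denom
    if not any_defined:
        raise ValueError("theta undefined: all loci monomorphic")
    return num / den


def interpret_fst(theta: float) -> str:
    """Qualitative differentiation band for a theta estimate."""
    for upper, label in FST_BANDS:
        if theta <= upper:
            return label
    return FST_BANDS[-1][1]


def association_report(
    loci: Sequence[GenotypeCounts], m_tests: int = 14
) -> pd.DataFrame:
    """Per-gene association summary from per-locus genotype counts.

    For each gene: the reported p-value is the smallest per-locus
    chi-square p among its loci, Bonferroni-corrected over ``m_tests``
    candidate genes; theta is single-locus for one locus and the
    multilocus ratio-of-sums otherwise.  Sample size is the largest
    per-locus genotyped total.  Rows are sorted by p-value.
    """
    by_gene: dict[str, list[GenotypeCounts]] = {}
    for counts in loci:
        gene = counts.gene or counts.locus
        by_gene.setdefault(gene, []).append(counts)
    rows = []
    for gene, gene_loci in by_gene.items():
        per_locus = [chi_square_independence(c) for c in gene_loci]
        chi2, df, p = min(per_locus, key=lambda t: t[2])
        try:
            theta = wc_fst_multilocus(gene_loci)
        except ValueError:
            theta = None
        n = max(int(round(sum(c.north) + sum(c.south))) for c in gene_loci)
        rows.append(
            AssociationResult(
                gene=gene,
                n_samples=n,
                n_loci=len(gene_loci),
                chi2=chi2,
                df=df,
                p_value=p,
                p_bonferroni=bonferroni(p, m_tests),
                theta=theta,
            )
        )
    frame = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n": r.n_samples,
                "n_nss": r.n_loci,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p_value,
                "p_bonferroni": r.p_bonferroni,
                "fst": r.theta,
            }
            for r in rows
        ]
    )
    return frame.sort_values("p", kind="stable").reset_index(drop=True)
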