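"""Correlated-mutation scores between protein alignment columns.

Implements the two classic covariation statistics used to prioritize
coevolving residue pairs between a nuclear-encoded protein and its
candidate mtDNA-encoded partners:

OMES (observed minus expected squared)
    For columns A and B restricted to species ungapped in both,
    ``sum over observed residue pairs (x, y) of
    (N_obs(x,y) - N_x * N_y / N)^2 / N``.

ELSC (explicit likelihood of subset covariation)
    Take the subset of species carrying the modal residue of column A.
    For each residue y of column B with full count ``N_y``, subset count
    ``n_y`` and ideally proportional subset count ``m_y`` (largest-
    remainder apportionment of the subset size), the score is
    ``-ln prod_y C(N_y, n_y) / C(N_y, m_y)``.

Scores above 5 (OMES) and 20 (ELSC) are conventionally taken to imply
coevolution.  A simplified per-column conservation grade (1-9, 9 most
conserved; >= 7 flags highest functionality) based on rank-binned relative
entropy is also provided; it is a deliberate simplification of
phylogenetic rate-based conservation indices and is labelled as such in
output metadata.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinMSA",
    "ColumnPairScore",
    "omes",
    "elsc",
    "scan_pair",
    "conservation_grades",
    "OMES_CUTOFF",
    "ELSC_CUTOFF",
    "CONSERVATION_CUTOFF",
]

log = logging.getLogger(__name__)

OMES_CUTOFF = 5.0
ELSC_CUTOFF = 20.0
CONSERVATION_CUTOFF = 7

GAP_CHARS = frozenset("-.")


@dataclass
class ProteinMSA:
    """A protein multiple sequence alignment with reference numbering.

    Rows are species, columns alignment positions.  Positions are reported
    1-based in the coordinate system of the reference sequence (first row
    by default), skipping columns gapped in the reference.
    """

    ids: list[str]
    matrix: np.ndarray  # (n_species, length), dtype '<U1', uppercase
    reference: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate species ids in alignment")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match species ids")
        if self.matrix.shape[0] == 0 or self.matrix.shape[1] == 0:
            raise ValueError("empty alignment")
        if self.reference is None:
            self.reference = self.ids[0]
        if self.reference not in self.ids:
            raise ValueError(f"reference {self.reference!r} not in alignment")

    @property
    def n_species(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, species: str) -> np.ndarray:
        return self.matrix[self.ids.index(species)]

    def ref_positions(self) -> dict[int, int]:
        """Map 1-based reference position -> alignment column index."""
        ref = self.row(self.reference)
        mapping, pos = {}, 0
        for col, residue in enumerate(ref):
            if residue not in GAP_CHARS:
                pos += 1
                mapping[pos] = col
        return mapping

    def column(self, index: int) -> np.ndarray:
        return self.matrix[:, index]


@dataclass(frozen=True)
class ColumnPairScore:
    pos_a: int
    pos_b: int
    omes: float
    elsc: float
    n_valid: int


def _valid_pair(col_a: np.ndarray, col_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    col_a = np.asarray(col_a, dtype="<U1")
    col_b = np.asarray(col_b, dtype="<U1")
    if col_a.shape != col_b.shape:
        raise ValueError("columns must cover the same species")
    valid = ~(np.isin(col_a, list(GAP_CHARS)) | np.isin(col_b, list(GAP_CHARS)))
    a, b = col_a[valid], col_b[valid]
    if a.size < 2:
        raise ValueError(f"fewer than 2 ungapped species in common ({a.size})")
    return a, b


def omes(col_a, col_b) -> float:
    """Observed-minus-expected-squared covariation of two columns."""
    a, b = _valid_pair(col_a, col_b)
    n = a.size
    pair_counts = Counter(zip(a, b))
    count_a = Counter(a)
    count_b = Counter(b)
    return sum(
        (obs - count_a[x] * count_b[y] / n) ** 2 / n
        for (x, y), obs in pair_counts.items()
    )


def _largest_remainder(full_counts: dict[str, int], subset_size: int) -> dict[str, int]:
    """Apportion ``subset_size`` over residues proportionally to full counts.

    Largest-remainder rounding; ties broken by larger full count, then
    lexicographic residue order, so the result is deterministic.
    """
    total = sum(full_counts.values())
    ideal = {y: full_counts[y] * subset_size / total for y in full_counts}
    base = {y: math.floor(v) for y, v in ideal.items()}
    short = subset_size - sum(base.values())
    order = sorted(
        full_counts,
        key=lambda y: (-(ideal[y] - base[y]), -full_counts[y], y),
    )
    for y in order[:short]:
        base[y] += 1
    return base


def elsc(col_a, col_b) -> float:
    """Explicit likelihood of subset covariation between two columns.

    The subset is the species carrying the modal residue of column A
    (modal ties broken lexicographically).  Clamped at zero: the
    proportional composition maximizes the combinatorial product up to
    integer rounding.
    """
    a, b = _valid_pair(col_a, col_b)
    count_a = Counter(a)
    modal = min(count_a, key=lambda x: (-count_a[x], x))
    subset = b[a == modal]
    full = Counter(b)
    sub = Counter(subset)
    ideal = _largest_remainder(dict(full), subset.size)
    log_score = 0.0
    for y, n_full in full.items():
        log_score += math.log(math.comb(n_full, ideal.get(y, 0)))
        log_score -= math.log(math.comb(n_full, sub.get(y, 0)))
    return max(log_score, 0.0)


def scan_pair(
    msa_a: ProteinMSA,
    msa_b: ProteinMSA,
    positions_a: list[int] | None = None,
    positions_b: list[int] | None = None,
) -> pd.DataFrame:
    """Score requested column pairs across two alignments.

    Columns are addressed by 1-based reference position (all reference
    positions when not restricted); species are matched by exact id and
    restricted to the intersection.  Returns a DataFrame with columns
    ``pos_a, pos_b, n_valid, omes, omes_pass, elsc, elsc_pass`` sorted by
    OMES descending.  The per-protein top score is the first row.
    """
    shared = [s for s in msa_a.ids if s in set(msa_b.ids)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared species between alignments")
    rows_a = np.array([msa_a.row(s) for s in shared])
    rows_b = np.array([msa_b.row(s) for s in shared])
    map_a = msa_a.ref_positions()
    map_b = msa_b.ref_positions()
    positions_a = sorted(map_a) if positions_a is None else list(positions_a)
    positions_b = sorted(map_b) if positions_b is None else list(positions_b)
    records = []
    for pa in positions_a:
        col_a = rows_a[:, map_a[pa]]
        for pb in positions_b:
            col_b = rows_b[:, map_b[pb]]
            try:
                a, b = _valid_pair(col_a, col_b)
            except ValueError:
                continue
            score_o = omes(col_a, col_b)
            score_e = elsc(col_a, col_b)
            records.append(
                {
                    "pos_a": pa,
                    "pos_b": pb,
                    "n_valid": a.size,
                    "omes": score_o,
                    "omes_pass": score_o > OMES_CUTOFF,
                    "elsc": score_e,
                    "elsc_pass": score_e > ELSC_CUTOFF,
                }
            )
    frame = pd.DataFrame(
        records,
        columns=["pos_a", "pos_b", "n_valid", "omes", "omes_pass", "elsc", "elsc_pass"],
    )
    return frame.sort_values(
        ["omes", "elsc"], ascending=False, kind="stable"
    ).reset_index(drop=True)


def conservation_grades(msa: ProteinMSA) -> pd.DataFrame:
    """Rank-binned relative-entropy conservation grade per reference position.

    The raw score of a column is the Kullback-Leibler divergence of its
    residue distribution (gaps excluded) from the uniform distribution
    over the alphabet observed anywhere in the alignment.  Raw scores are
    rank-binned into nine grades within the alignment (grade 9 = most
    conserved); grade >= 7 flags "highest functionality".  This is a
    simplified stand-in for phylogenetic rate-based conservation indices:
    it ranks columns by compositional bias only.
    """
    if msa.n_species < 5:
        raise ValueError("conservation grading needs at least 5 sequences")
    if msa.n_species < 20:
        log.warning(
            "conservation grades from only %d sequences; expect noisy ranks",
            msa.n_species,
        )
    alphabet = sorted(set(msa.matrix.ravel()) - GAP_CHARS)
    k = len(alphabet)
    mapping = msa.ref_positions()
    positions = sorted(mapping)
    raw = []
    for pos in positions:
        col = msa.column(mapping[pos])
        residues = col[~np.isin(col, list(GAP_CHARS))]
        if residues.size == 0:
            raw.append(0.0)
            continue
        counts = np.array(list(Counter(residues).values()), dtype=float)
        p = counts / counts.sum()
        raw.append(float(math.log(k) + (p * np.log(p)).sum()) if k > 1 else 0.0)
    raw_arr = pd.Series(raw, index=positions)
    pct = raw_arr.rank(method="average", pct=True)
    grade = np.ceil(pct * 9).clip(1, 9).astype(int)
    return pd.DataFrame(
        {
            "position": positions,
            "raw": raw_arr.to_numpy(),
            "grade": grade.to_numpy(),
            "high_functionality": (grade >= CONSERVATION_CUTOFF).to_numpy(),
        }
    )
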