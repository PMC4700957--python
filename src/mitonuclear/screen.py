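"""Differentiating-variant co-occurrence screen.

Given a boolean variants x samples presence matrix and an mtDNA-type group
label (north/south) per sample, a variant is a candidate differentiating
variant when it is present in at least ``min_in`` samples of one group and
in no more than ``max_out`` samples of the other.  Defaults (4, 1) suit a
design of about five transcriptomes per group.  Both directions are
evaluated; missing calls count as absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantPresenceMatrix",
    "screen_variants",
    "screen_summary",
    "null_pass_probability",
]

GROUPS = ("north", "south")


@dataclass
class VariantPresenceMatrix:
    """Boolean presence of variants (rows) across samples (columns).

    ``presence`` is indexed by variant id with one boolean column per
    sample; ``groups`` maps sample id to 'north' or 'south'; ``genes`` and
    ``effects`` optionally annotate variants (effect in
    {synonymous, nonsynonymous, other}).
    """

    presence: pd.DataFrame
    groups: pd.Series
    genes: pd.Series | None = None
    effects: pd.Series | None = None

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)
        missing = set(self.presence.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.presence.columns if self.groups[s] == group]


def screen_variants(
    matrix: VariantPresenceMatrix, min_in: int = 4, max_out: int = 1
) -> pd.DataFrame:
    """Apply the co-occurrence rule in both directions to every variant.

    Returns a DataFrame with columns ``variant, direction, n_in, n_out,
    n_north, n_south, passed``; ``direction`` is the enriched group of the
    better-supported direction.  A variant passes if either direction has
    ``n_in >= min_in`` and ``n_out <= max_out``.
    """
    north = matrix.samples_in("north")
    south = matrix.samples_in("south")
    if not north or not south:
        raise ValueError("both groups must contain at least one sample")
    n_north = matrix.presence[north].sum(axis=1).to_numpy()
    n_south = matrix.presence[south].sum(axis=1).to_numpy()
    pass_north = (n_north >= min_in) & (n_south <= max_out)
    pass_south = (n_south >= min_in) & (n_north <= max_out)
    direction = np.where(
        pass_north, "north-enriched",
        np.where(pass_south, "south-enriched",
                 np.where(n_north >= n_south, "north-enriched", "south-enriched")),
    )
    enriched_is_north = direction == "north-enriched"
    out = pd.DataFrame(
        {
            "variant": matrix.presence.index,
            "direction": direction,
            "n_in": np.where(enriched_is_north, n_north, n_south),
            "n_out": np.where(enriched_is_north, n_south, n_north),
            "n_north": n_north,
            "n_south": n_south,
            "passed": pass_north | pass_south,
        }
    )
    if matrix.genes is not None:
        out.insert(1, "gene", matrix.genes.reindex(out["variant"]).to_numpy())
    if matrix.effects is not None:
        out.insert(2, "effect", matrix.effects.reindex(out["variant"]).to_numpy())
    return out


def screen_summary(decisions: pd.DataFrame) -> dict:
    """Counts of passing variants, per-gene tallies, genes with >= 1 pass."""
    passed = decisions[decisions["passed"]] if len(decisions) else decisions
    per_gene: dict[str, int] = {}
    if "gene" in decisions.columns and len(passed):
        per_gene = passed.groupby("gene").size().to_dict()
    return {
        "n_variants": int(len(decisions)),
        "n_passing": int(len(passed)),
        "passing_per_gene": per_gene,
        "n_genes_with_passing": len(per_gene),
    }


def null_pass_probability(
    n_north: int,
    n_south: int,
    p_presence: float,
    min_in: int = 4,
    max_out: int = 1,
) -> float:
    """Exact pass probability for a group-independent null variant.

    Presence is i.i.d. Bernoulli(``p_presence``) per sample, so the group
    presence counts X ~ Bin(n_north, p) and Y ~ Bin(n_south, p) are
    independent; the screen pass event is the union of the two direction
    events, computed by inclusion-exclusion.
    """
    X = stats.binom(n_north, p_presence)
    Y = stats.binom(n_south, p_presence)

    def ge(d, k):  # P(D >= k)
        return float(d.sf(k - 1)) if k > 0 else 1.0

    def le(d, k):  # P(D <= k)
        return float(d.cdf(k))

    def between(d, lo, hi):  # P(lo <= D <= hi)
        if lo > hi:
            return 0.0
        return float(d.cdf(hi) - (d.cdf(lo - 1) if lo > 0 else 0.0))

    p_a = ge(X, min_in) * le(Y, max_out)
    p_b = ge(Y, min_in) * le(X, max_out)
    p_both = between(X, min_in, max_out) * between(Y, min_in, max_out)
    return p_a + p_b - p_both
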