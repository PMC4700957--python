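"""Readers and writers for the formats the pipeline touches.

Genotype TSV dialect
    Tab-separated, optional ``#``-prefixed metadata lines, then a header
    ``sample_id<TAB>group<TAB><locus>...``.  Genotype cells hold 0/1/2 =
    copies of allele 2, or ``.`` for missing.  Locus columns are named
    ``GENE_POS`` (gene symbol, 1-based position in the human reference
    ortholog).  A metadata line ``#alleles <locus> <a1> <a2>`` records
    allele labels.

Presence TSV dialect
    ``variant_id<TAB>gene<TAB>effect`` then one 0/1 column per sample;
    group labels come from a separate two-column map (sample_id, group).

Minimal VCF dialect
    Plain-text VCF with a GT FORMAT field, diploid, biallelic records
    only.  ``0/0 -> 0``, ``0/1``/``1/0`` (or phased) ``-> 1``,
    ``1/1 -> 2``, ``./. -> missing``; in presence mode a sample is
    "present" when its GT contains allele 1.

Aligned protein FASTA is read through Bio.AlignIO.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .coevolution import ProteinMSA
from .popgen import GenotypeCounts
from .screen import GROUPS, VariantPresenceMatrix

__all__ = [
    "GenotypeTable",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_presence_tsv",
    "read_group_map",
    "read_vcf_minimal",
    "read_fasta_msa",
    "load_table2_genotypes",
]

MISSING = "."


@dataclass
class GenotypeTable:
    """Diploid genotypes (copies of allele 2) for two mtDNA-typed groups.

    ``genotypes`` is samples x loci, float-valued with NaN for missing;
    ``groups`` maps sample id to 'north' or 'south'; ``alleles`` maps a
    locus to its two allele labels.
    """

    genotypes: pd.DataFrame
    groups: pd.Series
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotypes.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.genotypes.index) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups.loc[self.genotypes.index].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        values = self.genotypes.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotypes must be 0, 1, 2 or missing (biallelic loci)")

    @property
    def loci(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.index)

    def locus_counts(self, locus: str) -> GenotypeCounts:
        """Aggregate one locus into per-population genotype class counts."""
        col = self.genotypes[locus]
        counts = {}
        for group in GROUPS:
            vals = col[self.groups.loc[col.index] == group].dropna()
            counts[group] = tuple(float((vals == g).sum()) for g in (0, 1, 2))
        gene = locus.rsplit("_", 1)[0] if "_" in locus else locus
        return GenotypeCounts(
            locus=locus,
            north=counts["north"],
            south=counts["south"],
            gene=gene,
            alleles=self.alleles.get(locus, ("A1", "A2")),
        )

    def all_counts(self) -> list[GenotypeCounts]:
        return [self.locus_counts(locus) for locus in self.loci]


def read_genotype_tsv(path: str | Path) -> GenotypeTable:
    path = Path(path)
    alleles: dict[str, tuple[str, str]] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "alleles" and len(parts) == 4:
                    alleles[parts[1]] = (parts[2], parts[3])
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:2] != ["sample_id", "group"]:
                    raise ValueError(
                        f"{path}:{lineno}: header must start with 'sample_id\\tgroup'"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append(fields)
    if header is None or not rows:
        raise ValueError(f"{path}: empty genotype file")
    loci = header[2:]
    sample_ids = [r[0] for r in rows]
    groups = pd.Series([r[1] for r in rows], index=sample_ids)
    data = []
    for r in rows:
        parsed = []
        for locus, cell in zip(loci, r[2:]):
            if cell == MISSING:
                parsed.append(np.nan)
            elif cell in ("0", "1", "2"):
                parsed.append(float(cell))
            else:
                raise ValueError(
                    f"{path}: sample {r[0]}, locus {locus}: bad genotype {cell!r}"
                )
        data.append(parsed)
    genotypes = pd.DataFrame(data, index=sample_ids, columns=loci)
    return GenotypeTable(genotypes=genotypes, groups=groups, alleles=alleles)


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for locus, (a1, a2) in sorted(table.alleles.items()):
            fh.write(f"#alleles {locus} {a1} {a2}\n")
        fh.write("\t".join(["sample_id", "group", *table.loci]) + "\n")
        for sample in table.samples:
            cells = []
            for locus in table.loci:
                v = table.genotypes.at[sample, locus]
                cells.append(MISSING if pd.isna(v) else str(int(v)))
            fh.write("\t".join([sample, table.groups[sample], *cells]) + "\n")


def read_group_map(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series indexed by sample id."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                        comment="#", dtype=str)
    if frame["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in group map")
    return pd.Series(frame["group"].to_numpy(), index=frame["sample_id"].to_numpy())


def read_presence_tsv(path: str | Path, group_map: pd.Series) -> VariantPresenceMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["variant_id", "gene", "effect"]
    if list(frame.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    if frame["variant_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate variant ids")
    frame = frame.set_index("variant_id")
    samples = list(frame.columns[2:])
    cells = frame[samples]
    if not cells.isin(["0", "1"]).all().all():
        raise ValueError(f"{path}: presence cells must be 0 or 1")
    presence = cells.astype(int).astype(bool)
    return VariantPresenceMatrix(
        presence=presence,
        groups=group_map,
        genes=frame["gene"],
        effects=frame["effect"],
    )


def read_vcf_minimal(
    path: str | Path, group_map: pd.Series, as_presence: bool = False
) -> GenotypeTable | VariantPresenceMatrix:
    """Read the minimal GT-only VCF dialect.

    Returns a :class:`GenotypeTable` (allele-2 copy counts) or, with
    ``as_presence``, a :class:`VariantPresenceMatrix` where presence means
    the GT carries at least one alternate allele.
    """
    path = Path(path)
    samples: list[str] | None = None
    variant_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10 or fields[8] != "FORMAT":
                    raise ValueError(f"{path}:{lineno}: malformed #CHROM line")
                samples = fields[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            chrom, pos, _id, ref, alt = fields[:5]
            record = f"{chrom}:{pos}:{ref}>{alt}"
            if "," in alt:
                raise ValueError(f"{path}: multi-allelic record {record}")
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}: record {record} has no GT field")
            gt_idx = fmt.index("GT")
            parsed = []
            for sample, cell in zip(samples, fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                allele_strs = gt.split("/")
                if allele_strs == ["."] * len(allele_strs):
                    parsed.append(np.nan)
                    continue
                if len(allele_strs) != 2:
                    raise ValueError(
                        f"{path}: record {record}, sample {sample}: not diploid"
                    )
                alleles = [int(a) for a in allele_strs]
                if any(a not in (0, 1) for a in alleles):
                    raise ValueError(f"{path}: multi-allelic GT in record {record}")
                parsed.append(float(sum(alleles)))
            variant_ids.append(record)
            rows.append(parsed)
    if samples is None:
        raise ValueError(f"{path}: no #CHROM header")
    matrix = pd.DataFrame(rows, index=variant_ids, columns=samples)
    if as_presence:
        return VariantPresenceMatrix(
            presence=matrix.fillna(0.0) > 0, groups=group_map
        )
    return GenotypeTable(genotypes=matrix.T, groups=group_map)


def read_fasta_msa(path: str | Path, reference: str | None = None) -> ProteinMSA:
    """Read an aligned protein FASTA into a :class:`ProteinMSA`.

    Residues are uppercased; ragged alignments, empty files and duplicate
    ids are rejected.
    """
    path = Path(path)
    try:
        alignment = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid alignment ({exc})") from exc
    ids = [rec.id for rec in alignment]
    matrix = np.array(
        [list(str(rec.seq).upper()) for rec in alignment], dtype="<U1"
    )
    return ProteinMSA(ids=ids, matrix=matrix, reference=reference)


def load_table2_genotypes() -> GenotypeTable:
    """The shipped per-sample genotype fixture for the chameleon cohort.

    Sample ids are synthetic (the published data are per-population class
    counts); re-aggregating the fixture reproduces the published counts
    exactly.
    """
    resource = importlib.resources.files("mitonuclear.data") / "table2_genotypes.tsv"
    with importlib.resources.as_file(resource) as path:
        return read_genotype_tsv(path)
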