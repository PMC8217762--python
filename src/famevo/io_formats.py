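"""Readers and writers for the external formats the pipeline consumes.

Every downstream analysis module works with the domain types defined here
(:class:`SequenceSet`, :class:`AlignmentSet`, :class:`DomTblRow`,
:class:`GeneLocus`, :class:`OrthologPresence`, :class:`ExpressionMatrix`)
rather than with raw files, so this module is the only place that knows
about FASTA, Clustal, HMMER3 ``domtblout``, Newick, and the TSV tables.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (MGI/NCBI style).  The only
  half-open output is the optional BED export.
* Alignment gaps are ``-``; ``.`` is normalized to ``-`` on read.
* ``domtblout`` parsing is strictly column-index based, matching the fixed
  HMMER3 layout, never a regex over column names.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: Reference species for ortholog presence flags, ordered from the most
#: recent divergence from mouse (zebrafish) to the most ancient (yeast).
SPECIES_ORDER = ("zebrafish", "sea_urchin", "nematode", "yeast")


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: FASTA id, free-text description, residues."""

    id: str
    description: str
    sequence: str


@dataclass
class SequenceSet:
    """An ordered collection of protein sequences with unique ids.

    The alphabet is restricted to the 20 canonical residues plus ``X``;
    how ``X`` is treated (average mass, no charge) is up to the consumer.
    """

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            if not rec.sequence:
                raise ValueError(f"empty sequence for id {rec.id!r}")
            bad = set(rec.sequence) - AMINO_ACIDS - {"X"}
            if bad:
                raise ValueError(
                    f"non-canonical residue(s) {sorted(bad)} in {rec.id!r}"
                )

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def get(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a protein FASTA file, preserving record order.

    The description is the header text after the first whitespace.
    Raises on duplicate ids (naming the id) and on an empty file.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        desc = parts[1] if len(parts) > 1 else ""
        records.append(SequenceRecord(rec.id, desc, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in seqs
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class AlignmentSet:
    """A multiple sequence alignment: parallel lists of taxa and rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("alignment taxa must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for taxon, row in zip(self.taxa, self.rows):
            bad = set(row) - AMINO_ACIDS - {"X", GAP}
            if bad:
                raise ValueError(
                    f"non-canonical character(s) {sorted(bad)} in row {taxon!r}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def read_alignment(path: str | Path, fmt: str | None = None) -> AlignmentSet:
    """Read an alignment from aligned FASTA or Clustal.

    ``fmt`` is ``"fasta"`` or ``"clustal"``; when omitted it is inferred
    from the file extension (``.aln``/``.clustal`` mean Clustal).
    """
    if fmt is None:
        fmt = "clustal" if Path(path).suffix in {".aln", ".clustal"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    taxa = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", GAP) for rec in aln]
    return AlignmentSet(taxa, rows)


def write_alignment(aln: AlignmentSet, path: str | Path) -> None:
    bio = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# HMMER3 per-domain tabular output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomTblRow:
    """One domain line of HMMER3 ``domtblout`` (fields we consume)."""

    target_id: str
    query_accession: str
    full_seq_evalue: float
    full_seq_score: float
    domain_ievalue: float
    env_from: int
    env_to: int

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError(
                f"env_from > env_to ({self.env_from} > {self.env_to}) "
                f"for target {self.target_id!r}"
            )
        if self.full_seq_evalue < 0 or self.domain_ievalue < 0:
            raise ValueError(f"negative E-value for target {self.target_id!r}")


# Fixed 0-based column indices of the HMMER3 domtblout layout.
_DOMTBL_COLS = {
    "target_id": 0,
    "query_accession": 4,
    "full_seq_evalue": 6,
    "full_seq_score": 7,
    "domain_ievalue": 12,
    "env_from": 19,
    "env_to": 20,
}


def read_domtbl(path: str | Path) -> list[DomTblRow]:
    """Parse HMMER3 ``--domtblout`` output into one row per domain line.

    ``#`` comment lines are skipped.  A malformed numeric field raises
    ``ValueError`` with the 1-based line number.
    """
    rows: list[DomTblRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=22 domtblout columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(
                    DomTblRow(
                        target_id=parts[_DOMTBL_COLS["target_id"]],
                        query_accession=parts[_DOMTBL_COLS["query_accession"]],
                        full_seq_evalue=float(parts[_DOMTBL_COLS["full_seq_evalue"]]),
                        full_seq_score=float(parts[_DOMTBL_COLS["full_seq_score"]]),
                        domain_ievalue=float(parts[_DOMTBL_COLS["domain_ievalue"]]),
                        env_from=int(parts[_DOMTBL_COLS["env_from"]]),
                        env_to=int(parts[_DOMTBL_COLS["env_to"]]),
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed numeric field ({exc})"
                ) from exc
    return rows


# ---------------------------------------------------------------------------
# gene coordinate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """One annotated gene: 1-based inclusive coordinates on a chromosome.

    ``order_index`` is the rank of the gene among ALL annotated genes on
    its chromosome (1-based); it is usually assigned by
    :func:`famevo.genome_map.assign_order_index` rather than read from disk.
    Strand is carried if present but ignored by downstream analyses.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    family: str = "other"
    strand: str | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1 (1-based)")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


_GENE_REQUIRED = ("gene_id", "chromosome", "start", "end")


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read a TSV gene table with header.

    Required columns: gene_id, chromosome, start, end.
    Optional: family (default ``other``), strand.  The table may be
    unsorted; sorting/ordering is the consumer's job.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in _GENE_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    loci = []
    for rec in df.itertuples(index=False):
        loci.append(
            GeneLocus(
                gene_id=str(rec.gene_id),
                chromosome=str(rec.chromosome),
                start=int(rec.start),
                end=int(rec.end),
                family=str(rec.family) if "family" in df.columns else "other",
                strand=str(rec.strand) if "strand" in df.columns else None,
            )
        )
    return loci


def write_gene_table(loci: Sequence[GeneLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in loci],
            "family": [g.family for g in loci],
            "chromosome": [g.chromosome for g in loci],
            "start": [g.start for g in loci],
            "end": [g.end for g in loci],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(loci: Sequence[GeneLocus], path: str | Path) -> None:
    """Export loci as BED (0-based half-open), the only half-open output."""
    with open(path, "w") as fh:
        for g in loci:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# ortholog presence tables
# ---------------------------------------------------------------------------

@dataclass
class OrthologPresence:
    """Per-gene boolean ortholog flags over the four reference species.

    ``table`` is indexed by gene_id with one boolean column per species in
    :data:`SPECIES_ORDER`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in SPECIES_ORDER if s not in self.table.columns]
        if missing:
            raise ValueError(f"ortholog table missing species column(s): {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_id(s) in ortholog table: {dups}")
        self.table = self.table.loc[:, list(SPECIES_ORDER)].astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def flags(self, gene_id: str) -> tuple[bool, bool, bool, bool]:
        row = self.table.loc[gene_id]
        return tuple(bool(v) for v in row)  # type: ignore[return-value]


def _normalize_species(name: str) -> str:
    return name.strip().lower().replace(" ", "_").replace("-", "_")


def read_ortholog_table(path: str | Path) -> OrthologPresence:
    """Read a long-format ortholog TSV: gene_id, species, has_ortholog.

    Species names are normalized (lowercase, spaces to underscores) and
    must be among the four reference species.  Missing (gene, species)
    combinations default to absent.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "species", "has_ortholog"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["species"] = df["species"].map(_normalize_species)
    unknown = sorted(set(df["species"]) - set(SPECIES_ORDER))
    if unknown:
        raise ValueError(
            f"{path}: unknown species {unknown}; expected {list(SPECIES_ORDER)}"
        )
    genes = list(dict.fromkeys(df["gene_id"]))
    wide = (
        df.pivot_table(
            index="gene_id", columns="species", values="has_ortholog", aggfunc="max"
        )
        .reindex(index=genes, columns=list(SPECIES_ORDER))
        .fillna(False)
        .astype(bool)
    )
    wide.columns.name = None
    return OrthologPresence(wide)


def write_ortholog_table(pres: OrthologPresence, path: str | Path) -> None:
    long = (
        pres.table.astype(int)
        .reset_index(names="gene_id")
        .melt(id_vars="gene_id", var_name="species", value_name="has_ortholog")
    )
    long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized log2 expression values, genes x samples.

    ``groups`` maps sample id to a group label (e.g. ``Sham``/``TAC``);
    it may be None when only the matrix itself is needed.
    """

    values: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.values = self.values.astype(float)
        if self.groups is not None:
            unknown = sorted(set(self.groups) - set(self.values.columns))
            if unknown:
                raise ValueError(f"group labels for unknown samples: {unknown}")

    def samples_in(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("no sample groups attached to this matrix")
        return [s for s in self.values.columns if self.groups.get(s) == group]


def read_expression_tsv(
    path: str | Path, groups: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: expression table has no sample columns")
    return ExpressionMatrix(df, dict(groups) if groups is not None else None)


def write_expression_tsv(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree (branch lengths; internal labels = supports)."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
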