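"""Marker-gene catalogs: nifH / recA reference sequences with taxonomy.

A catalog bundles the nucleotide sequences that metagenomic reads are
recruited against, together with a per-sequence taxonomy (gene class,
taxon label, broad taxonomic group).  Outgroup sequences — homologs such
as chlorophyllide-reductase subunits (nifH-like) or RAD51/RADA (recA-like)
— are part of the same catalog and act as competitive decoys that absorb
reads which would otherwise be false-positive marker assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")

GENE_CLASSES = ("nifH", "recA", "outgroup_nifH_like", "outgroup_recA_like")


class CatalogError(ValueError):
    """Raised for malformed catalogs (duplicate ids, bad sequences, missing taxonomy)."""


@dataclass(frozen=True)
class MarkerSequence:
    """One reference sequence in a marker catalog."""

    id: str
    gene_class: str
    taxon_label: str
    taxonomic_group: str
    sequence: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise CatalogError(
                f"{self.id}: gene_class {self.gene_class!r} not one of {GENE_CLASSES}"
            )
        if len(self.sequence) == 0:
            raise CatalogError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise CatalogError(
                f"{self.id}: invalid characters {sorted(bad)} (alphabet is A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_outgroup(self) -> bool:
        return self.gene_class.startswith("outgroup")


@dataclass
class MarkerCatalog:
    """An ordered collection of :class:`MarkerSequence` with unique ids."""

    sequences: list[MarkerSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate sequence ids in catalog: {dupes}")
        self._by_id = {s.id: s for s in self.sequences}

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, seq_id: str) -> MarkerSequence:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def subset(self, gene_class: str) -> list[MarkerSequence]:
        return [s for s in self.sequences if s.gene_class == gene_class]

    def for_taxon(self, taxon_label: str, gene_class: str = "nifH") -> list[MarkerSequence]:
        return [
            s
            for s in self.sequences
            if s.taxon_label == taxon_label and s.gene_class == gene_class
        ]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.sequences:
                fh.write(f">{s.id}\n{s.sequence}\n")

    def taxonomy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.sequences],
                "gene_class": [s.gene_class for s in self.sequences],
                "taxon_label": [s.taxon_label for s in self.sequences],
                "taxonomic_group": [s.taxonomic_group for s in self.sequences],
            }
        )

    def to_taxonomy_tsv(self, path) -> None:
        self.taxonomy_frame().to_csv(path, sep="\t", index=False)


def read_catalog(fasta_path, taxonomy_table_path) -> MarkerCatalog:
    """Load a marker catalog from a FASTA file and a taxonomy TSV.

    The taxonomy table must have columns ``id``, ``gene_class``,
    ``taxon_label`` and ``taxonomic_group``.  Every FASTA record needs a
    taxonomy row; records lacking one are reported by id and rejected.

    Raises
    ------
    CatalogError
        On an empty FASTA, duplicate ids, invalid sequence characters, or
        records without taxonomy.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise CatalogError(f"no FASTA records found in {fasta_path}")

    tax = pd.read_csv(taxonomy_table_path, sep="\t", dtype=str)
    required = {"id", "gene_class", "taxon_label", "taxonomic_group"}
    missing_cols = required - set(tax.columns)
    if missing_cols:
        raise CatalogError(f"taxonomy table missing columns: {sorted(missing_cols)}")
    tax_by_id = tax.set_index("id")
    if tax_by_id.index.has_duplicates:
        raise CatalogError("duplicate ids in taxonomy table")

    orphans = [r.id for r in records if r.id not in tax_by_id.index]
    if orphans:
        raise CatalogError(f"FASTA records without taxonomy rows: {orphans}")

    sequences = []
    for rec in records:
        row = tax_by_id.loc[rec.id]
        sequences.append(
            MarkerSequence(
                id=rec.id,
                gene_class=str(row["gene_class"]),
                taxon_label=str(row["taxon_label"]),
                taxonomic_group=str(row["taxonomic_group"]),
                sequence=str(rec.seq).upper(),
            )
        )
    return MarkerCatalog(sequences)
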