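"""Readers and writers for the pipeline's plain-text formats.

Reads travel as FASTA/FASTQ (Biopython); everything tabular is TSV with
stable column names: latent/recruited counts (``sample_id``, ``taxon``,
``gene``, ``count``), Ecotaxa-style detection tables (``object_id``,
``sample_id``, ``label``, ``instrument``, ``major``, ``minor``, ``unit``)
and sample metadata.  UVP5 axes recorded in mm are converted to µm on
ingestion.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .recruitment import MarkerCounts


def write_reads_fasta(reads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(reads["read_id"], reads["sequence"]):
            fh.write(f">{rid}\n{seq}\n")


def write_reads_fastq(reads: pd.DataFrame, path, quality_char: str = "I") -> None:
    """FASTQ with a fixed per-base quality (the simulator carries none)."""
    with open(path, "w") as fh:
        for rid, seq in zip(reads["read_id"], reads["sequence"]):
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_reads(path, fmt: str | None = None) -> pd.DataFrame:
    """Load reads from FASTA/FASTQ into a read_id/sequence frame."""
    fmt = fmt or ("fastq" if str(path).endswith(("fq", "fastq")) else "fasta")
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]
    return pd.DataFrame(records, columns=["read_id", "sequence"])


def counts_to_frame(counts: MarkerCounts) -> pd.DataFrame:
    rows = [
        {"sample_id": counts.sample_id, "taxon": t, "gene": "nifH", "count": c}
        for t, c in sorted(counts.reads_nifH_by_taxon.items())
    ]
    rows.append(
        {"sample_id": counts.sample_id, "taxon": "bacteria", "gene": "recA",
         "count": counts.reads_recA}
    )
    rows.append(
        {"sample_id": counts.sample_id, "taxon": "none", "gene": "outgroup",
         "count": counts.reads_outgroup}
    )
    rows.append(
        {"sample_id": counts.sample_id, "taxon": "none", "gene": "unassigned",
         "count": counts.reads_unassigned}
    )
    return pd.DataFrame(rows)


def write_counts_tsv(counts: MarkerCounts, path) -> None:
    counts_to_frame(counts).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> list[MarkerCounts]:
    """Load a counts TSV (possibly many samples) back into MarkerCounts."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        nifh = grp[grp["gene"] == "nifH"]
        out.append(
            MarkerCounts(
                sample_id=str(sid),
                reads_recA=int(grp.loc[grp["gene"] == "recA", "count"].sum()),
                reads_nifH_by_taxon={
                    str(t): int(c) for t, c in zip(nifh["taxon"], nifh["count"])
                },
                reads_outgroup=int(grp.loc[grp["gene"] == "outgroup", "count"].sum()),
                reads_unassigned=int(grp.loc[grp["gene"] == "unassigned", "count"].sum()),
            )
        )
    return out


def read_detections_tsv(path) -> pd.DataFrame:
    """Load an Ecotaxa-style detection table, normalising axes to µm.

    Accepts either ``major_um``/``minor_um`` columns or ``major``/``minor``
    plus a ``unit`` column (``um`` or ``mm``; mm values — typical for UVP5
    exports — are multiplied by 1000).
    """
    df = pd.read_csv(path, sep="\t")
    if "major_um" in df.columns and "minor_um" in df.columns:
        return df
    if "unit" not in df.columns:
        raise ValueError("detection table needs major_um/minor_um or major/minor + unit")
    scale = df["unit"].map({"um": 1.0, "mm": 1000.0})
    if scale.isna().any():
        bad = sorted(df.loc[scale.isna(), "unit"].unique())
        raise ValueError(f"unknown axis units: {bad}")
    df = df.copy()
    df["major_um"] = df["major"] * scale
    df["minor_um"] = df["minor"] * scale
    return df.drop(columns=["major", "minor", "unit"])


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
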