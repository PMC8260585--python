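"""Competitive recruitment of reads against a nifH/recA catalog.

Each read is aligned to every catalog sequence (markers and outgroup
decoys together) and assigned to at most one reference: the best hit by
alignment score, with ties broken by higher identity, then more alignment
columns, then the lexicographically smallest reference id.  The filter
gates mirror the mapping parameters used on the full ocean metagenomes
(minimum read size 70 bp, ≥80% identity, ≥80% of the read aligned,
complexity 75%/30) and are applied AFTER best-hit selection, so raising a
threshold can only move reads to "unassigned" — never between references.

Reads whose best hit is an outgroup are recorded but excluded from marker
counts; assigned + outgroup + unassigned always equals the input total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import ScoringScheme, complexity_ok, encode, _gotoh_kernel
from .catalog import MarkerCatalog

#: status values a read can end with
STATUS_ASSIGNED = "assigned"
STATUS_OUTGROUP = "outgroup"
STATUS_TOO_SHORT = "unassigned_too_short"
STATUS_LOW_COMPLEXITY = "unassigned_low_complexity"
STATUS_NO_HIT = "unassigned_below_thresholds"

UNASSIGNED_STATUSES = (STATUS_TOO_SHORT, STATUS_LOW_COMPLEXITY, STATUS_NO_HIT)

RECRUITMENT_COLUMNS = [
    "read_id",
    "reference_id",
    "score",
    "identity",
    "aligned_fraction",
    "status",
]


@dataclass(frozen=True)
class RecruitmentParams:
    """Filter set and scoring for read recruitment."""

    min_read_size: int = 70
    min_identity: float = 80.0
    min_aligned_fraction: float = 80.0
    complexity_percent: float = 75.0
    complexity_number: int = 30
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.min_read_size < 1:
            raise ValueError("min_read_size must be >= 1")
        for v, name in (
            (self.min_identity, "min_identity"),
            (self.min_aligned_fraction, "min_aligned_fraction"),
            (self.complexity_percent, "complexity_percent"),
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.complexity_number < 1:
            raise ValueError("complexity_number must be >= 1")


@dataclass
class MarkerCounts:
    """Per-sample recruited-read tallies by gene and taxon."""

    sample_id: str
    reads_recA: int = 0
    reads_nifH_by_taxon: dict[str, int] = field(default_factory=dict)
    reads_outgroup: int = 0
    reads_unassigned: int = 0

    def __post_init__(self) -> None:
        if min(
            [self.reads_recA, self.reads_outgroup, self.reads_unassigned]
            + list(self.reads_nifH_by_taxon.values()),
            default=0,
        ) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def reads_nifH(self) -> int:
        return sum(self.reads_nifH_by_taxon.values())

    @property
    def total(self) -> int:
        return self.reads_recA + self.reads_nifH + self.reads_outgroup + self.reads_unassigned

    @classmethod
    def from_latent(cls, counts_df: pd.DataFrame, level: str = "taxon") -> "MarkerCounts":
        """Build counts from a simulator latent-count frame (one sample).

        This is the idealised, alignment-free route: the latent counts are
        what a perfect recruiter would recover.
        """
        samples = counts_df["sample_id"].unique()
        if len(samples) != 1:
            raise ValueError("from_latent expects a single sample's counts")
        if level != "taxon":
            raise ValueError("latent counts support level='taxon' only")
        nifh = counts_df[counts_df["gene"] == "nifH"]
        return cls(
            sample_id=str(samples[0]),
            reads_recA=int(counts_df.loc[counts_df["gene"] == "recA", "count"].sum()),
            reads_nifH_by_taxon={
                str(t): int(c) for t, c in zip(nifh["taxon"], nifh["count"]) if c > 0
            },
            reads_outgroup=int(counts_df.loc[counts_df["gene"] == "outgroup", "count"].sum()),
            reads_unassigned=int(
                counts_df.loc[counts_df["gene"] == "unassigned", "count"].sum()
            ),
        )


def _as_read_pairs(reads) -> list[tuple[str, str]]:
    if isinstance(reads, pd.DataFrame):
        return list(zip(reads["read_id"].astype(str), reads["sequence"].astype(str)))
    return [(str(rid), str(seq)) for rid, seq in reads]


def recruit(
    reads,
    catalog: MarkerCatalog,
    params: RecruitmentParams | None = None,
) -> pd.DataFrame:
    """Assign each read to at most one catalog sequence.

    *reads* is a DataFrame with ``read_id``/``sequence`` columns or an
    iterable of (read_id, sequence) pairs.  Returns a recruitment table
    with columns ``read_id``, ``reference_id``, ``score``, ``identity``,
    ``aligned_fraction``, ``status``.  An empty read set yields an empty
    table.
    """
    if len(catalog) == 0:
        raise ValueError("catalog must be non-empty")
    p = params or RecruitmentParams()
    sc = p.scoring
    refs = [(s.id, encode(s.sequence)) for s in catalog.sequences]

    rows = []
    for read_id, seq in _as_read_pairs(reads):
        if len(seq) < p.min_read_size:
            rows.append((read_id, "", 0, np.nan, np.nan, STATUS_TOO_SHORT))
            continue
        if not complexity_ok(seq, p.complexity_percent, p.complexity_number):
            rows.append((read_id, "", 0, np.nan, np.nan, STATUS_LOW_COMPLEXITY))
            continue
        enc = encode(seq)
        best = None  # (score, identity, columns, ref_id, fraction)
        for ref_id, ref_enc in refs:
            score, matches, columns, read_bases = _gotoh_kernel(
                enc,
                ref_enc,
                np.int32(sc.match),
                np.int32(sc.mismatch),
                np.int32(-sc.gap_open),
                np.int32(-sc.gap_extend),
            )
            identity = 100.0 * matches / columns if columns else 0.0
            fraction = 100.0 * read_bases / len(seq)
            cand = (int(score), identity, int(columns), ref_id, fraction)
            if best is None or _better(cand, best):
                best = cand
        score, identity, columns, ref_id, fraction = best
        if identity < p.min_identity or fraction < p.min_aligned_fraction:
            rows.append((read_id, "", score, identity, fraction, STATUS_NO_HIT))
        elif catalog[ref_id].is_outgroup:
            rows.append((read_id, ref_id, score, identity, fraction, STATUS_OUTGROUP))
        else:
            rows.append((read_id, ref_id, score, identity, fraction, STATUS_ASSIGNED))
    return pd.DataFrame(rows, columns=RECRUITMENT_COLUMNS)


def _better(cand, best) -> bool:
    """Candidate hit ordering: score, then identity, then alignment length,
    then lexicographically smallest reference id."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    if cand[2] != best[2]:
        return cand[2] > best[2]
    return cand[3] < best[3]


COUNT_LEVELS = ("gene", "group", "taxon")


def count_marker_reads(
    recruitment_table: pd.DataFrame,
    catalog: MarkerCatalog,
    sample_id: str = "sample",
    level: str = "taxon",
) -> MarkerCounts:
    """Tally a recruitment table into :class:`MarkerCounts`.

    *level* controls the nifH key granularity: ``taxon`` (taxon label),
    ``group`` (broad taxonomic group) or ``gene`` (single "nifH" bucket).
    Counts partition the input: assigned (recA + nifH) + outgroup +
    unassigned equals the number of table rows.
    """
    if level not in COUNT_LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {COUNT_LEVELS}")
    reads_recA = 0
    nifh: dict[str, int] = {}
    outgroup = 0
    unassigned = 0
    for ref_id, status in zip(
        recruitment_table["reference_id"], recruitment_table["status"]
    ):
        if status == STATUS_OUTGROUP:
            outgroup += 1
        elif status in UNASSIGNED_STATUSES:
            unassigned += 1
        elif status == STATUS_ASSIGNED:
            ref = catalog[ref_id]
            if ref.gene_class == "recA":
                reads_recA += 1
            elif ref.gene_class == "nifH":
                if level == "gene":
                    key = "nifH"
                elif level == "group":
                    key = ref.taxonomic_group
                else:
                    key = ref.taxon_label
                nifh[key] = nifh.get(key, 0) + 1
            else:  # outgroup gene_class but assigned status: inconsistent table
                raise ValueError(f"assigned read maps to outgroup reference {ref_id}")
        else:
            raise ValueError(f"unknown recruitment status {status!r}")
    return MarkerCounts(
        sample_id=sample_id,
        reads_recA=reads_recA,
        reads_nifH_by_taxon=nifh,
        reads_outgroup=outgroup,
        reads_unassigned=unassigned,
    )
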