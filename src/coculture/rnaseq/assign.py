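"""rRNA filtering, competitive read assignment, and gene counting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..synthdata.genomes import revcomp
from ..synthdata.reads import ReadRecord
from .index import ReferenceIndex

AMBIGUOUS = "AMBIGUOUS"
UNMAPPED = "UNMAPPED"
INTERGENIC = "__intergenic__"


@dataclass
class RrnaFilterResult:
    retained: list[ReadRecord]
    removed_count: int
    unclassifiable_count: int  # reads shorter than k, retained


def filter_rrna(
    reads: list[ReadRecord], index: ReferenceIndex, min_kmer_fraction: float = 0.5
) -> RrnaFilterResult:
    """Remove reads whose k-mer content is dominated by rRNA.

    A read is removed iff at least ``min_kmer_fraction`` of its k-mers
    (canonical form) occur in the rRNA k-mer set. Reads shorter than k are
    unclassifiable: retained and counted separately.
    """
    if not reads:
        raise ValueError("reads must be non-empty")
    if not 0 < min_kmer_fraction <= 1:
        raise ValueError("min_kmer_fraction must be in (0, 1]")
    k = index.k
    retained: list[ReadRecord] = []
    removed = 0
    unclassifiable = 0
    for r in reads:
        n = len(r.seq) - k + 1
        if n < 1:
            unclassifiable += 1
            retained.append(r)
            continue
        hits = 0
        for i in range(n):
            km = r.seq[i : i + k]
            if min(km, revcomp(km)) in index.rrna_kmers:
                hits += 1
        if hits / n >= min_kmer_fraction:
            removed += 1
        else:
            retained.append(r)
    return RrnaFilterResult(retained, removed, unclassifiable)


@dataclass
class Assignment:
    category: str  # strain id, AMBIGUOUS, or UNMAPPED
    anchor: int | None  # genome position of the anchor k-mer start
    score: int


def assign_read(read: ReadRecord | str, index: ReferenceIndex,
                min_match_fraction: float = 0.5) -> Assignment:
    """Competitively assign a read to the strain with strictly maximal k-mer score.

    Score per strain = max over orientations of the number of read k-mers
    found in that strain's genome. Ties at the top score across >= 2
    strains give AMBIGUOUS; a top score below ``min_match_fraction`` of the
    read's k-mers gives UNMAPPED.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    k = index.k
    n = len(seq) - k + 1
    if n < 1:
        return Assignment(UNMAPPED, None, 0)
    fwd = [seq[i : i + k] for i in range(n)]
    rseq = revcomp(seq)
    rev = [rseq[i : i + k] for i in range(n)]

    best_scores: dict[str, tuple[int, int | None]] = {}
    for strain, table in index.strain_kmers.items():
        sc_f = anchor_f = None
        hits_f = [table.get(km) for km in fwd]
        sc_f = sum(h is not None for h in hits_f)
        anchor_f = next((h for h in hits_f if h is not None), None)
        hits_r = [table.get(km) for km in rev]
        sc_r = sum(h is not None for h in hits_r)
        anchor_r = next((h for h in hits_r if h is not None), None)
        if sc_r > sc_f:
            best_scores[strain] = (sc_r, anchor_r)
        else:
            best_scores[strain] = (sc_f, anchor_f)

    top = max(sc for sc, _ in best_scores.values())
    if top < min_match_fraction * n or top == 0:
        return Assignment(UNMAPPED, None, int(top))
    winners = [s for s, (sc, _) in best_scores.items() if sc == top]
    if len(winners) > 1:
        return Assignment(AMBIGUOUS, None, int(top))
    strain = winners[0]
    return Assignment(strain, best_scores[strain][1], int(top))


@dataclass
class LibraryAssignment:
    """Per-library assignment results and accounting."""

    library: str
    total_reads: int
    rrna: int
    per_strain: dict[str, int]
    ambiguous: int
    unmapped: int
    assignments: list[tuple[ReadRecord, Assignment]]

    def accounting_ok(self) -> bool:
        return (
            self.rrna + sum(self.per_strain.values()) + self.ambiguous + self.unmapped
            == self.total_reads
        )


def assign_library(
    reads: list[ReadRecord],
    index: ReferenceIndex,
    library: str = "lib",
    min_kmer_fraction: float = 0.5,
    min_match_fraction: float = 0.5,
) -> LibraryAssignment:
    """rRNA-filter then competitively assign every read of one library."""
    filt = filter_rrna(reads, index, min_kmer_fraction)
    per_strain = {s: 0 for s in index.strains}
    ambiguous = unmapped = 0
    assignments = []
    for r in filt.retained:
        a = assign_read(r, index, min_match_fraction)
        if a.category == AMBIGUOUS:
            ambiguous += 1
        elif a.category == UNMAPPED:
            unmapped += 1
        else:
            per_strain[a.category] += 1
        assignments.append((r, a))
    return LibraryAssignment(
        library=library,
        total_reads=len(reads),
        rrna=filt.removed_count,
        per_strain=per_strain,
        ambiguous=ambiguous,
        unmapped=unmapped,
        assignments=assignments,
    )


def count_genes(
    libraries: dict[str, LibraryAssignment], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Count assigned reads per gene per library.

    A read increments gene i iff its anchor k-mer start lies within gene
    i's interval on the assigned strain (annotation is 1-based inclusive;
    0-based half-open internally). Reads anchored outside any gene go to a
    per-library intergenic sink row. Counting is strand-agnostic.
    """
    # interval lookup per strain via sorted starts
    per_strain = {}
    for strain, sub in annotation.groupby("strain"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy() - 1  # 0-based
        ends = sub["end"].to_numpy()  # half-open
        per_strain[strain] = (starts, ends, sub["gene_id"].to_numpy())

    gene_ids = list(annotation["gene_id"]) + [INTERGENIC]
    counts = pd.DataFrame(
        0, index=pd.Index(gene_ids, name="gene_id"), columns=list(libraries)
    )
    for lib, la in libraries.items():
        col = counts[lib].to_dict()
        for _read, a in la.assignments:
            if a.category in (AMBIGUOUS, UNMAPPED) or a.anchor is None:
                continue
            starts, ends, ids = per_strain[a.category]
            j = np.searchsorted(starts, a.anchor, side="right") - 1
            if j >= 0 and a.anchor < ends[j]:
                col[ids[j]] += 1
            else:
                col[INTERGENIC] += 1
        counts[lib] = pd.Series(col)
    return counts
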