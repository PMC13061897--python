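"""K-mer reference index over concatenated strain genomes."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ..synthdata.genomes import Genomes, revcomp


def kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


@dataclass
class ReferenceIndex:
    """Per-strain k-mer -> first genomic position maps plus the rRNA k-mer set.

    Genome k-mers are stored on the forward strand only; queries probe a
    read in both orientations. The rRNA set stores canonical k-mers (the
    lexicographic min of a k-mer and its reverse complement).
    """

    k: int
    strain_kmers: dict[str, dict[str, int]]
    rrna_kmers: set[str]
    annotation: pd.DataFrame
    genome_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return sorted(self.strain_kmers)

    def gene_lengths(self) -> pd.Series:
        return self.annotation.set_index("gene_id")["length"]


def build_index(genomes: Genomes, k: int = 21) -> ReferenceIndex:
    """Index genomes and rRNA sequences with k-mers of length ``k``."""
    if k < 11:
        raise ValueError("k must be >= 11")
    ann = genomes.annotation
    glen = {s: len(seq) for s, seq in genomes.sequences.items()}
    for row in ann.itertuples():
        if row.start < 1 or row.end > glen[row.strain]:
            raise ValueError(f"gene {row.gene_id} outside genome bounds")

    strain_kmers: dict[str, dict[str, int]] = {}
    for strain, seq in genomes.sequences.items():
        d: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if km not in d:  # keep first occurrence as the anchor position
                d[km] = i
        strain_kmers[strain] = d

    rrna: set[str] = set()
    for seq in genomes.rrna.values():
        for km in kmers(seq, k):
            rc = revcomp(km)
            rrna.add(min(km, rc))
    return ReferenceIndex(
        k=k, strain_kmers=strain_kmers, rrna_kmers=rrna,
        annotation=ann.copy(), genome_lengths=glen,
    )
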