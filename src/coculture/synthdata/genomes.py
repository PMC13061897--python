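"""Toy strain genomes with annotated genes, shared genes and rRNA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SyntheticDesign

ALPHABET = np.array(list("ACGT"))

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSizingError(ValueError):
    """Raised when the requested genes cannot be packed into the genome."""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[rng.integers(0, 4, size=n)])


@dataclass
class Genomes:
    """Per-strain genome sequences plus annotation and rRNA set."""

    sequences: dict[str, str]
    annotation: pd.DataFrame  # gene_id, strain, start, end, strand, length, shared
    rrna: dict[str, str]

    def gene_sequence(self, gene_id: str) -> str:
        row = self.annotation.set_index("gene_id").loc[gene_id]
        # annotation coordinates are 1-based inclusive
        seq = self.sequences[row["strain"]][row["start"] - 1 : row["end"]]
        return revcomp(seq) if row["strand"] == "-" else seq

    def write_fasta(self, genome_path, rrna_path=None) -> None:
        with open(genome_path, "w") as fh:
            for strain in sorted(self.sequences):
                fh.write(f">{strain}\n{self.sequences[strain]}\n")
        if rrna_path is not None:
            with open(rrna_path, "w") as fh:
                for strain in sorted(self.rrna):
                    fh.write(f">rRNA_{strain}\n{self.rrna[strain]}\n")


def gen_genomes(
    design: SyntheticDesign,
    genome_len: int = 30_000,
    n_genes: int = 20,
    shared_fraction: float = 0.0,
    gene_len: int = 300,
    rrna_len: int = 600,
    spacer: int = 60,
) -> Genomes:
    """Generate one genome per strain with planted gene structure.

    The first ``round(shared_fraction * n_genes)`` genes of every strain are
    byte-identical across strains (to exercise the ambiguous-read discard);
    the rest are unique. One rRNA-like sequence per strain is embedded in the
    genome and returned in the rRNA set. Annotation coordinates are 1-based
    inclusive.
    """
    if not 0 <= shared_fraction < 1:
        raise ValueError("shared_fraction must be in [0, 1)")
    needed = n_genes * (gene_len + spacer) + rrna_len + 2 * spacer
    if needed > genome_len:
        raise GenomeSizingError(
            f"cannot pack {n_genes} genes of {gene_len} bp plus rRNA into "
            f"{genome_len} bp (need >= {needed})"
        )

    rng = np.random.default_rng([design.seed, 101])
    n_shared = int(round(shared_fraction * n_genes))
    shared_seqs = [_random_seq(rng, gene_len) for _ in range(n_shared)]

    sequences: dict[str, str] = {}
    rrna: dict[str, str] = {}
    rows = []
    for strain in design.strains:
        srng = np.random.default_rng([design.seed, 102, hash_strain(strain)])
        parts: list[str] = []
        pos = 0
        for gi in range(n_genes):
            gap = _random_seq(srng, spacer)
            parts.append(gap)
            pos += spacer
            shared = gi < n_shared
            gseq = shared_seqs[gi] if shared else _random_seq(srng, gene_len)
            strand = "+" if srng.random() < 0.5 else "-"
            parts.append(gseq if strand == "+" else revcomp(gseq))
            rows.append(
                {
                    "gene_id": f"{strain}_g{gi:04d}",
                    "strain": strain,
                    "start": pos + 1,
                    "end": pos + gene_len,
                    "strand": strand,
                    "length": gene_len,
                    "shared": shared,
                }
            )
            pos += gene_len
        rseq = _random_seq(srng, rrna_len)
        parts.append(_random_seq(srng, spacer))
        parts.append(rseq)
        pos += spacer + rrna_len
        tail = genome_len - pos
        if tail > 0:
            parts.append(_random_seq(srng, tail))
        sequences[strain] = "".join(parts)
        rrna[strain] = rseq

    annotation = pd.DataFrame(rows)
    return Genomes(sequences=sequences, annotation=annotation, rrna=rrna)


def hash_strain(strain: str) -> int:
    from .design import stable_int

    return stable_int(strain)
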