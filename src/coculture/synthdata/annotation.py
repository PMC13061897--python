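"""Synthetic gene -> KO -> pathway annotation tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def gen_annotation(
    n_genes: int,
    n_pathways: int,
    genes_per_pathway: int,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate gene->KO and KO->pathway maps.

    Every gene receives exactly one KO; pathways are disjoint KO sets of
    size ``genes_per_pathway`` drawn from a random permutation, so the
    background universe equals the full gene set and each pathway's K equals
    ``genes_per_pathway`` (capped by gene availability for the last one).
    """
    if genes_per_pathway < 1:
        raise ValueError("genes_per_pathway must be >= 1")
    rng = np.random.default_rng([seed, 401])
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    kos = [f"K{i:05d}" for i in range(n_genes)]
    gene2ko = pd.DataFrame({"gene_id": gene_ids, "ko": kos})

    perm = rng.permutation(n_genes)
    rows = []
    for p in range(n_pathways):
        members = perm[p * genes_per_pathway : (p + 1) * genes_per_pathway]
        for m in members:
            rows.append({"ko": kos[m], "pathway": f"path{p:03d}"})
    ko2path = pd.DataFrame(rows, columns=["ko", "pathway"])
    return gene2ko, ko2path
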