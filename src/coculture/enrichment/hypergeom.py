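"""Hypergeometric over-representation test over KO pathway annotations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import exp, lgamma

import pandas as pd

from .._stats import bh_adjust


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N = background size, K = annotated genes in the pathway, n = query
    size, k = overlap. Exact tail summation via log-gamma; robust for
    large N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    lo = max(0, n + K - N)
    if k <= lo:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    denom = _log_comb(N, n)
    total = 0.0
    for i in range(k, hi + 1):
        total += exp(_log_comb(K, i) + _log_comb(N - K, n - i) - denom)
    return min(total, 1.0)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # pathway, K, N, n, k, p, padj, genes
    background_size: int
    query_size: int

    def significant(self, p_cut: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["padj"] < p_cut]


def _load_map(obj, cols: tuple[str, str]) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj[list(cols)]
    return pd.read_csv(obj, sep="\t")[list(cols)]


def hypergeom_enrich(
    query: set[str] | list[str],
    gene2ko: pd.DataFrame,
    ko2path: pd.DataFrame,
    min_size: int = 10,
    p_cut: float = 0.05,
    universe: str = "ko_mapped",
) -> EnrichmentResult:
    """Pathway over-representation of a query gene set.

    The background universe is the set of genes with a KO mapping
    (``'ko_mapped'``, the clusterProfiler convention) or all genes in
    ``gene2ko`` (``'all'``). Pathways with fewer than ``min_size``
    background genes are not tested. BH adjustment is applied across the
    tested pathways. Duplicate query genes are collapsed; query genes
    outside the background are dropped.
    """
    gene2ko = _load_map(gene2ko, ("gene_id", "ko"))
    ko2path = _load_map(ko2path, ("ko", "pathway"))

    if universe == "ko_mapped":
        background = set(gene2ko.loc[gene2ko["ko"].notna(), "gene_id"])
    elif universe == "all":
        background = set(gene2ko["gene_id"])
    else:
        raise ValueError("universe must be 'ko_mapped' or 'all'")
    N = len(background)

    q = set(query) & background
    if not q:
        warnings.warn("query is empty after restriction to the background")
        return EnrichmentResult(
            pd.DataFrame(columns=["pathway", "K", "N", "n", "k", "p", "padj", "genes"]),
            N, 0,
        )
    n = len(q)

    ko_of = gene2ko.set_index("gene_id")["ko"]
    genes_by_pathway: dict[str, set[str]] = {}
    path_of_ko = ko2path.groupby("ko")["pathway"].apply(list)
    for gene in background:
        ko = ko_of.get(gene)
        if ko is None or ko not in path_of_ko:
            continue
        for p in path_of_ko[ko]:
            genes_by_pathway.setdefault(p, set()).add(gene)

    rows = []
    for pathway, members in sorted(genes_by_pathway.items()):
        K = len(members)
        if K < min_size:
            continue
        overlap = sorted(q & members)
        k = len(overlap)
        p = hypergeom_sf(k, N, K, n)
        rows.append(
            {"pathway": pathway, "K": K, "N": N, "n": n, "k": k, "p": p,
             "genes": ";".join(overlap)}
        )
    tab = pd.DataFrame(rows, columns=["pathway", "K", "N", "n", "k", "p", "genes"])
    if len(tab):
        tab["padj"] = bh_adjust(tab["p"].to_numpy())
    else:
        tab["padj"] = pd.Series(dtype=float)
    tab = tab[["pathway", "K", "N", "n", "k", "p", "padj", "genes"]]
    return EnrichmentResult(tab.sort_values("p", ignore_index=True), N, n)


def de_to_query(
    de: pd.DataFrame,
    direction: str = "up",
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> set[str]:
    """Extract an up- or down-regulated gene set from a DE table."""
    padj = de["padj"]
    lfc = de["log2FoldChange"]
    if direction == "up":
        m = (padj <= padj_max) & (lfc > lfc_min)
    elif direction == "down":
        m = (padj <= padj_max) & (lfc < -lfc_min)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return set(de.index[m.fillna(False)])
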