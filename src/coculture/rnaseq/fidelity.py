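"""Multiplexing-fidelity check: singleplex vs pooled-library deconvolution."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..synthdata.reads import ReadRecord
from .assign import assign_library, count_genes, INTERGENIC
from .de import differential_expression, significant_genes
from .index import ReferenceIndex


@dataclass
class FidelityReport:
    singleplex_counts: pd.DataFrame  # gene x sample
    multiplex_counts: pd.DataFrame  # gene x sample (deconvolved)
    pearson_r: float
    n_de_between_arms: int
    identical_on_unique: bool


def _strain_of(annotation: pd.DataFrame) -> pd.Series:
    return annotation.set_index("gene_id")["strain"]


def multiplex_fidelity(
    singleplex: dict[str, list[ReadRecord]],
    multiplexed: list[ReadRecord],
    index: ReferenceIndex,
    sample_strains: dict[str, str],
    run_de: bool = True,
) -> FidelityReport:
    """Deconvolve both arms and compare per-gene counts.

    ``sample_strains`` maps each singleplex sample to the strain it came
    from; the multiplexed library is demultiplexed by strain assignment, so
    every strain must appear for exactly one sample.
    """
    if set(singleplex) != set(sample_strains):
        raise ValueError("singleplex samples and sample_strains disagree")
    strains = list(sample_strains.values())
    if len(set(strains)) != len(strains):
        raise ValueError("each strain may appear in only one multiplexed sample")

    ann = index.annotation
    single_las = {
        s: assign_library(reads, index, library=s) for s, reads in singleplex.items()
    }
    single_counts = count_genes(single_las, ann)

    multi_la = assign_library(multiplexed, index, library="multiplex")
    multi_counts = count_genes({"multiplex": multi_la}, ann)

    # deconvolved multiplex columns: counts of strain X's genes -> sample of X
    strain_of = _strain_of(ann)
    demux = pd.DataFrame(0, index=single_counts.index, columns=single_counts.columns)
    for sample, strain in sample_strains.items():
        genes = strain_of.index[strain_of == strain]
        demux.loc[genes, sample] = multi_counts.loc[genes, "multiplex"]

    gene_rows = [g for g in single_counts.index if g != INTERGENIC]
    sc = single_counts.loc[gene_rows]
    mc = demux.loc[gene_rows]

    unique_genes = ann.loc[~ann["shared"], "gene_id"]
    identical = bool((sc.loc[unique_genes] == mc.loc[unique_genes]).all().all())

    x = np.log1p(sc.to_numpy(dtype=float)).ravel()
    y = np.log1p(mc.to_numpy(dtype=float)).ravel()
    if np.std(x) == 0 or np.std(y) == 0:
        r = 1.0 if np.array_equal(x, y) else np.nan
    else:
        r = float(np.corrcoef(x, y)[0, 1])

    n_de = 0
    if run_de:
        joint = pd.concat(
            [sc.add_suffix("|single"), mc.add_suffix("|multi")], axis=1
        )
        joint = joint.loc[(joint != 0).any(axis=1)]
        meta = pd.DataFrame(
            {"group": [c.split("|")[1] for c in joint.columns]}, index=joint.columns
        )
        try:
            de = differential_expression(
                joint, meta, mode="wald", levels=("single", "multi")
            )
            n_de = int(len(significant_genes(de)))
        except ValueError:
            n_de = 0

    return FidelityReport(
        singleplex_counts=sc,
        multiplex_counts=mc,
        pearson_r=r,
        n_de_between_arms=n_de,
        identical_on_unique=identical,
    )
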