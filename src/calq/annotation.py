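"""Regulatory-element and gene-class taxonomies.

Active regulatory elements are accessibility (ATAC) peaks that also carry
H3K27ac; they segregate into active promoters (overlapping any TSS +/- 1 kb
window) and active enhancers (the rest).  Enhancers falling entirely outside
every annotated gene are flagged intergenic, and each gene promoter can be
linked to its nearest intergenic enhancer within 250 kb.

Genes partition into three classes by promoter (TSS +/- 1 kb) overlap:
``non_NMI`` (no nonmethylated CpG island at the promoter), ``PcG``
(NMI plus both RING1B- and SUZ12-bound sites — a Polycomb target), and
``non_PcG`` (NMI without joint PRC1/PRC2 occupancy).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .intervals import (
    Genome,
    IntervalSet,
    gene_intervals,
    nearest_within,
    overlaps,
    point_windows,
)

__all__ = [
    "tss_windows",
    "call_active_elements",
    "flag_intergenic",
    "link_promoter_to_enhancer",
    "classify_genes",
]

PROMOTER_FLANK = 1000  # bp each side of the TSS for classification windows


def tss_windows(
    tss: pd.DataFrame, flank: int = PROMOTER_FLANK, genome: Optional[Genome] = None
) -> IntervalSet:
    """TSS +/- flank windows from a (chrom, pos) table; exact duplicates
    are collapsed so multiple annotation sources can be concatenated."""
    if tss.empty:
        raise ValueError("empty TSS set")
    tss = tss.drop_duplicates(subset=["chrom", "pos"])
    df = pd.DataFrame(
        {
            "chrom": tss["chrom"].to_numpy(),
            "start": np.maximum(tss["pos"].to_numpy() - flank, 0),
            "end": tss["pos"].to_numpy() + flank,
        }
    )
    if genome is not None:
        df["end"] = np.minimum(df["end"], df["chrom"].map(genome.sizes))
        df = df[df["start"] < df["end"]]
    return IntervalSet(df)


def call_active_elements(
    atac_peaks: IntervalSet,
    h3k27ac_peaks: IntervalSet,
    tss: pd.DataFrame,
    genome: Optional[Genome] = None,
) -> pd.DataFrame:
    """ATAC peaks overlapping H3K27ac, classified promoter vs enhancer.

    Element coordinates are the ATAC peak (the accessibility footprint);
    H3K27ac acts only as a filter.  Returns a DataFrame with columns
    ``chrom, start, end, element_class``.
    """
    windows = tss_windows(tss, genome=genome)
    active = overlaps(atac_peaks, h3k27ac_peaks)
    elements = atac_peaks.df.loc[active, ["chrom", "start", "end"]].reset_index(drop=True)
    is_tss = overlaps(IntervalSet(elements), windows) if len(elements) else np.array([], bool)
    elements["element_class"] = np.where(is_tss, "active_promoter", "active_enhancer")
    return elements


def flag_intergenic(elements: pd.DataFrame, gene_annotations: IntervalSet) -> pd.DataFrame:
    """Add an ``intergenic`` flag: enhancers with zero gene overlap.

    ``gene_annotations`` should be the union of every gene annotation source
    used to build the TSS set; promoters are never intergenic by definition.
    """
    out = elements.copy()
    if len(out) == 0:
        out["intergenic"] = pd.Series(dtype=bool)
        return out
    hit = overlaps(IntervalSet(out[["chrom", "start", "end"]]), gene_annotations)
    out["intergenic"] = (~hit) & (out["element_class"] == "active_enhancer")
    return out


def link_promoter_to_enhancer(
    promoters: IntervalSet,
    intergenic_enhancers: IntervalSet,
    max_dist: int = 250_000,
) -> pd.DataFrame:
    """Nearest intergenic enhancer within ``max_dist`` of each promoter.

    ``promoters`` should carry gene ids in the name column.  Returns a
    DataFrame with gene_id, enhancer_index (-1 if none within range) and
    distance (0 for overlap, NaN if unlinked).
    """
    links = nearest_within(promoters, intergenic_enhancers, max_dist)
    links.insert(0, "gene_id", promoters.df["name"].to_numpy())
    return links.rename(columns={"subject_index": "enhancer_index"})


def classify_genes(
    genes: pd.DataFrame,
    nmis: IntervalSet,
    ring1b_sites: IntervalSet,
    suz12_sites: IntervalSet,
    genome: Optional[Genome] = None,
    flank: int = PROMOTER_FLANK,
) -> pd.DataFrame:
    """Partition genes into non_NMI / PcG / non_PcG by promoter overlap.

    The promoter is TSS +/- ``flank``.  A gene is ``non_NMI`` if the
    promoter overlaps no nonmethylated island; otherwise ``PcG`` if it
    overlaps at least one RING1B-bound *and* one SUZ12-bound site, else
    ``non_PcG``.  Every gene lands in exactly one class.
    """
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    promoters = point_windows(genes, flank, genome=genome)
    has_nmi = overlaps(promoters, nmis)
    has_ring1b = overlaps(promoters, ring1b_sites)
    has_suz12 = overlaps(promoters, suz12_sites)
    cls = np.where(
        ~has_nmi, "non_NMI", np.where(has_ring1b & has_suz12, "PcG", "non_PcG")
    )
    return pd.DataFrame({"gene_id": promoters.df["name"].to_numpy(), "gene_class": cls})
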