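"""Quantitative readouts over calibrated fragments.

Counts, per-kb densities and log2 fold changes over arbitrary region sets;
fixed-size genomic bins (chromosome-scale profiles use 250-kb bins,
fold-change analyses typically 10-kb bins); per-chromatin-state fold-change
distributions with an intergenic median baseline; meta-profiles around
stranded anchors; and replicate concordance gating.

Two counting semantics coexist, each exposed explicitly:

* region counting is any-overlap (a fragment counts in every region it
  shares >= 1 bp with), matching the usual region-quantitation tools;
* bin assignment uses the fragment midpoint, so bins that partition the
  genome conserve the total fragment count exactly.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import CoverageTrack
from .intervals import Genome, IntervalSet, _trees
from .simulate import FragmentSet

__all__ = [
    "count_in_regions",
    "region_quant",
    "region_lfc",
    "binned_coverage",
    "state_fold_changes",
    "metaprofile",
    "replicate_concordance",
]


def _frag_df(frags) -> pd.DataFrame:
    return frags.target if isinstance(frags, FragmentSet) else frags


def count_in_regions(frags, regions: IntervalSet) -> np.ndarray:
    """Integer fragment count per region; any-overlap (>= 1 shared bp).

    A fragment spanning several regions is counted in each of them.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    df = _frag_df(frags)
    counts = np.zeros(len(regions), dtype=np.int64)
    trees = _trees(regions)
    if len(df):
        for chrom, sub in df.groupby("chrom", sort=False):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                for iv in tree.overlap(s, e):
                    counts[iv.data] += 1
    return counts


def region_quant(
    counts: Mapping[str, np.ndarray] | pd.DataFrame, regions: IntervalSet
) -> pd.DataFrame:
    """Per-region densities: count/kb and log2(count/kb + 1) per sample.

    ``counts`` maps sample name -> integer count vector over ``regions``.
    """
    counts = pd.DataFrame(dict(counts))
    kb = regions.lengths() / 1000.0
    out = regions.df[["chrom", "start", "end", "name"]].copy()
    for sample in counts.columns:
        dens = counts[sample].to_numpy() / kb
        out[f"count_{sample}"] = counts[sample].to_numpy()
        out[f"density_{sample}"] = dens
        out[f"log2density_{sample}"] = np.log2(dens + 1.0)
    return out


def region_lfc(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    regions: IntervalSet,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2((B/kb + pc) / (A/kb + pc)) per region; antisymmetric in A/B."""
    kb = regions.lengths() / 1000.0
    return np.log2((counts_b / kb + pseudocount) / (counts_a / kb + pseudocount))


def binned_coverage(
    frags, genome: Genome, bin_bp: int = 250_000
) -> pd.DataFrame:
    """Fragment count per fixed-size genomic bin, assigned by midpoint.

    Bins partition each chromosome, so the counts sum to the number of
    fragments exactly.  Returns columns chrom, start, end, count.
    """
    if bin_bp <= 0:
        raise ValueError("bin size must be > 0")
    df = _frag_df(frags)
    by_chrom = {c: sub for c, sub in df.groupby("chrom", sort=False)} if len(df) else {}
    records = []
    for chrom, length in genome.sizes.items():
        nbins = int(np.ceil(length / bin_bp))
        counts = np.zeros(nbins, dtype=np.int64)
        sub = by_chrom.get(chrom)
        if sub is not None and len(sub):
            mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            np.add.at(counts, np.minimum(mid // bin_bp, nbins - 1), 1)
        starts = np.arange(nbins, dtype=np.int64) * bin_bp
        ends = np.minimum(starts + bin_bp, length)
        records.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "count": counts})
        )
    return pd.concat(records, ignore_index=True)


def _bin_states(bins: pd.DataFrame, states: IntervalSet) -> np.ndarray:
    """State label of each bin, by the state covering the bin midpoint.

    Assumes the states tile each chromosome (a genome segmentation).
    """
    labels = np.full(len(bins), "", dtype=object)
    sdf = states.df
    for chrom, sub in sdf.groupby("chrom", sort=False):
        sel = bins["chrom"] == chrom
        if not sel.any():
            continue
        mids = ((bins.loc[sel, "start"] + bins.loc[sel, "end"]) // 2).to_numpy()
        sub = sub.sort_values("start")
        idx = np.clip(
            np.searchsorted(sub["start"].to_numpy(), mids, side="right") - 1,
            0,
            len(sub) - 1,
        )
        labels[sel.to_numpy()] = sub["name"].to_numpy()[idx]
    return labels


def state_fold_changes(
    frags_a,
    frags_b,
    states: IntervalSet,
    genome: Genome,
    bin_bp: int = 10_000,
    pseudocount: float = 1.0,
    baseline_state: str = "intergenic",
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-state distributions of binned log2 fold changes (B vs A).

    The genome is tiled with ``bin_bp`` bins, each assigned to the chromatin
    state covering its midpoint; the per-bin LFC is
    ``log2((count_B + pc) / (count_A + pc))``.  Returns ``(bins, summary,
    baseline)`` where ``summary`` holds per-state quartiles with 1.5 x IQR
    whiskers and ``baseline`` is the median LFC of bins in the baseline
    (intergenic) state — the genome-wide change reference.
    """
    bins_a = binned_coverage(frags_a, genome, bin_bp)
    bins_b = binned_coverage(frags_b, genome, bin_bp)
    bins = bins_a.rename(columns={"count": "count_a"})
    bins["count_b"] = bins_b["count"].to_numpy()
    bins["lfc"] = np.log2(
        (bins["count_b"] + pseudocount) / (bins["count_a"] + pseudocount)
    )
    bins["state"] = _bin_states(bins, states)
    wanted = pd.unique(states.df["name"])
    rows = []
    for state in wanted:
        x = bins.loc[bins["state"] == state, "lfc"].to_numpy()
        if len(x) == 0:
            warnings.warn(f"state {state!r} absent from the binned segmentation")
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "state": state,
                "n": len(x),
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_lo": max(x.min(), q1 - 1.5 * iqr),
                "whisker_hi": min(x.max(), q3 + 1.5 * iqr),
            }
        )
    summary = pd.DataFrame(rows)
    base = bins.loc[bins["state"] == baseline_state, "lfc"]
    baseline = float(base.median()) if len(base) else float("nan")
    return bins, summary, baseline


def metaprofile(
    track: CoverageTrack,
    anchors: IntervalSet,
    flank_bp: int,
    nbins: int,
    stat: str = "mean",
) -> np.ndarray:
    """Per-bin mean or median read density around stranded anchors.

    The window is anchor midpoint +/- ``flank_bp``, split into ``nbins``
    equal bins; minus-strand anchors are reversed so bins run 5' -> 3'.
    Windows exceeding chromosome bounds are clipped with a warning (bins
    that fall entirely outside contribute nothing).
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    rows = []
    clipped = 0
    for row in anchors.df.itertuples(index=False):
        length = track.genome.sizes[row.chrom]
        center = (row.start + row.end) / 2.0
        lo, hi = center - flank_bp, center + flank_bp
        cuts = np.linspace(lo, hi, nbins + 1)
        vals = np.full(nbins, np.nan)
        if lo < 0 or hi > length:
            clipped += 1
        for i in range(nbins):
            a, b = max(cuts[i], 0.0), min(cuts[i + 1], float(length))
            if b > a:
                vals[i] = track.mean_over(row.chrom, a, b)
        if row.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    if clipped:
        warnings.warn(f"{clipped} anchor window(s) clipped to chromosome bounds")
    mat = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        return np.nanmean(mat, axis=0) if stat == "mean" else np.nanmedian(mat, axis=0)


def replicate_concordance(
    counts: pd.DataFrame,
    regions: IntervalSet,
    threshold: float = 0.9,
) -> tuple[pd.DataFrame, bool]:
    """Pairwise Pearson correlation of log2(count/kb + 1) across replicates.

    ``counts``: regions x replicates.  Merge is permitted only when every
    pairwise correlation exceeds ``threshold``; a zero-variance replicate
    yields undefined correlations and refuses the merge.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 replicates")
    kb = regions.lengths() / 1000.0
    log_dens = np.log2(counts.to_numpy() / kb[:, None] + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(log_dens, rowvar=False)
    rmat = pd.DataFrame(r, index=counts.columns, columns=counts.columns)
    off = rmat.to_numpy()[~np.eye(len(rmat), dtype=bool)]
    merge_ok = bool(np.all(np.isfinite(off)) and (off > threshold).all())
    return rmat, merge_ok
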