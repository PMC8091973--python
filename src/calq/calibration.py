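"""Spike-in calibration: mixing-corrected subsampling factors and coverage.

The calibration model
---------------------
Each sample mixes target cells with a fixed fraction of spike-in cells, so
the spike-in genome receives a constant share of the sequencing material per
cell.  For ChIP/ATAC sample ``i`` let ``S_i``/``M_i`` be the spike-in/target
fragment counts and ``s_i``/``m_i`` the same counts in the matched
input/gDNA control.  The control ratio ``alpha_i = s_i / m_i`` estimates the
realized cell mixing: doubling the spike-in cell input doubles both ``S_i``
and ``alpha_i``, so the mixing-corrected spike-in depth

    D_i = S_i / alpha_i

is invariant to pipetting variation in the mix and proportional to the
sequencing depth per target cell.  Target fragments are randomly subsampled
with probability

    p_i = min_j D_j / D_i

which places every sample at the corrected spike-in depth of the shallowest
sample (the minimum is the only reference that avoids upsampling).  After
subsampling, target coverage is directly comparable across samples on a
per-cell scale, which is what exposes genome-wide occupancy shifts that
per-library normalization silently divides away.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .intervals import Genome, IntervalSet
from .simulate import FragmentSet

__all__ = [
    "compute_calibration",
    "subsample_fragments",
    "filter_blacklist",
    "CoverageTrack",
    "pileup",
    "ratio_track",
]


def compute_calibration(
    chip: Mapping[str, FragmentSet],
    control: Mapping[str, FragmentSet],
) -> pd.DataFrame:
    """Per-sample calibration factors from ChIP/ATAC and matched controls.

    Returns a DataFrame indexed by sample with columns ``S`` (spike-in
    fragments in ChIP), ``M`` (target fragments in ChIP), ``s``/``m`` (the
    same in the matched input/gDNA), ``alpha = s/m``, ``D = S/alpha`` and the
    subsampling probability ``p = min(D)/D``.  Exactly the shallowest
    sample(s) get ``p = 1``; all others ``p < 1``.
    """
    rows = []
    for name, fs in chip.items():
        if name not in control:
            raise ValueError(f"sample {name!r} has no matched input/gDNA control")
        ctrl = control[name]
        S, M = fs.n_spike, fs.n_target
        s, m = ctrl.n_spike, ctrl.n_target
        for label, value in (("spike-in ChIP", S), ("target ChIP", M),
                             ("spike-in control", s), ("target control", m)):
            if value <= 0:
                raise ValueError(f"sample {name!r}: zero {label} fragment count")
        alpha = s / m
        rows.append((name, S, M, s, m, alpha, S / alpha))
    table = pd.DataFrame(
        rows, columns=["sample", "S", "M", "s", "m", "alpha", "D"]
    ).set_index("sample")
    table["p"] = table["D"].min() / table["D"]
    return table


def _sample_stream(seed: int, sample: str) -> np.random.Generator:
    # one stream per sample so adding samples never perturbs others
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(sample.encode()) & 0x7FFFFFFF]
    )


def subsample_fragments(frags: FragmentSet, p: float, seed: int) -> FragmentSet:
    """Keep each target fragment independently with probability ``p``.

    Spike-in fragments have served their purpose in factor computation and
    are dropped from the output.  Deterministic under ``seed``: the RNG
    stream is keyed by (seed, sample name).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"subsampling probability must be in (0, 1], got {p}")
    rng = _sample_stream(seed, frags.sample)
    keep = rng.random(len(frags.target)) < p
    return FragmentSet(
        sample=frags.sample,
        condition=frags.condition,
        target=frags.target[keep].reset_index(drop=True),
        spike=frags.spike.iloc[0:0].copy(),
    )


def filter_blacklist(frags: FragmentSet, blacklist: IntervalSet) -> FragmentSet:
    """Drop target fragments overlapping any blacklisted region."""
    from .intervals import overlaps

    if len(blacklist) == 0 or len(frags.target) == 0:
        return frags
    hit = overlaps(IntervalSet(frags.target), blacklist)
    return FragmentSet(
        sample=frags.sample,
        condition=frags.condition,
        target=frags.target[~hit].reset_index(drop=True),
        spike=frags.spike,
    )


@dataclass
class CoverageTrack:
    """A per-chromosome step function bp -> depth, run-length encoded.

    ``segments[chrom] = (edges, values)`` where ``edges`` has length k+1
    spanning [0, chrom length] and ``values`` has length k; depth is
    ``values[i]`` on ``[edges[i], edges[i+1])``.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray]]
    genome: Genome
    sample: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        for chrom, (edges, values) in self.segments.items():
            if len(edges) != len(values) + 1:
                raise ValueError(f"{chrom}: edges/values length mismatch")
        self._cum_cache: dict[str, np.ndarray] = {}

    def total_signal(self) -> float:
        """Sum over bp of depth(bp) = sum of fragment lengths for a pileup."""
        out = 0.0
        for edges, values in self.segments.values():
            out += float((np.diff(edges) * values).sum())
        return out

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum_cache:
            edges, values = self.segments[chrom]
            self._cum_cache[chrom] = np.concatenate(
                [[0.0], np.cumsum(np.diff(edges) * values)]
            )
        return self._cum_cache[chrom]

    def integral(self, chrom: str, pos: float) -> float:
        """Integral of depth over [0, pos)."""
        edges, values = self.segments[chrom]
        pos = min(max(pos, edges[0]), edges[-1])
        i = int(np.searchsorted(edges, pos, side="right")) - 1
        i = min(i, len(values) - 1)
        cum = self._cumulative(chrom)
        return float(cum[i] + values[i] * (pos - edges[i]))

    def mean_over(self, chrom: str, start: float, end: float) -> float:
        """Mean depth over [start, end) (clipped to the chromosome)."""
        if end <= start:
            raise ValueError("empty window")
        return (self.integral(chrom, end) - self.integral(chrom, start)) / (end - start)

    def binned(self, bin_bp: int) -> dict[str, np.ndarray]:
        """Mean depth per fixed-size bin (last bin may be short)."""
        out = {}
        for chrom, length in self.genome.sizes.items():
            nbins = int(np.ceil(length / bin_bp))
            cum = self._cumulative(chrom)
            edges, values = self.segments[chrom]
            cuts = np.minimum(np.arange(nbins + 1) * bin_bp, length).astype(float)
            idx = np.clip(np.searchsorted(edges, cuts, side="right") - 1, 0, len(values) - 1)
            integ = cum[idx] + values[idx] * (cuts - edges[idx])
            out[chrom] = np.diff(integ) / np.diff(cuts)
        return out

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, (edges, values) in self.segments.items():
                for i, v in enumerate(values):
                    if v != 0:
                        fh.write(f"{chrom}\t{int(edges[i])}\t{int(edges[i + 1])}\t{v:g}\n")

    @classmethod
    def constant(cls, genome: Genome, value: float = 0.0, **kw) -> "CoverageTrack":
        segs = {
            c: (np.array([0.0, float(l)]), np.array([float(value)]))
            for c, l in genome.sizes.items()
        }
        return cls(segs, genome, **kw)


def pileup(frags: pd.DataFrame | FragmentSet, genome: Genome, sample: str = "",
           calibrated: bool = False) -> CoverageTrack:
    """Fragment pileup: depth(x) = number of fragments covering x.

    Conserves base pairs exactly: the integral of the track equals the sum
    of fragment lengths.
    """
    if isinstance(frags, FragmentSet):
        sample = sample or frags.sample
        frags = frags.target
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom = {c: sub for c, sub in frags.groupby("chrom", sort=False)} if len(frags) else {}
    for chrom, length in genome.sizes.items():
        sub = by_chrom.get(chrom)
        if sub is None or not len(sub):
            segments[chrom] = (np.array([0.0, float(length)]), np.array([0.0]))
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts.min() < 0 or ends.max() > length:
            raise ValueError(f"fragment outside chromosome {chrom}")
        edges = np.unique(np.concatenate([[0, length], starts, ends])).astype(float)
        delta = np.zeros(len(edges))
        np.add.at(delta, np.searchsorted(edges, starts), 1.0)
        np.add.at(delta, np.searchsorted(edges, ends), -1.0)
        values = np.cumsum(delta)[:-1]
        segments[chrom] = (edges, values)
    return CoverageTrack(segments, genome, sample=sample, calibrated=calibrated)


def ratio_track(
    a: CoverageTrack,
    b: CoverageTrack,
    pseudocount: float = 1.0,
    bin_bp: int = 50,
) -> CoverageTrack:
    """log2((a + pc) / (b + pc)) on a common fixed-size binning.

    Both tracks are binned to ``bin_bp`` (mean depth per bin) before the
    ratio, mirroring differential coverage track generation.
    """
    if a.genome.sizes != b.genome.sizes:
        raise ValueError("tracks are on different genomes")
    ba, bb = a.binned(bin_bp), b.binned(bin_bp)
    segments = {}
    for chrom, length in a.genome.sizes.items():
        va = np.log2((ba[chrom] + pseudocount) / (bb[chrom] + pseudocount))
        nbins = len(va)
        edges = np.minimum(np.arange(nbins + 1) * bin_bp, length).astype(float)
        segments[chrom] = (edges, va)
    return CoverageTrack(
        segments, a.genome, sample=f"log2({a.sample}/{b.sample})", calibrated=True
    )
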