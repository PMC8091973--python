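"""Synthetic spike-in-mixed experiments with known ground truth.

The generator emulates two-condition, replicated, calibrated sequencing
designs in which cells of a target species are mixed with a small, fixed
proportion of cells from another species before library preparation:

* ChIP/ATAC-like fragment data: fragment positions drawn per chromatin
  state with intensity proportional to the state enrichment, times a
  genome-wide occupancy multiplier in the perturbed condition; spike-in
  fragments drawn uniformly with an expected share set by the cell mixing
  fraction; matched input/gDNA samples drawn uniformly over both genomes at
  the same mixing.
* RNA-like count data: negative-binomial per-gene counts with known size
  factors and per-gene log2 fold changes; a parallel block of spike-in gene
  counts that scales only with sequencing depth and the mixing jitter; and
  per-sample gDNA spike/target read ratios consistent with the mixing.

Every generator is a pure function of its parameters and the seed, so
re-runs are byte-identical and the emitted truth tables are sufficient to
score every downstream stage.

Default scale is deliberately small (target genome 2 x 5 Mb, spike-in
1 x 2 Mb) so a full simulated experiment runs in seconds.  The default cell
mixing fraction (0.04) mirrors a ~25:1 target:spike cell mix; per-sample
mixing jitter is lognormal with sigma 0.15, emulating pipetting variation in
the spike-in cell mix.  Fragment length is fixed (200 bp): sonication size
distributions do not affect counting logic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .intervals import Genome, IntervalSet

__all__ = [
    "SimTruth",
    "FragmentSet",
    "default_target_genome",
    "default_spike_genome",
    "make_state_segmentation",
    "simulate_chip_experiment",
    "make_rna_genes",
    "simulate_rna_counts",
    "make_fixture_annotations",
]

DEFAULT_STATE_ENRICHMENT = {
    "intergenic": 1.0,
    "active": 3.0,
    "polycomb": 8.0,
    "heterochromatin": 0.5,
}

DEFAULT_STATE_FRACTIONS = {
    "intergenic": 0.55,
    "active": 0.2,
    "polycomb": 0.1,
    "heterochromatin": 0.15,
}


def _stream(seed: int, *keys) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, *keys); strings are hashed."""
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


@dataclass
class SimTruth:
    """Ground truth for a simulated calibrated experiment.

    mixing_fraction
        Fraction of spike-in cells in the mix, in (0, 1).
    global_shift
        Genome-wide occupancy multiplier applied to the perturbed condition
        ("B"); 1.0 means no global change.
    state_enrichment
        Per-state fragment intensity multipliers over the uniform background.
    de_table
        gene_id -> true log2 fold change (condition B vs A) for RNA counts.
    size_factors
        True per-sample sequencing-depth multipliers for RNA samples,
        ordered A replicates then B replicates; drawn lognormally if None.
    mixing_jitter_sigma
        Lognormal sigma of the per-sample spike-in mixing jitter.
    """

    mixing_fraction: float = 0.04
    global_shift: float = 1.0
    state_enrichment: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_ENRICHMENT)
    )
    de_table: Optional[pd.Series] = None
    size_factors: Optional[np.ndarray] = None
    mixing_jitter_sigma: float = 0.15
    fragment_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing_fraction < 1.0:
            raise ValueError("mixing_fraction must be in (0, 1)")
        if self.global_shift <= 0:
            raise ValueError("global_shift must be > 0")
        for state, mult in self.state_enrichment.items():
            if mult <= 0:
                raise ValueError(f"enrichment for state {state!r} must be > 0")


@dataclass
class FragmentSet:
    """Aligned fragments of one sample, partitioned by genome of origin."""

    sample: str
    target: pd.DataFrame  # columns chrom, start, end
    spike: pd.DataFrame
    condition: Optional[str] = None

    @property
    def n_target(self) -> int:
        return len(self.target)

    @property
    def n_spike(self) -> int:
        return len(self.spike)

    def target_intervals(self) -> IntervalSet:
        return IntervalSet(self.target)


def default_target_genome() -> Genome:
    return Genome({"chr1": 5_000_000, "chr2": 5_000_000}, label="target")


def default_spike_genome() -> Genome:
    return Genome({"spk1": 2_000_000}, label="spike-in")


def make_state_segmentation(
    genome: Genome,
    seed: int = 0,
    block_bp: int = 50_000,
    fractions: Optional[Mapping[str, float]] = None,
) -> IntervalSet:
    """Partition the genome into fixed-size blocks with random state labels.

    Stands in for an unsupervised chromatin-state segmentation: every bp of
    every chromosome is assigned exactly one state, so the returned set tiles
    the genome.
    """
    fractions = dict(fractions or DEFAULT_STATE_FRACTIONS)
    names = list(fractions)
    probs = np.array([fractions[s] for s in names], dtype=float)
    probs = probs / probs.sum()
    rng = _stream(seed, "states")
    records = []
    for chrom, length in genome.sizes.items():
        edges = list(range(0, length, block_bp)) + [length]
        labels = rng.choice(len(names), size=len(edges) - 1, p=probs)
        for i in range(len(edges) - 1):
            records.append((chrom, edges[i], edges[i + 1], names[labels[i]]))
    return IntervalSet(pd.DataFrame(records, columns=["chrom", "start", "end", "name"]))


# -- ChIP/ATAC-like fragment simulation ------------------------------------

def _uniform_fragments(
    rng: np.random.Generator, genome: Genome, n: int, frag_len: int
) -> pd.DataFrame:
    chroms = np.array(genome.chroms)
    lengths = np.array([genome.sizes[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    starts = (rng.random(n) * lengths[ci]).astype(np.int64)
    ends = np.minimum(starts + frag_len, lengths[ci].astype(np.int64))
    df = pd.DataFrame({"chrom": chroms[ci], "start": starts, "end": ends})
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _state_fragments(
    rng: np.random.Generator,
    states: IntervalSet,
    enrichment: Mapping[str, float],
    n: int,
    frag_len: int,
    genome: Genome,
) -> pd.DataFrame:
    df = states.df
    w = (df["end"] - df["start"]).to_numpy(dtype=float) * np.array(
        [enrichment.get(s, 1.0) for s in df["name"]]
    )
    si = rng.choice(len(df), size=n, p=w / w.sum())
    s0 = df["start"].to_numpy()[si]
    s1 = df["end"].to_numpy()[si]
    starts = (s0 + rng.random(n) * (s1 - s0)).astype(np.int64)
    limits = df["chrom"].map(genome.sizes).to_numpy()[si]
    ends = np.minimum(starts + frag_len, limits)
    out = pd.DataFrame({"chrom": df["chrom"].to_numpy()[si], "start": starts, "end": ends})
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def simulate_chip_experiment(
    genome_target: Genome,
    genome_spike: Genome,
    states: IntervalSet,
    truth: SimTruth,
    n_replicates: int = 1,
    depth: int = 200_000,
    input_depth: Optional[int] = None,
) -> dict[str, FragmentSet]:
    """Simulate a two-condition calibrated ChIP/ATAC experiment.

    Each sample sequences ``depth`` fragments in total, split between target
    and spike-in genomes in proportion to their material: target weight is
    ``(1 - c) * mean_occupancy`` (times ``global_shift`` in condition B) and
    spike weight is ``c * jitter_i`` for cell mixing fraction ``c``.  Matched
    inputs use the same per-sample cell mix but uniform occupancy, so the
    spike/target ratio of an input estimates the mixing alone.

    Returns a dict of FragmentSets keyed ``{cond}_rep{r}`` for the
    ChIP samples and ``{cond}_rep{r}_input`` for their matched inputs.
    """
    if genome_target.total_bp == 0 or genome_spike.total_bp == 0:
        raise ValueError("zero-length genome")
    if input_depth is None:
        input_depth = depth
    c = truth.mixing_fraction
    frag_len = truth.fragment_length
    sdf = states.df
    state_bp = (sdf["end"] - sdf["start"]).to_numpy(dtype=float)
    mean_occ = float(
        (state_bp * np.array([truth.state_enrichment.get(s, 1.0) for s in sdf["name"]])).sum()
        / state_bp.sum()
    )
    out: dict[str, FragmentSet] = {}
    for cond in ("A", "B"):
        shift = truth.global_shift if cond == "B" else 1.0
        for rep in range(1, n_replicates + 1):
            name = f"{cond}_rep{rep}"
            rng = _stream(truth.seed, "chip", name)
            jitter = float(np.exp(rng.normal(0.0, truth.mixing_jitter_sigma)))
            # ChIP sample: target material scales with occupancy.
            w_t = (1.0 - c) * mean_occ * shift
            w_s = c * jitter
            n_spike = int(rng.binomial(depth, w_s / (w_t + w_s)))
            chip = FragmentSet(
                sample=name,
                condition=cond,
                target=_state_fragments(
                    rng, states,
                    {k: v * shift for k, v in truth.state_enrichment.items()},
                    depth - n_spike, frag_len, genome_target,
                ),
                spike=_uniform_fragments(rng, genome_spike, n_spike, frag_len),
            )
            out[name] = chip
            # Matched input: same cell mix, uniform occupancy.
            rng_in = _stream(truth.seed, "input", name)
            w_t_in = 1.0 - c
            n_spike_in = int(rng_in.binomial(input_depth, w_s / (w_t_in + w_s)))
            out[f"{name}_input"] = FragmentSet(
                sample=f"{name}_input",
                condition=cond,
                target=_uniform_fragments(
                    rng_in, genome_target, input_depth - n_spike_in, frag_len
                ),
                spike=_uniform_fragments(rng_in, genome_spike, n_spike_in, frag_len),
            )
    return out


# -- RNA-like count simulation ---------------------------------------------

def make_rna_genes(
    n_genes: int,
    seed: int = 0,
    mean_baseline: float = 100.0,
    prefix: str = "gene",
    length_range: tuple[int, int] = (500, 10_000),
) -> pd.DataFrame:
    """Gene table (gene_id, length_bp, baseline) with lognormal baselines."""
    rng = _stream(seed, "rna_genes", prefix)
    baseline = mean_baseline * np.exp(rng.normal(0.0, 1.0, n_genes) - 0.5)
    lengths = rng.integers(length_range[0], length_range[1], n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i:05d}" for i in range(n_genes)],
            "length_bp": lengths,
            "baseline": baseline,
        }
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2 (Poisson if 0)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_rna_counts(
    genes_target: pd.DataFrame,
    genes_spike: pd.DataFrame,
    truth: SimTruth,
    dispersion: float = 0.05,
    n_replicates: int = 3,
) -> dict:
    """Simulate a calibrated RNA count experiment.

    Target gene counts are NB(mean = baseline * sf_i * 2^(lfc_g * [cond==B]),
    dispersion); spike-in gene counts are NB(mean = baseline * sf_i *
    jitter_i) — they carry the sequencing depth and the cell-mixing jitter
    but no condition effect.  The emitted gDNA ratio rho_i is proportional to
    the true mixing of sample i, so dividing spike counts by rho_i cancels
    the jitter.

    Returns a dict with keys ``target`` (genes x samples counts), ``spike``,
    ``rho`` (per-sample gDNA spike/target read ratio), ``conditions``,
    ``size_factors`` (truth), ``jitter`` (truth).
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    samples = [f"A_rep{r}" for r in range(1, n_replicates + 1)] + [
        f"B_rep{r}" for r in range(1, n_replicates + 1)
    ]
    conditions = pd.Series(["A"] * n_replicates + ["B"] * n_replicates, index=samples)
    rng = _stream(truth.seed, "rna")
    if truth.size_factors is not None:
        sf = np.asarray(truth.size_factors, dtype=float)
        if len(sf) != len(samples):
            raise ValueError("size_factors truth must have one entry per sample")
    else:
        sf = np.exp(rng.normal(0.0, 0.2, len(samples)))
    jitter = np.exp(rng.normal(0.0, truth.mixing_jitter_sigma, len(samples)))
    lfc = np.zeros(len(genes_target))
    if truth.de_table is not None:
        lfc = (
            pd.Series(0.0, index=genes_target["gene_id"])
            .add(truth.de_table, fill_value=0.0)
            .reindex(genes_target["gene_id"])
            .to_numpy()
        )
    is_b = (conditions == "B").to_numpy()
    base_t = genes_target["baseline"].to_numpy()[:, None]
    mean_t = base_t * sf[None, :] * np.power(2.0, lfc[:, None] * is_b[None, :])
    base_s = genes_spike["baseline"].to_numpy()[:, None]
    mean_s = base_s * (sf * jitter)[None, :]
    target = pd.DataFrame(
        _nb_draw(rng, mean_t, dispersion),
        index=genes_target["gene_id"],
        columns=samples,
    )
    spike = pd.DataFrame(
        _nb_draw(rng, mean_s, dispersion),
        index=genes_spike["gene_id"],
        columns=samples,
    )
    c = truth.mixing_fraction
    rho = pd.Series(c * jitter / (1.0 - c), index=samples, name="rho")
    return {
        "target": target,
        "spike": spike,
        "rho": rho,
        "conditions": conditions,
        "size_factors": pd.Series(sf, index=samples, name="size_factor"),
        "jitter": pd.Series(jitter, index=samples, name="jitter"),
        "lfc_truth": pd.Series(lfc, index=genes_target["gene_id"], name="lfc"),
    }


# -- annotation fixtures ---------------------------------------------------

def make_fixture_annotations(
    genome_target: Genome,
    n_genes: int = 1000,
    seed: int = 0,
    frac_nmi: float = 0.7,
    frac_pcg_given_nmi: float = 0.4,
    frac_active_promoter: float = 0.5,
    frac_genic_enhancer: float = 0.15,
    frac_intergenic_enhancer: float = 0.2,
) -> dict:
    """Build gene/peak fixtures with the overlap structure the annotation
    stage assumes, plus truth labels for every classification.

    Genes are laid out on a regular grid so that promoter windows of
    neighbouring genes never collide and every planted overlap is
    unambiguous.  A fraction of genes carry a nonmethylated island (NMI) at
    their promoter; a subfraction of those additionally carry both RING1B-
    and SUZ12-bound sites (PcG class).  Some non-PcG genes carry only one of
    the two Polycomb marks and some non-NMI genes carry both, to exercise
    the classification rules.  Accessibility (ATAC) and H3K27ac peaks
    co-occur at designated active promoters and enhancers; decoy peaks with
    only one mark are planted and must not become elements.

    Returns a dict of gene table, interval sets, and truth DataFrames
    (``gene_truth`` with gene_class; ``element_truth`` with element_class and
    intergenic flag, aligned to the planted ATAC peaks that form elements).
    """
    total = genome_target.total_bp
    spacing = total // n_genes
    if spacing < 10_000:
        raise ValueError("genome too small for n_genes (need >= 10 kb per gene)")
    rng = _stream(seed, "fixture")

    chroms = genome_target.chroms
    lengths = [genome_target.sizes[c] for c in chroms]
    # genes per chromosome proportional to length
    per_chrom = [int(round(n_genes * l / total)) for l in lengths]
    per_chrom[-1] = n_genes - sum(per_chrom[:-1])

    genes = []
    gi = 0
    for chrom, length, cnt in zip(chroms, lengths, per_chrom):
        step = length // max(cnt, 1)
        for k in range(cnt):
            start = k * step + 2000
            glen = int(rng.integers(2000, 5001))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((chrom, start, start + glen, strand, f"g{gi:05d}"))
            gi += 1
    genes = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"])
    tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])

    u = rng.random(n_genes)
    has_nmi = u < frac_nmi
    is_pcg = has_nmi & (rng.random(n_genes) < frac_pcg_given_nmi)
    gene_class = np.where(~has_nmi, "non_NMI", np.where(is_pcg, "PcG", "non_PcG"))

    nmi, ring1b, suz12 = [], [], []
    for i in range(n_genes):
        chrom, t = genes.at[i, "chrom"], int(tss[i])
        if has_nmi[i]:
            nmi.append((chrom, t - 500, t + 500))
        if is_pcg[i]:
            ring1b.append((chrom, t - 400, t + 400))
            suz12.append((chrom, t - 350, t + 450))
        elif has_nmi[i] and rng.random() < 0.3:
            # one mark only: must stay non_PcG
            (ring1b if rng.random() < 0.5 else suz12).append((chrom, t - 400, t + 400))
        elif not has_nmi[i] and rng.random() < 0.1:
            # both marks without an NMI: must stay non_NMI
            ring1b.append((chrom, t - 400, t + 400))
            suz12.append((chrom, t - 350, t + 450))

    atac, k27ac, element_truth = [], [], []
    for i in range(n_genes):
        chrom, t = genes.at[i, "chrom"], int(tss[i])
        gstart, gend = int(genes.at[i, "start"]), int(genes.at[i, "end"])
        strand = genes.at[i, "strand"]
        r = rng.random()
        if r < frac_active_promoter:
            a = (chrom, t - 300, t + 300)
            atac.append(a)
            k27ac.append((chrom, t - 400, t + 200))
            element_truth.append((*a, "active_promoter", False))
        if rng.random() < frac_genic_enhancer:
            # inside the gene body, > 1 kb from this (and every) TSS
            pos = gstart + 300 if strand == "-" else gend - 600
            if min(abs(pos - t), abs(pos + 300 - t)) > 1200:
                a = (chrom, pos, pos + 300)
                atac.append(a)
                k27ac.append((chrom, pos - 100, pos + 200))
                element_truth.append((*a, "active_enhancer", False))
        if rng.random() < frac_intergenic_enhancer:
            # in the gap downstream of the gene interval, clear of genes/TSSs
            pos = gend + 1500
            if pos + 300 < genome_target.sizes[chrom]:
                a = (chrom, pos, pos + 300)
                atac.append(a)
                k27ac.append((chrom, pos - 100, pos + 200))
                element_truth.append((*a, "active_enhancer", True))
        if rng.random() < 0.1:
            # decoy: ATAC without H3K27ac -> not an element
            pos = gend + 2500
            if pos + 200 < genome_target.sizes[chrom]:
                atac.append((chrom, pos, pos + 200))
        if rng.random() < 0.1:
            # decoy: H3K27ac without ATAC -> not an element
            pos = gend + 3000
            if pos + 200 < genome_target.sizes[chrom]:
                k27ac.append((chrom, pos, pos + 200))

    def _iset(records, cols=("chrom", "start", "end")):
        return IntervalSet(pd.DataFrame(records, columns=list(cols)))

    return {
        "genes": genes,
        "tss": pd.DataFrame({"chrom": genes["chrom"], "pos": tss}),
        "nmis": _iset(nmi),
        "ring1b_sites": _iset(ring1b),
        "suz12_sites": _iset(suz12),
        "atac_peaks": _iset(sorted(atac)),
        "h3k27ac_peaks": _iset(sorted(k27ac)),
        "states": make_state_segmentation(genome_target, seed=seed),
        "gene_truth": pd.DataFrame(
            {"gene_id": genes["gene_id"], "gene_class": gene_class}
        ),
        "element_truth": pd.DataFrame(
            element_truth,
            columns=["chrom", "start", "end", "element_class", "intergenic"],
        ),
    }
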