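"""Region counts, genomic bins, state fold changes, meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from calq.calibration import CoverageTrack, pileup
from calq.intervals import Genome, IntervalSet
from calq.quantify import (
    binned_coverage,
    count_in_regions,
    metaprofile,
    region_lfc,
    region_quant,
    replicate_concordance,
    state_fold_changes,
)


@pytest.fixture
def genome():
    return Genome({"chr1": 1_000_000})


def test_region_density_log2(genome):
    regions = IntervalSet.from_records([("chr1", 0, 2000)])
    frags = pd.DataFrame({"chrom": "chr1", "start": np.arange(7) * 100, "end": np.arange(7) * 100 + 50})
    counts = count_in_regions(frags, regions)
    quant = region_quant({"s1": counts}, regions)
    assert quant.loc[0, "count_s1"] == 7
    assert quant.loc[0, "density_s1"] == pytest.approx(3.5)
    assert quant.loc[0, "log2density_s1"] == pytest.approx(np.log2(4.5), abs=1e-9)


def test_fragment_spanning_abutting_regions_counted_in_both():
    regions = IntervalSet.from_records([("chr1", 0, 100), ("chr1", 100, 200)])
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [110]})
    assert count_in_regions(frags, regions).tolist() == [1, 1]
    with pytest.raises(ValueError, match="empty region"):
        count_in_regions(frags, IntervalSet.empty())


def test_count_in_regions_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n_r, n_f = rng.integers(1, 20), rng.integers(0, 50)
        rs = rng.integers(0, 1000, n_r)
        regions = IntervalSet(
            pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], n_r),
                          "start": rs, "end": rs + rng.integers(1, 200, n_r)})
        )
        fs = rng.integers(0, 1000, n_f)
        frags = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], n_f),
                              "start": fs, "end": fs + rng.integers(1, 100, n_f)})
        counts = count_in_regions(frags, regions)
        rdf = regions.df
        for i in range(n_r):
            expected = int(
                ((frags["chrom"] == rdf.loc[i, "chrom"])
                 & (frags["start"] < rdf.loc[i, "end"])
                 & (frags["end"] > rdf.loc[i, "start"])).sum()
            )
            assert counts[i] == expected


def test_binned_coverage_midpoint_and_conservation(genome):
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300]})
    bins = binned_coverage(frags, genome, bin_bp=250_000)
    assert bins.loc[0, "count"] == 1  # midpoint 200 -> first bin
    assert bins["count"].sum() == 1
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 999_000, 5000)
    frags = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200})
    bins = binned_coverage(frags, genome, bin_bp=10_000)
    assert bins["count"].sum() == 5000  # bins partition the genome
    # uniform simulation: counts ~ Poisson(50), all within 4 sigma
    assert (np.abs(bins["count"] - 50) < 4 * np.sqrt(50)).all()


def test_state_fold_changes_identical_conditions(genome):
    states = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [0, 600_000], "end": [600_000, 1_000_000],
         "name": ["intergenic", "polycomb"]}
    ))
    rng = np.random.default_rng(1)
    starts = rng.integers(0, 999_000, 20_000)
    frags = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200})
    bins, summary, baseline = state_fold_changes(frags, frags, states, genome)
    assert (summary["median"] == 0).all()
    assert baseline == 0.0


def test_state_fold_changes_shift_and_state_specific(genome):
    states = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [0, 600_000], "end": [600_000, 1_000_000],
         "name": ["intergenic", "polycomb"]}
    ))
    rng = np.random.default_rng(2)

    def uniform(n):
        s = rng.integers(0, 999_800, n)
        return pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 200})

    def weighted(n, w_pc):
        # polycomb state is 40% of the genome; oversample it by w_pc
        frac_pc = 0.4 * w_pc / (0.6 + 0.4 * w_pc)
        n_pc = rng.binomial(n, frac_pc)
        s_bg = rng.integers(0, 600_000, n - n_pc)
        s_pc = rng.integers(600_000, 999_800, n_pc)
        s = np.concatenate([s_bg, s_pc])
        return pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 200})

    # uniform 2x shift: every state median ~ 1, baseline ~ 1
    a = uniform(50_000)
    b = uniform(100_000)
    _, summary, baseline = state_fold_changes(a, b, states, genome)
    med = summary.set_index("state")["median"]
    assert abs(med["intergenic"] - 1.0) < 0.1
    assert abs(med["polycomb"] - 1.0) < 0.1
    assert abs(baseline - 1.0) < 0.1
    # extra 2x in one state only: that state sits ~ baseline + 1
    b2 = weighted(int(50_000 * (0.6 + 0.8) / 1.0), 2.0)
    _, summary2, baseline2 = state_fold_changes(a, b2, states, genome)
    med2 = summary2.set_index("state")["median"]
    assert abs((med2["polycomb"] - baseline2) - 1.0) < 0.15


def test_state_fold_change_antisymmetric(genome):
    states = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [0], "end": [1_000_000], "name": ["intergenic"]}
    ))
    rng = np.random.default_rng(4)
    s1 = rng.integers(0, 999_800, 10_000)
    s2 = rng.integers(0, 999_800, 30_000)
    fa = pd.DataFrame({"chrom": "chr1", "start": s1, "end": s1 + 200})
    fb = pd.DataFrame({"chrom": "chr1", "start": s2, "end": s2 + 200})
    ab, _, _ = state_fold_changes(fa, fb, states, genome)
    ba, _, _ = state_fold_changes(fb, fa, states, genome)
    np.testing.assert_allclose(ab["lfc"], -ba["lfc"], atol=1e-12)


def test_region_lfc_antisymmetric():
    regions = IntervalSet.from_records([("chr1", 0, 1000), ("chr1", 1000, 3000)])
    ca = np.array([10, 40])
    cb = np.array([25, 5])
    np.testing.assert_allclose(
        region_lfc(ca, cb, regions), -region_lfc(cb, ca, regions), atol=1e-12
    )


def test_metaprofile_constant_and_symmetry():
    genome = Genome({"chr1": 10_000})
    const = CoverageTrack.constant(genome, 3.0)
    anchors = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [5000], "end": [5001], "strand": ["+"]}
    ))
    for stat in ("mean", "median"):
        prof = metaprofile(const, anchors, flank_bp=1000, nbins=10, stat=stat)
        np.testing.assert_allclose(prof, 3.0)
    # a peak left of a plus-strand anchor appears right of a minus-strand one
    frags = pd.DataFrame({"chrom": "chr1", "start": [4000] * 5, "end": [4500] * 5})
    track = pileup(frags, genome)
    plus = metaprofile(track, anchors, 1000, 10)
    minus_anchor = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [5000], "end": [5001], "strand": ["-"]}
    ))
    minus = metaprofile(track, minus_anchor, 1000, 10)
    np.testing.assert_allclose(plus, minus[::-1])


def test_metaprofile_single_anchor_binned_step():
    genome = Genome({"chr1": 1000})
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
    track = pileup(frags, genome)
    anchors = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [499], "end": [501], "strand": ["+"]}
    ))
    prof = metaprofile(track, anchors, flank_bp=100, nbins=4, stat="mean")
    # window [400, 600): bins [400,450),[450,500),[500,550),[550,600)
    np.testing.assert_allclose(prof, [0, 0, 1, 1])


def test_metaprofile_clipping_warns():
    genome = Genome({"chr1": 1000})
    track = CoverageTrack.constant(genome, 2.0)
    anchors = IntervalSet(pd.DataFrame(
        {"chrom": "chr1", "start": [10], "end": [11], "strand": ["+"]}
    ))
    with pytest.warns(UserWarning, match="clipped"):
        prof = metaprofile(track, anchors, flank_bp=100, nbins=4)
    assert np.isnan(prof[0])  # bin fully outside the chromosome
    np.testing.assert_allclose(prof[2:], 2.0)


def test_replicate_concordance_gate():
    regions = IntervalSet.from_records([("chr1", i * 1000, (i + 1) * 1000) for i in range(50)])
    rng = np.random.default_rng(6)
    base = rng.poisson(100, 50).astype(float)
    counts = pd.DataFrame({"r1": base, "r2": base})
    rmat, ok = replicate_concordance(counts, regions)
    assert rmat.loc["r1", "r2"] == pytest.approx(1.0)
    assert ok
    noisy = pd.DataFrame({"r1": base, "r2": rng.permutation(base)})
    _, ok2 = replicate_concordance(noisy, regions)
    assert not ok2
    flat = pd.DataFrame({"r1": base, "r2": np.full(50, 7.0)})
    rflat, ok3 = replicate_concordance(flat, regions)
    assert not ok3 and np.isnan(rflat.loc["r1", "r2"])


def test_replicate_concordance_recovers_known_correlation():
    regions = IntervalSet.from_records(
        [("chr1", i * 1000, (i + 1) * 1000) for i in range(5000)]
    )
    rng = np.random.default_rng(7)
    rho = 0.8
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
    counts = pd.DataFrame(np.round(np.exp(4 + z)), columns=["r1", "r2"])
    rmat, _ = replicate_concordance(counts, regions)
    # log2(count/kb+1) is a monotone transform; r near the generating rho
    assert abs(rmat.loc["r1", "r2"] - rho) < 0.05
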