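import numpy as np
import pytest

from senespread.coverage_quant import (
    gene_body_density,
    metagene_profile,
    profile_matrix,
    tss_profile,
    window_density,
)
from senespread.genome_io import CoverageTrack, GeneModel, GenomicWindow

from conftest import per_base_expansion, random_track


# ---------------------------------------------------------------------------
# window_density
# ---------------------------------------------------------------------------


def test_empty_track_zero_density(plus_gene):
    t = CoverageTrack.from_intervals([])
    wd = window_density(t, plus_gene, GenomicWindow("tss", -300, 200))
    assert wd.raw_tags == 0 and wd.norm_density == 0


def test_window_density_worked_example(plus_gene):
    # track value 4.0 over [9700, 10200); TSS at 10000; library 1e7
    t = CoverageTrack.from_intervals(
        [("chr1", 9700, 10_200, 4.0)], library_size=1e7
    )
    wd = window_density(t, plus_gene, GenomicWindow("tss", -300, 200))
    assert wd.raw_tags == pytest.approx(2000.0)
    assert wd.norm_density == pytest.approx(2000.0 / 0.5)  # 0.5 kb window


def test_window_density_strand_symmetry(minus_gene):
    # minus-strand gene with TSS at 10000: mirrored window is [9800, 10300)
    t = CoverageTrack.from_intervals(
        [("chr1", 9800, 10_300, 4.0)], library_size=1e7
    )
    wd = window_density(t, minus_gene, GenomicWindow("tss", -300, 200))
    assert wd.raw_tags == pytest.approx(2000.0)


def test_window_fully_clipped_raises():
    g = GeneModel("edge", "chr1", "-", 100, 500)  # TSS at 500 on minus strand
    t = CoverageTrack.from_intervals([("chr1", 0, 1000, 1.0)])
    with pytest.raises(ValueError, match="edge"):
        # transcribed window far downstream maps below 0 on minus strand
        window_density(t, g, GenomicWindow("tss", 600, 1000))


def test_window_density_per_base_oracle_randomized():
    """Acceptance surface: exact agreement with brute-force summation."""
    rng = np.random.default_rng(123)
    span = 3000
    n_cases = 0
    while n_cases < 120:
        records, t = random_track(rng, span=span)
        arr = per_base_expansion(records, "chr1", span)
        s = int(rng.integers(300, span - 600))
        e = int(rng.integers(s + 50, span - 300))
        strand = "+" if rng.random() < 0.5 else "-"
        g = GeneModel(f"g{n_cases}", "chr1", strand, s, e)
        w = GenomicWindow("tss", int(rng.integers(-200, 0)), int(rng.integers(1, 200)))
        chrom_start = min(g.tss + w.rel_start, g.tss - w.rel_end)
        if chrom_start < 0:
            continue
        wd = window_density(t, g, w)
        assert wd.raw_tags == pytest.approx(arr[wd.start : wd.end].sum(), abs=1e-9)
        n_cases += 1


# ---------------------------------------------------------------------------
# gene_body_density
# ---------------------------------------------------------------------------


def test_gene_body_density_uniform(plus_gene, uniform_track):
    wd = gene_body_density(uniform_track, plus_gene)
    # value 2.0/base -> 2000 tags/kb; library = 100k tags -> /0.01
    expect = 2000.0 / (uniform_track.library_size / 1e7)
    assert wd.norm_density == pytest.approx(expect)


def test_promoter_exclusion_reduces_peaked_density(plus_gene):
    t = CoverageTrack.from_intervals(
        [("chr1", 10_000, 10_400, 10.0), ("chr1", 10_400, 18_000, 1.0)]
    )
    d0 = gene_body_density(t, plus_gene, 0).norm_density
    d500 = gene_body_density(t, plus_gene, 500).norm_density
    assert d500 < d0


def test_gene_body_density_empty_track(plus_gene):
    t = CoverageTrack.from_intervals([])
    assert gene_body_density(t, plus_gene).norm_density == 0


def test_exclusion_longer_than_gene_raises(plus_gene):
    t = CoverageTrack.from_intervals([])
    with pytest.raises(ValueError):
        gene_body_density(t, plus_gene, promoter_exclusion_bp=plus_gene.length)


def test_gene_body_per_base_oracle():
    rng = np.random.default_rng(321)
    span = 3000
    for i in range(30):
        records, t = random_track(rng, span=span)
        arr = per_base_expansion(records, "chr1", span)
        s = int(rng.integers(0, 1000))
        e = int(rng.integers(s + 200, span))
        strand = "+" if rng.random() < 0.5 else "-"
        g = GeneModel(f"g{i}", "chr1", strand, s, e)
        excl = int(rng.integers(0, 150))
        wd = gene_body_density(t, g, excl)
        if strand == "+":
            expect = arr[s + excl : e].sum()
        else:
            expect = arr[s : e - excl].sum()
        assert wd.raw_tags == pytest.approx(expect, abs=1e-9)


# ---------------------------------------------------------------------------
# tss_profile
# ---------------------------------------------------------------------------


def test_tss_profile_uniform_flat(uniform_track):
    genes = [GeneModel(f"g{i}", "chr1", "+", 10_000 + i * 3000, 12_000 + i * 3000)
             for i in range(5)]
    prof = tss_profile(uniform_track, genes, flank_bp=1000, bin_bp=100)
    expect = 2.0 * 1000 / (uniform_track.library_size / 1e7)
    assert np.allclose(prof["mean_density"], expect)


def test_tss_profile_requires_divisible_bins(uniform_track, plus_gene):
    with pytest.raises(ValueError):
        tss_profile(uniform_track, [plus_gene], flank_bp=1000, bin_bp=333)


def test_tss_profile_empty_genes(uniform_track):
    with pytest.raises(ValueError):
        tss_profile(uniform_track, [])


def test_tss_profile_peak_at_tss():
    genes = [GeneModel("g1", "chr1", "+", 10_000, 20_000)]
    t = CoverageTrack.from_intervals([("chr1", 9950, 10_050, 5.0)])
    prof = tss_profile(t, genes, flank_bp=1000, bin_bp=100)
    peak_bins = prof.loc[prof["mean_density"].idxmax(), "rel_start"]
    assert peak_bins in (-100, 0)  # peak straddles the TSS


def test_tss_profile_strand_flip_oracle():
    """A mixture of + and - strand genes with mirrored peaks equals the
    single-strand profile."""
    span = 200_000
    gp = GeneModel("p", "chr1", "+", 50_000, 60_000)
    gm = GeneModel("m", "chr1", "-", span - 60_000, span - 50_000)
    peak = [("chr1", 50_100, 50_200, 3.0), ("chr1", 49_500, 49_700, 1.0)]
    mirrored = [
        ("chr1", span - e, span - s, v) for (_, s, e, v) in peak
    ]
    t = CoverageTrack.from_intervals(peak + mirrored, library_size=1e7)
    prof_p = tss_profile(t, [gp], flank_bp=2000, bin_bp=100)
    prof_mix = tss_profile(t, [gp, gm], flank_bp=2000, bin_bp=100)
    assert np.allclose(prof_p["mean_density"], prof_mix["mean_density"])


def test_tss_profile_clipped_bins_excluded():
    g_near_edge = GeneModel("e", "chr1", "+", 500, 5000)
    g_far = GeneModel("f", "chr1", "+", 50_000, 60_000)
    t = CoverageTrack.from_intervals([("chr1", 0, 100_000, 1.0)])
    prof = tss_profile(t, [g_near_edge, g_far], flank_bp=1000, bin_bp=100)
    # bins upstream of -500 are clipped for the edge gene: only 1 gene counted
    assert prof.loc[prof["rel_start"] == -1000, "n_genes"].item() == 1
    assert prof.loc[prof["rel_start"] == 0, "n_genes"].item() == 2


# ---------------------------------------------------------------------------
# metagene_profile
# ---------------------------------------------------------------------------


def make_body_genes(n=4, length=10_000, gap=30_000, start=50_000):
    return [
        GeneModel(f"g{i}", "chr1", "+", start + i * gap, start + i * gap + length)
        for i in range(n)
    ]


def test_metagene_constant_bodies_zero_flanks():
    genes = make_body_genes()
    records = [("chr1", g.start, g.end, 3.0) for g in genes]
    t = CoverageTrack.from_intervals(records, library_size=1e7)
    prof = metagene_profile(t, genes)
    assert np.allclose(prof.body_means, prof.body_means[0])
    assert prof.body_means[0] == pytest.approx(3000.0)  # 3 tags/base -> /kb
    flanks = np.concatenate(
        [prof.bin_means[: prof.n_flank_bins], prof.bin_means[-prof.n_flank_bins :]]
    )
    assert np.allclose(flanks, 0.0)


def test_metagene_single_body_bin_degenerate():
    genes = make_body_genes(n=3)
    records = [("chr1", g.start, g.end, float(i + 1)) for i, g in enumerate(genes)]
    t = CoverageTrack.from_intervals(records, library_size=1e7)
    prof = metagene_profile(t, genes, n_body_bins=1)
    means = [
        gene_body_density(t, g).norm_density for g in genes
    ]
    assert prof.body_means[0] == pytest.approx(np.mean(means))


def test_metagene_excludes_short_genes():
    genes = make_body_genes(n=3) + [GeneModel("tiny", "chr1", "+", 1000, 1050)]
    t = CoverageTrack.from_intervals([("chr1", 0, 200_000, 1.0)])
    prof = metagene_profile(t, genes, n_body_bins=100)
    assert prof.n_genes == 3
    assert prof.n_excluded_short == 1


def test_metagene_all_excluded_raises():
    genes = [GeneModel("tiny", "chr1", "+", 1000, 1050)]
    t = CoverageTrack.from_intervals([])
    with pytest.raises(ValueError):
        metagene_profile(t, genes, n_body_bins=100)


def test_metagene_strand_flip_invariance():
    span = 500_000
    genes_p = make_body_genes(n=3)
    records = []
    rng = np.random.default_rng(8)
    for g in genes_p:
        for _ in range(10):
            s = int(rng.integers(g.start - 2000, g.end + 1500))
            records.append(("chr1", s, s + 500, float(rng.uniform(0.5, 3))))
    genes_m = [
        GeneModel(g.gene_id + "m", "chr1", "-", span - g.end, span - g.start)
        for g in genes_p
    ]
    mirrored = [("chr1", span - e, span - s, v) for (_, s, e, v) in records]
    t_p = CoverageTrack.from_intervals(records, library_size=1e7)
    t_m = CoverageTrack.from_intervals(mirrored, library_size=1e7)
    prof_p = metagene_profile(t_p, genes_p)
    prof_m = metagene_profile(t_m, genes_m)
    assert np.allclose(prof_p.bin_means, prof_m.bin_means)


def test_spread_shape_recovery(spread_dataset):
    """Condition 1 promoter-peaked vs condition 2 spread over bodies."""
    _, genes, _, track_a, track_b = spread_dataset
    prof_a = metagene_profile(track_a, genes)
    prof_b = metagene_profile(track_b, genes)
    assert int(np.argmax(prof_a.body_means)) < 10  # first body decile
    assert np.mean(prof_b.body_means[20:]) > np.mean(prof_a.body_means[20:])


# ---------------------------------------------------------------------------
# profile_matrix
# ---------------------------------------------------------------------------


def test_profile_matrix_sorting_and_ties():
    g1 = GeneModel("aaa", "chr1", "+", 50_000, 60_000)
    g2 = GeneModel("bbb", "chr1", "+", 100_000, 110_000)
    g3 = GeneModel("ccc", "chr1", "+", 150_000, 160_000)
    t = CoverageTrack.from_intervals(
        [
            ("chr1", 49_500, 50_200, 5.0),
            ("chr1", 99_500, 100_200, 9.0),
            ("chr1", 149_500, 150_200, 5.0),
        ],
        library_size=1e7,
    )
    win = GenomicWindow("tss", -3000, 3000)
    sort_win = GenomicWindow("tss", -500, 200)
    mat = profile_matrix(t, [g1, g2, g3], win, 50, sort_window=sort_win)
    assert mat.gene_ids == ["bbb", "aaa", "ccc"]  # 9 first, then tie by id
    assert mat.values.shape == (3, 120)  # +/-3 kb in 50 bp bins -> 120 columns


def test_profile_matrix_window_smaller_than_bin():
    g = GeneModel("a", "chr1", "+", 50_000, 60_000)
    t = CoverageTrack.from_intervals([])
    with pytest.raises(ValueError):
        profile_matrix(t, [g], GenomicWindow("tss", 0, 20), 50)


def test_profile_matrix_row_values_match_window_density():
    g = GeneModel("a", "chr1", "+", 50_000, 60_000)
    t = CoverageTrack.from_intervals([("chr1", 49_000, 52_000, 2.0)], library_size=1e7)
    mat = profile_matrix(t, [g], GenomicWindow("tss", -1000, 1000), 100)
    for j, rel in enumerate(mat.bin_starts):
        wd = window_density(t, g, GenomicWindow("tss", int(rel), int(rel) + 100))
        assert mat.values[0, j] == pytest.approx(wd.norm_density)


# ---------------------------------------------------------------------------
# linearity / normalization invariants
# ---------------------------------------------------------------------------


def test_scaling_track_scales_densities(plus_gene):
    rng = np.random.default_rng(99)
    records, t = random_track(rng, span=30_000, n=60)
    t = CoverageTrack.from_intervals(records, library_size=1e7)
    tk = t.scaled(3.0)
    w = GenomicWindow("tss", -300, 200)
    g = GeneModel("g", "chr1", "+", 15_000, 25_000)
    assert window_density(tk, g, w).norm_density == pytest.approx(
        3.0 * window_density(t, g, w).norm_density
    )
    pa = metagene_profile(t, [g])
    pb = metagene_profile(tk, [g])
    assert np.allclose(pb.bin_means, 3.0 * pa.bin_means)


def test_doubling_library_size_halves_density(plus_gene):
    t1 = CoverageTrack.from_intervals([("chr1", 9000, 12_000, 2.0)], library_size=1e6)
    t2 = CoverageTrack.from_intervals([("chr1", 9000, 12_000, 2.0)], library_size=2e6)
    w = GenomicWindow("tss", -300, 200)
    d1 = window_density(t1, plus_gene, w).norm_density
    d2 = window_density(t2, plus_gene, w).norm_density
    assert d2 == pytest.approx(d1 / 2)
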