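import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ebsseq import (
    AlignedFragment, GenomicInterval, Mate, ReferenceGenome, SiteCounts,
    accumulate_site_counts, binned_correlation, build_cpg_index, call_fragment,
    cpg_normalized_signal, expression_correlation, high_confidence_sites,
    metagene_matrix, overlap_fractions, region_fragment_counts, rpkm,
    tile_genome, write_bedgraph, write_cytosine_report,
)
from ebsseq.quantify import read_bedgraph
from ebsseq.readcall import FragmentCallSet


def cs(contig, strand, positions, states, contexts=None):
    n = len(positions)
    return FragmentCallSet(
        "f", contig, strand,
        positions=np.asarray(positions, dtype=np.int64),
        context_codes=np.zeros(n, dtype=np.int8) if contexts is None
        else np.asarray(contexts, dtype=np.int8),
        states=np.asarray(states, dtype=np.int8),
    )


def make_frag(contig, start, end, fid="f"):
    return AlignedFragment(fid, contig, Mate(start, "A" * (end - start)), None, "OT")


@pytest.fixture()
def cg_genome():
    return ReferenceGenome({"c": "ACGTACGTACGT" * 50})  # dyads every 4 bp


class TestAccumulate:
    def test_two_unconverted_at_same_dyad(self, cg_genome):
        index = build_cpg_index(cg_genome)
        sets = [cs("c", "OT", [1], [2]), cs("c", "OT", [1], [2])]
        counts = accumulate_site_counts(sets, index)
        assert counts.hmc("c", 1) == 2 and counts.coverage("c", 1) == 2

    def test_converted_plus_unconverted(self, cg_genome):
        index = build_cpg_index(cg_genome)
        sets = [cs("c", "OT", [1], [1]), cs("c", "OT", [1], [2])]
        counts = accumulate_site_counts(sets, index)
        assert counts.hmc("c", 1) == 1 and counts.coverage("c", 1) == 2

    def test_reverse_strand_folds_onto_dyad(self, cg_genome):
        index = build_cpg_index(cg_genome)
        counts = accumulate_site_counts([cs("c", "OB", [2], [2])], index)
        assert counts.hmc("c", 1) == 1

    def test_unmerged_keeps_strands(self, cg_genome):
        index = build_cpg_index(cg_genome)
        counts = accumulate_site_counts(
            [cs("c", "OT", [1], [2]), cs("c", "OB", [2], [2])], index,
            merge_strands=False,
        )
        assert counts.hmc("c", 1, "+") == 1 and counts.hmc("c", 2, "-") == 1

    def test_ambiguous_not_counted(self, cg_genome):
        index = build_cpg_index(cg_genome)
        counts = accumulate_site_counts([cs("c", "OT", [1], [3])], index)
        assert counts.total_coverage == 0

    def test_off_index_call_is_error(self, cg_genome):
        index = build_cpg_index(cg_genome)
        with pytest.raises(ValueError, match="no dyad"):
            accumulate_site_counts([cs("c", "OT", [0], [2])], index)

    def test_conservation_against_callsets(self, sim_small):
        """Sum of site 5hmC counts equals the per-fragment unconverted-CpG sum."""
        genome = sim_small.genome
        index = build_cpg_index(genome)
        callsets = [call_fragment(f, genome) for f in sim_small.fragments[:300]]
        counts = accumulate_site_counts(callsets, index)
        assert counts.total_hmc == sum(c.n_unconverted_CpG for c in callsets)


class TestBedgraphAndReport:
    def test_bedgraph_format_and_round_trip(self, tmp_path):
        counts = SiteCounts()
        counts.add("c1", 100, ".", True)
        counts.add("c1", 100, ".", True)
        counts.add("c1", 100, ".", True)
        path = tmp_path / "x.bedGraph"
        write_bedgraph(counts, path, "hmc_count")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("track") and lines[1] == "c1\t100\t101\t3"
        assert read_bedgraph(path) == {("c1", 100): 3.0}
        # write -> read -> write is byte-identical
        path2 = tmp_path / "y.bedGraph"
        write_bedgraph(counts, path2, "hmc_count")
        assert path.read_bytes() == path2.read_bytes()

    def test_empty_counts_header_only(self, tmp_path):
        path = tmp_path / "e.bedGraph"
        write_bedgraph(SiteCounts(), path)
        assert path.read_text() == "track type=bedGraph\n"

    def test_cytosine_report_one_based_and_exhaustive(self, tmp_path, cg_genome):
        index = build_cpg_index(cg_genome)
        counts = accumulate_site_counts(
            [cs("c", "OT", [1], [2])], index, merge_strands=False
        )
        path = tmp_path / "rep.tsv"
        write_cytosine_report(counts, index, path)
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["contig", "pos", "strand", "unconv", "conv", "ctx"])
        assert len(df) == 2 * index.size()  # two rows per dyad, exhaustive
        row = df[(df.pos == 2) & (df.strand == "+")].iloc[0]
        assert row.unconv == 1 and row.conv == 0 and row.ctx == "CpG"
        # totals conserve against the counts object
        assert df.unconv.sum() == counts.total_hmc
        assert (df.unconv + df.conv).sum() == counts.total_coverage

    def test_report_requires_stranded_counts(self, tmp_path, cg_genome):
        index = build_cpg_index(cg_genome)
        with pytest.raises(ValueError):
            write_cytosine_report(SiteCounts(merged=True), index, tmp_path / "x")


class TestRegionCounts:
    def test_midpoint_rule(self):
        frags = [make_frag("c", 100, 300)]
        bins = [GenomicInterval("c", 0, 10_000)]
        assert region_fragment_counts(frags, bins)[0] == 1

    def test_straddling_fragment_counted_once(self):
        frags = [make_frag("c", 9_900, 10_100)]  # midpoint 10_000 -> second bin
        bins = [GenomicInterval("c", 0, 10_000), GenomicInterval("c", 10_000, 20_000)]
        assert list(region_fragment_counts(frags, bins)) == [0, 1]

    def test_tiling_conserves_library_size(self, sim_small):
        genome = sim_small.genome
        frags = [f for f in sim_small.fragments if f.contig == "chr1"]
        bins = tile_genome(genome, 5_000, contigs=["chr1"])
        counts = region_fragment_counts(frags, bins)
        assert counts.sum() == len(frags)


class TestRpkm:
    def test_arithmetic(self):
        assert rpkm(np.array([10]), np.array([2_000]), 1_000_000)[0] == pytest.approx(5.0)

    def test_zero_count(self):
        assert rpkm(np.array([0]), np.array([1_000]), 10)[0] == 0.0

    def test_scale_invariance(self):
        a = rpkm(np.array([5, 10]), np.array([1_000, 1_000]), 100)
        b = rpkm(np.array([10, 20]), np.array([1_000, 1_000]), 200)
        assert np.allclose(a, b)

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError):
            rpkm(np.array([1]), np.array([0]), 10)


class TestCpgNormalizedSignal:
    def test_arithmetic(self):
        counts = SiteCounts()
        genome = ReferenceGenome({"c": "CG" * 5 + "AT" * 100})
        index = build_cpg_index(genome)
        for i in range(5):
            for _ in range(2):
                counts.add("c", 2 * i, ".", True)
        region = GenomicInterval("c", 0, 10)
        # 10 signals in region; pretend library total is 1e6
        val = cpg_normalized_signal(counts, region, index, total_hmc=10**6)
        assert val == pytest.approx((10 / 1e6 * 1e6) / 5)

    def test_all_library_in_one_cpg_region(self):
        genome = ReferenceGenome({"c": "CGAT" * 10})
        index = build_cpg_index(genome)
        counts = SiteCounts()
        counts.add("c", 0, ".", True)
        val = cpg_normalized_signal(counts, GenomicInterval("c", 0, 2), index)
        assert val == pytest.approx(1e6)

    def test_no_cpg_region_is_nan(self):
        genome = ReferenceGenome({"c": "CGAT" + "AT" * 20})
        index = build_cpg_index(genome)
        counts = SiteCounts()
        counts.add("c", 0, ".", True)
        assert np.isnan(
            cpg_normalized_signal(counts, GenomicInterval("c", 10, 20), index)
        )

    def test_zero_total_is_error(self):
        genome = ReferenceGenome({"c": "CGAT"})
        index = build_cpg_index(genome)
        with pytest.raises(ValueError):
            cpg_normalized_signal(SiteCounts(), GenomicInterval("c", 0, 2), index)

    def test_density_invariance_fixture(self):
        """Equal per-CpG 5hmC rate at 10x CpG density: cpg_norm equal, RPKM ~10x.

        This is the distortion argument for normalizing enrichment signal by
        CpG count rather than by coverage.
        """
        dense = "CGAT" * 250  # 250 dyads in 1 kb
        sparse = ("CG" + "AT" * 19) * 25  # 25 dyads in 1 kb
        genome = ReferenceGenome({"dense": dense, "sparse": sparse})
        index = build_cpg_index(genome)
        counts = SiteCounts()
        frags = []
        per_cpg = 2  # identical per-CpG signal rate in both regions
        fid = 0
        for contig in ("dense", "sparse"):
            for dyad in index.positions[contig]:
                for _ in range(per_cpg):
                    counts.add(contig, int(dyad), ".", True)
                    frags.append(
                        make_frag(contig, max(int(dyad) - 10, 0), int(dyad) + 10, f"f{fid}")
                    )
                    fid += 1
        r_dense = GenomicInterval("dense", 0, 1_000)
        r_sparse = GenomicInterval("sparse", 0, 1_000)
        total = counts.total_hmc
        cn_dense = cpg_normalized_signal(counts, r_dense, index, total)
        cn_sparse = cpg_normalized_signal(counts, r_sparse, index, total)
        assert cn_dense == pytest.approx(cn_sparse, rel=1e-9)
        fc = region_fragment_counts(frags, [r_dense, r_sparse])
        rp = rpkm(fc, np.array([1_000, 1_000]), len(frags))
        assert rp[0] / rp[1] == pytest.approx(10.0, rel=1e-9)


class TestSiteSets:
    def test_high_confidence_threshold(self):
        counts = SiteCounts()
        for pos, n in (("a", 3), ("b", 2), ("c", 5)):
            for _ in range(n):
                counts.add(pos, 0, ".", True)
        assert high_confidence_sites(counts, 3) == {("a", 0), ("c", 0)}
        assert high_confidence_sites(counts, 1) == {("a", 0), ("b", 0), ("c", 0)}
        assert high_confidence_sites(counts, 99) == set()

    def test_min_signals_below_one_is_error(self):
        with pytest.raises(ValueError):
            high_confidence_sites(SiteCounts(), 0)

    def test_overlap_fractions(self):
        a = {("c", 1), ("c", 2), ("c", 3)}
        b = {("c", 2), ("c", 3), ("c", 4)}
        assert overlap_fractions(a, b) == (pytest.approx(2 / 3), pytest.approx(2 / 3))
        assert overlap_fractions(a, a | b) == (1.0, pytest.approx(3 / 4))
        assert overlap_fractions(a, {("c", 9)}) == (0.0, 0.0)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            overlap_fractions(set(), {("c", 1)})

    def test_brute_force_agreement_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = {("c", int(x)) for x in rng.integers(0, 50, size=30)}
            b = {("c", int(x)) for x in rng.integers(0, 50, size=30)}
            fa, fb = overlap_fractions(a, b)
            inter = sum(1 for k in a if k in b)
            assert fa == inter / len(a) and fb == inter / len(b)


class TestBinnedCorrelation:
    def test_identical_replicates_give_exactly_one(self, sim_small):
        frags = [f for f in sim_small.fragments if f.contig == "chr1"]
        mat, _bins = binned_correlation([frags, frags], sim_small.genome, contigs=["chr1"])
        assert mat.iloc[0, 1] == 1.0

    def test_anticorrelated_construction(self):
        genome = ReferenceGenome({"c": "A" * 40_000})
        # rep1 piles fragments in even bins, rep2 in odd bins
        rep1 = [make_frag("c", b * 10_000 + 100, b * 10_000 + 300, f"a{i}")
                for b in (0, 2) for i in range(10)]
        rep2 = [make_frag("c", b * 10_000 + 100, b * 10_000 + 300, f"b{i}")
                for b in (1, 3) for i in range(10)]
        mat, _ = binned_correlation([rep1, rep2], genome)
        assert mat.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, sim_small):
        """Hand-rolled Pearson equals scipy.stats.pearsonr to 1e-12."""
        genome = sim_small.genome
        frags = [f for f in sim_small.fragments if f.contig == "chr1"]
        half1, half2 = frags[::2], frags[1::2]
        mat, bins = binned_correlation([half1, half2], genome, bin_size=2_000, contigs=["chr1"])
        lengths = np.array([b.length for b in bins], dtype=float)
        v1 = rpkm(region_fragment_counts(half1, bins), lengths, len(half1))
        v2 = rpkm(region_fragment_counts(half2, bins), lengths, len(half2))
        expected = stats.pearsonr(v1, v2)[0]
        assert mat.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        genome = ReferenceGenome({"c": "A" * 30_000})
        rep1 = [make_frag("c", b * 10_000, b * 10_000 + 200, f"a{b}") for b in range(3)]
        rep2 = [make_frag("c", 100, 300, "b0")]
        mat, _ = binned_correlation([rep1, rep2], genome)
        assert np.isnan(mat.iloc[0, 1])


class TestMetagene:
    def test_uniform_coverage_is_flat(self):
        genome = ReferenceGenome({"c": "A" * 20_000})
        frags = [make_frag("c", 0, 20_000, "f0")]  # covers everything once
        region = GenomicInterval("c", 5_000, 10_000, "+")
        mat, profile = metagene_matrix(
            [region], "coverage", genome, fragments=frags,
            flank=1_000, body_bins=10, flank_bins=5,
        )
        assert np.allclose(profile, 1.0)

    def test_minus_strand_profile_is_reversed(self):
        genome = ReferenceGenome({"c": "A" * 20_000})
        # coverage step: high left of 8000, zero right
        frags = [make_frag("c", 5_000, 8_000, f"f{i}") for i in range(5)]
        plus = GenomicInterval("c", 6_000, 10_000, "+")
        minus = GenomicInterval("c", 6_000, 10_000, "-")
        mat_p, _ = metagene_matrix([plus], "coverage", genome, fragments=frags,
                                   flank=1_000, body_bins=8, flank_bins=4)
        mat_m, _ = metagene_matrix([minus], "coverage", genome, fragments=frags,
                                   flank=1_000, body_bins=8, flank_bins=4)
        assert np.allclose(mat_m[0], mat_p[0][::-1], equal_nan=True)

    def test_flank_bins_exceeding_flank_is_error(self):
        genome = ReferenceGenome({"c": "A" * 100})
        with pytest.raises(ValueError):
            metagene_matrix([GenomicInterval("c", 10, 20)], "coverage", genome,
                            fragments=[], flank=5, flank_bins=10)

    def test_body_enrichment_visible_in_hmc_per_cpg(self, sim_noiseless):
        """5hmC concentrated in gene bodies shows body > flank in the profile."""
        from ebsseq import PipelineConfig, run_pipeline_objects

        ds = sim_noiseless
        res = run_pipeline_objects(
            PipelineConfig(mode="ebs"), ds.genome, ds.fragments, design=None
        )
        index = build_cpg_index(ds.genome)
        mat, profile = metagene_matrix(
            ds.genes, "hmc_per_cpg", ds.genome, index=index, counts=res.site_counts,
            flank=1_000, body_bins=20, flank_bins=10,
        )
        body = np.nanmean(profile[10:30])
        flank_vals = np.concatenate([profile[:10], profile[30:]])
        assert body > np.nanmean(flank_vals)


class TestExpressionCorrelation:
    def test_exact_linear_gives_one(self):
        sig = {f"g{i}": float(i + 1) for i in range(10)}
        expr = {k: 2 * v for k, v in sig.items()}
        assert expression_correlation(sig, expr) == pytest.approx(1.0)

    def test_zero_on_either_side_excluded(self):
        sig = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.0, "e": 4.0}
        expr = {"a": 2.0, "b": 4.0, "c": 6.0, "d": 5.0, "e": 0.0}
        assert expression_correlation(sig, expr) == pytest.approx(1.0)

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError):
            expression_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_permuted_pairing_near_zero(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(size=500)
        sig = {f"g{i}": float(v) for i, v in enumerate(vals)}
        perm = rng.permutation(vals)
        expr = {f"g{i}": float(v) for i, v in enumerate(perm)}
        assert abs(expression_correlation(sig, expr)) < 0.15

    def test_monotone_simulation_beats_permutation_null(self, sim_noiseless):
        """Genes with 5hmC density increasing in expression give positive R."""
        rng = np.random.default_rng(4)
        ds = sim_noiseless
        index = build_cpg_index(ds.genome)
        callsets = [call_fragment(f, ds.genome) for f in ds.fragments]
        counts = accumulate_site_counts(callsets, index)
        # assign expression proportional to realised gene 5hmC plus noise
        sig = {}
        expr = {}
        for g in ds.genes:
            pos, hmc, _ = counts.contig_arrays(g.contig)
            lo, hi = np.searchsorted(pos, [g.start, g.end])
            s = float(hmc[lo:hi].sum())
            sig[g.name] = s
            expr[g.name] = s * (1 + 0.1 * rng.random()) + 0.1
        r = expression_correlation(sig, expr)
        null = []
        names = list(sig)
        vals = np.array([expr[k] for k in names])
        for _ in range(200):
            p = rng.permutation(vals)
            null.append(
                expression_correlation(sig, dict(zip(names, p)))
            )
        assert r > np.percentile(null, 95)
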