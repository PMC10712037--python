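"""Hi-C pair QC, matrix construction/balancing, and pattern metrics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucleocut import hic, simulate
from nucleocut.hic import ContactMap


def pair_row(rid, c1, p1, s1, c2, p2, s2):
    return dict(read_id=rid, chrom1=c1, pos1=p1, strand1=s1,
                chrom2=c2, pos2=p2, strand2=s2)


def pairs_df(rows):
    return pd.DataFrame(rows)


def dense_map(matrix, bin_size=100_000, chrom="chr1",
              weights=None, balanced=False):
    """ContactMap from an explicit dense symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    bins = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * bin_size,
        "end": (np.arange(n) + 1) * bin_size,
    })
    counts = sp.csr_matrix(np.triu(m))
    return ContactMap(bin_size=bin_size, bins=bins, counts=counts,
                      chrom_bin_ranges={chrom: (0, n)},
                      weights=weights, balanced=balanced)


class TestClassify:
    def test_exact_repeat_is_duplicate(self):
        df = pairs_df([
            pair_row("a", "chr1", 100, "+", "chr1", 50_000, "-"),
            pair_row("b", "chr1", 100, "+", "chr1", 50_000, "-"),
        ])
        out, report = hic.classify_pairs(df)
        assert sorted(out["qc_class"]) == ["duplicate", "valid"]
        assert report.counts["duplicate"] == 1

    def test_orientation_rule_for_dangling_ends(self):
        df = pairs_df([
            pair_row("a", "chr1", 1000, "+", "chr1", 1400, "-"),  # inward
            pair_row("b", "chr1", 1000, "-", "chr1", 1400, "+"),  # outward
            pair_row("c", "chr1", 1000, "+", "chr1", 1400, "+"),  # same
        ])
        out, _ = hic.classify_pairs(df, de_max_sep=1000)
        by_id = dict(zip(out["read_id"], out["qc_class"]))
        assert by_id == {"a": "dangling_end", "b": "valid", "c": "valid"}

    def test_separation_threshold_strict(self):
        df = pairs_df([
            pair_row("a", "chr1", 0, "+", "chr1", 999, "-"),
            pair_row("b", "chr1", 0, "+", "chr1", 1000, "-"),
        ])
        out, _ = hic.classify_pairs(df, de_max_sep=1000)
        assert list(out["qc_class"]) == ["dangling_end", "valid"]

    def test_noncanonical_input_is_canonicalized(self):
        df = pairs_df([
            pair_row("a", "chr1", 1400, "-", "chr1", 1000, "+"),
        ])
        out, _ = hic.classify_pairs(df, de_max_sep=1000)
        assert out.loc[0, "pos1"] == 1000
        assert out.loc[0, "qc_class"] == "dangling_end"

    def test_classified_fractions_recover_simulator_truth(
            self, genome_small, s1_fragments_small):
        pairs = simulate.simulate_hic(
            genome_small, s1_fragments_small, n_pairs=20_000,
            de_fraction=0.2, dup_fraction=0.05, seed=71)
        df = hic.pairs_frame(pairs)
        _, report = hic.classify_pairs(df)
        n = report.total
        for cls, p0 in (("dangling_end", 0.2), ("duplicate", 0.05)):
            sd = np.sqrt(p0 * (1 - p0) / n)
            assert abs(report.fractions[cls] - p0) < 3 * sd


class TestBinPairs:
    sizes = {"chr1": 1_000_000}

    def test_single_pair_lands_in_expected_bins(self):
        df = pairs_df([pair_row("a", "chr1", 0, "+", "chr1", 250_000, "-")])
        cmap = hic.bin_pairs(df, self.sizes, 100_000)
        assert cmap.counts[0, 2] == 1
        assert cmap.counts.sum() == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        rows = [pair_row(f"r{i}", "chr1", int(a), "+", "chr1", int(b), "-")
                for i, (a, b) in enumerate(
                    rng.integers(0, 999_999, (300, 2)))]
        df = pairs_df(rows)
        a = hic.bin_pairs(df, self.sizes, 100_000)
        b = hic.bin_pairs(df.sample(frac=1, random_state=1), self.sizes,
                          100_000)
        assert (a.counts != b.counts).nnz == 0

    def test_matches_dense_bruteforce(self):
        rng = np.random.default_rng(5)
        pos = rng.integers(0, 999_999, (500, 2))
        df = pairs_df([
            pair_row(f"r{i}", "chr1", int(a), "+", "chr1", int(b), "-")
            for i, (a, b) in enumerate(pos)])
        cmap = hic.bin_pairs(df, self.sizes, 100_000)
        dense = np.zeros((10, 10))
        for a, b in pos:
            i, j = sorted((a // 100_000, b // 100_000))
            dense[i, j] += 1
        assert np.array_equal(cmap.counts.toarray(), dense)

    def test_position_beyond_chromosome_raises(self):
        df = pairs_df([pair_row("a", "chr1", 0, "+", "chr1", 2_000_000, "-")])
        with pytest.raises(ValueError, match="beyond"):
            hic.bin_pairs(df, self.sizes, 100_000)

    def test_small_bins_rejected(self):
        with pytest.raises(ValueError):
            hic.bin_pairs(pairs_df([]), self.sizes, 500)


class TestBalance:
    def test_doubly_stochastic_fixed_point(self):
        m = np.array([[0.0, 2, 1], [2, 0, 1], [1, 1, 1]], dtype=float)
        # rows all sum to 3 already
        cmap = hic.balance(dense_map(m), min_nnz=0, mad_frac=0.0)
        w = cmap.weights
        assert np.allclose(w, w[0])

    def test_diagonal_closed_form(self):
        cmap = hic.balance(dense_map(np.diag([2.0, 1.0])),
                           min_nnz=0, mad_frac=0.0)
        # balanced diagonal needs w_i proportional to 1/sqrt(M_ii)
        ratio = cmap.weights[0] / cmap.weights[1]
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=1e-4)

    def test_balanced_rows_equal_within_tolerance(self):
        rng = np.random.default_rng(6)
        m = rng.poisson(5, (30, 30)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cmap = hic.balance(dense_map(m), min_nnz=0, mad_frac=0.0)
        s = np.nansum(cmap.balanced_full(), axis=1)
        assert np.abs(s / s.mean() - 1).max() < 1e-4

    def test_sparse_bins_masked_and_excluded(self):
        m = np.ones((12, 12))
        m[0, :] = m[:, 0] = 0.0  # empty bin
        cmap = hic.balance(dense_map(m), min_nnz=2, mad_frac=0.0)
        assert np.isnan(cmap.weights[0])
        assert np.isfinite(cmap.weights[1:]).all()
        bal = cmap.balanced_full()
        assert np.isnan(bal[0]).all()

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            hic.balance(dense_map(np.zeros((4, 4))), min_nnz=1,
                        mad_frac=0.0)


class TestExpectedAndOE:
    def test_constant_matrix_gives_unit_oe(self):
        cmap = hic.balance(dense_map(np.ones((20, 20))),
                           min_nnz=0, mad_frac=0.0)
        oe = hic.oe_matrix(cmap, "chr1")
        assert np.allclose(oe, 1.0)

    def test_powerlaw_decay_slope_recovered(self):
        n = 80
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        m = 1000.0 / np.maximum(d, 1) ** 1.3
        cmap = hic.balance(dense_map(m), min_nnz=0, mad_frac=0.0,
                           max_iter=2000)
        exp = hic.expected_by_distance(cmap)["chr1"]
        ds = np.arange(2, 40)
        slope = np.polyfit(np.log(ds), np.log(exp[ds]), 1)[0]
        assert slope == pytest.approx(-1.3, abs=0.1)


class TestSaddle:
    def block_oe(self, n=200, within=2.0, between=1.0):
        half = n // 2
        oe = np.full((n, n), between)
        oe[:half, :half] = within
        oe[half:, half:] = within
        e1 = np.concatenate([np.full(half, -1.0), np.full(half, 1.0)])
        # distinct ranks within blocks keep quantile groups well defined
        e1 += np.linspace(0, 0.1, n)
        return oe, e1

    def test_ideal_two_block_strength_and_auc(self):
        oe, e1 = self.block_oe()
        res = hic.saddle(oe, e1, n_qbins=10)
        assert np.allclose(res.strength, 2.0)
        assert res.auc_score == pytest.approx(2.0)

    def test_shuffled_e1_destroys_structure(self):
        oe, e1 = self.block_oe()
        rng = np.random.default_rng(7)
        res = hic.saddle(oe, rng.permutation(e1), n_qbins=10)
        assert res.auc_score == pytest.approx(1.0, abs=0.05)

    def test_qbins_reduced_with_warning(self):
        oe, e1 = self.block_oe(n=20)
        with pytest.warns(UserWarning, match="reducing"):
            hic.saddle(oe, e1, n_qbins=50)


class TestConvergentPairs:
    def sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])

    def test_basic_convergent_pair(self):
        out = hic.convergent_ctcf_pairs(
            self.sites([("chr1", 10_000, "+"), ("chr1", 200_000, "-")]))
        assert len(out) == 1
        assert (out.loc[0, "pos1"], out.loc[0, "pos2"]) == (10_000, 200_000)

    def test_divergent_orientation_excluded(self):
        out = hic.convergent_ctcf_pairs(
            self.sites([("chr1", 10_000, "-"), ("chr1", 200_000, "+")]))
        assert len(out) == 0

    def test_separation_range_enforced(self):
        out = hic.convergent_ctcf_pairs(self.sites([
            ("chr1", 0, "+"), ("chr1", 30_000, "-"),       # too close
            ("chr1", 1_500_000, "-"),                      # too far
            ("chr1", 800_000, "-"),                        # in range
        ]))
        assert list(out["pos2"]) == [800_000]

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        rows = [("chr1", int(p), s) for p, s in
                zip(rng.integers(0, 3_000_000, 60),
                    rng.choice(["+", "-"], 60))]
        sites = self.sites(rows)
        out = hic.convergent_ctcf_pairs(sites)
        got = set(zip(out["pos1"], out["pos2"]))
        expected = set()
        for _, a in sites.iterrows():
            for _, b in sites.iterrows():
                if (a["strand"], b["strand"]) == ("+", "-") \
                        and 50_000 <= b["pos"] - a["pos"] <= 1_000_000:
                    expected.add((a["pos"], b["pos"]))
        assert got == expected


class TestPileups:
    def test_uniform_oe_scores_one(self):
        avg = np.ones((81, 81))
        assert hic.loop_strength(avg) == 1.0
        assert hic.insulation_score(avg) == 1.0

    def test_loop_strength_hand_computed(self):
        rng = np.random.default_rng(9)
        avg = np.ones((81, 81)) + rng.normal(0, 0.01, (81, 81))
        avg[39:42, 39:42] += 1.5
        center = avg[39:42, 39:42].mean()
        corners = np.mean([avg[:3, :3].mean(), avg[:3, -3:].mean(),
                           avg[-3:, :3].mean(), avg[-3:, -3:].mean()])
        assert hic.loop_strength(avg) == pytest.approx(center / corners)

    def test_insulation_block_toy(self):
        avg = np.ones((81, 81))
        avg[:40, 41:] = 0.5
        avg[41:, :40] = 0.5
        assert hic.insulation_score(avg) == pytest.approx(0.5)

    def test_pileup_windows_average_and_bounds(self):
        oe = np.ones((50, 50))
        oe[10, 20] = 5.0
        avg, used, dropped = hic.pileup_windows(
            oe, [(10, 20), (30, 40), (1, 48)], flank_bins=3)
        assert used == 2 and dropped == 1
        assert avg[3, 3] == pytest.approx((5.0 + 1.0) / 2)

    def test_pileup_through_contact_map_uniform(self):
        cmap = hic.balance(dense_map(np.ones((60, 60)), bin_size=5000),
                           min_nnz=0, mad_frac=0.0)
        anchors = pd.DataFrame({
            "chrom": ["chr1"], "pos1": [100_000], "pos2": [200_000]})
        res = hic.loop_pileup(cmap, anchors, flank=25_000)
        assert res.score == pytest.approx(1.0)
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [150_000]})
        ins = hic.insulation_pileup(cmap, sites, flank=25_000)
        assert ins.score == pytest.approx(1.0)

    def test_anchor_order_and_scale_invariance(self, genome_2mb):
        pairs = simulate.simulate_hic(
            genome_2mb, [], n_pairs=40_000, loop_boost=6.0,
            homotypic_boost=1.0, de_fraction=0.0, dup_fraction=0.0, seed=81)
        df = hic.pairs_frame(pairs)
        cmap = hic.balance(hic.bin_pairs(df, genome_2mb.chrom_lengths, 5000),
                           min_nnz=1, mad_frac=0.0)
        anchors = hic.convergent_ctcf_pairs(genome_2mb.ctcf_sites)
        a = hic.loop_pileup(cmap, anchors, flank=50_000)
        b = hic.loop_pileup(cmap, anchors.iloc[::-1], flank=50_000)
        assert a.score == pytest.approx(b.score)
        scaled = ContactMap(
            bin_size=cmap.bin_size, bins=cmap.bins,
            counts=cmap.counts * 7.0,
            chrom_bin_ranges=cmap.chrom_bin_ranges,
            weights=cmap.weights, balanced=True)
        c = hic.loop_pileup(scaled, anchors, flank=50_000)
        assert c.score == pytest.approx(a.score)

    def test_loop_boost_raises_pileup_score(self, genome_2mb):
        scores = {}
        for boost in (1.0, 8.0):
            pairs = simulate.simulate_hic(
                genome_2mb, [], n_pairs=40_000, loop_boost=boost,
                homotypic_boost=1.0, de_fraction=0.0, dup_fraction=0.0,
                seed=83)
            df = hic.pairs_frame(pairs)
            cmap = hic.balance(
                hic.bin_pairs(df, genome_2mb.chrom_lengths, 5000),
                min_nnz=1, mad_frac=0.0)
            anchors = hic.convergent_ctcf_pairs(genome_2mb.ctcf_sites)
            scores[boost] = hic.loop_pileup(cmap, anchors,
                                            flank=50_000).score
        assert scores[8.0] > scores[1.0]
        assert scores[8.0] > 1.1


class TestReplicateSpearman:
    def test_identical_maps_give_unit_median(self):
        rng = np.random.default_rng(10)
        m = rng.poisson(8, (15, 15)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cmap = hic.balance(dense_map(m), min_nnz=0, mad_frac=0.0)
        coeffs, median, skipped = hic.replicate_spearman(cmap, cmap)
        assert np.allclose(coeffs, 1.0)
        assert median == 1.0

    def test_rank_reversed_rows_give_minus_one(self):
        n = 14
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        a = dense_map((i + j).astype(float), weights=np.ones(n),
                      balanced=True)
        b = dense_map((2 * n - i - j).astype(float), weights=np.ones(n),
                      balanced=True)
        coeffs, median, _ = hic.replicate_spearman(a, b)
        assert np.allclose(coeffs, -1.0)

    def test_split_half_stability(self, genome_2mb):
        pairs = simulate.simulate_hic(
            genome_2mb, [], n_pairs=60_000, de_fraction=0.0,
            dup_fraction=0.0, seed=91)
        df = hic.pairs_frame(pairs)
        rng = np.random.default_rng(92)

        def split_median(split_seed):
            mask = np.random.default_rng(split_seed).random(len(df)) < 0.5
            maps = []
            for sub in (df[mask], df[~mask]):
                cmap = hic.bin_pairs(sub, genome_2mb.chrom_lengths, 100_000)
                maps.append(hic.balance(cmap, min_nnz=1, mad_frac=0.0))
            _, med, _ = hic.replicate_spearman(*maps)
            return med
        m1, m2 = split_median(1), split_median(2)
        assert abs(m1 - m2) < 0.15
        assert m1 > 0.3  # replicates of the same library correlate

    def test_too_few_shared_positions(self):
        a = dense_map(np.ones((4, 4)), weights=np.ones(4), balanced=True)
        with pytest.raises(ValueError):
            hic.replicate_spearman(a, a)  # constant rows, all skipped


def test_compute_e1_recovers_block_structure(genome_2mb):
    pairs = simulate.simulate_hic(
        genome_2mb, [], n_pairs=120_000, homotypic_boost=4.0,
        loop_boost=1.0, de_fraction=0.0, dup_fraction=0.0, seed=95)
    df = hic.pairs_frame(pairs)
    cmap = hic.balance(hic.bin_pairs(df, genome_2mb.chrom_lengths, 100_000),
                       min_nnz=1, mad_frac=0.0)
    comp = genome_2mb.compartment_track
    truth = np.array([
        comp[(comp["start"] <= s) & (comp["end"] > s)]["score"].iloc[0]
        for s in cmap.bins["start"]
    ])
    e1 = hic.compute_e1(cmap, phasing=truth)
    good = np.isfinite(e1)
    r = np.corrcoef(e1[good], truth[good])[0, 1]
    assert r > 0.7
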