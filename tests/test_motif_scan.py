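"""HMM window scoring vs enumeration oracle, normalizations, regulatory
regions, Pgm, and target-set construction."""

import numpy as np
import pandas as pd
import pytest

from divscan import motif_scan as ms
from divscan.models import GeneModel, encode_seq
from divscan.synthetic_data import SimConfig, simulate_genome

from oracles import stubb_enumeration

BG = np.array([0.3, 0.2, 0.2, 0.3])


def toy_pwm(width=3, seed=0, motif_id="m"):
    rng = np.random.default_rng(seed)
    return ms.PWM(motif_id, rng.dirichlet(np.ones(4) * 0.7, size=width))


class TestPwm:
    def test_rows_normalised_with_pseudocount(self):
        pwm = ms.PWM("m", [[10, 0, 0, 0], [0, 5, 5, 0]], renormalize=True)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        assert (pwm.matrix > 0).all()

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            ms.PWM("m", np.ones((0, 4)))

    def test_information_content_of_deterministic_pwm(self):
        pwm = ms.PWM("m", np.eye(4)[[0, 1, 2, 3]])
        assert pwm.information_content() == pytest.approx(8.0)


class TestPartitionWindows:
    def test_one_kb_scaffold_yields_three_windows(self):
        genome = {"s1": np.zeros(1000, dtype=np.int8)}
        windows, _ = ms.partition_windows(genome)
        assert list(windows["start"]) == [0, 250, 500]
        assert not windows["truncated"].any()

    def test_short_scaffold_single_truncated_window(self):
        genome = {"s1": np.zeros(300, dtype=np.int8)}
        windows, _ = ms.partition_windows(genome)
        assert len(windows) == 1
        assert windows.loc[0, "truncated"]

    def test_fully_masked_window_excluded_and_gc_on_unmasked(self):
        seq = encode_seq("ACGT" * 250)
        genome = {"s1": seq}
        mask = pd.DataFrame({"scaffold": ["s1"], "start": [0], "end": [600]})
        windows, masked = ms.partition_windows(genome, mask=mask)
        assert not windows.loc[0, "scored"]          # fully masked
        assert windows.loc[2, "gc"] == pytest.approx(0.5)
        assert (masked["s1"][:600] == -1).all()


class TestBackground:
    def test_uniform_genome_frequencies(self):
        cfg = SimConfig(seed=5, genome_length=100_000, n_scaffolds=1, gc_mean=0.5,
                        n_genes=0, n_motifs=0, sweep_gene_fraction=0,
                        planted_gene_fraction=0)
        genome = simulate_genome(cfg)
        freq = ms.estimate_background(genome, [])
        assert np.all((freq >= 0.23) & (freq <= 0.27))
        assert freq.sum() == pytest.approx(1.0)

    def test_floor_applied_on_degenerate_composition(self):
        genome = {"s1": np.zeros(30_000, dtype=np.int8)}  # all A
        freq = ms.estimate_background(genome, [])
        assert freq[0] == pytest.approx(0.997, abs=1e-3)
        assert (freq[1:] >= 0.001 - 1e-12).all()

    def test_fallback_to_whole_genome_when_no_region_qualifies(self):
        genome = {"s1": np.zeros(10_000, dtype=np.int8)}  # scaffold < 22 kb
        freq = ms.estimate_background(genome, [])
        assert freq[0] > 0.99


class TestStubbScore:
    def test_zero_transition_scores_zero(self, rng):
        seq = rng.integers(0, 4, 40).astype(np.int8)
        assert ms.stubb_score_window(seq, toy_pwm(), BG, t=0.0) == pytest.approx(0.0)

    def test_planted_consensus_raises_score(self, rng):
        pwm = ms.PWM("m", np.eye(4)[[0, 1, 2, 3, 0, 1]] * 0.97 + 0.0075)
        base = rng.integers(0, 4, 80).astype(np.int8)
        planted = base.copy()
        planted[30:36] = [0, 1, 2, 3, 0, 1]
        assert ms.stubb_score_window(planted, pwm, BG) > ms.stubb_score_window(
            base, pwm, BG
        )

    def test_matches_placement_enumeration_oracle(self, rng):
        for trial in range(8):
            pwm = toy_pwm(width=int(rng.integers(2, 5)), seed=trial)
            seq = rng.integers(0, 4, int(rng.integers(8, 30))).astype(np.int8)
            impl = ms.stubb_score_window(seq, pwm, BG)
            oracle = stubb_enumeration(seq, pwm.matrix, BG, ms.DEFAULT_TRANSITION)
            assert impl == pytest.approx(oracle, abs=1e-9)

    def test_window_shorter_than_motif_undefined(self):
        assert np.isnan(ms.stubb_score_window(np.array([0, 1], dtype=np.int8),
                                              toy_pwm(width=5), BG))

    def test_vectorised_batch_equals_scalar_path(self, rng):
        pwm = toy_pwm(width=4, seed=3)
        seqs = rng.integers(0, 4, (6, 50)).astype(np.int8)
        batch = ms.stubb_score_windows(seqs, pwm, BG)
        singles = [ms.stubb_score_window(s, pwm, BG) for s in seqs]
        np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestNormalization:
    def test_rank_examples(self):
        np.testing.assert_allclose(ms.rank_normalize(np.array([5.0, 3, 1])), [0, 0.5, 1])
        np.testing.assert_allclose(
            ms.rank_normalize(np.array([5.0, 5, 1])), [0.25, 0.25, 1]
        )
        np.testing.assert_allclose(ms.rank_normalize(np.array([2.0, 7])), [1, 0])

    def test_identical_scores_map_to_half(self):
        np.testing.assert_allclose(ms.rank_normalize(np.full(5, 2.0)), 0.5)

    def test_attains_zero_and_one(self, rng):
        out = ms.rank_normalize(rng.normal(size=101))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_permutation_equivariance(self, rng):
        scores = rng.normal(size=60)
        perm = rng.permutation(60)
        np.testing.assert_allclose(
            ms.rank_normalize(scores)[perm], ms.rank_normalize(scores[perm])
        )

    def test_gc_bins_equal_counts_with_remainder_first(self, rng):
        gc = rng.uniform(0.3, 0.5, 41)
        bins = ms.gc_bin_assignment(gc, 20)
        sizes = np.bincount(bins)
        assert sizes[0] == 3 and (sizes[1:] == 2).all()

    def test_forty_windows_give_twenty_binary_bins(self, rng):
        gc = rng.uniform(0, 1, 40)
        scores = rng.normal(size=40)
        out = ms.gc_rank_normalize(scores, gc, 20)
        assert set(np.round(out, 6)) == {0.0, 1.0}

    def test_gc_confound_removed_by_binned_normalization(self, rng):
        # a score that is a pure function of GC: global ranking chases GC,
        # within-bin ranking does not
        gc = rng.uniform(0.25, 0.55, 2000)
        scores = gc.copy()
        rank = ms.rank_normalize(scores)
        gcn = ms.gc_rank_normalize(scores, gc, 20)
        top_rank = np.argsort(rank)[:100]
        top_gc = np.argsort(gcn)[:100]
        assert abs(gc[top_rank].mean() - gc.mean()) > 0.1
        assert abs(gc[top_gc].mean() - gc.mean()) < 0.02


class TestRegulatoryRegions:
    GENES = [
        GeneModel("a", "s1", 10_000, 12_000, "+"),
        GeneModel("b", "s1", 20_000, 22_000, "-"),
        GeneModel("c", "s1", 40_000, 42_000, "+"),
    ]
    LENGTHS = {"s1": 60_000}

    def region(self, gene_id, definition):
        gene = next(g for g in self.GENES if g.gene_id == gene_id)
        return ms.define_regulatory_region(gene, definition, self.GENES, self.LENGTHS)

    def test_one_kb_upstream_plus_strand(self):
        assert self.region("a", "1Kup").intervals == [(9_000, 10_000)]

    def test_one_kb_upstream_minus_strand_reflects(self):
        assert self.region("b", "1Kup").intervals == [(22_000, 23_000)]

    def test_five_up_two_down_oriented(self):
        assert self.region("a", "5Kup2Kdown").intervals == [(5_000, 12_000)]
        assert self.region("b", "5Kup2Kdown").intervals == [(20_000, 27_000)]

    def test_near_start_site_bisector(self):
        genes = [GeneModel("x", "s1", 0, 100, "+"), GeneModel("y", "s1", 10_000, 10_100, "+")]
        reg = ms.define_regulatory_region(genes[0], "NearStartSite", genes, {"s1": 20_000})
        assert reg.intervals == [(0, 5_000)]
        assert reg.midpoint_rule

    def test_gene_territory_extends_upstream(self):
        reg = self.region("c", "GeneTerr")
        # upstream neighbour boundary at 22,000 but 5 kb upstream of the
        # TSS (40,000) already reaches 35,000 > 22,000 -> keep 22,000
        assert reg.intervals == [(22_000, 60_000)]
        # no upstream neighbour: territory reaches the scaffold start,
        # which already exceeds the 5 kb upstream guarantee
        reg_a = self.region("a", "GeneTerr")
        assert reg_a.intervals == [(0, 20_000)]

    def test_scaffold_edge_clipping(self):
        gene = GeneModel("e", "s1", 500, 1_500, "+")
        reg = ms.define_regulatory_region(gene, "5Kup", [gene], {"s1": 60_000})
        assert reg.intervals == [(0, 500)]

    def test_unknown_definition_rejected(self):
        with pytest.raises(ValueError):
            self.region("a", "2Kup")


class TestGeneScores:
    def _setup(self):
        windows = pd.DataFrame(
            {
                "scaffold": ["s1"] * 4,
                "start": [8_750, 9_000, 9_250, 9_500],
                "end": [9_250, 9_500, 9_750, 10_000],
                "gc": 0.4,
                "masked_fraction": 0.0,
                "truncated": False,
                "scored": True,
            }
        )
        norm = pd.DataFrame({"m1": [0.5, 0.2, 0.8, 0.4]}, index=windows.index)
        genes = [GeneModel("a", "s1", 10_000, 12_000, "+")]
        return genes, windows, norm

    def test_pgm_formula_and_best_window(self):
        genes, windows, norm = self._setup()
        scores = ms.gene_motif_scores(
            genes, windows, {"rank": norm}, {"s1": 60_000}, regions=("1Kup",)
        )
        row = scores.iloc[0]
        assert row["Wg"] == 4
        assert row["Ngm"] == pytest.approx(0.2)
        assert row["Pgm"] == pytest.approx(1 - 0.8**4)

    @pytest.mark.parametrize(
        "ngm,wg,expected", [(0.5, 1, 0.5), (0.5, 2, 0.75), (0.0, 7, 0.0)]
    )
    def test_pgm_identities(self, ngm, wg, expected):
        assert 1 - (1 - ngm) ** wg == pytest.approx(expected)

    def test_pgm_monotone_in_ngm_and_wg(self):
        ngms = np.linspace(0.01, 0.99, 25)
        for wg in (1, 3, 10):
            pgm = 1 - (1 - ngms) ** wg
            assert (np.diff(pgm) > 0).all()
        for ngm in (0.1, 0.5, 0.9):
            pgm = [1 - (1 - ngm) ** w for w in range(1, 10)]
            assert (np.diff(pgm) > 0).all()


class TestTargetSets:
    def _scores(self, n_genes=50, n_motifs=3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(n_motifs):
            for norm in ("rank", "gc"):
                for region in ("1Kup", "GeneTerr"):
                    for g in range(n_genes):
                        rows.append(
                            {
                                "gene": f"g{g:03d}",
                                "motif": f"m{m}",
                                "region": region,
                                "normalization": norm,
                                "Wg": 1,
                                "Ngm": 0.5,
                                "Pgm": rng.uniform(),
                            }
                        )
        return pd.DataFrame(rows)

    def test_cardinality_one_motif_gives_eight_sets(self):
        sets = ms.build_target_sets(self._scores(n_motifs=1))
        assert len(sets) == 8

    def test_short_gene_list_taken_whole(self):
        sets = ms.build_target_sets(self._scores(n_genes=50, n_motifs=1))
        by_size = {s.size: s for s in sets if s.normalization == "rank" and s.region == "1Kup"}
        assert len(by_size[100].genes) == 50
        assert len(by_size[800].genes) == 50

    def test_ordering_ascending_pgm_ties_by_gene_id(self):
        df = pd.DataFrame(
            {
                "gene": ["gB", "gA", "gC"],
                "motif": "m0",
                "region": "1Kup",
                "normalization": "rank",
                "Wg": 1,
                "Ngm": 0.5,
                "Pgm": [0.2, 0.2, 0.1],
            }
        )
        sets = ms.build_target_sets(df, sizes=(2,), regions=("1Kup",),
                                    normalizations=("rank",))
        assert sets[0].genes == ("gC", "gA")

    def test_meme_roundtrip(self, tmp_path, tiny_sim):
        from divscan import io as dio

        path = tmp_path / "m.meme"
        dio.write_meme(tiny_sim.pwms, path)
        back = dio.read_meme(path)
        assert [p.motif_id for p in back] == [p.motif_id for p in tiny_sim.pwms]
        for a, b in zip(back, tiny_sim.pwms):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-5)

    def test_pwm_tsv_reader(self, tmp_path):
        from divscan import io as dio

        mat = np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]])
        path = tmp_path / "m.tsv"
        np.savetxt(path, mat.T, delimiter="\t")  # 4 x w orientation
        pwm = dio.read_pwm_tsv(path)
        assert pwm.width == 2
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0)
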