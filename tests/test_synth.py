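"""Synthetic-data generator: placement arithmetic, determinism, noise models."""

import numpy as np
import pandas as pd
import pytest

from nucshift import synth
from nucshift.synth import PlacementError


def _one_gene_genome(strand, tss, tes, length=100_000):
    genes = pd.DataFrame(
        [("g1", "chr1", strand, tss, tes)],
        columns=["gene_id", "chrom", "strand", "tss", "tes"],
    )
    return synth.GenomeAnnotation({"chr1": length}, genes)


class TestMakeGenome:
    def test_zero_genes_is_empty_annotation(self):
        g = synth.make_genome(1, 100_000, 0, seed=1)
        assert len(g.genes) == 0
        assert g.chromosomes == {"chr1": 100_000}

    def test_seed_determinism(self):
        a = synth.make_genome(1, 100_000, 10, 2000, seed=7)
        b = synth.make_genome(1, 100_000, 10, 2000, seed=7)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PlacementError):
            synth.make_genome(1, 10_000, 50, 2000, seed=1)

    def test_genes_do_not_overlap_and_both_strands_present(self):
        g = synth.make_genome(2, 80_000, 30, 1000, seed=5)
        for chrom, sub in g.genes.groupby("chrom"):
            spans = sorted(
                (min(r["tss"], r["tes"]), max(r["tss"], r["tes"]))
                for _, r in sub.iterrows()
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
        assert set(g.genes["strand"]) == {"+", "-"}


class TestPlaceNucleosomes:
    def test_plus_strand_arithmetic(self):
        g = _one_gene_genome("+", 1000, 3500)
        m = synth.place_nucleosomes(g, nfr_length=140, spacing=165, n_per_gene=2)
        assert list(m.entries["dyad"]) == [1070, 1235]
        assert list(m.entries["position_index"]) == [1, 2]

    def test_minus_strand_mirror(self):
        g = _one_gene_genome("-", 5000, 2500)
        m = synth.place_nucleosomes(g, nfr_length=140, spacing=165, n_per_gene=2)
        assert list(m.entries["dyad"]) == [4930, 4765]

    def test_count_per_gene(self):
        g = synth.make_genome(1, 500_000, 100, 1500, seed=2)
        m = synth.place_nucleosomes(g, n_per_gene=4)
        assert len(m.entries) == 400
        assert sorted(m.entries["position_index"].unique()) == [1, 2, 3, 4]

    def test_out_of_bounds_dropped_with_warning(self):
        g = _one_gene_genome("-", 200, 100, length=1000)
        with pytest.warns(UserWarning, match="outside chromosome"):
            m = synth.place_nucleosomes(g, nfr_length=140, spacing=165, n_per_gene=4)
        assert m.n_dropped > 0

    def test_sub_footprint_spacing_warns(self):
        g = _one_gene_genome("+", 1000, 3500)
        with pytest.warns(UserWarning, match="147"):
            synth.place_nucleosomes(g, spacing=100, n_per_gene=2)


class TestApplyShifts:
    @pytest.mark.parametrize(
        "strand,tss,tes,expected",
        [("+", 1000, 3500, [1070, 1245]), ("-", 5000, 2500, [4930, 4755])],
    )
    def test_downstream_positive_moves_away_from_tss(self, strand, tss, tes, expected):
        g = _one_gene_genome(strand, tss, tes)
        m = synth.place_nucleosomes(g, n_per_gene=2)
        shifted = synth.apply_shifts(m, {2: 10}, g)
        assert list(shifted.entries["dyad"]) == expected

    def test_empty_spec_is_identity(self):
        g = _one_gene_genome("+", 1000, 3500)
        m = synth.place_nucleosomes(g, n_per_gene=3)
        shifted = synth.apply_shifts(m, {}, g)
        pd.testing.assert_frame_equal(shifted.entries, m.entries)

    def test_strand_mirror_maps_are_exact_mirrors(self):
        # a genome and its coordinate-flipped mirror shift to mirrored maps
        L = 10_000
        gp = _one_gene_genome("+", 1000, 3500, length=L)
        gm = _one_gene_genome("-", L - 1 - 1000, L - 1 - 3500, length=L)
        mp = synth.apply_shifts(synth.place_nucleosomes(gp, n_per_gene=3), {2: 10}, gp)
        mm = synth.apply_shifts(synth.place_nucleosomes(gm, n_per_gene=3), {2: 10}, gm)
        assert list(L - 1 - mm.entries["dyad"]) == list(mp.entries["dyad"])


class TestSimulateFragments:
    def test_fragment_count_conservation(self):
        g = _one_gene_genome("+", 1000, 3500)
        m = synth.place_nucleosomes(g, n_per_gene=3)
        frags = synth.simulate_fragments(m, g, fragments_per_unit_weight=100, seed=1)
        assert len(frags) == 300

    def test_noiseless_fragments_recover_true_dyads(self):
        g = _one_gene_genome("+", 1000, 3500)
        m = synth.place_nucleosomes(g, n_per_gene=2, fuzziness_sd=0.0)
        frags = synth.simulate_fragments(
            m, g, 50, fragment_length_mean=147, fragment_length_sd=0, seed=1
        )
        mids = (frags["start"] + frags["end"] - 1) // 2
        assert set(mids) == {1070, 1235}

    def test_empirical_dyad_sd_matches_fuzziness(self):
        g = _one_gene_genome("+", 5000, 95_000)
        m = synth.place_nucleosomes(g, n_per_gene=1, fuzziness_sd=20.0)
        frags = synth.simulate_fragments(m, g, 10_000, seed=9)
        mids = (frags["start"] + frags["end"] - 1) // 2
        # SD of a Normal(., 20) sample of 10000: 3-sigma band is +/- 0.6 bp
        assert abs(np.std(mids, ddof=1) - 20.0) < 0.6

    def test_seed_determinism(self):
        g = _one_gene_genome("+", 1000, 3500)
        m = synth.place_nucleosomes(g, n_per_gene=3)
        f1 = synth.simulate_fragments(m, g, 100, seed=4)
        f2 = synth.simulate_fragments(m, g, 100, seed=4)
        pd.testing.assert_frame_equal(f1, f2)


class TestTitrationAndTimecourse:
    def test_noiseless_points_lie_on_hill_curve(self):
        conc = [0, 1, 2, 5, 10, 20, 60]
        df = synth.simulate_titration(5.0, 1.0, conc, noise_sd=0.0, replicates=1, seed=0)
        at_kd = df.loc[df["concentration"] == 5.0, "fraction_bound"].iloc[0]
        assert at_kd == pytest.approx(0.5, abs=1e-12)
        assert df.loc[df["concentration"] == 0, "fraction_bound"].iloc[0] == 0.0
        big = synth.hill([1e9], 5.0, 1.0)[0]
        assert big == pytest.approx(1.0, abs=1e-6)

    def test_titration_replicates_and_clipping_flag(self):
        df = synth.simulate_titration(5.29, 1.43, range(13), 0.3, 3, seed=1)
        assert set(df["replicate"]) == {0, 1, 2}
        assert df["fraction_bound"].between(0, 1).all()
        assert df["clipped"].any()  # noise sd 0.3 must clip somewhere

    def test_timecourse_initial_slope_is_v0(self):
        t = np.array(synth.REMODELING_TIMES_S, dtype=float)
        df = synth.simulate_timecourse(1.0, 20.0, t, noise_sd=0.0, seed=0)
        expected = 20 * (1 - np.exp(-0.05 * t))
        np.testing.assert_allclose(df["signal_nM"], expected, rtol=1e-12)
        eps = 1e-6
        slope = synth.saturating_exponential([eps], 1.0, 20.0)[0] / eps
        assert slope == pytest.approx(1.0, rel=1e-6)

    def test_zero_rate_gives_flat_zero(self):
        df = synth.simulate_timecourse(0.0, 20.0, [0, 10, 20, 40], 0.0, seed=0)
        assert (df["signal_nM"] == 0).all()

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            synth.simulate_timecourse(1.0, 20.0, [0, 10, 10], 0.0, seed=0)
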