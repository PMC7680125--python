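"""Gene assignment, filters, metagene profiles and median shifts."""

import numpy as np
import pandas as pd
import pytest

from nucshift import dyads, metagene, synth
from conftest import make_calls


def _genome(rows, length=100_000):
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    return synth.GenomeAnnotation({"chr1": length}, genes)


class TestAssignToGenes:
    def test_plus_strand_ordering(self):
        g = _genome([("g1", "chr1", "+", 1000, 2500)])
        idx = metagene.assign_to_genes(make_calls([1070, 1235, 1400]), g)
        assert list(idx["position_index"]) == [1, 2, 3]
        assert list(idx["dyad"]) == [1070, 1235, 1400]

    def test_minus_strand_mirror(self):
        g = _genome([("g1", "chr1", "-", 5000, 3500)])
        idx = metagene.assign_to_genes(make_calls([4765, 4930]), g)
        assert list(idx["dyad"]) == [4930, 4765]
        assert list(idx["position_index"]) == [1, 2]

    def test_upstream_slack_window(self):
        g = _genome([("g1", "chr1", "+", 1000, 2500)])
        idx = metagene.assign_to_genes(make_calls([900, 980, 1100]), g, upstream_slack=30)
        # 900 is 100 bp upstream: outside the 30 bp slack; 980 inside
        assert list(idx["dyad"]) == [980, 1100]

    def test_genes_without_calls_counted(self):
        g = _genome([("g1", "chr1", "+", 1000, 2500), ("g2", "chr1", "+", 9000, 9800)])
        idx = metagene.assign_to_genes(make_calls([1100]), g)
        assert idx.attrs["n_genes_without_calls"] == 1


class TestFilterGenes:
    @pytest.mark.parametrize(
        "tss,tes,n_nucs,kept",
        [
            (1000, 1560, 4, False),  # span exactly 560: "larger than" excludes
            (1000, 1561, 4, True),
            (1000, 2000, 3, False),  # under four nucleosomes
        ],
    )
    def test_length_and_count_rules(self, tss, tes, n_nucs, kept):
        g = _genome([("g1", "chr1", "+", tss, tes)])
        idx = pd.DataFrame(
            {
                "gene_id": ["g1"] * n_nucs,
                "chrom": "chr1",
                "strand": "+",
                "dyad": range(n_nucs),
                "position_index": range(1, n_nucs + 1),
            }
        )
        assert (metagene.filter_genes(idx, g) == {"g1"}) is kept


class TestSelectShiftedGenes:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "position_index", "p", "untestable"]
        )

    def test_position_window_and_alpha(self):
        res = self._results(
            [("g1", 2, 0.001, False), ("g2", 5, 0.001, False), ("g3", 2, 0.5, False)]
        )
        assert metagene.select_shifted_genes(res) == {"g1"}
        assert metagene.select_shifted_genes(res, alpha=0.0) == set()

    def test_untestable_never_selected(self):
        res = self._results([("g1", 2, np.nan, True)])
        assert metagene.select_shifted_genes(res) == set()


class TestMetageneProfile:
    def test_single_gene_profile_equals_oriented_track_window(self):
        g = _genome([("g1", "chr1", "-", 5000, 3500)], length=6000)
        pos = [4930] * 40 + [4765] * 40 + [4600] * 40 + [4435] * 40
        track = dyads.build_track(pd.DataFrame({"chrom": "chr1", "pos": pos}), g)
        idx = metagene.assign_to_genes(make_calls([4930, 4765, 4600, 4435]), g)
        prof = metagene.metagene_profile(track, track, idx, {"g1"}, range(0, 400))
        # oriented: offset increases downstream = decreasing coordinate
        np.testing.assert_allclose(
            prof.mean_a, track.values["chr1"][4930 - np.arange(400)]
        )
        assert prof.n_genes == 1

    def test_array_peaks_at_spacing_offsets(self, shifted_run):
        idx = metagene.assign_to_genes(shifted_run["calls_a"], shifted_run["genome"])
        genes = metagene.filter_genes(idx, shifted_run["genome"])
        prof = metagene.metagene_profile(
            shifted_run["track_a"], shifted_run["track_b"], idx, genes,
            range(-200, 801),
        )
        mean_a = np.nan_to_num(prof.mean_a)
        for expect in (0, 165, 330, 495, 660):
            window = mean_a[(prof.offsets >= expect - 20) & (prof.offsets <= expect + 20)]
            peak = prof.offsets[np.argmax(mean_a * ((prof.offsets >= expect - 20) & (prof.offsets <= expect + 20)))]
            assert abs(peak - expect) <= 5
        # condition B: +2 peak displaced ~10 bp downstream relative to A
        mean_b = np.nan_to_num(prof.mean_b)
        sel = (prof.offsets >= 120) & (prof.offsets <= 220)
        peak_b = prof.offsets[sel][np.argmax(mean_b[sel])]
        peak_a = prof.offsets[sel][np.argmax(mean_a[sel])]
        assert peak_b - peak_a == pytest.approx(10, abs=4)

    def test_empty_gene_set_raises(self, shifted_run):
        idx = metagene.assign_to_genes(shifted_run["calls_a"], shifted_run["genome"])
        with pytest.raises(ValueError, match="empty gene set"):
            metagene.metagene_profile(
                shifted_run["track_a"], shifted_run["track_b"], idx, set()
            )

    def test_flat_region_profile_mass_tends_to_one(self):
        g = _genome([("g1", "chr1", "+", 1000, 2500)], length=4000)
        track = dyads.build_track(
            pd.DataFrame({"chrom": "chr1", "pos": np.arange(4000)}), g
        )
        idx = metagene.assign_to_genes(make_calls([1070]), g)
        prof = metagene.metagene_profile(track, track, idx, {"g1"}, range(-200, 801))
        np.testing.assert_allclose(prof.mean_a, 1.0)


class TestMedianShift:
    def _results(self, shifts_by_gene):
        rows = []
        for gene, (k, s) in shifts_by_gene.items():
            rows.append((gene, k, s))
        return pd.DataFrame(rows, columns=["gene_id", "position_index", "signed_shift"])

    def test_median_of_odd_multiset(self):
        res = self._results({"g1": (2, 8.0), "g2": (2, 10.0), "g3": (2, 12.0)})
        table = metagene.median_shift_by_position(res, {"g1", "g2", "g3"}, (1, 2))
        assert table.loc[table["position_index"] == 2, "median_shift"].iloc[0] == 10.0
        # empty cell for +1 is absent, not zero
        assert 1 not in set(table["position_index"])

    def test_single_value_is_itself(self):
        res = self._results({"g1": (3, 7.0)})
        table = metagene.median_shift_by_position(res, {"g1"}, (3,))
        assert table["median_shift"].iloc[0] == 7.0

    def test_median_robust_to_contamination(self, shifted_run):
        res = shifted_run["results"].copy()
        sel = metagene.filter_genes(
            metagene.assign_to_genes(shifted_run["calls_a"], shifted_run["genome"]),
            shifted_run["genome"],
        )
        clean = metagene.median_shift_by_position(res, sel, (2,))
        plus2 = res.index[res["position_index"] == 2]
        spoil = plus2[: max(1, len(plus2) // 10)]  # contaminate <= 10% of pairs
        res.loc[spoil, "signed_shift"] = 60.0
        dirty = metagene.median_shift_by_position(res, sel, (2,))
        assert abs(
            dirty["median_shift"].iloc[0] - clean["median_shift"].iloc[0]
        ) < 2.0


class TestStrandInvariance:
    def test_mirrored_coordinates_leave_signed_medians_unchanged(self):
        from nucshift import calling, shifts as sh

        L = 60_000
        rows_p = [("g1", "chr1", "+", 2000, 4000), ("g2", "chr1", "+", 10_000, 12_000)]
        rows_m = [
            ("g1", "chr1", "-", L - 1 - 2000, L - 1 - 4000),
            ("g2", "chr1", "-", L - 1 - 10_000, L - 1 - 12_000),
        ]
        out = {}
        for tag, rows in (("fwd", rows_p), ("rev", rows_m)):
            g = _genome(rows, length=L)
            # zero fuzziness makes the mirror exact; with noise the
            # invariance holds only in distribution
            truth = synth.place_nucleosomes(g, n_per_gene=4, fuzziness_sd=0.0)
            mut = synth.apply_shifts(truth, {2: 10}, g, condition="mut")
            fa = synth.simulate_fragments(truth, g, 300, seed=5)
            fb = synth.simulate_fragments(mut, g, 300, seed=6)
            da, db = (dyads.fragments_to_dyads(f) for f in (fa, fb))
            ca = calling.call_nucleosomes(
                calling.smooth_track(dyads.build_track(da, g)), da
            )
            cb = calling.call_nucleosomes(
                calling.smooth_track(dyads.build_track(db, g)), db
            )
            res = sh.run_shift_analysis(ca, cb, g)
            table = metagene.median_shift_by_position(res, {"g1", "g2"}, (1, 2, 3, 4))
            out[tag] = table.set_index("position_index")["median_shift"]
        # same true dyad offsets, mirrored geometry: identical signed medians
        assert (out["fwd"] - out["rev"]).abs().max() == 0.0
        assert out["fwd"].loc[2] == 10.0
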