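"""Windowed composition, normalized coordinates, rank-sum contrasts, SMA."""

import numpy as np
import pandas as pd
import pytest

from conftest import feature_frame
from karyofuse.composition import (class_contrasts, fusion_point_contrast,
                                   normalized_positions, normalized_profile,
                                   region_repeat_scaling, sma_fit,
                                   sma_group_compare, window_composition)
from karyofuse.fusion import FusionEvent
from karyofuse.intervals import total_length
from karyofuse.io import ChromosomeRecord

MB = 1_000_000


def _records(**lengths_and_seqs):
    return [ChromosomeRecord(k, "sp", v) for k, v in lengths_and_seqs.items()]


class TestWindowComposition:
    def test_gc_and_union_coverage(self):
        seq = "G" * 100_000 + "AT" * 50_000
        recs = _records(c1=seq)
        repeats = feature_frame([("c1", 0, 30_000, ".", "repeat"),
                                 ("c1", 20_000, 50_000, ".", "repeat")])
        # two CDS overlapping by 10 kb spanning 60 kb total in window 2
        cds = feature_frame([("c1", 100_000, 140_000, "+", "CDS"),
                             ("c1", 130_000, 160_000, "+", "CDS")])
        w = window_composition(recs, repeats, cds, window_size=100_000)
        assert len(w) == 2
        assert w.iloc[0]["gc"] == 100.0
        assert w.iloc[0]["repeat"] == 50.0  # union of [0,30k)+[20k,50k)
        assert w.iloc[1]["coding"] == 60.0  # union rule, not 70
        assert w.iloc[1]["gc"] == 0.0  # the AT half carries no G or C

    def test_terminal_window_dropped_below_half(self):
        recs = _records(c1="A" * 149_000)
        w = window_composition(recs, feature_frame([]), feature_frame([]),
                               window_size=100_000)
        assert len(w) == 1
        recs = _records(c1="A" * 151_000)
        w = window_composition(recs, feature_frame([]), feature_frame([]),
                               window_size=100_000)
        assert len(w) == 2
        assert w.iloc[1]["end"] - w.iloc[1]["start"] == 51_000

    def test_gc_over_non_n_bases_only(self):
        recs = _records(c1="G" * 50_000 + "N" * 50_000)
        w = window_composition(recs, feature_frame([]), feature_frame([]),
                               window_size=100_000)
        assert w.iloc[0]["gc"] == 100.0

    def test_window_repeat_sums_match_merged_intervals(self, tiny_system):
        anc, _, _ = tiny_system
        rec = anc.records[0]
        rep = anc.features[(anc.features["chrom"] == rec.id)
                           & (anc.features["kind"] == "repeat")]
        # chromosome trimmed to a whole number of windows so no window drops
        wsize = 10_000
        trimmed = ChromosomeRecord(rec.id, rec.species,
                                   rec.sequence[:(rec.length // wsize) * wsize])
        rep = rep[rep["end"] <= trimmed.length]
        w = window_composition([trimmed], rep, feature_frame([]), wsize)
        win_bp = (w["repeat"] / 100.0 * (w["end"] - w["start"])).sum()
        merged_bp = total_length(rep["start"].to_numpy(), rep["end"].to_numpy())
        assert round(win_bp) == merged_bp

    def test_unknown_chromosome_rejected(self):
        recs = _records(c1="A" * 2000)
        bad = feature_frame([("cX", 0, 10, ".", "repeat")])
        with pytest.raises(ValueError, match="absent"):
            window_composition(recs, bad, feature_frame([]), 1000)

    def test_window_size_floor(self):
        with pytest.raises(ValueError, match="1 kb"):
            window_composition(_records(c1="A" * 2000), feature_frame([]),
                               feature_frame([]), 500)


class TestNormalizedProfile:
    def _windows(self):
        rows = []
        for start in range(0, 10 * MB, MB):
            rows.append({"chrom": "c1", "start": start, "end": start + MB,
                         "gc": 40.0, "repeat": 20.0, "coding": 10.0})
        return pd.DataFrame(rows)

    def test_breakpoint_maps_to_half(self):
        ev = FusionEvent("c1", "A", "B", int(5.5 * MB), 0, 0)
        # a window centred exactly on the breakpoint
        win = pd.DataFrame([{"chrom": "c1", "start": 5 * MB, "end": 6 * MB,
                             "gc": 0, "repeat": 0, "coding": 0}])
        out = normalized_positions(win, [ev], {"c1": 10 * MB})
        assert out["norm_pos"].iloc[0] == pytest.approx(0.5)

    def test_piecewise_linear_left_component(self):
        ev = FusionEvent("c1", "A", "B", 6 * MB, 0, 0)
        win = pd.DataFrame([{"chrom": "c1", "start": int(2.5 * MB),
                             "end": int(3.5 * MB),
                             "gc": 0, "repeat": 0, "coding": 0}])
        out = normalized_positions(win, [ev], {"c1": 10 * MB})
        # centre 3 Mb is the midpoint of the 6 Mb left component -> 0.25
        assert out["norm_pos"].iloc[0] == pytest.approx(0.25)

    def test_measure_preserving_within_components(self):
        ev = FusionEvent("c1", "A", "B", 6 * MB, 0, 0)
        w = self._windows()
        out = normalized_positions(w, [ev], {"c1": 10 * MB})
        lhs = out[out["start"] < 6 * MB]["norm_pos"].to_numpy()
        assert np.allclose(np.diff(lhs), np.diff(lhs)[0])  # equal bp, equal dx
        rhs = out[out["start"] >= 6 * MB]["norm_pos"].to_numpy()
        assert np.allclose(np.diff(rhs), np.diff(rhs)[0])

    def test_profile_bins_and_validation(self):
        ev = FusionEvent("c1", "A", "B", 6 * MB, 0, 0)
        prof = normalized_profile(self._windows(), [ev], {"c1": 10 * MB},
                                  n_bins=5)
        assert set(prof["set"]) == {"fused"}
        assert (prof[prof["metric"] == "repeat"]["mean"] == 20.0).all()
        with pytest.raises(ValueError, match="n_bins"):
            normalized_profile(self._windows(), [ev], {"c1": 10 * MB}, 2)

    def test_fusion_point_peak_detected_without_repeat_loss(self, tiny_config):
        """Concatenating tail-enriched chromosomes leaves a repeat peak at
        0.5; eroding repeats near the junction removes it."""
        import dataclasses

        from karyofuse.simulate import (apply_fusions,
                                        simulate_ancestral_genome)
        contrasts = {}
        for label, loss in (("kept", 0.0), ("eroded", 0.9)):
            cfg = dataclasses.replace(tiny_config, seed=42,
                                      breakpoint_repeat_loss=loss,
                                      n_chromosomes=10, n_fusions=5,
                                      length_range=(200_000, 400_000))
            anc, truth = simulate_ancestral_genome(cfg)
            der, truth = apply_fusions(anc, cfg, truth)
            rep = der.features[der.features["kind"] == "repeat"]
            w = window_composition(der.records, rep, der.features, 10_000)
            events = [FusionEvent(f.derived_chrom, f.left_homolog,
                                  f.right_homolog, f.breakpoint, 0, 0)
                      for f in truth.fusions.itertuples()]
            wn = normalized_positions(w, events, der.lengths())
            contrasts[label] = fusion_point_contrast(wn, width=0.06)
        assert contrasts["kept"]["peak_contrast"] > \
            contrasts["eroded"]["peak_contrast"]
        assert contrasts["kept"]["peak_contrast"] > 0
        # tails always dominate the junction region
        assert contrasts["eroded"]["edge_minus_center"] > 0


class TestClassContrasts:
    def test_exact_one_sided_rank_sum(self):
        df = pd.DataFrame({
            "chrom_class": ["SFC"] * 3 + ["NFC"] * 3,
            "length": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        res = class_contrasts(df, ["length"])
        row = res[(res["group_a"] == "SFC") & (res["group_b"] == "NFC")]
        # complete separation of n=3 vs 3: exact one-sided P = 1/C(6,3)
        assert row["p_value"].iloc[0] == pytest.approx(1 / 20)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=24)
        df = pd.DataFrame({"chrom_class": ["A"] * 12 + ["B"] * 12,
                           "x": vals})
        res = class_contrasts(df, ["x"])
        assert not res["significant"].any()

    def test_small_class_marked_na(self):
        df = pd.DataFrame({"chrom_class": ["A"] * 2 + ["B"] * 5,
                           "x": range(7)})
        res = class_contrasts(df, ["x"])
        assert res["p_value"].isna().all()


class TestSMA:
    def test_collinear_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = sma_fit(x, 3 * x + 1)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_slope_is_sd_ratio_with_sign_of_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2.0, 40)
        y = -0.5 * x + rng.normal(0, 3.0, 40)
        fit = sma_fit(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.slope == pytest.approx(
            np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1), abs=1e-12)

    def test_axis_exchange_inverts_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        assert sma_fit(x, y).slope * sma_fit(y, x).slope == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sma_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="n >= 3"):
            sma_fit([1, 2], [1, 2])
        with pytest.raises(ValueError, match="positive"):
            sma_fit([1, -1, 2], [1, 2, 3], log_transform=True)

    def test_group_compared_with_itself_gives_p_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 2 * x + rng.normal(0, 0.3, size=10)
        res = sma_group_compare({"a": (x, y), "b": (x.copy(), y.copy())},
                                n_permutations=199, seed=0)
        assert res["elevation"]["p_value"].iloc[0] == 1.0

    def test_permutation_count_floor(self):
        with pytest.raises(ValueError, match="99"):
            sma_group_compare({"a": ([1, 2, 3], [1, 2, 3]),
                               "b": ([1, 2, 3], [2, 3, 4])},
                              n_permutations=10)


class TestRegionRepeatScaling:
    def test_fully_repeat_covered_intron_point(self):
        # four chromosomes, each one gene with one intron; on c1 the intron
        # is wholly repeat-covered so its point is (log10 ibp, log10 ibp)
        ann_rows, rep_rows, lengths = [], [], {}
        for i, chrom in enumerate(["c1", "c2", "c3", "c4"]):
            lengths[chrom] = 100_000
            g0 = 10_000
            exon1 = (g0, g0 + 3_000)
            exon2 = (g0 + 3_000 + 4_000 * (i + 1), g0 + 6_000 + 4_000 * (i + 1))
            ann_rows += [
                (chrom, exon1[0], exon2[1], "+", "gene", f"{chrom}_g"),
                (chrom, exon1[0], exon2[1], "+", "mRNA", f"{chrom}_t",
                 f"{chrom}_g"),
                (chrom, exon1[0], exon1[1], "+", "exon", f"{chrom}_e1",
                 f"{chrom}_t"),
                (chrom, exon2[0], exon2[1], "+", "exon", f"{chrom}_e2",
                 f"{chrom}_t"),
                (chrom, exon1[1], exon2[0], "+", "intron", f"{chrom}_i",
                 f"{chrom}_t"),
            ]
            # repeats: cover the whole intron on c1, fragments elsewhere
            if chrom == "c1":
                rep_rows.append((chrom, exon1[1], exon2[0], ".", "repeat"))
            else:
                rep_rows.append((chrom, exon1[1], exon1[1] + 500, ".",
                                 "repeat"))
            rep_rows.append((chrom, 50_000 + 100 * i, 52_000 + 300 * i, ".",
                             "repeat"))
        res = region_repeat_scaling(feature_frame(ann_rows),
                                    feature_frame(rep_rows), lengths,
                                    n_permutations=99)
        pts = res["points"]
        p = pts[(pts["chrom"] == "c1") & (pts["kind"] == "intron")].iloc[0]
        assert p["repeat_bp"] == p["region_bp"] == 4_000
        assert {"intron", "intergenic"} <= set(res["fits"])
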