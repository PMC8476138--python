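"""4D-site calling, genotype filtering, windowed pi, recombination model."""

import numpy as np
import pandas as pd
import pytest

from conftest import feature_frame
from karyofuse.diversity import (FILTER_PROFILES, FourfoldSiteSet,
                                 call_fourfold_sites,
                                 chromosome_diversity_summary,
                                 diversity_recombination_correlation,
                                 filter_genotypes,
                                 nonoverlapping_coding_intervals, pairwise_pi,
                                 pi_windows, recombination_model,
                                 relative_diversity_change)
from karyofuse.genetic_code import reverse_complement
from karyofuse.io import ChromosomeRecord, VariantTable

MB = 1_000_000


def gene_annotation(chrom, cds_list, gene="g1", tid="t1", strand="+"):
    """Annotation for one single-transcript gene from CDS (start, end) pairs."""
    start = min(s for s, _ in cds_list)
    end = max(e for _, e in cds_list)
    rows = [(chrom, start, end, strand, "gene", gene),
            (chrom, start, end, strand, "mRNA", tid, gene)]
    ordered = sorted(cds_list, reverse=(strand == "-"))
    cum = 0
    phases = {}
    for s, e in ordered:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    for i, (s, e) in enumerate(cds_list):
        rows.append((chrom, s, e, strand, "exon", f"{tid}.e{i}", tid))
    frame = feature_frame(rows)
    cds_frame = feature_frame(
        [(chrom, s, e, strand, "CDS", f"{tid}.c{i}", tid, phases[(s, e)])
         for i, (s, e) in enumerate(cds_list)])
    return pd.concat([frame, cds_frame], ignore_index=True)


def variant_table(chrom, entries, n_samples=2):
    """entries: list of (pos, ref, alts, genotypes[(a,b) per sample])."""
    n = len(entries)
    vt = VariantTable(
        samples=[f"s{i}" for i in range(n_samples)],
        chroms=np.array([chrom] * n, dtype=object),
        pos=np.array([e[0] for e in entries], dtype=np.int64),
        ref=[e[1] for e in entries],
        alts=[tuple(e[2]) for e in entries],
        genotypes=np.array([e[3] for e in entries], dtype=np.int8),
        dp=np.full((n, n_samples), 30, dtype=np.int32),
        gq=np.full((n, n_samples), 99, dtype=np.int32),
    )
    return vt


class TestNonoverlappingCoding:
    def test_disjoint_genes_kept_overlap_removed_isoform_selected(self):
        rows = []
        # gene A with two isoforms (CDS 300 vs 450 bp)
        rows += [("c1", 0, 500, "+", "gene", "gA"),
                 ("c1", 0, 500, "+", "mRNA", "tA1", "gA"),
                 ("c1", 0, 300, "+", "CDS", "cA1", "tA1", 0),
                 ("c1", 0, 500, "+", "mRNA", "tA2", "gA"),
                 ("c1", 0, 450, "+", "CDS", "cA2", "tA2", 0)]
        # gene B disjoint
        rows += [("c1", 1000, 1300, "+", "gene", "gB"),
                 ("c1", 1000, 1300, "+", "mRNA", "tB", "gB"),
                 ("c1", 1000, 1300, "+", "CDS", "cB", "tB", 0)]
        # genes C and D overlapping by one CDS interval: both removed
        rows += [("c1", 2000, 2300, "+", "gene", "gC"),
                 ("c1", 2000, 2300, "+", "mRNA", "tC", "gC"),
                 ("c1", 2000, 2300, "+", "CDS", "cC", "tC", 0),
                 ("c1", 2200, 2500, "-", "gene", "gD"),
                 ("c1", 2200, 2500, "-", "mRNA", "tD", "gD"),
                 ("c1", 2200, 2500, "-", "CDS", "cD", "tD", 0)]
        ann = feature_frame(rows)
        kept, n_removed = nonoverlapping_coding_intervals(ann)
        assert set(kept["parent"]) == {"tA2", "tB"}  # longest-CDS isoform
        assert n_removed == 2


class TestGenotypeFilter:
    @pytest.mark.parametrize("dp,gq,profile,kept", [
        (10, 99, "default", False),  # strict: DP must exceed 10
        (11, 31, "default", True),
        (11, 30, "default", False),
        (6, 25, "low-coverage", True),
        (5, 25, "low-coverage", False),
    ])
    def test_strict_thresholds(self, dp, gq, profile, kept):
        vt = variant_table("c1", [(5, "A", ["G"], [(0, 1), (0, 0)])])
        vt.dp[0, 0] = dp
        vt.gq[0, 0] = gq
        out = filter_genotypes(vt, *FILTER_PROFILES[profile])
        assert (tuple(out.genotypes[0, 0]) != (-1, -1)) is kept
        # the untouched sample is never affected
        assert tuple(out.genotypes[0, 1]) == (0, 0)


class TestFourfoldCalling:
    def _genome(self, cds_seq, strand="+", pad=30):
        if strand == "-":
            chrom_seq = "A" * pad + reverse_complement(cds_seq) + "A" * pad
        else:
            chrom_seq = "A" * pad + cds_seq + "A" * pad
        rec = ChromosomeRecord("c1", "sp", chrom_seq)
        ann = gene_annotation("c1", [(pad, pad + len(cds_seq))],
                              strand=strand)
        kept, _ = nonoverlapping_coding_intervals(ann)
        return [rec], kept

    def test_reference_only_calls_exactly_the_fourfold_families(self):
        from karyofuse.genetic_code import BASES, FOURFOLD_CODONS
        all_codons = [a + b + c for a in BASES for b in BASES for c in BASES]
        recs, cds = self._genome("".join(all_codons))
        sites = call_fourfold_sites(recs, cds)
        assert sites.n_sites == 32
        called_codons = {all_codons[i] for i in
                         sites.sites["codon_index"]}
        assert called_codons == FOURFOLD_CODONS
        assert sites.provenance["codons_scanned"] == 64

    def test_strand_invariance_of_site_count(self):
        rng = np.random.default_rng(8)
        cds_seq = "".join(rng.choice(list("ACGT"), 300))
        recs_p, cds_p = self._genome(cds_seq, "+")
        recs_m, cds_m = self._genome(cds_seq, "-")
        plus = call_fourfold_sites(recs_p, cds_p)
        minus = call_fourfold_sites(recs_m, cds_m)
        assert plus.n_sites == minus.n_sites

    def test_variant_at_first_position_can_break_degeneracy(self):
        # CTA is 4-fold (Leu) but an observed C->T at position one makes the
        # codon TTA under the alternate allele, whose third position is
        # 2-fold: the conservative rule discards the site
        recs, cds = self._genome("CTA")
        vt = variant_table("c1", [(30, "C", ["T"], [(0, 1), (0, 0)])])
        assert call_fourfold_sites(recs, cds, vt).n_sites == 0
        # whereas a synonymous-preserving first-position variant keeps it:
        # CGA (Arg) with C->A gives AGA (Arg, but AGN is not 4-fold) ->
        # also discarded; use GGA with G->C -> CGA: both 4-fold families
        recs2, cds2 = self._genome("GGA")
        vt2 = variant_table("c1", [(30, "G", ["C"], [(0, 1), (0, 0)])])
        assert call_fourfold_sites(recs2, cds2, vt2).n_sites == 1

    def test_codon_with_two_variant_positions_discarded(self):
        recs, cds = self._genome("GGA")
        vt = variant_table("c1", [
            (30, "G", ["C"], [(0, 1), (0, 0)]),
            (32, "A", ["T"], [(0, 1), (0, 0)]),
        ])
        out = call_fourfold_sites(recs, cds, vt)
        assert out.n_sites == 0
        assert out.provenance["rejected_multi_variant"] == 1

    def test_unobserved_alt_does_not_count_as_variant(self):
        # ALT present in the VCF but never called in any genotype
        recs, cds = self._genome("CTA")
        vt = variant_table("c1", [(30, "C", ["T"], [(0, 0), (0, 0)])])
        assert call_fourfold_sites(recs, cds, vt).n_sites == 1

    def test_codons_with_n_discarded(self):
        recs, cds = self._genome("GGN")
        out = call_fourfold_sites(recs, cds)
        assert out.n_sites == 0
        assert out.provenance["rejected_n"] == 1


def _site_set(chrom, positions):
    return FourfoldSiteSet(sites=pd.DataFrame({
        "chrom": chrom, "pos": positions, "gene": "g",
        "codon_index": range(len(positions)), "strand": "+"}))


class TestPiEstimators:
    def test_single_site_worked_example(self):
        # genotypes 0/0 and 0/1: alleles {0,0,0,1}, 3 of 6 pairs differ
        vt = variant_table("c1", [(10, "A", ["G"], [(0, 0), (0, 1)])])
        w = pi_windows(_site_set("c1", [10]), vt, sites_per_window=1)
        assert w["pi"].iloc[0] == pytest.approx(0.5)

    def test_window_dilution_by_invariant_sites(self):
        vt = variant_table("c1", [(0, "A", ["G"], [(0, 0), (0, 1)])])
        sites = _site_set("c1", list(range(500)))
        w = pi_windows(sites, vt, sites_per_window=500)
        assert w["pi"].iloc[0] == pytest.approx(0.5 / 500)
        assert w["n_sites"].iloc[0] == 500

    def test_monomorphic_window_is_exactly_zero(self):
        vt = variant_table("c1", [(5, "A", ["G"], [(0, 0), (0, 0)])])
        w = pi_windows(_site_set("c1", [5, 6, 7, 8]), vt, sites_per_window=4)
        assert w["pi"].iloc[0] == 0.0

    def test_low_call_sites_excluded_from_denominator(self):
        vt = variant_table("c1", [(0, "A", ["G"], [(0, 1), (-1, -1)]),
                                  (1, "A", ["G"], [(0, 1), (0, 1)])])
        w = pi_windows(_site_set("c1", [0, 1]), vt, sites_per_window=2,
                       min_called_fraction=0.75)
        # site 0 has 2/4 alleles called -> excluded; only site 1 remains
        assert w["n_included"].iloc[0] == 1
        assert w["pi"].iloc[0] == pytest.approx(
            1 - (1 + 1) / 6)  # alleles {0,1,0,1}: 4 of 6 pairs differ

    def test_trailing_window_kept_if_half_full(self):
        vt = variant_table("c1", [])
        w = pi_windows(_site_set("c1", list(range(130))), vt,
                       sites_per_window=100)
        assert len(w) == 1  # trailing 30 < 50 dropped
        w = pi_windows(_site_set("c1", list(range(160))), vt,
                       sites_per_window=100)
        assert len(w) == 2

    @pytest.mark.parametrize("ga,gb,expected", [
        ((0, 0), (1, 1), 1.0),    # all four cross pairs differ
        ((0, 1), (0, 1), 0.5),    # {00,01,10,11}
        ((1, 1), (1, 1), 0.0),
    ])
    def test_pairwise_mode_cross_pairs(self, ga, gb, expected):
        vt = variant_table("c1", [(3, "A", ["G"], [ga, gb])])
        w = pairwise_pi(_site_set("c1", [3]), vt, ("s0", "s1"),
                        sites_per_window=1)
        assert w["pi"].iloc[0] == pytest.approx(expected)

    def test_pairwise_mode_needs_exactly_two_samples(self):
        vt = variant_table("c1", [(3, "A", ["G"], [(0, 0), (0, 1)])])
        with pytest.raises(ValueError, match="two samples"):
            pairwise_pi(_site_set("c1", [3]), vt, ("s0", "s1", "s0"))


class TestSummaries:
    def _classes(self):
        return pd.DataFrame({
            "homolog": ["h1", "h2", "h3", "h4"],
            "chrom_class": ["NFC", "NFC", "NFC", "SFC"],
        })

    def test_nfc_normalization(self):
        windows = pd.DataFrame({
            "chrom": ["h1", "h2", "h3", "h4"],
            "window_index": 0, "n_sites": 500, "n_included": 500,
            "pi": [0.01, 0.02, 0.03, 0.01],
        })
        s = chromosome_diversity_summary(windows, self._classes())
        nfc_norm = s.loc[s["chrom_class"] == "NFC", "pi_norm"]
        assert nfc_norm.mean() == pytest.approx(1.0)
        assert s.set_index("homolog").loc["h4", "pi_norm"] == pytest.approx(0.5)

    def test_relative_change_ratio_definition(self):
        base = self._classes()
        extant = base.assign(mean_pi=1.0, n_windows=1,
                             pi_norm=[1.0, 1.0, 1.0, 0.8])
        ancestor = base.assign(mean_pi=1.0, n_windows=1,
                               pi_norm=[1.0, 1.0, 1.0, 1.0])
        out = relative_diversity_change(extant, ancestor)
        assert out.set_index("homolog").loc["h4", "delta_pi_rel"] == \
            pytest.approx(-0.2)

    def test_missing_homolog_gets_na_row(self):
        windows = pd.DataFrame({"chrom": ["h1"], "window_index": [0],
                                "n_sites": [500], "n_included": [500],
                                "pi": [0.01]})
        s = chromosome_diversity_summary(windows, self._classes())
        assert s.set_index("homolog").loc["h2", "n_windows"] == 0
        assert np.isnan(s.set_index("homolog").loc["h2", "mean_pi"])


class TestRecombinationModel:
    def test_fused_and_shrunk_cases(self):
        table = recombination_model(
            {"sfc": 5 * MB, "nfc": 10 * MB, "same": 7 * MB},
            {"sfc": 20 * MB, "nfc": 8 * MB, "same": 7 * MB})
        t = table.set_index("homolog")
        assert t.loc["sfc", "r_anc"] == pytest.approx(10.0)   # cM/Mb
        assert t.loc["sfc", "r_extant"] == pytest.approx(2.5)
        assert t.loc["sfc", "delta_r_rel"] == pytest.approx(0.75)
        # shrinkage without fusion increases the per-bp rate
        assert t.loc["nfc", "delta_r_rel"] == pytest.approx(-0.25)
        assert t.loc["same", "delta_r_rel"] == 0.0

    def test_observed_map_lengths_override_default(self):
        table = recombination_model({"h": 10 * MB}, {"h": 10 * MB},
                                    50.0, {"h": 55.0})
        assert table["r_extant"].iloc[0] == pytest.approx(5.5)

    def test_missing_homolog_is_na(self):
        table = recombination_model({"h": 10 * MB, "x": MB}, {"h": 10 * MB})
        assert np.isnan(table.set_index("homolog").loc["x", "delta_r_rel"])


class TestCorrelation:
    def test_perfectly_monotone_decreasing(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        res = diversity_recombination_correlation(x, y)
        assert res["rho"] == pytest.approx(-1.0)
        # exact two-sided permutation: only identity and reversal reach |1|
        assert res["method"] == "exact-permutation"
        assert res["p_value"] == pytest.approx(2 / 720)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        res = diversity_recombination_correlation(x, x + rng.normal(size=30))
        assert res["method"] == "normal-approximation"
        assert 0 <= res["p_value"] <= 1

    def test_minimum_pairs_enforced(self):
        with pytest.raises(ValueError, match=">= 5"):
            diversity_recombination_correlation([1, 2, 3], [1, 2, 3])
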