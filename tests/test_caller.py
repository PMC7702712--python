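import numpy as np
import pandas as pd
import pytest

from editscan.caller import (
    call_editing_sites,
    call_variants,
    compare_conditions,
    editing_levels,
    finalize_sites,
    sample_purity_filter,
    snp_editing_proportion,
    split_by_snp,
)
from editscan.core import CallerThresholds, GenomicInterval
from editscan.simulate import SimConfig, simulate_editing_reads, simulate_reference

COLS = ["sample", "chrom", "pos", "ref", "nA", "nC", "nG", "nT"]


def counts_df(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestCallVariants:
    def test_basic_call_and_level(self):
        df = counts_df([("s1", "chr1", 100, "A", 17, 0, 3, 0)])
        calls = call_variants(df)
        assert len(calls) == 1
        c = calls.iloc[0]
        assert (c["ref"], c["alt"]) == ("A", "G")
        assert c["level"] == pytest.approx(0.15)

    def test_below_min_alt_reads_not_called(self):
        df = counts_df([("s1", "chr1", 100, "A", 19, 0, 1, 0)])
        assert call_variants(df).empty

    def test_two_alt_bases_give_two_calls(self):
        df = counts_df([("s1", "chr1", 100, "A", 10, 0, 2, 2)])
        calls = call_variants(df)
        assert sorted(calls["alt"]) == ["G", "T"]

    def test_region_class_from_alu_intervals(self):
        df = counts_df([
            ("s1", "chr1", 100, "A", 10, 0, 3, 0),
            ("s1", "chr1", 500, "A", 10, 0, 3, 0),
        ])
        calls = call_variants(df, alu=[GenomicInterval("chr1", 90, 110)])
        assert list(calls["region_class"]) == ["Alu", "nonAlu"]

    def test_raising_min_alt_reads_shrinks_call_set(self):
        rng = np.random.default_rng(0)
        rows = [
            ("s1", "chr1", int(p), "A", int(rng.integers(0, 20)), 0,
             int(rng.integers(0, 6)), 0)
            for p in range(1, 200)
        ]
        df = counts_df(rows)
        previous = None
        for min_alt in (2, 3, 4, 5):
            calls = call_variants(df, CallerThresholds(min_alt_reads=min_alt))
            keys = set(zip(calls["pos"], calls["alt"]))
            if previous is not None:
                assert keys.issubset(previous)
            previous = keys


class TestPurity:
    def _calls(self, spec):
        """spec: list of (sample, ref, alt) tuples."""
        rows = []
        for i, (s, ref, alt) in enumerate(spec):
            rows.append({"sample": s, "chrom": "chr1", "pos": i + 1, "ref": ref,
                         "alt": alt, "ref_count": 10, "alt_count": 5,
                         "level": 1 / 3, "region_class": "Alu"})
        return pd.DataFrame(rows)

    def test_exactly_80_percent_is_retained(self):
        calls = self._calls([("s1", "A", "G")] * 8 + [("s1", "C", "T")] * 2)
        retained, frac = sample_purity_filter(calls)
        assert retained == ["s1"]
        assert frac["s1"] == pytest.approx(0.8)

    def test_pure_sample_retained_and_mixed_dropped(self):
        calls = self._calls(
            [("s1", "A", "G")] * 10
            + [("s2", "A", "G")] * 7 + [("s2", "G", "A")] * 3
        )
        retained, frac = sample_purity_filter(calls)
        assert retained == ["s1"]
        assert frac["s2"] == pytest.approx(0.7)

    def test_t_to_c_counts_as_editing_consistent(self):
        calls = self._calls([("s1", "T", "C")] * 9 + [("s1", "C", "A")])
        retained, _ = sample_purity_filter(calls)
        assert retained == ["s1"]

    def test_zero_variant_sample_absent(self):
        calls = self._calls([("s1", "A", "G")])
        retained, frac = sample_purity_filter(calls)
        assert "s2" not in frac.index


class TestSplitBySnp:
    def _call(self, sample="s1", pos=100, ref="A", alt="G"):
        return pd.DataFrame([
            {"sample": sample, "chrom": "chr1", "pos": pos, "ref": ref,
             "alt": alt, "ref_count": 10, "alt_count": 5, "level": 1 / 3,
             "region_class": "Alu"}
        ])

    def test_homozygous_reference_concordant_becomes_snp_candidate(self):
        dna = {("s1", "chr1", 100): {"wgs": "AA", "array": "AA"}}
        parts = split_by_snp(self._call(), [("chr1", 100)], dna)
        assert len(parts["snp"]) == 1
        assert parts["nonsnp"].empty

    def test_heterozygous_dna_excluded(self):
        dna = {("s1", "chr1", 100): {"wgs": "AG"}}
        parts = split_by_snp(self._call(), [("chr1", 100)], dna)
        assert parts["snp"].empty
        assert list(parts["excluded"]["reason"]) == ["het_or_nonref"]

    def test_conflicting_resources_excluded(self):
        dna = {("s1", "chr1", 100): {"wgs": "AA", "array": "AG"}}
        parts = split_by_snp(self._call(), [("chr1", 100)], dna)
        assert parts["snp"].empty
        assert list(parts["excluded"]["reason"]) == ["conflict"]

    def test_call_away_from_snp_is_nonsnp_candidate(self):
        parts = split_by_snp(self._call(pos=555), [("chr1", 100)], {})
        assert parts["snp"].empty
        assert len(parts["nonsnp"]) == 1


class TestFinalize:
    def _cand(self, pos, ref, alt, ref_count=10, alt_count=5, region="Alu",
              sample="s1"):
        return {"sample": sample, "chrom": "chr1", "pos": pos, "ref": ref,
                "alt": alt, "ref_count": ref_count, "alt_count": alt_count,
                "level": alt_count / (ref_count + alt_count),
                "region_class": region}

    def test_t_to_c_in_minus_gene_becomes_sense_a_to_g(self, minus_gene):
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(minus_gene.start + 50 + 1, "T", "C")])}
        sites = finalize_sites(cands, CallerThresholds(), [minus_gene])
        assert len(sites) == 1
        assert sites.iloc[0]["strand"] == "-"

    def test_mismatch_contradicting_gene_strand_dropped(self, minus_gene):
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(minus_gene.start + 50 + 1, "A", "G")])}
        assert finalize_sites(cands, CallerThresholds(), [minus_gene]).empty

    def test_low_allele_support_dropped(self, plus_gene):
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(plus_gene.start + 50 + 1, "A", "G", ref_count=2,
                       alt_count=5)])}
        assert finalize_sites(cands, CallerThresholds(), [plus_gene]).empty

    def test_nonalu_low_level_dropped(self, plus_gene):
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(plus_gene.start + 50 + 1, "A", "G", ref_count=95,
                       alt_count=5, region="nonAlu")])}
        assert finalize_sites(cands, CallerThresholds(), [plus_gene]).empty

    def test_site_in_no_gene_keeps_genomic_strand(self, plus_gene):
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(99999, "T", "C")])}
        sites = finalize_sites(cands, CallerThresholds(), [plus_gene])
        assert sites.iloc[0]["strand"] == "."

    def test_site_on_double_stranded_gene_overlap_dropped(self, plus_gene):
        from tests.conftest import make_gene

        anti = make_gene("ganti", strand="-", start=plus_gene.start)
        pos = plus_gene.start + 50 + 1
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(pos, "A", "G")])}
        assert finalize_sites(cands, CallerThresholds(),
                              [plus_gene, anti]).empty

    def test_nonalu_homopolymer_context_dropped(self, plus_gene):
        pos = plus_gene.start + 50 + 1
        seq = "C" * (pos - 1) + "A" + "G" * 6 + "C" * 200
        seq = {"chr1": seq}
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(pos, "A", "G", region="nonAlu")])}
        assert finalize_sites(cands, CallerThresholds(), [plus_gene], seq).empty

    def test_nonalu_near_splice_boundary_dropped(self, plus_gene):
        # first internal exon boundary of the fixture gene is at start + 300
        pos0 = plus_gene.exons[0].end + 2
        seq = {"chr1": "ACGT" * ((pos0 + 300) // 4 + 1)}
        cands = {"snp": pd.DataFrame(), "nonsnp": pd.DataFrame([
            self._cand(pos0 + 1, "A", "G", region="nonAlu")])}
        assert finalize_sites(cands, CallerThresholds(), [plus_gene], seq).empty


class TestEditingLevels:
    SITES = pd.DataFrame([
        {"chrom": "chr1", "pos": 100, "strand": "+", "class": "nonsnp_editing",
         "ref": "A", "alt": "G", "alu_flag": True, "n_samples": 3},
    ])

    def test_level_and_representative_from_tissue_means(self):
        counts = counts_df([
            ("s1", "chr1", 100, "A", 15, 0, 5, 0),   # 0.25, tissue t1
            ("s2", "chr1", 100, "A", 10, 0, 10, 0),  # 0.50, tissue t2
            ("s3", "chr1", 100, "A", 20, 0, 0, 0),   # 0.00, tissue t2
        ])
        tissues = {"s1": "t1", "s2": "t2", "s3": "t2"}
        out = editing_levels(self.SITES, counts, tissues)
        row = out.iloc[0]
        assert row["level_s1"] == pytest.approx(0.25)
        assert row["level_s3"] == pytest.approx(0.0)
        assert row["tissue_mean_t2"] == pytest.approx(0.25)
        assert row["representative_level"] == pytest.approx(0.25)

    def test_zero_coverage_sample_excluded_from_tissue_mean(self):
        counts = counts_df([
            ("s1", "chr1", 100, "A", 15, 0, 5, 0),
            ("s2", "chr1", 100, "A", 0, 9, 0, 0),  # no A/G coverage
        ])
        out = editing_levels(self.SITES, counts, {"s1": "t", "s2": "t"})
        row = out.iloc[0]
        assert np.isnan(row["level_s2"])
        assert row["tissue_mean_t"] == pytest.approx(0.25)


class TestCompareConditions:
    SITES = pd.DataFrame([
        {"chrom": "chr1", "pos": 100, "strand": "+", "class": "nonsnp_editing",
         "ref": "A", "alt": "G"},
        {"chrom": "chr1", "pos": 200, "strand": "+", "class": "snp_editing",
         "ref": "A", "alt": "G"},
    ])

    def test_low_depth_sample_excludes_site(self):
        ctrl = counts_df([("c1", "chr1", 100, "A", 5, 0, 3, 0)])  # depth 8
        oe = counts_df([("o1", "chr1", 100, "A", 10, 0, 10, 0)])
        out = compare_conditions(self.SITES.iloc[[0]], {"ctrl": ctrl, "oe": oe})
        assert out.empty

    def test_snp_site_with_dna_g_reads_excluded(self):
        ctrl = counts_df([("c1", "chr1", 200, "A", 10, 0, 2, 0)])
        oe = counts_df([("o1", "chr1", 200, "A", 10, 0, 5, 0)])
        dna = counts_df([("d1", "chr1", 200, "A", 5, 0, 1, 0)])
        out = compare_conditions(self.SITES.iloc[[1]], {"ctrl": ctrl, "oe": oe},
                                 dna_counts=dna)
        assert out.empty

    def test_fewer_than_two_conditions_raises(self):
        with pytest.raises(ValueError):
            compare_conditions(self.SITES, {"only": counts_df([])})

    def test_planted_overexpression_raises_median_delta(self):
        from editscan.simulate import simulate_condition_reads, simulate_panel

        cfg = SimConfig(seed=31, n_samples=6, n_editing_sites=60,
                        n_sites_neutral=50, frac_snp_editing=0.0,
                        editing_level_beta=(2.0, 4.0), coverage_mean=40.0)
        ref = simulate_reference(cfg)
        panel = simulate_panel(cfg, ref)
        groups = simulate_condition_reads(cfg, ref, panel,
                                          {"actrl": 1.0, "oe": 1.5})
        sites = pd.DataFrame({
            "chrom": ref.truth["chrom"], "pos": ref.truth["pos"],
            "strand": ref.truth["strand"], "class": "nonsnp_editing",
            "ref": np.where(ref.truth["strand"] == "+", "A", "T"),
            "alt": np.where(ref.truth["strand"] == "+", "G", "C"),
        })
        out = compare_conditions(sites, groups)
        assert len(out) > 20
        assert out["delta_oe"].median() > 0


def test_snp_editing_proportion():
    assert snp_editing_proportion(1, 3) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        snp_editing_proportion(0, 0)


class TestSyntheticRecovery:
    def test_pipeline_recovers_planted_sites(self, small_sim):
        ref = small_sim["reference"]
        panel = small_sim["panel"]
        sites, diag = call_editing_sites(
            small_sim["rna"], [r.key for r in panel.records],
            small_sim["dna_genotypes"], ref.genes, ref.sequences, ref.alu,
        )
        planted = set(zip(ref.truth["chrom"], ref.truth["pos"]))
        called = set(zip(sites["chrom"], sites["pos"]))
        assert called, "no sites called"
        assert called.issubset(planted)  # precision 1.0
        assert len(called & planted) / len(planted) >= 0.9

    def test_called_classes_match_truth(self, small_sim):
        ref = small_sim["reference"]
        panel = small_sim["panel"]
        sites, _ = call_editing_sites(
            small_sim["rna"], [r.key for r in panel.records],
            small_sim["dna_genotypes"], ref.genes, ref.sequences, ref.alu,
        )
        merged = sites.merge(ref.truth[["chrom", "pos", "kind"]],
                             on=["chrom", "pos"])
        assert (merged["class"] == merged["kind"]).all()

    def test_planted_heterozygous_dna_never_called_as_snp_editing(self, small_sim):
        """Force one DNA resource heterozygous at every SNP-editing site: the
        pipeline must call none of them (hard guarantee by construction)."""
        ref = small_sim["reference"]
        panel = small_sim["panel"]
        dna = {k: dict(v) for k, v in small_sim["dna_genotypes"].items()}
        ed_pos = set(ref.truth.loc[ref.truth["kind"] == "snp_editing", "pos"])
        for (s, c, p) in list(dna):
            if p in ed_pos:
                gt = dna[(s, c, p)]["wgs"]
                dna[(s, c, p)] = {"wgs": gt[0] + ("G" if gt[0] != "G" else "A")}
        sites, _ = call_editing_sites(
            small_sim["rna"], [r.key for r in panel.records], dna,
            ref.genes, ref.sequences, ref.alu,
        )
        assert (sites["class"] != "snp_editing").all()
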