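import numpy as np
import pandas as pd
import pytest

import somascope as s
from somascope.genotyper import ReadObs, SiteEvidence
from somascope.intervals import GenomeIntervals
from somascope.somatic import (apply_validation_filters, compare_callsets,
                               common_callable_territory,
                               detect_somatic_indels, detect_ssnv)


def _tumor_calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "genotype",
                                       "mpv_score", "callable"])


def _normal_calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "genotype", "callable"])


class TestDetectSsnv:
    def test_loh_dropped(self):
        """Tumor AA against normal AG carries no novel allele."""
        out = detect_ssnv(
            _tumor_calls([("chr1", 100, "A", "AA", 50.0, True)]),
            _normal_calls([("chr1", 100, "AG", True)]))
        assert len(out) == 0

    def test_novel_allele_kept(self):
        out = detect_ssnv(
            _tumor_calls([("chr1", 100, "A", "AG", 50.0, True)]),
            _normal_calls([("chr1", 100, "AA", True)]))
        assert len(out) == 1
        assert out.loc[0, "somatic_allele"] == "G"

    def test_uncallable_normal_excluded(self):
        out = detect_ssnv(
            _tumor_calls([("chr1", 100, "A", "AG", 50.0, True)]),
            _normal_calls([("chr1", 100, "AA", False)]))
        assert len(out) == 0

    def test_known_variant_position_removed(self):
        out = detect_ssnv(
            _tumor_calls([("chr1", 100, "A", "AG", 50.0, True)]),
            _normal_calls([("chr1", 100, "AA", True)]),
            known_variants={("chr1", 100)})
        assert len(out) == 0

    def test_indel_window_boundary_inclusive_at_ten(self):
        tumor = _tumor_calls([("chr1", 100, "A", "AG", 50.0, True),
                              ("chr1", 200, "A", "AG", 50.0, True)])
        normal = _normal_calls([("chr1", 100, "AA", True),
                                ("chr1", 200, "AA", True)])
        indels = pd.DataFrame({"chrom": ["chr1", "chr1"],
                               "pos": [110, 211], "allele": ["+A", "+A"],
                               "score": [50.0, 50.0]})
        out = detect_ssnv(tumor, normal, None, indels)
        # 100 is 10 bp from 110 (dropped); 200 is 11 bp from 211 (kept)
        assert list(out["pos"]) == [200]

    def test_unsorted_input_rejected(self):
        tumor = _tumor_calls([("chr1", 200, "A", "AG", 50.0, True),
                              ("chr1", 100, "A", "AG", 50.0, True)])
        with pytest.raises(ValueError, match="unsorted"):
            detect_ssnv(tumor, _normal_calls([("chr1", 100, "AA", True)]))

    def test_recall_precision_on_pure_simulation(self):
        """Planted somatics at 30x, purity 1: recall >= 0.95, precision >= 0.99."""
        from somascope.pipeline import PipelineConfig, scan_pair

        sim_cfg = s.SimulationConfig(genome_length=500_000, purity=1.0,
                                     somatic_rate=200, seed=21)
        ref = s.simulate_reference(sim_cfg)
        truth = s.simulate_truth(ref, sim_cfg)
        normal, tumor = s.simulate_pileups(ref, truth, sim_cfg)
        cfg = PipelineConfig(sim=sim_cfg)
        tc, nc, *_ = scan_pair(normal, tumor, cfg)
        known = set(zip(truth.germline["chrom"], truth.germline["pos"]))
        calls = detect_ssnv(tc, nc, known)
        called = set(zip(calls["chrom"], calls["pos"]))
        planted = set(zip(truth.somatic["chrom"], truth.somatic["pos"]))
        recall = len(called & planted) / len(planted)
        precision = len(called & planted) / len(called)
        assert recall >= 0.95
        assert precision >= 0.99


def _evidence(chrom, pos, ref, reads):
    return SiteEvidence(chrom, pos, ref, reads)


class TestValidationFilters:
    def _run(self, fixture_set):
        return apply_validation_filters(
            fixture_set.variants, fixture_set.normal_evidence,
            fixture_set.tumor_evidence, fixture_set.low_mapq_indels)

    def test_tissue_fixture_outcomes(self, validation_fixture):
        """29 of 30 discordant removed, 0 of 43 concordant removed."""
        out = self._run(validation_fixture.tissue)
        disc = out[~out["concordant"]]
        conc = out[out["concordant"]]
        assert int((~disc["pass_filters"]).sum()) == 29
        assert int((~conc["pass_filters"]).sum()) == 0
        retained = out[out["pass_filters"]]
        assert len(retained) == 44
        assert retained["concordant"].sum() / len(retained) == \
            pytest.approx(43 / 44)

    def test_cell_culture_fixture_outcomes(self, validation_fixture):
        """2 of 3 discordant removed, 0 of 75 concordant removed."""
        out = self._run(validation_fixture.cell_culture)
        disc = out[~out["concordant"]]
        conc = out[out["concordant"]]
        assert int((~disc["pass_filters"]).sum()) == 2
        assert int((~conc["pass_filters"]).sum()) == 0
        retained = out[out["pass_filters"]]
        assert retained["concordant"].sum() / len(retained) == \
            pytest.approx(75 / 76)

    def test_strand_bias_flag_on_one_sided_reads(self):
        variants = pd.DataFrame([("chr1", 50, "A", "AA", "T")],
                                columns=["chrom", "pos", "ref",
                                         "normal_genotype", "somatic_allele"])
        tumor = _evidence("chr1", 50, "A",
                          [ReadObs("T", 40, 37, "+")] * 5
                          + [ReadObs("A", 40, 37, "-")] * 10)
        normal = _evidence("chr1", 50, "A", [ReadObs("A", 40, 37, "+")] * 20)
        out = apply_validation_filters(variants, {("chr1", 50): normal},
                                       {("chr1", 50): tumor})
        assert out.loc[0, "filter_flags"] == "strand_bias"

    def test_single_alt_read_does_not_trigger_strand_bias(self):
        variants = pd.DataFrame([("chr1", 50, "A", "AA", "T")],
                                columns=["chrom", "pos", "ref",
                                         "normal_genotype", "somatic_allele"])
        tumor = _evidence("chr1", 50, "A",
                          [ReadObs("T", 40, 37, "+")]
                          + [ReadObs("A", 40, 37, "-")] * 10)
        normal = _evidence("chr1", 50, "A", [ReadObs("A", 40, 37, "+")] * 20)
        out = apply_validation_filters(variants, {("chr1", 50): normal},
                                       {("chr1", 50): tumor})
        assert out.loc[0, "pass_filters"]

    def test_normal_lookup_counts_low_mapq_reads(self):
        variants = pd.DataFrame([("chr1", 50, "A", "AA", "T")],
                                columns=["chrom", "pos", "ref",
                                         "normal_genotype", "somatic_allele"])
        tumor = _evidence("chr1", 50, "A",
                          [ReadObs("T", 40, 37, st) for st in "+-"]
                          + [ReadObs("A", 40, 37, "+")] * 10)
        normal = _evidence("chr1", 50, "A",
                           [ReadObs("A", 40, 37, "+")] * 20
                           + [ReadObs("T", 30, 1, "+")])
        out = apply_validation_filters(variants, {("chr1", 50): normal},
                                       {("chr1", 50): tumor})
        assert out.loc[0, "filter_flags"] == "normal_lookup"

    def test_missing_evidence_raises_with_site_name(self, validation_fixture):
        fs = validation_fixture.tissue
        with pytest.raises(KeyError, match="fixA"):
            apply_validation_filters(fs.variants, {}, fs.tumor_evidence)

    def test_cascade_idempotent(self, validation_fixture):
        fs = validation_fixture.tissue
        once = self._run(fs)
        twice = apply_validation_filters(
            once, fs.normal_evidence, fs.tumor_evidence, fs.low_mapq_indels)
        pd.testing.assert_frame_equal(once, twice)


class TestCallsetComparison:
    FULL = GenomeIntervals({"chr1": np.array([[0, 1_000]])})

    def test_identical_callsets_fully_shared(self):
        calls = [("chr1", 5), ("chr1", 10)]
        cmp = compare_callsets(calls, calls, self.FULL)
        assert cmp.fraction_shared == 1.0

    def test_toy_half_shared(self):
        a = [("chr1", 1), ("chr1", 2), ("chr1", 3)]
        b = [("chr1", 2), ("chr1", 3), ("chr1", 4)]
        cmp = compare_callsets(a, b, self.FULL)
        assert cmp.n_shared == 2 and cmp.n_union == 4
        assert cmp.fraction_shared == 0.5

    def test_symmetric_under_label_swap(self):
        a = [("chr1", 1), ("chr1", 2)]
        b = [("chr1", 2), ("chr1", 9)]
        assert compare_callsets(a, b, self.FULL).fraction_shared == \
            compare_callsets(b, a, self.FULL).fraction_shared

    def test_disjoint_masks_empty_result(self):
        m1 = GenomeIntervals({"chr1": np.array([[0, 10]])})
        m2 = GenomeIntervals({"chr1": np.array([[20, 30]])})
        common = common_callable_territory(m1, m2)
        cmp = compare_callsets([("chr1", 5)], [("chr1", 25)], common)
        assert cmp.n_union == 0 and cmp.fraction_shared == 0.0

    def test_cnv_mask_excludes_sites(self):
        a = [("chr1", 5), ("chr1", 500)]
        cnv = GenomeIntervals({"chr1": np.array([[400, 600]])})
        cmp = compare_callsets(a, a, self.FULL, cnv_mask=cnv)
        assert cmp.n_shared == 1


class TestSomaticIndels:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "allele", "score"])

    def test_toy_enumeration(self):
        """5 candidates, 2 matching the normal call -> 3 somatic."""
        tumor = self._table([("chr1", p, a, 30.0) for p, a in
                             [(10, "+A"), (20, "-1"), (30, "+CG"),
                              (40, "-2"), (50, "+T")]])
        normal = self._table([("chr1", 20, "-1", 40.0),
                              ("chr1", 40, "-2", 40.0)])
        out, hist = detect_somatic_indels(tumor, normal)
        assert list(out["pos"]) == [10, 30, 50]
        assert hist.to_dict() == {1: 2, 2: 1}

    def test_low_scoring_tumor_calls_dropped(self):
        tumor = self._table([("chr1", 10, "+A", 9.9)])
        out, _ = detect_somatic_indels(tumor, self._table([]))
        assert len(out) == 0

    def test_normal_call_below_threshold_ignored(self):
        tumor = self._table([("chr1", 10, "+A", 30.0)])
        normal = self._table([("chr1", 10, "+A", 5.0)])
        out, _ = detect_somatic_indels(tumor, normal)
        assert len(out) == 1

    def test_cnv_region_excluded(self):
        tumor = self._table([("chr1", 10, "+A", 30.0),
                             ("chr1", 500, "+A", 30.0)])
        mask = GenomeIntervals({"chr1": np.array([[0, 100]])})
        out, _ = detect_somatic_indels(tumor, self._table([]), mask)
        assert list(out["pos"]) == [10]
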