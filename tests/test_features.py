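import numpy as np
import pandas as pd
import pytest

import somascope as s
from somascope.features import (GeneModels, LANDMARK_ORDER,
                                chromatin_state_mask,
                                nongenic_constraint_bins,
                                partition_by_landmark, per_state_rate,
                                positions_by_chrom, regress_mutation_rate,
                                transcript_distance_profile)
from somascope.intervals import GenomeIntervals


def _gene(gene_id, chrom, start, end, strand, cds, utr5, utr3, exons):
    genes = [(gene_id, chrom, start, end, strand)]
    parts = [(gene_id, "exon", chrom, a, b) for a, b in exons]
    parts += [(gene_id, "CDS", chrom, a, b) for a, b in cds]
    parts += [(gene_id, "five_prime_UTR", chrom, a, b) for a, b in utr5]
    parts += [(gene_id, "three_prime_UTR", chrom, a, b) for a, b in utr3]
    return genes, parts


def _toy_models():
    g, p = _gene("g1", "chr1", 20_000, 30_000, "+",
                 cds=[(20_100, 20_500), (29_000, 29_500)],
                 utr5=[(20_000, 20_100)], utr3=[(29_500, 30_000)],
                 exons=[(20_000, 20_500), (29_000, 30_000)])
    return GeneModels(pd.DataFrame(g, columns=["gene_id", "chrom", "start",
                                               "end", "strand"]),
                      pd.DataFrame(p, columns=["gene_id", "feature", "chrom",
                                               "start", "end"]))


LENGTHS = {"chr1": 100_000}


class TestLandmarkPartition:
    def test_partition_tiles_genome_exactly(self):
        part = partition_by_landmark(_toy_models(), LENGTHS)
        part.check_partition()
        total = sum(part.territory(n) for n in LANDMARK_ORDER)
        assert total == 100_000

    def test_priority_coding_beats_intron(self):
        part = partition_by_landmark(_toy_models(), LENGTHS)
        assert part.categories["coding"].contains(
            "chr1", np.array([20_200]))[0]
        assert not part.categories["intron"].contains(
            "chr1", np.array([20_200]))[0]

    def test_tss_window_boundary(self):
        """Within 5,000 bp of the TSS is proximal; 5,001 bp is distal."""
        part = partition_by_landmark(_toy_models(), LENGTHS)
        # TSS at 20,000 (+ strand); upstream intergenic territory
        assert part.categories["tss_proximal"].contains(
            "chr1", np.array([15_000]))[0]
        assert part.categories["tss_distal"].contains(
            "chr1", np.array([14_999]))[0]

    def test_target_assignment_priority_first(self):
        models = _toy_models()
        target = GenomeIntervals.from_records([
            ("chr1", 20_400, 20_700),   # overlaps CDS and intron -> coding
            ("chr1", 25_000, 25_100),   # intron only
            ("chr1", 5_000, 5_100),     # far upstream -> distal
        ])
        df = partition_by_landmark(models, LENGTHS, target=target)
        assert list(df.sort_values("start")["category"]) == \
            ["tss_distal", "coding", "intron"]

    def test_base_totals_match_brute_force_oracle(self, rng):
        """Random gene fixtures against independent per-base labeling."""
        for trial in range(3):
            local = np.random.default_rng(100 + trial)
            genes_rows, parts_rows = [], []
            cursor = 2_000
            for i in range(10):
                start = cursor + int(local.integers(2_000, 6_000))
                end = start + int(local.integers(2_000, 5_000))
                cursor = end
                strand = "+-"[local.integers(2)]
                e1 = (start, start + 300)
                e2 = (end - 300, end)
                g, p = _gene(f"g{i}", "chr1", start, end, strand,
                             cds=[(start + 100, start + 300),
                                  (end - 300, end - 100)],
                             utr5=[(start, start + 100) if strand == "+"
                                   else (end - 100, end)],
                             utr3=[(end - 100, end) if strand == "+"
                                   else (start, start + 100)],
                             exons=[e1, e2])
                genes_rows += g
                parts_rows += p
            models = GeneModels(
                pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start",
                                                  "end", "strand"]),
                pd.DataFrame(parts_rows, columns=["gene_id", "feature",
                                                  "chrom", "start", "end"]))
            part = partition_by_landmark(models, LENGTHS)
            part.check_partition()

            # independent oracle: explicit per-base painting
            label = np.zeros(100_000, dtype=int)  # 0 -> tss_distal
            priorities = {"tss_proximal": 1, "intron": 2, "utr3": 3,
                          "utr5": 4, "coding": 5}
            for t in models.tss().itertuples(index=False):
                lo, hi = max(0, t.pos - 5_000), min(100_000, t.pos + 5_001)
                label[lo:hi] = np.maximum(label[lo:hi], 1)
            for g in models.genes.itertuples(index=False):
                label[g.start:g.end] = np.maximum(label[g.start:g.end], 2)
            feature_map = {"three_prime_UTR": 3, "five_prime_UTR": 4,
                           "CDS": 5}
            for p in models.parts.itertuples(index=False):
                if p.feature in feature_map:
                    label[p.start:p.end] = np.maximum(
                        label[p.start:p.end], feature_map[p.feature])
            names = {0: "tss_distal", 1: "tss_proximal", 2: "intron",
                     3: "utr3", 4: "utr5", 5: "coding"}
            for code, name in names.items():
                assert part.territory(name) == int((label == code).sum()), name


class TestChromatinStates:
    def test_repeat_states_dropped(self):
        seg = pd.DataFrame([("chr1", 0, 100, 14), ("chr1", 100, 200, 15)],
                           columns=["chrom", "start", "end", "state"])
        assert chromatin_state_mask(seg) == {}

    def test_retained_states_conserve_territory(self):
        seg = pd.DataFrame([("chr1", i * 100, (i + 1) * 100, i + 1)
                            for i in range(13)],
                           columns=["chrom", "start", "end", "state"])
        masks = chromatin_state_mask(seg)
        assert set(masks) == set(range(1, 14))
        assert sum(m.total_length for m in masks.values()) == 1_300

    def test_state_13_supports_background_rate(self):
        seg = pd.DataFrame([("chr1", 0, 1_000_000, 13)],
                           columns=["chrom", "start", "end", "state"])
        masks = chromatin_state_mask(seg)
        rates = per_state_rate({"chr1": np.arange(42) * 1_000}, masks)
        assert rates.loc[0, "rate_per_mb"] == pytest.approx(42.0)


class TestNongenicBins:
    def _one_gene(self):
        g, p = _gene("g1", "chr1", 0, 10_000, "+", cds=[(100, 9_900)],
                     utr5=[(0, 100)], utr3=[(9_900, 10_000)],
                     exons=[(0, 10_000)])
        return GeneModels(
            pd.DataFrame(g, columns=["gene_id", "chrom", "start", "end",
                                     "strand"]),
            pd.DataFrame(p, columns=["gene_id", "feature", "chrom", "start",
                                     "end"]))

    def test_mask_pad_boundary(self):
        """Territory closer than 10 kb to a gene contributes no tiles."""
        lengths = {"chr1": 170_000}
        constrained = GenomeIntervals({"chr1": np.array([[0, 170_000]])})
        tiles = nongenic_constraint_bins(self._one_gene(), constrained,
                                         lengths)
        assert (tiles["start"] >= 20_000).all()
        # allowed region [20_000, 170_000) fits exactly 3 x 50 kb tiles
        assert len(tiles) == 3

    def test_zero_overlap_tiles_discarded(self):
        lengths = {"chr1": 170_000}
        constrained = GenomeIntervals({"chr1": np.array([[20_000, 70_000]])})
        tiles = nongenic_constraint_bins(self._one_gene(), constrained,
                                         lengths)
        assert len(tiles) == 1

    @pytest.mark.parametrize("n_tiles,last_bin", [(100, 10), (103, 13)])
    def test_decile_remainder_to_last_bin(self, n_tiles, last_bin, rng):
        # synthetic tile table routed through the binning logic directly
        lengths = {"chr1": (n_tiles + 1) * 50_000 + 20_000}
        empty_genes = GeneModels(
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                  "strand"]),
            pd.DataFrame(columns=["gene_id", "feature", "chrom", "start",
                                  "end"]))
        recs = [("chr1", i * 50_000, i * 50_000 + (i + 1) * 10)
                for i in range(n_tiles)]
        constrained = GenomeIntervals.from_records(recs)
        tiles = nongenic_constraint_bins(empty_genes, constrained, lengths)
        assert len(tiles) == n_tiles
        counts = tiles["bin"].value_counts()
        assert counts[9] == last_bin
        assert (counts[range(9)] == n_tiles // 10).all()


class TestRegression:
    def test_constant_response_zero_slopes(self, rng):
        table = pd.DataFrame({"rate": 5.0,
                              "constraint": rng.uniform(0, 1, 10),
                              "gc": rng.uniform(0.3, 0.5, 10),
                              "transcribed": rng.uniform(0, 0.4, 10)})
        out = regress_mutation_rate(table)
        coefs = out["coefficients"].drop(index="const")["coef"]
        np.testing.assert_allclose(coefs, 0.0, atol=1e-10)

    def test_planted_slope_recovered(self, rng):
        n = 50
        tx = rng.uniform(0, 1, n)
        rate = 40.0 - 12.0 * tx + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"rate": rate, "constraint": rng.uniform(0, 1, n),
                              "gc": rng.uniform(0.3, 0.5, n),
                              "transcribed": tx})
        out = regress_mutation_rate(table)
        row = out["coefficients"].loc["transcribed"]
        assert row["coef"] == pytest.approx(-12.0, abs=3 * row["stderr"])

    def test_perfect_anticorrelation_spearman(self):
        tx = np.linspace(0, 1, 12)
        table = pd.DataFrame({"rate": -tx, "constraint": 0.5, "gc": 0.4,
                              "transcribed": tx})
        rho, _ = regress_mutation_rate(table)["spearman_transcribed"]
        assert rho == pytest.approx(-1.0)


class TestTranscriptProfile:
    def test_variant_at_tss_plus_one_in_bin_zero(self):
        profile = transcript_distance_profile({"chr1": np.array([20_001])},
                                              _toy_models())
        assert profile.loc[0, "n_variants"] == 1
        assert profile.loc[0, "distance_bin_start"] == 0

    def test_minus_strand_distance_runs_leftward(self):
        g, p = _gene("g1", "chr1", 20_000, 30_000, "-", cds=[], utr5=[],
                     utr3=[], exons=[(20_000, 30_000)])
        models = GeneModels(
            pd.DataFrame(g, columns=["gene_id", "chrom", "start", "end",
                                     "strand"]),
            pd.DataFrame(p, columns=["gene_id", "feature", "chrom", "start",
                                     "end"]))
        profile = transcript_distance_profile({"chr1": np.array([29_500])},
                                              models)
        # 29,500 is 499 bp from the minus-strand TSS at 29,999 -> bin 0
        assert profile.loc[0, "n_variants"] == 1

    def test_uniform_variants_give_flat_profile(self, rng):
        g, p = _gene("g1", "chr1", 0, 50_000, "+", cds=[], utr5=[], utr3=[],
                     exons=[(0, 50_000)])
        models = GeneModels(
            pd.DataFrame(g, columns=["gene_id", "chrom", "start", "end",
                                     "strand"]),
            pd.DataFrame(p, columns=["gene_id", "feature", "chrom", "start",
                                     "end"]))
        pos = np.sort(rng.integers(0, 50_000, size=2_000))
        profile = transcript_distance_profile({"chr1": pos}, models)
        lam = 2_000 / 10
        # Poisson oracle: each of 10 bins within 4 sigma of its mean
        assert (np.abs(profile["n_variants"] - lam)
                < 4 * np.sqrt(lam)).all()


class TestPerStateRate:
    def test_counts_over_territory_oracle(self, rng):
        masks = {1: GenomeIntervals({"chr1": np.array([[0, 300_000]])}),
                 2: GenomeIntervals({"chr1": np.array([[300_000, 400_000]])})}
        pos = np.sort(rng.integers(0, 400_000, size=500))
        rates = per_state_rate({"chr1": pos}, masks)
        n1 = int((pos < 300_000).sum())
        assert rates.loc[0, "n_variants"] == n1
        assert rates.loc[0, "rate_per_mb"] == pytest.approx(n1 / 0.3)
        assert rates.loc[1, "rate_per_mb"] == pytest.approx(
            (500 - n1) / 0.1, rel=1e-9)

    def test_empty_state_reports_territory(self):
        masks = {7: GenomeIntervals({"chr1": np.array([[0, 10_000]])})}
        rates = per_state_rate({}, masks)
        assert rates.loc[0, "n_variants"] == 0
        assert rates.loc[0, "territory_bp"] == 10_000
        assert rates.loc[0, "rate_per_mb"] == 0.0


class TestGeneModelsIO:
    def test_gff3_round_trip(self, tmp_path):
        models = _toy_models()
        path = tmp_path / "genes.gff3"
        models.to_gff3(path)
        back = GeneModels.from_gff3(path)
        pd.testing.assert_frame_equal(
            back.genes[["gene_id", "chrom", "start", "end", "strand"]],
            models.genes)
        assert len(back.parts) == len(models.parts)
        for feature in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            assert back.feature_intervals(feature) == \
                models.feature_intervals(feature)
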