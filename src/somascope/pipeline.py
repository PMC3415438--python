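"""End-to-end driver: simulate, genotype, call, and summarize.

``run_pipeline`` chains every stage on a synthetic tumor/normal pair:
reference and truth simulation, genome-wide MPG/MPV scoring of both
samples, somatic SSNV subtraction and the three-filter cascade, CNV
tiling and segmentation, purity estimation from somatic allele
fractions, somatic indels, mutational spectra with transcribed-strand
bias, landmark/chromatin-state summaries, rotation-null enrichment
profiles with a common-variant control, and the DHS cell-type analysis.
Every output is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import dhs as dhs_mod
from . import features as feat_mod
from .enrichment import Territory, enrichment_profile
from . import io as io_mod
from . import purity as purity_mod
from . import sim as sim_mod
from . import somatic as som_mod
from . import spectrum as spec_mod
from .genotyper import GENOTYPE_STRINGS, HOM_INDEX, score_pileup
from .intervals import GenomeIntervals


#: Pipeline stages in execution order; simulation and genotyping always run.
STAGES = ("somatic", "cnv", "purity", "indels", "spectrum", "features",
          "enrichment", "dhs")


class StageDependencyError(RuntimeError):
    """A disabled stage is required by an enabled downstream stage."""


@dataclass
class PipelineConfig:
    """All thresholds, at the pipeline's standard defaults."""

    sim: sim_mod.SimulationConfig = field(
        default_factory=sim_mod.SimulationConfig)
    stages: Tuple[str, ...] = STAGES
    min_mapq: int = 30
    min_baseq: int = 20
    min_mpg: float = 10.0
    ratio: float = 0.5
    min_mpv: float = 10.0
    indel_window: int = 10
    cnv_gate: float = 0.1
    tile_size: int = 5_000
    mappability_threshold: float = 0.8
    amp_threshold: float = 0.25
    del_threshold: float = -0.25
    n_samplings: int = 10_000
    min_overlap: int = 10
    tss_window: int = 5_000
    nongenic_mask: int = 10_000
    tile50k: int = 50_000
    rna_mapq: int = 30
    purity_min_sites: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "base_q_model" in sim_raw:
            sim_raw["base_q_model"] = tuple(
                (int(q), float(p)) for q, p in sim_raw["base_q_model"])
        return cls(sim=sim_mod.SimulationConfig(**sim_raw), **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def bundled_config(seed: int = 1) -> PipelineConfig:
    """The standard 10 Mb demonstration run: ten 1 Mb chromosomes at the
    default study conditions (42 SSNVs/Mb, purity 0.58, ~30x)."""
    return PipelineConfig(
        sim=sim_mod.SimulationConfig(genome_length=1_000_000, n_chroms=10,
                                     seed=seed))


def mask_from_bool(flags: Dict[str, np.ndarray]) -> GenomeIntervals:
    """Per-chromosome boolean arrays -> interval set of True runs."""
    recs = {}
    for chrom, arr in flags.items():
        arr = np.asarray(arr, dtype=bool)
        if not arr.any():
            continue
        padded = np.concatenate([[False], arr, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        recs[chrom] = edges.reshape(-1, 2)
    return GenomeIntervals(recs)


def scan_pair(normal, tumor, config: PipelineConfig):
    """Genome-wide scoring of a tumor/normal pair.

    Returns (tumor candidate calls, normal calls at those sites,
    normal callable mask, tumor callable mask, depth arrays).
    """
    t_rows, n_rows = [], []
    n_mask_flags, t_mask_flags = {}, {}
    n_depth, t_depth = {}, {}
    for chrom in sorted(tumor.chroms):
        ref_codes = tumor.ref[chrom]
        results = {}
        for name, pileup in (("tumor", tumor), ("normal", normal)):
            counts = pileup.retained_counts(chrom, config.min_mapq)
            results[name] = score_pileup(counts, ref_codes,
                                         pileup.qual_values, config.min_baseq)
        t_res, n_res = results["tumor"], results["normal"]

        def mpg_callable(res):
            return (res["called"] & (res["mpg_score"] >= config.min_mpg)
                    & (res["coverage_ratio"] >= config.ratio))

        n_mask_flags[chrom] = mpg_callable(n_res)
        t_mask_flags[chrom] = mpg_callable(t_res)
        n_depth[chrom] = normal.retained_depth(
            chrom, config.min_mapq, config.min_baseq).astype(np.int32)
        t_depth[chrom] = tumor.retained_depth(
            chrom, config.min_mapq, config.min_baseq).astype(np.int32)

        cand = np.flatnonzero(t_res["called"]
                              & (t_res["mpv_score"] >= config.min_mpv))
        from .genotyper import BASES
        for i in cand:
            t_rows.append((chrom, int(i), BASES[ref_codes[i]],
                           GENOTYPE_STRINGS[t_res["variant_genotype_index"][i]],
                           float(t_res["mpv_score"][i]), True))
            n_rows.append((chrom, int(i),
                           GENOTYPE_STRINGS[n_res["genotype_index"][i]],
                           bool(n_mask_flags[chrom][i])))
    tumor_calls = pd.DataFrame(
        t_rows, columns=["chrom", "pos", "ref", "genotype", "mpv_score",
                         "callable"])
    normal_calls = pd.DataFrame(
        n_rows, columns=["chrom", "pos", "genotype", "callable"])
    return (tumor_calls, normal_calls, mask_from_bool(n_mask_flags),
            mask_from_bool(t_mask_flags), n_depth, t_depth)


def _gc_fraction(ref_codes: np.ndarray, start: int, end: int) -> float:
    sub = ref_codes[start:end]
    return float(((sub == 1) | (sub == 2)).mean()) if len(sub) else 0.0


def run_pipeline(config: PipelineConfig, outdir) -> Dict[str, object]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: List[str] = []
    enabled = set(config.stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    def note(msg: str) -> None:
        log.append(msg)

    def require(stage: str, needed_by: str) -> None:
        if stage not in enabled:
            raise StageDependencyError(
                f"stage '{needed_by}' requires disabled stage '{stage}'")

    # -- simulation ----------------------------------------------------
    ref = sim_mod.simulate_reference(config.sim)
    truth = sim_mod.simulate_truth(ref, config.sim)
    normal, tumor = sim_mod.simulate_pileups(ref, truth, config.sim)
    annotations = sim_mod.simulate_annotations(ref, config.sim)
    indel_calls = sim_mod.simulate_indel_calls(truth, config.sim)
    chrom_lengths = config.sim.chrom_lengths
    note(f"simulated genome: {len(chrom_lengths)} chromosomes x "
         f"{config.sim.genome_length} bp, seed {config.sim.seed}")
    note(f"truth: {len(truth.germline)} germline, {len(truth.somatic)} "
         f"somatic SSNVs, {len(truth.somatic_indels)} somatic indels")

    # -- genotyping and somatic SSNVs ----------------------------------
    (tumor_calls, normal_calls, normal_mask, tumor_mask,
     n_depth, t_depth) = scan_pair(normal, tumor, config)
    common_mask = som_mod.common_callable_territory(normal_mask, tumor_mask)
    note(f"callable: normal {normal_mask.total_length} bp, tumor "
         f"{tumor_mask.total_length} bp, common {common_mask.total_length} bp")

    results: Dict[str, object] = {
        "truth": truth, "common_mask": common_mask, "log": log,
        "somatic": None, "somatic_pass": None, "tiles": None,
        "segments": None, "non_cnv": None, "contamination": None,
        "fraction_distribution": None, "spectrum": None, "strand_bias": None,
        "state_rates": None, "enrichment_states": None,
        "enrichment_landmarks": None, "regression_table": None,
        "clusters": None, "tree": None, "combination": None,
        "somatic_indels": None,
    }

    def finish() -> Dict[str, object]:
        with open(outdir / "log.txt", "w") as fh:
            fh.write("\n".join(log) + "\n")
        return results

    if "somatic" not in enabled:
        note("somatic stage disabled; downstream stages skipped")
        for stage in ("purity", "spectrum", "features", "enrichment", "dhs"):
            if stage in enabled:
                require("somatic", stage)
        return finish()

    known = set(zip(truth.germline["chrom"], truth.germline["pos"]))
    tumor_indel_df = indel_calls["tumor"][indel_calls["tumor"]["score"]
                                          >= config.min_mpv]
    candidates = som_mod.detect_ssnv(tumor_calls, normal_calls, known,
                                     tumor_indel_df, config.indel_window)
    note(f"somatic candidates after subtraction: {len(candidates)} "
         f"(from {len(tumor_calls)} tumor non-reference calls)")

    n_ev = {(r.chrom, r.pos): normal.site_evidence(r.chrom, r.pos)
            for r in candidates.itertuples(index=False)}
    t_ev = {(r.chrom, r.pos): tumor.site_evidence(r.chrom, r.pos)
            for r in candidates.itertuples(index=False)}
    low_indels = [(r.chrom, int(r.pos)) for r in
                  indel_calls["tumor_lowmapq"].itertuples(index=False)
                  if r.score >= config.min_mpv]
    filtered = som_mod.apply_validation_filters(
        candidates, n_ev, t_ev, low_indels, config.indel_window)
    somatic_pass = filtered[filtered["pass_filters"]].reset_index(drop=True)
    for f in som_mod.FILTER_NAMES:
        n_flagged = sum(f in flags for flags in filtered["filter_flags"])
        note(f"filter {f}: flagged {n_flagged} calls")
    note(f"somatic SSNVs passing filters: {len(somatic_pass)}")
    io_mod.write_vcf(filtered, chrom_lengths, outdir / "somatic.vcf")

    results["somatic"] = filtered
    results["somatic_pass"] = somatic_pass

    # -- CNV -----------------------------------------------------------
    tiles = non_cnv = None
    if "cnv" in enabled:
        tiles = cnv_mod.tile_depths(n_depth, t_depth, annotations.mappability,
                                    config.tile_size,
                                    config.mappability_threshold)
        non_cnv = cnv_mod.non_cnv_mask(tiles, gate=config.cnv_gate)
        note(f"CNV tiles: {len(tiles)}, non-CNV territory "
             f"{non_cnv.total_length} bp")
        results["tiles"] = tiles
        results["non_cnv"] = non_cnv
        io_mod.write_bed(non_cnv, outdir / "non_cnv_mask.bed")

    # -- purity --------------------------------------------------------
    est_purity = config.sim.purity
    if "purity" in enabled:
        require("cnv", "purity")
        frac_dist = purity_mod.somatic_allele_fractions(
            somatic_pass, tumor, non_cnv, min_mapq=config.min_mapq)
        try:
            contamination = purity_mod.estimate_contamination(
                frac_dist, min_sites=config.purity_min_sites)
            est_purity = 1.0 - contamination / 100.0
            note(f"purity: mode {frac_dist.mode():.2f}, estimated "
                 f"{contamination:.1f}% normal cells "
                 f"({frac_dist.n_sites} sites)")
        except purity_mod.InsufficientSitesError as exc:
            contamination = float("nan")
            note(f"purity: insufficient sites ({exc}); copy numbers use the "
                 f"configured purity")
        frac_dist.to_frame().to_csv(outdir / "purity_histogram.tsv",
                                    sep="\t", index=False)
        with open(outdir / "purity.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_sites\t{frac_dist.n_sites}\n")
            mode = frac_dist.mode() if frac_dist.n_sites else "NA"
            fh.write(f"observed_mode\t{mode}\n")
            fh.write(f"percent_normal_cells\t{contamination}\n")
        results["contamination"] = contamination
        results["fraction_distribution"] = frac_dist

    if "cnv" in enabled:
        segments = cnv_mod.call_cnv_segments(
            tiles, config.amp_threshold, config.del_threshold,
            purity=est_purity)
        seg_df = cnv_mod.segments_to_frame(segments)
        note(f"CNV segments: {len(seg_df)}")
        io_mod.write_bed(
            GenomeIntervals.from_frame(seg_df) if len(seg_df)
            else GenomeIntervals(),
            outdir / "cnv_segments.bed",
            names=[f"{'amp' if d == 'amplification' else 'del'}:"
                   f"{c:.2f}" for d, c in zip(seg_df["direction"],
                                              seg_df["purity_adjusted_cn"])]
            if len(seg_df) else None)
        results["segments"] = seg_df

    # -- somatic indels ------------------------------------------------
    if "indels" in enabled:
        require("cnv", "indels")
        som_indels, indel_hist = som_mod.detect_somatic_indels(
            indel_calls["tumor"], indel_calls["normal"], non_cnv,
            config.min_mpv)
        note(f"somatic indels in non-CNV territory: {len(som_indels)}")
        som_indels.to_csv(outdir / "somatic_indels.tsv", sep="\t",
                          index=False)
        results["somatic_indels"] = som_indels

    # -- spectrum ------------------------------------------------------
    if "spectrum" in enabled:
        spec = spec_mod.collapse_spectrum(somatic_pass)
        spec.to_frame().to_csv(outdir / "spectrum.tsv", sep="\t",
                               index=False)
        note("spectrum class fractions: " + ", ".join(
            f"{c}={f:.2f}" for c, f in spec.class_fractions().items()))
        oriented = spec_mod.orient_by_transcript(somatic_pass,
                                                 annotations.genes)
        bias = spec_mod.strand_bias_test(oriented)
        bias.to_csv(outdir / "strand_bias.tsv", sep="\t", index=False)
        results["spectrum"] = spec
        results["strand_bias"] = bias

    # -- landmark / chromatin features ---------------------------------
    positions = feat_mod.positions_by_chrom(somatic_pass)
    partition = states = None
    if "features" in enabled:
        partition = feat_mod.partition_by_landmark(
            annotations.genes, chrom_lengths, tss_window=config.tss_window)
        partition.check_partition()
        states = feat_mod.chromatin_state_mask(annotations.chromatin)
        state_rates = feat_mod.per_state_rate(positions, states)
        state_rates.to_csv(outdir / "state_rates.tsv", sep="\t", index=False)
        profile = feat_mod.transcript_distance_profile(positions,
                                                       annotations.genes)
        profile.to_csv(outdir / "transcript_profile.tsv", sep="\t",
                       index=False)
        results["state_rates"] = state_rates

    # -- enrichment ----------------------------------------------------
    territory = None
    positions_in = {c: p[common_mask.contains(c, p)]
                    for c, p in positions.items()}
    if "enrichment" in enabled:
        require("features", "enrichment")
        territory = Territory(common_mask)
        control = {c: sub["pos"].to_numpy(np.int64) for c, sub in
                   truth.germline.groupby("chrom")}
        control = {c: p[common_mask.contains(c, p)]
                   for c, p in control.items()}
        variant_sets = {"somatic": positions_in, "common_control": control}
        state_features = {f"state_{s}": iv for s, iv in states.items()}
        prof_states = enrichment_profile(
            variant_sets, state_features, territory,
            n_samplings=config.n_samplings, seed=config.sim.seed,
            min_overlap=config.min_overlap)
        prof_states.to_csv(outdir / "enrichment_states.tsv", sep="\t",
                           index=False)
        prof_marks = enrichment_profile(
            variant_sets, partition.categories, territory,
            n_samplings=config.n_samplings, seed=config.sim.seed + 1,
            min_overlap=config.min_overlap)
        prof_marks.to_csv(outdir / "enrichment_landmarks.tsv", sep="\t",
                          index=False)
        note(f"enrichment: {len(prof_states)} state rows, {len(prof_marks)} "
             f"landmark rows at {config.n_samplings} samplings")
        results["enrichment_states"] = prof_states
        results["enrichment_landmarks"] = prof_marks

        # non-genic constraint bins and regression
        tiles50 = feat_mod.nongenic_constraint_bins(
            annotations.genes, annotations.constrained, chrom_lengths,
            config.nongenic_mask, config.tile50k)
        if len(tiles50) >= 10:
            rna_hi = annotations.rna[annotations.rna["mapq"]
                                     >= config.rna_mapq]
            rna_iv = GenomeIntervals.from_frame(rna_hi) if len(rna_hi) \
                else GenomeIntervals()
            rows = []
            for b, sub in tiles50.groupby("bin"):
                terr = (sub["end"] - sub["start"]).sum()
                count = gc_sum = tx_sum = 0
                for r in sub.itertuples(index=False):
                    pos = positions.get(r.chrom, np.empty(0, np.int64))
                    count += int(((pos >= r.start) & (pos < r.end)).sum())
                    gc_sum += _gc_fraction(ref[r.chrom], r.start, r.end)
                    tx_sum += rna_iv.overlap_length(r.chrom, r.start, r.end) \
                        / (r.end - r.start)
                rows.append((b, len(sub), 1e6 * count / terr,
                             sub["constrained_fraction"].mean(),
                             gc_sum / len(sub), tx_sum / len(sub)))
            reg_table = pd.DataFrame(rows, columns=["bin", "n_tiles", "rate",
                                                    "constraint", "gc",
                                                    "transcribed"])
            reg_table.to_csv(outdir / "constraint_bins.tsv", sep="\t",
                             index=False)
            reg = feat_mod.regress_mutation_rate(reg_table)
            reg["coefficients"].to_csv(outdir / "regression.tsv", sep="\t")
            rho, rho_p = reg["spearman_transcribed"]
            note(f"regression R2 {reg['r_squared']:.3f}; Spearman(rate, "
                 f"transcribed) rho={rho:.3f} p={rho_p:.3g}")
            results["regression_table"] = reg_table
        else:
            note("non-genic tiling: too few constrained tiles for regression")

    # -- DHS analysis --------------------------------------------------
    if "dhs" in enabled:
        require("features", "dhs")
        require("enrichment", "dhs")
        clusters = dhs_mod.cluster_dhs(annotations.dhs)
        assigned = feat_mod.partition_by_landmark(
            annotations.genes, chrom_lengths,
            target=GenomeIntervals.from_frame(clusters),
            tss_window=config.tss_window)
        key = ["chrom", "start", "end"]
        clusters = clusters.merge(assigned, on=key, how="left")
        clusters["transcribed"] = dhs_mod.transcribed_dhs(
            clusters, annotations.rna, config.rna_mapq)
        clusters_out = clusters.copy()
        clusters_out["members"] = [",".join(m)
                                   for m in clusters_out["members"]]
        clusters_out.to_csv(outdir / "dhs_clusters.tsv", sep="\t",
                            index=False)
        note(f"DHS clusters: {len(clusters)} "
             f"({(clusters['specificity'] == 'ubiquitous').sum()} ubiquitous, "
             f"{(clusters['specificity'] == 'cell_type_specific').sum()} "
             f"specific)")

        cell_types = sorted(annotations.dhs)
        outgroup = [c for c in cell_types if c.startswith("Gm")]
        tree = dhs_mod.build_tree(clusters, cell_types,
                                  outgroup=outgroup or None)
        with open(outdir / "dhs_tree.nwk", "w") as fh:
            fh.write(tree.newick + "\n")

        distal = clusters[clusters["category"] == "tss_distal"]
        combo = dhs_mod.combination_enrichment(
            distal, config.sim.dhs_focal_cell_type, positions_in, territory,
            n_samplings=min(config.n_samplings, 1_000),
            seed=config.sim.seed + 2, min_overlap=config.min_overlap)
        combo.to_csv(outdir / "dhs_combination.tsv", sep="\t", index=False)
        results["clusters"] = clusters
        results["tree"] = tree
        results["combination"] = combo

        focal = config.sim.dhs_focal_cell_type
        spec_focal = distal[[m == (focal,) for m in distal["members"]]]
        spec_other = distal[[(len(m) == 1 and m != (focal,))
                             for m in distal["members"]]]
        if len(spec_focal) and len(spec_other):
            table, odds, p = dhs_mod.compare_transcription(
                spec_focal["transcribed"], spec_other["transcribed"])
            pd.DataFrame({
                "set": [focal, "other_specific"],
                "transcribed": table[:, 0], "untranscribed": table[:, 1],
                "odds_ratio": [odds, odds], "p_value": [p, p],
            }).to_csv(outdir / "dhs_transcription.tsv", sep="\t",
                      index=False)
            note(f"DHS transcription Fisher test: odds {odds:.2f}, "
                 f"p {p:.3g}")
        else:
            note("DHS transcription comparison skipped: empty specific set")

    return finish()
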