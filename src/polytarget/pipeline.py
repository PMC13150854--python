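"""End-to-end orchestration: files in, classified targets and reports out.

The run config is a flat dict (usually loaded from YAML) with two blocks:

``inputs``: gff3, layout, homoeolog_map, rep1, rep2, deg_table and
optionally bin_map, proteomics.

``params`` (all optional, defaults shown by ``default_params``): peak
filtering (min_fold, max_q), validation levels (d_vl2, d_vl3, idr_max,
idr_score), promoter window (promoter_up, promoter_down), DEG selection
(min_abs_log2fc, max_fdr, require_both_lines, stage_rule), enrichment
(bin_level, top_bins) and alpha for the bias tests.

Every output count lands in a JSON manifest so any reported percentage can
be recomputed from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    assign_target_genes,
    classify_features,
    feature_distribution,
    tss_profile,
)
from .bias import pooled_subgenome_test, results_table, group_bias_tests
from .enrichment import enrich, read_bin_map, top_bins
from .errors import ConfigError, DataError
from .genome import read_gff3, read_homoeolog_map, read_layout
from .idr import estimate_idr_for_pairs
from .integrate import (
    attach_homoeolog_groups,
    classify_direct_indirect,
    collapse_to_homoeologs,
    read_deg_table,
    select_consistent_degs,
    summarize_classification,
)
from .peaks import (
    LEVELS,
    assign_validation_levels,
    filter_peaks,
    overlap_replicates,
    peaks_at_level,
    read_narrowpeak,
    write_peaks_bed,
)
from .proximity import filter_exclusive_candidates, read_evidence

__all__ = ["default_params", "run_pipeline", "load_config"]

REQUIRED_INPUTS = ("gff3", "layout", "homoeolog_map", "rep1", "rep2", "deg_table")


def default_params():
    return {
        "min_fold": 2.0,
        "max_q": 1e-3,
        "d_vl2": 200,
        "d_vl3": 100,
        "idr_max": 0.05,
        "idr_score": "fold_enrichment",
        "promoter_up": 2000,
        "promoter_down": 100,
        "min_abs_log2fc": 1.0,
        "max_fdr": 0.05,
        "require_both_lines": True,
        "stage_rule": "any_stage",
        "bin_level": 2,
        "top_bins": 10,
        "alpha": 0.05,
    }


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "inputs" not in cfg:
        raise ConfigError(f"{path}: config needs an 'inputs' block")
    return cfg


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _preflight(inputs):
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise ConfigError(f"config inputs missing keys: {missing}")
    absent = [p for p in inputs.values() if not os.path.exists(p)]
    if absent:
        raise ConfigError(f"input files not found: {absent}")


def run_pipeline(config, outdir):
    """Run every stage and write BEDs, TSVs, the JSON summary and manifest.

    Fails before any stage runs if an input is missing; on a stage error the
    manifest (written on the way out) records partial progress.
    """
    inputs = dict(config.get("inputs", {}))
    params = {**default_params(), **(config.get("params") or {})}
    _preflight(inputs)
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {"inputs": inputs, "params": params},
        "checksums": {k: _sha256(v) for k, v in inputs.items()},
        "counts": {},
        "stages_completed": [],
    }
    counts = manifest["counts"]

    def _done(stage):
        manifest["stages_completed"].append(stage)

    try:
        layout = read_layout(inputs["layout"])
        genes = read_gff3(inputs["gff3"], layout)
        hmap = read_homoeolog_map(inputs["homoeolog_map"])
        counts["n_genes"] = len(genes)
        counts["n_chromosomes"] = len(layout)
        counts["n_homoeolog_entries"] = len(hmap)
        _done("annotation")

        rep1 = read_narrowpeak(inputs["rep1"])
        rep2 = read_narrowpeak(inputs["rep2"])
        counts["n_peaks_rep1_raw"] = len(rep1)
        counts["n_peaks_rep2_raw"] = len(rep2)
        rep1 = filter_peaks(rep1, params["min_fold"], params["max_q"])
        rep2 = filter_peaks(rep2, params["min_fold"], params["max_q"])
        counts["n_peaks_rep1_filtered"] = len(rep1)
        counts["n_peaks_rep2_filtered"] = len(rep2)
        pairs = overlap_replicates(rep1, rep2)
        counts["n_reproducible_pairs"] = len(pairs)
        _done("overlap")

        fit = estimate_idr_for_pairs(pairs, score=params["idr_score"])
        manifest["idr_fit"] = {
            "p": fit.p, "mu": fit.mu, "sigma": fit.sigma, "rho": fit.rho,
            "n_iter": fit.n_iter,
        }
        pairs = assign_validation_levels(
            pairs, fit.global_idr,
            d_vl2=params["d_vl2"], d_vl3=params["d_vl3"],
            idr_max=params["idr_max"],
        )
        for level in LEVELS:
            counts[f"n_peaks_{level}"] = len(peaks_at_level(pairs, level))
        write_peaks_bed(pairs, os.path.join(outdir, "reproducible_peaks.bed"))
        _done("validation_levels")

        assignments = classify_features(pairs, genes)
        dist = feature_distribution(assignments)
        counts["feature_distribution"] = dist
        with open(os.path.join(outdir, "peak_features.tsv"), "w") as fh:
            fh.write("peak\tcategory\tgene_id\tsigned_tss_distance\n")
            for a in assignments:
                fh.write(
                    f"{a.peak_name}\t{a.category}\t{a.gene_id or 'NA'}\t"
                    f"{'NA' if a.signed_tss_distance is None else a.signed_tss_distance}\n"
                )
        profile = tss_profile(pairs, genes)
        with open(os.path.join(outdir, "tss_profile.tsv"), "w") as fh:
            fh.write("bin_start\tbin_end\tcount\n")
            for i in range(profile.counts.size):
                fh.write(
                    f"{profile.bin_edges[i]}\t{profile.bin_edges[i + 1]}\t"
                    f"{profile.counts[i]}\n"
                )
        counts["n_peaks_in_tss_window"] = profile.total_in_window
        target_maps = {
            level: assign_target_genes(
                peaks_at_level(pairs, level), genes,
                up=params["promoter_up"], down=params["promoter_down"],
            )
            for level in LEVELS
        }
        for level in LEVELS:
            counts[f"n_bound_genes_{level}"] = len(target_maps[level])
        with open(os.path.join(outdir, "target_map.tsv"), "w") as fh:
            fh.write("gene_id\tpeak_name\tlevel\n")
            for gene in sorted(target_maps["VL1"]):
                for rp in target_maps["VL1"][gene]:
                    fh.write(f"{gene}\t{rp.name}\t{rp.level}\n")
        _done("peak_annotation")

        deg = read_deg_table(inputs["deg_table"])
        counts["n_deg_rows"] = len(deg)
        selected = select_consistent_degs(
            deg,
            min_abs_log2fc=params["min_abs_log2fc"],
            max_fdr=params["max_fdr"],
            require_both_lines=params["require_both_lines"],
            stage_rule=params["stage_rule"],
        )
        counts["n_selected_degs"] = len(selected)
        calls = classify_direct_indirect(
            selected, target_maps, universe=[g.gene_id for g in genes]
        )
        calls = attach_homoeolog_groups(calls, hmap)
        with open(os.path.join(outdir, "target_calls.tsv"), "w") as fh:
            fh.write("gene_id\tdeg_status\tbound_at\tclass\tdirection\thomoeolog_group\n")
            for c in calls:
                fh.write(
                    f"{c.gene_id}\t{c.deg_status}\t{c.bound_at or 'none'}\t"
                    f"{c.cls}\t{c.direction}\t{c.homoeolog_group or 'NA'}\n"
                )
        summary = summarize_classification(calls)
        homoeo = collapse_to_homoeologs(calls, hmap)
        summary_dict = {
            **summary.to_dict(),
            "unique_homoeologs": homoeo,
            "stage_rule": params["stage_rule"],
            "require_both_lines": params["require_both_lines"],
        }
        with open(os.path.join(outdir, "classification_summary.json"), "w") as fh:
            json.dump(summary_dict, fh, indent=2)
        counts["classification"] = summary.to_dict()
        _done("integration")

        bias_results = group_bias_tests(pairs, layout, alpha=params["alpha"])
        tab = results_table(bias_results)
        pooled = pooled_subgenome_test(pairs, layout, alpha=params["alpha"])
        tab = pd.concat([tab, results_table([pooled])], ignore_index=True)
        tab.to_csv(os.path.join(outdir, "subgenome_bias.tsv"), sep="\t",
                   index=False, float_format="%.6g")
        counts["n_bias_significant_groups"] = int(
            sum(r.significant for r in bias_results)
        )
        _done("subgenome_bias")

        if "bin_map" in inputs:
            bmap = read_bin_map(inputs["bin_map"])
            universe = [g.gene_id for g in genes]
            direct_vl1 = [c.gene_id for c in calls if c.direct_at("VL1")]
            res = enrich(direct_vl1, universe, bmap, level=params["bin_level"])
            top_bins(res, params["top_bins"]).to_csv(
                os.path.join(outdir, "enrichment_direct_VL1.tsv"),
                sep="\t", index=False, float_format="%.6g",
            )
            counts["n_bins_tested"] = len(res)
            _done("enrichment")

        if "proteomics" in inputs:
            evidence = read_evidence(inputs["proteomics"])
            retained, psum = filter_exclusive_candidates(evidence)
            retained.to_csv(os.path.join(outdir, "interactor_candidates.tsv"),
                            sep="\t", index=False)
            counts["proximity"] = {
                "n_groups": psum.n_groups,
                "n_peptides": psum.n_peptides,
                "n_unique_proteins": psum.n_unique_proteins,
            }
            _done("proximity")
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
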