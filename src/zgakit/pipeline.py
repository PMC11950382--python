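"""Configuration-driven orchestration of the full synthetic analysis.

``run_pipeline`` executes the enabled stages in dependency order
(synthetic data → CUT&Tag normalization → chromatin states → multiome
core → peak-to-gene linkage → RNAPII pausing), writes TSV/JSON outputs
into the configured directory and returns a manifest recording seeds,
parameter values and per-stage record counts.  Identical config + seed
gives identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin_states as cs
from . import cutntag, linkage, multiome, pausing, simulate
from .genomic import write_bed, write_counts, write_genes

__all__ = ["default_config", "load_config", "run_pipeline"]

#: every threshold the analyses use, with its standard default
DEFAULT_THRESHOLDS = {
    "peak_min_width": 20,
    "peak_max_width": 10_000,
    "quantify_flank": 1000,
    "tss_assign_dist": 10_000,
    "qc_min_counts": 300,
    "qc_min_genes": 200,
    "qc_max_mito_frac": 0.20,
    "n_hvgs": 2000,
    "de_min_expr_frac": 0.01,
    "link_window": 20_000,
    "link_n_background": 200,
    "link_alpha": 0.05,
    "promoter_flank": 500,
    "enhancer_window": 20_000,
    "pausing_prox": 300,
    "pausing_body_end": 5000,
}

STAGE_ORDER = ("synthetic", "norm", "states", "multiome", "linkage", "pausing")


def default_config(outdir: str = "zgakit_out", seed: int = 0) -> dict:
    """Demo configuration: synthetic data plus every stage.

    Thresholds carry the standard defaults except the cell-QC cutoffs,
    which are rescaled to the synthetic library size: the simulator
    draws ~10² genes rather than a genome-wide transcriptome, so the
    droplet-scale minima (300 counts, 200 genes) would discard every
    cell.  Runs on real data should restore them via the config file.
    """
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds["qc_min_counts"] = 30
    thresholds["qc_min_genes"] = 10
    return {
        "seed": seed,
        "outdir": outdir,
        "synthetic": {},  # overrides for SyntheticConfig fields
        "stages": {s: True for s in STAGE_ORDER},
        "thresholds": thresholds,
        "kd": {"n_leak_layers": 2, "leak_rate": 0.5},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if key in ("synthetic", "stages", "thresholds", "kd") and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = set(cfg["thresholds"]) - set(DEFAULT_THRESHOLDS)
    if unknown:
        raise ValueError(f"unknown thresholds: {sorted(unknown)}")
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict) -> dict:
    """Run the enabled stages; return (and write) the run manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thr = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    stages = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGE_ORDER}
    scfg = simulate.SyntheticConfig(**{**config.get("synthetic", {}), "seed": seed})

    manifest: dict = {
        "seed": seed,
        "thresholds": thr,
        "synthetic_config": asdict(scfg),
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    downstream = [s for s in STAGE_ORDER[1:] if stages[s]]
    if downstream and not stages["synthetic"]:
        raise ValueError(
            f"stage '{downstream[0]}' requires the synthetic stage (or external "
            "inputs, which this runner does not wire up)"
        )

    data = {}
    if stages["synthetic"]:
        rna, atac, cells, genes, peaks, truth = simulate.simulate_multiome(scfg)
        libs, _, mark_peaks, mark_truth = simulate.simulate_mark_libraries(scfg)
        s5p_wt, s5p_kd, s5p_truth = simulate.simulate_rnapii_tracks(scfg, genes)
        data.update(
            rna=rna, atac=atac, cells=cells, genes=genes, peaks=peaks,
            truth=truth, libs=libs, mark_peaks=mark_peaks,
            mark_truth=mark_truth, s5p_wt=s5p_wt, s5p_kd=s5p_kd,
        )
        write_bed(peaks, outdir / "peaks.bed")
        write_genes(genes, outdir / "genes.bed")
        write_counts(rna, cells, outdir / "rna.mtx.txt",
                     outdir / "rna.features.txt", outdir / "cells.tsv")
        write_counts(atac, cells, outdir / "atac.mtx.txt",
                     outdir / "atac.features.txt", outdir / "cells.atac.tsv")
        truth.to_json(outdir / "truth.multiome.json")
        mark_truth.to_json(outdir / "truth.marks.json")
        manifest["outputs"] += [
            "peaks.bed", "genes.bed", "rna.mtx.txt", "atac.mtx.txt",
            "truth.multiome.json", "truth.marks.json",
        ]
        manifest["stages"]["synthetic"] = {
            "n_cells": len(cells), "n_genes": len(genes),
            "n_peaks": len(peaks), "n_mark_peaks": len(mark_peaks),
            "n_mark_libraries": len(libs),
        }

    if stages["norm"]:
        libs = data["libs"]
        h3_by_id = {l.sample_id: l for l in libs if l.mark == "H3"}
        reference_h3 = next(l for l in libs if l.mark == "H3")
        rows = []
        for lib in libs:
            if lib.mark == "H3":
                continue
            track = cutntag.normalized_track(
                lib, h3_by_id[lib.paired_h3_sample], reference_h3
            )
            sig = cutntag.quantify_peaks(
                track, data["mark_peaks"], flank=thr["quantify_flank"]
            )
            for pid, val in sig.items():
                rows.append((lib.sample_id, lib.mark, pid, val))
        emit("peak_signal.tsv", pd.DataFrame(
            rows, columns=["sample", "mark", "peak", "signal"]
        ))
        manifest["stages"]["norm"] = {"n_rows": len(rows)}

    if stages["states"]:
        mark_truth, mark_peaks = data["mark_truth"], data["mark_peaks"]
        me3_all, ac_all = simulate.mark_peak_sets(mark_truth, mark_peaks)
        unified = cs.unify_peaks([me3_all, ac_all])
        pooled = cs.classify_stage(unified, me3_all, ac_all, stage="pooled")
        layer0 = sorted({ct for ct, _ in mark_truth.mark_of})[0]
        me3_s, ac_s = simulate.mark_peak_sets(mark_truth, mark_peaks, layer0)
        sorted_cls = cs.classify_stage(unified, me3_s, ac_s, stage=f"sorted_{layer0}")
        flows = cs.transitions(sorted_cls, pooled)
        emit("states.tsv", pd.DataFrame(
            {
                "peak": list(pooled.states),
                "pooled_state": list(pooled.states.values()),
                "sorted_state": [sorted_cls.states[p] for p in pooled.states],
            }
        ))
        flows.reset_index().to_csv(outdir / "transitions.tsv", sep="\t", index=False)
        manifest["outputs"].append("transitions.tsv")
        assoc = cs.peaks_to_genes(unified, data["genes"], thr["tss_assign_dist"])
        emit("peak_genes.tsv", pd.DataFrame(
            [(p, ";".join(sorted(gs))) for p, gs in assoc.items()],
            columns=["peak", "genes"],
        ))
        manifest["stages"]["states"] = dict(pooled.counts())

    if stages["multiome"]:
        rna, cells = data["rna"], data["cells"]
        mito = {f for f in rna.features if f.startswith("mt:")}
        rna_qc, cells_qc = multiome.qc_filter(
            rna, cells, mito,
            min_counts=thr["qc_min_counts"], min_genes=thr["qc_min_genes"],
            max_mito_frac=thr["qc_max_mito_frac"],
        )
        norm = multiome.normalize_rna(rna_qc)
        atac_norm = multiome.tfidf(data["atac"])
        n_hvg = min(thr["n_hvgs"], len(norm.features))
        hvgs = multiome.select_hvgs(norm, n=n_hvg)
        truth = data["truth"]
        score_rows = []
        for layer, markers in truth.marker_genes.items():
            present = sorted(set(markers) & set(norm.features))
            if not present:
                continue
            sc = multiome.signature_score(norm, present, seed=seed)
            for layer2 in sorted(set(cells_qc.germ_layer)):
                mask = cells_qc.germ_layer == layer2
                score_rows.append((layer, layer2, float(sc[mask].mean())))
        emit("signature_scores.tsv", pd.DataFrame(
            score_rows, columns=["signature", "layer", "mean_score"]
        ))
        marker_genes = [g.gene_id for g in data["genes"]]
        primary = multiome.primary_germ_layers(norm, cells_qc, marker_genes)
        ids = multiome.gene_identity_score(norm, cells_qc, marker_genes, primary)
        emit("gene_identity.tsv", ids)
        data.update(norm=norm, atac_norm=atac_norm, hvgs=hvgs,
                    cells_qc=cells_qc, primary=primary)
        manifest["stages"]["multiome"] = {
            "n_cells_pass_qc": len(cells_qc),
            "n_hvgs": len(hvgs),
            "mean_gene_id_score": float(ids["score"].mean()),
        }

    if stages["linkage"]:
        norm, atac_norm = data["norm"], data["atac_norm"]
        # align ATAC cells to the RNA cells that survived QC
        keep = [atac_norm.cells.index(c) for c in norm.cells]
        atac_aligned = multiome.NormalizedMatrix(
            atac_norm.features, [atac_norm.cells[i] for i in keep],
            atac_norm.X[:, keep],
        )
        n_bg = min(thr["link_n_background"], len(data["peaks"]) - 1)
        links = linkage.link_peaks(
            norm, atac_aligned, data["genes"], data["peaks"],
            window=thr["link_window"], n_background=n_bg,
        )
        emit("links.tsv", links)
        cre = linkage.build_cre_map(
            atac_aligned, data["genes"], data["peaks"], links,
            promoter_flank=thr["promoter_flank"],
            enhancer_window=thr["enhancer_window"], alpha=thr["link_alpha"],
        )
        emit("cre_map.tsv", cre)
        hvg_universe = data["hvgs"]
        rho_p = linkage.per_cell_correlation(norm, atac_aligned, cre, hvg_universe, "promoter")
        rho_e = linkage.per_cell_correlation(norm, atac_aligned, cre, hvg_universe, "enhancer")
        u, p = linkage.compare_correlations(rho_p, rho_e)
        emit("per_cell_correlation.tsv", pd.DataFrame(
            {"cell": norm.cells, "rho_promoter": rho_p, "rho_enhancer": rho_e}
        ))
        manifest["stages"]["linkage"] = {
            "n_links": len(links),
            "n_genes_with_both_elements": int(
                cre.dropna(subset=["promoter_peak", "enhancer_peak"]).shape[0]
            ),
            "median_rho_promoter": float(np.nanmedian(rho_p)),
            "median_rho_enhancer": float(np.nanmedian(rho_e)),
            "mannwhitney_p": p,
        }

    if stages["pausing"]:
        recs_wt = pausing.pausing_index(
            data["s5p_wt"], data["genes"],
            prox=thr["pausing_prox"], body_end=thr["pausing_body_end"],
        )
        recs_kd = pausing.pausing_index(
            data["s5p_kd"], data["genes"],
            prox=thr["pausing_prox"], body_end=thr["pausing_body_end"],
        )
        emit("pausing_wt.tsv", pausing.records_frame(recs_wt))
        emit("pausing_kd.tsv", pausing.records_frame(recs_kd))
        comp = pausing.compare_pausing(recs_wt, recs_kd)
        emit("pausing_comparison.tsv", comp)
        manifest["stages"]["pausing"] = {
            "n_scored_wt": int(sum(r.pi is not None for r in recs_wt)),
            "median_ratio": float(comp["median_ratio"].iloc[0]) if len(comp) else None,
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    return manifest
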