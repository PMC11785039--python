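"""End-to-end orchestration: preprocess -> fit -> select -> enrich -> target response.

A run is described by one flat configuration mapping (typically a YAML file):
either a ``simulation`` block handled by :mod:`chemoshift.simulate`, or paths
to an expression matrix, sample sheet, optional probe map and a GMT
collection.  All randomness flows from the single top-level seed, every stage
writes its table into the output directory as it completes (so partial output
survives a downstream failure), and a machine-readable manifest records
parameters and per-stage row counts.  Rerunning with the same configuration
and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

from . import __version__
from .enrichment import bh_qvalues, enrich_collection, rank_tfs, volcano_table
from .errors import ChemoshiftError, ConfigError
from .interaction import InteractionModel
from .io import (
    read_expression,
    read_gmt,
    read_probe_map,
    write_gmt,
    write_matrix,
    write_results_table,
)
from .preprocess import preprocess_pipeline
from .simulate import SimulationConfig, simulate_experiment
from .target_response import fold_changes, summarize_by_target

logger = logging.getLogger(__name__)

__all__ = ["StageError", "run_all"]


class StageError(ChemoshiftError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ChemoshiftError as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def run_all(config: dict[str, Any], outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full analysis graph; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = seed
    manifest: dict[str, Any] = {
        "package": "chemoshift",
        "version": __version__,
        "config": _jsonable(cfg),
        "stages": {},
    }

    # ----- inputs: simulation or files -------------------------------------
    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"] or {})
        if seed is not None:
            sim_kwargs["seed"] = int(seed)  # explicit argument beats the config
        elif "seed" in cfg and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = int(cfg["seed"])
        sim_config = SimulationConfig(**sim_kwargs)
        matrix, design, collection, truth = _stage("simulate")(simulate_experiment)(sim_config)
        write_matrix(matrix, outdir / "matrix.tsv")
        design.table.to_csv(outdir / "sample_sheet.tsv", sep="\t", index_label="sample")
        write_gmt(collection, outdir / "gene_sets.gmt")
        truth_df = truth.params.reset_index()
        write_results_table(truth_df, outdir / "truth.tsv")
        manifest["stages"]["simulate"] = {
            "n_genes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "n_sets": len(collection),
            "active_tf": truth.active_tf,
        }
        probe_map = None
        skip_qn = True
        skip_log2 = True
        tf_of_interest = cfg.get("tf", truth.active_tf)
    else:
        for key in ("matrix", "sample_sheet"):
            if key not in cfg:
                raise StageError(f"stage 'inputs': missing config key {key!r}")
        if "gmt" not in cfg:
            raise StageError("stage 'enrich': missing config key 'gmt'")
        matrix, design = _stage("inputs")(read_expression)(
            cfg["matrix"],
            cfg["sample_sheet"],
            treatment_ref=cfg.get("treatment_ref"),
            phenotype_ref=cfg.get("phenotype_ref"),
        )
        collection = _stage("inputs")(read_gmt)(cfg["gmt"])
        probe_map = (
            _stage("inputs")(read_probe_map)(cfg["probe_map"]) if cfg.get("probe_map") else None
        )
        skip_qn = bool(cfg.get("skip_qn", probe_map is None))
        skip_log2 = bool(cfg.get("skip_log2", probe_map is None))
        tf_of_interest = cfg.get("tf")
        manifest["stages"]["inputs"] = {
            "n_rows": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "n_sets": len(collection),
        }
    logger.info("inputs: %d rows x %d samples, %d gene sets", *matrix.shape, len(collection))

    # ----- preprocess -------------------------------------------------------
    matrix = _stage("preprocess")(preprocess_pipeline)(
        matrix, probe_map=probe_map, skip_qn=skip_qn, skip_log2=skip_log2
    )
    write_matrix(matrix, outdir / "expression_gene_level.tsv")
    manifest["stages"]["preprocess"] = {
        "n_genes": matrix.shape[0],
        "skip_qn": skip_qn,
        "skip_log2": skip_log2,
    }
    logger.info("preprocess: %d genes", matrix.shape[0])

    # ----- interaction fit & selection --------------------------------------
    results = _stage("fit-interaction")(lambda: InteractionModel(matrix, design).fit())()
    fits_df = results.to_frame().reset_index()
    write_results_table(fits_df, outdir / "interaction_fits.tsv")
    fraction = float(cfg.get("fraction", 0.05))
    selection = _stage("select")(results.select_responsive)(fraction)
    sel_rows = [{"gene": g, "tail": "top"} for g in selection.top_genes] + [
        {"gene": g, "tail": "bottom"} for g in selection.bottom_genes
    ]
    write_results_table(sel_rows, outdir / "responsive_selection.tsv")
    manifest["stages"]["fit"] = {"n_genes": len(fits_df), "n_samples": results.n_obs}
    manifest["stages"]["select"] = {
        "fraction": fraction,
        "n_top": len(selection.top_genes),
        "n_bottom": len(selection.bottom_genes),
    }
    logger.info("selection: %d top + %d bottom genes", len(selection.top_genes), len(selection.bottom_genes))

    # ----- enrichment --------------------------------------------------------
    universe_mode = cfg.get("universe_mode", "intersect")
    alpha = float(cfg.get("alpha", 1e-5))
    records = _stage("enrich")(enrich_collection)(
        selection, collection, matrix.gene_ids, universe_mode=universe_mode
    )
    ranked = rank_tfs(records, alpha=alpha)
    if cfg.get("bh", False):
        qs = bh_qvalues([r.p_value for r in ranked])
        ranked = [dataclasses.replace(r, q_value=float(q)) for r, q in zip(ranked, qs)]
    write_results_table(ranked, outdir / "enrichment.tsv")
    write_results_table(volcano_table(ranked), outdir / "volcano.tsv")
    top_hit = ranked[0].set_name if ranked else None
    manifest["stages"]["enrich"] = {
        "n_sets_tested": len(ranked),
        "universe_mode": universe_mode,
        "alpha": alpha,
        "n_significant": sum(bool(r.significant) for r in ranked),
        "top_hit": top_hit,
    }
    logger.info("enrichment: %d sets, top hit %s", len(ranked), top_hit)

    # ----- target response ---------------------------------------------------
    tf_name = tf_of_interest or top_hit
    if tf_name is not None and tf_name in collection:
        targets = collection[tf_name].members
        fc_records = _stage("target-response")(fold_changes)(matrix, design, targets)
        fc_rows = [
            {
                "gene": r.gene,
                "fc_ref": r.fc_ref,
                "fc_alt": r.fc_alt,
                "delta": r.delta,
                "is_target": r.is_target,
            }
            for r in fc_records
        ]
        write_results_table(fc_rows, outdir / "fold_changes.tsv")
        tgt, non, dod = _stage("target-response")(summarize_by_target)(fc_records)
        write_results_table([tgt, non], outdir / "target_summary.tsv")
        manifest["stages"]["target_response"] = {
            "tf": tf_name,
            "n_targets": tgt.n,
            "n_non_targets": non.n,
            "delta_of_deltas": dod,
            "welch_p": tgt.welch_p,
        }
        logger.info("target response for %s: delta-of-deltas %.4g", tf_name, dod)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
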