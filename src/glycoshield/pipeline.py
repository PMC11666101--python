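"""End-to-end pipeline: scan -> conserve -> graft -> sample -> occlusion ->
verdicts -> variants, on either packaged synthetic inputs or user files.

``run_pipeline`` executes every stage on the toy study system and writes
one JSON bundle plus CSVs; it is deterministic for a fixed seed and
embeds the full parameter echo in the bundle.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from glycoshield import io
from glycoshield.config import RunConfig
from glycoshield.glycan_tree import load_representative_tree, composition
from glycoshield.graft_sample import SamplerParams, graft, sample_ensemble
from glycoshield.occupancy_occlusion import (
    binding_verdict,
    build_grid,
    occlusion_report_rows,
    occlusion_score,
    pore_block_check,
)
from glycoshield.seq_sites import align_isoforms, map_conserved_sequons
from glycoshield.synthetic_data import (
    family_sequon_sets,
    load_reference_tables,
    make_isoform_context,
    make_sequence_family,
    make_toy_channel,
    nav_family_params,
)
from glycoshield.variant_glyco import build_variant_report, disrupting_count

logger = logging.getLogger("glycoshield")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    logger.info("stage=%s wall_time=%.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: RunConfig | None = None, outdir=None, seed: int | None = None) -> dict:
    """Run the full analysis on the packaged synthetic study system."""
    config = config or RunConfig()
    if seed is not None:
        config = config.override(seed=int(seed))
    seed = int(config["seed"])
    logger.info("pipeline seed=%d", seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    bundle: dict = {"config": config.echo(), "seed": seed}

    # -- sequence family: scan + conservation -------------------------------
    seqs, truth = _stage("family", make_sequence_family, nav_family_params(seed=seed))
    sequons = family_sequon_sets(seqs, truth)
    msa = _stage("align", align_isoforms, seqs)
    cmap = _stage("conserve", map_conserved_sequons, msa, sequons, True)
    bundle["conservation"] = {
        "n_groups": len(cmap.groups),
        "n_all": len(cmap.groups_of_class("all")),
        "n_subset": len(cmap.groups_of_class("subset")),
        "n_unique": len(cmap.groups_of_class("unique")),
        "all_positions_nav15": sorted(
            pos
            for g in cmap.groups_of_class("all")
            for iso, pos in g.members
            if iso == "NaV1.5"
        ),
    }

    # -- variants ------------------------------------------------------------
    tables = load_reference_tables()
    variant_rows = []
    counts = {}
    for iso in ("NaV1.1", "NaV1.5", "NaV1.6"):
        ctx = make_isoform_context(iso)
        records = [v for v in tables.variants if v.isoform_id == iso]
        report = _stage(f"variants:{iso}", build_variant_report, ctx, records)
        counts[iso] = disrupting_count(report)
        variant_rows.append(report)
    variants = pd.concat(variant_rows, ignore_index=True)
    bundle["variants"] = {"disrupting_counts": counts, "n_rows": len(variants)}

    # -- glycan tree ---------------------------------------------------------
    tree = load_representative_tree()
    bundle["glycan_tree"] = {"composition": composition(tree), "n_nodes": len(tree)}

    # -- toy channel: graft + sample + occlusion -----------------------------
    toy = _stage("toy_channel", make_toy_channel)
    grafts = [
        _stage(
            f"graft:{site}", graft, toy.structure, site, tree,
            seed + i, toy.sequence.residues, toy.membrane,
            config["clash_cutoff_A"],
        )
        for i, site in enumerate(toy.glycosites)
    ]
    params = SamplerParams(
        snapshots=config["snapshots"],
        interval=config["interval"],
        move_width=config["move_width_deg"],
        temperature=config["temperature"],
        clash_cutoff=config["clash_cutoff_A"],
        seed=seed,
        max_attempts=config["max_attempts"],
    )
    ensemble = _stage("sample", sample_ensemble, toy.structure, grafts, toy.membrane, params)
    grid = _stage("grid", build_grid, ensemble, config["voxel_size_A"])
    reports = {}
    for name, (lo, hi) in toy.annotation.regions.items():
        if not name.startswith("ECTL"):
            continue
        reports[name] = occlusion_score(
            ensemble, range(lo, hi + 1), region_name=name,
            contact_cutoff=config["contact_cutoff_A"],
            frame_fraction=config["frame_fraction"],
            blocked_threshold=config["blocked_threshold"],
            accessible_threshold=config["accessible_threshold"],
        )
    pore = _stage(
        "pore", pore_block_check, ensemble, toy.pore_axis_point, toy.pore_axis_dir,
        config["pore_radius_A"], config["pore_length_A"],
    )
    bundle["ensemble"] = {
        "n_frames": ensemble.n_frames,
        "status": ensemble.status,
        "acceptance": round(float(ensemble.acceptance), 4),
        "occupied_voxels": grid.occupied_voxels(),
        "pore_blocked_fraction": pore,
    }
    bundle["occlusion"] = occlusion_report_rows(reports)
    bundle["verdicts"] = binding_verdict(
        reports, config["blocked_threshold"], config["accessible_threshold"]
    )

    if outdir is not None:
        io.write_json(bundle, outdir / "bundle.json")
        variants.to_csv(outdir / "variants.csv", index=False)
        cmap.to_frame().to_csv(outdir / "conservation.csv", index=False)
        pd.DataFrame(bundle["occlusion"]).to_csv(outdir / "occlusion.csv", index=False)
    return bundle


def validate_bundle(bundle: dict) -> list[str]:
    """Schema sanity check on a re-ingested bundle: fractions within [0, 1],
    counts nonnegative.  Returns a list of violations (empty = valid)."""
    errors = []

    def frac(path, v):
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            errors.append(f"{path}: {v!r} not a fraction in [0,1]")

    def count(path, v):
        if not (isinstance(v, int) and v >= 0):
            errors.append(f"{path}: {v!r} not a nonnegative count")

    ens = bundle.get("ensemble", {})
    frac("ensemble.pore_blocked_fraction", ens.get("pore_blocked_fraction"))
    count("ensemble.n_frames", ens.get("n_frames"))
    count("ensemble.occupied_voxels", ens.get("occupied_voxels"))
    for row in bundle.get("occlusion", []):
        frac(f"occlusion[{row.get('region')}].coverage", row.get("coverage"))
        frac(f"occlusion[{row.get('region')}].mean_contact_fraction", row.get("mean_contact_fraction"))
        count(f"occlusion[{row.get('region')}].n_residues", row.get("n_residues"))
    for iso, c in bundle.get("variants", {}).get("disrupting_counts", {}).items():
        count(f"variants.{iso}", c)
    for key in ("n_groups", "n_all", "n_subset", "n_unique"):
        count(f"conservation.{key}", bundle.get("conservation", {}).get(key))
    return errors
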