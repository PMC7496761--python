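"""Stage-wise pipeline: simulate → screen → fit → ensemble → hotspots → change.

Each stage reads its inputs from the run directory written by earlier stages
and leaves its own outputs in a stage subdirectory, so any suffix of the
pipeline can be re-run from cached intermediates.  A manifest records seeds,
stage completion and SHA-256 checksums of every stage output; identical config
and seed produce identical outputs.

Layout of a run directory::

    world/{present,2050,2100}/<layer>.asc   predictor rasters
    world/occurrences/<species>.csv         conditioned occurrence tables
    world/roster.json                       species metadata (group, depth, candidates)
    screen/<species>.csv|.json              screening reports / selected predictors
    fit/<species>__<family>.npz             surviving replicate binaries per scenario
    fit/evaluation.csv                      per-replicate AUC/TSS/threshold/exclusion
    ensemble/<species>__<scenario>.asc      consensus binary maps (depth-masked)
    hotspots/richness_<group>_<scenario>.asc, breaks.json, areas.csv
    change/summary.csv, change_all_<period>.asc, report.txt
    manifest.json, run.log
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .config import RunConfig
from .evaluation import apply_depth_mask, consensus
from .grid import EnvStack, Layer, read_ascii_grid, write_ascii_grid
from .hotspots import (
    GAIN, LOSS, STABLE_SUITABLE,
    area_by_category, change_map, group_summaries, jenks_breaks, stack_richness,
)
from .models import ModelSpec, run_replicates
from .screening import select_predictors
from .synthetic import (
    GROUPS, arctic_mask, default_roster, make_scenarios, sample_occurrences,
)

log = logging.getLogger("stacksdm")

STAGES = ("simulate", "screen", "fit", "ensemble", "hotspots", "change")
SCENARIOS = ("present", "2050", "2100")


class StageInputError(RuntimeError):
    """A stage's required inputs are missing from the run directory."""


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_manifest(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _record_stage(outdir: Path, stage: str, cfg: RunConfig, files: list[Path]) -> None:
    manifest = _load_manifest(outdir)
    manifest["seed"] = cfg.seed
    manifest["stages"][stage] = {
        "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": {str(f.relative_to(outdir)): _sha256(f) for f in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def verify_manifest(outdir: str | Path) -> dict[str, list[str]]:
    """Re-hash every recorded stage output; returns {stage: [mismatched files]}."""
    outdir = Path(outdir)
    manifest = _load_manifest(outdir)
    bad: dict[str, list[str]] = {}
    for stage, info in manifest.get("stages", {}).items():
        mism = [
            rel for rel, digest in info.get("checksums", {}).items()
            if not (outdir / rel).exists() or _sha256(outdir / rel) != digest
        ]
        if mism:
            bad[stage] = mism
    return bad


# ---------------------------------------------------------------------------
# world I/O
# ---------------------------------------------------------------------------


def _write_stack(stack: EnvStack, d: Path) -> list[Path]:
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for name, layer in stack.layers.items():
        p = d / f"{name}.asc"
        write_ascii_grid(layer, p)
        written.append(p)
    return written


def _read_stack(d: Path, scenario: str) -> EnvStack:
    if not d.is_dir():
        raise StageInputError(f"missing scenario directory {d}; run the simulate stage first")
    layers = {p.stem: read_ascii_grid(p) for p in sorted(d.glob("*.asc"))}
    if not layers:
        raise StageInputError(f"no rasters in {d}; run the simulate stage first")
    any_layer = next(iter(layers.values()))
    sea = ~any_layer.nodata_mask
    return EnvStack(layers=layers, scenario=scenario, sea_mask=sea)


def load_world(outdir: str | Path) -> tuple[dict[str, EnvStack], dict, dict[str, np.ndarray]]:
    """Load scenario stacks, roster metadata and per-species presence cells."""
    outdir = Path(outdir)
    world = outdir / "world"
    stacks = {s: _read_stack(world / s, s) for s in SCENARIOS}
    roster_path = world / "roster.json"
    if not roster_path.exists():
        raise StageInputError(f"missing {roster_path}; run the simulate stage first")
    roster = json.loads(roster_path.read_text())
    grid = stacks["present"].grid
    cells: dict[str, np.ndarray] = {}
    for sp in roster:
        occ_path = world / "occurrences" / f"{sp}.csv"
        if not occ_path.exists():
            raise StageInputError(f"missing {occ_path}; run the simulate stage first")
        df = pd.read_csv(occ_path)
        from .grid import condition_occurrences

        occ = condition_occurrences(
            sp, df[["lon", "lat"]].to_numpy(), grid, stacks["present"].sea_mask,
            range_tags=list(df["range_tag"]) if "range_tag" in df else None,
        )
        cells[sp] = occ.cells
    return stacks, roster, cells


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate the synthetic world and occurrence tables."""
    log.info("simulate: building scenario stacks (%dx%d grid)",
             cfg.world.n_rows, cfg.world.n_cols)
    stacks = make_scenarios(cfg.world.scenario_config(derive_seed(cfg.seed, "world")))
    world = outdir / "world"
    files: list[Path] = []
    for scenario, stack in stacks.items():
        files += _write_stack(stack, world / scenario)

    roster = default_roster()
    meta = {}
    occ_dir = world / "occurrences"
    occ_dir.mkdir(parents=True, exist_ok=True)
    for niche in roster:
        occ = sample_occurrences(
            niche, stacks["present"], cfg.n_presences,
            seed=derive_seed(cfg.seed, "occ", niche.species_id),
            contamination=cfg.contamination,
        )
        df = pd.DataFrame({
            "species_id": niche.species_id,
            "lon": occ.points[:, 0],
            "lat": occ.points[:, 1],
            "range_tag": "unknown",
        })
        p = occ_dir / f"{niche.species_id}.csv"
        df.to_csv(p, index=False)
        files.append(p)
        meta[niche.species_id] = {
            "group": niche.group,
            "max_depth": niche.max_depth,
            "candidates": list(niche.candidates),
        }
    rp = world / "roster.json"
    rp.write_text(json.dumps(meta, indent=1, sort_keys=True))
    files.append(rp)
    _record_stage(outdir, "simulate", cfg, files)
    log.info("simulate: wrote %d files", len(files))


def stage_screen(cfg: RunConfig, outdir: Path) -> None:
    """Predictor screening per species."""
    stacks, roster, cells = load_world(outdir)
    sdir = outdir / "screen"
    sdir.mkdir(parents=True, exist_ok=True)
    files = []
    selected = {}
    for sp, meta in sorted(roster.items()):
        rep = select_predictors(
            meta["candidates"], cells[sp], stacks["present"],
            seed=derive_seed(cfg.seed, "screen", sp),
            n_background=cfg.n_background,
            contribution_threshold=cfg.contribution_threshold,
            correlation_threshold=cfg.correlation_threshold,
            min_predictors=cfg.min_predictors,
            with_jackknife=cfg.screen_jackknife,
        )
        selected[sp] = rep.selected
        p = sdir / f"{sp}.csv"
        rep.to_frame().to_csv(p, index=False)
        files.append(p)
        log.info("screen: %s -> %s", sp, rep.selected)
    sel_path = sdir / "selected.json"
    sel_path.write_text(json.dumps(selected, indent=1, sort_keys=True))
    files.append(sel_path)
    _record_stage(outdir, "screen", cfg, files)


def _load_selected(outdir: Path) -> dict[str, list[str]]:
    p = outdir / "screen" / "selected.json"
    if not p.exists():
        raise StageInputError(f"missing {p}; run the screen stage first")
    return json.loads(p.read_text())


def stage_fit(cfg: RunConfig, outdir: Path) -> None:
    """Fit all model families × replicates per species; store replicate binaries."""
    stacks, roster, cells = load_world(outdir)
    selected = _load_selected(outdir)
    fdir = outdir / "fit"
    fdir.mkdir(parents=True, exist_ok=True)
    files = []
    eval_rows = []
    for sp in sorted(roster):
        for family in cfg.families:
            spec = ModelSpec(
                family,
                n_background=cfg.n_background,
                n_replicates=cfg.n_replicates,
                train_fraction=cfg.train_fraction,
                seed=cfg.seed,
                exclusion_rule=cfg.exclusion_rule,
                tss_cutoff=cfg.tss_exclusion,
            )
            reps, failures = run_replicates(spec, cells[sp], stacks["present"],
                                            selected[sp], species_id=sp)
            for r, msg in failures:
                log.warning("fit: %s/%s replicate %d failed: %s", sp, family, r, msg)
                eval_rows.append({"species": sp, "family": family, "replicate": r,
                                  "auc": np.nan, "sensitivity": np.nan,
                                  "specificity": np.nan, "tss": np.nan,
                                  "threshold": np.nan, "excluded": True,
                                  "reason": f"failed: {msg}"})
            surviving = []
            for rep in reps:
                er = rep.report
                eval_rows.append({"species": sp, "family": family,
                                  "replicate": rep.replicate_id,
                                  "auc": er.auc, "sensitivity": er.sensitivity,
                                  "specificity": er.specificity, "tss": er.tss,
                                  "threshold": er.threshold,
                                  "excluded": er.excluded, "reason": er.exclusion_reason})
                if not er.excluded:
                    surviving.append(rep)
            arrays = {}
            for scenario in SCENARIOS:
                if surviving:
                    arrays[f"s{scenario}"] = np.stack(
                        [rep.binary_map(stacks[scenario]) for rep in surviving]
                    ).astype(np.uint8)
                else:
                    arrays[f"s{scenario}"] = np.zeros(
                        (0, *stacks[scenario].grid.shape), dtype=np.uint8
                    )
            p = fdir / f"{sp}__{family}.npz"
            np.savez_compressed(p, **arrays)
            files.append(p)
            log.info("fit: %s/%s %d/%d replicates retained", sp, family,
                     len(surviving), cfg.n_replicates)
    ev = fdir / "evaluation.csv"
    pd.DataFrame(eval_rows).to_csv(ev, index=False)
    files.append(ev)
    _record_stage(outdir, "fit", cfg, files)


def stage_ensemble(cfg: RunConfig, outdir: Path) -> None:
    """Two-stage consensus per species and scenario, plus the depth mask."""
    stacks, roster, _ = load_world(outdir)
    fdir = outdir / "fit"
    if not fdir.is_dir():
        raise StageInputError(f"missing {fdir}; run the fit stage first")
    edir = outdir / "ensemble"
    edir.mkdir(parents=True, exist_ok=True)
    depth = stacks["present"].layers["depth"].values
    grid = stacks["present"].grid
    files = []
    flagged = []
    for sp, meta in sorted(roster.items()):
        per_family: dict[str, dict[str, list[np.ndarray]]] = {s: {} for s in SCENARIOS}
        for family in cfg.families:
            p = fdir / f"{sp}__{family}.npz"
            if not p.exists():
                raise StageInputError(f"missing {p}; run the fit stage first")
            with np.load(p) as z:
                for scenario in SCENARIOS:
                    arr = z[f"s{scenario}"]
                    if len(arr):
                        per_family[scenario][family] = list(arr)
        if not per_family["present"]:
            flagged.append(sp)
            log.warning("ensemble: %s has no surviving replicates; flagged", sp)
            continue
        for scenario in SCENARIOS:
            cons = consensus(per_family[scenario])
            cons = apply_depth_mask(cons, depth, meta["group"], meta["max_depth"])
            layer = Layer(grid, cons.astype(float), ~stacks[scenario].sea_mask)
            p = edir / f"{sp}__{scenario}.asc"
            write_ascii_grid(layer, p)
            files.append(p)
    fp = edir / "flagged.json"
    fp.write_text(json.dumps(flagged, indent=1))
    files.append(fp)
    _record_stage(outdir, "ensemble", cfg, files)


def _load_ensemble(outdir: Path, roster: dict) -> dict[str, dict[str, np.ndarray]]:
    edir = outdir / "ensemble"
    if not edir.is_dir():
        raise StageInputError(f"missing {edir}; run the ensemble stage first")
    flagged = set(json.loads((edir / "flagged.json").read_text())
                  if (edir / "flagged.json").exists() else [])
    out: dict[str, dict[str, np.ndarray]] = {s: {} for s in SCENARIOS}
    for sp in roster:
        if sp in flagged:
            continue
        for scenario in SCENARIOS:
            p = edir / f"{sp}__{scenario}.asc"
            if not p.exists():
                raise StageInputError(f"missing {p}; run the ensemble stage first")
            layer = read_ascii_grid(p)
            out[scenario][sp] = np.nan_to_num(layer.values, nan=0.0).astype(np.uint8)
    if not out["present"]:
        raise StageInputError("no ensemble maps available (all species flagged?)")
    return out


def stage_hotspots(cfg: RunConfig, outdir: Path) -> None:
    """Group-wise richness maps, Jenks categories and per-category areas."""
    stacks, roster, _ = load_world(outdir)
    binaries = _load_ensemble(outdir, roster)
    groups = {sp: m["group"] for sp, m in roster.items()}
    grid = stacks["present"].grid
    hdir = outdir / "hotspots"
    hdir.mkdir(parents=True, exist_ok=True)
    files = []
    breaks_out = {}
    area_rows = []
    for gname in list(GROUPS) + ["all"]:
        for scenario in SCENARIOS:
            rm = stack_richness(binaries[scenario], groups, grid, scenario, gname)
            layer = Layer(grid, rm.counts.astype(float), ~stacks[scenario].sea_mask)
            p = hdir / f"richness_{gname}_{scenario}.asc"
            write_ascii_grid(layer, p)
            files.append(p)
            positive = rm.counts[rm.counts > 0]
            if len(np.unique(positive)) >= 2:
                br = jenks_breaks(positive, cfg.jenks_k)
            else:
                br = np.empty(0)
            breaks_out[f"{gname}_{scenario}"] = [float(b) for b in br]
            df = area_by_category(rm, br)
            df.insert(0, "scenario", scenario)
            df.insert(0, "group", gname)
            area_rows.append(df)
    bp = hdir / "breaks.json"
    bp.write_text(json.dumps(breaks_out, indent=1, sort_keys=True))
    files.append(bp)
    ap = hdir / "areas.csv"
    pd.concat(area_rows, ignore_index=True).to_csv(ap, index=False)
    files.append(ap)
    _record_stage(outdir, "hotspots", cfg, files)


def stage_change(cfg: RunConfig, outdir: Path) -> None:
    """Gain/loss/stable maps and net percentage change by group and extent."""
    stacks, roster, _ = load_world(outdir)
    binaries = _load_ensemble(outdir, roster)
    groups = {sp: m["group"] for sp, m in roster.items()}
    grid = stacks["present"].grid
    extents = {
        "global": stacks["present"].sea_mask,
        "pan_arctic": arctic_mask(stacks["present"], cfg.world.arctic_lat_min),
    }
    cdir = outdir / "change"
    cdir.mkdir(parents=True, exist_ok=True)
    files = []
    table = group_summaries(binaries, groups, extents, grid)
    sp_path = cdir / "summary.csv"
    table.to_csv(sp_path, index=False)
    files.append(sp_path)
    for period in ("2050", "2100"):
        bp = np.any([b.astype(bool) for b in binaries["present"].values()], axis=0)
        bf = np.any([b.astype(bool) for b in binaries[period].values()], axis=0)
        cm = change_map(bp, bf, grid, "all", f"present->{period}")
        layer = Layer(grid, cm.categories.astype(float), ~stacks["present"].sea_mask)
        p = cdir / f"change_all_{period}.asc"
        write_ascii_grid(layer, p)
        files.append(p)
    lines = ["habitat change summary (net % of present suitable area)", ""]
    for _, row in table.iterrows():
        lines.append(
            f"{row['group']:>14} {row['extent']:>11} {row['period']:>14}: "
            f"net {row['net_pct']:+8.1f}%  (gain {row['gain_km2']:.3e} km2, "
            f"loss {row['loss_km2']:.3e} km2)"
        )
    rp = cdir / "report.txt"
    rp.write_text("\n".join(lines) + "\n")
    files.append(rp)
    _record_stage(outdir, "change", cfg, files)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "fit": stage_fit,
    "ensemble": stage_ensemble,
    "hotspots": stage_hotspots,
    "change": stage_change,
}


def run(cfg: RunConfig, outdir: str | Path, stages: list[str] | None = None) -> Path:
    """Execute the requested stages (default: all) into a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    cfg.to_yaml(outdir / "config.yaml")
    for stage in stages:
        t0 = time.time()
        log.info("=== stage %s ===", stage)
        _STAGE_FUNCS[stage](cfg, outdir)
        log.info("=== stage %s done (%.1f s) ===", stage, time.time() - t0)
    return outdir
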