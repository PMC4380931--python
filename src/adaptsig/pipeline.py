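"""End-to-end orchestration: simulate -> preprocess -> model -> report.

Runs the full analysis from a single plain-text (YAML) configuration:
synthetic data generation, per-cell-line preprocessing of both scanner
analyses, response assembly, PLSR fitting with cross-validation, signed VIP
profiles merged across the two analyses, hierarchical clustering of cell
lines, Bliss synergy scoring, and single-cell gating. Every stage writes
plain CSV/JSON under one run directory and the run manifest records the
config snapshot, per-stage seeds, timings, and a content digest for every
output file, so a rerun with the same config reproduces identical digests
for the deterministic stages.

Config keys (all optional, defaults shown in DEFAULT_CONFIG): ``simulate``
overrides SimConfig fields; ``plsr`` sets n_components / n_folds / cv_seed;
``vip`` sets the clustering exclusion list and the sign source;
``gating.random_state`` seeds the mixture fit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from adaptsig import __version__, preprocess, response, simulate, synergy
from adaptsig import gating as gating_mod
from adaptsig import vip as vip_mod
from adaptsig.pls import PLSRModel

__all__ = ["DEFAULT_CONFIG", "RunManifest", "load_config", "run_pipeline"]

log = logging.getLogger("adaptsig.pipeline")

DEFAULT_CONFIG: dict = {
    "simulate": {},                      # SimConfig field overrides
    "plsr": {"n_components": 3, "n_folds": 10, "cv_seed": 0},
    "vip": {"exclude": ["pMEK", "pERK"], "sign_from": "correlation"},
    "gating": {"random_state": 0},
}


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    version: str
    stage_seconds: dict = field(default_factory=dict)
    file_digests: dict = field(default_factory=dict)

    def add_file(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.file_digests[str(path.relative_to(root))] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stage_seconds": self.stage_seconds,
            "file_digests": self.file_digests,
        }, indent=1, sort_keys=True))


def load_config(source) -> dict:
    """Merge a YAML file / mapping over the defaults."""
    if source is None:
        user = {}
    elif isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    else:
        user = dict(source)
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in user.items():
        if key in cfg and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest.stage_seconds[name] = round(dt, 3)
            if exc is not None:
                log.error("stage %s: FAILED after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Timer()


def run_pipeline(config=None, out_dir: str | Path = "run",
                 seed: int | None = None) -> RunManifest:
    """Execute every stage and return the run manifest (written last)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(cfg["simulate"])
    if seed is not None:
        sim_kwargs["seed"] = seed
    if "drugs" in sim_kwargs:
        sim_kwargs["drugs"] = tuple(sim_kwargs["drugs"])
    for key in ("times_signal", "times_pheno"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(float(t) for t in sim_kwargs[key])
    sim_cfg = simulate.SimConfig(**sim_kwargs)
    manifest = RunManifest(config=cfg, seed=sim_cfg.seed, version=__version__)
    manifest.config["simulate"] = dataclasses.asdict(sim_cfg)

    with _stage(manifest, "simulate"):
        tensor, truth = simulate.generate_rppa(sim_cfg)
        pheno = simulate.generate_phenotype(sim_cfg, truth)
        cells = simulate.generate_single_cell(sim_cfg, truth)
        combo = simulate.generate_synergy(sim_cfg, truth)
        tensor.to_csv(out / "rppa.csv", index=False)
        pheno.to_csv(out / "phenotype.csv", index=False)
        cells.to_csv(out / "single_cell.csv", index=False)
        combo.to_csv(out / "synergy_grid.csv", index=False)
        simulate.write_truth_json(truth, out / "truth.json")

    with _stage(manifest, "preprocess"):
        fc = {sc: preprocess.collapse_log2fc(
            tensor[tensor["scanner"] == sc]) for sc in ("A", "B")}
        viab = response.nonapoptotic_viability(pheno)
        viab.to_csv(out / "viability.csv", index=False)

    plsr_cfg = cfg["plsr"]
    vip_cfg = cfg["vip"]
    profiles = {}
    model_rows = []
    with _stage(manifest, "model"):
        for cl in sim_cfg.cell_lines:
            cl_dir = out / "cell_lines" / cl
            cl_dir.mkdir(parents=True, exist_ok=True)
            designs = {}
            for sc in ("A", "B"):
                sub = fc[sc][fc[sc]["cell_line"] == cl]
                designs[sc] = preprocess.assemble_design(
                    sub, signals=list(sim_cfg.signals),
                    times=list(sim_cfg.times_signal),
                    drugs=list(sim_cfg.drugs))
            designs["A"].to_csv(cl_dir, stem="design")
            y = response.assemble_response(viab, cell_line=cl)
            y.to_csv(cl_dir / "response.csv")
            mask, frac = preprocess.consistency_mask(
                fc["A"][fc["A"]["cell_line"] == cl],
                fc["B"][fc["B"]["cell_line"] == cl])
            mask.to_frame().to_csv(cl_dir / "consistency_mask.csv")

            prof = {}
            for sc in ("A", "B"):
                model = PLSRModel.from_design(designs[sc], y)
                res = model.fit(plsr_cfg["n_components"])
                if sc == "A":
                    res.to_csv(cl_dir / "plsr")
                    cv = model.cross_validate(
                        plsr_cfg["n_components"],
                        n_folds=plsr_cfg["n_folds"],
                        seed=plsr_cfg["cv_seed"])
                    model_rows.append({
                        "cell_line": cl, "R2": res.r2, "Q2": cv.q2,
                        "MSPE_percent": cv.mspe,
                        "n_components": res.n_components,
                        "consistency_fraction": frac,
                    })
                prof[sc] = vip_mod.sign_and_threshold(
                    res.vip(), designs[sc].values, y,
                    sign_from=vip_cfg.get("sign_from", "correlation"),
                    coef=res.coef)
            merged, report = vip_mod.merge_consistent_vip(
                prof["A"], prof["B"], mask)
            log.info("cell line %s: %d/%d variables consistent",
                     cl, report["n_kept"], report["n_variables"])
            merged.to_csv(cl_dir / "vip_profile.csv")
            full = pd.Series(0.0, index=prof["A"].index)
            full[merged.index] = merged["signed_vip"]
            profiles[cl] = full
        pd.DataFrame(model_rows).to_csv(out / "model_metrics.csv",
                                        index=False)

    with _stage(manifest, "cluster"):
        if len(profiles) >= 2:
            clust = vip_mod.cluster_cell_lines(
                profiles, exclude=tuple(vip_cfg.get("exclude", ())))
            clust.merge_table().to_csv(out / "cluster_merges.csv",
                                       index=False)
            (out / "cluster.nwk").write_text(clust.to_newick())

    with _stage(manifest, "synergy"):
        grid = synergy.eobi_from_table(combo)
        grid.to_frame().to_csv(out / "synergy_eobi.csv", index=False)

    with _stage(manifest, "gating"):
        import numpy as np
        wide = cells.pivot_table(index=["condition", "dose", "cell_id"],
                                 columns="marker", values="intensity")
        wide = np.log2(wide)
        markers = tuple(wide.columns[:2])
        ctrl = wide.xs(simulate.CONTROL_LABEL, level="condition")
        gates = {m: gating_mod.fit_gate(
            ctrl[m], random_state=cfg["gating"]["random_state"])
            for m in markers}
        thresholds = {m: g.threshold for m, g in gates.items()}
        rows = []
        results = {}
        for cond, grp in wide.groupby(level="condition"):
            gr = gating_mod.quadrant_fractions(
                grp.reset_index(drop=True), thresholds, markers=markers)
            results[cond] = gr
            for quad, fracv in gr.fractions.items():
                rows.append({"condition": cond,
                             "quadrant": f"{markers[0]}-{quad[0]}/"
                                         f"{markers[1]}-{quad[1]}",
                             "fraction": fracv, "n_cells": gr.n_cells})
        pd.DataFrame(rows).to_csv(out / "quadrant_fractions.csv",
                                  index=False)
        shift_frames = []
        ctrl_result = results[simulate.CONTROL_LABEL]
        for cond, gr in results.items():
            if cond == simulate.CONTROL_LABEL:
                continue
            shift = gating_mod.population_shift(ctrl_result, gr)
            shift["condition"] = cond
            shift_frames.append(shift.reset_index())
        if shift_frames:
            pd.concat(shift_frames, ignore_index=True).to_csv(
                out / "population_shifts.csv", index=False)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.add_file(path, out)
    manifest.write(out / "manifest.json")
    return manifest
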