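"""Pipeline orchestration: simulate -> select CSF form -> select tying model
-> per-observer attributes -> asymmetry summary, with a provenance manifest.

Model selection runs in two stages on the pooled group-level likelihood:

1. every candidate CSF form is fit under the most permissive tying model
   (each cell its own group) to all conditions, and ranked by BIC;
2. the six tying models are fit with the stage-1 winner to the fixed-size
   conditions only, and ranked by BIC.

Attribute extraction then refits the winning form per observer (each cell
free) and summarizes eccentricity effects and polar-angle asymmetries.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import bootstrap_ci, hva_extent, vma_extent
from .config import PipelineConfig
from .crf import CRFSpec
from .csf import extract_attributes
from .fitting import (
    FIXED_CELLS,
    FitOptions,
    FitResult,
    LocationCell,
    build_tying,
    compare_models,
    fit_model,
    full_tying,
)
from .io import read_trials, write_trials
from .observer import ExperimentDesign, _default_conditions, make_observer, simulate_experiment

__all__ = ["PipelineError", "ReportBundle", "run_pipeline", "stage1_csf_selection",
           "stage2_tying_selection", "observer_attributes", "asymmetry_summary",
           "extent_curves", "TYING_FLAGS"]

TYING_FLAGS = [
    (True, True, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, False, False),
    (False, False, False),
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    trials: pd.DataFrame
    stage1: pd.DataFrame
    stage2: pd.DataFrame
    attributes: pd.DataFrame
    asymmetries: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _cells_in(trials: pd.DataFrame) -> tuple[LocationCell, ...]:
    combos = trials[["angle", "ecc", "scaled"]].drop_duplicates()
    return tuple(
        LocationCell(str(r.angle), float(r.ecc), bool(r.scaled))
        for r in combos.itertuples()
    )


def stage1_csf_selection(
    trials: pd.DataFrame, csf_models, opts: FitOptions, crf: CRFSpec
) -> tuple[pd.DataFrame, str]:
    """Rank CSF forms under the most permissive tying model, all conditions."""
    cells = _cells_in(trials)
    fits = [
        fit_model(trials, m, full_tying(m, cells), opts=opts, crf=crf)
        for m in csf_models
    ]
    ranking = compare_models(fits)
    return ranking, str(ranking["csf_model"].iloc[0])


def stage2_tying_selection(
    trials: pd.DataFrame, csf_model: str, opts: FitOptions, crf: CRFSpec
) -> tuple[pd.DataFrame, FitResult]:
    """Rank the six tying models with the winning form, fixed-size trials only."""
    fixed = trials[trials["scaled"] == 0]
    fits = [
        fit_model(fixed, csf_model, build_tying(e, h, v, csf_model), opts=opts, crf=crf)
        for e, h, v in TYING_FLAGS
    ]
    ranking = compare_models(fits)
    winner = next(f for f in fits if f.vf_spec.name == ranking["vf_model"].iloc[0])
    return ranking, winner


def observer_attributes(
    trials: pd.DataFrame, csf_model: str, opts: FitOptions, crf: CRFSpec,
    half_max_on: str = "log",
) -> pd.DataFrame:
    """Per-observer, per-cell CSF fits and attribute extraction."""
    rows = []
    for obs_id, sub in trials.groupby("observer"):
        cells = _cells_in(sub)
        fit = fit_model(sub, csf_model, full_tying(csf_model, cells), opts=opts, crf=crf)
        for cell in cells:
            params = fit.params_for_cell(cell)
            attrs = extract_attributes(params, half_max_on=half_max_on)
            rows.append(
                {
                    "observer": obs_id,
                    "angle": cell.angle,
                    "ecc": cell.ecc,
                    "scaled": int(cell.scaled),
                    "csf_model": csf_model,
                    "alpha": params.alpha,
                    "beta": params.beta,
                    "gamma": params.gamma,
                    "delta": params.delta,
                    "peak_cs": attrs.peak_cs,
                    "peak_sf": attrs.peak_sf,
                    "cutoff_sf": attrs.cutoff_sf,
                    "aulcsf": attrs.aulcsf,
                    "bandwidth": attrs.bandwidth,
                    "flags": ";".join(attrs.flags),
                }
            )
    return pd.DataFrame(rows)


def extent_curves(attributes: pd.DataFrame, sfs) -> pd.DataFrame:
    """Per-SF eccentricity-effect / HVA / VMA extents per observer.

    Sensitivities are evaluated from the fitted per-cell CSF parameters
    stored in the attribute table, at the design spatial frequencies.
    """
    from .asymmetry import percent_change
    from .csf import CSFParamSet, csf_sensitivity

    sfs = np.asarray(sfs, dtype=float)
    rows = []
    for obs_id, sub in attributes.groupby("observer"):
        def sens(angle, ecc, scaled):
            sel = sub[(sub.angle == angle) & (sub.ecc == ecc) & (sub.scaled == scaled)]
            if not len(sel):
                return None
            r = sel.iloc[0]
            gamma = None if pd.isna(r["gamma"]) else float(r["gamma"])
            params = CSFParamSet(r["csf_model"], float(r["alpha"]), float(r["beta"]),
                                 float(r["delta"]), gamma)
            return np.maximum(csf_sensitivity(params, sfs), 1e-9)

        grids = {
            (a, e, s): sens(a, e, s)
            for a in ("HM", "LVM", "UVM")
            for e, s in ((2.0, 0), (6.0, 0), (6.0, 1))
        }
        for cond, ecc, scl in (("2", 2.0, 0), ("6", 6.0, 0), ("6_M", 6.0, 1)):
            hm, lvm, uvm = (grids[(a, ecc, scl)] for a in ("HM", "LVM", "UVM"))
            if hm is None or lvm is None or uvm is None:
                continue
            for f, h, l, u in zip(sfs, hm, lvm, uvm):
                rows.append({"observer": obs_id, "condition": cond, "sf_cpd": f,
                             "comparison": "HVA", "value": hva_extent(h, l, u)})
                rows.append({"observer": obs_id, "condition": cond, "sf_cpd": f,
                             "comparison": "VMA", "value": vma_extent(l, u)})
        for tag, scl in (("2v6", 0), ("2v6M", 1)):
            near = [grids[(a, 2.0, 0)] for a in ("HM", "LVM", "UVM")]
            far = [grids[(a, 6.0, scl)] for a in ("HM", "LVM", "UVM")]
            if any(g is None for g in near + far):
                continue
            mean_near = np.mean(near, axis=0)
            mean_far = np.mean(far, axis=0)
            for f, l1, l2 in zip(sfs, mean_near, mean_far):
                rows.append({"observer": obs_id, "condition": tag, "sf_cpd": f,
                             "comparison": f"ecc {tag}", "value": percent_change(l1, l2)})
    return pd.DataFrame(rows)


def asymmetry_summary(
    attributes: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Peak-CS eccentricity effects, HVA and VMA extents per observer and
    condition, with group-level bootstrapped 68% CIs over observers."""
    rows = []
    conditions = [("2", 2.0, 0), ("6", 6.0, 0)]
    if (attributes["scaled"] == 1).any():
        conditions.append(("6_M", 6.0, 1))
    for obs_id, sub in attributes.groupby("observer"):
        def peak(angle, ecc, scaled):
            sel = sub[(sub.angle == angle) & (sub.ecc == ecc) & (sub.scaled == scaled)]
            return float(sel["peak_cs"].iloc[0]) if len(sel) else np.nan

        for name, ecc, scaled in conditions:
            hm, lvm, uvm = (peak(a, ecc, scaled) for a in ("HM", "LVM", "UVM"))
            if not np.isnan([hm, lvm, uvm]).any():
                rows.append({"observer": obs_id, "condition": name,
                             "comparison": "HVA", "value": hva_extent(hm, lvm, uvm)})
                rows.append({"observer": obs_id, "condition": name,
                             "comparison": "VMA", "value": vma_extent(lvm, uvm)})
        for tag, scaled in (("2v6", 0), ("2v6M", 1)):
            vals2 = [peak(a, 2.0, 0) for a in ("HM", "LVM", "UVM")]
            vals6 = [peak(a, 6.0, scaled) for a in ("HM", "LVM", "UVM")]
            if not (np.isnan(vals2).any() or np.isnan(vals6).any()):
                from .asymmetry import percent_change

                rows.append({"observer": obs_id, "condition": tag,
                             "comparison": f"ecc {tag}",
                             "value": percent_change(np.mean(vals2), np.mean(vals6))})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    cis = []
    for (cond, comp), grp in table.groupby(["condition", "comparison"]):
        vals = grp["value"].to_numpy()
        lo, hi = bootstrap_ci(vals, np.mean, level=0.68, n_boot=n_boot, seed=seed)
        cis.append({"condition": cond, "comparison": comp, "mean": vals.mean(),
                    "ci68_lo": lo, "ci68_hi": hi, "n": len(vals)})
    summary = pd.DataFrame(cis)
    return table.merge(summary, on=["condition", "comparison"], how="left")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline; writes tables + manifest under ``out_dir``.

    Deterministic given the configured seeds: re-running with the same
    config yields byte-identical stage outputs (and thus manifest hashes).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "seeds": {
        "sim": config.sim_seed, "fit": config.fit_seed, "bootstrap": config.bootstrap_seed}}
    crf = CRFSpec(kappa=config.kappa, pl=config.pl, pu=config.pu, pt=config.pt)
    opts = FitOptions(n_starts=config.n_starts, seed=config.fit_seed)

    def record(stage: str, path: Path, t0: float) -> None:
        manifest["stages"][stage] = {
            "output": path.name, "sha256": _sha(path), "seconds": round(time.time() - t0, 3)}

    # --- trials ---------------------------------------------------------
    t0 = time.time()
    if config.simulate:
        conditions = _default_conditions(
            config.trials_per_sf_hm, config.trials_per_sf_vm, config.trials_per_sf_mscale
        )
        if not config.include_mscale:
            conditions = tuple(c for c in conditions if c.name != "M-scale")
        frames = []
        for i in range(config.n_observers):
            obs = make_observer(
                config.scenario, observer_id=f"obs{i + 1:02d}",
                include_scaled=config.include_mscale, crf=crf,
            )
            design = ExperimentDesign(
                sfs=config.sfs, conditions=conditions, seed=config.sim_seed + i
            )
            frames.append(simulate_experiment(obs, design))
        trials = pd.concat(frames, ignore_index=True)
    elif config.trials_path:
        trials = read_trials(config.trials_path)
    else:
        raise PipelineError("input", "config requests no simulation and no trials_path")
    if trials.empty:
        raise PipelineError("input", "no trials available")
    trials_path = out / "trials.csv"
    write_trials(trials, trials_path)
    record("trials", trials_path, t0)

    # --- stage 1: CSF form ---------------------------------------------
    t0 = time.time()
    try:
        stage1, winner_form = stage1_csf_selection(trials, config.csf_models, opts, crf)
    except Exception as err:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError("stage1-csf-selection", str(err)) from err
    p = out / "stage1_csf_ranking.csv"
    stage1.to_csv(p, index=False)
    record("stage1", p, t0)
    manifest["stage1_winner"] = winner_form

    # --- stage 2: tying model ------------------------------------------
    t0 = time.time()
    try:
        stage2, _ = stage2_tying_selection(trials, winner_form, opts, crf)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("stage2-tying-selection", str(err)) from err
    p = out / "stage2_tying_ranking.csv"
    stage2.to_csv(p, index=False)
    record("stage2", p, t0)
    manifest["stage2_winner"] = str(stage2["vf_model"].iloc[0])

    # --- attributes -----------------------------------------------------
    t0 = time.time()
    try:
        attributes = observer_attributes(
            trials, winner_form, opts, crf, half_max_on=config.half_max_on
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("attributes", str(err)) from err
    p = out / "attributes.csv"
    attributes.to_csv(p, index=False)
    record("attributes", p, t0)

    # --- asymmetries ----------------------------------------------------
    t0 = time.time()
    try:
        asym = asymmetry_summary(attributes, seed=config.bootstrap_seed)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("asymmetry", str(err)) from err
    p = out / "asymmetries.csv"
    asym.to_csv(p, index=False)
    record("asymmetry", p, t0)

    curves = extent_curves(attributes, config.sfs)
    p = out / "extent_curves.csv"
    curves.to_csv(p, index=False)
    record("extent_curves", p, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(trials, stage1, stage2, attributes, asym, manifest)
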