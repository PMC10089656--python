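"""Ground-truth observers and full-experiment simulation.

An observer owns one CSF per visual-field location cell.  Three knobs shape
the location layout:

* ``ecc_drop`` — fractional loss of peak sensitivity from 2 deg to 6 deg;
* ``hva_pct`` — percent change (symmetric-mean normalization) between the
  HM peak and the mean of the two vertical-meridian peaks;
* ``vma_pct`` — percent change between the LVM and UVM peaks.

The angular knobs are applied by inverting the symmetric percent-change
formula 100*(l1-l2)/(0.5*(l1+l2)), so forward evaluation on the true peak
sensitivities recovers the knob settings exactly.  M-scaled 6-deg cells
receive the 2-deg gain of their meridian by default (scaling restores the
eccentricity effect but not the angular asymmetries).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crf import CRFSpec
from .csf import CSFParamSet, csf_sensitivity
from .fitting import ANGLES, FIXED_CELLS, SCALED_CELLS, LocationCell
from .titration import run_titration

__all__ = [
    "DEFAULT_SFS",
    "DEFAULT_BASE_CSF",
    "SCENARIOS",
    "GroundTruthObserver",
    "ExperimentDesign",
    "ConditionDesign",
    "make_observer",
    "simulate_experiment",
    "TRIAL_COLUMNS",
]

DEFAULT_SFS = (0.5, 1.0, 1.4, 2.0, 2.8, 4.0, 8.0, 11.3)

DEFAULT_BASE_CSF = CSFParamSet(model="LP", alpha=2.0, beta=2.2, delta=80.0)

#: named presets: (ecc_drop, hva_pct, vma_pct)
SCENARIOS = {
    "paper-like": (0.5, 30.0, 15.0),
    "null": (0.0, 0.0, 0.0),
    "no-vma": (0.5, 30.0, 0.0),
}

TRIAL_COLUMNS = (
    "observer",
    "condition",
    "angle",
    "ecc",
    "scaled",
    "sf_cpd",
    "log10_contrast",
    "orientation",
    "response",
    "trial_index",
)


@dataclass(frozen=True)
class GroundTruthObserver:
    observer_id: str
    csf_by_cell: dict[LocationCell, CSFParamSet] = field(hash=False)
    crf: CRFSpec = field(default_factory=CRFSpec)
    ecc_drop: float = 0.0
    hva_pct: float = 0.0
    vma_pct: float = 0.0

    def sensitivity(self, cell: LocationCell, f):
        return csf_sensitivity(self.csf_by_cell[cell], f)

    def true_ct(self, cell: LocationCell, f) -> float:
        """True log10 contrast threshold at (cell, f)."""
        return float(-np.log10(self.sensitivity(cell, f)))


def _ratio_from_pct(pct: float) -> float:
    """Invert p = 100*(l1-l2)/(0.5*(l1+l2)) for the ratio l1/l2."""
    return (200.0 + pct) / (200.0 - pct)


def make_observer(
    scenario: str | None = None,
    *,
    ecc_drop: float = 0.0,
    hva_pct: float = 0.0,
    vma_pct: float = 0.0,
    base: CSFParamSet = DEFAULT_BASE_CSF,
    observer_id: str = "obs1",
    include_scaled: bool = True,
    mscale_restores_ecc: bool = True,
    alpha_shift: float = 1.0,
    crf: CRFSpec | None = None,
) -> GroundTruthObserver:
    """Build a ground-truth observer from a preset or explicit knobs.

    ``base`` sets the 2-deg vertical-meridian-mean CSF; all cells are
    derived by scaling its gain ``delta``.  ``alpha_shift`` optionally
    divides the 6-deg peak frequency (acuity loss mode); 1.0 leaves shape
    untouched.
    """
    if scenario is not None:
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}")
        ecc_drop, hva_pct, vma_pct = SCENARIOS[scenario]
    for name, pct in (("hva_pct", hva_pct), ("vma_pct", vma_pct)):
        if not (-100.0 < pct < 100.0):
            raise ValueError(f"{name} must lie in (-100, 100)")
    if not (0.0 <= ecc_drop < 1.0):
        raise ValueError("ecc_drop must lie in [0, 1)")

    r_hva = _ratio_from_pct(hva_pct)
    r_vma = _ratio_from_pct(vma_pct)
    # vertical-meridian mean gain v: UVM = 2v/(1+r_vma), LVM = r_vma*UVM, HM = r_hva*v
    gains_by_angle = {
        "UVM": 2.0 / (1.0 + r_vma),
        "LVM": 2.0 * r_vma / (1.0 + r_vma),
        "HM": r_hva,
    }

    csf_by_cell: dict[LocationCell, CSFParamSet] = {}
    for cell in FIXED_CELLS:
        gain = gains_by_angle[cell.angle]
        changes = {"delta": base.delta * gain}
        if cell.ecc > 2.0:
            changes["delta"] *= 1.0 - ecc_drop
            if alpha_shift != 1.0:
                changes["alpha"] = base.alpha / alpha_shift
        csf_by_cell[cell] = replace(base, **changes)
    if include_scaled:
        for cell in SCALED_CELLS:
            source = (
                LocationCell(cell.angle, 2.0)
                if mscale_restores_ecc
                else LocationCell(cell.angle, 6.0)
            )
            csf_by_cell[cell] = csf_by_cell[source]

    return GroundTruthObserver(
        observer_id=observer_id,
        csf_by_cell=csf_by_cell,
        crf=crf or CRFSpec(),
        ecc_drop=ecc_drop,
        hva_pct=hva_pct,
        vma_pct=vma_pct,
    )


@dataclass(frozen=True)
class ConditionDesign:
    """One experimental condition: its cells, trial budget, and procedure."""

    name: str
    cells: tuple[LocationCell, ...]
    trials_per_sf: int
    procedure: str

    def __post_init__(self) -> None:
        if self.trials_per_sf < 1:
            raise ValueError("trials_per_sf must be positive")
        if self.procedure not in ("best_pest", "staircase"):
            raise ValueError("procedure must be 'best_pest' or 'staircase'")


def _default_conditions(trials_hm: int, trials_vm: int, trials_ms: int):
    hm_cells = tuple(c for c in FIXED_CELLS if c.angle == "HM")
    vm_cells = tuple(c for c in FIXED_CELLS if c.angle != "HM")
    return (
        ConditionDesign("HM", hm_cells, trials_hm, "staircase"),
        ConditionDesign("VM", vm_cells, trials_vm, "best_pest"),
        ConditionDesign("M-scale", SCALED_CELLS, trials_ms, "best_pest"),
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Experiment layout: SFs, per-condition cells/budgets/procedures, seed.

    Default per-SF trial counts follow the source design (HM 160, VM 140,
    M-scale 84 trials per SF per location).
    """

    sfs: tuple[float, ...] = DEFAULT_SFS
    conditions: tuple[ConditionDesign, ...] = field(
        default_factory=lambda: _default_conditions(160, 140, 84)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        sfs = tuple(float(s) for s in self.sfs)
        if any(s <= 0 for s in sfs) or len(set(sfs)) != len(sfs):
            raise ValueError("SFs must be positive and unique")
        object.__setattr__(self, "sfs", sfs)

    @classmethod
    def small(
        cls,
        trials_per_sf: int = 40,
        seed: int = 0,
        sfs=DEFAULT_SFS,
        include_mscale: bool = True,
    ) -> "ExperimentDesign":
        """Reduced-budget design for tests: same layout, fewer trials."""
        conditions = _default_conditions(trials_per_sf, trials_per_sf, trials_per_sf)
        if not include_mscale:
            conditions = tuple(c for c in conditions if c.name != "M-scale")
        return cls(sfs=sfs, conditions=conditions, seed=seed)


def simulate_experiment(
    observer: GroundTruthObserver, design: ExperimentDesign
) -> pd.DataFrame:
    """Simulate the full experiment; returns the tidy trial table.

    Contrast is titrated independently for every (condition, cell, SF)
    combination with its own spawned random substream, then trials are
    interleaved within each condition by a seeded shuffle (order within a
    combination is preserved, as the adaptive track is sequential).
    Deterministic for a fixed ``design.seed``.
    """
    root = np.random.SeedSequence(design.seed)
    frames = []
    for cond in design.conditions:
        missing = [c.label for c in cond.cells if c not in observer.csf_by_cell]
        if missing:
            raise ValueError(
                f"design condition {cond.name!r} references cells absent from "
                f"the observer: {missing}"
            )
        combo_keys = [(cell, f) for cell in cond.cells for f in design.sfs]
        streams = root.spawn(len(combo_keys) + 1)
        rows = []
        for combo_id, ((cell, f), ss) in enumerate(zip(combo_keys, streams[:-1])):
            rng = np.random.default_rng(ss)
            res = run_titration(
                true_ct=observer.true_ct(cell, f),
                procedure=cond.procedure,
                n_trials=cond.trials_per_sf,
                seed=rng,
                constants=observer.crf,
            )
            tilt = rng.choice([-45, 45], size=cond.trials_per_sf)
            rows.append(
                pd.DataFrame(
                    {
                        "observer": observer.observer_id,
                        "condition": cond.name,
                        "angle": cell.angle,
                        "ecc": cell.ecc,
                        "scaled": int(cell.scaled),
                        "sf_cpd": f,
                        "log10_contrast": res.contrasts,
                        "orientation": tilt,
                        "response": res.responses,
                        "_combo": combo_id,
                    }
                )
            )
        cond_table = pd.concat(rows, ignore_index=True)
        # interleave combos with a seeded shuffle; the sequential order of
        # each adaptive track is preserved by sorting its slots
        slots = np.random.default_rng(streams[-1]).permutation(len(cond_table))
        cond_table["_slot"] = slots
        cond_table["_slot"] = cond_table.groupby("_combo")["_slot"].transform(
            lambda s: np.sort(s.to_numpy())
        )
        cond_table = (
            cond_table.sort_values("_slot", kind="mergesort")
            .drop(columns=["_slot", "_combo"])
            .reset_index(drop=True)
        )
        frames.append(cond_table)
    table = pd.concat(frames, ignore_index=True)
    table["trial_index"] = np.arange(len(table))
    return table[list(TRIAL_COLUMNS)]
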