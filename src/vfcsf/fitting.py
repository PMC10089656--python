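"""Trial-wise maximum-likelihood CSF fitting across visual-field locations.

Each trial is a Bernoulli observation whose success probability comes from
the logistic CRF evaluated at the trial's log10 contrast, with the CRF
threshold tied across spatial frequency by a parametric CSF:

    ct(f, cell) = -log10( S(f; params[group(cell)]) )

Visual-field "tying" models share CSF parameters across location cells.
Because tying partitions the cells, the likelihood separates by group and
each group is optimized independently (bounded quasi-Newton, seeded
multistart, positive parameters in log10 space).

Model comparison uses BIC = k*ln(n) - 2*lnL, lower is better.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .crf import CRFSpec, crf_probability
from .csf import CSFParamSet, csf_sensitivity, n_params, param_specs

__all__ = [
    "ANGLES",
    "LocationCell",
    "FIXED_CELLS",
    "SCALED_CELLS",
    "VisualFieldModelSpec",
    "FitOptions",
    "FitResult",
    "build_tying",
    "full_tying",
    "trials_data_hash",
    "negative_log_likelihood",
    "fit_model",
    "bic",
    "compare_models",
]

ANGLES = ("HM", "LVM", "UVM")
_SENS_FLOOR = 1e-9
_P_EPS = 1e-12


@dataclass(frozen=True, order=True)
class LocationCell:
    """One visual-field location cell: polar angle x eccentricity x scaling.

    Left and right HM presentations map to the single HM cell.
    """

    angle: str
    ecc: float
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.angle not in ANGLES:
            raise ValueError(f"unknown angle {self.angle!r}; expected one of {ANGLES}")
        if self.ecc < 0:
            raise ValueError("eccentricity must be non-negative")

    @property
    def label(self) -> str:
        suffix = "_M" if self.scaled else ""
        return f"{self.angle}_{self.ecc:g}{suffix}"


FIXED_CELLS = tuple(
    LocationCell(angle, ecc) for ecc in (2.0, 6.0) for angle in ANGLES
)
SCALED_CELLS = tuple(LocationCell(angle, 6.0, scaled=True) for angle in ANGLES)


def _angle_groups(hva: bool, vma: bool) -> dict[str, int]:
    # HVA off: HM ties to LVM.  VMA off: UVM ties to LVM.
    groups = {"HM": 0, "LVM": 1, "UVM": 2}
    if not hva:
        groups["HM"] = groups["LVM"]
    if not vma:
        groups["UVM"] = groups["LVM"]
    # compact ids
    remap = {g: i for i, g in enumerate(dict.fromkeys(groups.values()))}
    return {a: remap[g] for a, g in groups.items()}


@dataclass(frozen=True)
class VisualFieldModelSpec:
    """A tying model: which location cells share one CSF parameter set."""

    ecc_flag: bool
    hva_flag: bool
    vma_flag: bool
    csf_model: str
    partition: dict[LocationCell, int] = field(hash=False)

    @property
    def name(self) -> str:
        return "".join(
            ("+" if f else "-") + n
            for f, n in ((self.ecc_flag, "Ecc"), (self.hva_flag, "HVA"), (self.vma_flag, "VMA"))
        )

    @property
    def n_groups(self) -> int:
        return len(set(self.partition.values()))

    @property
    def k(self) -> int:
        """Total free-parameter count."""
        return self.n_groups * n_params(self.csf_model)


def build_tying(
    ecc_flag: bool,
    hva_flag: bool,
    vma_flag: bool,
    csf_model: str,
    cells: tuple[LocationCell, ...] = FIXED_CELLS,
) -> VisualFieldModelSpec:
    """Build the tied-parameter partition over the fixed-size cells.

    Group count = (2 if ecc_flag else 1) x (1 + hva_flag + vma_flag).
    Scaled cells, if included, each get their own group: tying applies to
    the fixed-size conditions only.
    """
    n_params(csf_model)  # validates the label
    angle_map = _angle_groups(hva_flag, vma_flag)
    n_angle = len(set(angle_map.values()))
    partition: dict[LocationCell, int] = {}
    next_extra = (2 if ecc_flag else 1) * n_angle
    for cell in cells:
        if cell.scaled:
            partition[cell] = next_extra
            next_extra += 1
            continue
        ecc_idx = 1 if (ecc_flag and cell.ecc > 2.0) else 0
        partition[cell] = ecc_idx * n_angle + angle_map[cell.angle]
    return VisualFieldModelSpec(ecc_flag, hva_flag, vma_flag, csf_model, partition)


def full_tying(csf_model: str, cells: tuple[LocationCell, ...]) -> VisualFieldModelSpec:
    """Most permissive model over an arbitrary cell set: one group per cell."""
    n_params(csf_model)
    partition = {cell: i for i, cell in enumerate(sorted(set(cells)))}
    return VisualFieldModelSpec(True, True, True, csf_model, partition)


# ---------------------------------------------------------------------------
# likelihood


def _trial_cells(trials: pd.DataFrame) -> pd.Series:
    return trials.apply(
        lambda r: LocationCell(str(r["angle"]), float(r["ecc"]), bool(r["scaled"])), axis=1
    )


def trials_data_hash(trials: pd.DataFrame) -> str:
    """Order-insensitive fingerprint of the trial set used to fit."""
    cols = ["angle", "ecc", "scaled", "sf_cpd", "log10_contrast", "response"]
    rows = trials[cols].copy()
    rows["scaled"] = rows["scaled"].astype(int)
    rec = rows.round(12).to_csv(index=False, header=False).splitlines()
    payload = "\n".join(sorted(rec)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _group_arrays(trials: pd.DataFrame, partition: dict[LocationCell, int]):
    """Split trials into per-group (f, c, y) arrays; error on unknown cells."""
    cells = _trial_cells(trials)
    known = set(partition)
    unknown = sorted({c.label for c in cells if c not in known})
    if unknown:
        raise ValueError(
            f"trials reference unknown cells {unknown}; known cells: "
            f"{sorted(c.label for c in known)}"
        )
    gids = np.array([partition[c] for c in cells])
    out = {}
    f = trials["sf_cpd"].to_numpy(float)
    c = trials["log10_contrast"].to_numpy(float)
    y = trials["response"].to_numpy(float)
    for g in np.unique(gids):
        m = gids == g
        out[int(g)] = (f[m], c[m], y[m])
    return out


def _nll_arrays(f, c, y, params: CSFParamSet, crf: CRFSpec) -> float:
    sens = np.maximum(csf_sensitivity(params, f), _SENS_FLOOR)
    ct = -np.log10(sens)
    p = np.clip(crf_probability(c, crf, ct=ct), _P_EPS, 1.0 - _P_EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


def negative_log_likelihood(
    trials: pd.DataFrame,
    params_by_group: dict[int, CSFParamSet],
    partition: dict[LocationCell, int],
    crf: CRFSpec | None = None,
) -> float:
    """Total negative log-likelihood (nats) of the trials; additive over trials."""
    crf = crf or CRFSpec()
    total = 0.0
    for g, (f, c, y) in _group_arrays(trials, partition).items():
        if g not in params_by_group:
            raise ValueError(f"no parameters supplied for group {g}")
        total += _nll_arrays(f, c, y, params_by_group[g], crf)
    return total


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitOptions:
    """Optimizer options: seeded multistart bounded quasi-Newton (L-BFGS-B)."""

    n_starts: int = 20
    seed: int = 0
    maxiter: int = 400


@dataclass(frozen=True)
class FitResult:
    csf_model: str
    vf_spec: VisualFieldModelSpec
    params_by_group: dict[int, CSFParamSet] = field(hash=False)
    loglik: float
    k: int
    n: int
    bic: float
    converged: dict[int, bool] = field(hash=False)
    n_starts: int
    seed: int
    data_hash: str

    def params_for_cell(self, cell: LocationCell) -> CSFParamSet:
        """The tied parameter object for a cell (identical object across a group)."""
        return self.params_by_group[self.vf_spec.partition[cell]]

    @property
    def success(self) -> bool:
        return all(self.converged.values())


def _transform(values, specs, inverse=False):
    out = []
    for v, s in zip(values, specs, strict=True):
        if s.log:
            out.append(10.0**v if inverse else np.log10(v))
        else:
            out.append(v)
    return np.array(out, dtype=float)


def _fit_group(model, f, c, y, crf, opts) -> tuple[CSFParamSet, float, bool]:
    specs = param_specs(model)
    bounds = [
        (np.log10(s.lo), np.log10(s.hi)) if s.log else (s.lo, s.hi) for s in specs
    ]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x):
        params = CSFParamSet.from_free_values(model, _transform(x, specs, inverse=True))
        return _nll_arrays(f, c, y, params, crf)

    rng = np.random.default_rng(opts.seed)
    # heuristic start: peak near median tested SF, gain from best-seen contrast
    guess = {"alpha": float(np.median(f)), "beta": 2.0, "gamma": 0.5, "delta": 50.0}
    if model == "dEXP":
        guess["alpha"] = 1.0
    if model == "MS":
        guess["beta"] = 0.5
        guess["gamma"] = 2.0
    x_heur = _transform(
        [min(max(guess[s.name], s.lo), s.hi) for s in specs], specs
    )
    starts = [x_heur] + [lo + rng.random(len(specs)) * (hi - lo) for _ in range(opts.n_starts - 1)]

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": opts.maxiter}
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = CSFParamSet.from_free_values(model, _transform(best.x, specs, inverse=True))
    return params, float(best.fun), any_ok


def fit_model(
    trials: pd.DataFrame,
    csf_model: str,
    vf_spec: VisualFieldModelSpec,
    opts: FitOptions | None = None,
    crf: CRFSpec | None = None,
) -> FitResult:
    """Fit one CSF form under one tying model by multistart bounded MLE.

    Deterministic given ``opts.seed``.  Raises if any tied group has no
    trials or if a trial references a cell outside the partition.  A group
    for which no optimizer start converged is flagged in ``converged``.
    """
    if csf_model != vf_spec.csf_model:
        vf_spec = replace(vf_spec, csf_model=csf_model)
    opts = opts or FitOptions()
    crf = crf or CRFSpec()
    groups = _group_arrays(trials, vf_spec.partition)
    missing = set(vf_spec.partition.values()) - set(groups)
    if missing:
        raise ValueError(f"tied groups with no trials: {sorted(missing)}")

    params_by_group: dict[int, CSFParamSet] = {}
    converged: dict[int, bool] = {}
    nll_total = 0.0
    for g, (f, c, y) in sorted(groups.items()):
        gopts = replace(opts, seed=opts.seed + 1009 * g)
        params, nll, ok = _fit_group(csf_model, f, c, y, crf, gopts)
        params_by_group[g] = params
        converged[g] = ok
        nll_total += nll

    n = int(len(trials))
    k = vf_spec.k
    loglik = -nll_total
    return FitResult(
        csf_model=csf_model,
        vf_spec=vf_spec,
        params_by_group=params_by_group,
        loglik=loglik,
        k=k,
        n=n,
        bic=bic_value(k, n, loglik),
        converged=converged,
        n_starts=opts.n_starts,
        seed=opts.seed,
        data_hash=trials_data_hash(trials),
    )


def bic_value(k: int, n: int, loglik: float) -> float:
    """BIC = k*ln(n) - 2*lnL; lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * np.log(n) - 2.0 * loglik


def bic(fit: FitResult) -> float:
    return bic_value(fit.k, fit.n, fit.loglik)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits on one trial set by BIC (delta-BIC relative to the minimum).

    Ties at machine precision break toward the smaller parameter count.
    Raises if the fits were not computed on the same trial set.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different trial sets")
    rows = [
        {
            "csf_model": f.csf_model,
            "vf_model": f.vf_spec.name,
            "k": f.k,
            "n": f.n,
            "loglik": f.loglik,
            "bic": f.bic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows)
    table = table.sort_values(["bic", "k"], kind="mergesort").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    table["rank"] = np.arange(1, len(table) + 1)
    return table
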