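"""Reading and writing the tidy trial-record table.

Column dictionary (schema v1, comma-delimited, header required):

========== ======= ====================================================
column      type    meaning
========== ======= ====================================================
observer    str     observer identifier
condition   str     HM / VM / M-scale
angle       str     polar-angle cell: HM, LVM or UVM
ecc         float   eccentricity in degrees
scaled      0/1     1 for the M-scaled condition
sf_cpd      float   spatial frequency, cycles per degree
log10_contrast float  log10 Michelson contrast (<= 0)
orientation int     tilt in degrees (optional; +-45)
response    0/1     1 = correct
trial_index int     presentation order (optional)
========== ======= ====================================================
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .fitting import ANGLES

__all__ = ["REQUIRED_COLUMNS", "read_trials", "write_trials", "TrialValidationError"]

REQUIRED_COLUMNS = (
    "observer",
    "condition",
    "angle",
    "ecc",
    "scaled",
    "sf_cpd",
    "log10_contrast",
    "response",
)


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema; lists offending lines."""


def _validate(table: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialValidationError(f"{source}: missing required columns {missing}")
    problems: list[str] = []
    # data lines start at 2 (line 1 is the header)
    lines = table.index.to_numpy() + 2
    resp = pd.to_numeric(table["response"], errors="coerce")
    bad = ~resp.isin([0, 1])
    for ln in lines[bad.to_numpy()]:
        problems.append(f"line {ln}: response must be 0 or 1")
    bad_angle = ~table["angle"].isin(ANGLES)
    for ln in lines[bad_angle.to_numpy()]:
        problems.append(f"line {ln}: unknown cell angle (expected one of {ANGLES})")
    for col in ("ecc", "sf_cpd", "log10_contrast"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad_num = vals.isna()
        for ln in lines[bad_num.to_numpy()]:
            problems.append(f"line {ln}: non-numeric {col}")
    if problems:
        head = "; ".join(problems[:20])
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        raise TrialValidationError(f"{source}: {head}{more}")
    table = table.copy()
    table["response"] = resp.astype(int)
    table["scaled"] = pd.to_numeric(table["scaled"]).astype(int)
    for col in ("ecc", "sf_cpd", "log10_contrast"):
        table[col] = pd.to_numeric(table[col]).astype(float)
    return table


def read_trials(path) -> pd.DataFrame:
    """Read and validate a tidy trial table; empty files give an empty table."""
    path = Path(path)
    table = pd.read_csv(path)
    if table.empty:
        warnings.warn(f"{path}: no trial records", stacklevel=2)
        for col in REQUIRED_COLUMNS:
            if col not in table.columns:
                table[col] = pd.Series(dtype=float)
        return table
    return _validate(table, str(path))


def write_trials(table: pd.DataFrame, path) -> None:
    """Write the tidy trial table as comma-delimited text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
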