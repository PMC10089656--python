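"""Candidate contrast sensitivity function (CSF) forms and attribute extraction.

Nine parametric forms map spatial frequency f (cpd) to contrast sensitivity
(inverse contrast threshold).  Three forms (LP, dEXP) use three parameters;
the rest use four.  Sensitivity values that would be algebraically negative
(possible for the difference-type forms) are clipped to zero.

NOTE on YQM, aLP and MS: the source table for these three rows is garbled in
extraction, so canonical published forms from the cited CSF-modeling
literature are implemented instead and pinned by unit tests:

* aLP — log parabola with separate left (beta) and right (gamma) octave
  widths split at the peak frequency alpha;
* MS  — delta * (1 - beta + f/alpha) * exp(-(f/alpha)**gamma);
* YQM — delta * exp(-f/alpha) / (1 + gamma / (1 + (f/beta)**2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "CSF_MODELS",
    "CSFParamSet",
    "CSFAttributes",
    "ParamSpec",
    "param_specs",
    "n_params",
    "csf_sensitivity",
    "extract_attributes",
]


@dataclass(frozen=True)
class ParamSpec:
    """One free parameter: name, bounds, and whether it is fit in log space."""

    name: str
    lo: float
    hi: float
    log: bool = True


_SCALE = ParamSpec("alpha", 0.05, 60.0)
_WIDTH_B = ParamSpec("beta", 0.05, 60.0)
_GAIN = ParamSpec("delta", 1.0, 2000.0)

#: model -> ordered free-parameter specs
_PARAM_SPECS: dict[str, tuple[ParamSpec, ...]] = {
    "LP": (_SCALE, ParamSpec("beta", 0.1, 10.0), _GAIN),
    "aLP": (_SCALE, ParamSpec("beta", 0.1, 10.0), ParamSpec("gamma", 0.1, 10.0, log=True), _GAIN),
    "dEXP": (ParamSpec("alpha", 0.0, 4.0, log=False), _WIDTH_B, _GAIN),
    "DoG": (_SCALE, _WIDTH_B, ParamSpec("gamma", 0.0, 1.0, log=False), _GAIN),
    "HmH": (_SCALE, _WIDTH_B, ParamSpec("gamma", 0.0, 1.0, log=False), _GAIN),
    "HmG": (_SCALE, _WIDTH_B, ParamSpec("gamma", 0.0, 1.0, log=False), _GAIN),
    "EmG": (_SCALE, _WIDTH_B, ParamSpec("gamma", 0.0, 1.0, log=False), _GAIN),
    "YQM": (_SCALE, _WIDTH_B, ParamSpec("gamma", 0.0, 10.0, log=False), _GAIN),
    "MS": (_SCALE, ParamSpec("beta", 0.0, 1.0, log=False), ParamSpec("gamma", 0.25, 8.0, log=False), _GAIN),
}

CSF_MODELS = tuple(_PARAM_SPECS)


def param_specs(model: str) -> tuple[ParamSpec, ...]:
    try:
        return _PARAM_SPECS[model]
    except KeyError:
        raise ValueError(f"unknown CSF model {model!r}; expected one of {CSF_MODELS}") from None


def n_params(model: str) -> int:
    """Free-parameter count of the named form (3 or 4)."""
    return len(param_specs(model))


@dataclass(frozen=True)
class CSFParamSet:
    """A named CSF form with its parameters.

    ``gamma`` is None for the 3-parameter forms (LP, dEXP).
    """

    model: str
    alpha: float
    beta: float
    delta: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        specs = param_specs(self.model)
        has_gamma = any(s.name == "gamma" for s in specs)
        if has_gamma and self.gamma is None:
            raise ValueError(f"{self.model} requires gamma")
        if not has_gamma and self.gamma is not None:
            raise ValueError(f"{self.model} takes no gamma")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        # MS's beta is a linear offset in [0, 1); elsewhere beta is a scale
        if self.model == "MS":
            if self.beta < 0:
                raise ValueError("MS offset beta must be non-negative")
        elif not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.model != "dEXP" and not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.model == "dEXP" and self.alpha < 0:
            raise ValueError("dEXP exponent alpha must be non-negative")

    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, s.name) for s in param_specs(self.model))

    @classmethod
    def from_free_values(cls, model: str, values) -> "CSFParamSet":
        kw = {s.name: float(v) for s, v in zip(param_specs(model), values, strict=True)}
        return cls(model=model, **kw)


def _sech(x):
    return 1.0 / np.cosh(x)


def _eval(model: str, f, a: float, b: float, g: float | None, d: float):
    if model == "LP":
        return d * np.exp(-((np.log2(f / a) / b) ** 2))
    if model == "aLP":
        width = np.where(f < a, b, g)
        return d * np.exp(-((np.log2(f / a) / width) ** 2))
    if model == "dEXP":
        return d * f**a * np.exp(-f / b)
    if model == "DoG":
        return d * (np.exp(-((f / a) ** 2)) - g * np.exp(-((f / b) ** 2)))
    if model == "HmH":
        return d * (_sech(f / a) - g * _sech(f / b))
    if model == "HmG":
        return d * (_sech(f / a) - g * np.exp(-((f / b) ** 2)))
    if model == "EmG":
        return d * (np.exp(-f / a) - g * np.exp(-((f / b) ** 2)))
    if model == "YQM":
        return d * np.exp(-f / a) / (1.0 + g / (1.0 + (f / b) ** 2))
    if model == "MS":
        return d * (1.0 - b + f / a) * np.exp(-((f / a) ** g))
    raise ValueError(f"unknown CSF model {model!r}; expected one of {CSF_MODELS}")


def csf_sensitivity(params: CSFParamSet, f):
    """Contrast sensitivity at spatial frequency ``f`` (cpd); clipped at 0.

    Vectorized over ``f``; scalar in, scalar out.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("spatial frequency must be positive")
    out = np.maximum(
        _eval(params.model, f_arr, params.alpha, params.beta, params.gamma, params.delta),
        0.0,
    )
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class CSFAttributes:
    """Summary attributes of a CSF over an evaluation window.

    ``cutoff_sf`` is NaN when sensitivity never crosses 1 from above inside
    the window (flag ``cutoff-below-window``) and set to the upper window
    edge with flag ``cutoff-above-window`` when sensitivity is still above 1
    there.  ``bandwidth`` is the octave span where log10 sensitivity exceeds
    half the log10 peak (clipped to the window, flagged if so).
    """

    peak_cs: float
    peak_sf: float
    cutoff_sf: float
    aulcsf: float
    bandwidth: float
    flags: tuple[str, ...] = field(default=())


def _largest_crossing(fgrid: np.ndarray, vals: np.ndarray, level: float) -> float | None:
    """Rightmost downward crossing of ``vals`` through ``level``; None if absent."""
    above = vals >= level
    idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        return None
    i = idx[-1]
    return brentq(lambda x: float(np.interp(x, fgrid, vals)) - level, fgrid[i], fgrid[i + 1], xtol=1e-12)


def extract_attributes(
    params: CSFParamSet,
    f_lo: float = 0.25,
    f_hi: float = 24.0,
    n_grid: int = 512,
    half_max_on: str = "log",
) -> CSFAttributes:
    """Extract peak-CS, peak-SF, cutoff-SF, AULCSF and bandwidth.

    Sensitivity is scanned on ``n_grid`` log-spaced points over
    [``f_lo``, ``f_hi``], the peak is refined by bounded scalar
    minimization in log2-frequency, and the unit crossing is bracketed and
    root-found.  AULCSF integrates log10 sensitivity (clipped at 0) against
    log10 frequency.  ``half_max_on`` selects whether the bandwidth's
    half-maximum criterion applies to log10 sensitivity (default, per
    common qCSF practice) or linear sensitivity.
    """
    if half_max_on not in ("log", "linear"):
        raise ValueError("half_max_on must be 'log' or 'linear'")
    if not (0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")

    x = np.linspace(np.log2(f_lo), np.log2(f_hi), n_grid)  # octave axis
    fgrid = 2.0**x
    sens = csf_sensitivity(params, fgrid)
    flags: list[str] = []

    # peak: bracket around the best grid point, then golden-section refine
    i = int(np.argmax(sens))
    if i in (0, n_grid - 1):
        flags.append("peak-at-edge")
        peak_x = x[i]
        peak_cs = float(sens[i])
    else:
        res = minimize_scalar(
            lambda xx: -csf_sensitivity(params, 2.0**xx),
            bounds=(x[i - 1], x[i + 1]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        peak_x = float(res.x)
        peak_cs = float(-res.fun)
        if sens[i] > peak_cs:  # refinement must never lose to the grid
            peak_x, peak_cs = x[i], float(sens[i])
    peak_sf = 2.0**peak_x

    # cutoff: rightmost downward unit crossing
    dense_sens = lambda xx: csf_sensitivity(params, 2.0**xx)
    if peak_cs < 1.0:
        cutoff = math.nan
        flags.append("cutoff-below-window")
    elif sens[-1] >= 1.0:
        cutoff = f_hi
        flags.append("cutoff-above-window")
    else:
        above = sens >= 1.0
        idx = np.nonzero(above[:-1] & ~above[1:])[0]
        i_cross = idx[-1]
        x_cut = brentq(lambda xx: dense_sens(xx) - 1.0, x[i_cross], x[i_cross + 1], xtol=1e-13)
        cutoff = 2.0**x_cut

    # AULCSF: trapezoid of clipped log10 sensitivity against log10 f
    log_s = np.log10(np.maximum(sens, 1e-300))
    aul = float(np.trapezoid(np.clip(log_s, 0.0, None), x * math.log10(2.0)))

    # bandwidth at half maximum
    if half_max_on == "log" and peak_cs > 1.0:
        level_fun = lambda xx: np.log10(np.maximum(dense_sens(xx), 1e-300))
        vals = log_s
        half = 0.5 * math.log10(peak_cs)
    else:
        level_fun = dense_sens
        vals = sens
        half = 0.5 * peak_cs
        if half_max_on == "log":
            flags.append("bandwidth-linear-fallback")  # log10(peak) <= 0

    left = x[0]
    right = x[-1]
    below = np.nonzero((vals < half) & (x < peak_x))[0]
    if below.size:
        j = below[-1]
        left = brentq(lambda xx: float(level_fun(xx)) - half, x[j], min(x[j + 1], peak_x), xtol=1e-13)
    else:
        flags.append("bandwidth-left-at-edge")
    above_r = np.nonzero((vals < half) & (x > peak_x))[0]
    if above_r.size:
        j = above_r[0]
        right = brentq(lambda xx: float(level_fun(xx)) - half, max(x[j - 1], peak_x), x[j], xtol=1e-13)
    else:
        flags.append("bandwidth-right-at-edge")
    bandwidth = max(right - left, 0.0)

    return CSFAttributes(
        peak_cs=peak_cs,
        peak_sf=peak_sf,
        cutoff_sf=cutoff,
        aulcsf=aul,
        bandwidth=bandwidth,
        flags=tuple(flags),
    )
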