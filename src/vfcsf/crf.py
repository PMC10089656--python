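"""Logistic contrast-response function (CRF) with fixed slope and asymptotes.

Performance as a function of log10 Michelson contrast is modeled as

    p(c) = s / (1 + exp(-kappa * (c - t))) + pl

where ``s = 1 - (1 - pu) - pl`` scales the dynamic range and ``t`` is a
transformed threshold chosen so that ``p(ct) == pt`` exactly for the
nominal threshold ``ct``:

    t = ct - (1/kappa) * ln(pr / (1 - pr)),   pr = (pt - pl) / s

The natural log is required here (the logistic's own base); any other base
breaks the targeting identity.  All contrasts are log10-transformed
Michelson contrast, conventionally within [-3, 0].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CRFSpec",
    "dynamic_range",
    "threshold_transform",
    "crf_probability",
    "sample_response",
]


@dataclass(frozen=True)
class CRFSpec:
    """CRF constants plus an optional location/SF-dependent threshold ``ct``.

    Defaults match a titration procedure targeting 75% correct in a 2AFC
    task: slope ``kappa`` = 11.8 per log10-contrast unit, guess rate
    ``pl`` = 0.5, upper asymptote ``pu`` = 0.99 (lapses absorbed into pu).
    """

    kappa: float = 11.8
    pl: float = 0.5
    pu: float = 0.99
    pt: float = 0.75
    ct: float | None = None

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not (0.0 <= self.pl < self.pt < self.pu <= 1.0):
            raise ValueError("asymptotes must satisfy 0 <= pl < pt < pu <= 1")
        s = self.s
        if not (0.0 < s <= 1.0):
            raise ValueError("dynamic range s must lie in (0, 1]")
        pr = self.pr
        if not (0.0 < pr < 1.0):
            raise ValueError("performance ratio pr must lie in (0, 1)")

    @property
    def s(self) -> float:
        """Dynamic range of the function."""
        return dynamic_range(self.pl, self.pu)

    @property
    def pr(self) -> float:
        """Targeted performance as a fraction of the dynamic range."""
        return (self.pt - self.pl) / self.s


def dynamic_range(pl: float, pu: float) -> float:
    """``s = 1 - (1 - pu) - pl``; the probability mass the logistic spans."""
    if not (0.0 <= pl < pu <= 1.0):
        raise ValueError("require 0 <= pl < pu <= 1")
    return 1.0 - (1.0 - pu) - pl


def threshold_transform(ct, spec: CRFSpec):
    """Map a nominal threshold ``ct`` to the logistic midpoint ``t``.

    Guarantees that the CRF evaluated at ``c = ct`` returns ``spec.pt``.
    Accepts scalars or arrays.
    """
    pr = spec.pr
    return np.asarray(ct, dtype=float) - np.log(pr / (1.0 - pr)) / spec.kappa


def crf_probability(c, spec: CRFSpec, ct=None):
    """Probability correct at log10 contrast ``c``.

    ``ct`` overrides ``spec.ct``; one of the two must be given.  Vectorized
    over ``c`` and/or ``ct`` (broadcasting); returns a scalar for scalar
    inputs.
    """
    if ct is None:
        ct = spec.ct
    if ct is None:
        raise ValueError("a contrast threshold ct is required (in spec or argument)")
    c = np.asarray(c, dtype=float)
    t = threshold_transform(ct, spec)
    p = spec.s / (1.0 + np.exp(-spec.kappa * (c - t))) + spec.pl
    if p.ndim == 0:
        return float(p)
    return p


def sample_response(p, rng: np.random.Generator):
    """Draw Bernoulli responses (1 = correct) with probability ``p``.

    Vectorized; reproducible given a seeded ``numpy.random.Generator``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    draws = (rng.random(p.shape) < p).astype(np.int8)
    if p.ndim == 0:
        return int(draws)
    return draws
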