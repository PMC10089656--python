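"""Linear cortical magnification along the principal meridians and M-scaling.

Linear cortical magnification M(E) gives millimeters of V1 per degree of
visual angle at eccentricity E.  A peripheral stimulus can be enlarged in
inverse proportion to M so that its cortical representation matches that of
a reference stimulus at a smaller eccentricity ("M-scaling").  The vertical
meridians have their own coefficient pairs; the horizontal meridian is
handled by averaging the nasal- and temporal-meridian scaled sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MagnificationModel",
    "ScalingRequest",
    "DEFAULT_M0",
    "MERIDIANS",
    "SCALE_MERIDIANS",
    "default_models",
    "magnification",
    "mscaled_size",
]

DEFAULT_M0 = 7.99
"""Foveal magnification in mm per degree."""

MERIDIANS = ("nasal", "temporal", "LVM", "UVM")
SCALE_MERIDIANS = ("HM", "LVM", "UVM")

#: (linear, cubic) eccentricity coefficients per meridian.
_COEFFICIENTS = {
    "LVM": (0.42, 0.000055),
    "UVM": (0.42, 0.00012),
    "nasal": (0.33, 0.00007),
    "temporal": (0.29, 0.000012),
}


@dataclass(frozen=True)
class MagnificationModel:
    """Inverse-polynomial magnification model for one half meridian.

    ``M(E) = m0 / (1 + a*E + b*E**3)`` with ``m0`` in mm/deg, ``a`` per
    degree and ``b`` per cubic degree.
    """

    meridian: str
    a: float
    b: float
    m0: float = DEFAULT_M0

    def __post_init__(self) -> None:
        if self.meridian not in MERIDIANS:
            raise ValueError(
                f"unknown meridian {self.meridian!r}; expected one of {MERIDIANS}"
            )
        if not self.m0 > 0:
            raise ValueError("m0 must be positive")
        if not self.a > 0:
            raise ValueError("linear coefficient a must be positive")
        if self.b < 0:
            raise ValueError("cubic coefficient b must be non-negative")


@dataclass(frozen=True)
class ScalingRequest:
    """Request to M-scale a stimulus from one eccentricity to another."""

    meridian: str
    base_size: float
    base_ecc: float
    target_ecc: float

    def __post_init__(self) -> None:
        if self.meridian not in SCALE_MERIDIANS:
            raise ValueError(
                f"unknown meridian {self.meridian!r}; expected one of {SCALE_MERIDIANS}"
            )
        if not self.base_size > 0:
            raise ValueError("base_size must be positive")
        if self.base_ecc < 0 or self.target_ecc < 0:
            raise ValueError("eccentricities must be non-negative")


def default_models(m0: float = DEFAULT_M0) -> dict[str, MagnificationModel]:
    """Meridian-specific magnification models with the standard coefficients."""
    return {
        name: MagnificationModel(name, a, b, m0)
        for name, (a, b) in _COEFFICIENTS.items()
    }


def magnification(model: MagnificationModel, ecc: float) -> float:
    """Linear cortical magnification in mm/deg at eccentricity ``ecc`` (deg).

    Strictly decreasing in eccentricity; ``magnification(model, 0) == model.m0``.
    """
    if ecc < 0:
        raise ValueError("eccentricity must be non-negative")
    return model.m0 / (1.0 + model.a * ecc + model.b * ecc**3)


def _scaled_along(model: MagnificationModel, req: ScalingRequest) -> float:
    return req.base_size * (
        magnification(model, req.base_ecc) / magnification(model, req.target_ecc)
    )


def mscaled_size(
    req: ScalingRequest,
    models: dict[str, MagnificationModel] | None = None,
) -> float:
    """Stimulus size (deg) at ``target_ecc`` matching the cortical extent of
    ``base_size`` at ``base_ecc`` along ``req.meridian``.

    For the vertical meridians the size scales by the magnification ratio of
    that meridian's model.  For the HM, the nasal- and temporal-scaled sizes
    are averaged.  Full precision is returned; round at the reporting layer.
    """
    if models is None:
        models = default_models()
    if req.meridian == "HM":
        missing = [m for m in ("nasal", "temporal") if m not in models]
        if missing:
            raise ValueError(f"HM scaling requires nasal and temporal models; missing {missing}")
        return 0.5 * (
            _scaled_along(models["nasal"], req) + _scaled_along(models["temporal"], req)
        )
    if req.meridian not in models:
        raise ValueError(
            f"no magnification model for {req.meridian!r}; have {sorted(models)}"
        )
    return _scaled_along(models[req.meridian], req)
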