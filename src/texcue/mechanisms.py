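"""Cone-contrast algebra for the three post-receptoral cardinal mechanisms.

Patch colours are expressed as Weber cone contrasts against the mid-grey
background: ``(dL/L, dM/M, dS/S)`` for the long-, middle- and short-wavelength
cones.  Three post-receptoral mechanisms read these out:

* ``LUM``  — luminance, the weighted sum ``(k*Lc + Mc) / (k + 1)``, where the
  observer-specific weight ``k`` sets the relative L and M inputs (measured
  per observer at isoluminance, shipped here as a fixture table);
* ``L-M``  — the red-green opponent difference ``Lc - Mc``;
* ``S``    — the violet-lime opponent difference ``Sc - (Lc + Mc) / 2``.

A *mechanism-isolating* stimulus drives exactly one of these while nulling the
other two.  This module builds such stimuli for the three colour/luminance
cues (Dark = luminance decrement, Red = L-M increment, Violet = S increment),
computes each cue's contrast metric, and converts cone contrasts to linear
display primaries through a calibration matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTransformError,
    GamutError,
    InconsistentCueError,
    InvalidCueError,
)

__all__ = [
    "COLOUR_CUES",
    "CUE_KINDS",
    "ConeContrastVector",
    "CueSpec",
    "DisplayCalibration",
    "MechanismVector",
    "cone_to_mechanism",
    "cone_to_primary",
    "cue_contrast",
    "isolating_cone_contrast",
    "load_isoluminance_table",
    "mechanism_matrix",
    "mechanism_to_cone",
]

#: Cue kinds in canonical order; the first three live on colour-space axes,
#: Texture is a second-order (contrast-modulation) cue handled by `stimulus`.
CUE_KINDS = ("Dark", "Red", "Violet", "Texture")
COLOUR_CUES = ("Dark", "Red", "Violet")

_ISOLATION_TOL = 1e-9  # consistency tolerance for the Dark common contrast


def _check_k(k: float) -> None:
    if not (math.isfinite(k) and k > 0):
        raise InvalidCueError(f"luminance weight k must be finite and > 0, got {k!r}")


@dataclass(frozen=True)
class ConeContrastVector:
    """Weber cone contrasts of a patch against the background.

    Components are dimensionless; the background itself is ``(0, 0, 0)``.
    """

    l_contrast: float
    m_contrast: float
    s_contrast: float

    def __post_init__(self):
        for name in ("l_contrast", "m_contrast", "s_contrast"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.l_contrast, self.m_contrast, self.s_contrast], dtype=float
        )

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "ConeContrastVector":
        l, m, s = (float(v) for v in a)
        return cls(l, m, s)


@dataclass(frozen=True)
class MechanismVector:
    """Responses of the three cardinal mechanisms for a given weight k."""

    lum: float
    lm: float
    s: float
    k: float

    def __post_init__(self):
        _check_k(self.k)
        for name in ("lum", "lm", "s"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.lum, self.lm, self.s], dtype=float)

    def isolates(self, atol: float = 1e-12) -> bool:
        """True if exactly one mechanism responds (within atol)."""
        nonzero = np.abs(self.as_array()) > atol
        return int(nonzero.sum()) == 1


@dataclass(frozen=True)
class CueSpec:
    """A cue kind plus its contrast on that cue's own metric.

    Dark is applied as a decrement; Red, Violet and Texture as increments.
    """

    cue_kind: str
    contrast: float

    def __post_init__(self):
        if self.cue_kind not in CUE_KINDS:
            raise InvalidCueError(
                f"unknown cue kind {self.cue_kind!r}; expected one of {CUE_KINDS}"
            )
        if not (math.isfinite(self.contrast) and self.contrast >= 0):
            raise InvalidCueError(
                f"cue contrast must be finite and >= 0, got {self.contrast!r}"
            )


def mechanism_matrix(k: float) -> np.ndarray:
    """3x3 matrix mapping cone contrasts to (LUM, L-M, S) responses."""
    _check_k(k)
    return np.array(
        [
            [k / (k + 1.0), 1.0 / (k + 1.0), 0.0],
            [1.0, -1.0, 0.0],
            [-0.5, -0.5, 1.0],
        ]
    )


def cone_to_mechanism(cc: ConeContrastVector, k: float) -> MechanismVector:
    """Project a cone-contrast vector onto the three cardinal mechanisms."""
    _check_k(k)
    lum, lm, s = mechanism_matrix(k) @ cc.as_array()
    return MechanismVector(lum=lum, lm=lm, s=s, k=k)


def mechanism_to_cone(mv: MechanismVector) -> ConeContrastVector:
    """Invert :func:`cone_to_mechanism` for the vector's own k."""
    m = mechanism_matrix(mv.k)
    # cond guards against a pathological k making the system near-singular
    if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
        raise DegenerateTransformError(
            f"mechanism matrix is numerically singular for k={mv.k}"
        )
    return ConeContrastVector.from_array(np.linalg.solve(m, mv.as_array()))


# Row selecting each cue's contrast metric in the isolation solve:
# Dark pins the (common) L-cone contrast, Red the L-M cone difference,
# Violet the raw S-cone contrast.  Dark is a decrement, hence sign -1.
_CUE_METRIC_ROW = {
    "Dark": (np.array([1.0, 0.0, 0.0]), -1.0),
    "Red": (np.array([1.0, -1.0, 0.0]), +1.0),
    "Violet": (np.array([0.0, 0.0, 1.0]), +1.0),
}
_TARGET_INDEX = {"Dark": 0, "Red": 1, "Violet": 2}  # row of mechanism_matrix


def isolating_cone_contrast(
    cue_kind: str, contrast: float, k: float
) -> ConeContrastVector:
    """Cone contrasts that drive one mechanism only, at a given cue contrast.

    Solves the linear system that zeroes the two non-target mechanism
    responses while pinning the cue's own contrast metric to ``contrast``.

    Parameters
    ----------
    cue_kind : {"Dark", "Red", "Violet"}
        Target axis; Texture is not a colour-axis cue and is rejected.
    contrast : float
        Cue contrast (>= 0) on the metric of ``cue_kind``.
    k : float
        Observer L:M luminance weight (> 0).
    """
    if cue_kind == "Texture":
        raise InvalidCueError(
            "Texture is a second-order cue; it has no colour-axis direction "
            "(use stimulus.texture_patch)"
        )
    if cue_kind not in COLOUR_CUES:
        raise InvalidCueError(
            f"unknown cue kind {cue_kind!r}; expected one of {COLOUR_CUES}"
        )
    if not (math.isfinite(contrast) and contrast >= 0):
        raise InvalidCueError(f"contrast must be finite and >= 0, got {contrast!r}")
    _check_k(k)

    m = mechanism_matrix(k)
    target = _TARGET_INDEX[cue_kind]
    metric_row, sign = _CUE_METRIC_ROW[cue_kind]
    a = np.vstack([m[[i for i in range(3) if i != target]], metric_row])
    b = np.array([0.0, 0.0, sign * contrast])
    return ConeContrastVector.from_array(np.linalg.solve(a, b))


def cue_contrast(cue_kind: str, cc: ConeContrastVector) -> float:
    """Contrast of a cone-contrast vector on a cue's own metric.

    Dark reads the common cone contrast (all three cones must agree to
    within 1e-9), Red the absolute L-M cone difference, Violet the absolute
    S-cone contrast.
    """
    arr = cc.as_array()
    if cue_kind == "Dark":
        if np.ptp(arr) > _ISOLATION_TOL:
            raise InconsistentCueError(
                "Dark requires equal contrast in all three cones; got "
                f"spread {np.ptp(arr):.3e}"
            )
        return float(abs(arr[0]))
    if cue_kind == "Red":
        return float(abs(cc.l_contrast - cc.m_contrast))
    if cue_kind == "Violet":
        return float(abs(cc.s_contrast))
    raise InvalidCueError(
        f"no contrast metric for cue kind {cue_kind!r}; expected one of {COLOUR_CUES}"
    )


# ---------------------------------------------------------------------------
# Display calibration


def _default_lms_to_primary() -> np.ndarray:
    """sRGB-like default: Hunt-Pointer-Estevez cone matrix o sRGB-to-XYZ."""
    xyz_to_lms = np.array(
        [
            [0.38971, 0.68898, -0.07868],
            [-0.22981, 1.18340, 0.04641],
            [0.0, 0.0, 1.0],
        ]
    )
    rgb_to_xyz = np.array(
        [
            [0.4124, 0.3576, 0.1805],
            [0.2126, 0.7152, 0.0722],
            [0.0193, 0.1192, 0.9505],
        ]
    )
    return np.linalg.inv(xyz_to_lms @ rgb_to_xyz)


@dataclass(frozen=True)
class DisplayCalibration:
    """Linear map between cone excitations and display primaries.

    The 3x3 ``lms_to_primary_matrix`` stands in for the full spectral
    calibration (cone fundamentals x phosphor spectra); the background is the
    mid-grey anchor against which all cone contrasts are defined.
    """

    background_chromaticity: tuple[float, float] = (0.282, 0.311)
    background_luminance: float = 40.0  # cd/m^2
    lms_to_primary_matrix: np.ndarray = field(
        default_factory=_default_lms_to_primary
    )
    background_primaries: np.ndarray = field(
        default_factory=lambda: np.full(3, 0.5)
    )
    observer_k: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.lms_to_primary_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("lms_to_primary_matrix must be 3x3")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise ValueError("lms_to_primary_matrix must be invertible")
        object.__setattr__(self, "lms_to_primary_matrix", m)
        bg = np.asarray(self.background_primaries, dtype=float)
        if bg.shape != (3,):
            raise ValueError("background_primaries must have 3 entries")
        if np.any(bg <= 0.05) or np.any(bg >= 0.95):
            raise ValueError(
                "background must map to mid-range primaries (0.05-0.95)"
            )
        object.__setattr__(self, "background_primaries", bg)
        _check_k(self.observer_k)

    @property
    def background_lms(self) -> np.ndarray:
        return np.linalg.solve(self.lms_to_primary_matrix, self.background_primaries)

    def to_json(self) -> str:
        return json.dumps(
            {
                "background_chromaticity": list(self.background_chromaticity),
                "background_luminance": self.background_luminance,
                "lms_to_primary_matrix": self.lms_to_primary_matrix.tolist(),
                "background_primaries": self.background_primaries.tolist(),
                "observer_k": self.observer_k,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DisplayCalibration":
        d = json.loads(text)
        return cls(
            background_chromaticity=tuple(d["background_chromaticity"]),
            background_luminance=float(d["background_luminance"]),
            lms_to_primary_matrix=np.asarray(d["lms_to_primary_matrix"]),
            background_primaries=np.asarray(d["background_primaries"]),
            observer_k=float(d.get("observer_k", 1.0)),
        )


_PRIMARY_NAMES = ("R", "G", "B")


def cone_to_primary(
    cc: ConeContrastVector, cal: DisplayCalibration
) -> np.ndarray:
    """Convert cone contrasts to linear primary intensities in [0, 1].

    Affine in the cone contrasts: the background (zero contrast) maps to the
    calibration's background primaries.  An out-of-gamut request raises
    :class:`GamutError` naming the offending channel — never silently clamped,
    because clamping would corrupt the cue-contrast metric.
    """
    lms = cal.background_lms * (1.0 + cc.as_array())
    p = cal.lms_to_primary_matrix @ lms
    for name, v in zip(_PRIMARY_NAMES, p):
        if v < 0.0 or v > 1.0:
            raise GamutError(
                f"primary {name} = {v:.4f} outside [0, 1] gamut", channel=name
            )
    return p


def load_isoluminance_table() -> pd.DataFrame:
    """Per-observer isoluminance fixture: columns observer, k, lum_s_ratio."""
    with resources.files("texcue.data").joinpath(
        "isoluminance.csv"
    ).open() as fh:
        return pd.read_csv(fh, comment="#")
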