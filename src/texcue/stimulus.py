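"""Lattice stimuli: ringed circles on a diagonal grid carrying one cue each.

The display is a disc-shaped grid of small circles laid out on a square
lattice rotated 45 degrees, so circles form runs along the two oblique axes
(separation 0.68 deg obliquely, 0.96 deg cardinally at the reference viewing
geometry).  Cues occupy alternate oblique rows; the perceptual task is which
oblique orientation looks more salient.

Two presentation pages alternate at the frame rate.  In the Separate
condition a cue pattern alternates with a blank mid-grey page; in the
Combined condition the two cue patterns alternate with each other.  Either
way the temporal average carries each cue at half its nominal contrast, and
contrasts are reported as the halved (effective) values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EmptyLatticeError, GamutError, InvalidCueError
from .mechanisms import (
    COLOUR_CUES,
    ConeContrastVector,
    CueSpec,
    DisplayCalibration,
    cone_to_primary,
    isolating_cone_contrast,
)

__all__ = [
    "ContrastLadder",
    "FramePair",
    "Lattice",
    "LatticeGeometry",
    "StimulusSpec",
    "assign_cues",
    "build_lattice",
    "make_ladder",
    "render",
    "texture_patch",
]

ORIENTATIONS = ("left-oblique", "right-oblique")


@dataclass(frozen=True)
class LatticeGeometry:
    """Geometry of the circle grid, in degrees of visual angle."""

    grid_diameter: float = 8.9
    circle_diameter: float = 0.383
    oblique_separation: float = 0.68
    cardinal_separation: float = 0.96
    ring_width_px: int = 1
    pixels_per_degree: float = 40.0

    def __post_init__(self):
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be > 0")
        if self.circle_diameter >= self.oblique_separation:
            raise ValueError("circles must be smaller than their separation")
        expected = self.oblique_separation * math.sqrt(2.0)
        if abs(self.cardinal_separation - expected) > 0.01 * expected:
            raise ValueError(
                "cardinal separation must equal oblique separation * sqrt(2) "
                f"within 1% (got {self.cardinal_separation}, expected ~{expected:.4f})"
            )


@dataclass(frozen=True)
class Lattice:
    """Circle centres (deg, grid-centred) with their oblique row labels.

    ``left_row`` indexes runs along the left-oblique ("\\") axis and
    ``right_row`` runs along the right-oblique ("/") axis; two circles share
    a label iff they lie on the same oblique line.
    """

    centres_deg: np.ndarray  # (n, 2) x right / y up
    left_row: np.ndarray  # (n,) int
    right_row: np.ndarray  # (n,) int
    geometry: LatticeGeometry

    def __len__(self) -> int:
        return self.centres_deg.shape[0]


# Unit vectors of the two oblique axes; a right-oblique run advances along
# _U_RIGHT and is indexed by its coordinate along _U_LEFT, and vice versa.
_U_RIGHT = np.array([1.0, 1.0]) / math.sqrt(2.0)
_U_LEFT = np.array([1.0, -1.0]) / math.sqrt(2.0)


def build_lattice(geometry: LatticeGeometry) -> Lattice:
    """Enumerate circle centres of the rotated square lattice inside the grid.

    Circles that would be clipped by the grid boundary are excluded entirely
    so every rendered circle carries a well-defined cue contrast.
    """
    s = geometry.oblique_separation
    r_grid = geometry.grid_diameter / 2.0
    r_circle = geometry.circle_diameter / 2.0
    n_max = int(math.ceil(r_grid / s)) + 1

    centres, lefts, rights = [], [], []
    for i in range(-n_max, n_max + 1):  # coordinate along the right-oblique axis
        for j in range(-n_max, n_max + 1):  # along the left-oblique axis
            p = s * (i * _U_RIGHT + j * _U_LEFT)
            if np.hypot(*p) + r_circle <= r_grid:
                centres.append(p)
                lefts.append(i)  # circles sharing i lie on one left-oblique run
                rights.append(j)
    if not centres:
        raise EmptyLatticeError(
            f"no circle of diameter {geometry.circle_diameter} fits inside a "
            f"grid of diameter {geometry.grid_diameter}"
        )
    return Lattice(
        centres_deg=np.array(centres),
        left_row=np.array(lefts, dtype=int),
        right_row=np.array(rights, dtype=int),
        geometry=geometry,
    )


@dataclass(frozen=True)
class ContrastLadder:
    """Eight log-spaced contrast levels per cue, paired in opposition.

    Level ``a_i`` is shown against ``b_{9-i}`` (1-based), so the log contrast
    ratio ``log10(a_i / b_{9-i})`` sweeps from strongly-b to strongly-a.
    """

    a_levels: np.ndarray
    b_levels: np.ndarray

    def __post_init__(self):
        for name in ("a_levels", "b_levels"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.ndim != 1 or len(v) != len(self.a_levels):
                raise ValueError("ladder level sets must be 1-d, equal length")
            if np.any(v <= 0) or np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be positive, strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.a_levels)

    def pairs(self) -> list[tuple[float, float]]:
        """(a_i, b_{n+1-i}) pairs, i = 1..n."""
        return list(zip(self.a_levels, self.b_levels[::-1]))

    @property
    def log_ratios(self) -> np.ndarray:
        """log10(a_i / b_{n+1-i}), strictly increasing."""
        return np.log10(self.a_levels / self.b_levels[::-1])

    def to_dict(self) -> dict:
        return {
            "a_levels": self.a_levels.tolist(),
            "b_levels": self.b_levels.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContrastLadder":
        return cls(np.asarray(d["a_levels"]), np.asarray(d["b_levels"]))


def make_ladder(
    a_min: float, a_max: float, b_min: float, b_max: float, n_levels: int = 8
) -> ContrastLadder:
    """Build the paired log-spaced contrast ladder (8 levels by default)."""
    for name, lo, hi in (("a", a_min, a_max), ("b", b_min, b_max)):
        if not (0 < lo < hi):
            raise ValueError(
                f"ladder bounds for cue {name} must satisfy 0 < min < max, "
                f"got ({lo}, {hi})"
            )
    return ContrastLadder(
        a_levels=np.geomspace(a_min, a_max, n_levels),
        b_levels=np.geomspace(b_min, b_max, n_levels),
    )


@dataclass(frozen=True)
class StimulusSpec:
    """One presentation: condition, cue pair, orientation and geometry.

    ``duration_ms``/``isi_ms`` are carried as metadata only; no display loop
    is implemented.  In the Combined condition the cue pair must be Texture
    against one colour/luminance cue, the design's only pairings.
    """

    condition: str  # "Separate" | "Combined"
    cue_a: CueSpec
    cue_b: Optional[CueSpec] = None
    orientation_a: str = "right-oblique"
    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)
    noise_seed: int = 0
    balanced_texture: bool = False
    duration_ms: float = 500.0
    isi_ms: float = 500.0

    def __post_init__(self):
        if self.condition not in ("Separate", "Combined"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.orientation_a not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation_a!r}")
        if self.noise_seed < 0:
            raise ValueError("noise_seed must be a non-negative integer")
        if self.condition == "Combined":
            if self.cue_b is None:
                raise ValueError("Combined condition requires cue_b")
            kinds = {self.cue_a.cue_kind, self.cue_b.cue_kind}
            if "Texture" not in kinds or len(kinds) != 2:
                raise InvalidCueError(
                    "Combined pairs are Texture vs one of Dark/Red/Violet, "
                    f"got {self.cue_a.cue_kind} vs {self.cue_b.cue_kind}"
                )

    @property
    def orientation_b(self) -> str:
        return ORIENTATIONS[1 - ORIENTATIONS.index(self.orientation_a)]

    def to_json(self) -> str:
        d = {
            "condition": self.condition,
            "cue_a": {"cue_kind": self.cue_a.cue_kind, "contrast": self.cue_a.contrast},
            "cue_b": None
            if self.cue_b is None
            else {"cue_kind": self.cue_b.cue_kind, "contrast": self.cue_b.contrast},
            "orientation_a": self.orientation_a,
            "geometry": {
                "grid_diameter": self.geometry.grid_diameter,
                "circle_diameter": self.geometry.circle_diameter,
                "oblique_separation": self.geometry.oblique_separation,
                "cardinal_separation": self.geometry.cardinal_separation,
                "ring_width_px": self.geometry.ring_width_px,
                "pixels_per_degree": self.geometry.pixels_per_degree,
            },
            "noise_seed": self.noise_seed,
            "balanced_texture": self.balanced_texture,
            "duration_ms": self.duration_ms,
            "isi_ms": self.isi_ms,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StimulusSpec":
        d = json.loads(text)
        return cls(
            condition=d["condition"],
            cue_a=CueSpec(**d["cue_a"]),
            cue_b=None if d["cue_b"] is None else CueSpec(**d["cue_b"]),
            orientation_a=d["orientation_a"],
            geometry=LatticeGeometry(**d["geometry"]),
            noise_seed=d["noise_seed"],
            balanced_texture=d.get("balanced_texture", False),
            duration_ms=d.get("duration_ms", 500.0),
            isi_ms=d.get("isi_ms", 500.0),
        )


def assign_cues(lattice: Lattice, spec: StimulusSpec) -> np.ndarray:
    """Map each circle to ``"a"``, ``"b"`` or ``""`` (background).

    Cue a takes alternate (even-indexed) rows of its oblique axis.  In the
    Combined condition cue b takes alternate rows of the orthogonal axis
    among the circles cue a did not claim, so no circle ever carries both
    cues; at row crossings cue a wins.  Cue stride is every second row.
    """
    if spec.orientation_a == "right-oblique":
        a_row, b_row = lattice.right_row, lattice.left_row
    else:
        a_row, b_row = lattice.left_row, lattice.right_row

    labels = np.full(len(lattice), "", dtype="<U1")
    a_mask = a_row % 2 == 0
    labels[a_mask] = "a"
    if spec.condition == "Combined":
        b_mask = (~a_mask) & (b_row % 2 == 0)
        labels[b_mask] = "b"
    return labels


def texture_patch(
    radius_px: int,
    amplitude: float,
    seed: int | np.random.SeedSequence,
    balanced: bool = False,
) -> np.ndarray:
    """Binary-noise disc: luminance factors ``1 +/- amplitude`` about mid-grey.

    Returns a ``(2r+1, 2r+1)`` array of multiplicative luminance factors;
    pixels outside the disc are background (factor 1).  Each in-disc pixel is
    independently light or dark with probability one half, so the patch mean
    stays at the background level in expectation and the texture adds no
    low-frequency luminance signal.  ``balanced=True`` instead forces exactly
    equal counts of light and dark pixels.

    The texture contrast metric is amplitude/mean, i.e. ``amplitude`` itself.
    """
    if not (0 <= amplitude):
        raise ValueError("amplitude must be >= 0")
    if amplitude > 1.0:
        raise GamutError(
            f"texture amplitude {amplitude} drives luminance negative",
            channel="luminance",
        )
    size = 2 * radius_px + 1
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    mask = xx * xx + yy * yy <= radius_px * radius_px
    rng = np.random.default_rng(seed)
    patch = np.ones((size, size))
    n = int(mask.sum())
    if balanced:
        signs = np.repeat([1.0, -1.0], [(n + 1) // 2, n // 2])[:n]
        rng.shuffle(signs)
    else:
        signs = rng.choice([1.0, -1.0], size=n)
    patch[mask] = 1.0 + amplitude * signs
    return patch


@dataclass(frozen=True)
class FramePair:
    """The two alternating video pages of one presentation.

    Pages are (H, W, 3) cone-contrast images (L, M, S Weber contrast per
    pixel relative to the mid-grey background); the black rings live in a
    separate boolean mask, outside the cone-contrast algebra.  ``circle_id``
    maps each pixel to its circle's index in the lattice (-1 = background),
    counting only cue-fill pixels (rings excluded).
    """

    page_1: np.ndarray
    page_2: np.ndarray
    ring_mask: np.ndarray
    circle_id: np.ndarray
    labels: np.ndarray
    lattice: Lattice
    metadata: StimulusSpec

    def effective(self) -> np.ndarray:
        """Temporal average of the two pages (halves each cue's contrast)."""
        return 0.5 * (self.page_1 + self.page_2)

    def to_primaries(self, cal: DisplayCalibration, page: np.ndarray) -> np.ndarray:
        """Linear RGB image of one page; rings rendered black."""
        lms = cal.background_lms * (1.0 + page)
        rgb = lms @ cal.lms_to_primary_matrix.T
        rgb[self.ring_mask] = 0.0
        return rgb


def _colour_cue_vector(cue: CueSpec, k: float) -> ConeContrastVector:
    return isolating_cone_contrast(cue.cue_kind, cue.contrast, k)


def render(spec: StimulusSpec, cal: DisplayCalibration) -> FramePair:
    """Rasterise a stimulus into its two alternating pages.

    Page 1 carries cue a; page 2 carries cue b (Combined) or stays mid-grey
    (Separate).  Colour cues use the mechanism-isolating direction for the
    calibration's observer weight k.  All cue contrasts are gamut-checked at
    full (pre-halving) amplitude before any pixel is written.
    """
    geom = spec.geometry
    lattice = build_lattice(geom)
    labels = assign_cues(lattice, spec)
    ppd = geom.pixels_per_degree
    size = int(round(geom.grid_diameter * ppd))
    r_px = geom.circle_diameter / 2.0 * ppd
    fill_r = r_px - geom.ring_width_px

    # gamut pre-check at full amplitude, before touching any pixel
    cue_vectors: dict[str, ConeContrastVector | None] = {}
    for label, cue in (("a", spec.cue_a), ("b", spec.cue_b)):
        if cue is None:
            continue
        if cue.cue_kind == "Texture":
            if cue.contrast > 1.0:
                raise GamutError(
                    f"texture amplitude {cue.contrast} drives luminance negative",
                    channel="luminance",
                )
            for sign in (+1.0, -1.0):
                v = sign * cue.contrast
                cone_to_primary(ConeContrastVector(v, v, v), cal)
            cue_vectors[label] = None
        else:
            cc = _colour_cue_vector(cue, cal.observer_k)
            cone_to_primary(cc, cal)
            cue_vectors[label] = cc

    page_1 = np.zeros((size, size, 3))
    page_2 = np.zeros((size, size, 3))
    ring_mask = np.zeros((size, size), dtype=bool)
    circle_id = np.full((size, size), -1, dtype=int)
    centre = (size - 1) / 2.0

    for idx in range(len(lattice)):
        x_deg, y_deg = lattice.centres_deg[idx]
        cx = centre + x_deg * ppd
        cy = centre - y_deg * ppd  # image rows grow downwards
        lo_x, hi_x = int(math.floor(cx - r_px)) - 1, int(math.ceil(cx + r_px)) + 2
        lo_y, hi_y = int(math.floor(cy - r_px)) - 1, int(math.ceil(cy + r_px)) + 2
        yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        dist = np.hypot(xx - cx, yy - cy)
        in_ring = (dist <= r_px) & (dist > fill_r)
        in_fill = dist <= fill_r

        ring_mask[lo_y:hi_y, lo_x:hi_x][in_ring] = True
        label = labels[idx]
        if label:
            cue = spec.cue_a if label == "a" else spec.cue_b
            page = page_1 if label == "a" else page_2
            if spec.condition == "Separate":
                page = page_1  # Separate shows only cue_a, page 2 stays blank
            view = page[lo_y:hi_y, lo_x:hi_x]
            if cue.cue_kind == "Texture":
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.noise_seed, idx])
                )
                n_pix = int(in_fill.sum())
                if spec.balanced_texture:
                    signs = np.repeat(
                        [1.0, -1.0], [(n_pix + 1) // 2, n_pix // 2]
                    )[:n_pix]
                    rng.shuffle(signs)
                else:
                    signs = rng.choice([1.0, -1.0], size=n_pix)
                view[in_fill] = (cue.contrast * signs)[:, None] * np.ones(3)
            else:
                view[in_fill] = cue_vectors[label].as_array()
            circle_id[lo_y:hi_y, lo_x:hi_x][in_fill] = idx

    return FramePair(
        page_1=page_1,
        page_2=page_2,
        ring_mask=ring_mask,
        circle_id=circle_id,
        labels=labels,
        lattice=lattice,
        metadata=spec,
    )
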