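"""Parametric 2-D phantoms: primitives, builders, rasterization, exact projection.

A :class:`Phantom` is a list of geometric primitives, each carrying a signed
*additive* attenuation contrast in mm⁻¹.  Overlapping elements add, which is
what makes nested anatomy (low-attenuation lung fields inside a body ellipse)
expressible; the composite attenuation map is expected to be non-negative and
:func:`rasterize` warns when it is not.

All primitives support exact line integrals (`chord_lengths`), so an analytic
fan-beam projector needs no image-domain discretization at all.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import FanBeamGeometry, ImageGrid

__all__ = [
    "Disk",
    "Ellipse",
    "BarGroup",
    "Phantom",
    "make_rod_phantom",
    "make_bar_phantom",
    "make_lung_like_phantom",
    "rasterize",
    "ray_integral_analytic",
]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Disk:
    center_mm: tuple[float, float]
    radius_mm: float
    attenuation_per_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("disk radius must be positive")

    @property
    def bounding_radius_mm(self) -> float:
        return self.radius_mm

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center_mm
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius_mm**2

    def chord_lengths(self, source: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Length of the intersection of each ray (infinite line) with the disk."""
        b = np.asarray(self.center_mm, dtype=float) - source
        t0 = directions @ b  # closest-approach parameter
        d2 = float(b @ b) - t0**2
        inside = self.radius_mm**2 - d2
        return 2.0 * np.sqrt(np.clip(inside, 0.0, None))


@dataclass(frozen=True)
class Ellipse:
    center_mm: tuple[float, float]
    semiaxes_mm: tuple[float, float]
    angle_rad: float
    attenuation_per_mm: float

    def __post_init__(self) -> None:
        if min(self.semiaxes_mm) <= 0:
            raise ValueError("ellipse semiaxes must be positive")

    @property
    def bounding_radius_mm(self) -> float:
        return max(self.semiaxes_mm)

    def _to_frame(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cx, cy = self.center_mm
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        dx, dy = x - cx, y - cy
        return c * dx + s * dy, -s * dx + c * dy

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u, v = self._to_frame(np.asarray(x, float), np.asarray(y, float))
        a, b = self.semiaxes_mm
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def chord_lengths(self, source: np.ndarray, directions: np.ndarray) -> np.ndarray:
        a, b = self.semiaxes_mm
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        # source and directions in the axis-aligned unit-circle frame
        px, py = self._to_frame(source[0], source[1])
        p = np.array([px / a, py / b])
        ux = (c * directions[..., 0] + s * directions[..., 1]) / a
        uy = (-s * directions[..., 0] + c * directions[..., 1]) / b
        # |p + t u|^2 = 1  (t keeps world-mm units because directions are unit)
        aa = ux**2 + uy**2
        bb = 2.0 * (p[0] * ux + p[1] * uy)
        cc = float(p @ p) - 1.0
        disc = bb**2 - 4.0 * aa * cc
        return np.where(disc > 0, np.sqrt(np.clip(disc, 0.0, None)) / aa, 0.0)


@dataclass(frozen=True)
class _Rect:
    """Axis-angle rectangle (internal building block of bar groups)."""

    center_mm: tuple[float, float]
    half_w_mm: float  # half size along the rectangle's local x
    half_h_mm: float  # half size along the rectangle's local y
    angle_rad: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center_mm
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        dx, dy = x - cx, y - cy
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (np.abs(u) <= self.half_w_mm) & (np.abs(v) <= self.half_h_mm)

    def chord_lengths(self, source: np.ndarray, directions: np.ndarray) -> np.ndarray:
        cx, cy = self.center_mm
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        px = c * (source[0] - cx) + s * (source[1] - cy)
        py = -s * (source[0] - cx) + c * (source[1] - cy)
        ux = c * directions[..., 0] + s * directions[..., 1]
        uy = -s * directions[..., 0] + c * directions[..., 1]
        # slab clipping along each local axis
        with np.errstate(divide="ignore", invalid="ignore"):
            tx1 = (-self.half_w_mm - px) / ux
            tx2 = (self.half_w_mm - px) / ux
            ty1 = (-self.half_h_mm - py) / uy
            ty2 = (self.half_h_mm - py) / uy
        tx_lo, tx_hi = np.minimum(tx1, tx2), np.maximum(tx1, tx2)
        ty_lo, ty_hi = np.minimum(ty1, ty2), np.maximum(ty1, ty2)
        # rays parallel to a slab: inside -> infinite slab range, outside -> empty
        par_x = np.abs(ux) < 1e-12
        par_y = np.abs(uy) < 1e-12
        in_x = np.abs(px) <= self.half_w_mm
        in_y = np.abs(py) <= self.half_h_mm
        big = 1e12
        tx_lo = np.where(par_x, np.where(in_x, -big, big), tx_lo)
        tx_hi = np.where(par_x, np.where(in_x, big, -big), tx_hi)
        ty_lo = np.where(par_y, np.where(in_y, -big, big), ty_lo)
        ty_hi = np.where(par_y, np.where(in_y, big, -big), ty_hi)
        lo = np.maximum(tx_lo, ty_lo)
        hi = np.minimum(tx_hi, ty_hi)
        return np.clip(hi - lo, 0.0, None)


@dataclass(frozen=True)
class BarGroup:
    """Alternating high-contrast bars at a fixed spatial frequency.

    The bars modulate along the group's local x axis; ``orientation_rad``
    rotates the whole group.  ``frequency_lp_per_cm`` line pairs per cm give a
    bar period of 10/f mm (10 lp/cm ⇒ 1 mm period, 0.5 mm bars).  Only the
    high-attenuation bars are material; the gaps are background.
    """

    center_mm: tuple[float, float]
    frequency_lp_per_cm: float
    n_bars: int
    bar_length_mm: float
    attenuation_per_mm: float
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_lp_per_cm <= 0:
            raise ValueError("bar frequency must be positive")
        if self.n_bars < 2:
            raise ValueError("need at least 2 bars")
        if self.bar_length_mm <= 0:
            raise ValueError("bar length must be positive")

    @property
    def period_mm(self) -> float:
        return 10.0 / self.frequency_lp_per_cm

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width along modulation axis, bar length)."""
        return (self.n_bars * self.period_mm - 0.5 * self.period_mm, self.bar_length_mm)

    @property
    def bounding_radius_mm(self) -> float:
        w, h = self.extent_mm
        return 0.5 * float(np.hypot(w, h))

    def bars(self) -> list[_Rect]:
        half_bar = 0.25 * self.period_mm
        cx, cy = self.center_mm
        c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
        out = []
        for k in range(self.n_bars):
            # bar centers spaced one period apart, centred on the group center
            u = (k - (self.n_bars - 1) / 2.0) * self.period_mm
            out.append(
                _Rect(
                    (cx + c * u, cy + s * u),
                    half_bar,
                    0.5 * self.bar_length_mm,
                    self.orientation_rad,
                )
            )
        return out

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        m = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for r in self.bars():
            m |= r.contains(x, y)
        return m

    def chord_lengths(self, source: np.ndarray, directions: np.ndarray) -> np.ndarray:
        total = np.zeros(directions.shape[:-1])
        for r in self.bars():
            total = total + r.chord_lengths(source, directions)
        return total


Primitive = Disk | Ellipse | BarGroup


# ---------------------------------------------------------------------------
# phantom container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Phantom:
    """A list of additive primitives plus a constant background level.

    The background applies to :func:`rasterize` only (a constant offset over
    the whole grid); analytic ray integrals cover the primitives, whose chord
    lengths are finite.
    """

    elements: tuple[Primitive, ...]
    background_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.background_per_mm < 0:
            raise ValueError("background attenuation must be non-negative")

    def check_inside_fov(self, geometry: FanBeamGeometry) -> None:
        """Warn about elements protruding beyond the FOV disk."""
        r_fov = geometry.fov_radius_mm
        for el in self.elements:
            cx, cy = el.center_mm
            if np.hypot(cx, cy) + el.bounding_radius_mm > r_fov:
                warnings.warn(
                    f"phantom element centred at ({cx:.1f}, {cy:.1f}) mm extends "
                    f"beyond the FOV radius {r_fov:.1f} mm",
                    stacklevel=2,
                )

    # -- JSON schema: {"background_per_mm": float, "elements": [{"type": ...}]}

    def to_json(self) -> str:
        items = []
        for el in self.elements:
            d = asdict(el)
            d["type"] = type(el).__name__.lower()
            items.append(d)
        return json.dumps(
            {"background_per_mm": self.background_per_mm, "elements": items}, indent=2
        )

    @staticmethod
    def from_json(text: str) -> "Phantom":
        data = json.loads(text)
        kinds = {"disk": Disk, "ellipse": Ellipse, "bargroup": BarGroup}
        elements = []
        for item in data["elements"]:
            item = dict(item)
            kind = kinds[item.pop("type")]
            for key in ("center_mm", "semiaxes_mm"):
                if key in item:
                    item[key] = tuple(item[key])
            elements.append(kind(**item))
        return Phantom(tuple(elements), data.get("background_per_mm", 0.0))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

#: attenuation of aluminium at diagnostic energies, mm^-1 (rod material)
ALUMINIUM_MU_PER_MM = 0.08
#: soft-tissue-like attenuation, mm^-1
TISSUE_MU_PER_MM = 0.02


def make_rod_phantom(
    offsets_mm: list[float],
    rod_diameter_mm: float = 1.0,
    attenuation: float = ALUMINIUM_MU_PER_MM,
    geometry: FanBeamGeometry | None = None,
    flip_sign: bool = False,
) -> Phantom:
    """Thin cylindrical rods on the source–isocenter line of the β = 0 view.

    A positive offset moves the rod from the isocenter toward the detector of
    the first view (i.e. *away* from the source, to (0, −offset) in world
    coordinates); ``flip_sign`` reverses that convention.  With a geometry
    given, offsets that place any part of a rod outside the FOV are rejected.
    """
    if rod_diameter_mm <= 0:
        raise ValueError("rod diameter must be positive")
    radius = 0.5 * rod_diameter_mm
    if geometry is not None:
        r_fov = geometry.fov_radius_mm
        for off in offsets_mm:
            if abs(off) + radius >= r_fov:
                raise ValueError(
                    f"rod offset {off} mm places the rod outside the FOV "
                    f"(radius {r_fov:.1f} mm)"
                )
    sign = 1.0 if flip_sign else -1.0
    disks = tuple(
        Disk((0.0, sign * float(off)), radius, attenuation) for off in offsets_mm
    )
    return Phantom(disks)


def make_bar_phantom(
    offset_mm: float,
    frequency_lp_per_cm: float = 10.0,
    n_bars: int = 8,
    bar_length_mm: float = 12.0,
    attenuation: float = TISSUE_MU_PER_MM,
    orientation_rad: float = 0.0,
    geometry: FanBeamGeometry | None = None,
    include_references: bool = True,
) -> Phantom:
    """A bar-pattern resolution group at a signed offset from the isocenter.

    The group is centred at (0, −offset) (same signed convention as
    :func:`make_rod_phantom`) with bars modulating along x.  When
    ``include_references`` is set, a solid disk of the bar material is placed
    next to the group so that reconstructed images contain a uniform patch of
    each material for contrast normalization in MTF estimation.
    """
    group = BarGroup(
        (0.0, -float(offset_mm)),
        frequency_lp_per_cm,
        n_bars,
        bar_length_mm,
        attenuation,
        orientation_rad,
    )
    elements: list[Primitive] = [group]
    if include_references:
        # uniform full-material patch, clear of the bars
        ref_radius = 4.0
        gap = 4.0
        elements.append(
            Disk(
                (0.0, -float(offset_mm) + 0.5 * bar_length_mm + gap + ref_radius),
                ref_radius,
                attenuation,
            )
        )
    phantom = Phantom(tuple(elements))
    if geometry is not None:
        r_fov = geometry.fov_radius_mm
        for el in phantom.elements:
            cx, cy = el.center_mm
            if np.hypot(cx, cy) + el.bounding_radius_mm >= r_fov:
                raise ValueError(
                    f"bar phantom at offset {offset_mm} mm does not fit inside "
                    f"the FOV (radius {r_fov:.1f} mm)"
                )
    return phantom


def make_lung_like_phantom(
    seed: int, scale_mm: float = 130.0, n_nodules: int = 6
) -> Phantom:
    """Reproducible thorax-like layout: body ellipse, two lung fields, nodules.

    Entirely determined by ``seed``.  The lung fields are negative additive
    contrast inside the body ellipse; nodules are small soft-tissue disks
    placed inside the lungs by rejection sampling.  ``scale_mm`` bounds the
    body's larger semiaxis so the phantom fits a chosen FOV.
    """
    rng = np.random.default_rng(seed)
    body_a = 0.92 * scale_mm
    body_b = 0.62 * scale_mm
    mu_body = TISSUE_MU_PER_MM
    mu_lung = -0.016  # additive: body + lung field ≈ 0.004 /mm
    elements: list[Primitive] = [Ellipse((0.0, 0.0), (body_a, body_b), 0.0, mu_body)]
    lung_a, lung_b = 0.36 * scale_mm, 0.44 * scale_mm
    lung_centers = [(-0.42 * scale_mm, 0.0), (0.42 * scale_mm, 0.0)]
    for cx, cy in lung_centers:
        elements.append(Ellipse((cx, cy), (lung_a, lung_b), 0.0, mu_lung))
    lungs = elements[1:3]
    placed = 0
    while placed < n_nodules:
        lung = lungs[int(rng.integers(0, 2))]
        lcx, lcy = lung.center_mm
        u = rng.uniform(-0.8, 0.8)
        v = rng.uniform(-0.8, 0.8)
        if u * u / 0.64 + v * v / 0.64 > 1.0:
            continue
        r = float(rng.uniform(2.0, 6.0))
        cx = lcx + u * lung_a
        cy = lcy + v * lung_b
        # nodule must sit fully inside its lung field
        if (abs(cx - lcx) + r) / lung_a > 0.95 or (abs(cy - lcy) + r) / lung_b > 0.95:
            continue
        elements.append(Disk((cx, cy), r, 0.012))
        placed += 1
    return Phantom(tuple(elements))


# ---------------------------------------------------------------------------
# rasterization and exact projection
# ---------------------------------------------------------------------------


def rasterize(phantom: Phantom, grid: ImageGrid, supersample: int = 4) -> np.ndarray:
    """Pixelwise attenuation map with area-weighted anti-aliasing.

    Each pixel is subdivided ``supersample × supersample`` times and the
    occupancy-weighted additive attenuation is averaged.  Bar groups whose
    period falls below twice the pixel pitch cannot be represented on the
    grid and raise a ``ValueError``.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    for el in phantom.elements:
        if isinstance(el, BarGroup) and el.period_mm < 2.0 * grid.pixel_mm:
            raise ValueError(
                f"bar period {el.period_mm:.3f} mm is below the grid Nyquist "
                f"limit {2 * grid.pixel_mm:.3f} mm; use finer pixels"
            )
    n, p, s = grid.n_pixels, grid.pixel_mm, supersample
    fine = (np.arange(n * s) + 0.5) / s - n / 2.0
    x = fine * p
    y = -fine * p
    xx, yy = np.meshgrid(x, y)
    img = np.zeros((n * s, n * s))
    for el in phantom.elements:
        img += el.attenuation_per_mm * el.contains(xx, yy)
    img = img.reshape(n, s, n, s).mean(axis=(1, 3))
    img += phantom.background_per_mm
    if img.min() < -1e-12:
        warnings.warn(
            f"composite attenuation is negative (min {img.min():.3e} /mm); "
            "check element contrasts",
            stacklevel=2,
        )
    return img


def ray_integral_analytic(
    phantom: Phantom, source_point: np.ndarray, direction: np.ndarray
) -> float | np.ndarray:
    """Exact line integral(s) of the phantom along one or many rays.

    ``direction`` must hold unit vectors; shape (2,) for a single ray or
    (n, 2) for a batch sharing one source point.  The background level is not
    included (an unbounded constant has no finite line integral).
    """
    direction = np.asarray(direction, dtype=float)
    norms = np.linalg.norm(direction, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError("direction must be a unit vector")
    source = np.asarray(source_point, dtype=float)
    total = np.zeros(direction.shape[:-1])
    for el in phantom.elements:
        total = total + el.attenuation_per_mm * el.chord_lengths(source, direction)
    return float(total) if total.shape == () else total
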