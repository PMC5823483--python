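"""Acquisition geometry and reconstruction-grid definitions.

Coordinate convention (used by every module in this package):

* isocenter at the origin, all lengths in millimetres;
* the +y axis points toward the source position of the first view (β = 0),
  so the detector of that view lies on the −y side;
* the view angle β increases counter-clockwise;
* the fan angle γ is measured from the central ray of each view, positive
  toward the counter-clockwise side of the fan.

The detector is an equal-angle arc centred on the source: channel *c* sits
at fan angle γ_c = (c − (n−1)/2)·Δγ with Δγ = pitch / source_detector_mm.
The field of view (FOV) is the disk of radius R = D·sin(γ_m) seen by every
view, where D is the source–isocenter distance and γ_m the half fan angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FanBeamGeometry", "ImageGrid"]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Equal-angle fan-beam acquisition geometry for a full 2π rotation.

    Parameters
    ----------
    source_isocenter_mm:
        Distance D from the X-ray source to the rotation center.
    source_detector_mm:
        Distance from the source to the detector arc (the arc radius).
    n_channels:
        Number of detector cells in a row.
    channel_pitch_mm:
        Detector cell size measured along the arc.
    n_views:
        Number of projections, uniformly spaced over [0, 2π).
    """

    source_isocenter_mm: float = 600.0
    source_detector_mm: float = 1100.0
    n_channels: int = 912
    channel_pitch_mm: float = 1.09
    n_views: int = 1440

    def __post_init__(self) -> None:
        if not self.source_detector_mm > self.source_isocenter_mm > 0:
            raise ValueError(
                "require source_detector_mm > source_isocenter_mm > 0, got "
                f"{self.source_detector_mm} and {self.source_isocenter_mm}"
            )
        if self.n_channels < 2:
            raise ValueError("n_channels must be at least 2")
        if self.channel_pitch_mm <= 0:
            raise ValueError("channel_pitch_mm must be positive")
        if self.n_views < 1:
            raise ValueError("n_views must be at least 1")
        if not 0 < self.gamma_max_rad < np.pi / 2:
            raise ValueError(
                f"half fan angle {self.gamma_max_rad:.4f} rad outside (0, pi/2); "
                "reduce n_channels or channel_pitch_mm"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def delta_gamma_rad(self) -> float:
        """Angular pitch of one detector channel (arc detector)."""
        return self.channel_pitch_mm / self.source_detector_mm

    @property
    def gamma_max_rad(self) -> float:
        """Half fan angle γ_m subtended by the detector."""
        return 0.5 * self.n_channels * self.channel_pitch_mm / self.source_detector_mm

    @property
    def fov_radius_mm(self) -> float:
        """Radius of the FOV disk, D·sin(γ_m)."""
        return self.source_isocenter_mm * np.sin(self.gamma_max_rad)

    @property
    def delta_beta_rad(self) -> float:
        return 2.0 * np.pi / self.n_views

    @property
    def view_angles_rad(self) -> np.ndarray:
        """β of each view: uniform over [0, 2π), strictly increasing."""
        return np.arange(self.n_views) * self.delta_beta_rad

    @property
    def channel_angles_rad(self) -> np.ndarray:
        """γ of each channel, symmetric about 0, bounded by ±γ_m."""
        c = np.arange(self.n_channels) - (self.n_channels - 1) / 2.0
        return c * self.delta_gamma_rad

    # -- per-view geometry --------------------------------------------------

    def source_position(self, beta: float) -> np.ndarray:
        """Source position S(β) = D·(−sin β, cos β)."""
        d = self.source_isocenter_mm
        return np.array([-d * np.sin(beta), d * np.cos(beta)])

    def view_axes(self, beta: float) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (d0, p0) of the view frame.

        d0 points from the source toward the isocenter (the central ray);
        p0 = d0 rotated +90° so that a ray at fan angle γ has direction
        cos γ · d0 + sin γ · p0.
        """
        d0 = np.array([np.sin(beta), -np.cos(beta)])
        p0 = np.array([np.cos(beta), np.sin(beta)])
        return d0, p0

    def ray_directions(self, beta: float) -> np.ndarray:
        """(n_channels, 2) unit direction of every channel's ray at view β."""
        d0, p0 = self.view_axes(beta)
        g = self.channel_angles_rad
        return np.cos(g)[:, None] * d0 + np.sin(g)[:, None] * p0

    def fan_coordinates(
        self, beta: float, x: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Source distance L and fan angle γ′ of points (x, y) at view β.

        L is the distance from the source to each point; γ′ is the fan angle
        of the ray through the point, in the same sign convention as the
        channel angles.
        """
        s = self.source_position(beta)
        d0, p0 = self.view_axes(beta)
        vx = np.asarray(x) - s[0]
        vy = np.asarray(y) - s[1]
        along = vx * d0[0] + vy * d0[1]
        across = vx * p0[0] + vy * p0[1]
        return np.hypot(vx, vy), np.arctan2(across, along)


@dataclass(frozen=True)
class ImageGrid:
    """Square reconstruction grid with the isocenter at its center.

    Pixel (iy, ix) has center ((ix − (n−1)/2)·p, ((n−1)/2 − iy)·p) so that
    row index increases downward (image convention) while +y points up.
    """

    n_pixels: int = 512
    pixel_mm: float = 0.9

    def __post_init__(self) -> None:
        if self.n_pixels < 16:
            raise ValueError("n_pixels must be at least 16")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")

    @property
    def half_extent_mm(self) -> float:
        return 0.5 * self.n_pixels * self.pixel_mm

    def covers_radius(self, radius_mm: float) -> bool:
        """Whether the square grid fully contains a centred disk."""
        return self.half_extent_mm >= radius_mm

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of pixel-center world coordinates in mm."""
        n, p = self.n_pixels, self.pixel_mm
        c = (np.arange(n) - (n - 1) / 2.0) * p
        x = c
        y = -c  # row index increases downward
        return np.meshgrid(x, y)

    def radius_map(self) -> np.ndarray:
        x, y = self.pixel_coordinates()
        return np.hypot(x, y)

    def index_of(self, x_mm: float, y_mm: float) -> tuple[int, int]:
        """(row, col) of the pixel whose center is nearest to a world point."""
        n, p = self.n_pixels, self.pixel_mm
        col = int(round(x_mm / p + (n - 1) / 2.0))
        row = int(round((n - 1) / 2.0 - y_mm / p))
        if not (0 <= row < n and 0 <= col < n):
            raise ValueError(f"point ({x_mm}, {y_mm}) mm falls outside the grid")
        return row, col
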