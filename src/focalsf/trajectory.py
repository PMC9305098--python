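"""Parametric nerve-fiber bundle trajectory model and VF-to-disc mapping.

The model lives in a canonical frame: fovea at the origin, optic disc at a
canonical position (degrees of visual angle, x nasal-positive, y
superior-positive for a right eye).  Around the disc we use polar
coordinates (r, phi) where phi = 0 points along the fovea-disc axis *away*
from the fovea and phi increases counterclockwise (superior hemiretina has
phi > 0).  A bundle entering the disc circle r = r0 at angle phi0 follows

    phi(r) = phi0 + b(phi0) * (r - r0) ** c(phi0)

with b and c drawn from hemifield-specific tanh coefficient tables loaded
from a versioned JSON config, so alternative trajectory atlases are
drop-in replacements.

Individual eyes are registered to the canonical frame by a similarity
transform fitted to the eye's fovea-disc distance and angle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .config import MM_PER_DEG, RING_DIAMETER_MM
from .vf_data import VFLocation

__all__ = [
    "EyeGeometry",
    "HemifieldCoefficients",
    "TrajectoryModelParams",
    "EyeTransform",
    "WedgeROI",
    "TrajectoryDomainError",
    "WedgeBuilder",
    "load_default_params",
    "load_params",
    "trace_trajectory",
    "fit_to_eye",
    "vf_point_to_phi0",
    "build_wedge",
    "write_wedge_overlay",
    "read_geometry_csv",
]


@dataclass(frozen=True)
class EyeGeometry:
    """Fovea/disc centers of one eye plus derived fovea-disc geometry.

    Pixel coordinates use image conventions (origin top-left, y down); the
    fovea may legitimately fall outside the image for peripapillary scans.
    ``fd_angle_deg`` is the elevation of the disc center above the
    horizontal through the fovea (retinal y-up sense).
    """

    fovea_xy: tuple[float, float]
    disc_xy: tuple[float, float]
    fd_distance_deg: float
    fd_angle_deg: float
    mm_per_deg: float = MM_PER_DEG

    def __post_init__(self) -> None:
        if self.fd_distance_deg <= 0:
            raise ValueError("fovea-disc distance must be positive")
        if abs(self.fd_angle_deg) >= 45:
            raise ValueError("fovea-disc angle implausibly large (|angle| >= 45 deg)")

    @classmethod
    def from_pixels(
        cls,
        fovea_xy: tuple[float, float],
        disc_xy: tuple[float, float],
        mm_per_px: float,
        mm_per_deg: float = MM_PER_DEG,
    ) -> "EyeGeometry":
        dx = disc_xy[0] - fovea_xy[0]
        dy_up = fovea_xy[1] - disc_xy[1]  # image y points down
        dist_px = math.hypot(dx, dy_up)
        if dist_px == 0:
            raise ValueError("fovea and disc centers coincide")
        deg_per_px = mm_per_px / mm_per_deg
        return cls(
            fovea_xy=tuple(fovea_xy),
            disc_xy=tuple(disc_xy),
            fd_distance_deg=dist_px * deg_per_px,
            fd_angle_deg=math.degrees(math.atan2(dy_up, dx)),
            mm_per_deg=mm_per_deg,
        )


@dataclass(frozen=True)
class HemifieldCoefficients:
    """tanh coefficient table for one hemifield.

    With u = (center_deg - |phi0|) / width_deg:
        b(phi0) = sign * exp(beta0 + beta1 * tanh(u)) * taper(|phi0|)
        c(phi0) = c0 - c1 * tanh(u)
    """

    sign: float
    beta0: float
    beta1: float
    center_deg: float
    width_deg: float
    c0: float
    c1: float

    def bc(self, phi0_abs: float, taper_deg: float) -> tuple[float, float]:
        u = (self.center_deg - phi0_abs) / self.width_deg
        t = math.tanh(u)
        b = self.sign * math.exp(self.beta0 + self.beta1 * t)
        if taper_deg > 0:
            b *= math.tanh(phi0_abs / taper_deg)
        c = self.c0 - self.c1 * t
        return b, c


@dataclass(frozen=True)
class TrajectoryModelParams:
    r0_deg: float
    variability_sd_deg: float
    canonical_disc_xy_deg: tuple[float, float]
    nasal_taper_deg: float
    superior: HemifieldCoefficients
    inferior: HemifieldCoefficients
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if self.r0_deg <= 0:
            raise ValueError("r0 must be positive")
        if self.variability_sd_deg <= 0:
            raise ValueError("variability_sd_deg must be positive")

    @property
    def canonical_fd_distance_deg(self) -> float:
        return math.hypot(*self.canonical_disc_xy_deg)

    @property
    def canonical_fd_angle_deg(self) -> float:
        x, y = self.canonical_disc_xy_deg
        return math.degrees(math.atan2(y, x))

    def coefficients(self, phi0: float) -> tuple[float, float]:
        """(b, c) for a disc-entry angle phi0 in (-180, 180]."""
        if not (-180.0 < phi0 <= 180.0):
            raise ValueError(f"phi0={phi0} outside covered range (-180, 180]")
        if phi0 == 0.0:
            # nasal horizontal: radial limit shared by both tables
            return 0.0, 1.0
        table = self.superior if phi0 > 0 else self.inferior
        return table.bc(abs(phi0), self.nasal_taper_deg)


def _params_from_dict(cfg: dict) -> TrajectoryModelParams:
    def hemi(d: dict) -> HemifieldCoefficients:
        return HemifieldCoefficients(
            sign=float(d["sign"]),
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            center_deg=float(d["center_deg"]),
            width_deg=float(d["width_deg"]),
            c0=float(d["c0"]),
            c1=float(d["c1"]),
        )

    return TrajectoryModelParams(
        r0_deg=float(cfg["r0_deg"]),
        variability_sd_deg=float(cfg["variability_sd_deg"]),
        canonical_disc_xy_deg=tuple(cfg["canonical_disc_xy_deg"]),
        nasal_taper_deg=float(cfg.get("nasal_taper_deg", 0.0)),
        superior=hemi(cfg["hemifields"]["superior"]),
        inferior=hemi(cfg["hemifields"]["inferior"]),
        name=cfg.get("name", "unnamed"),
    )


def load_params(path: str | Path) -> TrajectoryModelParams:
    with open(path) as fh:
        return _params_from_dict(json.load(fh))


def load_default_params() -> TrajectoryModelParams:
    text = resources.files("focalsf.data").joinpath("trajectory_default.json").read_text()
    return _params_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# trajectory tracing


def trace_trajectory(
    phi0: float,
    params: TrajectoryModelParams,
    r: np.ndarray | float,
) -> np.ndarray | float:
    """Angular position phi(r) of the bundle entering the disc at phi0.

    ``r`` is radius from the disc center in degrees, r >= r0.  Returned
    angles are unwrapped (they may exceed +-180 far from the disc).
    """
    b, c = params.coefficients(phi0)
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < params.r0_deg - 1e-12):
        raise ValueError("r must be >= r0")
    dr = np.clip(r_arr - params.r0_deg, 0.0, None)
    phi = phi0 + b * dr**c
    return float(phi) if np.isscalar(r) else phi


# ---------------------------------------------------------------------------
# eye registration


@dataclass(frozen=True)
class EyeTransform:
    """Similarity transform between image pixels and the canonical model frame.

    Composition for px -> deg: translate the fovea to the origin, flip image
    y to retinal y-up, convert px to degrees, rotate the individual
    fovea-disc axis onto the canonical one, and scale the individual
    fovea-disc distance to the canonical distance.
    """

    geometry: EyeGeometry
    params: TrajectoryModelParams
    deg_per_px: float
    rotation_deg: float
    scale: float

    def _rot(self, inverse: bool = False) -> np.ndarray:
        a = math.radians(-self.rotation_deg if inverse else self.rotation_deg)
        return np.array(
            [[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]]
        )

    def px_to_model(self, pts_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_px, dtype=float))
        v = pts - np.asarray(self.geometry.fovea_xy)
        v = v * np.array([1.0, -1.0]) * self.deg_per_px  # y-up, degrees
        out = (self._rot() @ v.T).T * self.scale
        return out.reshape(np.shape(pts_px))

    def model_to_px(self, pts_deg: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_deg, dtype=float))
        v = (self._rot(inverse=True) @ (pts / self.scale).T).T
        v = v / self.deg_per_px * np.array([1.0, -1.0])
        out = v + np.asarray(self.geometry.fovea_xy)
        return out.reshape(np.shape(pts_deg))

    def field_to_model(self, x_deg: float, y_deg: float) -> np.ndarray:
        """Project a visual-field point (right-eye orientation) to the model frame.

        Field points reflect through fixation onto the retina: temporal
        field maps to nasal retina (model +x), superior field to inferior
        retina (model -y).  The projection lands in the individual's
        anatomical fovea-centered frame and is then rotated/scaled into the
        canonical frame exactly like image points.
        """
        retina = np.array([x_deg, -y_deg], dtype=float)
        a = math.radians(
            self.params.canonical_fd_angle_deg - self.geometry.fd_angle_deg
        )
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        return rot @ retina * (
            self.params.canonical_fd_distance_deg / self.geometry.fd_distance_deg
        )


def fit_to_eye(params: TrajectoryModelParams, geom: EyeGeometry) -> EyeTransform:
    """Build the px <-> canonical-frame similarity transform for one eye."""
    if geom.fovea_xy == geom.disc_xy:
        raise ValueError("degenerate geometry: fovea and disc centers coincide")
    # deg/px from the eye's own geometry so the px fovea-disc distance maps
    # exactly onto fd_distance_deg before canonical scaling.
    dx = geom.disc_xy[0] - geom.fovea_xy[0]
    dy_up = geom.fovea_xy[1] - geom.disc_xy[1]
    dist_px = math.hypot(dx, dy_up)
    deg_per_px = geom.fd_distance_deg / dist_px
    rotation = params.canonical_fd_angle_deg - geom.fd_angle_deg
    scale = params.canonical_fd_distance_deg / geom.fd_distance_deg
    return EyeTransform(
        geometry=geom,
        params=params,
        deg_per_px=deg_per_px,
        rotation_deg=rotation,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# disc-centered polar helpers (canonical frame)


def _disc_polar(params: TrajectoryModelParams, pts_deg: np.ndarray):
    """(r, phi) around the canonical disc; phi from the outward fovea-disc axis."""
    disc = np.asarray(params.canonical_disc_xy_deg)
    axis = math.radians(params.canonical_fd_angle_deg)
    pts = np.atleast_2d(np.asarray(pts_deg, dtype=float)) - disc
    ca, sa = math.cos(axis), math.sin(axis)
    along = pts[..., 0] * ca + pts[..., 1] * sa
    perp = -pts[..., 0] * sa + pts[..., 1] * ca
    r = np.hypot(along, perp)
    phi = np.degrees(np.arctan2(perp, along))
    return r, phi


def _disc_cartesian(params: TrajectoryModelParams, r, phi):
    disc = np.asarray(params.canonical_disc_xy_deg)
    axis = math.radians(params.canonical_fd_angle_deg)
    ang = np.radians(phi) + axis
    x = disc[0] + r * np.cos(ang)
    y = disc[1] + r * np.sin(ang)
    return np.stack([x, y], axis=-1)


class TrajectoryDomainError(ValueError):
    """Raised when no trajectory of the model reaches a requested point."""


def vf_point_to_phi0(
    loc: VFLocation,
    transform: EyeTransform,
    params: TrajectoryModelParams | None = None,
    tol_deg: float = 1e-9,
) -> float:
    """Disc-entry angle of the trajectory through a VF location's retinal image."""
    params = params or transform.params
    if loc.is_blind_spot:
        raise ValueError(f"location {loc.index} is a blind-spot point")
    pt = transform.field_to_model(loc.x_deg, loc.y_deg)
    r, phi = _disc_polar(params, pt)
    r, phi = float(np.ravel(r)[0]), float(np.ravel(phi)[0])
    if r < params.r0_deg - 1e-9:
        raise TrajectoryDomainError(
            f"location {loc.index}: retinal point inside the disc circle "
            f"(r = {r:.2f} deg < r0 = {params.r0_deg} deg)"
        )
    lo, hi = (1e-6, 180.0) if phi >= 0 else (-180.0 + 1e-9, -1e-6)

    def g(phi0: float) -> float:
        return trace_trajectory(phi0, params, r) - phi

    # scan for a sign change; the map is monotone for the default atlas but
    # a grid scan keeps alternative atlases safe
    grid = np.linspace(lo, hi, 721)
    vals = np.array([g(p) for p in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    exact = np.nonzero(vals == 0.0)[0]
    if exact.size:
        return float(grid[exact[0]])
    if not sign_changes.size:
        raise TrajectoryDomainError(
            f"location {loc.index}: no trajectory reaches (r={r:.2f}, "
            f"phi={phi:.2f}) deg; hemifield coverage gap"
        )
    i = sign_changes[0]
    return float(brentq(g, grid[i], grid[i + 1], xtol=tol_deg))


# ---------------------------------------------------------------------------
# wedges


@dataclass(frozen=True)
class WedgeROI:
    """Per-VF-location peripapillary region of interest."""

    location_index: int
    phi0_center: float
    phi0_lo: float
    phi0_hi: float
    pixel_mask: np.ndarray
    ring_arc: tuple[float, float]

    @property
    def ring_arc_width(self) -> float:
        return self.ring_arc[1] - self.ring_arc[0]


def _bound_phi_at(params: TrajectoryModelParams, phi0: float, r) -> np.ndarray:
    """phi(r) for a bounding trajectory, clamping phi0 into the covered range."""
    phi0 = min(max(phi0, -180.0 + 1e-9), 180.0)
    return trace_trajectory(phi0, params, r)


class WedgeBuilder:
    """Rasterizes wedge ROIs on a normalized en-face frame.

    Precomputes the disc-centered polar coordinates of every pixel once per
    (eye, frame) so per-location wedges are cheap.
    """

    def __init__(
        self,
        transform: EyeTransform,
        map_shape: tuple[int, int],
        mm_per_px: float,
        disc_xy_px: tuple[float, float] | None = None,
        params: TrajectoryModelParams | None = None,
    ) -> None:
        self.transform = transform
        self.params = params or transform.params
        self.map_shape = tuple(map_shape)
        self.mm_per_px = float(mm_per_px)
        if disc_xy_px is None:
            disc_xy_px = transform.geometry.disc_xy
        self.disc_xy_px = tuple(disc_xy_px)

        h, w = self.map_shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts_px = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(float)
        deg_per_px = self.mm_per_px / transform.geometry.mm_per_deg
        # pixel centers -> canonical model frame; the normalized frame keeps
        # the eye's orientation, so only disc offset, y-flip, rotation, and
        # scale apply.
        v = (pts_px - np.asarray(self.disc_xy_px)) * np.array([1.0, -1.0])
        v = v * deg_per_px
        a = math.radians(transform.rotation_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        pts_model = (rot @ v.T).T * transform.scale + np.asarray(
            self.params.canonical_disc_xy_deg
        )
        self._r, self._phi = _disc_polar(self.params, pts_model)
        self._ok = self._r >= self.params.r0_deg
        self._r_ok = self._r[self._ok]
        # physical 1.75-mm ring radius around the individual disc, in the
        # canonical frame (the similarity transform scales radii)
        self.r_ring = (
            RING_DIAMETER_MM / 2.0 / transform.geometry.mm_per_deg
        ) * transform.scale

    def phi0_field(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (phi0, r): disc-entry angle of the trajectory through
        each pixel (NaN inside the disc circle or in coverage gaps).

        Inverts phi -> phi0 at each radius by interpolating a dense forward
        evaluation per hemifield; used by the synthetic generator.
        """
        h, w = self.map_shape
        params = self.params
        phi0_grid_sup = np.linspace(1e-4, 180.0, 1441)
        phi0_grid_inf = np.linspace(-180.0 + 1e-4, -1e-4, 1441)
        out = np.full(self._r.size, np.nan)
        r = self._r
        phi = self._phi
        ok = self._ok
        # quantize radii so the forward curve is evaluated once per radius bin
        r_binned = np.round(r, 2)
        for grid in (phi0_grid_sup, phi0_grid_inf):
            bc = [params.coefficients(p) for p in grid]
            b = np.array([x[0] for x in bc])
            c = np.array([x[1] for x in bc])
            sel = ok & ((phi >= 0) if grid[0] > 0 else (phi < 0))
            if not sel.any():
                continue
            sel_idx = np.flatnonzero(sel)
            for rv in np.unique(r_binned[sel]):
                at_r = sel_idx[r_binned[sel] == rv]
                curve = grid + b * (rv - params.r0_deg) ** c  # monotone in phi0
                tgt = phi[at_r]
                vals = np.interp(tgt, curve, grid, left=np.nan, right=np.nan)
                out[at_r] = vals
        return out.reshape(h, w), r.reshape(h, w)

    def wedge(self, loc: VFLocation, phi0: float | None = None) -> WedgeROI:
        params = self.params
        if phi0 is None:
            phi0 = vf_point_to_phi0(loc, self.transform, params)
        half = 1.96 * params.variability_sd_deg
        phi0_lo, phi0_hi = phi0 - half, phi0 + half

        mask = np.zeros(self._r.shape, dtype=bool)
        if self._r_ok.size:
            lo_phi = _bound_phi_at(params, phi0_lo, self._r_ok)
            hi_phi = _bound_phi_at(params, phi0_hi, self._r_ok)
            rel = np.mod(self._phi[self._ok] - lo_phi, 360.0)
            mask[self._ok] = rel <= (hi_phi - lo_phi)
        mask = mask.reshape(self.map_shape)
        if not mask.any():
            raise ValueError(f"location {loc.index}: ROI outside field")

        arc = (
            float(_bound_phi_at(params, phi0_lo, self.r_ring)),
            float(_bound_phi_at(params, phi0_hi, self.r_ring)),
        )
        if not arc[0] < arc[1]:
            raise ValueError(f"location {loc.index}: degenerate ring arc")
        return WedgeROI(
            location_index=loc.index,
            phi0_center=phi0,
            phi0_lo=phi0_lo,
            phi0_hi=phi0_hi,
            pixel_mask=mask,
            ring_arc=arc,
        )


def build_wedge(
    loc: VFLocation,
    transform: EyeTransform,
    map_shape: tuple[int, int],
    mm_per_px: float,
    params: TrajectoryModelParams | None = None,
    phi0: float | None = None,
    disc_xy_px: tuple[float, float] | None = None,
) -> WedgeROI:
    """ROI between the 95% CI pair of trajectories for one VF location.

    Convenience wrapper over :class:`WedgeBuilder` for one-off wedges;
    ``map_shape``/``mm_per_px`` describe the normalized en-face frame the
    pixel mask is rasterized on and ``disc_xy_px`` the disc center on that
    frame.  The wedge runs from the disc circle r0 out to the image
    boundary; the ring arc is the interval swept by the two bounding
    trajectories at the 3.5-mm-ring radius.
    """
    builder = WedgeBuilder(transform, map_shape, mm_per_px, disc_xy_px, params)
    return builder.wedge(loc, phi0=phi0)


def write_wedge_overlay(
    perfused: np.ndarray,
    wedges: "list[WedgeROI]",
    path: str | Path,
    highlight: tuple[int, ...] = (),
) -> None:
    """QC overlay: wedge outlines over the binary perfusion map (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.asarray(perfused, float), cmap="gray", interpolation="nearest")
    for w in wedges:
        color = "deepskyblue" if w.location_index in highlight else "orange"
        ax.contour(w.pixel_mask.astype(float), levels=[0.5],
                   colors=color, linewidths=0.6)
    ax.set_axis_off()
    fig.savefig(path, dpi=130, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# geometry ingest


def read_geometry_csv(path: str | Path, mm_per_px_by_subject: dict[str, float]):
    """Read fovea/disc centers; returns {subject_id: EyeGeometry}."""
    import csv as _csv

    out: dict[str, EyeGeometry] = {}
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            sid = row["subject_id"]
            out[sid] = EyeGeometry.from_pixels(
                fovea_xy=(float(row["fovea_x_px"]), float(row["fovea_y_px"])),
                disc_xy=(float(row["disc_x_px"]), float(row["disc_y_px"])),
                mm_per_px=mm_per_px_by_subject[sid],
            )
    return out
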