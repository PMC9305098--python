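"""Synthetic cohort generator with known ground truth.

Produces complete per-eye input bundles (en-face angiograms, circumpapillary
RNFL profiles, 30-2 exams, fovea/disc geometry) whose structure-function
relationship is a configured broken stick with per-subject random
intercepts.  Damage is parameterized on the disc-entry angle so structural
and functional ground truth stay consistent by construction through the
same trajectory mapping the pipeline uses, which is what makes closed-loop
tests meaningful.

Two tiers are provided: :func:`simulate_cohort` renders full image bundles
for pipeline tests, and :func:`simulate_focal_records` draws analysis-table
rows directly for statistical simulations where imaging is irrelevant.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, disk as disk_footprint

from . import vf_data
from .config import MM_PER_DEG, TARGET_MM
from .focal_metrics import RNFLProfile, write_rnfl_csv
from .octa_preproc import OCTAImage
from .trajectory import (
    EyeGeometry,
    TrajectoryModelParams,
    WedgeBuilder,
    fit_to_eye,
    load_default_params,
    vf_point_to_phi0,
)
from .vf_data import VFExam, write_vf_exam

__all__ = [
    "CohortConfig",
    "BrokenStickLink",
    "SubjectTruth",
    "CohortBundle",
    "simulate_cohort",
    "render_angiogram",
    "truth_table",
    "write_cohort",
    "simulate_focal_records",
    "simulate_comparison_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults target the published cohort's scale."""

    n_subjects: int = 46
    seed: int = 0
    md_range_db: tuple[float, float] = (-26.0, 0.0)
    # broken-stick link (structure as a function of fVFD, breakpoint in dB)
    psi_true_db: float = -9.0
    slope_before_cd: float = 0.002
    slope_change_cd: float = 0.013
    slope_before_t: float = 0.65
    slope_change_t: float = 0.92
    # healthy baselines
    cd_base: float = 0.22
    t_base_um: float = 85.0
    t_hump_amplitude_um: float = 12.0
    # noise
    sigma_b_cd: float = 0.015
    sigma_b_t: float = 3.0
    sigma_vf_db: float = 1.0
    image_noise_sd: float = 6.0
    profile_noise_sd_um: float = 1.5
    # rendering; the pixel scale is locked to the normalized frame's scale
    # (TARGET_MM / normalized_px) so normalization is an exact center crop
    # and never resamples the capillary texture
    image_px: int = 384
    normalized_px: int = 350
    vessel_count: int = 4
    vessel_width_mm: float = 0.10
    n_ring_samples: int = 768
    disc_radius_deg: float = 1.8
    # geometry jitter (truncated at +-2 SD; large fovea-disc distances
    # would otherwise scale near-disc VF points inside the model's r0)
    fd_distance_sd_deg: float = 0.4
    fd_angle_sd_deg: float = 2.0
    disc_center_jitter_px: float = 4.0
    # damage field
    max_bumps: int = 3
    diffuse_max: float = 0.15
    qc_fail_rate: float = 0.0

    @property
    def mm_per_px(self) -> float:
        return TARGET_MM / self.normalized_px

    @property
    def image_mm(self) -> float:
        return self.image_px * self.mm_per_px

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not (0 < self.cd_base < 1):
            raise ValueError("cd_base must be in (0, 1)")
        if self.image_px < self.normalized_px:
            raise ValueError("rendered field must cover the normalized frame")
        if not (self.md_range_db[0] < self.psi_true_db < self.md_range_db[1]):
            raise ValueError("breakpoint must lie inside the MD range")
        for name in ("sigma_b_cd", "sigma_b_t", "sigma_vf_db",
                     "image_noise_sd", "profile_noise_sd_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        link = BrokenStickLink.for_cd(self)
        if link.structure(self.md_range_db[0]) <= 0:
            raise ValueError("infeasible config: capillary floor below zero")

    def noiseless(self) -> "CohortConfig":
        from dataclasses import replace

        return replace(
            self,
            sigma_b_cd=0.0,
            sigma_b_t=0.0,
            sigma_vf_db=0.0,
            image_noise_sd=0.0,
            profile_noise_sd_um=0.0,
        )


@dataclass(frozen=True)
class BrokenStickLink:
    """Two-slope structural response to functional loss.

    structure(v) is piecewise linear in fVFD v (dB, <= 0), equal to ``base``
    at v = 0, with slope ``slope_after`` right of the breakpoint ``psi`` and
    the shallower ``slope_before`` left of it (the floor side).
    """

    psi: float
    slope_before: float
    slope_after: float
    base: float

    @classmethod
    def for_cd(cls, cfg: CohortConfig) -> "BrokenStickLink":
        return cls(
            psi=cfg.psi_true_db,
            slope_before=cfg.slope_before_cd,
            slope_after=cfg.slope_before_cd + cfg.slope_change_cd,
            base=cfg.cd_base,
        )

    @classmethod
    def for_t(cls, cfg: CohortConfig) -> "BrokenStickLink":
        return cls(
            psi=cfg.psi_true_db,
            slope_before=cfg.slope_before_t,
            slope_after=cfg.slope_before_t + cfg.slope_change_t,
            base=cfg.t_base_um,
        )

    @property
    def value_at_bp(self) -> float:
        return self.base + self.slope_after * self.psi

    def structure(self, v):
        v = np.asarray(v, float)
        out = np.where(
            v >= self.psi,
            self.base + self.slope_after * v,
            self.value_at_bp + self.slope_before * (v - self.psi),
        )
        return out if out.ndim else float(out)

    def inverse(self, s):
        s = np.asarray(s, float)
        out = np.where(
            s >= self.value_at_bp,
            (s - self.base) / self.slope_after,
            self.psi + (s - self.value_at_bp) / self.slope_before,
        )
        return out if out.ndim else float(out)


@dataclass
class SubjectTruth:
    subject_id: str
    geometry: EyeGeometry
    mm_per_px: float
    md_target_db: float
    intercept_cd: float
    intercept_t: float
    damage_amplitude: float
    bump_centers: tuple[float, ...]
    bump_widths: tuple[float, ...]
    bump_amps: tuple[float, ...]
    diffuse: float
    vessel_phi0: tuple[float, ...]
    large_vessel_mask: np.ndarray | None = None


@dataclass
class CohortBundle:
    config: CohortConfig
    exams: dict[str, VFExam]
    images: dict[str, OCTAImage]
    profiles: dict[str, RNFLProfile]
    geometries: dict[str, EyeGeometry]
    subject_truth: dict[str, SubjectTruth]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# damage field


def _damage_v(phi0, truth: SubjectTruth, cfg: CohortConfig):
    """Noiseless fVFD field over disc-entry angle (dB, <= 0); NaN -> healthy."""
    phi0 = np.asarray(phi0, float)
    u = np.full(phi0.shape, truth.diffuse)
    for c, w, a in zip(truth.bump_centers, truth.bump_widths, truth.bump_amps):
        u = u + a * np.exp(-0.5 * ((phi0 - c) / w) ** 2)
    u = np.clip(u, 0.0, 1.0) * truth.damage_amplitude
    v = cfg.md_range_db[0] * u
    return np.where(np.isnan(phi0), 0.0, v)


def _sample_subject(
    sid: str, cfg: CohortConfig, params: TrajectoryModelParams, rng: np.random.Generator
) -> SubjectTruth:
    # geometry: disc near the image center, fovea outside the frame
    mm_per_px = cfg.mm_per_px
    deg_per_px = mm_per_px / MM_PER_DEG
    center = cfg.image_px / 2.0
    disc = (
        center + rng.normal(0, cfg.disc_center_jitter_px),
        center + rng.normal(0, cfg.disc_center_jitter_px),
    )
    def trunc_normal(sd: float) -> float:
        return float(np.clip(rng.normal(0, sd), -2 * sd, 2 * sd)) if sd > 0 else 0.0

    fd_dist = params.canonical_fd_distance_deg + trunc_normal(cfg.fd_distance_sd_deg)
    fd_angle = params.canonical_fd_angle_deg + trunc_normal(cfg.fd_angle_sd_deg)
    fovea = (
        disc[0] - fd_dist * math.cos(math.radians(fd_angle)) / deg_per_px,
        disc[1] + fd_dist * math.sin(math.radians(fd_angle)) / deg_per_px,
    )
    geom = EyeGeometry(
        fovea_xy=fovea,
        disc_xy=disc,
        fd_distance_deg=fd_dist,
        fd_angle_deg=fd_angle,
    )

    n_bumps = int(rng.integers(1, cfg.max_bumps + 1))
    hemis = rng.choice([-1.0, 1.0], size=n_bumps)
    centers = tuple(h * rng.uniform(40.0, 140.0) for h in hemis)
    widths = tuple(rng.uniform(12.0, 35.0) for _ in range(n_bumps))
    amps = tuple(rng.uniform(0.5, 1.0) for _ in range(n_bumps))
    diffuse = float(rng.uniform(0.0, cfg.diffuse_max))
    md_target = float(rng.uniform(*cfg.md_range_db))

    truth = SubjectTruth(
        subject_id=sid,
        geometry=geom,
        mm_per_px=mm_per_px,
        md_target_db=md_target,
        intercept_cd=float(rng.normal(0, cfg.sigma_b_cd)),
        intercept_t=float(rng.normal(0, cfg.sigma_b_t)),
        damage_amplitude=1.0,
        bump_centers=centers,
        bump_widths=widths,
        bump_amps=amps,
        diffuse=diffuse,
        vessel_phi0=tuple(
            base + rng.uniform(-8, 8)
            for base in (62.0, 104.0, -62.0, -104.0)[: cfg.vessel_count]
        ),
    )
    return truth


def _calibrate_amplitude(
    truth: SubjectTruth,
    cfg: CohortConfig,
    phi0_by_loc: dict[int, float],
) -> None:
    """Scale the damage field so the implied MD is close to the target.

    Bisection on the amplitude in [0, 1]; severe targets may saturate at 1.
    """
    phi0s = np.array(list(phi0_by_loc.values()))
    lo, hi = 0.0, 1.0
    target = truth.md_target_db
    for _ in range(40):
        truth.damage_amplitude = 0.5 * (lo + hi)
        md = float(np.mean(_damage_v(phi0s, truth, cfg)))
        if md > target:  # too mild (md closer to 0)
            lo = truth.damage_amplitude
        else:
            hi = truth.damage_amplitude
    truth.damage_amplitude = 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# rendering


def _vectorized_bc(params: TrajectoryModelParams, phi0: np.ndarray):
    b = np.zeros_like(phi0)
    c = np.ones_like(phi0)
    for hemi, sel in (
        (params.superior, phi0 > 0),
        (params.inferior, phi0 < 0),
    ):
        if not sel.any():
            continue
        a = np.abs(phi0[sel])
        u = (hemi.center_deg - a) / hemi.width_deg
        t = np.tanh(u)
        bb = hemi.sign * np.exp(hemi.beta0 + hemi.beta1 * t)
        if params.nasal_taper_deg > 0:
            bb = bb * np.tanh(a / params.nasal_taper_deg)
        b[sel] = bb
        c[sel] = hemi.c0 - hemi.c1 * t
    return b, c


def render_angiogram(
    truth: SubjectTruth,
    cfg: CohortConfig,
    params: TrajectoryModelParams,
    rng: np.random.Generator,
    density_field: np.ndarray | None = None,
    builder: WedgeBuilder | None = None,
) -> tuple[OCTAImage, np.ndarray]:
    """Render an en-face angiogram and return it with the true vessel mask.

    Capillaries are drawn as short segments oriented along the local
    trajectory tangent; per-pixel seeding probability is chosen so expected
    coverage equals the target density field exactly.  Large vessels are
    smooth arcade curves (traced trajectories) of configured width.
    """
    n = cfg.image_px
    mm_per_px = cfg.mm_per_px
    if builder is None:
        transform = fit_to_eye(params, truth.geometry)
        builder = WedgeBuilder(transform, (n, n), mm_per_px, params=params)
    phi0_map, r_map = builder.phi0_field()

    if density_field is None:
        v = _damage_v(phi0_map, truth, cfg)
        link = BrokenStickLink.for_cd(cfg)
        density_field = np.clip(link.structure(v) + truth.intercept_cd, 0.005, 0.95)

    # tangent direction of the trajectory through each pixel
    b, c = _vectorized_bc(params, np.nan_to_num(phi0_map))
    dr = np.clip(r_map - params.r0_deg, 1e-6, None)
    dphi_dr = b * c * dr ** (c - 1.0)  # deg per deg
    phi_map = builder._phi.reshape(n, n)
    # absolute position angle in the individual's image frame (y-up)
    ang = np.radians(phi_map) + math.radians(truth.geometry.fd_angle_deg)
    k = r_map * np.radians(dphi_dr)  # tangential component e_r + k*e_phi
    tx = np.cos(ang) - k * np.sin(ang)
    ty = np.sin(ang) + k * np.cos(ang)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    tx, ty = tx / norm, -ty / norm  # flip to image y-down

    seg_len = 4
    p_seed = 1.0 - (1.0 - density_field) ** (1.0 / seg_len)
    seeds = rng.random((n, n)) < p_seed
    cap = np.zeros((n, n), dtype=bool)
    ys, xs = np.nonzero(seeds)
    dxs, dys = tx[ys, xs], ty[ys, xs]
    for k in range(seg_len):
        px = np.clip(np.round(xs + k * dxs).astype(int), 0, n - 1)
        py = np.clip(np.round(ys + k * dys).astype(int), 0, n - 1)
        cap[py, px] = True

    # large vessels: arcade centerlines traced from near the disc outward
    vessel = np.zeros((n, n), dtype=bool)
    deg_per_px = mm_per_px / MM_PER_DEG
    disc = np.asarray(truth.geometry.disc_xy)
    axis_indiv = math.radians(truth.geometry.fd_angle_deg)
    r_line = np.arange(0.8, n * deg_per_px * 0.9, deg_per_px * 0.5)
    for phi0 in truth.vessel_phi0:
        bb, cc = params.coefficients(phi0)
        phi_line = phi0 + bb * np.clip(r_line - params.r0_deg, 0, None) ** cc
        a = np.radians(phi_line) + axis_indiv
        x = disc[0] + (r_line / deg_per_px) * np.cos(a)
        y = disc[1] - (r_line / deg_per_px) * np.sin(a)
        xi = np.round(x).astype(int)
        yi = np.round(y).astype(int)
        ok = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n)
        vessel[yi[ok], xi[ok]] = True
    width_px = max(2, int(round(cfg.vessel_width_mm / mm_per_px)))
    vessel = dilation(vessel, disk_footprint(width_px // 2))

    # thin (or pad) the segment texture to the per-sector target density:
    # within 2-degree disc-entry-angle bins the realized coverage of
    # vessel-free pixels inside the eventual normalization crop is forced to
    # the integral of the density field, so wedge-averaged density carries
    # no binomial sampling noise
    off = (cfg.image_px - cfg.normalized_px) // 2
    crop = np.zeros((n, n), dtype=bool)
    crop[off : off + cfg.normalized_px, off : off + cfg.normalized_px] = True
    cap = _thin_to_density(
        cap, density_field, np.where(vessel | ~crop, np.nan, phi0_map), rng
    )

    img = np.full((n, n), 20.0)
    img[cap] = 170.0
    # avascular disc area
    rr, cc_idx = draw_disk(
        (truth.geometry.disc_xy[1], truth.geometry.disc_xy[0]),
        cfg.disc_radius_deg / deg_per_px,
        shape=(n, n),
    )
    img[rr, cc_idx] = 35.0
    img[vessel] = 230.0
    if cfg.image_noise_sd > 0:
        img = img + rng.normal(0, cfg.image_noise_sd, (n, n))
    img = np.clip(img, 0, 255)
    truth.large_vessel_mask = vessel
    return OCTAImage(pixels=img, mm_per_px=mm_per_px), vessel


def _thin_to_density(
    cap: np.ndarray,
    density: np.ndarray,
    phi0_map: np.ndarray,
    rng: np.random.Generator,
    bin_deg: float = 2.0,
) -> np.ndarray:
    """Match realized coverage to the density integral per phi0 bin."""
    cap = cap.copy()
    flat_cap = cap.ravel()
    flat_density = density.ravel()
    phi0 = phi0_map.ravel()
    valid = ~np.isnan(phi0)
    bins = np.full(phi0.shape, -1, dtype=int)
    bins[valid] = ((phi0[valid] + 180.0) / bin_deg).astype(int)
    for b in np.unique(bins[valid]):
        idx = np.flatnonzero(bins == b)
        target = int(round(flat_density[idx].sum()))
        on = idx[flat_cap[idx]]
        if on.size > target:
            drop = rng.choice(on, size=on.size - target, replace=False)
            flat_cap[drop] = False
        elif on.size < target:
            off = idx[~flat_cap[idx]]
            add = rng.choice(off, size=min(target - on.size, off.size), replace=False)
            flat_cap[add] = True
    return flat_cap.reshape(cap.shape)


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(
    cfg: CohortConfig,
    params: TrajectoryModelParams | None = None,
) -> CohortBundle:
    """Generate the full input bundle plus ground truth for one cohort."""
    params = params or load_default_params()
    rng = np.random.default_rng(cfg.seed)
    sub_rngs = rng.spawn(cfg.n_subjects)
    grid = vf_data.build_grid("right")
    locations = vf_data.analysis_locations(grid)
    link_cd = BrokenStickLink.for_cd(cfg)
    link_t = BrokenStickLink.for_t(cfg)

    exams, images, profiles, geoms, truths = {}, {}, {}, {}, {}
    truth_rows = []
    for i in range(cfg.n_subjects):
        srng = sub_rngs[i]
        sid = f"S{i + 1:03d}"
        truth = _sample_subject(sid, cfg, params, srng)
        transform = fit_to_eye(params, truth.geometry)
        builder = WedgeBuilder(
            transform, (cfg.image_px, cfg.image_px), truth.mm_per_px, params=params
        )
        phi0_by_loc = {
            loc.index: vf_point_to_phi0(loc, transform, params)
            for loc in locations
        }
        _calibrate_amplitude(truth, cfg, phi0_by_loc)

        # density field and angiogram
        phi0_map, _ = builder.phi0_field()
        v_field = _damage_v(phi0_map, truth, cfg)
        density = np.clip(
            link_cd.structure(v_field) + truth.intercept_cd, 0.005, 0.95
        )
        image, vessel_mask = render_angiogram(
            truth, cfg, params, srng, density_field=density, builder=builder
        )

        # ring profile: thickness from the damage field at the ring angles
        theta = np.linspace(0.0, 360.0, cfg.n_ring_samples, endpoint=False)
        phi0_ring = _invert_ring_angles(params, builder.r_ring, theta)
        v_ring = _damage_v(phi0_ring, truth, cfg)
        hump = _double_hump(theta, cfg)
        thickness = (
            link_t.structure(v_ring)
            + hump
            - hump.mean()
            + truth.intercept_t
        )
        if cfg.profile_noise_sd_um > 0:
            thickness = thickness + srng.normal(0, cfg.profile_noise_sd_um, theta.size)
        thickness = np.clip(thickness, 0.0, None)
        profile = RNFLProfile(angles_deg=theta, thickness_um=thickness)

        # per-location truth and exam; truth integrals are restricted to the
        # central crop the pipeline retains after scale normalization
        crop = np.zeros((cfg.image_px, cfg.image_px), dtype=bool)
        off = (cfg.image_px - cfg.normalized_px) // 2
        crop[off : off + cfg.normalized_px, off : off + cfg.normalized_px] = True
        td = {}
        for loc in locations:
            wedge = builder.wedge(loc, phi0=phi0_by_loc[loc.index])
            roi_ok = wedge.pixel_mask & ~vessel_mask & crop
            fcd_true = float(density[roi_ok].mean()) if roi_ok.any() else np.nan
            arc_sel = np.mod(theta - wedge.ring_arc[0], 360.0) < (
                wedge.ring_arc[1] - wedge.ring_arc[0]
            )
            frnflt_true = float(thickness[arc_sel].mean()) if arc_sel.any() else np.nan
            v_loc = link_cd.inverse(np.clip(fcd_true - truth.intercept_cd,
                                            link_cd.structure(cfg.md_range_db[0]),
                                            cfg.cd_base))
            v_loc = float(np.clip(v_loc, cfg.md_range_db[0], 10.0))
            noise = float(srng.normal(0, cfg.sigma_vf_db)) if cfg.sigma_vf_db > 0 else 0.0
            td[loc.index] = float(np.clip(v_loc + noise, -40.0, 10.0))
            truth_rows.append(
                {
                    "subject_id": sid,
                    "loc_index": loc.index,
                    "phi0_deg": phi0_by_loc[loc.index],
                    "damage_v_db": v_loc,
                    "fCD_true": fcd_true,
                    "fRNFLT_true_um": frnflt_true,
                    "fVFD_noiseless_db": v_loc,
                }
            )

        qc_fail = srng.random() < cfg.qc_fail_rate
        exam = VFExam(
            subject_id=sid,
            eye="right",
            td=td,
            md=float(np.mean(list(td.values()))),
            fixation_loss_frac=float(srng.uniform(0.34, 0.6)) if qc_fail
            else float(srng.uniform(0.0, 0.25)),
            fp_frac=float(srng.uniform(0.0, 0.15)),
            fn_frac=float(srng.uniform(0.0, 0.15)),
        )
        exams[sid] = exam
        images[sid] = image
        profiles[sid] = profile
        geoms[sid] = truth.geometry
        truths[sid] = truth

    return CohortBundle(
        config=cfg,
        exams=exams,
        images=images,
        profiles=profiles,
        geometries=geoms,
        subject_truth=truths,
        truth=pd.DataFrame(truth_rows),
    )


def _double_hump(theta: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Superior/inferior thickness humps of the healthy TSNIT profile."""
    tw = np.mod(theta + 180.0, 360.0) - 180.0
    return cfg.t_hump_amplitude_um * (
        np.exp(-0.5 * ((tw - 100.0) / 45.0) ** 2)
        + np.exp(-0.5 * ((tw + 100.0) / 45.0) ** 2)
    )


def _invert_ring_angles(
    params: TrajectoryModelParams, r_ring: float, theta: np.ndarray
) -> np.ndarray:
    """phi0 of the trajectory crossing the ring at each position angle."""
    out = np.full(theta.shape, np.nan)
    tw = np.mod(theta + 180.0, 360.0) - 180.0
    for sign in (1.0, -1.0):
        grid = sign * np.linspace(1e-4, 180.0 - 1e-6, 1441)
        if sign < 0:
            grid = grid[::-1]
        bc = [params.coefficients(p) for p in grid]
        b = np.array([x[0] for x in bc])
        c = np.array([x[1] for x in bc])
        curve = grid + b * (r_ring - params.r0_deg) ** c
        sel = (tw >= 0) if sign > 0 else (tw < 0)
        out[sel] = np.interp(tw[sel], curve, grid, left=np.nan, right=np.nan)
    return out


def truth_table(bundle: CohortBundle) -> pd.DataFrame:
    return bundle.truth.copy()


# ---------------------------------------------------------------------------
# file emission


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict:
    """Write the bundle in the exact dialects the ingest readers consume."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": [], "config": asdict(bundle.config)}
    geo_rows = []
    for sid in sorted(bundle.exams):
        img = bundle.images[sid]
        Image.fromarray(np.round(img.pixels).astype(np.uint8)).save(
            out / f"octa_{sid}.png"
        )
        with open(out / f"octa_{sid}.json", "w") as fh:
            json.dump({"mm_per_px": img.mm_per_px, "field_deg": img.field_deg}, fh)
        write_rnfl_csv(bundle.profiles[sid], out / f"rnfl_{sid}.csv")
        write_vf_exam(
            bundle.exams[sid], out / f"vf_{sid}.csv", out / f"vf_{sid}.json"
        )
        g = bundle.geometries[sid]
        geo_rows.append(
            {
                "subject_id": sid,
                "eye": "right",
                "fovea_x_px": g.fovea_xy[0],
                "fovea_y_px": g.fovea_xy[1],
                "disc_x_px": g.disc_xy[0],
                "disc_y_px": g.disc_xy[1],
            }
        )
        manifest["subjects"].append(sid)
    pd.DataFrame(geo_rows).to_csv(out / "geometry.csv", index=False)
    bundle.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# lightweight statistical generators


def simulate_focal_records(
    n_subjects: int,
    n_locations: int,
    psi: float,
    slope_before: float,
    slope_change: float,
    sigma_b: float,
    sigma_e: float,
    rng: np.random.Generator,
    x_range: tuple[float, float] = (-26.0, 0.0),
    base: float = 0.22,
    predictor_id: str = "fCD",
) -> pd.DataFrame:
    """Analysis-table rows from an explicit broken-stick mixed model.

    fVFD values are uniform on ``x_range``; the structural response follows
    the two-slope line with breakpoint ``psi`` plus a per-subject random
    intercept (sd ``sigma_b``) and residual noise (sd ``sigma_e``).
    """
    link = BrokenStickLink(
        psi=psi, slope_before=slope_before,
        slope_after=slope_before + slope_change, base=base,
    )
    n = n_subjects * n_locations
    subjects = np.repeat([f"S{i + 1:03d}" for i in range(n_subjects)], n_locations)
    v = rng.uniform(x_range[0], x_range[1], n)
    b = np.repeat(rng.normal(0.0, sigma_b, n_subjects), n_locations)
    s = link.structure(v) + b + rng.normal(0.0, sigma_e, n)
    col = "fCD" if predictor_id == "fCD" else "fRNFLT_um"
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "loc_index": np.tile(np.arange(1, n_locations + 1), n_subjects),
            "fVFD_db": v,
            col: s,
        }
    )


def simulate_comparison_cohort(
    rng: np.random.Generator,
    n_subjects: int = 46,
    n_locations: int = 74,
    sigma_cd: float = 0.02,
    sigma_t: float = 8.0,
    sigma_vf: float = 2.0,
    cfg: CohortConfig | None = None,
) -> pd.DataFrame:
    """Analysis table where both structural channels are informative but the
    thickness channel is noisier; used for model-comparison simulations.
    """
    cfg = cfg or CohortConfig()
    link_cd = BrokenStickLink.for_cd(cfg)
    link_t = BrokenStickLink.for_t(cfg)
    n = n_subjects * n_locations
    subjects = np.repeat([f"S{i + 1:03d}" for i in range(n_subjects)], n_locations)
    severity = np.repeat(rng.uniform(-20.0, -2.0, n_subjects), n_locations)
    v = np.clip(severity + rng.normal(0, 6.0, n), cfg.md_range_db[0], 0.0)
    fcd = link_cd.structure(v) + rng.normal(0, sigma_cd, n)
    frnflt = link_t.structure(v) + rng.normal(0, sigma_t, n)
    fvfd = v + rng.normal(0, sigma_vf, n)
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "loc_index": np.tile(np.arange(1, n_locations + 1), n_subjects),
            "fVFD_db": fvfd,
            "fCD": fcd,
            "fRNFLT_um": frnflt,
        }
    )
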