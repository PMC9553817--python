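"""Digital cardiac phantom: known geometry + kinetics, forward-simulated PET.

The left ventricle is an ellipsoidal shell (epicardial minus endocardial
ellipsoid, common centre, long axis along z before tilting), optionally with a
septal wedge: within an angular span facing the right ventricle the
endocardial surface is pulled inward, thickening the wall.  The right
ventricle is a clipped cylinder abutting the septum, and the surrounding
thorax carries a low perfusable-tissue background (lung/mediastinum) — real
hearts are not embedded in vacuum, and surrounding activity is what pushes
edge-detection contours outward on blurry scanners.

Every phantom knows its analytic truth: LV mass from the closed-form shell
volume (plus a numerically integrated wedge), and mid-septal wall thickness as
the epi-endo gap along the LV-to-RV line in the equatorial plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict


import numpy as np
from scipy.ndimage import gaussian_filter

from .kinetics import (
    DEFAULT_PARTITION_COEFFICIENT,
    DynamicImage,
    FrameSchedule,
    InputFunctions,
    ParametricMaps,
    frame_average,
    tissue_response,
)

#: Specific gravity of soft tissue, g/mL.
TISSUE_DENSITY = 1.05

#: Voxel labels in GroundTruth.labels.
LABEL_BACKGROUND, LABEL_WALL, LABEL_LV_CAVITY, LABEL_RV_CAVITY, LABEL_THORAX = 0, 1, 2, 3, 4

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GammaVariate:
    """Bolus model A ((t-t0)/(alpha beta))^alpha exp(alpha - (t-t0)/beta); peak A at t0+alpha*beta."""

    t0: float = 11.0          # s, bolus arrival
    alpha: float = 3.0
    beta: float = 4.0         # s
    amplitude: float = 200.0  # kBq/mL at the peak


@dataclass
class SubjectInfo:
    sex: str = "male"
    height_cm: float = 178.0
    weight_kg: float = 82.0


@dataclass
class PhantomSpec:
    """Generative description of one synthetic heart and its acquisition."""

    # geometry, mm; semi-axes ordered (long, short-x, short-y); long axis -> z
    epi_semi_axes: tuple[float, float, float] = (45.0, 30.0, 30.0)
    endo_semi_axes: tuple[float, float, float] = (36.0, 21.0, 21.0)
    septal_extra_mm: float = 0.0
    septal_span_deg: float = 120.0
    long_axis_tilt: tuple[float, float] = (0.0, 0.0)   # degrees about (y, x)
    rv_enabled: bool = True
    rv_offset_mm: float = 22.0       # cylinder centre offset along +x
    rv_radius_mm: float = 20.0
    # kinetics
    ptf_myo: float = 0.70            # mL/mL
    mbf_myo: float = 0.9             # mL.min-1.mL-1 (rest; stress is just a larger value)
    va_myo: float = 0.15             # arterial blood fraction inside the wall
    background_enabled: bool = True
    ptf_background: float = 0.25     # lung/mediastinal perfusable fraction
    mbf_background: float = 0.25
    arterial_input: GammaVariate = field(default_factory=GammaVariate)
    rv_input: GammaVariate = field(default_factory=lambda: GammaVariate(t0=5.0, alpha=2.5, beta=4.0, amplitude=220.0))
    partition_coefficient: float = DEFAULT_PARTITION_COEFFICIENT
    # acquisition
    psf_fwhm: float = 5.0            # mm, isotropic Gaussian
    noise_scale: float = 1.5         # unitless, see simulate_dynamic
    voxel_size: float = 2.0          # mm, isotropic
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    supersample: int = 3             # per-axis sub-voxel sampling for tissue fractions
    seed: int = 0
    subject: SubjectInfo = field(default_factory=SubjectInfo)

    def __post_init__(self):
        epi = np.asarray(self.epi_semi_axes, float)
        endo = np.asarray(self.endo_semi_axes, float)
        if np.any(endo >= epi):
            raise ValueError("endocardial semi-axes must be smaller than epicardial, component-wise")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.septal_extra_mm < 0 or not 0 < self.septal_span_deg <= 360:
            raise ValueError("invalid septal wedge parameters")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key, typ in (("arterial_input", GammaVariate), ("rv_input", GammaVariate),
                         ("subject", SubjectInfo)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        for key in ("epi_semi_axes", "endo_semi_axes", "long_axis_tilt", "grid_shape",
                    "center_offset_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)


@dataclass
class GroundTruth:
    """Rasterised labels, analytic scalars and true parametric maps for one phantom."""

    labels: np.ndarray                  # uint8, (nx, ny, nz)
    tissue_fractions: dict              # label name -> float volume of per-voxel fractions
    true_lvm_analytic: float            # g
    true_lvm_voxelized: float           # g
    true_wt: float                      # mm at mid-septum
    true_maps: ParametricMaps
    lv_center_mm: np.ndarray            # volume-frame coordinates of the LV centre
    rv_center_mm: np.ndarray | None
    spacing: tuple[float, float, float]
    thin_wall_warning: bool = False


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _tilt_matrix(tilt_deg: tuple[float, float]) -> np.ndarray:
    """Rotation applied to the phantom (about y, then x)."""
    ay, ax = np.deg2rad(tilt_deg[0]), np.deg2rad(tilt_deg[1])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    return rx @ ry


def _phantom_frame(points: np.ndarray, spec: PhantomSpec, center: np.ndarray) -> np.ndarray:
    """Map volume-frame mm points into the (untilted) phantom frame."""
    R = _tilt_matrix(spec.long_axis_tilt)
    return (points - center) @ R  # == R.T applied to each row


def _inside_ellipsoid(q: np.ndarray, semi_axes_xyz: np.ndarray) -> np.ndarray:
    return (q / semi_axes_xyz) ** 2 @ np.ones(3) <= 1.0


def _septal_shrink(q: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Per-point endocardial shrink delta(theta): extra wall inside the septal span."""
    if spec.septal_extra_mm == 0:
        return np.zeros(q.shape[0])
    theta = np.arctan2(q[:, 1], q[:, 0])
    half = np.deg2rad(spec.septal_span_deg) / 2
    return np.where(np.abs(theta) <= half, spec.septal_extra_mm, 0.0)


def _classify_points(q: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Label phantom-frame points; later labels never override earlier heart labels."""
    a, b, c = spec.epi_semi_axes
    ae, be, ce = spec.endo_semi_axes
    epi_axes = np.array([b, c, a])           # phantom frame: (x, y, z)
    delta = _septal_shrink(q, spec)
    endo_axes = np.stack([be - delta, ce - delta, ae - delta], axis=1)
    inside_epi = _inside_ellipsoid(q, epi_axes)
    inside_endo = np.einsum("ij,ij->i", (q / endo_axes), (q / endo_axes)) <= 1.0

    labels = np.zeros(q.shape[0], dtype=np.uint8)
    labels[inside_epi] = LABEL_WALL
    labels[inside_epi & inside_endo] = LABEL_LV_CAVITY
    if spec.rv_enabled:
        rv = (
            ((q[:, 0] - spec.rv_offset_mm) ** 2 + q[:, 1] ** 2 <= spec.rv_radius_mm**2)
            & (np.abs(q[:, 2]) <= 0.6 * a)
            & ~inside_epi
        )
        labels[rv] = LABEL_RV_CAVITY
    if spec.background_enabled:
        labels[labels == LABEL_BACKGROUND] = LABEL_THORAX
    return labels


def _wedge_volume(spec: PhantomSpec, n_theta: int = 256, n_z: int = 512) -> float:
    """Extra endocardium-displacement volume, by 2-D quadrature in (theta, z)."""
    if spec.septal_extra_mm == 0:
        return 0.0
    ae, be, ce = spec.endo_semi_axes
    d = spec.septal_extra_mm
    half = np.deg2rad(spec.septal_span_deg) / 2
    theta = np.linspace(-half, half, n_theta)
    z = np.linspace(-ae, ae, n_z)

    def r2(theta_, z_, axes):  # squared radial boundary of an ellipsoid cross-section
        az, bx, by = axes
        s = 1 - (z_[None, :] / az) ** 2
        s = np.clip(s, 0.0, None)
        bx2 = (bx**2) * s
        by2 = (by**2) * s
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_ = 1.0 / (np.cos(theta_[:, None]) ** 2 / bx2 + np.sin(theta_[:, None]) ** 2 / by2)
        return np.where(s > 0, r2_, 0.0)

    r2_base = r2(theta, z, (ae, be, ce))
    r2_shrunk = r2(theta, z, (ae - d, be - d, ce - d))
    integrand = 0.5 * (r2_base - r2_shrunk)
    return float(np.trapezoid(np.trapezoid(integrand, z, axis=1), theta))


def analytic_shell_mass(spec: PhantomSpec) -> float:
    """Closed-form LV mass in grams: 1.05 g/mL x shell volume (+ septal wedge)."""
    a, b, c = spec.epi_semi_axes
    ae, be, ce = spec.endo_semi_axes
    vol_mm3 = 4.0 / 3.0 * np.pi * (a * b * c - ae * be * ce) + _wedge_volume(spec)
    return TISSUE_DENSITY * vol_mm3 / 1000.0


def analytic_septal_wt(spec: PhantomSpec) -> float:
    """Epi-endo gap along the LV->RV line (the +x axis) in the equatorial plane."""
    b = spec.epi_semi_axes[1]
    be = spec.endo_semi_axes[1]
    half = np.deg2rad(spec.septal_span_deg) / 2
    delta = spec.septal_extra_mm if half > 0 else 0.0
    return b - (be - delta)


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    """Voxel-centre coordinates in volume-frame mm, origin at the volume centre."""
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    axes = [(np.arange(n) - (n - 1) / 2.0) * vs for n in (nx, ny, nz)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    return pts


def build_anatomy(spec: PhantomSpec) -> GroundTruth:
    """Rasterise the phantom and compute its analytic truth."""
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    center = np.asarray(spec.center_offset_mm, dtype=float)
    pts = _grid_points(spec)
    q = _phantom_frame(pts, spec, center)
    labels = _classify_points(q, spec).reshape(spec.grid_shape)

    # per-voxel tissue fractions by sub-voxel sampling
    ss = max(1, int(spec.supersample))
    fracs = {lab: np.zeros(nx * ny * nz) for lab in
             (LABEL_WALL, LABEL_LV_CAVITY, LABEL_RV_CAVITY, LABEL_THORAX)}
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    for ox in offs:
        for oy in offs:
            for oz in offs:
                sub = q + (np.array([ox, oy, oz]) * vs) @ _tilt_matrix(spec.long_axis_tilt)
                sub_labels = _classify_points(sub, spec)
                for lab in fracs:
                    fracs[lab] += sub_labels == lab
    for lab in fracs:
        fracs[lab] /= ss**3

    tf_wall = fracs[LABEL_WALL].reshape(spec.grid_shape)
    tf_lv = fracs[LABEL_LV_CAVITY].reshape(spec.grid_shape)
    tf_rv = fracs[LABEL_RV_CAVITY].reshape(spec.grid_shape)
    tf_bg = fracs[LABEL_THORAX].reshape(spec.grid_shape)

    ptf = spec.ptf_myo * tf_wall + spec.ptf_background * tf_bg
    va = spec.va_myo * tf_wall + tf_lv
    vrv = tf_rv.copy()
    mbf = np.where(tf_wall > 0, spec.mbf_myo, np.where(tf_bg > 0, spec.mbf_background, 0.0))
    true_maps = ParametricMaps(
        mbf=mbf, ptf=ptf, va=va, vrv=vrv,
        rss=np.zeros(spec.grid_shape), valid=np.ones(spec.grid_shape, dtype=bool),
        spacing=(vs, vs, vs),
    )

    voxel_vol_ml = vs**3 / 1000.0
    true_lvm_vox = float((labels == LABEL_WALL).sum()) * voxel_vol_ml * TISSUE_DENSITY
    true_lvm = analytic_shell_mass(spec)
    wt = analytic_septal_wt(spec)

    min_gap = min(
        spec.epi_semi_axes[i] - spec.endo_semi_axes[i] for i in range(3)
    )
    thin = min_gap < vs

    R = _tilt_matrix(spec.long_axis_tilt)
    rv_center = None
    if spec.rv_enabled:
        rv_center = center + R @ np.array([spec.rv_offset_mm + spec.rv_radius_mm / 2, 0.0, 0.0])
    return GroundTruth(
        labels=labels,
        tissue_fractions={"wall": tf_wall, "lv_cavity": tf_lv, "rv_cavity": tf_rv, "thorax": tf_bg},
        true_lvm_analytic=true_lvm,
        true_lvm_voxelized=true_lvm_vox,
        true_wt=wt,
        true_maps=true_maps,
        lv_center_mm=center,
        rv_center_mm=rv_center,
        spacing=(vs, vs, vs),
        thin_wall_warning=thin,
    )


# ---------------------------------------------------------------------------
# Input curves and forward simulation
# ---------------------------------------------------------------------------

def gamma_variate_input(params: GammaVariate, time_grid: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate bolus on a time grid (zero before arrival)."""
    if params.alpha <= 0 or params.beta <= 0 or params.amplitude <= 0:
        raise ValueError("alpha, beta and amplitude must be positive")
    time_grid = np.asarray(time_grid, dtype=float)
    if params.t0 >= time_grid[-1]:
        raise ValueError("bolus arrival t0 lies beyond the scan end")
    dt = time_grid - params.t0
    out = np.zeros_like(dt)
    pos = dt > 0
    x = dt[pos] / (params.alpha * params.beta)
    out[pos] = params.amplitude * x**params.alpha * np.exp(params.alpha - dt[pos] / params.beta)
    return out


def input_functions_for(spec: PhantomSpec, schedule: FrameSchedule, dt: float = 0.5) -> InputFunctions:
    """The simulator's true arterial and RV curves on a fine grid."""
    time = np.arange(0.0, schedule.frame_end[-1] + dt / 2, dt)
    ca = gamma_variate_input(spec.arterial_input, time)
    crv = gamma_variate_input(spec.rv_input, time)
    return InputFunctions(time=time, ca=ca, crv=crv)


def simulate_dynamic(
    gt: GroundTruth,
    spec: PhantomSpec,
    schedule: FrameSchedule | None = None,
) -> DynamicImage:
    """Forward-simulate the dynamic scan: kinetics -> PSF blur -> frame noise.

    Noise is image-domain Gaussian with per-frame standard deviation
    ``noise_scale * sqrt(mean_frame_activity / frame_duration)`` — the
    observable noise on reconstructed images, scaled the way count statistics
    scale with frame duration.  Activities are decay-corrected by construction.
    """
    if schedule is None:
        schedule = FrameSchedule.default()
    ifs = input_functions_for(spec, schedule)
    ca_f = frame_average(ifs.time, ifs.ca, schedule)
    crv_f = frame_average(ifs.time, ifs.crv, schedule)

    tf = gt.tissue_fractions
    p = spec.partition_coefficient
    ptf_terms = [(spec.ptf_myo * tf["wall"], spec.mbf_myo)]
    if spec.background_enabled:
        ptf_terms.append((spec.ptf_background * tf["thorax"], spec.mbf_background))
    va_map = spec.va_myo * tf["wall"] + tf["lv_cavity"]
    vrv_map = tf["rv_cavity"]

    nx, ny, nz = spec.grid_shape
    frames = np.zeros((nx, ny, nz, schedule.n_frames))
    for ptf_map, flow in ptf_terms:
        fine = tissue_response(ifs.time, ifs.ca, flow, p)
        b_f = frame_average(ifs.time, fine, schedule)
        frames += ptf_map[..., None] * b_f
    frames += va_map[..., None] * ca_f + vrv_map[..., None] * crv_f

    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm * _FWHM_TO_SIGMA / spec.voxel_size
        for k in range(schedule.n_frames):
            frames[..., k] = gaussian_filter(frames[..., k], sigma_vox, mode="nearest")

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        means = frames.mean(axis=(0, 1, 2))
        stds = spec.noise_scale * np.sqrt(np.clip(means, 0.0, None) / schedule.durations)
        frames += rng.standard_normal(frames.shape) * stds
    return DynamicImage(voxels=frames, spacing=(spec.voxel_size,) * 3, schedule=schedule)
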