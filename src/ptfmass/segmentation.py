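"""Radial-profile delineation of the LV wall on parametric PTF images.

The perfusable-tissue-fraction volume is rotated to short-axis orientation;
on every included slice, 36 radial profiles (10-degree increments) are cast
from the cavity centre and the inner and outer wall contours are placed where
each profile crosses a predefined fraction (default 67%) of its maximum.
LV mass is the tissue volume enclosed between the contours times the specific
gravity of soft tissue (1.05 g/mL); mid-septal wall thickness is the mean
contour separation over the 5 profiles closest to the LV-to-RV direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

TISSUE_DENSITY = 1.05  # g/mL


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ShortAxisVolume:
    """PTF volume resampled so the slice axis (z) is the LV long axis."""

    ptf: np.ndarray
    spacing: tuple[float, float, float]
    rotation: np.ndarray          # original -> short-axis rotation matrix
    center_mm: np.ndarray         # rotation centre, original-frame mm

    def __post_init__(self):
        if abs(self.spacing[0] - self.spacing[1]) > 1e-9:
            raise ValueError("in-plane spacing must be isotropic")


@dataclass
class SegmentationConfig:
    fraction: float = 0.67            # contour threshold as fraction of profile max
    profile_step: float = 0.5         # mm along each ray
    max_radius: float = 80.0          # mm
    slice_range: tuple[int, int] | None = None   # inclusive; None = all slices
    n_septal_profiles: int = 5
    max_from: str = "profile"         # "profile" (default) or "slice"

    def __post_init__(self):
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if self.n_septal_profiles % 2 == 0:
            raise ValueError("n_septal_profiles must be odd")
        if self.max_from not in ("profile", "slice"):
            raise ValueError("max_from must be 'profile' or 'slice'")


@dataclass
class RadialContour:
    """Per-slice contour: radii (mm) at 10-degree angles from the cavity centre."""

    slice_index: int
    center: tuple[float, float]       # mm, slice plane
    angles: np.ndarray                # degrees, [0, 350]
    r_inner: np.ndarray
    r_outer: np.ndarray
    valid: np.ndarray                 # per-angle: contour found directly
    open_center: np.ndarray = None    # per-angle: r_inner collapsed to centre

    def __post_init__(self):
        if self.open_center is None:
            self.open_center = np.zeros_like(self.valid)


@dataclass
class LVMeasurement:
    lvm: float                        # g
    lvm_indexed: float | None         # g/m2
    wt: float                         # mm
    bsa: float | None                 # m2
    slices_used: list[int] = field(default_factory=list)
    fraction_used: float = 0.67
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reorientation
# ---------------------------------------------------------------------------

def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation mapping unit vector u onto unit vector v (Rodrigues)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees: rotate about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2 * K @ K
    w = np.cross(u, v)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def _angles_to_rotation(angles_deg: tuple[float, float]) -> np.ndarray:
    ay, ax = np.deg2rad(angles_deg[0]), np.deg2rad(angles_deg[1])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    return rx @ ry


def principal_long_axis(ptf: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Long axis = principal axis of voxels with PTF >= 50% of the robust (99th pct) max."""
    robust_max = np.percentile(ptf[ptf > 0], 99) if np.any(ptf > 0) else 0.0
    mask = ptf >= 0.5 * robust_max
    if mask.sum() < 10:
        raise ValueError("too few high-PTF voxels to determine the long axis")
    coords = np.argwhere(mask) * np.asarray(spacing)
    coords = coords - coords.mean(axis=0)
    cov = coords.T @ coords / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if (evals[2] - evals[1]) < 0.05 * evals[2]:
        raise ValueError(
            "degenerate principal axes (near-spherical PTF blob); supply explicit angles"
        )
    return evecs[:, 2]


def reorient_to_short_axis(
    ptf_volume: np.ndarray,
    spacing: tuple[float, float, float],
    axis: str | tuple[float, float] = "auto",
    companions: list[np.ndarray] | None = None,
) -> ShortAxisVolume | tuple[ShortAxisVolume, list[np.ndarray]]:
    """Rigidly rotate the volume so the LV long axis lies along z.

    ``axis="auto"`` estimates the long axis from the high-PTF voxel cloud;
    a pair of explicit angles (about y then x, degrees) may be given instead.
    ``companions`` are resampled with the identical transform (e.g. a V_RV map).
    Output grid is isotropic at the smallest input spacing.
    """
    ptf_volume = np.asarray(ptf_volume, dtype=float)
    if ptf_volume.size == 0:
        raise ValueError("empty volume")
    if isinstance(axis, str):
        if axis != "auto":
            raise ValueError("axis must be 'auto' or a pair of angles")
        u = principal_long_axis(ptf_volume, spacing)
        R = _rotation_aligning(np.array([0.0, 0.0, 1.0]), u)  # short-axis -> original
    else:
        R = _angles_to_rotation(axis)

    spacing = np.asarray(spacing, dtype=float)
    out_vs = float(spacing.min())
    in_shape = np.asarray(ptf_volume.shape)
    extent = in_shape * spacing
    out_shape = tuple(int(np.ceil(e / out_vs)) for e in extent)
    center_in = (in_shape - 1) / 2.0 * spacing
    center_out = (np.asarray(out_shape) - 1) / 2.0 * out_vs

    # output index -> input index: i_in = S_in^-1 (R (i_out * s_out - c_out) + c_in)
    M = np.diag(1.0 / spacing) @ R * out_vs
    offset = (center_in - R @ center_out) / spacing

    def _resample(vol):
        return ndimage.affine_transform(
            vol, M, offset=offset, output_shape=out_shape, order=1, mode="constant", cval=0.0
        )

    sav = ShortAxisVolume(
        ptf=_resample(ptf_volume),
        spacing=(out_vs, out_vs, out_vs),
        rotation=R,
        center_mm=center_in,
    )
    if companions is not None:
        return sav, [_resample(np.asarray(c, dtype=float)) for c in companions]
    return sav


# ---------------------------------------------------------------------------
# Cavity centre and profiles
# ---------------------------------------------------------------------------

def find_cavity_center(
    slice_ptf: np.ndarray,
    spacing: float,
    prior_center: tuple[float, float] | None = None,
) -> tuple[float, float] | None:
    """Centroid of the myocardial ring (PTF >= 50% of slice max), one re-weighted pass.

    Returns slice-plane mm coordinates (origin at the slice centre), or the
    prior centre / None when no ring is found.
    """
    smax = float(slice_ptf.max(initial=0.0))
    mask = slice_ptf >= 0.5 * smax if smax > 0 else np.zeros_like(slice_ptf, bool)
    if mask.sum() < 8:
        return prior_center
    ij = np.argwhere(mask).astype(float)
    c = ij.mean(axis=0)
    # one iteration of radial re-weighting: voxels on a ring get equal angular say
    r = np.linalg.norm(ij - c, axis=1)
    w = 1.0 / np.clip(r, 0.5, None)
    c = (ij * w[:, None]).sum(axis=0) / w.sum()
    center_idx = (np.asarray(slice_ptf.shape) - 1) / 2.0
    return tuple((c - center_idx) * spacing)


def sample_profile(
    slice_ptf: np.ndarray,
    spacing: float,
    center_mm: tuple[float, float],
    angle_deg: float,
    step: float,
    max_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear PTF samples along a ray from the centre; returns (radii, values)."""
    radii = np.arange(0.0, max_radius + step / 2, step)
    th = np.deg2rad(angle_deg)
    center_idx = (np.asarray(slice_ptf.shape) - 1) / 2.0
    x = (center_mm[0] + radii * np.cos(th)) / spacing + center_idx[0]
    y = (center_mm[1] + radii * np.sin(th)) / spacing + center_idx[1]
    # edge-value extension: running off the field of view must not fabricate
    # a downward threshold crossing
    vals = ndimage.map_coordinates(slice_ptf, np.stack([x, y]), order=1, mode="nearest")
    return radii, vals


def contour_from_profile(
    radii: np.ndarray,
    values: np.ndarray,
    fraction: float,
    profile_max: float | None = None,
) -> tuple[float, float, bool] | None:
    """Locate (r_inner, r_outer) at fraction x max; None if no usable crossings.

    The third element flags an inner contour collapsed to the centre
    (profile already above threshold at r = 0, e.g. a slice through the
    solid apical cap).
    """
    if profile_max is None:
        profile_max = float(values.max(initial=0.0))
    if profile_max <= 0:
        return None
    thr = fraction * profile_max
    peak = int(np.argmax(values))
    above = values >= thr

    # inner: innermost upward crossing between the centre and the peak
    open_center = False
    if above[0]:
        r_in = 0.0
        open_center = True
    else:
        idx = np.flatnonzero(~above[: peak + 1][:-1] & above[1 : peak + 1])
        if idx.size == 0:
            return None
        i = idx[0]
        f = (thr - values[i]) / (values[i + 1] - values[i])
        r_in = radii[i] + f * (radii[i + 1] - radii[i])

    # outer: first downward crossing beyond the peak
    idx = np.flatnonzero(above[peak:-1] & ~above[peak + 1 :])
    if idx.size == 0:
        return None
    j = peak + idx[0]
    f = (values[j] - thr) / (values[j] - values[j + 1])
    r_out = radii[j] + f * (radii[j + 1] - radii[j])
    if r_out <= r_in:
        return None
    return r_in, r_out, open_center


def delineate(vol: ShortAxisVolume, cfg: SegmentationConfig) -> list[RadialContour]:
    """Contour every slice in the configured range; neighbour-fill invalid angles."""
    nz = vol.ptf.shape[2]
    if cfg.slice_range is None:
        lo, hi = 0, nz - 1
    else:
        lo, hi = cfg.slice_range
        if not (0 <= lo <= hi < nz):
            raise ValueError(f"slice_range {cfg.slice_range} outside volume with {nz} slices")
    angles = np.arange(0.0, 360.0, 10.0)
    contours: list[RadialContour] = []
    prior = None
    # Slices must actually contain myocardium: require the slice peak to reach
    # half the volume's robust maximum, otherwise low-grade surroundings (lung,
    # mediastinum) would be contoured as if they were wall.
    pos = vol.ptf[vol.ptf > 0]
    robust_max = float(np.percentile(pos, 99)) if pos.size else 0.0
    for k in range(lo, hi + 1):
        sl = vol.ptf[:, :, k]
        # robust slice peak: a noisy surround must not pass for myocardium
        if sl.size == 0 or np.percentile(sl, 99) < 0.5 * robust_max:
            continue
        center = find_cavity_center(sl, vol.spacing[0], prior_center=prior)
        if center is None:
            logger.info("slice %d: no myocardial ring found; excluded", k)
            continue
        prior = center
        slice_max = float(sl.max(initial=0.0))
        r_in = np.full(angles.size, np.nan)
        r_out = np.full(angles.size, np.nan)
        valid = np.zeros(angles.size, dtype=bool)
        open_c = np.zeros(angles.size, dtype=bool)
        for a, ang in enumerate(angles):
            radii, vals = sample_profile(sl, vol.spacing[0], center, ang,
                                         cfg.profile_step, cfg.max_radius)
            pmax = slice_max if cfg.max_from == "slice" else None
            res = contour_from_profile(radii, vals, cfg.fraction, profile_max=pmax)
            if res is not None:
                r_in[a], r_out[a], open_c[a] = res
                valid[a] = True
        if valid.sum() <= angles.size // 2:
            logger.info("slice %d: %d/%d valid profiles; excluded", k, int(valid.sum()), angles.size)
            continue
        # carry invalid angles from circular neighbour interpolation, flagged invalid
        if not valid.all():
            good = np.flatnonzero(valid)
            ang_ext = np.concatenate([angles[good] - 360, angles[good], angles[good] + 360])
            for arr in (r_in, r_out):
                v_ext = np.tile(arr[good], 3)
                arr[~valid] = np.interp(angles[~valid], ang_ext, v_ext)
        contours.append(RadialContour(
            slice_index=k, center=center, angles=angles,
            r_inner=r_in, r_outer=r_out, valid=valid, open_center=open_c,
        ))
    return _plausible_stack(contours)


def _plausible_stack(contours: list[RadialContour]) -> list[RadialContour]:
    """Anatomical plausibility of the slice stack.

    Slices whose contours collapse to a solid disk (open centre) are apical or
    basal caps: they must be contiguous with the block of ring slices and
    cannot be wider than the adjacent ring slice — the ventricle tapers.
    Noisy surroundings occasionally admit wide spurious disks; this pass
    removes them.
    """
    if not contours:
        return contours
    is_ring = np.array([np.mean(c.open_center) < 0.5 for c in contours])
    if not is_ring.any():
        return []
    med_out = np.array([float(np.median(c.r_outer)) for c in contours])
    ring_idx = np.flatnonzero(is_ring)
    first, last = ring_idx[0], ring_idx[-1]
    keep = np.zeros(len(contours), dtype=bool)
    keep[first : last + 1] = True
    bound = 1.1 * med_out[first]
    for i in range(first - 1, -1, -1):
        gap = contours[i + 1].slice_index - contours[i].slice_index
        if gap != 1 or med_out[i] > bound:
            break
        keep[i] = True
        bound = 1.1 * med_out[i]
    bound = 1.1 * med_out[last]
    for i in range(last + 1, len(contours)):
        gap = contours[i].slice_index - contours[i - 1].slice_index
        if gap != 1 or med_out[i] > bound:
            break
        keep[i] = True
        bound = 1.1 * med_out[i]
    dropped = [contours[i].slice_index for i in np.flatnonzero(~keep)]
    if dropped:
        logger.info("implausible cap slices removed: %s", dropped)
    return [c for i, c in enumerate(contours) if keep[i]]


# ---------------------------------------------------------------------------
# Mass, wall thickness, indexing, classification
# ---------------------------------------------------------------------------

def _star_boundary_radius(angles_deg: np.ndarray, radii: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Polygon boundary radius at query angles, for a star-shaped radial contour.

    The chord between consecutive vertices (theta_i, r_i), (theta_j, r_j)
    crosses direction phi at  r = r_i r_j sin(theta_j - theta_i) /
    (r_j sin(theta_j - phi) + r_i sin(phi - theta_i)).
    """
    n = angles_deg.size
    step = np.deg2rad(angles_deg[1] - angles_deg[0])
    phi = np.mod(phi, 2 * np.pi)
    i = np.minimum((phi // step).astype(np.intp), n - 1)
    j = (i + 1) % n
    th_i = i * step
    ri, rj = radii[i], radii[j]
    num = ri * rj * np.sin(step)
    den = rj * np.sin(th_i + step - phi) + ri * np.sin(phi - th_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.where(den > 1e-300, r, 0.0)


def compute_lvm(
    contours: list[RadialContour],
    spacing: tuple[float, float, float],
    refine: int = 16,
    rule: str = "corners",
) -> float:
    """LV mass in grams from per-slice contour polygons.

    A raster cell contributes iff it is fully enclosed between the contours:
    with ``rule="corners"`` all four in-plane corners must lie inside the
    outer polygon and outside the inner one (the strictest reading);
    ``rule="center"`` tests the cell centre only.  ``refine`` subdivides the
    in-plane voxel pitch so the count converges to the polygon-ring area.
    """
    if not contours:
        raise ValueError("no valid contours")
    if rule not in ("corners", "center"):
        raise ValueError("rule must be 'corners' or 'center'")
    dx = spacing[0] / refine
    dz = spacing[2]
    total_mm3 = 0.0
    for ct in contours:
        lo = ct.r_outer.max()
        xs = np.arange(ct.center[0] - lo - dx, ct.center[0] + lo + 2 * dx, dx)
        ys = np.arange(ct.center[1] - lo - dx, ct.center[1] + lo + 2 * dx, dx)
        if rule == "center":
            gx, gy = np.meshgrid(xs[:-1] + dx / 2, ys[:-1] + dx / 2, indexing="ij")
        else:
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
        phi = np.arctan2(gy - ct.center[1], gx - ct.center[0])
        rad = np.hypot(gx - ct.center[0], gy - ct.center[1])
        ok = rad <= _star_boundary_radius(ct.angles, ct.r_outer, phi)
        if np.any(ct.r_inner > 0):
            ok &= rad >= _star_boundary_radius(ct.angles, ct.r_inner, phi)
        if rule == "center":
            count = int(ok.sum())
        else:
            cell = ok[:-1, :-1] & ok[1:, :-1] & ok[:-1, 1:] & ok[1:, 1:]
            count = int(cell.sum())
        total_mm3 += count * dx * dx * dz
    return TISSUE_DENSITY * total_mm3 / 1000.0


def contours_to_csv(contours: list[RadialContour], path) -> None:
    """Per-slice contour table: slice, angle_deg, r_inner_mm, r_outer_mm, valid."""
    import pandas as pd

    rows = []
    for ct in contours:
        for a in range(ct.angles.size):
            rows.append({
                "slice": ct.slice_index,
                "angle_deg": ct.angles[a],
                "r_inner_mm": ct.r_inner[a],
                "r_outer_mm": ct.r_outer[a],
                "valid": bool(ct.valid[a]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def find_rv_center(
    vrv_map: np.ndarray,
    slice_index: int,
    spacing: float,
) -> tuple[float, float]:
    """Intensity-weighted centroid of the RV blood-volume map on one slice (mm)."""
    sl = np.asarray(vrv_map[:, :, slice_index], dtype=float)
    w = np.clip(sl, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("no RV signal in slice; a manual point is required")
    ij = np.indices(sl.shape).reshape(2, -1).T.astype(float)
    c = (ij * w.ravel()[:, None]).sum(axis=0) / w.sum()
    center_idx = (np.asarray(sl.shape) - 1) / 2.0
    return tuple((c - center_idx) * spacing)


def compute_wt(
    contours: list[RadialContour],
    lv_center: tuple[float, float],
    rv_center: tuple[float, float],
    cfg: SegmentationConfig,
    mid_index: int | None = None,
) -> float:
    """Mid-septal wall thickness: mean contour gap over the profiles nearest LV->RV.

    The mid-septal level defaults to the middle contoured slice.  Profiles that
    are invalid or have a collapsed inner contour are dropped with a warning;
    fewer than 3 usable profiles is an error.
    """
    if not contours:
        raise ValueError("no valid contours")
    if mid_index is None:
        ct = contours[len(contours) // 2]
    else:
        match = [c for c in contours if c.slice_index == mid_index]
        if not match:
            raise ValueError(f"slice {mid_index} has no valid contour")
        ct = match[0]
    direction = np.array(rv_center) - np.array(lv_center)
    theta = np.rad2deg(np.arctan2(direction[1], direction[0])) % 360.0
    nearest = int(np.argmin(np.abs(((ct.angles - theta) + 180) % 360 - 180)))
    half = cfg.n_septal_profiles // 2
    picks = [(nearest + d) % ct.angles.size for d in range(-half, half + 1)]
    gaps = []
    for a in picks:
        if not ct.valid[a] or ct.open_center[a]:
            logger.warning("septal profile at %.0f deg unusable; dropped", ct.angles[a])
            continue
        gaps.append(ct.r_outer[a] - ct.r_inner[a])
    if len(gaps) < 3:
        raise ValueError("fewer than 3 usable septal profiles")
    return float(np.mean(gaps))


def index_lvm(lvm: float, height_cm: float, weight_kg: float) -> tuple[float, float]:
    """Du Bois body-surface area and indexed LV mass (g/m2)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    bsa = 0.007184 * height_cm**0.725 * weight_kg**0.425
    return bsa, lvm / bsa


#: Sex-specific indexed-LVM hypertrophy cutoffs, g/m2 (strict inequality).
LVH_CUTOFFS = {"female": 81.0, "male": 85.0}
#: Wall-thickness class boundaries, mm.
WT_NORMAL_BELOW = 12.0
WT_SEVERE_ABOVE = 15.0


def classify_hypertrophy(m: LVMeasurement, sex: str | None = None) -> dict:
    """Hypertrophy labels from indexed LVM (sex-specific) and WT (12/15 mm bands)."""
    out: dict = {}
    if m.wt < WT_NORMAL_BELOW:
        out["wt_class"] = "normal"
    elif m.wt > WT_SEVERE_ABOVE:
        out["wt_class"] = "severe"
    else:
        out["wt_class"] = "increased"
    if m.lvm_indexed is not None:
        if sex not in LVH_CUTOFFS:
            raise ValueError("sex ('female' or 'male') is required to classify indexed LVM")
        out["lvh_mass"] = bool(m.lvm_indexed > LVH_CUTOFFS[sex])
    return out
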