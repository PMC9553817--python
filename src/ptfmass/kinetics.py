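"""Single-tissue-compartment kinetic modelling of dynamic 15O-water PET.

The voxel model is

    C_PET(t) = PTF * F * exp(-F t / p) (x) C_A(t)  +  V_A * C_A(t)  +  V_RV * C_RV(t)

where ``(x)`` denotes convolution, ``F`` is myocardial blood flow
(mL.min-1.mL-1), ``p`` the water partition coefficient (mL/mL), ``PTF`` the
perfusable tissue fraction (mL/mL) and ``V_A``/``V_RV`` arterial and
right-ventricular blood spill-over fractions.  Fitting uses the basis-function
method: the non-linear parameter ``F`` is discretised on a grid, and for each
candidate flow the three linear coefficients are obtained by non-negative
weighted least squares; the grid flow with minimal weighted residual sum of
squares wins.  All activities are assumed decay-corrected, as reconstructed
clinically, so no decay constant appears anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Literature-standard water partition coefficient (mL water per mL tissue).
DEFAULT_PARTITION_COEFFICIENT = 0.91

#: Default candidate-flow grid, mL.min-1.mL-1.
DEFAULT_FLOW_GRID = np.geomspace(0.05, 5.0, 50)

#: Soft physical bound on PTF + V_A + V_RV; violations are flagged, not clipped.
VOLUME_FRACTION_BOUND = 1.2


# ---------------------------------------------------------------------------
# Frame timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping reconstruction frames, in seconds."""

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.shape != end.shape or start.ndim != 1 or start.size == 0:
            raise ValueError("frame_start and frame_end must be matching 1-D arrays")
        if np.any(end <= start):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], end[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        end = t0 + np.cumsum(durations)
        start = np.concatenate(([t0], end[:-1]))
        return cls(start, end)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The clinical 6-minute protocol: 1x10, 8x5, 4x10, 2x15, 3x20, 2x30, 2x60 s."""
        durations = [10.0] + [5.0] * 8 + [10.0] * 4 + [15.0] * 2 + [20.0] * 3 + [30.0] * 2 + [60.0] * 2
        return cls.from_durations(durations)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    def __len__(self) -> int:
        return self.n_frames

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])


def frame_average(time: np.ndarray, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a finely sampled curve over each frame interval (trapezoid rule).

    Frame boundaries that fall between grid points are handled by linear
    interpolation, so the result is exact for piecewise-linear curves.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time[0] > schedule.frame_start[0] + 1e-9 or time[-1] < schedule.frame_end[-1] - 1e-9:
        raise ValueError(
            f"time grid [{time[0]}, {time[-1]}] does not cover the frame "
            f"schedule [{schedule.frame_start[0]}, {schedule.frame_end[-1]}]"
        )
    out = np.empty(schedule.n_frames)
    for k, (a, b) in enumerate(zip(schedule.frame_start, schedule.frame_end)):
        inner = time[(time > a) & (time < b)]
        pts = np.concatenate(([a], inner, [b]))
        vals = np.interp(pts, time, values)
        out[k] = np.trapezoid(vals, pts) / (b - a)
    return out


# ---------------------------------------------------------------------------
# Input functions
# ---------------------------------------------------------------------------

@dataclass
class InputFunctions:
    """Arterial and right-ventricular blood curves on a fine uniform time grid."""

    time: np.ndarray        # seconds, uniform
    ca: np.ndarray          # arterial whole-blood activity, kBq/mL
    crv: np.ndarray         # RV blood-pool activity, kBq/mL

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        self.crv = np.asarray(self.crv, dtype=float)
        if not (self.time.shape == self.ca.shape == self.crv.shape):
            raise ValueError("time, ca and crv must share one grid")
        dt = np.diff(self.time)
        if self.time.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform with >= 2 samples")
        if np.any(self.ca < 0) or np.any(self.crv < 0):
            raise ValueError("input-function activities must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def frame_averages(self, schedule: FrameSchedule) -> tuple[np.ndarray, np.ndarray]:
        return (frame_average(self.time, self.ca, schedule),
                frame_average(self.time, self.crv, schedule))

    @classmethod
    def from_csv(cls, path) -> "InputFunctions":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["Ca_kBq_ml"].to_numpy(), df["Crv_kBq_ml"].to_numpy())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.time, "Ca_kBq_ml": self.ca, "Crv_kBq_ml": self.crv}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Dynamic image container
# ---------------------------------------------------------------------------

@dataclass
class DynamicImage:
    """4-D activity volume (x, y, z, frame) in kBq/mL with mm voxel spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({self.voxels.shape[3]}) does not match "
                f"schedule length ({self.schedule.n_frames})"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


# ---------------------------------------------------------------------------
# Basis functions
# ---------------------------------------------------------------------------

@dataclass
class BasisSet:
    """Frame-averaged tissue impulse responses convolved with the arterial input."""

    flow_grid: np.ndarray          # mL.min-1.mL-1, strictly increasing
    p: float                       # partition coefficient, mL/mL
    curves: np.ndarray             # (n_flow, n_frames), frame-averaged
    schedule: FrameSchedule

    def __post_init__(self):
        self.flow_grid = np.asarray(self.flow_grid, dtype=float)
        if np.any(self.flow_grid <= 0):
            raise ValueError("flows must be positive")
        if np.any(np.diff(self.flow_grid) <= 0):
            raise ValueError("flow grid must be strictly increasing")
        if np.any(self.curves < -1e-12):
            raise ValueError("basis curves must be non-negative")


def tissue_response(time: np.ndarray, ca: np.ndarray, flow: float, p: float) -> np.ndarray:
    """``F exp(-F t / p) (x) C_A`` on the fine grid, exact for piecewise-linear C_A.

    ``flow`` is in mL.min-1.mL-1 while ``time`` is in seconds, so the washout
    rate is ``F / (60 p)`` s-1 and the leading flow factor ``F / 60`` s-1.
    The convolution integral satisfies ``y' = (F/60) C_A - lam y`` which is
    integrated exactly over each grid step for a linear segment of ``C_A``.
    """
    if flow <= 0:
        raise ValueError("flow must be positive")
    time = np.asarray(time, dtype=float)
    ca = np.asarray(ca, dtype=float)
    dt = time[1] - time[0]
    f_s = flow / 60.0
    lam = f_s / p
    x = lam * dt
    decay = np.exp(-x)
    one_minus = -np.expm1(-x)
    # y_{n+1} = y_n E + f_s [ c0 (1-E)/lam + c1 (dt/lam - (1-E)/lam^2) ]
    c0 = ca[:-1]
    c1 = np.diff(ca) / dt
    k0 = f_s * one_minus / lam
    k1 = f_s * (dt / lam - one_minus / lam**2)
    y = np.zeros_like(ca)
    incr = c0 * k0 + c1 * k1
    for n in range(len(ca) - 1):
        y[n + 1] = y[n] * decay + incr[n]
    return y


def make_basis(
    schedule: FrameSchedule,
    input_fns: InputFunctions,
    flow_grid: np.ndarray | None = None,
    p: float = DEFAULT_PARTITION_COEFFICIENT,
) -> BasisSet:
    """Precompute frame-averaged basis curves for every candidate flow."""
    if flow_grid is None:
        flow_grid = DEFAULT_FLOW_GRID
    flow_grid = np.asarray(flow_grid, dtype=float)
    if flow_grid.size == 0:
        raise ValueError("flow grid must be non-empty")
    if input_fns.time[-1] < schedule.frame_end[-1] - 1e-9:
        raise ValueError("input-function time grid is shorter than the frame schedule")
    curves = np.empty((flow_grid.size, schedule.n_frames))
    for i, f in enumerate(flow_grid):
        fine = tissue_response(input_fns.time, input_fns.ca, f, p)
        curves[i] = frame_average(input_fns.time, fine, schedule)
    curves[curves < 0] = 0.0
    return BasisSet(flow_grid=flow_grid, p=p, curves=curves, schedule=schedule)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ParametricMaps:
    """Voxel-wise kinetic parameters; out-of-mask / failed voxels carry valid=False."""

    mbf: np.ndarray
    ptf: np.ndarray
    va: np.ndarray
    vrv: np.ndarray
    rss: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def bound_violations(self) -> np.ndarray:
        """Voxels whose volume fractions exceed the soft physical bound."""
        total = self.ptf + self.va + self.vrv
        return self.valid & (total > VOLUME_FRACTION_BOUND)


# Support subsets for exact 3-regressor NNLS by enumeration (plus the empty set).
_SUBSETS = [s for k in (1, 2, 3) for s in combinations(range(3), k)]


def _nnls_over_flows(
    Y: np.ndarray,
    basis: BasisSet,
    ca_f: np.ndarray,
    crv_f: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact weighted NNLS of every column of Y against each flow's design matrix.

    Y is (n_frames, n_vox).  Returns (flow_index, coef (3, n_vox), rss (n_vox)).
    The 3-variable NNLS is solved by enumerating all support subsets, which is
    exact because the optimum's active set must be one of them; ties in RSS
    across flows resolve to the lower flow (strict-improvement update).
    """
    nf, nvox = Y.shape
    sw = np.sqrt(weights)[:, None]
    Yw = Y * sw
    yy = np.einsum("fv,fv->v", Yw, Yw)
    cols_fixed = np.stack([ca_f, crv_f], axis=1) * sw  # (nf, 2)

    best_rss = np.full(nvox, np.inf)
    best_flow = np.zeros(nvox, dtype=np.intp)
    best_coef = np.zeros((3, nvox))

    for i in range(basis.flow_grid.size):
        X = np.concatenate([basis.curves[i][:, None] * sw, cols_fixed], axis=1)  # (nf, 3)
        G = X.T @ X
        B = X.T @ Yw  # (3, nvox)

        rss_i = yy.copy()            # empty support: all coefficients zero
        coef_i = np.zeros((3, nvox))
        for S in _SUBSETS:
            idx = np.asarray(S)
            GS = G[np.ix_(idx, idx)]
            # pinv guards rank deficiency (e.g. an identically-zero RV curve)
            coef_S = np.linalg.pinv(GS, rcond=1e-12) @ B[idx]
            feasible = np.all(coef_S >= -1e-9, axis=0)
            rss_S = yy - np.einsum("sv,sv->v", coef_S, B[idx])
            improve = feasible & (rss_S < rss_i - 1e-12 * (yy + 1e-30))
            if np.any(improve):
                rss_i[improve] = rss_S[improve]
                coef_i[:, improve] = 0.0
                coef_i[np.ix_(idx, np.flatnonzero(improve))] = np.clip(
                    coef_S[:, improve], 0.0, None
                )
        take = rss_i < best_rss * (1 - 1e-12) - 1e-300
        best_rss[take] = rss_i[take]
        best_flow[take] = i
        best_coef[:, take] = coef_i[:, take]

    best_rss = np.clip(best_rss, 0.0, None)
    return best_flow, best_coef, best_rss


def fit_voxel_tac(
    tac: np.ndarray,
    basis: BasisSet,
    input_fns: InputFunctions,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float, float, float]:
    """Fit one time-activity curve; returns (MBF, PTF, V_A, V_RV, rss).

    The coefficient of the basis curve is the PTF by construction.  A voxel
    whose best fit assigns zero tissue signal reports MBF = 0 (flow is not
    identifiable without a tissue component).
    """
    tac = np.asarray(tac, dtype=float)
    if tac.ndim != 1 or tac.size != basis.schedule.n_frames:
        raise ValueError("tac length must equal the frame count")
    if np.any(np.isnan(tac)):
        raise ValueError("tac contains NaN")
    if weights is None:
        weights = basis.schedule.durations
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("all-zero frame weights")
    ca_f, crv_f = input_fns.frame_averages(basis.schedule)
    fi, coef, rss = _nnls_over_flows(tac[:, None], basis, ca_f, crv_f, weights)
    ptf, va, vrv = (float(coef[j, 0]) for j in range(3))
    mbf = float(basis.flow_grid[fi[0]]) if ptf > 0 else 0.0
    return mbf, ptf, va, vrv, float(rss[0])


def compute_parametric_maps(
    dyn: DynamicImage,
    input_fns: InputFunctions,
    mask: np.ndarray,
    flow_grid: np.ndarray | None = None,
    p: float = DEFAULT_PARTITION_COEFFICIENT,
    weights: np.ndarray | None = None,
) -> ParametricMaps:
    """Voxel-wise basis-function fit over a mask, returning parametric maps."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.shape:
        raise ValueError("mask shape must match the volume")
    if not mask.any():
        raise ValueError("empty mask")
    basis = make_basis(dyn.schedule, input_fns, flow_grid, p)
    if weights is None:
        weights = dyn.schedule.durations
    weights = np.asarray(weights, dtype=float)
    if not np.any(weights > 0):
        raise ValueError("all-zero frame weights")

    Y = dyn.voxels[mask].T  # (n_frames, n_vox)
    nan_vox = np.any(np.isnan(Y), axis=0)
    if nan_vox.any():
        warnings.warn(f"{int(nan_vox.sum())} in-mask voxels contain NaN; treated as out-of-mask")
        logger.warning("%d in-mask voxels contain NaN; excluded from fitting", nan_vox.sum())
    Yc = Y[:, ~nan_vox]

    ca_f, crv_f = input_fns.frame_averages(dyn.schedule)
    fi, coef, rss = _nnls_over_flows(Yc, basis, ca_f, crv_f, weights)

    shape = dyn.shape
    maps = {name: np.zeros(shape) for name in ("mbf", "ptf", "va", "vrv", "rss")}
    valid = np.zeros(shape, dtype=bool)

    flat_idx = np.flatnonzero(mask.ravel())[~nan_vox]
    mbf_vals = basis.flow_grid[fi]
    mbf_vals = np.where(coef[0] > 0, mbf_vals, 0.0)
    for name, vals in zip(
        ("mbf", "ptf", "va", "vrv", "rss"),
        (mbf_vals, coef[0], coef[1], coef[2], rss),
    ):
        maps[name].ravel()[flat_idx] = vals
    valid.ravel()[flat_idx] = True

    result = ParametricMaps(**maps, valid=valid, spacing=dyn.spacing)
    n_viol = int(result.bound_violations.sum())
    if n_viol:
        logger.warning(
            "%d voxels exceed the soft bound PTF + Va + Vrv <= %.1f", n_viol, VOLUME_FRACTION_BOUND
        )
    return result


def extract_input_functions(
    dyn: DynamicImage,
    arterial_roi: np.ndarray,
    rv_roi: np.ndarray,
    time_step: float = 0.5,
) -> InputFunctions:
    """Mean ROI time-activity curves, linearly interpolated (frame midpoints) to a fine grid."""
    curves = []
    for roi in (arterial_roi, rv_roi):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != dyn.shape:
            raise ValueError("ROI shape must match the volume")
        if not roi.any():
            raise ValueError("empty ROI")
        curves.append(dyn.voxels[roi].mean(axis=0))
    t_end = dyn.schedule.frame_end[-1]
    time = np.arange(0.0, t_end + time_step / 2, time_step)
    mid = dyn.schedule.midpoints
    ca = np.clip(np.interp(time, mid, curves[0]), 0.0, None)
    crv = np.clip(np.interp(time, mid, curves[1]), 0.0, None)
    return InputFunctions(time=time, ca=ca, crv=crv)
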