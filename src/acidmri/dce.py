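"""Dynamic contrast-enhanced MRI: VFA T1 mapping, concentration conversion,
and extended-Tofts pharmacokinetic fitting.

The tissue model is the extended Tofts model

    Ct(t) = v_p Cp(t) + Ktrans * int_0^t Cp(tau) exp(-(Ktrans/v_e)(t-tau)) dtau

with Ktrans the volume transfer constant (1/s), v_e the
extravascular-extracellular volume fraction and v_p the plasma volume
fraction. Signals follow the spoiled-gradient-echo (FLASH) steady state
S = M0 sin(a) (1-E1)/(1-E1 cos(a)), E1 = exp(-TR/T1); baseline T1 comes from
a variable-flip-angle series and gadolinium concentration from fast-exchange
linear relaxivity, 1/T1(t) = 1/T10 + r1 C(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import AcquisitionConfig

__all__ = [
    "T1Fit",
    "ConcentrationCurve",
    "ToftsParams",
    "DCEQCReport",
    "spgr_signal",
    "fit_vfa_t1",
    "signal_to_concentration",
    "tofts_concentration",
    "fit_extended_tofts",
    "compute_dce_maps",
]


def spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    """Spoiled-gradient-echo steady-state signal."""
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclass
class T1Fit:
    t1_ms: float
    m0: float
    residual: float
    valid: bool


@dataclass
class ConcentrationCurve:
    """Tissue gadolinium concentration vs time for one voxel."""

    time_s: np.ndarray
    ct_mM: np.ndarray
    n_baseline: int
    clipped_frames: int = 0  # frames with nonphysical signal clamped to C=0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ct_mM = np.asarray(self.ct_mM, dtype=float)
        if self.time_s.shape != self.ct_mM.shape:
            raise ValueError("time and concentration must match")


@dataclass
class ToftsParams:
    ktrans: float          # 1/s
    ve: float              # fraction
    vp: float              # fraction
    residual_norm: float
    converged: bool
    n_iter: int
    valid: bool = True


@dataclass
class DCEQCReport:
    n_mask_voxels: int
    n_invalid_t1: int
    n_invalid_fit: int
    invalid_fit_fraction: float
    median_residual: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def fit_vfa_t1(signals, angles_deg, tr_ms: float, method: str = "linearized") -> T1Fit:
    """Estimate T1 and M0 from a variable-flip-angle spoiled-GRE series.

    The default estimator uses the standard linearization
    S/sin(a) = E1 * S/tan(a) + M0 (1-E1), solved by least squares; a slope
    outside (0, 1) (nonphysical E1) marks the voxel invalid. ``method=
    "nonlinear"`` refines the linearized solution with bounded least squares
    on the signal equation itself.
    """
    signals = np.asarray(signals, dtype=float)
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if signals.shape != angles.shape or signals.size < 3:
        raise ValueError("need matching signals for >= 3 flip angles")
    if np.any(signals < 0):
        raise ValueError("signals must be nonnegative")
    if np.all(signals == 0):
        return T1Fit(t1_ms=float("nan"), m0=0.0, residual=0.0, valid=False)

    y = signals / np.sin(angles)
    x = signals / np.tan(angles)
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.sqrt(res[0])) if res.size else 0.0
    if not 0.0 < slope < 1.0:
        return T1Fit(t1_ms=float("nan"), m0=float("nan"), residual=residual, valid=False)
    t1 = -tr_ms / np.log(slope)
    m0 = intercept / (1.0 - slope)

    if method == "nonlinear":
        def resid(p):
            return spgr_signal(p[0], p[1], tr_ms, np.rad2deg(angles)) - signals

        sol = least_squares(resid, x0=[m0, t1],
                            bounds=([0, 1e-3], [np.inf, 1e7]), xtol=1e-12, ftol=1e-12)
        m0, t1 = sol.x
        residual = float(np.linalg.norm(sol.fun))
    elif method != "linearized":
        raise ValueError("method must be 'linearized' or 'nonlinear'")
    return T1Fit(t1_ms=float(t1), m0=float(m0), residual=residual, valid=True)


def signal_to_concentration(
    signal: np.ndarray,
    time_s: np.ndarray,
    n_baseline: int,
    t10_ms: float,
    r1: float,
    tr_ms: float,
    flip_deg: float,
) -> ConcentrationCurve:
    """Invert the spoiled-GRE signal equation frame by frame to Gd concentration.

    M0 is inferred from the pre-contrast baseline mean and the supplied T10,
    so the baseline frames map to ~0 mM by construction. Frames whose signal
    implies a nonphysical T1 (inversion argument outside (0, 1)) are clamped
    to 0 and counted in ``clipped_frames``.
    """
    signal = np.asarray(signal, dtype=float)
    if t10_ms <= 0:
        raise ValueError("T10 must be positive")
    if n_baseline < 2:
        raise ValueError("need >= 2 baseline frames")
    a = np.deg2rad(flip_deg)
    e10 = np.exp(-tr_ms / t10_ms)
    s_base = float(np.mean(signal[:n_baseline]))
    if s_base <= 0:
        raise ValueError("nonpositive baseline signal")
    m0 = s_base * (1.0 - e10 * np.cos(a)) / (np.sin(a) * (1.0 - e10))

    y = signal / (m0 * np.sin(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - y) / (1.0 - y * np.cos(a))
    bad = ~np.isfinite(e1) | (e1 <= 0) | (e1 >= 1)
    e1_safe = np.where(bad, e10, e1)
    t1_s = -(tr_ms / 1000.0) / np.log(e1_safe)
    conc = (1.0 / t1_s - 1000.0 / t10_ms) / r1
    conc[bad] = 0.0
    return ConcentrationCurve(time_s=time_s, ct_mM=conc,
                              n_baseline=n_baseline, clipped_frames=int(bad.sum()))


def _trapz_weights(t: np.ndarray) -> np.ndarray:
    """Lower-triangular trapezoid weight matrix: row i integrates over [t0, t_i]."""
    n = t.size
    half = 0.5 * np.diff(t)
    w = np.zeros((n, n))
    for i in range(1, n):
        w[i, 0] = half[0]
        w[i, 1:i] = half[: i - 1] + half[1:i]
        w[i, i] = half[i - 1]
    return w


_WEIGHT_CACHE: dict[bytes, np.ndarray] = {}


def tofts_concentration(t: np.ndarray, cp: np.ndarray,
                        ktrans: float, ve: float, vp: float) -> np.ndarray:
    """Extended-Tofts forward model on a discrete time grid.

    The convolution integral is evaluated by the trapezoid rule on the frame
    grid; with vp = 0 this is the standard Tofts model.
    """
    t = np.asarray(t, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if t.shape != cp.shape:
        raise ValueError("time grid and plasma curve must match")
    key = t.tobytes()
    w = _WEIGHT_CACHE.get(key)
    if w is None:
        w = _trapz_weights(t)
        if len(_WEIGHT_CACHE) > 8:
            _WEIGHT_CACHE.clear()
        _WEIGHT_CACHE[key] = w
    kep = ktrans / ve if ve > 0 else np.inf
    if not np.isfinite(kep):
        conv = np.zeros_like(t)
    else:
        lag = t[:, None] - t[None, :]
        integrand = cp[None, :] * np.exp(-kep * np.maximum(lag, 0.0))
        conv = np.sum(w * integrand, axis=1)
    return vp * cp + ktrans * conv


_DEFAULT_STARTS = ((1e-4, 0.2, 0.02), (2e-3, 0.2, 0.02), (2e-2, 0.2, 0.02))
_DEFAULT_BOUNDS = ((0.0, 1e-4, 0.0), (0.5, 1.0, 0.5))


def fit_extended_tofts(
    ct: ConcentrationCurve,
    cp: np.ndarray,
    init: tuple | None = None,
    bounds: tuple | None = None,
) -> ToftsParams:
    """Fit (Ktrans, v_e, v_p) to a tissue concentration curve.

    Bounded least squares with three default initializations spanning low,
    mid and high Ktrans; the best-residual solution is kept. A flat curve is
    reported as Ktrans = 0, v_p = 0 with v_e at its lower bound and flagged
    invalid (v_e is unidentifiable without uptake).
    """
    cp = np.asarray(cp, dtype=float)
    t = ct.time_s
    if cp.shape != t.shape:
        raise ValueError("ct and cp must share a time grid")
    if not np.any(cp != 0):
        raise ValueError("plasma curve is identically zero")
    lb, ub = bounds if bounds is not None else _DEFAULT_BOUNDS
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)

    if np.max(np.abs(ct.ct_mM)) < 1e-12:
        return ToftsParams(ktrans=0.0, ve=float(lb[1]), vp=0.0,
                           residual_norm=0.0, converged=True, n_iter=0, valid=False)

    def resid(p):
        return tofts_concentration(t, cp, *p) - ct.ct_mM

    starts = [np.asarray(init, dtype=float)] if init is not None else [
        np.asarray(s, dtype=float) for s in _DEFAULT_STARTS
    ]
    solutions = []
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        solutions.append(least_squares(resid, x0=x0, bounds=(lb, ub),
                                       ftol=1e-8, xtol=1e-10, gtol=1e-8))
    # At coarse temporal sampling a fast-exchange solution (kep * dt >> 1)
    # can alias the plasma term and tie the true minimum to machine
    # precision; among numerically indistinguishable costs prefer the
    # parsimonious (smallest-Ktrans) solution.
    best_cost = min(s.cost for s in solutions)
    tol = max(1e-12, 1e-8 * 0.5 * float(np.sum(ct.ct_mM**2)))
    best = min((s for s in solutions if s.cost <= best_cost + tol),
               key=lambda s: s.x[0])
    converged = bool(best.success)
    ktrans, ve, vp = (float(v) for v in best.x)
    return ToftsParams(
        ktrans=ktrans, ve=ve, vp=vp,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=converged, n_iter=int(best.nfev), valid=converged,
    )


def compute_dce_maps(
    vfa_stack: np.ndarray,
    dyn_stack: np.ndarray,
    mask: np.ndarray,
    acq: AcquisitionConfig,
    cp: np.ndarray,
) -> tuple[dict, DCEQCReport]:
    """Voxelwise VFA T1 -> concentration -> extended-Tofts chain over a mask.

    Parameters
    ----------
    vfa_stack
        4-D (x, y, z, n_angles) variable-flip-angle series.
    dyn_stack
        4-D (x, y, z, n_frames) dynamic series.
    cp
        Plasma concentration (mM) at the dynamic frame times.

    Returns ``(maps, qc)`` with float volumes ``ktrans``, ``ve``, ``vp``,
    ``t1_ms`` (NaN where invalid or outside the mask).
    """
    vfa_stack = np.asarray(vfa_stack, dtype=float)
    dyn_stack = np.asarray(dyn_stack, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if vfa_stack.shape[:3] != mask.shape or dyn_stack.shape[:3] != mask.shape:
        raise ValueError("stack and mask geometries differ")
    if dyn_stack.shape[3] != acq.dce_n_frames:
        raise ValueError("dynamic frame count does not match acquisition config")
    if vfa_stack.shape[3] != len(acq.vfa_angles_deg):
        raise ValueError("VFA frame count does not match angle table")
    if not mask.any():
        raise ValueError("empty tumor mask")

    t = acq.frame_times_s
    maps = {k: np.full(mask.shape, np.nan) for k in ("ktrans", "ve", "vp", "t1_ms")}
    n_bad_t1 = 0
    n_bad_fit = 0
    residuals = []
    for idx in np.argwhere(mask):
        i, j, k = map(int, idx)
        t1fit = fit_vfa_t1(vfa_stack[i, j, k], acq.vfa_angles_deg, acq.tr_ms)
        if not t1fit.valid:
            n_bad_t1 += 1
            continue
        maps["t1_ms"][i, j, k] = t1fit.t1_ms
        curve = signal_to_concentration(
            dyn_stack[i, j, k], t, acq.dce_n_baseline,
            t1fit.t1_ms, acq.r1_relaxivity, acq.tr_ms, acq.flip_deg,
        )
        params = fit_extended_tofts(curve, cp)
        maps["ktrans"][i, j, k] = params.ktrans
        maps["ve"][i, j, k] = params.ve
        maps["vp"][i, j, k] = params.vp
        residuals.append(params.residual_norm)
        if not params.valid:
            n_bad_fit += 1

    n_mask = int(mask.sum())
    qc = DCEQCReport(
        n_mask_voxels=n_mask,
        n_invalid_t1=n_bad_t1,
        n_invalid_fit=n_bad_fit,
        invalid_fit_fraction=(n_bad_t1 + n_bad_fit) / n_mask,
        median_residual=float(np.median(residuals)) if residuals else float("nan"),
    )
    return maps, qc
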