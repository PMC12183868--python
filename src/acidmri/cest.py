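"""CEST Z-spectrum processing and ratiometric extracellular-pH mapping.

The chain implemented here converts pre- and post-agent saturation-frequency
image stacks into pH_e maps:

1. normalize each voxel's saturation sweep by its unsaturated reference
   (Z-spectrum);
2. fit a smoothing spline per voxel, locate the water minimum to estimate the
   local B0 shift, and resample the spectrum on the shifted grid;
3. read the saturation-transfer contrast ST = 1 - Z at the two agent
   resonances, form the post-minus-pre difference dST to cancel endogenous
   contributions, and
4. convert the dST ratio to pH through a log-linear ratiometric calibration.

Voxels failing detectability or B0-reliability checks are flagged invalid;
out-of-range pH values are clamped to the calibration range and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .config import AcquisitionConfig, CalibrationModel

__all__ = [
    "ZSpectrum",
    "B0Correction",
    "PHMap",
    "CESTQCReport",
    "normalize_zspectrum",
    "fit_zspectrum_spline",
    "interpolate_b0_correct",
    "st_contrast",
    "delta_st",
    "ratiometric_ph",
    "compute_ph_map",
]


@dataclass
class ZSpectrum:
    """Normalized saturation signal versus frequency offset for one voxel."""

    offsets: np.ndarray  # ppm, strictly ascending
    signal: np.ndarray   # dimensionless, normalized to S0
    voxel_index: tuple[int, int, int] | None = None
    spline: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.offsets.shape != self.signal.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and signal must be 1-D arrays of equal length")
        if not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class B0Correction:
    """Result of spline interpolation + water-minimum B0 estimation."""

    corrected: ZSpectrum
    shift_ppm: float
    reliable: bool


@dataclass
class PHMap:
    """Per-voxel extracellular pH with validity/clamp bookkeeping.

    ``ph`` is NaN outside the validity mask; clamped voxels carry the range
    boundary value and are both valid and flagged.
    """

    ph: np.ndarray
    valid_mask: np.ndarray
    clamped_mask: np.ndarray
    geometry: dict | None = None


@dataclass
class CESTQCReport:
    n_mask_voxels: int
    n_valid: int
    n_invalid: int
    n_clamped: int
    n_b0_unreliable: int
    n_bad_reference: int
    mean_b0_shift_pre: float
    mean_b0_shift_post: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def normalize_zspectrum(
    raw: np.ndarray,
    offsets: np.ndarray,
    s0: float,
    voxel_index: tuple[int, int, int] | None = None,
) -> ZSpectrum:
    """Divide a raw saturation sweep by the unsaturated reference signal."""
    if not np.isfinite(s0) or s0 <= 0:
        raise ValueError("degenerate unsaturated reference: S0 must be > 0")
    raw = np.asarray(raw, dtype=float)
    return ZSpectrum(offsets=np.asarray(offsets, dtype=float), signal=raw / s0,
                     voxel_index=voxel_index)


class SmoothingSplineFitter:
    """Natural cubic smoothing spline on a fixed knot grid (Reinsch form).

    Minimizes ``sum (y_i - f(x_i))^2 + lam * int f''(u)^2 du`` over natural
    cubic splines with knots at the data sites. The hat matrix is
    ``(I + lam K)^-1`` with the Green-Silverman roughness matrix
    ``K = D^T W^-1 D``; its eigendecomposition is computed once per grid, so
    fitting another voxel's spectrum — including the per-voxel generalized
    cross-validation choice of ``lam`` — costs only O(n^2).
    """

    #: log10 grid over which GCV searches the penalty weight
    LAM_GRID = np.logspace(-8.0, 4.0, 49)

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size < 7 or not np.all(np.diff(x) > 0):
            raise ValueError("need >= 7 strictly increasing knots")
        self.x = x
        n = x.size
        h = np.diff(x)
        d = np.zeros((n - 2, n))
        rows = np.arange(n - 2)
        d[rows, rows] = 1.0 / h[:-1]
        d[rows, rows + 1] = -(1.0 / h[:-1] + 1.0 / h[1:])
        d[rows, rows + 2] = 1.0 / h[1:]
        w = (np.diag((h[:-1] + h[1:]) / 3.0)
             + np.diag(h[1:-1] / 6.0, 1) + np.diag(h[1:-1] / 6.0, -1))
        k = d.T @ np.linalg.solve(w, d)
        evals, evecs = np.linalg.eigh((k + k.T) / 2.0)
        self._d = np.clip(evals, 0.0, None)
        self._u = evecs

    def fit(self, y: np.ndarray, lam: float | None = None) -> CubicSpline:
        """Fit one spectrum; ``lam=None`` selects the penalty by GCV."""
        y = np.asarray(y, dtype=float)
        if y.shape != self.x.shape:
            raise ValueError("signal length does not match knot grid")
        yt = self._u.T @ y
        if lam is None:
            lam = self.gcv_lambda(yt)
        fitted = self._u @ (yt / (1.0 + lam * self._d))
        return CubicSpline(self.x, fitted, bc_type="natural")

    #: robustness weight of the RGCV criterion; 1.0 recovers plain GCV
    RGCV_GAMMA = 0.3

    def gcv_lambda(self, yt: np.ndarray) -> float:
        """Penalty weight minimizing the robust GCV score.

        Plain GCV occasionally collapses to near-interpolation on individual
        noisy spectra; the robust variant multiplies the GCV score by
        ``gamma + (1 - gamma) tr(S^2)/n`` (Lukas' RGCV), which penalizes
        undersmoothed, high-variance fits while leaving the noiseless case
        (where GCV already picks near-zero smoothing) unaffected.
        """
        n = yt.size
        shrink = self.LAM_GRID[:, None] * self._d[None, :]
        inv = 1.0 / (1.0 + shrink)
        rss = (((1.0 - inv) * yt[None, :]) ** 2).sum(axis=1)
        trace = inv.sum(axis=1)
        gcv = (rss / n) / (1.0 - trace / n) ** 2
        mu = (inv ** 2).sum(axis=1) / n
        score = (self.RGCV_GAMMA + (1.0 - self.RGCV_GAMMA) * mu) * gcv
        return float(self.LAM_GRID[int(np.argmin(score))])


_FITTER_CACHE: dict[bytes, SmoothingSplineFitter] = {}


def _fitter_for(x: np.ndarray) -> SmoothingSplineFitter:
    key = np.asarray(x, dtype=float).tobytes()
    fitter = _FITTER_CACHE.get(key)
    if fitter is None:
        fitter = SmoothingSplineFitter(x)
        if len(_FITTER_CACHE) > 8:
            _FITTER_CACHE.clear()
        _FITTER_CACHE[key] = fitter
    return fitter


def fit_zspectrum_spline(z: ZSpectrum, smoothing: float | None = None) -> CubicSpline:
    """Cubic smoothing spline through a Z-spectrum.

    ``smoothing`` is the roughness-penalty weight (lambda); when None it is
    chosen per voxel by generalized cross-validation, which collapses to
    near-interpolation on noiseless data.
    """
    return _fitter_for(z.offsets).fit(z.signal, lam=smoothing)


def interpolate_b0_correct(
    z: ZSpectrum,
    smoothing: float | None = None,
    search_window: float = 1.5,
) -> B0Correction:
    """Estimate the per-voxel B0 shift and resample the spectrum shifted.

    A smoothing spline is fit to the spectrum and the water resonance is taken
    as the spline minimum within ``+/- search_window`` ppm. The corrected
    spectrum is the spline evaluated on the original offset grid displaced by
    the estimated shift. A minimum sitting at the window boundary indicates
    no identifiable water line (e.g. pure noise) and is flagged unreliable.
    """
    if z.offsets.size < 7:
        raise ValueError("need >= 7 offsets for spline B0 correction")
    if search_window <= 0 or search_window > min(-z.offsets[0], z.offsets[-1]):
        raise ValueError("search window must be positive and inside the offset range")
    spline = fit_zspectrum_spline(z, smoothing)
    grid = np.linspace(-search_window, search_window, 601)
    vals = spline(grid)
    i = int(np.argmin(vals))
    shift = float(grid[i])
    step = grid[1] - grid[0]
    reliable = 0 < i < grid.size - 1 and abs(shift) < search_window - step
    shifted = lambda x: spline(np.asarray(x, dtype=float) + shift)  # noqa: E731
    corrected = ZSpectrum(
        offsets=z.offsets.copy(),
        signal=np.asarray(shifted(z.offsets), dtype=float),
        voxel_index=z.voxel_index,
        spline=shifted,
    )
    return B0Correction(corrected=corrected, shift_ppm=shift, reliable=reliable)


def st_contrast(z: ZSpectrum, offset: float, smoothing: float | None = None) -> float:
    """Saturation-transfer contrast ST = 1 - Z at a requested offset (ppm).

    Z is evaluated from the voxel's spline at exactly the requested offset;
    if the spectrum carries no spline (e.g. raw data), one is fit first.
    """
    if not z.offsets[0] <= offset <= z.offsets[-1]:
        raise ValueError(f"offset {offset} ppm outside sampled range")
    spline = z.spline if z.spline is not None else fit_zspectrum_spline(z, smoothing)
    return float(1.0 - spline(np.asarray([offset]))[0])


def delta_st(st_pre: np.ndarray, st_post: np.ndarray) -> np.ndarray:
    """Agent-specific contrast: post-injection ST minus pre-injection ST."""
    st_pre = np.asarray(st_pre, dtype=float)
    st_post = np.asarray(st_post, dtype=float)
    if st_pre.shape != st_post.shape:
        raise ValueError("pre and post ST maps must share geometry")
    return st_post - st_pre


def _ratiometric(
    dst1: np.ndarray,
    dst2: np.ndarray,
    cal: CalibrationModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ratiometric conversion. Returns (ph, valid, clamped)."""
    dst1 = np.asarray(dst1, dtype=float)
    dst2 = np.asarray(dst2, dtype=float)
    valid = (
        np.isfinite(dst1) & np.isfinite(dst2)
        & (dst1 >= cal.min_delta_st) & (dst2 >= cal.min_delta_st)
        & (dst2 > 0)
    )
    ph = np.full(dst1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ph[valid] = cal.ph_for_ratio(dst1[valid] / dst2[valid])
    lo, hi = cal.valid_ph_range
    clamped = valid & ((ph < lo) | (ph > hi))
    ph[valid] = np.clip(ph[valid], lo, hi)
    return ph, valid, clamped


def ratiometric_ph(dst1: float, dst2: float, cal: CalibrationModel) -> tuple[float, str]:
    """pH from the ratio of agent-offset dST contrasts.

    Returns ``(ph, status)`` where status is ``"valid"``, ``"clamped"`` (pH
    fell outside the calibration range and was clamped to its boundary) or
    ``"invalid"`` (either contrast below the detectability floor, or a
    nonpositive denominator); invalid voxels report NaN.
    """
    if not (np.isfinite(dst1) and np.isfinite(dst2)):
        raise ValueError("dST inputs must be finite")
    ph, valid, clamped = _ratiometric(np.array([dst1]), np.array([dst2]), cal)
    if not valid[0]:
        return float("nan"), "invalid"
    return float(ph[0]), "clamped" if clamped[0] else "valid"


def compute_ph_map(
    pre_stack: np.ndarray,
    post_stack: np.ndarray,
    s0_pre: np.ndarray,
    s0_post: np.ndarray,
    mask: np.ndarray,
    acq: AcquisitionConfig,
    cal: CalibrationModel,
    smoothing: float | None = None,
    search_window: float = 1.5,
    geometry: dict | None = None,
) -> tuple[PHMap, dict, CESTQCReport]:
    """Full per-voxel chain from saturation stacks to a pH_e map.

    Parameters
    ----------
    pre_stack, post_stack
        4-D arrays (x, y, z, n_offsets) acquired before/after agent injection.
    s0_pre, s0_post
        3-D unsaturated reference volumes matching the stack geometry.
    mask
        Binary tumor mask; only mask voxels are processed.

    Returns
    -------
    (PHMap, st_maps, CESTQCReport)
        ``st_maps`` holds float volumes ``st_pre_1``, ``st_pre_2``,
        ``st_post_1``, ``st_post_2``, ``delta_st_1``, ``delta_st_2`` and
        ``b0_shift`` (offsets 1/2 = the two agent resonances).
    """
    pre_stack = np.asarray(pre_stack, dtype=float)
    post_stack = np.asarray(post_stack, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if pre_stack.shape != post_stack.shape or pre_stack.ndim != 4:
        raise ValueError("pre and post stacks must be 4-D with identical shape")
    if pre_stack.shape[:3] != mask.shape or s0_pre.shape != mask.shape:
        raise ValueError("stack, S0 and mask geometries differ")
    if pre_stack.shape[3] != acq.sat_offsets.size:
        raise ValueError("stack frame count does not match offset table")
    if not mask.any():
        raise ValueError("empty tumor mask")

    off1, off2 = acq.agent_offsets
    shape = mask.shape
    nan_vol = lambda: np.full(shape, np.nan)  # noqa: E731
    st_maps = {k: nan_vol() for k in (
        "st_pre_1", "st_pre_2", "st_post_1", "st_post_2",
        "delta_st_1", "delta_st_2", "b0_shift",
    )}
    dst1 = nan_vol()
    dst2 = nan_vol()
    usable = np.zeros(shape, dtype=bool)
    n_bad_ref = 0
    n_b0_bad = 0
    shifts_pre: list[float] = []
    shifts_post: list[float] = []

    for idx in np.argwhere(mask):
        i, j, k = map(int, idx)
        try:
            z_pre = normalize_zspectrum(pre_stack[i, j, k], acq.sat_offsets,
                                        float(s0_pre[i, j, k]), (i, j, k))
            z_post = normalize_zspectrum(post_stack[i, j, k], acq.sat_offsets,
                                         float(s0_post[i, j, k]), (i, j, k))
        except ValueError:
            n_bad_ref += 1
            continue
        c_pre = interpolate_b0_correct(z_pre, smoothing, search_window)
        c_post = interpolate_b0_correct(z_post, smoothing, search_window)
        if not (c_pre.reliable and c_post.reliable):
            n_b0_bad += 1
            continue
        shifts_pre.append(c_pre.shift_ppm)
        shifts_post.append(c_post.shift_ppm)
        sp1 = st_contrast(c_pre.corrected, off1)
        sp2 = st_contrast(c_pre.corrected, off2)
        so1 = st_contrast(c_post.corrected, off1)
        so2 = st_contrast(c_post.corrected, off2)
        st_maps["st_pre_1"][i, j, k] = sp1
        st_maps["st_pre_2"][i, j, k] = sp2
        st_maps["st_post_1"][i, j, k] = so1
        st_maps["st_post_2"][i, j, k] = so2
        st_maps["b0_shift"][i, j, k] = c_pre.shift_ppm
        dst1[i, j, k] = so1 - sp1
        dst2[i, j, k] = so2 - sp2
        usable[i, j, k] = True

    st_maps["delta_st_1"] = dst1
    st_maps["delta_st_2"] = dst2

    ph, ratio_valid, clamped = _ratiometric(dst1, dst2, cal)
    valid = usable & ratio_valid
    ph[~valid] = np.nan
    clamped &= valid

    n_mask = int(mask.sum())
    qc = CESTQCReport(
        n_mask_voxels=n_mask,
        n_valid=int(valid.sum()),
        n_invalid=n_mask - int(valid.sum()),
        n_clamped=int(clamped.sum()),
        n_b0_unreliable=n_b0_bad,
        n_bad_reference=n_bad_ref,
        mean_b0_shift_pre=float(np.mean(shifts_pre)) if shifts_pre else float("nan"),
        mean_b0_shift_post=float(np.mean(shifts_post)) if shifts_post else float("nan"),
    )
    return PHMap(ph=ph, valid_mask=valid, clamped_mask=clamped, geometry=geometry), st_maps, qc
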