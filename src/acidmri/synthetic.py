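"""Digital tumor phantoms and forward-simulated CEST / DCE acquisitions.

This module generates everything the analysis pipelines consume, with known
ground truth:

* ellipsoidal tumor phantoms with per-voxel extracellular pH (truncated
  normal, optional core-vs-rim offset), B0 shift, and pharmacokinetic truth
  maps;
* Z-spectra built from a sum of Lorentzian lines (water direct saturation, a
  broad semisolid/MT background, and two agent amide pools at 4.2 / 5.5 ppm)
  whose amplitudes are parameterized so that the noiseless post-minus-pre
  saturation-transfer ratio inverts exactly through the ratiometric
  calibration — the closure that makes recovery tests meaningful;
* spoiled-gradient-echo DCE series driven by a biexponential population
  arterial input function through the extended Tofts model, with Rician
  noise;
* two-group cohort tables with the group-level means and spreads of a
  metastatic (4T1-like) vs non-metastatic (67NR-like) murine breast-tumor
  study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cest import ZSpectrum
from .config import AcquisitionConfig, CalibrationModel
from .dce import spgr_signal, tofts_concentration
from .heterogeneity import split_rim_core

__all__ = [
    "PhantomSpec",
    "Phantom",
    "AIFParams",
    "GroupParams",
    "CESTStudy",
    "DCEStudy",
    "make_phantom",
    "simulate_zspectrum",
    "simulate_cest_study",
    "population_aif",
    "simulate_dce_series",
    "simulate_cohort",
    "METASTATIC_GROUP",
    "NONMETASTATIC_GROUP",
    "DEFAULT_AGENT_BASE_ST",
]

# Lorentzian line parameters of the Z-spectrum forward model. Amplitudes are
# fractions of the unsaturated signal, widths are half-width-at-half-maximum
# in ppm. Direct water saturation dominates; the semisolid pool adds a broad
# floor; agent pools are narrow amide lines.
WATER_AMP = 0.85
WATER_HWHM = 1.0
MT_AMP = 0.05
MT_HWHM = 30.0
AGENT_HWHM = 0.7
DEFAULT_AGENT_BASE_ST = 0.10  # noiseless dST at the 5.5 ppm resonance (high-dose agent)


def _lorentzian(x, hwhm):
    return hwhm * hwhm / (hwhm * hwhm + np.asarray(x, dtype=float) ** 2)


@dataclass
class PhantomSpec:
    """Parameters of a digital tumor phantom.

    pH truth is a truncated normal (mean ``ph_mean``, SD ``ph_sd``, truncated
    to ``ph_range``); ``rim_core_offset`` (core mean minus rim mean, pH
    units) redistributes acidity inward while preserving the overall mean.
    B0 shifts are normal per voxel. Pharmacokinetic truth maps are normal
    around (``ktrans``, ``ve``, ``vp``) with their SDs, clipped to physical
    bounds. Ktrans is in 1/s against a seconds time axis.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 8)
    voxel_size: tuple[float, float, float] = (0.234, 0.234, 1.5)  # mm
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = (12.0, 12.0, 3.0)  # voxels
    ph_mean: float = 6.72
    ph_sd: float = 0.10
    ph_range: tuple[float, float] = (6.0, 7.4)
    rim_core_offset: float = 0.0
    rim_core_depth: int = 2
    b0_mean: float = 0.0
    b0_sd: float = 0.15
    ktrans: float = 0.0012
    ktrans_sd: float = 0.0
    ve: float = 0.2
    ve_sd: float = 0.0
    vp: float = 0.04
    vp_sd: float = 0.0
    t10_ms: float = 1800.0
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be positive")
        if min(self.ph_sd, self.b0_sd, self.ktrans_sd, self.ve_sd, self.vp_sd) < 0:
            raise ValueError("SDs must be nonnegative")
        if not (0 <= self.vp <= 1 and 0 <= self.ve <= 1 and self.ve + self.vp <= 1):
            raise ValueError("require 0 <= ve, vp and ve + vp <= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.t10_ms <= 0:
            raise ValueError("t10 must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "voxel_size", "center", "radii", "ph_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Phantom:
    """Ground-truth container; truth fields are NaN outside the tumor mask."""

    tumor_mask: np.ndarray
    ph_truth: np.ndarray
    b0_truth: np.ndarray
    ktrans_truth: np.ndarray
    ve_truth: np.ndarray
    vp_truth: np.ndarray
    t10_map: np.ndarray
    spec: PhantomSpec | None = field(default=None, repr=False)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal; exact for sd = 0."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate mean outside truncation range")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(1000):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build an ellipsoidal tumor phantom with per-voxel truth maps."""
    shape = tuple(spec.grid_shape)
    center = spec.center if spec.center is not None else tuple((s - 1) / 2.0 for s in shape)
    for c, r, s in zip(center, spec.radii, shape):
        if c - r < 0 or c + r > s - 1:
            raise ValueError("tumor ellipsoid extends outside the grid")
    ii, jj, kk = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    mask = (
        ((ii - center[0]) / spec.radii[0]) ** 2
        + ((jj - center[1]) / spec.radii[1]) ** 2
        + ((kk - center[2]) / spec.radii[2]) ** 2
    ) <= 1.0
    n = int(mask.sum())
    rng = np.random.default_rng(spec.seed)

    lo, hi = spec.ph_range
    ph_vals = _truncated_normal(rng, spec.ph_mean, spec.ph_sd, lo, hi, n)
    ph = np.full(shape, np.nan)
    ph[mask] = ph_vals
    if spec.rim_core_offset != 0.0:
        regions = split_rim_core(mask, spec.rim_core_depth)
        n_core = int(regions.core.sum())
        n_rim = int(regions.rim.sum())
        if n_core and n_rim:
            # mean-preserving shift: core - rim difference = rim_core_offset
            ph[regions.core] += spec.rim_core_offset * n_rim / n
            ph[regions.rim] -= spec.rim_core_offset * n_core / n
            ph[mask] = np.clip(ph[mask], lo, hi)

    def truth(mean, sd, lo_c, hi_c):
        vol = np.full(shape, np.nan)
        vol[mask] = np.clip(rng.normal(mean, sd, n) if sd > 0 else mean, lo_c, hi_c)
        return vol

    b0 = np.full(shape, np.nan)
    b0[mask] = rng.normal(spec.b0_mean, spec.b0_sd, n) if spec.b0_sd > 0 else spec.b0_mean
    ktrans = truth(spec.ktrans, spec.ktrans_sd, 0.0, 0.5)
    ve = truth(spec.ve, spec.ve_sd, 0.0, 0.9)
    vp = truth(spec.vp, spec.vp_sd, 0.0, 0.3)
    over = mask & (ve + vp > 1.0)
    if over.any():
        scale = 0.99 / (ve[over] + vp[over])
        ve[over] *= scale
        vp[over] *= scale
    t10 = np.full(shape, float(spec.t10_ms))
    return Phantom(tumor_mask=mask, ph_truth=ph, b0_truth=b0, ktrans_truth=ktrans,
                   ve_truth=ve, vp_truth=vp, t10_map=t10, spec=spec)


def _agent_amplitudes(ph, acq: AcquisitionConfig, cal: CalibrationModel,
                      base_st: float) -> tuple[np.ndarray, np.ndarray]:
    """Amide-pool amplitudes realizing the calibration's ST ratio at ``ph``.

    Solves the 2x2 cross-talk system so the noiseless dST at the two agent
    offsets is (R * base_st, base_st) with R the calibration inverse ratio.
    """
    off1, off2 = acq.agent_offsets
    c = float(_lorentzian(off2 - off1, AGENT_HWHM))
    r = np.asarray(cal.ratio_for_ph(ph), dtype=float)
    denom = 1.0 - c * c
    a1 = base_st * (r - c) / denom
    a2 = base_st * (1.0 - r * c) / denom
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError(
            "pH outside the range realizable with nonnegative agent amplitudes"
        )
    return a1, a2


def _zspectra_batch(ph, agent, b0, acq, cal, noise_sigma, rng, base_st):
    """Vectorized Z-spectra: rows = voxels, columns = saturation offsets."""
    ph = np.atleast_1d(np.asarray(ph, dtype=float))
    agent = np.atleast_1d(np.asarray(agent, dtype=bool))
    b0 = np.atleast_1d(np.asarray(b0, dtype=float))
    off = acq.sat_offsets
    off1, off2 = acq.agent_offsets
    x = off[None, :] - b0[:, None]
    z = 1.0 - WATER_AMP * _lorentzian(x, WATER_HWHM) - MT_AMP * _lorentzian(x, MT_HWHM)
    if agent.any():
        a1 = np.zeros(ph.shape)
        a2 = np.zeros(ph.shape)
        a1[agent], a2[agent] = _agent_amplitudes(ph[agent], acq, cal, base_st)
        z -= a1[:, None] * _lorentzian(x - off1, AGENT_HWHM)
        z -= a2[:, None] * _lorentzian(x - off2, AGENT_HWHM)
    if noise_sigma > 0:
        z = z + rng.normal(0.0, noise_sigma, z.shape)
    return np.clip(z, 0.0, 1.0 + 5.0 * noise_sigma)


def simulate_zspectrum(
    ph: float,
    agent_present: bool,
    acq: AcquisitionConfig,
    cal: CalibrationModel,
    b0_shift: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    base_st: float = DEFAULT_AGENT_BASE_ST,
) -> ZSpectrum:
    """Forward-simulate one voxel's Z-spectrum.

    With the agent present, the two amide-pool amplitudes are chosen so that
    the noiseless post-minus-pre dST ratio at the agent offsets equals the
    ratiometric calibration inverse 10**((ph - p0) / p1); pH must then lie in
    the calibration's valid range.
    """
    if agent_present:
        lo, hi = cal.valid_ph_range
        if not lo <= ph <= hi:
            raise ValueError(f"pH {ph} outside calibration range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    z = _zspectra_batch([ph], [agent_present], [b0_shift], acq, cal,
                        noise_sigma, rng, base_st)[0]
    return ZSpectrum(offsets=acq.sat_offsets.copy(), signal=z)


@dataclass
class CESTStudy:
    """Pre/post-agent saturation stacks plus unsaturated reference volumes."""

    pre: np.ndarray       # (x, y, z, n_offsets)
    post: np.ndarray
    s0_pre: np.ndarray    # (x, y, z)
    s0_post: np.ndarray


def simulate_cest_study(
    phantom: Phantom,
    acq: AcquisitionConfig,
    cal: CalibrationModel,
    noise_sigma: float | None = None,
    seed: int = 0,
    base_st: float = DEFAULT_AGENT_BASE_ST,
    s0_scale: float = 1000.0,
) -> CESTStudy:
    """Simulate the paired pre-/post-injection CEST acquisition of a phantom.

    Tumor voxels carry the agent pools in the post stack only; background
    voxels see water + MT in both. ``noise_sigma`` defaults to the phantom
    spec's value and is Gaussian relative to the unsaturated signal.
    """
    if noise_sigma is None:
        noise_sigma = phantom.spec.noise_sigma if phantom.spec is not None else 0.0
    rng = np.random.default_rng(seed)
    shape = phantom.tumor_mask.shape
    n_off = acq.sat_offsets.size
    mask = phantom.tumor_mask
    flat_n = int(np.prod(shape))

    ph = np.where(mask, phantom.ph_truth, np.nan).reshape(flat_n)
    b0 = np.where(mask, phantom.b0_truth, 0.0).reshape(flat_n)
    agent_post = mask.reshape(flat_n)
    no_agent = np.zeros(flat_n, dtype=bool)

    z_pre = _zspectra_batch(ph, no_agent, b0, acq, cal, noise_sigma, rng, base_st)
    z_post = _zspectra_batch(ph, agent_post, b0, acq, cal, noise_sigma, rng, base_st)

    def s0_vol():
        if noise_sigma > 0:
            return s0_scale * (1.0 + rng.normal(0.0, noise_sigma, shape))
        return np.full(shape, s0_scale)

    return CESTStudy(
        pre=(s0_scale * z_pre).reshape(shape + (n_off,)),
        post=(s0_scale * z_post).reshape(shape + (n_off,)),
        s0_pre=s0_vol(),
        s0_post=s0_vol(),
    )


@dataclass
class AIFParams:
    """Biexponential population arterial input function (amplitudes in mM,
    decay rates in 1/s): Cp(t) = a1 e^(-m1 dt) + a2 e^(-m2 dt) after the
    bolus, zero before."""

    a1: float = 5.8
    m1: float = 0.01
    a2: float = 0.7
    m2: float = 0.0002

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be nonnegative")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("AIF decay rates must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AIFParams":
        return cls(**d)


def population_aif(t: np.ndarray, bolus_time: float, params: AIFParams | None = None) -> np.ndarray:
    """Plasma concentration (mM) of the population AIF at times ``t`` (s)."""
    params = params or AIFParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    dt = t - bolus_time
    cp = params.a1 * np.exp(-params.m1 * dt) + params.a2 * np.exp(-params.m2 * dt)
    return np.where(dt < 0, 0.0, cp)


@dataclass
class DCEStudy:
    """VFA T1-mapping series plus dynamic contrast-enhanced series."""

    vfa: np.ndarray       # (x, y, z, n_angles)
    dynamic: np.ndarray   # (x, y, z, n_frames)
    cp: np.ndarray        # plasma concentration per frame (mM)
    bolus_time_s: float


def simulate_dce_series(
    phantom: Phantom,
    acq: AcquisitionConfig,
    aif: AIFParams | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    m0: float = 1000.0,
) -> DCEStudy:
    """Forward-simulate the VFA series and the dynamic DCE series.

    Tissue concentration follows the extended Tofts model driven by the
    population AIF with the bolus at the first post-baseline frame;
    concentration maps to signal through the spoiled-gradient-echo equation
    with 1/T1(t) = 1/T10 + r1 C(t). ``noise_sigma`` is the Rician channel
    sigma as a fraction of each voxel's baseline signal (SNR = 1/sigma).
    """
    aif = aif or AIFParams()
    rng = np.random.default_rng(seed)
    t = acq.frame_times_s
    bolus_time = acq.dce_n_baseline * acq.frame_interval_s
    cp = population_aif(t, bolus_time, aif)
    shape = phantom.tumor_mask.shape
    mask = phantom.tumor_mask

    conc = np.zeros(shape + (acq.dce_n_frames,))
    for idx in np.argwhere(mask):
        i, j, k = map(int, idx)
        conc[i, j, k] = tofts_concentration(
            t, cp,
            float(phantom.ktrans_truth[i, j, k]),
            float(phantom.ve_truth[i, j, k]),
            float(phantom.vp_truth[i, j, k]),
        )

    t10 = phantom.t10_map[..., None]
    t1_ms = 1.0 / (1.0 / t10 + acq.r1_relaxivity * conc / 1000.0)
    dynamic = spgr_signal(m0, t1_ms, acq.tr_ms, acq.flip_deg)

    angles = np.asarray(acq.vfa_angles_deg)
    vfa = np.stack(
        [spgr_signal(m0, phantom.t10_map, acq.tr_ms, a) for a in angles], axis=-1
    )

    if noise_sigma > 0:
        sigma = noise_sigma * spgr_signal(m0, phantom.t10_map, acq.tr_ms, acq.flip_deg)
        sigma4 = sigma[..., None]
        dynamic = np.sqrt(
            (dynamic + rng.normal(0, 1, dynamic.shape) * sigma4) ** 2
            + (rng.normal(0, 1, dynamic.shape) * sigma4) ** 2
        )
        vfa = np.sqrt(
            (vfa + rng.normal(0, 1, vfa.shape) * sigma4) ** 2
            + (rng.normal(0, 1, vfa.shape) * sigma4) ** 2
        )
    return DCEStudy(vfa=vfa, dynamic=dynamic, cp=cp, bolus_time_s=bolus_time)


@dataclass
class GroupParams:
    """Per-group (mean, SD) pairs for the cohort-level metrics."""

    name: str
    ph_e: tuple[float, float]
    acidity_score: tuple[float, float]
    ktrans: tuple[float, float]
    vp: tuple[float, float]
    tgr: tuple[float, float]
    volume_mm3: tuple[float, float] = (220.0, 90.0)
    rim_core_offset: float = 0.0  # within-tumor core-minus-rim pH offset

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroupParams":
        d = dict(d)
        for key in ("ph_e", "acidity_score", "ktrans", "vp", "tgr", "volume_mm3"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Printed group-level summaries of the metastatic (4T1) and non-metastatic
# (67NR) murine mammary-carcinoma models; SDs here are between tumors. The
# metastatic line acidifies its core (core pH 6.69 vs rim 6.74); the
# non-metastatic line is spatially uniform.
METASTATIC_GROUP = GroupParams(
    name="metastatic",
    ph_e=(6.72, 0.06),
    acidity_score=(2.11, 0.10),
    ktrans=(0.0012, 0.0004),
    vp=(0.04, 0.02),
    tgr=(0.67, 0.17),
    rim_core_offset=-0.05,
)
NONMETASTATIC_GROUP = GroupParams(
    name="non-metastatic",
    ph_e=(6.81, 0.07),
    acidity_score=(1.96, 0.12),
    ktrans=(0.0052, 0.0026),
    vp=(0.03, 0.02),
    tgr=(0.49, 0.15),
    rim_core_offset=0.01,
)


def simulate_cohort(
    n_per_group: int = 14,
    group_params: tuple[GroupParams, GroupParams] = (METASTATIC_GROUP, NONMETASTATIC_GROUP),
    seed: int = 0,
    day: int = 14,
) -> pd.DataFrame:
    """Draw a two-group cohort table of per-tumor summary metrics.

    Each tumor's metrics are independent normal draws from its group's
    (mean, SD); Ktrans and v_p are floored at small positive values. The
    default of 14 tumors per group reflects bilateral inoculation in 7 mice.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 tumors per group")
    rng = np.random.default_rng(seed)
    rows = []
    tumor_id = 0
    for gp in group_params:
        for _ in range(n_per_group):
            rows.append({
                "tumor_id": f"T{tumor_id:03d}",
                "group": gp.name,
                "volume_mm3": max(rng.normal(*gp.volume_mm3), 20.0),
                "day": day,
                "ph_e": rng.normal(*gp.ph_e),
                "acidity_score": rng.normal(*gp.acidity_score),
                "ktrans": max(rng.normal(*gp.ktrans), 1e-5),
                "vp": max(rng.normal(*gp.vp), 1e-4),
                "tgr": rng.normal(*gp.tgr),
            })
            tumor_id += 1
    return pd.DataFrame(rows)
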