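"""Acquisition and calibration configuration shared by the simulator and pipelines.

The acquisition geometry mirrors a small-animal protocol: a saturation-frequency
sweep of 46 offsets over +/-10 ppm at 3 uT for CEST, and a FLASH/spoiled
gradient-echo protocol (TR 58 ms, flip 30 deg, 60 dynamic frames of which 6 are
pre-contrast, variable-flip-angle series at 5-60 deg) for DCE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["AcquisitionConfig", "CalibrationModel", "default_sat_offsets"]


def default_sat_offsets() -> np.ndarray:
    """Default 46-entry saturation-offset grid (ppm), ascending over +/-10.

    Sampling is densified around the water resonance (B0 estimation) and over
    3.5-6.5 ppm where the pH-reporting amide resonances sit; the far wings are
    sampled coarsely.
    """
    neg = np.arange(-10.0, -1.5, 1.0)          # -10 .. -2, 9 pts
    water = np.arange(-1.5, 1.75, 0.25)        # -1.5 .. 1.5, 13 pts
    mid = np.array([2.0, 2.5, 3.0, 3.25])
    agent = np.arange(3.5, 6.75, 0.25)         # 3.5 .. 6.5, 13 pts
    far = np.arange(7.0, 10.5, 0.5)            # 7 .. 10, 7 pts
    offsets = np.concatenate([neg, water, mid, agent, far])
    assert offsets.size == 46
    return offsets


@dataclass
class AcquisitionConfig:
    """Acquisition parameters for the CEST and DCE arms of a study.

    Parameters
    ----------
    sat_offsets
        Saturation frequency offsets in ppm, strictly ascending, spanning 0.
    sat_power_uT
        Continuous-wave presaturation amplitude (microtesla); metadata.
    agent_offsets
        The two pH-reporting agent resonances (ppm) used by the ratiometric
        readout.
    dce_n_frames, dce_n_baseline
        Total dynamic frames and the number of pre-contrast baseline frames.
    tr_ms, te_ms, flip_deg
        Spoiled-gradient-echo timing and excitation angle for the dynamic
        series (TE is metadata only; the signal model is TE-free).
    vfa_angles_deg
        Flip angles of the variable-flip-angle T1-mapping series.
    frame_interval_s
        Dynamic frame spacing in seconds (60 frames in 13 min -> 13 s).
    r1_relaxivity
        Contrast-agent longitudinal relaxivity (1/mM/s).
    gd_dose
        Injected gadolinium dose (mmol/kg); metadata.
    """

    sat_offsets: np.ndarray = field(default_factory=default_sat_offsets)
    sat_power_uT: float = 3.0
    agent_offsets: tuple[float, float] = (4.2, 5.5)
    dce_n_frames: int = 60
    dce_n_baseline: int = 6
    tr_ms: float = 58.0
    te_ms: float = 1.82
    flip_deg: float = 30.0
    vfa_angles_deg: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0, 45.0, 60.0)
    frame_interval_s: float = 13.0
    r1_relaxivity: float = 3.3
    gd_dose: float = 0.1

    def __post_init__(self) -> None:
        self.sat_offsets = np.asarray(self.sat_offsets, dtype=float)
        if self.sat_offsets.ndim != 1 or self.sat_offsets.size < 2:
            raise ValueError("sat_offsets must be a 1-D array of >= 2 values")
        if not np.all(np.diff(self.sat_offsets) > 0):
            raise ValueError("sat_offsets must be strictly increasing")
        if not (self.sat_offsets[0] <= 0.0 <= self.sat_offsets[-1]):
            raise ValueError("sat_offsets must span 0 ppm (water)")
        angles = np.asarray(self.vfa_angles_deg + (self.flip_deg,))
        if np.any((angles <= 0) | (angles > 90)):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if len(self.vfa_angles_deg) < 3:
            raise ValueError("need >= 3 VFA angles")
        if not 0 <= self.dce_n_baseline < self.dce_n_frames:
            raise ValueError("dce_n_baseline must be < dce_n_frames")
        if self.tr_ms <= 0 or self.frame_interval_s <= 0:
            raise ValueError("TR and frame interval must be positive")

    @property
    def frame_times_s(self) -> np.ndarray:
        """Frame-center times of the dynamic series (s), starting at 0."""
        return np.arange(self.dce_n_frames) * self.frame_interval_s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sat_offsets"] = self.sat_offsets.tolist()
        d["agent_offsets"] = list(self.agent_offsets)
        d["vfa_angles_deg"] = list(self.vfa_angles_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if "sat_offsets" in d:
            d["sat_offsets"] = np.asarray(d["sat_offsets"], dtype=float)
        if "agent_offsets" in d:
            d["agent_offsets"] = tuple(d["agent_offsets"])
        if "vfa_angles_deg" in d:
            d["vfa_angles_deg"] = tuple(d["vfa_angles_deg"])
        return cls(**d)


@dataclass
class CalibrationModel:
    """Ratiometric pH calibration: pH = p0 + p1 * log10(ST ratio).

    ``p0`` is the pH at unit ratio of the two agent-offset saturation-transfer
    contrasts and ``p1`` the slope in pH units per decade of ratio. ``p1 > 0``
    with the 4.2/5.5 ppm ratio convention: a larger ratio reads out as a less
    acidic voxel. ``min_delta_st`` is the detectability floor: voxels whose
    post-minus-pre ST contrast at either agent offset falls below it are
    flagged invalid rather than ratioed.
    """

    p0: float = 6.9
    p1: float = 1.5
    valid_ph_range: tuple[float, float] = (6.0, 7.4)
    min_delta_st: float = 0.005

    def __post_init__(self) -> None:
        if self.p1 == 0:
            raise ValueError("p1 must be nonzero")
        lo, hi = self.valid_ph_range
        if not lo < hi:
            raise ValueError("valid_ph_range must be nondegenerate (lo < hi)")
        if self.min_delta_st < 0:
            raise ValueError("min_delta_st must be >= 0")

    def ratio_for_ph(self, ph: float | np.ndarray) -> float | np.ndarray:
        """Inverse calibration: the ST ratio that reads out as ``ph``."""
        return 10.0 ** ((np.asarray(ph, dtype=float) - self.p0) / self.p1)

    def ph_for_ratio(self, ratio: float | np.ndarray) -> float | np.ndarray:
        return self.p0 + self.p1 * np.log10(np.asarray(ratio, dtype=float))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["valid_ph_range"] = list(self.valid_ph_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        if "valid_ph_range" in d:
            d["valid_ph_range"] = tuple(d["valid_ph_range"])
        return cls(**d)
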