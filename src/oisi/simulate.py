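"""Synthetic multispectral trial generator (the forward model the analysis inverts).

A trial is simulated in three stages:

1. chromophore kinetics — gamma-variate kernels produce dHbO(t), dHbR(t)
   (hemodynamic response, optionally delayed from the stimulus) and dS(t)
   (light-scattering pseudo-chromophore, peaking during the stimulation
   train and decaying slowly);
2. optics — the modified Beer-Lambert forward model turns chromophores into
   per-band attenuation traces (:func:`oisi.mbll.forward_project`);
3. camera — each band trace modulates a spatial Gaussian "active barrel"
   blob on a constant-intensity frame, multiplied by a slow global
   illumination fluctuation shared by all pixels, plus per-pixel Gaussian
   shot-like noise.

Two presets mirror the two response regimes of interest: ``neonatal`` (an
early scattering phase peaking at the stimulation offset, hemodynamics
delayed with HbT peaking ~30 s after onset) and ``adult`` (both components
fast and overlapping inside the 10 s train).

All randomness descends from one scene seed through per-(trial, band)
``numpy`` seed-sequence substreams, so identical parameters give
bit-identical stacks and noiseless scenes are fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import FrameStack, LFPTrace, Protocol, TrialSet
from .mbll import ChromophoreTimecourses, SpectralBand, forward_project

__all__ = [
    "ResponseParams",
    "SceneParams",
    "NEONATAL",
    "ADULT",
    "gamma_variate",
    "shape_for_half_recovery",
    "simulate_chromophores",
    "render_trial",
    "render_trials",
    "spatial_blob",
    "simulate_lfp",
]


def gamma_variate(t: np.ndarray, peak_time: float, shape: float) -> np.ndarray:
    """Unit-peak gamma-variate kernel ``(t/tp)^a * exp(a*(1 - t/tp))``.

    Zero for ``t <= 0``; rises to 1 at ``t = peak_time`` and decays with a
    rate set by the shape ``a`` (larger = narrower).
    """
    if peak_time <= 0 or shape <= 0:
        raise ValueError("peak_time and shape must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_time
    out[pos] = np.exp(shape * (np.log(x) + 1.0 - x))
    return out


def shape_for_half_recovery(peak_time: float, half_recovery: float) -> float:
    """Shape parameter whose kernel falls to half peak ``half_recovery`` s after the peak.

    For the unit-peak kernel, f(tp + th) = exp(a*(ln(1+r) - r)) with
    r = th/tp, giving the closed form a = ln2 / (r - ln(1+r)).
    """
    if peak_time <= 0 or half_recovery <= 0:
        raise ValueError("peak_time and half_recovery must be > 0")
    r = half_recovery / peak_time
    return math.log(2.0) / (r - math.log1p(r))


@dataclass(frozen=True)
class ResponseParams:
    """Kinetic parameters of the simulated evoked response.

    Times are seconds relative to stimulus onset; hemoglobin amplitudes in
    uM (signed changes from baseline), ``ls_amp`` is the dimensionless peak
    of the scattering pseudo-chromophore dS.  ``kernel_shape`` shapes the
    hemodynamic kernels; the dS kernel's shape is derived from its peak time
    and half-recovery so both are honored exactly.

    Defaults are the neonatal regime: scattering peaks at the 10 s
    stimulation offset with a 25 s half-recovery, hemodynamics lag the
    stimulus by 10 s and HbT peaks ~30 s after onset.  Amplitudes are
    illustrative values on the small-signal scale of evoked OIS.
    """

    hr_delay: float = 10.0
    hr_peak_time: float = 30.0
    hbo_amp: float = 2.0
    hbr_amp: float = -0.5
    ls_amp: float = 5.0e-3
    ls_peak_time: float = 10.0
    ls_half_recovery: float = 25.0
    kernel_shape: float = 3.0

    def __post_init__(self) -> None:
        for name in ("hr_delay", "hr_peak_time", "ls_peak_time", "ls_half_recovery"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"ResponseParams.{name} must be finite and >= 0, got {v!r}")
        for name in ("hbo_amp", "hbr_amp", "ls_amp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"ResponseParams.{name} must be finite")
        if not np.isfinite(self.kernel_shape) or self.kernel_shape <= 0:
            raise ValueError("kernel_shape must be > 0")
        if (self.hbo_amp != 0 or self.hbr_amp != 0) and self.hr_peak_time <= self.hr_delay:
            raise ValueError("hr_peak_time must exceed hr_delay for a nonzero HR")


NEONATAL = ResponseParams()
ADULT = ResponseParams(
    hr_delay=0.5,
    hr_peak_time=6.0,
    hbo_amp=4.0,
    hbr_amp=-1.2,
    ls_amp=4.0e-3,
    ls_peak_time=4.0,
    ls_half_recovery=6.0,
    kernel_shape=3.0,
)


@dataclass(frozen=True)
class SceneParams:
    """Geometry, intensity and noise of the rendered scene.

    The default frame matches the acquisition geometry the pipeline targets:
    130 x 174 pixels at 5 Hz, a 5/10/45 s baseline/stimulation/recovery
    protocol, a Gaussian active-barrel blob, a 1% multiplicative 0.1 Hz
    global illumination fluctuation, and per-pixel Gaussian noise of 0.5%
    of baseline.
    """

    height: int = 130
    width: int = 174
    blob_center: tuple[int, int] = (64, 86)
    blob_sigma: float = 8.0
    baseline_intensity: float = 1000.0
    illumination_fluctuation_amp: float = 0.01
    illumination_freq_hz: float = 0.1
    noise_sigma: float = 5.0
    n_trials: int = 12
    seed: int = 0
    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        if self.baseline_intensity < 0:
            raise ValueError("baseline_intensity must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.blob_sigma <= 0:
            raise ValueError("blob_sigma must be > 0")
        r, c = self.blob_center
        m = 3.0 * self.blob_sigma
        if not (r - m >= 0 and r + m <= self.height - 1 and c - m >= 0 and c + m <= self.width - 1):
            raise ValueError("blob (center +- 3 sigma) must lie fully inside the frame")


def simulate_chromophores(
    params: ResponseParams, protocol: Protocol | None = None
) -> ChromophoreTimecourses:
    """Sample dHbO, dHbR, dS on the protocol's frame-time grid.

    All components are zero before stimulus onset.  dS peaks at
    ``ls_peak_time`` after onset and first reaches half peak
    ``ls_half_recovery`` later; HbT peaks at ``hr_peak_time`` after onset.
    """
    protocol = protocol or Protocol()
    t = protocol.times()
    rel = t - protocol.stim_onset_s
    if params.ls_amp != 0.0:
        a_ls = shape_for_half_recovery(params.ls_peak_time, params.ls_half_recovery)
        d_s = params.ls_amp * gamma_variate(rel, params.ls_peak_time, a_ls)
    else:
        d_s = np.zeros_like(t)
    if params.hbo_amp != 0.0 or params.hbr_amp != 0.0:
        f_hr = gamma_variate(
            rel - params.hr_delay, params.hr_peak_time - params.hr_delay, params.kernel_shape
        )
    else:
        f_hr = np.zeros_like(t)
    return ChromophoreTimecourses(
        t=t,
        d_hbo=params.hbo_amp * f_hr,
        d_hbr=params.hbr_amp * f_hr,
        d_s=d_s,
        stim_onset_s=protocol.stim_onset_s,
    )


def spatial_blob(scene: SceneParams) -> np.ndarray:
    """Unit-peak spatial Gaussian response profile (height, width)."""
    rr, cc = np.mgrid[0 : scene.height, 0 : scene.width]
    r0, c0 = scene.blob_center
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    return np.exp(-0.5 * d2 / scene.blob_sigma**2)


def _trial_rng(scene: SceneParams, trial: int, band_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=scene.seed, spawn_key=(trial, band_index))
    return np.random.default_rng(ss)


def render_trial(
    scene: SceneParams,
    trace: np.ndarray,
    band: str,
    trial: int,
    band_index: int = 0,
    mode: str = "reflectance",
) -> FrameStack:
    """Render one band's frame stack for one trial.

    frame(t) = baseline * (1 + g(t)) * (1 -/+ trace(t) * B) + noise, where
    B is the unit-peak blob and g(t) the shared illumination fluctuation.
    Reflectance darkens the blob for positive (attenuating) traces;
    transmission brightens it.
    """
    trace = np.asarray(trace, dtype=float)
    n = scene.protocol.n_frames
    if trace.shape != (n,):
        raise ValueError(f"trace length {trace.shape} != protocol frame count {n}")
    if mode not in ("reflectance", "transmission"):
        raise ValueError(f"unknown imaging mode {mode!r}")
    t = scene.protocol.times()
    g = scene.illumination_fluctuation_amp * np.sin(
        2.0 * np.pi * scene.illumination_freq_hz * t
    )
    B = spatial_blob(scene)
    sign = -1.0 if mode == "reflectance" else 1.0
    frames = (
        scene.baseline_intensity
        * (1.0 + g)[:, None, None]
        * (1.0 + sign * trace[:, None, None] * B[None, :, :])
    )
    if scene.noise_sigma > 0:
        rng = _trial_rng(scene, trial, band_index)
        frames = frames + rng.normal(0.0, scene.noise_sigma, frames.shape)
    return FrameStack(data=frames, band=band, protocol=scene.protocol, mode=mode)


def render_trials(
    scene: SceneParams,
    band_traces: Mapping[str, np.ndarray],
    mode: str = "reflectance",
) -> dict[str, TrialSet]:
    """Render all trials for every band; one synchronized time grid per band."""
    out: dict[str, TrialSet] = {}
    for bi, (band, trace) in enumerate(band_traces.items()):
        out[band] = TrialSet(
            trials=[
                render_trial(scene, trace, band, trial=k, band_index=bi, mode=mode)
                for k in range(scene.n_trials)
            ]
        )
    return out


def simulate_lfp(
    stim_rate_hz: float,
    response_amp_uv: float,
    depression: float = 1.0,
    noise_sigma_uv: float = 0.0,
    seed: int = 0,
    protocol: Protocol | None = None,
    sampling_rate_hz: float = 1000.0,
    deflection_peak_s: float = 0.01,
) -> LFPTrace:
    """Simulate an evoked LFP trace: one deflection per stimulus in the train.

    Deflections are negative alpha-shaped waves peaking ``deflection_peak_s``
    after each stimulus; successive amplitudes are geometrically depressed
    (``amp * depression**k``), emulating use-dependent synaptic depression.
    """
    if not (0.0 < depression <= 1.0):
        raise ValueError("depression must be in (0, 1]")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    if stim_rate_hz <= 0:
        raise ValueError("stim_rate_hz must be > 0")
    protocol = protocol or Protocol()
    n = int(round(protocol.duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    v = np.zeros(n)
    n_stim = max(1, int(round(stim_rate_hz * protocol.stim_s)))
    for k in range(n_stim):
        t0 = protocol.stim_onset_s + k / stim_rate_hz
        tau = t - t0
        pos = tau > 0
        x = tau[pos] / deflection_peak_s
        v[pos] += -response_amp_uv * depression**k * x * np.exp(1.0 - x)
    if noise_sigma_uv > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xFB,)))
        v = v + rng.normal(0.0, noise_sigma_uv, n)
    return LFPTrace(t=t, v=v, stim_onset_s=protocol.stim_onset_s, stim_rate_hz=stim_rate_hz)
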