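"""Synthetic tremor accelerometry with controllable entrainment.

The study's accelerometer recordings were never deposited, so the analysis
is exercised on a generator that emulates their statistical structure:

* tremor is a single stochastic phase oscillator — a Kuramoto-style forced
  phase with Wiener phase diffusion and a slow Ornstein-Uhlenbeck frequency
  drift — because the downstream analysis consumes only phase/amplitude
  structure and this is the minimal model with a controllable degree of
  entrainment (the coupling gain ``kappa``);
* the amplitude envelope is a reflected Ornstein-Uhlenbeck process, giving
  the right-skewed positive amplitudes the Box-Cox stage expects;
* the oscillation is projected onto three accelerometer axes through a
  fixed unit vector (the z-axis dominant, mirroring sensor placement on the
  plane of maximal tremor) with additive white sensor noise per axis;
* stimulation waveforms follow the delivered protocol: a sinusoid with no
  DC offset at 2000 uA peak-to-peak with a 10 s linear ramp-up (sham holds
  for a further 10 s and then ramps back down), and a rectangular photic
  pulse train at the stimulation frequency.

Phase dynamics (Euler-Maruyama at the recording rate)::

    d(theta) = 2 pi f(t) dt + 2 pi kappa(t) sin(phi_stim - theta) dt
               + 2 pi s_j dW

with ``f(t) = f0 + OU drift`` and ``s_j`` the phase-diffusion intensity in
Hz s^-1/2. Coupling is scaled by the normalized stimulation amplitude, so
sham blocks are forced only during the brief ramp window.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .io_core import (
    BlockDesign,
    Condition,
    Recording,
    STIM_CONDITIONS,
    ValidationError,
)

__all__ = [
    "StimWaveformSpec",
    "TremorModelParams",
    "SubjectParams",
    "simulate_stim_waveform",
    "simulate_photic_train",
    "simulate_tremor_block",
    "generate_experiment",
    "draw_subject",
    "DEFAULT_KAPPA_BY_CONDITION",
    "GROUP_MEAN_F0",
    "GROUP_SD_F0",
]

#: Group tremor peak frequency: mean 8.28 Hz, SD = SEM 0.44 x sqrt(12).
GROUP_MEAN_F0 = 8.28
GROUP_SD_F0 = 0.44 * math.sqrt(12)

#: Condition -> phase-coupling gain emulating the reported findings:
#: entrainment through the right-shoulder return montage, weaker photic
#: entrainment, nothing elsewhere.
DEFAULT_KAPPA_BY_CONDITION: dict[Condition, float] = {
    Condition.RSH: 0.1,
    Condition.PHOTIC: 0.05,
}


@dataclasses.dataclass
class StimWaveformSpec:
    """Parameters of a tACS (or sham) stimulation waveform."""

    freq: float
    peak_to_peak: float = 2000.0
    ramp_s: float = 10.0
    sham: bool = False
    duration_s: float = 180.0
    fs: float = 2048.0

    def validate(self) -> None:
        if not self.freq > 0:
            raise ValidationError(f"freq must be positive, got {self.freq}")
        if self.peak_to_peak < 0:
            raise ValidationError("peak_to_peak must be >= 0")
        if self.ramp_s < 0:
            raise ValidationError("ramp_s must be >= 0")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValidationError("duration_s and fs must be positive")


def ramp_envelope(t: np.ndarray, ramp_s: float, sham: bool) -> np.ndarray:
    """Normalized (0..1) amplitude envelope of the stimulation current.

    Linear ramp-up over ``[0, ramp_s]``; the sham waveform holds full
    amplitude for a further ``ramp_s`` seconds and then ramps back down,
    staying at zero afterwards.
    """
    if ramp_s == 0:
        env = np.ones_like(t)
    else:
        env = np.clip(t / ramp_s, 0.0, 1.0)
    if sham:
        if ramp_s == 0:
            return np.zeros_like(t)
        down = np.clip((3.0 * ramp_s - t) / ramp_s, 0.0, 1.0)
        env = np.minimum(env, down)
    return env


def simulate_stim_waveform(spec: StimWaveformSpec) -> np.ndarray:
    """Sinusoidal stimulation current in microamperes.

    Steady-state peak-to-peak amplitude equals ``spec.peak_to_peak`` and the
    waveform carries no DC offset; the sham variant ramps down again and is
    identically zero after ``3 * ramp_s``.
    """
    spec.validate()
    if spec.fs < 4 * spec.freq:
        raise ValidationError(
            f"fs = {spec.fs} Hz undersamples a {spec.freq} Hz waveform (need >= 4x)"
        )
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    env = ramp_envelope(t, spec.ramp_s, spec.sham)
    return (spec.peak_to_peak / 2.0) * env * np.sin(2.0 * np.pi * spec.freq * t)


def simulate_photic_train(
    freq: float, duration_s: float, fs: float, duty: float = 0.05,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Rectangular pulse train of light flashes at ``freq`` Hz.

    Pulse onsets are strictly periodic; ``duty`` is the fraction of each
    period the lamp is on (kept small — flashes are brief).
    """
    if not freq > 0:
        raise ValidationError(f"freq must be positive, got {freq}")
    if not 0 < duty < 1:
        raise ValidationError(f"duty cycle must lie in (0, 1), got {duty}")
    if duration_s <= 0 or fs <= 0:
        raise ValidationError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    cycle_pos = np.mod(t * freq, 1.0)
    return amplitude * (cycle_pos < duty).astype(float)


@dataclasses.dataclass
class TremorModelParams:
    """Parameters of the stochastic tremor oscillator.

    ``freq_jitter_sd`` is the phase-diffusion intensity in Hz s^-1/2 (the
    instantaneous frequency picks up white noise of this strength);
    ``kappa`` is the phase-coupling gain towards the stimulation phase in
    Hz (the maximum frequency pull of the forcing). The envelope follows a
    reflected Ornstein-Uhlenbeck process with mean ``env_mean``, stationary
    SD ``env_sd`` and correlation time ``env_tau_s`` (arbitrary
    acceleration units). ``drift_sd``/``drift_tau_s`` parameterize a slow
    OU drift of the oscillator frequency around ``f0``.
    """

    f0: float = GROUP_MEAN_F0
    freq_jitter_sd: float = 0.1
    kappa: float = 0.0
    env_mean: float = 1.0
    env_tau_s: float = 4.0
    env_sd: float = 0.35
    axis_vector: tuple[float, float, float] = (0.15, 0.25, 0.956)
    noise_sd: float = 0.05
    drift_sd: float = 0.02
    drift_tau_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis_vector, dtype=float)
        norm = float(np.linalg.norm(axis))
        if axis.shape != (3,) or norm == 0:
            raise ValidationError("axis_vector must be a nonzero 3-vector")
        self.axis_vector = tuple(axis / norm)
        self.validate()

    def validate(self) -> None:
        if not self.f0 > 0:
            raise ValidationError(f"f0 must be positive, got {self.f0}")
        if self.kappa < 0:
            raise ValidationError(f"kappa must be >= 0, got {self.kappa}")
        if self.freq_jitter_sd < 0 or self.noise_sd < 0 or self.env_sd < 0:
            raise ValidationError("noise intensities must be >= 0")
        if not self.env_tau_s > 0 or not self.drift_tau_s > 0:
            raise ValidationError("OU time constants must be positive")
        if self.drift_sd < 0:
            raise ValidationError("drift_sd must be >= 0")


def _ou_path(
    rng: np.random.Generator, n: int, dt: float, sd: float, tau: float
) -> np.ndarray:
    """Zero-mean OU path via its exact AR(1) discretization."""
    a = math.exp(-dt / tau)
    innov = rng.standard_normal(n) * (sd * math.sqrt(1.0 - a * a))
    x0 = rng.standard_normal() * sd
    out, _ = signal.lfilter([1.0], [1.0, -a], innov, zi=np.array([a * x0]))
    return out


def _phase_path(
    rng: np.random.Generator,
    n: int,
    dt: float,
    f_inst: np.ndarray,
    jitter_sd: float,
    kappa_t: np.ndarray | None,
    stim_phase: np.ndarray | None,
    theta0: float,
) -> np.ndarray:
    """Integrate the forced phase SDE; fast cumulative-sum path when unforced."""
    base = 2.0 * np.pi * f_inst * dt + rng.standard_normal(n) * (
        2.0 * np.pi * jitter_sd * math.sqrt(dt)
    )
    if kappa_t is None or stim_phase is None or not np.any(kappa_t):
        return theta0 + np.cumsum(base)
    gain = 2.0 * np.pi * np.broadcast_to(kappa_t, (n,)) * dt
    theta = np.empty(n)
    th = theta0
    sin = math.sin
    for i, (b, g, sp) in enumerate(zip(base.tolist(), gain.tolist(),
                                       stim_phase.tolist())):
        th = th + b + g * sin(sp - th)
        theta[i] = th
    return theta


def simulate_tremor_block(
    params: TremorModelParams,
    duration_s: float = 180.0,
    fs: float = 2048.0,
    *,
    stim: np.ndarray | None = None,
    stim_phase: np.ndarray | None = None,
    coupling_scale: np.ndarray | None = None,
    stim_channel_name: str = "stim",
    condition: Condition | str = Condition.INITIAL,
    block_id: str = "block0",
    stim_freq: float | None = None,
) -> Recording:
    """Simulate one condition block of tri-axial tremor accelerometry.

    ``stim`` (if given) is stored as an additional channel of the Recording,
    mirroring the shared-amplifier acquisition of the real experiment;
    ``stim_phase`` is the forcing phase used by the coupling term, and
    ``coupling_scale`` (0..1 per sample, e.g. the normalized current
    envelope) modulates the coupling gain over the block. The same
    ``params.seed`` always yields a bit-identical Recording.
    """
    params.validate()
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValidationError("block too short")
    for name, arr in (("stim", stim), ("stim_phase", stim_phase),
                      ("coupling_scale", coupling_scale)):
        if arr is not None and len(arr) != n:
            raise ValidationError(
                f"{name} length {len(arr)} does not match block length {n}"
            )
    dt = 1.0 / fs
    rng = np.random.default_rng(params.seed)

    drift = (
        _ou_path(rng, n, dt, params.drift_sd, params.drift_tau_s)
        if params.drift_sd > 0
        else np.zeros(n)
    )
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    kappa_t = None
    if params.kappa > 0 and stim_phase is not None:
        kappa_t = params.kappa * (
            coupling_scale if coupling_scale is not None else np.ones(n)
        )
    theta = _phase_path(
        rng, n, dt, params.f0 + drift, params.freq_jitter_sd,
        kappa_t, stim_phase, theta0,
    )
    envelope = np.abs(
        params.env_mean + _ou_path(rng, n, dt, params.env_sd, params.env_tau_s)
    )
    acc = envelope * np.cos(theta)
    axis = np.asarray(params.axis_vector)
    samples = axis[:, None] * acc[None, :]
    samples = samples + params.noise_sd * rng.standard_normal((3, n))

    names = ["acc_x", "acc_y", "acc_z"]
    if stim is not None:
        samples = np.vstack([samples, np.asarray(stim, dtype=float)])
        names.append(stim_channel_name)
    return Recording(
        samples=samples,
        fs=fs,
        channel_names=names,
        block_id=block_id,
        condition=condition,
        stim_freq=stim_freq,
    )


@dataclasses.dataclass
class SubjectParams:
    """Everything needed to simulate one subject's full experiment."""

    subject_id: str = "S01"
    tremor: TremorModelParams = dataclasses.field(default_factory=TremorModelParams)
    kappa_by_condition: Mapping[Condition, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_KAPPA_BY_CONDITION)
    )
    block_s: float = 180.0
    initial_s: float = 360.0
    fs: float = 2048.0
    peak_to_peak_uA: float = 2000.0
    ramp_s: float = 10.0
    photic_duty: float = 0.05
    seed: int = 0


def draw_subject(
    subject_id: str,
    seed: int,
    rng: np.random.Generator | None = None,
    **overrides,
) -> SubjectParams:
    """Draw subject parameters from the group distribution.

    The tremor base frequency is Normal(8.28, 1.52^2) Hz truncated to
    [4, 14] (SD reconstructed from the reported group SEM at N = 12).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    f0 = float(rng.normal(GROUP_MEAN_F0, GROUP_SD_F0))
    while not 4.0 <= f0 <= 14.0:
        f0 = float(rng.normal(GROUP_MEAN_F0, GROUP_SD_F0))
    tremor = dataclasses.replace(
        overrides.pop("tremor", TremorModelParams()), f0=f0, seed=seed
    )
    return SubjectParams(
        subject_id=subject_id, tremor=tremor, seed=seed, **overrides
    )


def _block_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed) % (2**31), index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_experiment(
    subject: SubjectParams, design: BlockDesign
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a subject's full protocol with known ground truth.

    Returns the initial 360 s stimulation-free recording followed by the 12
    condition blocks of ``design``, plus a ground-truth table recording the
    coupling gain, base frequency and per-block seed actually used.
    """
    design.validate(full_protocol=True)
    fs, n = subject.fs, int(round(subject.block_s * subject.fs))
    t = np.arange(n) / fs
    recordings: list[Recording] = []
    truth_rows = []

    def record(rec: Recording, kappa: float) -> None:
        recordings.append(rec)
        truth_rows.append(
            {
                "subject_id": subject.subject_id,
                "block_id": rec.block_id,
                "condition": rec.condition.value,
                "f0": subject.tremor.f0,
                "stim_freq": rec.stim_freq,
                "kappa": kappa,
                "seed": rec_params.seed,
            }
        )

    # Initial stimulation-free recording (twice the block length).
    rec_params = dataclasses.replace(
        subject.tremor, kappa=0.0, seed=_block_seed(subject.seed, 0)
    )
    record(
        simulate_tremor_block(
            rec_params, subject.initial_s, fs,
            condition=Condition.INITIAL, block_id="initial",
        ),
        0.0,
    )

    for i, (block_id, condition, stim_freq) in enumerate(design.blocks, start=1):
        kappa = float(subject.kappa_by_condition.get(condition, 0.0))
        rec_params = dataclasses.replace(
            subject.tremor, kappa=kappa, seed=_block_seed(subject.seed, i)
        )
        if condition in STIM_CONDITIONS or condition is Condition.SHAM:
            spec = StimWaveformSpec(
                freq=stim_freq,
                peak_to_peak=subject.peak_to_peak_uA,
                ramp_s=subject.ramp_s,
                sham=condition is Condition.SHAM,
                duration_s=subject.block_s,
                fs=fs,
            )
            stim = simulate_stim_waveform(spec)
            scale = ramp_envelope(t, spec.ramp_s, spec.sham)
            channel = "stim"
        elif condition is Condition.PHOTIC:
            stim = simulate_photic_train(
                stim_freq, subject.block_s, fs, duty=subject.photic_duty
            )
            scale = np.ones(n)
            channel = "photic"
        else:  # pragma: no cover - design validation excludes this
            raise ValidationError(f"unexpected condition {condition}")
        record(
            simulate_tremor_block(
                rec_params, subject.block_s, fs,
                stim=stim,
                stim_phase=2.0 * np.pi * stim_freq * t,
                coupling_scale=scale,
                stim_channel_name=channel,
                condition=condition,
                block_id=block_id,
                stim_freq=stim_freq,
            ),
            kappa,
        )
    return recordings, pd.DataFrame(truth_rows)
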