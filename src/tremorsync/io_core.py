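"""Recording containers, disk round-trip and pipeline configuration.

A tremor experiment is a set of fixed-length condition blocks. Each block is
held in a :class:`Recording`: a channels-by-samples matrix (tri-axial
accelerometer plus, where applicable, the recorded stimulation or photic
reference waveform), the sampling rate, and block metadata. On disk a
Recording is a headered CSV (column 1 is time in seconds, one column per
channel, '.' decimal, LF line endings) next to a JSON sidecar carrying the
metadata — deliberately language-neutral and diff-able.

:class:`PipelineConfig` collects every tunable of the analysis chain with
the defaults used throughout; :func:`load_config` reads a YAML/JSON file and
rejects unknown keys so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tremorsync")

__all__ = [
    "Condition",
    "STIM_CONDITIONS",
    "Recording",
    "BlockDesign",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "load_config",
    "ValidationError",
    "FormatError",
    "ConfigError",
    "DegenerateInputError",
    "SolverError",
]


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """On-disk data is malformed or incomplete."""


class ConfigError(ValueError):
    """Configuration file contains unknown keys or malformed values."""


class DegenerateInputError(ValueError):
    """Input is formally valid but carries no usable information."""


class SolverError(RuntimeError):
    """Iterative solver failed to reach the requested tolerance."""


class Condition(str, enum.Enum):
    """Experimental block condition.

    Four tACS montages named after the return-electrode position (the
    stimulating electrode is fixed over left M1), plus sham, photic
    stimulation, and the stimulation-free initial recording used to
    determine the peak tremor frequency.
    """

    FO = "FO"
    CM1 = "cM1"
    LSH = "LSh"
    RSH = "RSh"
    SHAM = "sham"
    PHOTIC = "photic"
    INITIAL = "initial"


#: Conditions in which current is delivered through scalp electrodes.
STIM_CONDITIONS = (Condition.FO, Condition.CM1, Condition.LSH, Condition.RSH)

#: The six conditions of one experimental cycle.
CYCLE_CONDITIONS = STIM_CONDITIONS + (Condition.SHAM, Condition.PHOTIC)


@dataclasses.dataclass
class Recording:
    """One condition block of multi-channel time series data.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Channel data; accelerometer channels in arbitrary acceleration
        units, stimulation channel in microamperes.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per row of ``samples``; accelerometer channels are
        conventionally ``acc_x/acc_y/acc_z`` and the reference waveform
        ``stim`` or ``photic``.
    block_id : str
        Unique identifier of the block within its experiment.
    condition : Condition
        Experimental condition of the block.
    stim_freq : float or None
        Stimulation frequency in Hz (None for the initial recording).
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    block_id: str = "block0"
    condition: Condition = Condition.INITIAL
    stim_freq: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if isinstance(self.condition, str):
            try:
                self.condition = Condition(self.condition)
            except ValueError as exc:
                raise ValidationError(
                    f"unknown condition {self.condition!r}"
                ) from exc
        self.channel_names = list(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 2 or 0 in self.samples.shape:
            raise ValidationError("samples must be a non-empty 2-D matrix")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if self.stim_freq is not None and not self.stim_freq > 0:
            raise ValidationError(f"stim_freq must be positive, got {self.stim_freq}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name (a view, not a copy)."""
        try:
            return self.samples[self.channel_names.index(name)]
        except ValueError as exc:
            raise KeyError(f"no channel named {name!r}") from exc

    def accel_channels(self) -> list[str]:
        """Names of the accelerometer channels (prefix ``acc``)."""
        return [c for c in self.channel_names if c.startswith("acc")]


def _csv_and_sidecar(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    csv = p if p.suffix == ".csv" else p.with_suffix(".csv")
    return csv, csv.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as headered CSV plus a JSON metadata sidecar.

    The CSV uses '%.17g' formatting so that float64 values survive the
    round-trip bit-exactly; :func:`read_recording` inverts this writer.
    """
    rec.validate()
    csv_path, sidecar = _csv_and_sidecar(path)
    cols = np.column_stack([rec.time] + [ch for ch in rec.samples])
    header = ",".join(["time_s"] + rec.channel_names)
    np.savetxt(
        csv_path, cols, delimiter=",", header=header, comments="",
        fmt="%.17g", newline="\n",
    )
    meta = {
        "fs": rec.fs,
        "block_id": rec.block_id,
        "condition": rec.condition.value,
        "stim_freq": rec.stim_freq,
        "channel_names": rec.channel_names,
        "duration_s": rec.duration_s,
        "n_samples": rec.n_samples,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def read_recording(path: str | Path) -> Recording:
    """Read a Recording written by :func:`write_recording`."""
    csv_path, sidecar = _csv_and_sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    if not csv_path.exists():
        raise FormatError(f"missing samples file {csv_path}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    fs = float(meta["fs"])
    if fs <= 0:
        raise ValidationError(f"sidecar fs must be positive, got {fs}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise FormatError("first CSV column must be time_s")
    names = list(df.columns[1:])
    if names != list(meta.get("channel_names", names)):
        raise FormatError("CSV channel columns disagree with sidecar")
    data = df[names].to_numpy()
    if data.dtype.kind not in "fiu":
        raise FormatError("non-numeric cell in samples file")
    expected = int(round(float(meta.get("duration_s", len(df) / fs)) * fs))
    if expected != len(df):
        raise ValidationError(
            f"sample count {len(df)} inconsistent with duration x fs = {expected}"
        )
    return Recording(
        samples=data.T,
        fs=fs,
        channel_names=names,
        block_id=str(meta.get("block_id", csv_path.stem)),
        condition=meta.get("condition", "initial"),
        stim_freq=meta.get("stim_freq"),
    )


@dataclasses.dataclass
class BlockDesign:
    """Ordered manifest of the experimental blocks of one subject.

    ``blocks`` is an ordered list of ``(block_id, condition, stim_freq_Hz)``.
    The full protocol is two cycles of six randomly interleaved conditions
    (four tACS montages, sham, photic), i.e. exactly 12 blocks, all sharing
    one subject-specific stimulation frequency.
    """

    subject_id: str
    blocks: list[tuple[str, Condition, float | None]]
    rest_s: float = 30.0

    def __post_init__(self) -> None:
        self.blocks = [
            (str(b), Condition(c), None if f is None else float(f))
            for b, c, f in self.blocks
        ]

    def validate(self, full_protocol: bool = False) -> None:
        ids = [b for b, _, _ in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate block_ids in design")
        freqs = {f for _, c, f in self.blocks if f is not None}
        if len(freqs) > 1:
            raise ValidationError(
                f"stim_freq must be identical across blocks, got {sorted(freqs)}"
            )
        if full_protocol:
            if len(self.blocks) != 12:
                raise ValidationError(
                    f"full protocol requires 12 blocks, got {len(self.blocks)}"
                )
            counts = {c: 0 for c in CYCLE_CONDITIONS}
            for _, c, _ in self.blocks:
                if c not in counts:
                    raise ValidationError(f"{c} is not an experimental condition")
                counts[c] += 1
            if any(v != 2 for v in counts.values()):
                raise ValidationError(
                    "full protocol requires each condition exactly twice"
                )

    @property
    def stim_freq(self) -> float | None:
        for _, _, f in self.blocks:
            if f is not None:
                return f
        return None

    @classmethod
    def standard(
        cls, subject_id: str, stim_freq: float, rng: np.random.Generator
    ) -> "BlockDesign":
        """Two cycles of the six conditions, each cycle independently shuffled."""
        blocks: list[tuple[str, Condition, float | None]] = []
        for cycle in range(2):
            order = list(CYCLE_CONDITIONS)
            rng.shuffle(order)
            for cond in order:
                blocks.append(
                    (f"b{len(blocks):02d}_{cond.value}", cond, float(stim_freq))
                )
        design = cls(subject_id=subject_id, blocks=blocks)
        design.validate(full_protocol=True)
        return design

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": self.subject_id,
                    "block_id": b,
                    "condition": c.value,
                    "stim_freq": f,
                }
                for b, c, f in self.blocks
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rest_s: float = 30.0) -> "BlockDesign":
        subjects = df["subject_id"].unique()
        if len(subjects) != 1:
            raise ValidationError("design frame must describe exactly one subject")
        blocks = [
            (r.block_id, Condition(r.condition),
             None if pd.isna(r.stim_freq) else float(r.stim_freq))
            for r in df.itertuples()
        ]
        return cls(subject_id=str(subjects[0]), blocks=blocks, rest_s=rest_s)


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, with the package defaults.

    Attributes
    ----------
    passband_half_width : float
        Half-width of the tremor band-pass in Hz; the high-/low-pass
        cutoffs sit at peak ± half-width (2 Hz passband at the default 1.0).
    filter_order : int
        Order of each Butterworth section (default 3).
    n_tapers : int
        Number of DPSS tapers K for the multitaper spectrum (default 12);
        the time-bandwidth product is NW = (K+1)/2 unless overridden.
    n_bins : int
        Phase-difference histogram bins (default 20).
    profile_f_max, profile_step : float
        Phase-stability profile grid: 0..profile_f_max in profile_step
        increments (defaults 20.0 and 0.1 give 201 points).
    smoothing_width : float
        Total width in Hz of the profile smoothing kernel (default 1.0).
    smoothing_kernel : str
        ``gaussian`` (default; width read as FWHM) or ``boxcar``.
    edge_trim_s : float
        Seconds discarded at each end of the filtered block before
        phase/amplitude extraction (filter and Hilbert edge transients).
    peak_band : tuple
        Frequency band searched for the tremor spectral peak (Hz).
    peak_round : float
        Peak frequency is rounded to the nearest multiple of this (Hz).
    decimate_to : float or None
        If set, anti-alias decimate to this rate before analysis.
    exclude_ramp : bool
        If True, drop the first ``ramp_s`` seconds (stimulation ramp-up)
        from the analyzed segment in addition to the edge trim.
    ramp_s : float
        Nominal stimulation ramp duration in seconds.
    boxcox_shift : float
        Offset added to the envelope before the Box-Cox transform.
    boxcox_lambda_min/max/step : float
        Grid over which the Box-Cox exponent is profiled.
    stabilize_envelope : bool
        Apply the Box-Cox variance stabilization to the amplitude envelope.
    solver_tol : float
        Relative residual target of the current-density CG solve.
    solver_max_iter : int
        Iteration cap of the CG solve.
    seed : int
        Seed for every stochastic stage driven by this configuration.
    """

    passband_half_width: float = 1.0
    filter_order: int = 3
    n_tapers: int = 12
    n_bins: int = 20
    profile_f_max: float = 20.0
    profile_step: float = 0.1
    smoothing_width: float = 1.0
    smoothing_kernel: str = "gaussian"
    edge_trim_s: float = 2.0
    peak_band: tuple[float, float] = (4.0, 14.0)
    peak_round: float = 0.1
    decimate_to: float | None = None
    exclude_ramp: bool = False
    ramp_s: float = 10.0
    boxcox_shift: float = 0.0
    boxcox_lambda_min: float = -2.0
    boxcox_lambda_max: float = 2.0
    boxcox_lambda_step: float = 0.01
    stabilize_envelope: bool = True
    solver_tol: float = 1e-8
    solver_max_iter: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_band = tuple(float(v) for v in self.peak_band)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        positive = {
            "passband_half_width": self.passband_half_width,
            "profile_step": self.profile_step,
            "peak_round": self.peak_round,
            "boxcox_lambda_step": self.boxcox_lambda_step,
            "solver_tol": self.solver_tol,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ValidationError(f"{name} must be positive, got {val}")
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")
        if self.n_tapers < 1:
            raise ValidationError("n_tapers must be >= 1")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.profile_f_max <= 0:
            raise ValidationError("profile_f_max must be positive")
        if self.smoothing_width < 0:
            raise ValidationError("smoothing_width must be >= 0")
        if self.smoothing_kernel not in ("boxcar", "gaussian"):
            raise ValidationError(
                f"smoothing_kernel must be boxcar|gaussian, got {self.smoothing_kernel!r}"
            )
        if self.edge_trim_s < 0 or self.ramp_s < 0:
            raise ValidationError("edge_trim_s and ramp_s must be >= 0")
        lo, hi = self.peak_band
        if not 0 <= lo < hi:
            raise ValidationError(f"peak_band must satisfy 0 <= lo < hi, got {self.peak_band}")
        if self.decimate_to is not None and self.decimate_to <= 0:
            raise ValidationError("decimate_to must be positive when set")
        if self.boxcox_lambda_min >= self.boxcox_lambda_max:
            raise ValidationError("boxcox lambda grid is empty")
        if self.solver_max_iter < 1:
            raise ValidationError("solver_max_iter must be >= 1")

    @property
    def profile_freqs(self) -> np.ndarray:
        n = int(round(self.profile_f_max / self.profile_step)) + 1
        return np.round(np.arange(n) * self.profile_step, 10)

    def describe(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON configuration file; missing file fields keep defaults.

    Unknown keys raise :class:`ConfigError` so misspelled tunables cannot be
    silently ignored; out-of-range values raise :class:`ValidationError`.
    ``path=None`` returns the defaults.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
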