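"""Epoched MEG sensor-data simulation.

A trial is a sum of dipole-source contributions and one sensor-noise
realisation,

    m(t) = Σ_i  l_i q_i(t) + n(t),

with each source's moment timecourse q_i(t) a boxcar-gated white Gaussian
process: within the source's active window the samples are white with a
per-trial standard deviation drawn once per trial from
Normal(amplitude_mean, amplitude_sd) (truncated at zero), and zero outside
it.  Sensor noise is either white Gaussian (equal amplitude on every
channel, uncorrelated) or a phase-randomised surrogate of a user-supplied
multichannel record, which preserves the record's Fourier amplitude spectra
and cross-channel linear covariance while scrambling phases.

All randomness flows through :class:`numpy.random.SeedSequence` children of a
single seed, with the source and noise streams separated so that a noisy and
a noiseless simulation of the same seed share the source samples exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import h5py
import numpy as np
import scipy.signal

from .geometry import NAM, DipoleSource, HeadModel, SensorArray, lead_field

__all__ = [
    "Paradigm",
    "NoiseModel",
    "SensorDataset",
    "boxcar_timecourse",
    "iter_trials",
    "trial_streams",
    "simulate_dataset",
    "phase_randomized_surrogate",
    "bandpass",
    "bandpass_sos",
    "correlated_noise_record",
    "save_dataset",
    "load_dataset",
    "trial_to_tsv",
]

FT = 1e-15  # fT -> T


@dataclass(frozen=True)
class Paradigm:
    """Trial structure: which source is active when, and the sampling grid."""

    trial_length: float = 20.0  # s
    sampling_rate: float = 600.0  # Hz
    n_trials: int = 44
    active_windows: tuple[tuple[int, float, float], ...] = ((0, 0.0, 2.0), (1, 10.0, 12.0))

    def __post_init__(self) -> None:
        if self.trial_length <= 0 or self.sampling_rate <= 0 or self.n_trials < 1:
            raise ValueError("trial_length, sampling_rate and n_trials must be positive")
        n = self.trial_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_length × sampling_rate must be an integer sample count")
        wins = tuple((int(i), float(a), float(b)) for i, a, b in self.active_windows)
        for i, a, b in wins:
            if not (0.0 <= a < b <= self.trial_length):
                raise ValueError(f"active window ({a}, {b}) outside [0, trial_length]")
        for (i1, a1, b1) in wins:
            for (i2, a2, b2) in wins:
                if i1 < i2 and a1 < b2 and a2 < b1:
                    raise ValueError("active windows of distinct sources must not overlap")
        object.__setattr__(self, "active_windows", wins)

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.sampling_rate))

    def window_of(self, source_index: int) -> tuple[float, float]:
        for i, a, b in self.active_windows:
            if i == source_index:
                return a, b
        raise ValueError(f"source {source_index} has no active window in the paradigm")

    def sample_slice(self, start: float, end: float) -> slice:
        fs = self.sampling_rate
        return slice(int(round(start * fs)), int(round(end * fs)))


@dataclass(frozen=True)
class NoiseModel:
    """Sensor-noise description.

    ``gaussian_amplitude`` is the per-sample, per-channel standard deviation
    in fT.  For ``kind="surrogate"``, ``surrogate_record`` is a (channels,
    samples) array in tesla; each trial receives an independent
    phase-randomised surrogate of it.  ``kind="none"`` yields silence.
    """

    kind: str = "gaussian"  # "gaussian" | "surrogate" | "none"
    gaussian_amplitude: float = 21.0  # fT
    surrogate_record: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "surrogate", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian" and self.gaussian_amplitude <= 0:
            raise ValueError("gaussian_amplitude must be positive")
        if self.kind == "surrogate" and self.surrogate_record is None:
            raise ValueError("surrogate noise requires a surrogate_record")

    def per_sample_variance(self) -> float:
        """Mean per-channel noise variance in T² (the υ² of the pseudo-z)."""
        if self.kind == "gaussian":
            return (self.gaussian_amplitude * FT) ** 2
        if self.kind == "surrogate":
            return float(np.mean(np.var(self.surrogate_record, axis=1)))
        return 0.0


@dataclass
class SensorDataset:
    """Epoched multichannel data: (trials, channels, samples) in tesla."""

    data: np.ndarray
    paradigm: Paradigm
    sensors: SensorArray

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if d.shape[2] != self.paradigm.n_samples:
            raise ValueError(
                f"sample count {d.shape[2]} does not equal trial_length × sampling_rate "
                f"= {self.paradigm.n_samples}"
            )
        if d.shape[1] != self.sensors.n_channels:
            raise ValueError("channel count mismatch between data and sensor array")
        if not np.all(np.isfinite(d)):
            raise ValueError("dataset contains non-finite values")
        self.data = d

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def boxcar_timecourse(
    paradigm: Paradigm,
    source_index: int,
    amplitude_mean: float,
    amplitude_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trial's dipole moment timecourse (nAm) for one source.

    Zero outside the source's active window; white Gaussian inside, scaled by
    a per-trial strength drawn from Normal(amplitude_mean, amplitude_sd)
    truncated at zero.
    """
    if amplitude_sd < 0:
        raise ValueError("amplitude_sd must be non-negative")
    a, b = paradigm.window_of(source_index)
    sl = paradigm.sample_slice(a, b)
    q = np.zeros(paradigm.n_samples)
    sigma = max(rng.normal(amplitude_mean, amplitude_sd) if amplitude_sd > 0 else amplitude_mean, 0.0)
    q[sl] = sigma * rng.standard_normal(sl.stop - sl.start)
    return q


def trial_streams(seed) -> tuple[np.random.Generator, np.random.Generator]:
    """The (source, noise) random streams a given seed unfolds into.

    Exposed so callers can reproduce either component of a simulation
    independently (e.g. regenerate the exact noise realisation of a run).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    src_ss, noise_ss = ss.spawn(2)
    return np.random.default_rng(src_ss), np.random.default_rng(noise_ss)


def _noise_trial(
    noise: NoiseModel, n_channels: int, n_samples: int, rng: np.random.Generator, dtype
) -> np.ndarray:
    if noise.kind == "none":
        return np.zeros((n_channels, n_samples), dtype=dtype)
    if noise.kind == "gaussian":
        x = rng.standard_normal((n_channels, n_samples), dtype=dtype)
        x *= dtype(noise.gaussian_amplitude * FT)
        return x
    record = np.asarray(noise.surrogate_record)
    if record.shape[0] != n_channels:
        raise ValueError(
            f"surrogate record has {record.shape[0]} channels, sensors have {n_channels}"
        )
    return phase_randomized_surrogate(record, n_samples, rng).astype(dtype, copy=False)


def iter_trials(
    sources: Sequence[DipoleSource],
    paradigm: Paradigm,
    head: HeadModel,
    sensors: SensorArray,
    noise: NoiseModel,
    seed,
    dtype=np.float64,
) -> Iterator[np.ndarray]:
    """Yield trial arrays (channels, samples) in tesla, one at a time.

    This is the single source of truth for the simulation's sample stream:
    materialising a dataset and streaming covariance accumulation both
    consume it, so they are draw-for-draw identical for a given seed.
    """
    dtype = np.dtype(dtype).type
    lf = [lead_field(s.position, s.orientation, head, sensors).astype(dtype) for s in sources]
    src_rng, noise_rng = trial_streams(seed)
    n_ch, n_s = sensors.n_channels, paradigm.n_samples
    for _ in range(paradigm.n_trials):
        x = _noise_trial(noise, n_ch, n_s, noise_rng, dtype)
        for i, s in enumerate(sources):
            a, b = paradigm.window_of(i)
            sl = paradigm.sample_slice(a, b)
            sigma = max(
                src_rng.normal(s.amplitude_mean, s.amplitude_sd)
                if s.amplitude_sd > 0
                else s.amplitude_mean,
                0.0,
            )
            q = src_rng.standard_normal(sl.stop - sl.start, dtype=dtype)
            q *= dtype(sigma * NAM)
            x[:, sl] += np.outer(lf[i], q)
        yield x


def simulate_dataset(
    sources: Sequence[DipoleSource],
    paradigm: Paradigm,
    head: HeadModel,
    sensors: SensorArray,
    noise: NoiseModel,
    seed=None,
    dtype=np.float64,
) -> SensorDataset:
    """Simulate a full epoched dataset (additive sources + noise)."""
    if seed is None:
        seed = noise.seed if noise.seed is not None else 0
    data = np.empty((paradigm.n_trials, sensors.n_channels, paradigm.n_samples), dtype=dtype)
    for t, x in enumerate(iter_trials(sources, paradigm, head, sensors, noise, seed, dtype)):
        data[t] = x
    return SensorDataset(data=data, paradigm=paradigm, sensors=sensors)


def phase_randomized_surrogate(
    record: np.ndarray, n_samples_out: int, rng: np.random.Generator
) -> np.ndarray:
    """Multivariate phase-randomised surrogate of a multichannel record.

    One random phase per frequency bin is applied to *all* channels, which
    preserves every channel's Fourier amplitude spectrum exactly and, because
    all cross-spectra are untouched, the cross-channel linear covariance.
    The DC and (for even lengths) Nyquist bins are left untouched to keep the
    output real.  The first ``n_samples_out`` samples are returned.
    """
    record = np.asarray(record, dtype=float)
    if record.ndim != 2 or record.shape[0] < 2:
        raise ValueError("record must be (channels >= 2, samples)")
    n = record.shape[1]
    if n < n_samples_out:
        raise ValueError(f"record length {n} is shorter than n_samples_out {n_samples_out}")
    if np.any(np.std(record, axis=1) == 0):
        raise ValueError("record contains a constant (zero-variance) channel")
    spec = np.fft.rfft(record, axis=1)
    n_bins = spec.shape[1]
    hi = n_bins - 1 if n % 2 == 0 else n_bins  # exclude Nyquist bin for even n
    phases = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=hi - 1))
    spec[:, 1:hi] *= phases[None, :]
    out = np.fft.irfft(spec, n=n, axis=1)
    return out[:, :n_samples_out]


def bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the default zero-phase band-pass prototype."""
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist {nyq}")
    return scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(obj, low: float, high: float, fs: float | None = None, order: int = 4):
    """Zero-phase band-pass (forward–backward Butterworth) along the time axis.

    Accepts a :class:`SensorDataset` (sampling rate taken from its paradigm)
    or a plain array whose last axis is time (``fs`` required).
    """
    if isinstance(obj, SensorDataset):
        sos = bandpass_sos(low, high, obj.paradigm.sampling_rate, order)
        out = scipy.signal.sosfiltfilt(sos, obj.data, axis=-1)
        return SensorDataset(data=out, paradigm=obj.paradigm, sensors=obj.sensors)
    if fs is None:
        raise ValueError("fs is required when filtering a plain array")
    sos = bandpass_sos(low, high, fs, order)
    return scipy.signal.sosfiltfilt(sos, np.asarray(obj), axis=-1)


def correlated_noise_record(
    n_channels: int = 10,
    n_samples: int = 60000,
    rng: np.random.Generator | None = None,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Spatially mixed AR(1) processes: a correlated multichannel test record.

    A stand-in for an environmental-interference recording: temporally
    coloured latent processes mixed across channels so that both the spectra
    and the cross-channel covariance are non-trivial.  ``amplitude`` sets the
    mean per-channel standard deviation (same units as the output).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rho = rng.uniform(0.5, 0.95, size=n_channels)
    innov = rng.standard_normal((n_channels, n_samples))
    latent = np.empty_like(innov)
    for i in range(n_channels):
        latent[i] = scipy.signal.lfilter([1.0], [1.0, -rho[i]], innov[i])
    mixing = rng.standard_normal((n_channels, n_channels)) / np.sqrt(n_channels)
    mixing += 0.5 * np.eye(n_channels)
    out = mixing @ latent
    out *= amplitude / np.mean(np.std(out, axis=1))
    return out


# --------------------------------------------------------------------------
# container I/O
# --------------------------------------------------------------------------


def save_dataset(dataset: SensorDataset, path, provenance: dict | None = None) -> None:
    """Write a dataset to the portable HDF5 layout (/data, /fs, JSON attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("fs", data=dataset.paradigm.sampling_rate)
        f.attrs["paradigm"] = json.dumps(
            {
                "trial_length": dataset.paradigm.trial_length,
                "sampling_rate": dataset.paradigm.sampling_rate,
                "n_trials": dataset.paradigm.n_trials,
                "active_windows": dataset.paradigm.active_windows,
            }
        )
        f.attrs["sensors"] = dataset.sensors.to_json()
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def trial_to_tsv(dataset: SensorDataset, trial: int, path) -> None:
    """Dump one trial as TSV (first column time in s, one column per channel)."""
    if not 0 <= trial < dataset.n_trials:
        raise ValueError(f"trial {trial} out of range (0..{dataset.n_trials - 1})")
    fs = dataset.paradigm.sampling_rate
    t = np.arange(dataset.paradigm.n_samples) / fs
    header = "time_s\t" + "\t".join(dataset.sensors.names)
    np.savetxt(path, np.column_stack([t, dataset.data[trial].T]),
               delimiter="\t", header=header, comments="")


def load_dataset(path) -> SensorDataset:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        p = json.loads(f.attrs["paradigm"])
        paradigm = Paradigm(
            trial_length=p["trial_length"],
            sampling_rate=p["sampling_rate"],
            n_trials=p["n_trials"],
            active_windows=tuple(tuple(w) for w in p["active_windows"]),
        )
        sensors = SensorArray.from_json(f.attrs["sensors"])
    return SensorDataset(data=data, paradigm=paradigm, sensors=sensors)
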