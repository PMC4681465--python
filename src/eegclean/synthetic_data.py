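"""Ground-truth contamination scenarios: clean EEG plus ocular or cardiac
artifacts mixed through a nonlinear pathway.

Real contaminated recordings never come with the artifact-free EEG, so
method evaluation needs simulated data where the clean signal, the
reference artifact channel and the artifact's true contribution to the
EEG channel are all known.  The generators here emulate short scalp
recordings: an alpha-dominant EEG background with 1/f noise, a blink
(EOG) channel of sparse raised-cosine pulses, and a QRS-like cardiac
(ECG) pulse train.  The contamination pathway is a saturating
nonlinearity followed by a short FIR smoothing kernel — the simplest
mixing model a purely linear cancellation filter cannot represent — and
also admits the purely linear case for controlled recovery experiments.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .signal_model import TimeSeries

__all__ = [
    "PathwaySpec",
    "ContaminationScenario",
    "gen_clean_eeg",
    "gen_eog",
    "gen_ecg",
    "contaminate",
    "default_scenario",
    "linear_scenario",
]

#: Default sampling rate (Hz) and epoch length (s) for generated recordings.
DEFAULT_FS_HZ = 256.0
DEFAULT_DURATION_S = 10.0

#: Clean-EEG band mix: (low Hz, high Hz, relative RMS amplitude).
EEG_BANDS = {
    "theta": (4.0, 8.0, 0.5),
    "alpha": (8.0, 13.0, 1.0),
    "beta": (13.0, 30.0, 0.3),
}
#: Relative RMS of the 1/f-shaped broadband noise floor.
EEG_PINK_LEVEL = 0.4
#: Overall clean-EEG RMS in signal units (think microvolts).
EEG_RMS = 10.0


@dataclass(frozen=True)
class PathwaySpec:
    """Parameters of the artifact-to-EEG mixing pathway.

    The artifact reaches the EEG electrode as ``FIR(g(gain * a))`` where
    ``g`` is a saturating nonlinearity.  ``nonlinearity="tanh"`` uses the
    scaled form ``saturation * tanh(x / saturation)`` so the saturation
    level is expressed in signal units; ``"identity"`` gives the purely
    linear pathway.  ``fir_taps`` is a short smoothing kernel (its L1 norm
    bounds the contribution when the nonlinearity saturates).
    """

    gain: float = 0.8
    nonlinearity: str = "tanh"
    saturation: float = 50.0
    fir_taps: tuple[float, ...] = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        if self.nonlinearity not in ("tanh", "identity"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.nonlinearity == "tanh" and not (self.saturation > 0):
            raise ValueError("saturation must be positive")
        if len(self.fir_taps) < 1:
            raise ValueError("fir_taps must have at least one tap")
        object.__setattr__(self, "fir_taps", tuple(float(t) for t in self.fir_taps))

    @classmethod
    def linear(cls, gain: float = 1.0, fir_taps: tuple[float, ...] = (1.0,)) -> "PathwaySpec":
        return cls(gain=gain, nonlinearity="identity", fir_taps=fir_taps)


@dataclass(frozen=True)
class ContaminationScenario:
    """Synthetic ground truth for one contaminated recording.

    Invariant: ``contaminated == clean_eeg + true_contribution`` exactly
    (bit-exact, enforced at construction), and all four series share
    length and sampling rate.
    """

    clean_eeg: TimeSeries
    reference_artifact: TimeSeries
    true_contribution: TimeSeries
    contaminated: TimeSeries
    pathway_spec: PathwaySpec
    seed: int = 0
    description: str = field(default="")

    def __post_init__(self) -> None:
        series = (self.clean_eeg, self.reference_artifact,
                  self.true_contribution, self.contaminated)
        n = {len(s) for s in series}
        fs = {s.sampling_rate_hz for s in series}
        if len(n) != 1 or len(fs) != 1:
            raise ValueError("all scenario series must share length and sampling rate")
        if not np.array_equal(self.contaminated.samples,
                              self.clean_eeg.samples + self.true_contribution.samples):
            raise ValueError("contaminated must equal clean_eeg + true_contribution exactly")


def _n_samples(duration_s: float, fs_hz: float) -> int:
    n = int(round(duration_s * fs_hz))
    if n < 1:
        raise ValueError("duration too short for the given sampling rate")
    return n


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [f_lo, f_hi] via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-shaped noise (flat below 1 Hz to keep variance finite)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= shaping
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_clean_eeg(duration_s: float = DEFAULT_DURATION_S, fs_hz: float = DEFAULT_FS_HZ,
                  seed: int = 0, rms: float = EEG_RMS) -> TimeSeries:
    """Generate artifact-free EEG background.

    Sum of band-limited oscillatory components (alpha dominant, plus
    theta and beta at the relative amplitudes in :data:`EEG_BANDS`) and a
    1/f-shaped noise floor, scaled to overall RMS ``rms`` and mean-centred.
    Deterministic per ``seed``.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    if fs_hz < 64:
        raise ValueError("fs_hz must be at least 64 Hz to represent the beta band")
    n = _n_samples(duration_s, fs_hz)
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for f_lo, f_hi, amp in EEG_BANDS.values():
        x += amp * _bandpass_noise(rng, n, fs_hz, f_lo, f_hi)
    x += EEG_PINK_LEVEL * _pink_noise(rng, n, fs_hz)
    x -= np.mean(x)
    x *= rms / np.sqrt(np.mean(x**2))
    return TimeSeries(x, fs_hz, label="EEG")


def gen_eog(duration_s: float = DEFAULT_DURATION_S, fs_hz: float = DEFAULT_FS_HZ,
            blink_rate_hz: float = 1.0, seed: int = 0,
            blink_width_s: float = 0.3, blink_amplitude: float = 5.0 * EEG_RMS,
            drift_amplitude: float = 0.2 * EEG_RMS) -> TimeSeries:
    """Generate an EOG reference channel: sparse blinks on a slow drift.

    Blinks are raised-cosine pulses (default width 300 ms) at
    Poisson-process times, with high amplitude relative to the EEG
    background (default 5x the clean-EEG RMS) — blinks are low-frequency,
    high-amplitude events.  ``blink_rate_hz=0`` yields the drift-only
    channel.  Deterministic per ``seed``.
    """
    if not (0 <= blink_rate_hz < 2):
        raise ValueError("blink_rate_hz must be in [0, 2)")
    if blink_rate_hz > 0 and blink_width_s >= 1.0 / blink_rate_hz:
        raise ValueError("blink pulse width must be below the mean inter-blink interval")
    n = _n_samples(duration_s, fs_hz)
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    # Poisson process: exponential inter-arrival times.
    if blink_rate_hz > 0:
        t = rng.exponential(1.0 / blink_rate_hz)
        width_n = max(int(round(blink_width_s * fs_hz)), 3)
        pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width_n) / (width_n - 1)))
        while t < duration_s:
            k0 = int(round(t * fs_hz))
            k1 = min(k0 + width_n, n)
            if k0 < n:
                amp = blink_amplitude * (1.0 + 0.15 * rng.standard_normal())
                x[k0:k1] += amp * pulse[: k1 - k0]
            t += rng.exponential(1.0 / blink_rate_hz)
    # Slow baseline drift below 0.5 Hz.
    if drift_amplitude > 0:
        x += drift_amplitude * _bandpass_noise(rng, n, fs_hz, 0.0, 0.5)
    return TimeSeries(x, fs_hz, label="EOG")


def _qrs_template(fs_hz: float, width_s: float = 0.08) -> np.ndarray:
    """Narrow biphasic QRS-like pulse (Mexican-hat shape), unit peak."""
    width_n = max(int(round(width_s * fs_hz)), 5)
    t = np.linspace(-3.0, 3.0, width_n)
    tpl = (1.0 - t**2) * np.exp(-0.5 * t**2)
    return tpl / np.max(np.abs(tpl))


def gen_ecg(duration_s: float = DEFAULT_DURATION_S, fs_hz: float = DEFAULT_FS_HZ,
            heart_rate_bpm: float = 72.0, seed: int = 0,
            amplitude: float = 4.0 * EEG_RMS, interval_jitter: float = 0.05) -> TimeSeries:
    """Generate an ECG reference channel: jittered QRS pulse train.

    Beat intervals are ``60 / heart_rate_bpm`` seconds with Gaussian
    multiplicative jitter (default 5% sd).  Deterministic per ``seed``.
    """
    if not (30 <= heart_rate_bpm <= 200):
        raise ValueError("heart_rate_bpm must be in [30, 200]")
    if fs_hz < 64:
        raise ValueError("fs_hz too low to represent the QRS width")
    n = _n_samples(duration_s, fs_hz)
    rng = np.random.default_rng(seed)
    tpl = _qrs_template(fs_hz)
    x = np.zeros(n)
    mean_rr = 60.0 / heart_rate_bpm
    t = mean_rr * (0.5 + 0.5 * rng.random())  # random phase of the first beat
    while t < duration_s:
        k0 = int(round(t * fs_hz))
        k1 = min(k0 + tpl.size, n)
        if k0 < n:
            x[k0:k1] += amplitude * tpl[: k1 - k0]
        rr = mean_rr * (1.0 + interval_jitter * rng.standard_normal())
        t += max(rr, 0.2)  # refractory floor
    return TimeSeries(x, fs_hz, label="ECG")


def contaminate(clean: TimeSeries, artifact: TimeSeries,
                pathway: PathwaySpec | None = None, seed: int = 0,
                description: str = "") -> ContaminationScenario:
    """Mix an artifact channel into clean EEG through the pathway.

    ``true_contribution = FIR(g(gain * artifact))`` with ``g`` the
    pathway's nonlinearity; ``contaminated = clean + true_contribution``
    exactly.  The FIR is applied causally (zero initial state) so the
    contribution stays sample-aligned with the reference.
    """
    if pathway is None:
        pathway = PathwaySpec()
    if len(clean) != len(artifact) or clean.sampling_rate_hz != artifact.sampling_rate_hz:
        raise ValueError("clean and artifact must share length and sampling rate")
    a = pathway.gain * artifact.samples
    if pathway.nonlinearity == "tanh":
        g = pathway.saturation * np.tanh(a / pathway.saturation)
    else:
        g = a
    taps = np.asarray(pathway.fir_taps)
    contribution = np.convolve(g, taps)[: len(clean)]
    contaminated = clean.samples + contribution
    return ContaminationScenario(
        clean_eeg=clean,
        reference_artifact=artifact,
        true_contribution=TimeSeries(contribution, clean.sampling_rate_hz, "contribution"),
        contaminated=TimeSeries(contaminated, clean.sampling_rate_hz, "contaminated"),
        pathway_spec=pathway,
        seed=seed,
        description=description,
    )


def default_scenario(seed: int = 0, duration_s: float = DEFAULT_DURATION_S,
                     fs_hz: float = DEFAULT_FS_HZ, artifact: str = "eog") -> ContaminationScenario:
    """The default nonlinear blink (or heartbeat) contamination scenario."""
    clean = gen_clean_eeg(duration_s, fs_hz, seed=seed)
    if artifact == "eog":
        ref = gen_eog(duration_s, fs_hz, seed=seed + 1)
    elif artifact == "ecg":
        ref = gen_ecg(duration_s, fs_hz, seed=seed + 1)
    else:
        raise ValueError(f"unknown artifact type {artifact!r}")
    return contaminate(clean, ref, PathwaySpec(), seed=seed,
                       description=f"default nonlinear {artifact} scenario")


def linear_scenario(seed: int = 0, duration_s: float = DEFAULT_DURATION_S,
                    fs_hz: float = DEFAULT_FS_HZ, gain: float = 0.8,
                    delayed_gain: float = 0.3) -> ContaminationScenario:
    """Identity-nonlinearity scenario: contribution = gain*a(k) + delayed_gain*a(k-1).

    Used for controlled linear-recovery experiments where every filter
    should essentially reproduce the true contribution.
    """
    clean = gen_clean_eeg(duration_s, fs_hz, seed=seed)
    ref = gen_eog(duration_s, fs_hz, seed=seed + 1)
    pathway = PathwaySpec.linear(gain=1.0, fir_taps=(gain, delayed_gain))
    return contaminate(clean, ref, pathway, seed=seed,
                       description="linear blink scenario")


def write_scenario_csv(scenario: ContaminationScenario, csv_path, sidecar_json_path=None) -> None:
    """Write a scenario as CSV (time_s, clean, reference, contribution,
    contaminated) plus a sidecar JSON of pathway parameters and seed."""
    import pandas as pd

    df = pd.DataFrame({
        "time_s": scenario.clean_eeg.times_s,
        "clean": scenario.clean_eeg.samples,
        "reference": scenario.reference_artifact.samples,
        "contribution": scenario.true_contribution.samples,
        "contaminated": scenario.contaminated.samples,
    })
    df.to_csv(csv_path, index=False)
    if sidecar_json_path is not None:
        meta = {
            "sampling_rate_hz": scenario.clean_eeg.sampling_rate_hz,
            "seed": scenario.seed,
            "description": scenario.description,
            "pathway": asdict(scenario.pathway_spec),
        }
        with open(sidecar_json_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
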