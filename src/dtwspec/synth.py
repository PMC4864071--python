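"""Seeded generators of synthetic EEG, trial tables and BOLD-style courses.

The generated recording emulates the layout of a block-design EEG session:
alternating task and rest blocks (default 5, ~1 min each at 50 Hz), a fixed
total number of trial markers (default 112) spaced evenly within blocks, and
a superposition of

* a piecewise-constant topographic (microstate) sequence with geometric
  dwell times over k orthogonal zero-mean maps,
* a band-limited alpha oscillation with slow phase drift, block-dependent
  amplitude and a fixed channel loading,
* 1/f-shaped background noise, and
* rare high-amplitude multi-channel transients (a shared latent spike times
  per-channel loadings) that the avalanche detector picks up.

Defaults are chosen so rest blocks carry stronger alpha but double the
background noise, i.e. the rest signal is the less predictable one, and so
the expected transient count per recording is near the trial count.  All
randomness flows from a single seed; identical seeds give identical output.
The generator makes no biophysical claim — no head model, no neural-mass
dynamics — it provides controllable structure for testing the measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MEASURE_NAMES, EEGRecording, TrialMeasures, TrialTable
from .glm import trial_regressor

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_eeg",
    "generate_dataset",
    "generate_microstate_recording",
    "generate_alpha_burst_segments",
    "generate_null_measures",
    "generate_bold",
]


@dataclass
class SynthConfig:
    n_subjects: int = 15
    n_channels: int = 32
    rate: float = 50.0
    n_blocks: int = 5  # alternating, starting with task
    block_seconds: float = 60.0
    n_trials: int = 112
    k_states: int = 4
    state_dwell_mean: float = 4.0  # samples (80 ms at 50 Hz)
    ms_amp: float = 0.3
    alpha_freq: float = 10.0
    alpha_amp_task: float = 1.0
    alpha_amp_rest: float = 1.2
    alpha_amp_cv: float = 0.4  # slow waxing/waning of alpha amplitude
    phase_drift_task: float = 0.02  # phase random-walk step SD, rad/sample
    phase_drift_rest: float = 0.7
    noise_sd: float = 0.3
    noise_scale_rest: float = 1.5
    event_rate: float = 0.37  # transients / second; ~n_trials over 5 blocks
    coupling: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_channels, self.n_blocks, self.n_trials, self.k_states) < 1:
            raise ValueError("all counts must be positive")
        if not (8.0 <= self.alpha_freq <= 13.0):
            raise ValueError("alpha_freq must lie in the 8-13 Hz band")
        if self.rate <= 0 or self.block_seconds <= 0:
            raise ValueError("rate and block_seconds must be positive")
        if self.noise_sd < 0 or self.event_rate < 0:
            raise ValueError("noise_sd and event_rate must be nonnegative")

    @property
    def samples_per_block(self) -> int:
        return int(round(self.block_seconds * self.rate))

    @property
    def n_samples(self) -> int:
        return self.n_blocks * self.samples_per_block

    def block_types(self) -> list[str]:
        return ["task" if b % 2 == 0 else "rest" for b in range(self.n_blocks)]


@dataclass
class GroundTruth:
    state_labels: np.ndarray  # per-sample planted microstate
    state_maps: np.ndarray  # k x channels
    event_samples: np.ndarray  # transient onset samples
    block_alpha_amp: np.ndarray  # per-block oscillation amplitude
    coupling: list[tuple[str, str, float]]


def _orthonormal_zero_mean_maps(k: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """k orthonormal rows in the average-reference (zero-sum) subspace."""
    if k >= n_channels:
        raise ValueError("need k < n_channels for orthogonal zero-mean maps")
    M = rng.standard_normal((k, n_channels))
    M -= M.mean(axis=1, keepdims=True)
    # Gram-Schmidt; the zero-sum subspace is closed under linear combination
    for i in range(k):
        for j in range(i):
            M[i] -= (M[i] @ M[j]) * M[j]
        M[i] /= np.linalg.norm(M[i])
    return M


def _state_sequence(
    n_samples: int, k: int, dwell_mean: float, rng: np.random.Generator
) -> np.ndarray:
    labels = np.empty(n_samples, dtype=int)
    t = 0
    state = int(rng.integers(k))
    p = min(1.0, 1.0 / dwell_mean)
    while t < n_samples:
        dwell = int(rng.geometric(p))
        labels[t : t + dwell] = state
        t += dwell
        if k > 1:
            state = (state + int(rng.integers(1, k))) % k
    return labels


def _pink_noise(shape: tuple[int, int], rate: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit SD per channel."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    spec = (rng.standard_normal((shape[0], freqs.size)) + 1j * rng.standard_normal((shape[0], freqs.size))) * scale
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _trial_positions(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Evenly spaced trial samples within blocks, margins clear of windows."""
    base, extra = divmod(cfg.n_trials, cfg.n_blocks)
    counts = [base + (1 if b < extra else 0) for b in range(cfg.n_blocks)]
    margin = int(2 * cfg.rate)  # room for the 1 s window + MLP lags
    samples, block_ids, block_types = [], [], []
    types = cfg.block_types()
    for b, cnt in enumerate(counts):
        start = b * cfg.samples_per_block + margin
        stop = (b + 1) * cfg.samples_per_block - margin
        pos = np.unique(np.linspace(start, stop, cnt).round().astype(int))
        samples.extend(pos.tolist())
        block_ids.extend([b] * len(pos))
        block_types.extend([types[b]] * len(pos))
    return np.array(samples), np.array(block_ids), block_types


def generate_eeg(cfg: SynthConfig, seed: int | None = None) -> tuple[EEGRecording, TrialTable, GroundTruth]:
    """One subject's recording, trial table and planted ground truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_ch, n_s = cfg.n_channels, cfg.n_samples
    t = np.arange(n_s) / cfg.rate

    # microstate component
    maps = _orthonormal_zero_mean_maps(cfg.k_states, n_ch, rng)
    labels = _state_sequence(n_s, cfg.k_states, cfg.state_dwell_mean, rng)
    envelope = 0.6 + 0.8 * np.abs(np.sin(2 * np.pi * cfg.alpha_freq * t + rng.uniform(0, 2 * np.pi)))
    ms = maps[labels].T * (cfg.ms_amp * envelope * np.sqrt(n_ch))[None, :]

    # alpha oscillation: phase-locked in task, wandering in rest, with
    # block-dependent amplitude — the designed predictability contrast
    types = cfg.block_types()
    block_amp = np.array(
        [cfg.alpha_amp_task if bt == "task" else cfg.alpha_amp_rest for bt in types]
    )
    amp_series = np.repeat(block_amp, cfg.samples_per_block)
    # alpha waxes and wanes on a seconds scale: lognormal slow modulation so
    # trial-to-trial band power (hence both spectral SD measures) varies
    if cfg.alpha_amp_cv > 0:
        slow = np.convolve(
            rng.standard_normal(n_s), np.ones(int(4 * cfg.rate)) / (4 * cfg.rate), mode="same"
        )
        slow /= slow.std() or 1.0
        amp_series = amp_series * np.exp(cfg.alpha_amp_cv * slow - cfg.alpha_amp_cv**2 / 2)
    drift_sd = np.repeat(
        [cfg.phase_drift_task if bt == "task" else cfg.phase_drift_rest for bt in types],
        cfg.samples_per_block,
    )
    phase = np.cumsum(rng.standard_normal(n_s) * drift_sd) + rng.uniform(0, 2 * np.pi)
    # channel 0 is the designated alpha-rich ("occipital") measurement channel
    loading = 0.3 + 0.4 * rng.uniform(0.0, 1.0, size=n_ch)
    loading[0] = 1.0
    alpha = loading[:, None] * (amp_series * np.sin(2 * np.pi * cfg.alpha_freq * t + phase))[None, :]

    # background noise, stronger in rest blocks
    noise_scale = np.where(
        np.repeat([bt == "rest" for bt in types], cfg.samples_per_block),
        cfg.noise_sd * cfg.noise_scale_rest,
        cfg.noise_sd,
    )
    noise = _pink_noise((n_ch, n_s), cfg.rate, rng) * noise_scale[None, :]

    # rare multi-channel transients: shared spike x per-channel loadings
    # transients propagate across channels: staggered per-channel onsets so a
    # burst occupies several consecutive bins of the avalanche detector
    n_events = rng.poisson(cfg.event_rate * n_s / cfg.rate)
    event_samples = np.sort(rng.choice(n_s - 16, size=n_events, replace=False)) if n_events else np.array([], dtype=int)
    transients = np.zeros((n_ch, n_s))
    sd_scale = np.sqrt(cfg.ms_amp**2 + amp_series.mean() ** 2 / 2 + cfg.noise_sd**2)
    for s in event_samples:
        spread = int(rng.integers(1, 11))  # samples over which the burst travels
        amp = rng.uniform(4.0, 5.5) * sd_scale
        load = rng.uniform(0.6, 1.0, size=n_ch) * rng.choice([-1.0, 1.0], size=n_ch)
        onsets = s + rng.integers(0, spread + 1, size=n_ch)
        for c in range(n_ch):
            o = int(onsets[c])
            transients[c, o] += amp * load[c]
            if o + 1 < n_s:
                transients[c, o + 1] += 0.4 * amp * load[c]

    data = ms + alpha + noise + transients
    rec = EEGRecording(
        data=data,
        rate=cfg.rate,
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        subject_id="s0",
    )
    samples, block_ids, block_types = _trial_positions(cfg)
    trials = TrialTable(trial_sample=samples, block_id=block_ids, block_type=block_types)
    truth = GroundTruth(
        state_labels=labels,
        state_maps=maps,
        event_samples=event_samples,
        block_alpha_amp=block_amp,
        coupling=list(cfg.coupling),
    )
    return rec, trials, truth


def generate_dataset(cfg: SynthConfig) -> list[tuple[EEGRecording, TrialTable, GroundTruth]]:
    """All subjects, each from an independent child seed of ``cfg.seed``."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    out = []
    for i, ss in enumerate(seeds):
        rec, trials, truth = generate_eeg(cfg, seed=np.random.default_rng(ss).integers(2**31))
        rec.subject_id = f"s{i}"
        out.append((rec, trials, truth))
    return out


def generate_microstate_recording(
    n_channels: int = 16,
    n_samples: int = 6000,
    k_states: int = 4,
    dwell_mean: float = 4.0,
    snr: float = 3.0,
    rate: float = 50.0,
    seed: int = 0,
) -> tuple[EEGRecording, np.ndarray, np.ndarray]:
    """Microstate-only fixture: (recording, planted labels, planted maps).

    Signal is the planted map sequence under an oscillatory amplitude
    envelope plus white channel noise at the requested map-to-noise SNR
    (amplitude ratio at envelope peak).
    """
    rng = np.random.default_rng(seed)
    maps = _orthonormal_zero_mean_maps(k_states, n_channels, rng)
    labels = _state_sequence(n_samples, k_states, dwell_mean, rng)
    t = np.arange(n_samples) / rate
    envelope = 0.4 + 0.6 * np.abs(np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)))
    signal = maps[labels].T * (envelope * np.sqrt(n_channels))[None, :]
    noise = rng.standard_normal((n_channels, n_samples)) / snr
    rec = EEGRecording(data=signal + noise, rate=rate, subject_id="ms-fixture")
    return rec, labels, maps


def generate_alpha_burst_segments(
    n_segments: int,
    n_samples: int = 50,
    rate: float = 50.0,
    band: tuple[float, float] = (8.0, 13.0),
    snr_db: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-trial-like segments: an alpha burst over a 1/f background.

    Each segment is a unit-amplitude sinusoid at a uniform random in-band
    frequency with random phase, plus pink noise scaled so the sine-to-noise
    power ratio equals ``snr_db``.  Returns (segments, true frequencies).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate
    noise_sd = float(np.sqrt(0.5 / 10 ** (snr_db / 10.0)))
    freqs = rng.uniform(band[0], band[1], size=n_segments)
    segs = np.empty((n_segments, n_samples))
    for i, f in enumerate(freqs):
        pn = _pink_noise((1, n_samples), rate, rng)[0]
        segs[i] = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) + noise_sd * pn
    return segs, freqs


def generate_null_measures(
    n_subjects: int,
    n_trials: int,
    seed: int = 0,
    coupling: list[tuple[str, str, float]] | None = None,
    noise_sd: float = 1.0,
) -> list[TrialMeasures]:
    """Independent standard-normal measure tables (exchangeable null).

    With ``coupling`` entries ``(target, predictor, beta)`` the target column
    becomes ``beta * predictor + noise_sd * N(0,1)`` — a planted linear effect
    for recovery tests.
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        cols = {name: rng.standard_normal(n_trials) for name in MEASURE_NAMES}
        for target, predictor, beta in coupling or []:
            if target not in cols or predictor not in cols:
                raise ValueError(f"unknown measure in coupling: {(target, predictor)}")
            cols[target] = beta * cols[predictor] + noise_sd * rng.standard_normal(n_trials)
        out.append(TrialMeasures(table=pd.DataFrame(cols), subject_id=f"s{s}"))
    return out


def generate_bold(
    measures: TrialMeasures,
    trials: TrialTable,
    n_samples: int,
    rate: float,
    tr: float = 2.0,
    coupling: list[tuple[str, str, float]] | None = None,
    noise_sd: float = 1.0,
    n_null_networks: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic network time courses (rows = TR frames, cols = networks).

    Each coupled network is a beta-weighted sum of HRF-convolved,
    TR-resampled trial-measure regressors plus white noise; extra pure-noise
    networks can be appended.  This stands in for data-driven network time
    courses (e.g. dual-regression outputs) which real pipelines would supply.
    """
    rng = np.random.default_rng(seed)
    frames = len(np.arange(0, n_samples, int(round(tr * rate))))
    courses: dict[str, np.ndarray] = {}
    for net, measure, beta in coupling or []:
        if measure not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {measure!r}")
        reg = trial_regressor(measures.table[measure].to_numpy(), trials, n_samples, rate, tr)
        sd = reg.std() or 1.0
        courses[net] = courses.get(net, np.zeros(frames)) + beta * reg / sd
    for name in courses:
        courses[name] = courses[name] + noise_sd * rng.standard_normal(frames)
    for j in range(n_null_networks):
        courses[f"null{j}"] = noise_sd * rng.standard_normal(frames)
    if not courses:
        raise ValueError("no networks requested: give coupling and/or n_null_networks")
    return pd.DataFrame(courses)
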