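"""Assembly of the six per-trial measures for one subject or a dataset.

Per trial the pipeline extracts, from the 1 s pre-trial window:

* ``dtw_sd``  — SD of the DTW spectrum (8-13 Hz sine bank) of one channel,
* ``dft_sd``  — SD of the matched direct DFT power spectrum,
* ``sse``     — one-step MLP prediction error summed over the window,
* ``ms_length`` / ``mean_gfp`` — length of and mean GFP over the microstate
  run containing the trial sample,
* ``ava_length`` — length (bins) of the cascade at or before the trial.

For a multi-subject dataset the microstate maps are clustered at the group
level: GFP-peak maps pooled across subjects, one k-means, then per-subject
back-fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .avalanches import AvalancheConfig, pretrial_cascade_length, select_threshold
from .dtw import DTWConfig
from .io import EEGRecording, TrialMeasures, TrialTable
from .microstates import (
    MicrostateConfig,
    cluster_maps,
    detect_gfp_peaks,
    fit_microstates,
    global_field_power,
    pretrial_measures,
)
from .predictor import MLPConfig, trial_sse
from .spectra import dft_spectrum, dtw_spectrum, make_templates

__all__ = ["spectral_sd_measures", "subject_measures", "dataset_measures"]


def spectral_sd_measures(
    eeg: EEGRecording,
    trials: TrialTable,
    channel: str | int,
    band: tuple[float, float, float] = (8.0, 13.0, 0.1),
    dtw_cfg: DTWConfig | None = None,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(dtw_sd, dft_sd) per trial from the pre-trial window of one channel."""
    dtw_cfg = dtw_cfg or DTWConfig()
    window = int(round(eeg.rate))
    f_lo, f_hi, step = band
    bank = make_templates(f_lo, f_hi, step, window, eeg.rate)
    signal = eeg.channel(channel)
    dtw_sd = np.zeros(len(trials))
    dft_sd = np.zeros(len(trials))
    for i, t in enumerate(trials.trial_sample):
        if t - window < 0:
            raise ValueError(f"trial at sample {t} lacks a full 1 s pre-trial window")
        seg = signal[t - window : t]
        dtw_sd[i] = dtw_spectrum(seg, bank, dtw_cfg, standardize=standardize).sd
        dft_sd[i] = dft_spectrum(seg, eeg.rate, bank.frequencies).sd
    return dtw_sd, dft_sd


def subject_measures(
    eeg: EEGRecording,
    trials: TrialTable,
    channel: str | int = 0,
    band: tuple[float, float, float] = (8.0, 13.0, 0.1),
    dtw_cfg: DTWConfig | None = None,
    mlp_cfg: MLPConfig | None = None,
    ms_cfg: MicrostateConfig | None = None,
    ava_cfg: AvalancheConfig | None = None,
    group_maps: np.ndarray | None = None,
) -> TrialMeasures:
    """All six measures for one subject.

    ``group_maps`` injects group-level microstate centroids; without them the
    subject's own GFP-peak maps are clustered.
    """
    trials.check_bounds(eeg.n_samples)
    ms_cfg = ms_cfg or MicrostateConfig()
    ava_cfg = ava_cfg or AvalancheConfig(target_count=len(trials))
    mlp_cfg = mlp_cfg or MLPConfig()

    dtw_sd, dft_sd = spectral_sd_measures(eeg, trials, channel, band, dtw_cfg)
    sse = trial_sse(eeg, trials, channel, mlp_cfg)
    model = fit_microstates(eeg, ms_cfg, group_maps=group_maps)
    ms_length, mean_gfp = pretrial_measures(model.labels, model.gfp, trials)
    _, avas = select_threshold(eeg, ava_cfg)
    ava_length = pretrial_cascade_length(avas, trials)

    table = pd.DataFrame(
        {
            "dtw_sd": dtw_sd,
            "dft_sd": dft_sd,
            "sse": sse,
            "ms_length": ms_length,
            "mean_gfp": mean_gfp,
            "ava_length": ava_length,
        }
    )
    return TrialMeasures(table=table, subject_id=eeg.subject_id)


def group_microstate_maps(
    recordings: list[EEGRecording],
    ms_cfg: MicrostateConfig,
    max_peak_maps: int = 20000,
) -> np.ndarray:
    """Group-level centroids: pool GFP-peak maps across subjects, one k-means.

    Pooled maps are subsampled (seeded) beyond ``max_peak_maps`` to bound the
    clustering cost.
    """
    pooled = []
    for rec in recordings:
        gfp = global_field_power(rec)
        peaks = detect_gfp_peaks(gfp)
        pooled.append(rec.data[:, peaks].T)
    X = np.concatenate(pooled)
    if len(X) > max_peak_maps:
        rng = np.random.default_rng(ms_cfg.seed)
        X = X[rng.choice(len(X), size=max_peak_maps, replace=False)]
    return cluster_maps(X, ms_cfg)


def dataset_measures(
    dataset: list[tuple[EEGRecording, TrialTable]],
    channel: str | int = 0,
    band: tuple[float, float, float] = (8.0, 13.0, 0.1),
    dtw_cfg: DTWConfig | None = None,
    mlp_cfg: MLPConfig | None = None,
    ms_cfg: MicrostateConfig | None = None,
    ava_cfg: AvalancheConfig | None = None,
) -> list[TrialMeasures]:
    """Six measures for every subject, with group-level microstate maps."""
    ms_cfg = ms_cfg or MicrostateConfig()
    maps = group_microstate_maps([rec for rec, _ in dataset], ms_cfg)
    out = []
    for i, (rec, trials) in enumerate(dataset):
        mlp = mlp_cfg or MLPConfig()
        mlp = MLPConfig(**{**mlp.__dict__, "seed": mlp.seed + 1000 * i})
        out.append(
            subject_measures(
                rec, trials, channel, band, dtw_cfg, mlp, ms_cfg, ava_cfg, group_maps=maps
            )
        )
    return out
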