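"""Synthetic preterm-EEG cohort generator.

The generator embodies the maturational structure the pipeline is built
to detect, with a planted, recoverable ground truth:

* *discontinuity*: burst timing is a renewal process with lognormal
  interburst intervals whose median shortens linearly from 12 s at an
  effective age of 25 weeks to 3 s at 38 weeks;
* *burst shape*: each burst's amplitude profile is a two-sided power
  kernel s(u) = (u/p)² rising / ((1−u)/(1−p))² decaying, whose
  asymmetry is exactly p − ½; the peak position p is set from a linear
  asymmetry-versus-age map (−0.35 at 25 wk to −0.05 at 38 wk), so
  bursts become more symmetric with maturation;
* *carrier*: band-limited (0.5–16 Hz) Gaussian noise, independent per
  electrode, amplitude-modulated by the shared burst envelope riding on
  a continuous ~7 µV interburst background plus a 2 µV amplifier noise
  floor — burst timing is common across channels (so envelope-coupling
  measures see structure) while phases are not.  The background keeps
  interburst activity above the 5 µV low-amplitude artifact floor, as
  in real discontinuous preterm EEG, which is why clean epochs survive
  artifact rejection;
* *outcome*: infants in the abnormal group mature with a fixed lag of
  the effective age behind PMA (mildly abnormal: half the lag), which
  is exactly the predicted-age-difference construct the evaluation
  module tests.

All randomness flows from one integer seed through numpy SeedSequence
substreams, so a cohort is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecording, write_edf

__all__ = ["CohortConfig", "simulate_recording", "simulate_cohort", "REFERENTIAL_CHANNELS"]

log = logging.getLogger(__name__)

REFERENTIAL_CHANNELS = ["Fp1", "Fp2", "C3", "C4", "Cz", "T3", "T4", "O1", "O2"]

AGE_ANCHORS_WK = (25.0, 38.0)
#: mean of |analytic signal| of unit-variance Gaussian noise (Rayleigh mean)
_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))


@dataclass
class CohortConfig:
    n_infants: int = 40
    ga_range_weeks: tuple[float, float] = (24.0, 28.0)
    recordings_per_infant: int = 3
    first_pma_weeks: float = 27.0
    recording_interval_weeks: float = 2.0
    epoch_minutes: float = 10.0
    recording_minutes: float | None = None  # None: recording = one epoch
    fs_hz: float = 256.0
    asymmetry_at_25wk: float = -0.35
    asymmetry_at_38wk: float = -0.05
    ibi_median_at_25wk_s: float = 12.0
    ibi_median_at_38wk_s: float = 3.0
    ibi_sigma_ln: float = 0.6
    burst_duration_median_s: float = 2.0
    burst_duration_sigma_ln: float = 0.5
    amplitude_scale_uv: float = 60.0
    amplitude_sigma_ln: float = 0.35
    background_uv: float = 7.0
    noise_floor_uv: float = 2.0
    outcome_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)  # normal/mild/abnormal
    abnormal_lag_weeks: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.outcome_mix) - 1.0) > 1e-9:
            raise ValueError("outcome_mix proportions must sum to 1")
        if self.ga_range_weeks[0] > self.ga_range_weeks[1]:
            raise ValueError("ga_range_weeks must be ordered")


def _interp_age(a: float, lo_val: float, hi_val: float) -> float:
    lo_wk, hi_wk = AGE_ANCHORS_WK
    a = np.clip(a, lo_wk, hi_wk)
    return lo_val + (a - lo_wk) / (hi_wk - lo_wk) * (hi_val - lo_val)


def _burst_kernel(n: int, peak_pos: float) -> np.ndarray:
    """Two-sided power burst profile with unit peak at fraction peak_pos.

    With quadratic rise/decay the shape's asymmetry (normalized first
    moment about the midpoint) is exactly peak_pos − 0.5.
    """
    u = np.linspace(0.0, 1.0, n)
    p = float(np.clip(peak_pos, 0.02, 0.98))
    shape = np.where(u < p, (u / p) ** 2, ((1.0 - u) / (1.0 - p)) ** 2)
    return shape


def _bandlimited_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to 0.5–16 Hz."""
    sos = sps.butter(4, (0.5, 16.0), "bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def simulate_recording(
    pma_weeks: float,
    effective_lag_weeks: float,
    cfg: CohortConfig,
    seed: int,
    subject_id: str = "sim",
    recording_id: str | None = None,
    ga_weeks: float | None = None,
    channels: list[str] | None = None,
) -> EEGRecording:
    """One referential multichannel recording at a given PMA and lag.

    The *effective age* ``pma_weeks − effective_lag_weeks`` drives every
    age-dependent parameter.
    """
    if not 24.0 <= pma_weeks <= 40.0:
        raise ValueError("pma_weeks must lie in [24, 40]")
    channels = channels if channels is not None else list(REFERENTIAL_CHANNELS)
    rng = np.random.default_rng(seed)
    fs = cfg.fs_hz
    minutes = cfg.recording_minutes if cfg.recording_minutes is not None else cfg.epoch_minutes
    n = int(round(minutes * 60.0 * fs))
    a = pma_weeks - effective_lag_weeks

    ibi_med = _interp_age(a, cfg.ibi_median_at_25wk_s, cfg.ibi_median_at_38wk_s)
    asym = _interp_age(a, cfg.asymmetry_at_25wk, cfg.asymmetry_at_38wk)
    peak_pos = asym + 0.5

    # shared burst envelope (µV): renewal process of asymmetric kernels
    env = np.zeros(n)
    t = rng.lognormal(np.log(ibi_med), cfg.ibi_sigma_ln) * fs
    while t < n:
        dur_s = rng.lognormal(np.log(cfg.burst_duration_median_s), cfg.burst_duration_sigma_ln)
        dur_s = float(np.clip(dur_s, 0.4, 16.0))
        dur_n = int(round(dur_s * fs))
        peak = rng.lognormal(np.log(cfg.amplitude_scale_uv), cfg.amplitude_sigma_ln)
        i0 = int(t)
        i1 = min(i0 + dur_n, n)
        if i1 - i0 > 4:
            env[i0:i1] += peak * _burst_kernel(i1 - i0, peak_pos)
        gap = rng.lognormal(np.log(ibi_med), cfg.ibi_sigma_ln)
        t = i0 + dur_n + gap * fs

    env_total = env + cfg.background_uv + cfg.noise_floor_uv

    # independent band-limited carriers, common envelope; the bipolar
    # difference of two unit carriers has variance 2, so scale by √2
    # to land derivations on the configured amplitude scale
    carriers = _bandlimited_noise(rng, len(channels), n, fs)
    signal = carriers * (env_total / (_RAYLEIGH_MEAN * np.sqrt(2.0)))

    return EEGRecording(
        subject_id=subject_id,
        pma_weeks=float(pma_weeks),
        ga_weeks=float(ga_weeks if ga_weeks is not None else min(pma_weeks, 28.0)),
        sample_rate_hz=fs,
        channel_labels=channels,
        signal=signal,
        montage_kind="referential",
        recording_id=recording_id or f"{subject_id}_r0",
    )


_GROUPS = ("normal", "mildly_abnormal", "abnormal")


def _lag_for_group(group: str, cfg: CohortConfig) -> float:
    return {"normal": 0.0, "mildly_abnormal": 0.5 * cfg.abnormal_lag_weeks,
            "abnormal": cfg.abnormal_lag_weeks}[group]


def cohort_truth(cfg: CohortConfig) -> pd.DataFrame:
    """Planted per-infant ground truth (group, lag, GA) for a config."""
    return _cohort_plan(cfg)[0]


def _cohort_plan(cfg: CohortConfig):
    """Deterministic cohort layout: truth table + per-recording schedule."""
    root = np.random.SeedSequence(cfg.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    rec_seeds = root.spawn(cfg.n_infants * cfg.recordings_per_infant)

    # outcome assignment: deterministic proportions, shuffled
    counts = np.floor(np.array(cfg.outcome_mix) * cfg.n_infants).astype(int)
    while counts.sum() < cfg.n_infants:
        counts[int(np.argmax(np.array(cfg.outcome_mix) * cfg.n_infants - counts))] += 1
    groups = np.repeat(_GROUPS, counts)
    cohort_rng.shuffle(groups)

    truth_rows, schedule = [], []
    k = 0
    for i in range(cfg.n_infants):
        sid = f"sub{i:03d}"
        ga = cohort_rng.uniform(*cfg.ga_range_weeks)
        group = str(groups[i])
        lag = _lag_for_group(group, cfg)
        first = max(ga + 0.7, cohort_rng.normal(cfg.first_pma_weeks, 0.8))
        truth_rows.append({"subject_id": sid, "group": group, "true_lag_weeks": lag,
                           "ga_weeks": ga})
        for j in range(cfg.recordings_per_infant):
            pma = first + j * cfg.recording_interval_weeks + cohort_rng.normal(0.0, 0.3)
            pma = float(np.clip(pma, max(24.0, ga + 0.2), 40.0))
            rid = f"{sid}_r{j}"
            schedule.append(dict(subject_id=sid, recording_id=rid, ga_weeks=ga,
                                 pma_weeks=pma, group=group, lag=lag,
                                 seed=rec_seeds[k]))
            k += 1
    return pd.DataFrame(truth_rows), schedule


def iter_cohort(cfg: CohortConfig):
    """Lazily yield ``(recording, meta_row)`` pairs for a cohort.

    Recordings are generated one at a time so cohorts with long
    recordings can be processed in bounded memory.
    """
    _, schedule = _cohort_plan(cfg)
    for item in schedule:
        rec = simulate_recording(
            item["pma_weeks"], item["lag"], cfg, seed=item["seed"],
            subject_id=item["subject_id"], recording_id=item["recording_id"],
            ga_weeks=item["ga_weeks"],
        )
        rec.outcome = item["group"]
        meta = {"file": f"{item['recording_id']}.edf", "subject_id": item["subject_id"],
                "ga_weeks": item["ga_weeks"], "pma_weeks": item["pma_weeks"],
                "outcome": item["group"]}
        yield rec, meta


def simulate_cohort(cfg: CohortConfig, out_dir: str | Path | None = None):
    """Generate a cohort of serial recordings with metadata and truth tables.

    Returns ``(recordings, metadata, truth)``: the in-memory referential
    recordings, the sidecar metadata table (file, subject_id, ga_weeks,
    pma_weeks, outcome) and the truth table of planted lags.  When
    ``out_dir`` is given, EDF files plus ``metadata.csv`` and
    ``truth.csv`` are also written there.  For cohorts too large to
    hold in memory, use :func:`iter_cohort` instead.
    """
    truth, _ = _cohort_plan(cfg)
    recordings, meta_rows = [], []
    for rec, meta in iter_cohort(cfg):
        recordings.append(rec)
        meta_rows.append(meta)

    metadata = pd.DataFrame(meta_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(recordings, meta_rows):
            write_edf(rec, out / row["file"])
        metadata.to_csv(out / "metadata.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return recordings, metadata, truth


def simulate_cohort_features(cfg: CohortConfig, epoch_s: float | None = None,
                             overlap: float = 0.0,
                             montage: str = "vienna_double_banana"):
    """Stream a cohort through preprocessing and feature extraction.

    Each recording is simulated, montaged, band-limited, segmented,
    artifact-checked and reduced to feature rows before the next one is
    generated, keeping memory bounded.  Returns ``(feature_table,
    truth)``.
    """
    from .features import build_feature_table
    from .io import apply_montage
    from .preprocess import bandlimit, reject_artifacts, segment

    if epoch_s is None:
        epoch_s = cfg.epoch_minutes * 60.0
    frames = []
    for rec, _meta in iter_cohort(cfg):
        rec = bandlimit(apply_montage(rec, montage))
        epochs = [reject_artifacts(ep) for ep in segment(rec, epoch_s, overlap)]
        frames.append(build_feature_table(epochs))
    table = pd.concat(frames, ignore_index=True)
    return table, cohort_truth(cfg)
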