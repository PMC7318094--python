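"""Band-limiting, epoching and artifact rejection.

The preterm EEG pipeline analyses band-limited (0.5–16 Hz) signals in
overlapping fixed-length epochs.  Epochs contaminated by artifact are
removed by three rules applied to every epoch:

1. *spatial imbalance* — one derivation's mean absolute amplitude
   differs from another's by more than a factor of 2;
2. *excessive amplitude* — more than 25 % of envelope samples exceed
   500 µV;
3. *low amplitude* — more than 50 % of envelope samples fall below
   5 µV.

All rules are evaluated so rejection reasons accumulate.  Filtering is
causal (forward-only), matching real-time cot-side operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import EEGRecording

__all__ = ["Epoch", "bandlimit", "segment", "reject_artifacts", "filter_sos"]

log = logging.getLogger(__name__)

HIGHPASS_HZ = 0.5
HIGHPASS_ORDER = 4
LOWPASS_HZ = 16.0
LOWPASS_ORDER = 6

# Artifact rule constants
IMBALANCE_RATIO = 2.0
EXCESS_AMP_UV = 500.0
EXCESS_AMP_FRACTION = 0.25
LOW_AMP_UV = 5.0
LOW_AMP_FRACTION = 0.50


@dataclass
class Epoch:
    """One analysis window of a (filtered, bipolar) recording."""

    parent: EEGRecording
    start_s: float
    duration_s: float
    signal: np.ndarray  # derivations x samples, µV
    status: str = "kept"
    reject_reasons: frozenset[str] = frozenset()

    @property
    def sample_rate_hz(self) -> float:
        return self.parent.sample_rate_hz

    @property
    def channel_labels(self) -> list[str]:
        return self.parent.channel_labels

    @property
    def kept(self) -> bool:
        return self.status == "kept"


def filter_sos(fs: float) -> np.ndarray:
    """Second-order sections of the high-pass → low-pass Butterworth cascade."""
    if fs <= 2 * LOWPASS_HZ:
        raise ValueError(
            f"sample rate {fs} Hz too low: low-pass cutoff {LOWPASS_HZ} Hz "
            "must lie below Nyquist"
        )
    hp = sps.butter(HIGHPASS_ORDER, HIGHPASS_HZ, "highpass", fs=fs, output="sos")
    lp = sps.butter(LOWPASS_ORDER, LOWPASS_HZ, "lowpass", fs=fs, output="sos")
    return np.vstack([hp, lp])


def bandlimit(rec: EEGRecording) -> EEGRecording:
    """Apply the 0.5 Hz high-pass / 16 Hz low-pass Butterworth cascade.

    Forward-only (causal) filtering; output length equals input length.
    """
    sos = filter_sos(rec.sample_rate_hz)
    filtered = sps.sosfilt(sos, rec.signal, axis=1)
    return replace(rec, signal=filtered)


def segment(rec: EEGRecording, epoch_s: float = 3600.0, overlap: float = 0.75) -> list[Epoch]:
    """Split a recording into fully contained overlapping epochs.

    Epochs start at multiples of ``stride = epoch_s * (1 - overlap)``;
    a recording shorter than one epoch yields an empty list (logged),
    not an error.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    fs = rec.sample_rate_hz
    total_s = rec.n_samples / fs
    if total_s < epoch_s:
        log.warning(
            "recording %s (%.0f s) shorter than epoch length %.0f s; no epochs",
            rec.recording_id, total_s, epoch_s,
        )
        return []
    stride_s = epoch_s * (1.0 - overlap)
    n_epochs = int(np.floor((total_s - epoch_s) / stride_s)) + 1
    epoch_n = int(round(epoch_s * fs))
    epochs = []
    for k in range(n_epochs):
        start_s = k * stride_s
        i0 = int(round(start_s * fs))
        epochs.append(
            Epoch(
                parent=rec,
                start_s=start_s,
                duration_s=epoch_s,
                signal=rec.signal[:, i0 : i0 + epoch_n],
            )
        )
    return epochs


def reject_artifacts(epoch: Epoch, burst_amp_fn=None) -> Epoch:
    """Apply the three artifact rules and set epoch status/reasons.

    ``burst_amp_fn(signal_row, fs) -> envelope`` supplies the per-sample
    amplitude envelope used by rules 2 and 3; by default the same
    smoothed analytic-signal envelope as burst detection, keeping the
    "burst amplitude" and "EEG activity" readings consistent with the
    burst analysis.
    """
    if burst_amp_fn is None:
        from .bursts import envelope as burst_amp_fn  # noqa: PLC0415

    reasons: set[str] = set()
    fs = epoch.sample_rate_hz

    # Rule 1: spatial imbalance of mean absolute amplitude (strict > 2).
    if epoch.signal.shape[0] >= 2:
        means = np.mean(np.abs(epoch.signal), axis=1)
        if means.min() <= 0 or means.max() / means.min() > IMBALANCE_RATIO:
            reasons.add("spatial_imbalance")
    else:
        log.info("single-derivation epoch at %.0f s: spatial-imbalance rule skipped", epoch.start_s)

    env = np.vstack([burst_amp_fn(row, fs) for row in epoch.signal])
    if np.mean(env > EXCESS_AMP_UV) > EXCESS_AMP_FRACTION:
        reasons.add("excessive_amplitude")
    if np.mean(env < LOW_AMP_UV) > LOW_AMP_FRACTION:
        reasons.add("low_amplitude")

    status = "rejected" if reasons else "kept"
    if reasons:
        log.info("epoch %s@%.0fs rejected: %s", epoch.parent.recording_id, epoch.start_s, sorted(reasons))
    return replace(epoch, status=status, reject_reasons=frozenset(reasons))
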