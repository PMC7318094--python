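"""Phenomenological qEEG features (m = 46): the measures a clinical
reader extracts visually — amplitudes, spectral band powers, range-EEG
(rEEG) and discontinuity statistics.

All features are computed per derivation and aggregated across
derivations by the median (robust to a single noisy derivation); the
same aggregation policy is used by the other feature families.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats

from .bursts import BurstSet

__all__ = [
    "spectral_features",
    "amplitude_features",
    "discontinuity_features",
    "phenom_feature_vector",
    "BANDS_HZ",
]

#: Neonatal band split (delta / theta / alpha-beta), Hz.
BANDS_HZ = {"delta": (0.5, 3.0), "theta": (3.0, 8.0), "alphabeta": (8.0, 15.0)}
TOTAL_BAND_HZ = (0.5, 16.0)
WELCH_SEG_S = 8.0
WELCH_OVERLAP = 0.5
REEG_WINDOW_S = 2.0
SUPPRESSION_UV = 5.0  # "EEG activity" floor shared with the artifact rule
SUPPRESSED_MIN_S = 2.0


def _welch(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(WELCH_SEG_S * fs)
    nperseg = min(nperseg, len(x))
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=int(nperseg * WELCH_OVERLAP))


def _band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    mask = (f >= lo) & (f < hi)
    if not mask.any():
        return 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def _sef(f: np.ndarray, p: np.ndarray, frac: float, lo: float, hi: float) -> float:
    """Spectral edge: frequency below which ``frac`` of band power lies."""
    mask = (f >= lo) & (f < hi)
    fb, pb = f[mask], p[mask]
    cum = np.cumsum(pb)
    if cum[-1] <= 0:
        return np.nan
    cum = cum / cum[-1]
    idx = int(np.searchsorted(cum, frac))
    return float(fb[min(idx, len(fb) - 1)])


def spectral_features(signal: np.ndarray, fs: float) -> dict[str, float]:
    """Welch band powers (absolute + relative), spectral edges, ratios."""
    f, p = _welch(signal, fs)
    total = _band_power(f, p, *TOTAL_BAND_HZ)
    out: dict[str, float] = {}
    abs_powers = {}
    for name, (lo, hi) in BANDS_HZ.items():
        bp = _band_power(f, p, lo, hi)
        abs_powers[name] = bp
        out[f"abs_power_{name}"] = bp
        out[f"rel_power_{name}"] = bp / total if total > 0 else np.nan
    out["total_power"] = total
    for frac, name in ((0.75, "sef75"), (0.90, "sef90"), (0.95, "sef95")):
        out[name] = _sef(f, p, frac, *TOTAL_BAND_HZ)
    out["log_ratio_delta_theta"] = (
        np.log10(abs_powers["delta"] / abs_powers["theta"])
        if abs_powers["theta"] > 0 else np.nan
    )
    out["log_ratio_theta_alphabeta"] = (
        np.log10(abs_powers["theta"] / abs_powers["alphabeta"])
        if abs_powers["alphabeta"] > 0 else np.nan
    )
    in_band = (f >= TOTAL_BAND_HZ[0]) & (f < TOTAL_BAND_HZ[1])
    out["peak_frequency"] = float(f[in_band][np.argmax(p[in_band])]) if in_band.any() else np.nan
    out["spectral_centroid"] = (
        float(np.sum(f[in_band] * p[in_band]) / np.sum(p[in_band]))
        if in_band.any() and p[in_band].sum() > 0 else np.nan
    )
    return out


def _reeg(signal: np.ndarray, fs: float) -> np.ndarray:
    """Range EEG: peak-to-peak amplitude in non-overlapping 2 s windows."""
    w = int(REEG_WINDOW_S * fs)
    n = len(signal) // w
    if n == 0:
        return np.array([])
    blocks = signal[: n * w].reshape(n, w)
    return blocks.max(axis=1) - blocks.min(axis=1)


def amplitude_features(signal: np.ndarray, env: np.ndarray, fs: float) -> dict[str, float]:
    """Envelope moments/percentiles and rEEG statistics."""
    out: dict[str, float] = {}
    out["env_mean"] = float(np.mean(env))
    out["env_sd"] = float(np.std(env, ddof=1))
    out["env_skew"] = float(stats.skew(env)) if out["env_sd"] > 0 else np.nan
    out["env_kurt"] = float(stats.kurtosis(env)) if out["env_sd"] > 0 else np.nan
    for q in (5, 25, 50, 75, 95):
        out[f"env_p{q}"] = float(np.percentile(env, q))

    r = _reeg(signal, fs)
    if len(r) == 0:
        for k in ("reeg_mean", "reeg_sd", "reeg_p5", "reeg_p25", "reeg_p50",
                  "reeg_p75", "reeg_p95", "reeg_asymmetry", "reeg_bandwidth"):
            out[k] = np.nan
        return out
    out["reeg_mean"] = float(np.mean(r))
    out["reeg_sd"] = float(np.std(r, ddof=1)) if len(r) > 1 else np.nan
    p5, p25, p50, p75, p95 = np.percentile(r, [5, 25, 50, 75, 95])
    out.update(reeg_p5=float(p5), reeg_p25=float(p25), reeg_p50=float(p50),
               reeg_p75=float(p75), reeg_p95=float(p95))
    spread = p95 - p50
    out["reeg_asymmetry"] = float((p50 - p5) / spread) if spread > 0 else np.nan
    out["reeg_bandwidth"] = float(p95 - p5)
    return out


def discontinuity_features(bs: BurstSet) -> dict[str, float]:
    """Interburst intervals, discontinuous-time fraction and suppression."""
    out: dict[str, float] = {}
    fs = bs.fs
    total_s = len(bs.envelope) / fs
    ibi = bs.interburst_intervals()
    if len(ibi) >= 1:
        out["ibi_mean"] = float(np.mean(ibi))
        out["ibi_median"] = float(np.median(ibi))
        out["ibi_max"] = float(np.max(ibi))
        out["ibi_p95"] = float(np.percentile(ibi, 95))
        out["ibi_p5"] = float(np.percentile(ibi, 5))
        out["ibi_sd"] = float(np.std(ibi, ddof=1)) if len(ibi) > 1 else np.nan
    else:
        for k in ("ibi_mean", "ibi_median", "ibi_max", "ibi_p95", "ibi_p5", "ibi_sd"):
            out[k] = np.nan

    low = bs.envelope < SUPPRESSION_UV
    out["pct_discontinuous"] = float(100.0 * np.mean(low))
    out["bursts_per_hour"] = float(len(bs.bursts) / (total_s / 3600.0)) if total_s > 0 else np.nan
    out["pct_time_burst"] = (
        float(100.0 * bs.durations.sum() / total_s) if total_s > 0 else np.nan
    )

    # suppressed periods: runs of envelope < 5 µV lasting > 2 s
    d = np.diff(np.concatenate(([0], low.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    run_s = (ends - starts) / fs
    long_runs = run_s[run_s > SUPPRESSED_MIN_S]
    out["n_suppressed_gt2s"] = float(len(long_runs))
    out["total_suppressed_s"] = float(long_runs.sum())
    out["longest_suppressed_s"] = float(run_s.max()) if len(run_s) else 0.0

    if len(bs.bursts):
        out["mean_burst_duration_s"] = float(np.mean(bs.durations))
        out["median_burst_duration_s"] = float(np.median(bs.durations))
    else:
        out["mean_burst_duration_s"] = np.nan
        out["median_burst_duration_s"] = np.nan
    return out


def phenom_feature_vector(signal: np.ndarray, env: np.ndarray, bs: BurstSet, fs: float) -> dict[str, float]:
    """All 46 ``phenom.*`` features for one derivation."""
    feats: dict[str, float] = {}
    feats.update(spectral_features(signal, fs))
    feats.update(amplitude_features(signal, env, fs))
    feats.update(discontinuity_features(bs))
    return {f"phenom.{k}": float(v) for k, v in feats.items()}
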