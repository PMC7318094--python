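"""The qEEG feature registry: 96 named features in three families.

Families and counts follow the standard grouping for preterm
maturational qEEG: phenomenological (m = 46, mirroring visual review),
burst / crackling-noise analysis (m = 40), and other advanced measures
(m = 10).  The exact item list is this package's documented
reconstruction of those families; the registry fixes the names, family
tags, definition strings and — critically — the column order of every
feature table the pipeline produces.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FeatureSpec", "REGISTRY", "feature_names", "family_names", "REGISTRY_VERSION"]

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str
    definition: str


def _burst_entries() -> list[FeatureSpec]:
    e = []

    def add(name, definition):
        e.append(FeatureSpec(f"burst.{name}", "burst", definition))

    add("shape_asymmetry", "normalized first moment of mean burst shape about u=0.5")
    add("shape_sharpness", "negative second difference of mean shape at its peak / (grid step)^2")
    for lo, hi in ((0.5, 1), (1, 2), (2, 4), (4, 8)):
        tag = f"d{lo:g}_{hi:g}".replace(".", "p")
        add(f"shape_asymmetry_{tag}", f"shape asymmetry, bursts with duration in [{lo},{hi}) s")
        add(f"shape_sharpness_{tag}", f"shape sharpness, bursts with duration in [{lo},{hi}) s")
    for q in ("duration", "area", "peak"):
        add(f"log_{q}_mean", f"mean of log10 burst {q}")
        add(f"log_{q}_sd", f"SD of log10 burst {q}")
    add("rate_per_min", "bursts per minute")
    add("time_in_burst_frac", "fraction of epoch time inside bursts")
    add("duration_ccdf_slope", "OLS slope of log-log CCDF of burst duration (central 90%)")
    add("area_ccdf_slope", "OLS slope of log-log CCDF of burst area (central 90%)")
    add("area_duration_exponent", "OLS slope of log10 area vs log10 duration")
    for k in ("median", "iqr", "p95", "mean", "cv", "max"):
        add(f"ibi_{k}_s" if k != "cv" else "ibi_cv", f"interburst interval {k}")
    add("count", "number of detected bursts")
    for k in ("p5", "p50", "p95", "iqr", "max"):
        add(f"duration_{k}_s", f"burst duration {k} (s)")
    for k in ("p5", "p50", "p95", "iqr", "max"):
        add(f"peak_{k}_uv", f"burst peak amplitude {k} (µV)")
    add("area_p50_uvs", "burst area median (µV·s)")
    add("area_iqr_uvs", "burst area IQR (µV·s)")
    return e


def _phenom_entries() -> list[FeatureSpec]:
    e = []

    def add(name, definition):
        e.append(FeatureSpec(f"phenom.{name}", "phenomenological", definition))

    for band, rng in (("delta", "0.5-3"), ("theta", "3-8"), ("alphabeta", "8-15")):
        add(f"abs_power_{band}", f"absolute Welch power {rng} Hz (µV²)")
        add(f"rel_power_{band}", f"power {rng} Hz / power 0.5-16 Hz")
    add("total_power", "Welch power 0.5-16 Hz (µV²)")
    for f in (75, 90, 95):
        add(f"sef{f}", f"spectral edge frequency at {f}% cumulative power")
    add("log_ratio_delta_theta", "log10 delta/theta power ratio")
    add("log_ratio_theta_alphabeta", "log10 theta/alpha-beta power ratio")
    add("peak_frequency", "frequency of spectral maximum in 0.5-16 Hz")
    add("spectral_centroid", "power-weighted mean frequency in 0.5-16 Hz")
    for k in ("mean", "sd", "skew", "kurt"):
        add(f"env_{k}", f"envelope {k}")
    for q in (5, 25, 50, 75, 95):
        add(f"env_p{q}", f"envelope {q}th percentile (µV)")
    add("reeg_mean", "mean rEEG (2 s peak-to-peak) amplitude")
    add("reeg_sd", "SD of rEEG amplitude")
    for q in (5, 25, 50, 75, 95):
        add(f"reeg_p{q}", f"rEEG {q}th percentile (µV)")
    add("reeg_asymmetry", "(median-5th)/(95th-median) of rEEG")
    add("reeg_bandwidth", "rEEG 95th-5th percentile (µV)")
    for k in ("mean", "median", "max", "p95", "p5", "sd"):
        add(f"ibi_{k}", f"interburst interval {k} (s)")
    add("pct_discontinuous", "% of time envelope < 5 µV")
    add("bursts_per_hour", "burst count scaled to per-hour rate")
    add("pct_time_burst", "% of time inside bursts")
    add("n_suppressed_gt2s", "number of suppressed (<5 µV) periods > 2 s")
    add("total_suppressed_s", "total duration of suppressed periods > 2 s")
    add("longest_suppressed_s", "longest suppressed run (s)")
    add("mean_burst_duration_s", "mean burst duration (s)")
    add("median_burst_duration_s", "median burst duration (s)")
    return e


def _advanced_entries() -> list[FeatureSpec]:
    defs = {
        "suppression_auc": "mean fraction of time envelope < h over log grid 1-100 µV",
        "suppression_half_uv": "threshold at which suppression fraction = 0.5",
        "mse_mean": "mean sample entropy over coarse-graining scales 1-10",
        "mse_slope": "OLS slope of sample entropy vs log scale",
        "mpli": "median phase lag index over derivation pairs, 0.5-8 Hz",
        "asi": "median windowed log-envelope correlation over pairs (activation synchrony)",
        "path_length": "characteristic path length of thresholded coherence graph",
        "spectral_entropy": "Shannon entropy of normalized spectrum, bits",
        "higuchi_fd": "Higuchi fractal dimension",
        "line_length": "mean absolute first difference per second",
    }
    return [FeatureSpec(f"adv.{k}", "advanced", v) for k, v in defs.items()]


REGISTRY: tuple[FeatureSpec, ...] = tuple(_burst_entries() + _phenom_entries() + _advanced_entries())

_COUNTS = {"burst": 40, "phenomenological": 46, "advanced": 10}
for fam, want in _COUNTS.items():
    got = sum(1 for f in REGISTRY if f.family == fam)
    if got != want:
        raise RuntimeError(f"registry family {fam} has {got} entries, expected {want}")


def feature_names(family: str | None = None) -> list[str]:
    """Registry-ordered feature names, optionally for one family."""
    if family is None:
        return [f.name for f in REGISTRY]
    return [f.name for f in REGISTRY if f.family == family]


def family_names() -> list[str]:
    return ["phenomenological", "burst", "advanced"]
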