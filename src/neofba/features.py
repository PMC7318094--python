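"""Per-epoch feature extraction and feature-table assembly.

One row per kept epoch: identifiers (subject_id, recording_id, start_s,
pma_weeks) followed by the 96 registry features in registry order.
Burst and phenomenological features are computed per derivation and
median-aggregated; the advanced family contains genuinely cross-channel
measures computed over all derivations at once.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .advanced import advanced_feature_vector
from .bursts import burst_feature_vector, detect_bursts, envelope
from .phenom import phenom_feature_vector
from .preprocess import Epoch
from .registry import REGISTRY_VERSION, feature_names

__all__ = ["extract_epoch_features", "build_feature_table", "ID_COLUMNS"]

log = logging.getLogger(__name__)

ID_COLUMNS = ["subject_id", "recording_id", "start_s", "pma_weeks"]


def extract_epoch_features(epoch: Epoch) -> dict[str, float]:
    """All 96 registry features for one kept epoch.

    Raises ValueError on a rejected epoch: artifact epochs never enter
    the feature table.
    """
    if not epoch.kept:
        raise ValueError(
            f"cannot extract features from rejected epoch "
            f"({sorted(epoch.reject_reasons)})"
        )
    fs = epoch.sample_rate_hz
    signals = epoch.signal
    envs = np.vstack([envelope(row, fs) for row in signals])
    burst_sets = [detect_bursts(env, fs) for env in envs]

    per_channel: list[dict[str, float]] = []
    for sig, env, bs in zip(signals, envs, burst_sets):
        row = {}
        row.update(burst_feature_vector(bs))
        row.update(phenom_feature_vector(sig, env, bs, fs))
        per_channel.append(row)

    feats: dict[str, float] = {}
    keys = per_channel[0].keys()
    for k in keys:
        vals = np.array([c[k] for c in per_channel])
        feats[k] = float(np.nanmedian(vals)) if np.any(np.isfinite(vals)) else np.nan

    feats.update(advanced_feature_vector(signals, envs, fs))

    ordered = {name: feats.get(name, np.nan) for name in feature_names()}
    missing = set(feats) - set(ordered)
    if missing:
        raise RuntimeError(f"features not in registry: {sorted(missing)}")
    return ordered


def build_feature_table(epochs: list[Epoch]) -> pd.DataFrame:
    """Feature table over the kept epochs of one or many recordings."""
    rows = []
    for ep in epochs:
        if not ep.kept:
            continue
        rec = ep.parent
        row: dict = {
            "subject_id": rec.subject_id,
            "recording_id": rec.recording_id,
            "start_s": ep.start_s,
            "pma_weeks": rec.pma_weeks,
        }
        row.update(extract_epoch_features(ep))
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=ID_COLUMNS + feature_names())
    df = pd.DataFrame(rows, columns=ID_COLUMNS + feature_names())
    dup = df.duplicated(subset=["recording_id", "start_s"])
    if dup.any():
        raise ValueError("duplicate (recording_id, start_s) rows in feature table")
    df.attrs["registry_version"] = REGISTRY_VERSION
    return df
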