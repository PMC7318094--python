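"""EDF input/output, recording containers and bipolar montages.

Recordings are held referentially (one row per scalp electrode) until a
bipolar montage is applied; all downstream analysis operates on bipolar
derivations, whose order is fixed by the montage — never by the file.

EDF files are written in a fixed clinical dialect: physical range
±1000 µV, 16-bit digital range, one data record per second.  The
resulting quantization step is 2000/65535 ≈ 0.0305 µV, which bounds the
round-trip error of the writer/reader pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "Montage",
    "MONTAGES",
    "ELECTRODE_VOCABULARY",
    "read_edf",
    "write_edf",
    "read_metadata",
    "apply_montage",
]

#: Neonatal 10-20 electrode subset accepted in montage definitions.
ELECTRODE_VOCABULARY = frozenset(
    {"Fp1", "Fp2", "C3", "C4", "Cz", "T3", "T4", "O1", "O2", "F3", "F4", "P3", "P4"}
)

_EDF_PHYS_MIN = -1000.0  # µV
_EDF_PHYS_MAX = 1000.0
_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767

#: Labels treated as non-EEG auxiliary channels and dropped on read.
_NON_EEG_TOKENS = ("ECG", "EKG", "RESP", "EMG", "EOG", "SAO2", "SPO2", "PULSE", "STATUS", "ANNOTATION")


class FormatError(ValueError):
    """Raised when a file cannot be parsed as EDF."""


class MontageError(KeyError):
    """Raised when a montage references an electrode absent from a recording."""


class MetadataError(ValueError):
    """Raised when required recording metadata is missing or invalid."""


@dataclass
class EEGRecording:
    """Multichannel EEG with age metadata.

    signal is channels × samples in microvolts.  montage_kind is
    "referential" for raw electrode channels and "bipolar" once a
    montage has been applied.
    """

    subject_id: str
    pma_weeks: float
    ga_weeks: float
    sample_rate_hz: float
    channel_labels: list[str]
    signal: np.ndarray
    montage_kind: str = "referential"
    recording_id: str = ""
    outcome: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.pma_weeks < self.ga_weeks:
            raise MetadataError("pma_weeks must be >= ga_weeks")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        if not self.recording_id:
            self.recording_id = self.subject_id

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(frozen=True)
class Montage:
    """Ordered list of bipolar (anode, cathode) electrode pairs."""

    name: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError(f"montage {self.name!r} has duplicate pairs")
        for a, c in self.pairs:
            for lbl in (a, c):
                if lbl not in ELECTRODE_VOCABULARY:
                    raise ValueError(f"unknown electrode label {lbl!r} in montage {self.name!r}")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]


#: Montage presets.  "vienna_double_banana" is the 8-derivation
#: longitudinal bipolar layout used on 9-electrode neonatal recordings;
#: "utrecht_2ch" the fronto-parietal 2-channel aEEG-monitor layout;
#: "frontocentral_2ch" the fronto-central pair used to transfer a model
#: trained on the full montage onto 2-channel recordings.
MONTAGES: dict[str, Montage] = {
    "vienna_double_banana": Montage(
        "vienna_double_banana",
        (
            ("Fp1", "C3"), ("C3", "O1"), ("Fp1", "T3"), ("T3", "O1"),
            ("Fp2", "C4"), ("C4", "O2"), ("Fp2", "T4"), ("T4", "O2"),
        ),
    ),
    "utrecht_2ch": Montage("utrecht_2ch", (("F4", "P4"), ("F3", "P3"))),
    "frontocentral_2ch": Montage("frontocentral_2ch", (("Fp1", "C3"), ("Fp2", "C4"))),
}


def _normalize_label(raw: str) -> str:
    """Case-normalize an electrode label ('FP1', 'EEG Fp1-Ref' -> 'Fp1')."""
    token = raw.strip()
    if token.upper().startswith("EEG"):
        token = token[3:].strip()
    token = token.split("-")[0].strip()
    for vocab in ELECTRODE_VOCABULARY:
        if token.upper() == vocab.upper():
            return vocab
    return token


def _is_eeg_label(label: str) -> bool:
    up = label.upper()
    return not any(tok in up for tok in _NON_EEG_TOKENS)


def read_edf(path: str | Path, metadata: dict) -> EEGRecording:
    """Read an EDF/EDF+ file into a referential :class:`EEGRecording`.

    Non-EEG channels (ECG, respiration, ...) are dropped by label.
    metadata must provide subject_id, pma_weeks and ga_weeks; values are
    attached unchanged.
    """
    import mne

    path = Path(path)
    if "pma_weeks" not in metadata or metadata["pma_weeks"] is None:
        raise MetadataError(f"missing pma_weeks for {path.name}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt input
        raise FormatError(f"cannot read {path} as EDF: {exc}") from exc

    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise FormatError(f"mixed sampling rates in {path}")

    labels = [_normalize_label(ch) for ch in raw.ch_names]
    keep = [i for i, lbl in enumerate(labels) if _is_eeg_label(lbl)]
    if not keep:
        raise FormatError(f"no EEG channels found in {path}")
    data = raw.get_data(picks=keep) * 1e6  # mne works in volts
    return EEGRecording(
        subject_id=str(metadata["subject_id"]),
        pma_weeks=float(metadata["pma_weeks"]),
        ga_weeks=float(metadata.get("ga_weeks", metadata["pma_weeks"])),
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_labels=[labels[i] for i in keep],
        signal=data,
        montage_kind="referential",
        recording_id=str(metadata.get("recording_id", path.stem)),
        outcome=metadata.get("outcome"),
    )


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as plain EDF (16-bit, ±1000 µV, 1-s records).

    Samples outside ±1000 µV are clipped.  The sampling rate must be an
    integer so that one data record holds a whole second.
    """
    path = Path(path)
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = rec.n_channels
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.signal[:, : n_records * fs]

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (_EDF_PHYS_MAX - _EDF_PHYS_MIN)
    dig = np.clip(data, _EDF_PHYS_MIN, _EDF_PHYS_MAX)
    dig = np.round((dig - _EDF_PHYS_MIN) * scale + _EDF_DIG_MIN).astype("<i2")

    def _pad(s: str, n: int) -> bytes:
        return s.encode("ascii", "replace")[:n].ljust(n)

    header = b"".join([
        _pad("0", 8),
        _pad(f"X X X {rec.subject_id}"[:80], 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        (16, [lbl for lbl in rec.channel_labels]),
        (80, ["" for _ in range(ns)]),
        (8, ["uV"] * ns),
        (8, [f"{_EDF_PHYS_MIN:g}"] * ns),
        (8, [f"{_EDF_PHYS_MAX:g}"] * ns),
        (8, [str(_EDF_DIG_MIN)] * ns),
        (8, [str(_EDF_DIG_MAX)] * ns),
        (80, ["" for _ in range(ns)]),
        (8, [str(fs)] * ns),
        (32, ["" for _ in range(ns)]),
    ]
    sig_header = b"".join(b"".join(_pad(v, w) for v in vals) for w, vals in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = dig[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar metadata CSV (file, subject_id, ga_weeks, pma_weeks, outcome)."""
    df = pd.read_csv(path)
    required = {"file", "subject_id", "ga_weeks", "pma_weeks"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata CSV missing columns: {sorted(missing)}")
    if df["pma_weeks"].isna().any():
        raise MetadataError("metadata CSV has rows with missing pma_weeks")
    return df


def apply_montage(rec: EEGRecording, montage: Montage | str) -> EEGRecording:
    """Form bipolar derivations (anode − cathode) in montage order."""
    if isinstance(montage, str):
        montage = MONTAGES[montage]
    if rec.montage_kind != "referential":
        raise ValueError("apply_montage requires a referential recording")
    index = {lbl: i for i, lbl in enumerate(rec.channel_labels)}
    rows = []
    for anode, cathode in montage.pairs:
        for lbl in (anode, cathode):
            if lbl not in index:
                raise MontageError(f"electrode {lbl!r} not present in recording")
        rows.append(rec.signal[index[anode]] - rec.signal[index[cathode]])
    return replace(
        rec,
        channel_labels=montage.labels,
        signal=np.vstack(rows),
        montage_kind="bipolar",
    )
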