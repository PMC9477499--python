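"""Recordings, hypnograms, sleep architecture and the long-format feature table.

EEG recordings travel as :class:`Recording` (channels x samples, microvolts);
sleep staging as :class:`Hypnogram` (30-s epochs by default).  On-disk formats
are plain EDF (16-bit, one sampling rate across channels), a one-stage-per-line
(or CSV) hypnogram file, and a long-format CSV feature table whose measure
vocabulary is closed over the 21 per-subject, per-electrode EEG measures the
pipeline derives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("nremtools")

STAGES = ("W", "N1", "N2", "N3", "REM", "ART")
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "REM"})

#: closed vocabulary of (measure, stage_context) pairs in the feature table
MEASURE_VOCAB = (
    [(m, s) for m in ("slow_delta_power_db", "sigma_power_db", "sigma_peak_hz")
     for s in ("N2", "N3")]
    + [(m, s) for m in ("aperiodic_slope", "aperiodic_intercept")
       for s in ("N2", "N3", "REM")]
    + [(m, "NREM") for m in (
        "spindle_density_per_min", "spindle_amplitude_uv", "spindle_frequency_hz",
        "sw_density_per_min", "sw_amplitude_uv", "sw_duration_s",
        "coupling_overlap_z", "coupling_mrl_z", "coupling_mean_angle_deg")]
)
MEASURE_NAMES = frozenset(m for m, _ in MEASURE_VOCAB)


class EDFFormatError(ValueError):
    """Raised for malformed or unsupported EDF files."""


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "s1"
    family_id: str = "f1"
    group_label: str = "control"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels (W, N1, N2, N3, REM, ART)."""

    stages: list[str]
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("hypnogram must be non-empty")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage tokens: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.stages)

    def stage_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def epochs_of(self, *stages: str) -> np.ndarray:
        """Indices of epochs whose stage is in ``stages``."""
        arr = self.stage_array()
        return np.flatnonzero(np.isin(arr, list(stages)))


@dataclass
class SleepArchitecture:
    tst_min: float
    se_pct: float
    n1_latency_min: float
    rem_latency_min: float
    pct_n1: float
    pct_n2: float
    pct_n3: float
    pct_rem: float
    awakenings_n: int


# ---------------------------------------------------------------------------
# EDF read/write
#
# Plain EDF: 256-byte fixed header, 256 bytes per signal, then data records of
# little-endian int16.  One sampling rate across channels, record duration 1 s.
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as a 16-bit EDF file.

    The sampling rate must be a positive integer and the recording length a
    whole number of seconds (records are 1 s long).
    """
    fs = rec.fs
    if fs != int(fs):
        raise EDFFormatError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise EDFFormatError(
            "recording length must be a whole number of seconds "
            f"(got {rec.n_samples} samples at {fs} Hz)")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    pmax = np.maximum(np.max(np.abs(rec.samples), axis=1), 1e-6)
    pmin = -pmax
    dmax, dmin = 32767, -32768

    now = datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(rec.subject_id, 80),
        _pad(rec.group_label, 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_pad(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad("uV", 8) for _ in range(ns)),
        b"".join(_pad(f"{pmin[i]:.6g}"[:8], 8) for i in range(ns)),
        b"".join(_pad(f"{pmax[i]:.6g}"[:8], 8) for i in range(ns)),
        b"".join(_pad(str(dmin), 8) for _ in range(ns)),
        b"".join(_pad(str(dmax), 8) for _ in range(ns)),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad(str(fs), 8) for _ in range(ns)),
        b"".join(_pad("", 32) for _ in range(ns)),
    ])
    # re-read the physical bounds exactly as a reader will parse them, so the
    # digital mapping is consistent to the printed precision
    pmin_r = np.array([float(f"{pmin[i]:.6g}"[:8]) for i in range(ns)])
    pmax_r = np.array([float(f"{pmax[i]:.6g}"[:8]) for i in range(ns)])
    gain = (dmax - dmin) / (pmax_r - pmin_r)
    dig = np.rint((rec.samples - pmin_r[:, None]) * gain[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            block = dig[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def _ascii(buf: bytes, start: int, width: int) -> str:
    return buf[start:start + width].decode("ascii", "replace").strip()


def read_edf(path: str | Path) -> Recording:
    """Read a plain EDF file into a :class:`Recording` (voltages in µV)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EDFFormatError(f"{path}: file too short to hold an EDF header")
    try:
        n_records = int(_ascii(raw, 236, 8))
        rec_dur = float(_ascii(raw, 244, 8))
        ns = int(_ascii(raw, 252, 4))
    except ValueError as exc:
        raise EDFFormatError(f"{path}: malformed EDF header") from exc
    if ns <= 0 or n_records < 0 or rec_dur <= 0:
        raise EDFFormatError(f"{path}: malformed EDF header fields")
    if len(raw) < 256 * (1 + ns):
        raise EDFFormatError(f"{path}: truncated signal header")

    # field layout offsets (per-signal bytes): label 0, transducer 16, dim 96,
    # pmin 104, pmax 112, dmin 120, dmax 128, prefilter 136, nsamp 216
    base = 256
    w = {"label": (0, 16), "pmin": (104, 8), "pmax": (112, 8),
         "dmin": (120, 8), "dmax": (128, 8), "nsamp": (216, 8)}

    def field(name: str) -> list[str]:
        off, width = w[name]
        start = base + off * ns
        return [_ascii(raw, start + i * width, width) for i in range(ns)]

    labels = field("label")
    try:
        pmin = np.array([float(v) for v in field("pmin")])
        pmax = np.array([float(v) for v in field("pmax")])
        dmin = np.array([float(v) for v in field("dmin")])
        dmax = np.array([float(v) for v in field("dmax")])
        nsamp = np.array([int(v) for v in field("nsamp")])
    except ValueError as exc:
        raise EDFFormatError(f"{path}: malformed signal header") from exc

    if len(set(nsamp.tolist())) != 1:
        odd = labels[int(np.argmax(nsamp != nsamp[0]))]
        raise EDFFormatError(
            f"{path}: unequal per-channel sampling rates (channel {odd!r}); "
            "only single-rate EDF is supported")
    spr = int(nsamp[0])
    fs = spr / rec_dur

    data_start = 256 * (1 + ns)
    expect = n_records * ns * spr * 2
    payload = raw[data_start:data_start + expect]
    if len(payload) < expect:
        raise EDFFormatError(f"{path}: truncated data records")
    dig = np.frombuffer(payload, dtype="<i2").reshape(n_records, ns, spr)
    dig = np.transpose(dig, (1, 0, 2)).reshape(ns, n_records * spr)
    gain = (pmax - pmin) / (dmax - dmin)
    phys = (dig - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return Recording(samples=phys, fs=fs, channel_labels=labels,
                     subject_id=_ascii(raw, 8, 80) or "s1")


# ---------------------------------------------------------------------------
# Hypnogram files
# ---------------------------------------------------------------------------

_TOKEN_MAP = {"W": "W", "WAKE": "W", "N1": "N1", "N2": "N2", "N3": "N3",
              "REM": "REM", "R": "REM", "ART": "ART", "A": "ART"}


def read_hypnogram(path: str | Path, epoch_len_s: float = 30.0) -> Hypnogram:
    """Read a hypnogram from a plain text file (one stage token per line)
    or a CSV with a ``stage`` column.  Tokens are case-folded."""
    lines = Path(path).read_text().splitlines()
    stages: list[str] = []
    header_skipped = False
    for lineno, line in enumerate(lines, start=1):
        tok = line.strip()
        if not tok:
            continue
        if "," in tok or tok.lower() == "stage":
            cells = [c.strip() for c in tok.split(",")]
            if not header_skipped and any(c.lower() == "stage" for c in cells):
                header_skipped = True
                stage_col = [c.lower() for c in cells].index("stage")
                continue
            tok = cells[stage_col if header_skipped else -1]
        up = tok.upper()
        if up not in _TOKEN_MAP:
            raise ValueError(f"{path}: unknown stage token {tok!r} at line {lineno}")
        stages.append(_TOKEN_MAP[up])
    return Hypnogram(stages=stages, epoch_len_s=epoch_len_s)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("stage\n" + "\n".join(h.stages) + "\n")


# ---------------------------------------------------------------------------
# Sleep architecture
# ---------------------------------------------------------------------------

def sleep_architecture(h: Hypnogram) -> SleepArchitecture:
    """Standard derived sleep variables from a hypnogram.

    TST counts N1+N2+N3+REM epochs; sleep efficiency uses the full hypnogram
    duration as the time-in-bed proxy; N1 latency is referenced to the record
    start, REM latency to the first sleep epoch; awakenings are contiguous W
    bouts strictly between the first and last sleep epoch.  ART epochs count
    toward total time but never toward sleep.
    """
    stages = h.stage_array()
    ep_min = h.epoch_len_s / 60.0
    is_sleep = np.isin(stages, list(SLEEP_STAGES))
    n_sleep = int(is_sleep.sum())
    tst = n_sleep * ep_min
    se = 100.0 * n_sleep / len(stages)

    def first_min(mask: np.ndarray, ref: int = 0) -> float:
        idx = np.flatnonzero(mask)
        return (idx[0] - ref) * ep_min if idx.size else float("nan")

    n1_lat = first_min(stages == "N1")
    if n_sleep:
        onset = int(np.flatnonzero(is_sleep)[0])
        last = int(np.flatnonzero(is_sleep)[-1])
        rem_lat = first_min(stages == "REM", ref=onset)
        inner_w = (stages == "W")[onset:last + 1]
        # count contiguous W bouts inside the sleep period
        awak = int(np.sum(inner_w & ~np.r_[False, inner_w[:-1]]))
        pct = {s: 100.0 * np.sum(stages == s) / n_sleep
               for s in ("N1", "N2", "N3", "REM")}
    else:
        rem_lat = float("nan")
        awak = 0
        pct = {s: float("nan") for s in ("N1", "N2", "N3", "REM")}
    return SleepArchitecture(
        tst_min=tst, se_pct=se, n1_latency_min=n1_lat, rem_latency_min=rem_lat,
        pct_n1=pct["N1"], pct_n2=pct["N2"], pct_n3=pct["N3"], pct_rem=pct["REM"],
        awakenings_n=awak)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["subject_id", "channel", "stage", "measure", "value"]


def make_feature_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate a long-format feature table."""
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    validate_feature_table(df)
    return df


def validate_feature_table(df: pd.DataFrame) -> None:
    if list(df.columns) != FEATURE_COLUMNS:
        raise ValueError(f"feature table must have columns {FEATURE_COLUMNS}")
    bad = set(df["measure"]) - MEASURE_NAMES
    if bad:
        raise ValueError(f"measure names outside the closed vocabulary: {sorted(bad)}")
    key = df[["subject_id", "channel", "stage", "measure"]]
    dup = key[key.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature keys: {dup.values.tolist()}")


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table CSV with deterministic row ordering."""
    validate_feature_table(df)
    out = df.sort_values(["subject_id", "channel", "measure", "stage"],
                         kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_feature_table(df)
    return df
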