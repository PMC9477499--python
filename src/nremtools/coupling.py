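"""Spindle–slow-wave temporal and phase coupling.

The slow-wave phase convention follows the detector: on the 0.25–4 Hz
filtered signal, 0° is the positive-to-negative zero crossing, 90° the
trough, 180° the negative-to-positive crossing and 270° the peak (the raw
analytic-signal angle shifted by −90°, modulo 360).

Three per-channel metrics: the fraction of spindles whose peak falls within
±1.5 s of a slow-wave trough (z-scored against repositioning every spindle
peak uniformly within its own 30-s epoch); the mean resultant length of the
slow-wave phase at overlapping spindle peaks (z-scored against repositioning
each paired peak uniformly within its shuffle domain — the ±1.5 s matching
window by default, or the host slow wave's extent); and the circular mean
coupling angle.  Shuffle nulls use 1000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .events import (SlowWaveEvent, SpindleEvent, contiguous_segments,
                     sw_bandpass, _cfbs_mag_raw)
from .io import logger

MATCH_WINDOW_S = 1.5
N_SHUFFLES = 1000
SCALO_FREQS = np.arange(8.0, 16.0001, 0.5)
SCALO_WINDOW_S = (-2.0, 2.0)
SCALO_BASELINE_S = (-2.0, -1.5)


@dataclass
class CouplingSummary:
    n_spindles: int
    n_overlapping: int
    overlap_raw: float
    overlap_z: float
    mrl_raw: float
    mrl_z: float
    mean_angle_deg: float


# ---------------------------------------------------------------------------
# Phase
# ---------------------------------------------------------------------------

def sw_phase_series(filtered: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample slow-wave phase in degrees [0, 360) of an already
    band-passed contiguous segment (Hilbert transform, −90° remap)."""
    x = np.asarray(filtered, dtype=float)
    if x.size < 4 * fs:
        raise ValueError("segment shorter than 4 s; analytic signal unstable")
    ana = signal.hilbert(x)
    return (np.rad2deg(np.angle(ana)) - 90.0) % 360.0


def phase_series_full(x_full: np.ndarray, fs: float, indices: np.ndarray
                      ) -> np.ndarray:
    """Record-length phase array: slow-wave phase on each analyzed contiguous
    segment (filtered per segment), NaN elsewhere."""
    out = np.full(x_full.shape[-1], np.nan)
    for a, b in contiguous_segments(indices):
        if b - a < 4 * fs:
            logger.warning("skipping %.1f s segment (too short for phase)",
                           (b - a) / fs)
            continue
        xf = sw_bandpass(x_full[a:b], fs)
        out[a:b] = sw_phase_series(xf, fs)
    return out


# ---------------------------------------------------------------------------
# Matching and circular statistics
# ---------------------------------------------------------------------------

def match_spindles_to_sw(spindles: list[SpindleEvent],
                         sws: list[SlowWaveEvent]
                         ) -> list[tuple[SpindleEvent, SlowWaveEvent]]:
    """Pairs (spindle, SW) with |spindle peak − SW trough| ≤ 1.5 s; a spindle
    near several SWs goes to the nearest trough, ties to the earlier one."""
    if not spindles or not sws:
        return []
    sws_sorted = sorted(sws, key=lambda s: s.trough_s)
    troughs = np.array([s.trough_s for s in sws_sorted])
    pairs = []
    for sp in spindles:
        k = np.searchsorted(troughs, sp.peak_s)
        best = None
        for j in (k - 1, k):        # earlier candidate first: ties -> earlier
            if 0 <= j < troughs.size:
                d = abs(sp.peak_s - troughs[j])
                if d <= MATCH_WINDOW_S and (best is None or d < best[0]):
                    best = (d, j)
        if best is not None:
            pairs.append((sp, sws_sorted[best[1]]))
    return pairs


def circ_mean_mrl(angles_deg: np.ndarray) -> tuple[float, float]:
    """(mrl, mean angle in degrees [0,360)); angle is NaN when mrl ≈ 0."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    v = np.mean(np.exp(1j * th))
    mrl = float(np.abs(v))
    ang = float(np.rad2deg(np.angle(v)) % 360.0) if mrl > 1e-12 else np.nan
    return mrl, ang


def coupling_stats(pairs, phase_full: np.ndarray, fs: float
                   ) -> tuple[float, float]:
    """MRL and circular-mean angle of the SW phase at paired spindle peaks."""
    if not pairs:
        return np.nan, np.nan
    idx = np.array([int(round(sp.peak_s * fs)) for sp, _ in pairs])
    th = phase_full[idx]
    th = th[np.isfinite(th)]
    if th.size == 0:
        return np.nan, np.nan
    return circ_mean_mrl(th)


# ---------------------------------------------------------------------------
# Shuffle nulls
# ---------------------------------------------------------------------------

def overlap_null_z(spindles: list[SpindleEvent], sws: list[SlowWaveEvent],
                   fs: float, epoch_len_s: float = 30.0,
                   n_shuffles: int = N_SHUFFLES, seed: int = 0) -> float:
    """z-score of the observed overlap fraction against repositioning every
    spindle peak uniformly within its own 30-s epoch."""
    if not spindles:
        return np.nan
    troughs = np.sort([s.trough_s for s in sws]) if sws else np.empty(0)

    def frac(peaks: np.ndarray) -> np.ndarray:
        if troughs.size == 0:
            return np.zeros(peaks.shape[:-1])
        k = np.searchsorted(troughs, peaks)
        d_lo = np.abs(peaks - troughs[np.clip(k - 1, 0, troughs.size - 1)])
        d_hi = np.abs(peaks - troughs[np.clip(k, 0, troughs.size - 1)])
        return (np.minimum(d_lo, d_hi) <= MATCH_WINDOW_S).mean(axis=-1)

    peaks = np.array([sp.peak_s for sp in spindles])
    obs = float(frac(peaks))
    rng = np.random.default_rng(seed)
    ep0 = np.floor(peaks / epoch_len_s) * epoch_len_s
    null_peaks = ep0[None, :] + rng.uniform(
        0, epoch_len_s, size=(n_shuffles, peaks.size))
    null = frac(null_peaks)
    sd = null.std()
    if sd == 0:
        return np.nan
    return float((obs - null.mean()) / sd)


def mrl_null_z(pairs, phase_full: np.ndarray, fs: float,
               n_shuffles: int = N_SHUFFLES, seed: int = 0,
               domain: str = "window") -> float:
    """z-score of the observed MRL against repositioning each paired spindle
    peak uniformly within its shuffle domain ("window": trough ±1.5 s,
    "extent": the host SW's start–end span).  Needs ≥ 5 pairs."""
    if domain not in ("window", "extent"):
        raise ValueError("domain must be 'window' or 'extent'")
    if len(pairs) < 5:
        logger.warning("fewer than 5 spindle-SW pairs; MRL z unstable")
        return np.nan
    n = phase_full.size
    obs, _ = coupling_stats(pairs, phase_full, fs)
    if not np.isfinite(obs):
        return np.nan
    if domain == "extent":
        lo = np.array([int(round(sw.start_s * fs)) for _, sw in pairs])
        hi = np.array([int(round(sw.end_s * fs)) for _, sw in pairs])
    else:
        tr = np.array([sw.trough_s for _, sw in pairs])
        lo = np.clip(((tr - MATCH_WINDOW_S) * fs).round().astype(int), 0, n - 1)
        hi = np.clip(((tr + MATCH_WINDOW_S) * fs).round().astype(int), 0, n - 1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(lo[None, :], hi[None, :] + 1,
                       size=(n_shuffles, len(pairs)))
    th = phase_full[idx]
    # redraw samples that landed where no phase is defined (segment gaps)
    for _ in range(100):
        bad = ~np.isfinite(th)
        if not bad.any():
            break
        redraw = rng.integers(np.broadcast_to(lo, th.shape)[bad],
                              np.broadcast_to(hi, th.shape)[bad] + 1)
        th[bad] = phase_full[redraw]
    ok = np.isfinite(th)
    z = np.exp(1j * np.deg2rad(np.where(ok, th, 0.0)))
    z[~ok] = 0
    null = np.abs(z.sum(axis=1) / np.maximum(ok.sum(axis=1), 1))
    sd = null.std()
    if sd == 0:
        return np.nan
    return float((obs - null.mean()) / sd)


# ---------------------------------------------------------------------------
# Trough-locked views
# ---------------------------------------------------------------------------

def sw_locked_average(x_full: np.ndarray, sws: list[SlowWaveEvent], fs: float,
                      window_s: tuple[float, float] = (-2.0, 2.0)
                      ) -> tuple[np.ndarray, int]:
    """Average raw-signal window centered on SW troughs; SWs whose window
    leaves the record are excluded.  Returns (waveform, n_used)."""
    lo = int(round(window_s[0] * fs))
    hi = int(round(window_s[1] * fs))
    n = x_full.shape[-1]
    segs = []
    for sw in sws:
        t = int(round(sw.trough_s * fs))
        if t + lo < 0 or t + hi + 1 > n:
            continue
        segs.append(x_full[t + lo:t + hi + 1])
    if not segs:
        raise ValueError("no slow wave fully inside the averaging window")
    return np.mean(segs, axis=0), len(segs)


def sw_locked_scalogram(x_full: np.ndarray, sws: list[SlowWaveEvent],
                        fs: float, freqs: np.ndarray = SCALO_FREQS
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trough-locked wavelet scalogram, z-scored per SW and per frequency
    against the −2…−1.5 s pre-trough baseline, then averaged across SWs.

    Returns (freqs, lags_s, z[F, T]).
    """
    if len(sws) < 5:
        raise ValueError("need at least 5 slow waves for a scalogram")
    lo = int(round(SCALO_WINDOW_S[0] * fs))
    hi = int(round(SCALO_WINDOW_S[1] * fs))
    lags = np.arange(lo, hi + 1) / fs
    base = (lags >= SCALO_BASELINE_S[0]) & (lags <= SCALO_BASELINE_S[1])
    n = x_full.shape[-1]
    mags = np.stack([_cfbs_mag_raw(x_full, fs, f0) for f0 in freqs])
    per_sw = []
    for sw in sws:
        t = int(round(sw.trough_s * fs))
        if t + lo < 0 or t + hi + 1 > n:
            continue
        m = mags[:, t + lo:t + hi + 1]
        mu = m[:, base].mean(axis=1, keepdims=True)
        sd = m[:, base].std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = (m - mu) / sd
        zz[np.broadcast_to(sd == 0, zz.shape)] = np.nan
        per_sw.append(zz)
    if not per_sw:
        raise ValueError("no slow wave fully inside the scalogram window")
    return freqs, lags, np.nanmean(per_sw, axis=0)


# ---------------------------------------------------------------------------
# Channel-level summary
# ---------------------------------------------------------------------------

def coupling_summary(x_full: np.ndarray, fs: float, indices: np.ndarray,
                     spindles: list[SpindleEvent], sws: list[SlowWaveEvent],
                     seed: int = 0, n_shuffles: int = N_SHUFFLES,
                     mrl_domain: str = "window") -> CouplingSummary:
    """All coupling metrics for one channel's detected events."""
    pairs = match_spindles_to_sw(spindles, sws)
    overlap = len(pairs) / len(spindles) if spindles else np.nan
    phase = phase_series_full(x_full, fs, indices)
    mrl, angle = coupling_stats(pairs, phase, fs)
    oz = overlap_null_z(spindles, sws, fs, n_shuffles=n_shuffles, seed=seed)
    mz = mrl_null_z(pairs, phase, fs, n_shuffles=n_shuffles, seed=seed + 1,
                    domain=mrl_domain)
    return CouplingSummary(
        n_spindles=len(spindles), n_overlapping=len(pairs),
        overlap_raw=overlap, overlap_z=oz, mrl_raw=mrl, mrl_z=mz,
        mean_angle_deg=angle)
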