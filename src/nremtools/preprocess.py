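"""Signal conditioning and epoch-level artifact rejection.

Conditioning: anti-aliased resampling to 128 Hz plus a 0.25 Hz high-pass
detrend.  Artifact rejection runs on pooled N2+N3 epochs, per channel,
applying three criteria in order:

1. flanking band power — delta (1–4 Hz) > mean + 2.5 SD or beta (16–25 Hz)
   > mean + 2 SD of up to 7 pooled-NREM epochs on each side;
2. clipping — more than 5 % of epoch samples pinned at the channel's global
   minimum or maximum;
3. a three-cycle iterative pass rejecting epochs whose RMS exceeds twice the
   whole surviving signal's SD, or whose Hjorth scores (sqrt-activity,
   mobility, complexity) more than double their whole-signal counterparts,
   with the reference recomputed from the survivors each cycle.

Band-power statistics for the flanking criterion are computed in decibels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import Hypnogram, Recording, logger

TARGET_FS = 128.0
HP_CUTOFF_HZ = 0.25
DELTA_BAND = (1.0, 4.0)
BETA_BAND = (16.0, 25.0)
DELTA_SD = 2.5
BETA_SD = 2.0
FLANK = 7
CLIP_FRACTION = 0.05
ITER_CYCLES = 3
ITER_SD = 2.0
MIN_FLANKERS = 3
MIN_SURVIVORS = 5

REASONS = ("none", "flank_delta", "flank_beta", "clipping",
           "iter_rms", "iter_hjorth")


@dataclass
class HjorthParams:
    activity: float     # µV², variance
    mobility: float     # sqrt(var(dx)/var(x))
    complexity: float   # mobility(dx)/mobility(x)


def hjorth(x: np.ndarray) -> HjorthParams:
    """Hjorth time-domain descriptors of one epoch."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    act = float(np.var(x))
    if act == 0:
        raise ValueError("Hjorth parameters undefined for a constant signal")
    dx = np.diff(x)
    mob = float(np.sqrt(np.var(dx) / act))
    vdx = np.var(dx)
    if vdx == 0:
        raise ValueError("Hjorth complexity undefined (constant derivative)")
    mob_dx = float(np.sqrt(np.var(np.diff(dx)) / vdx))
    return HjorthParams(activity=act, mobility=mob, complexity=mob_dx / mob)


class EpochMask:
    """Per-(channel, epoch) keep flags with a single rejection reason.

    Only pooled N2/N3 epochs are rejection candidates; other stages keep
    their samples (REM epochs feed the aperiodic analysis unmasked).
    """

    def __init__(self, channel_labels: list[str], n_epochs: int,
                 candidate: np.ndarray):
        self.channel_labels = list(channel_labels)
        self.keep = np.ones((len(channel_labels), n_epochs), dtype=bool)
        self.reason = np.full((len(channel_labels), n_epochs), "none",
                              dtype=object)
        self.candidate = np.asarray(candidate, dtype=bool)

    def reject(self, ch: int, epoch: int, reason: str) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        if self.keep[ch, epoch]:           # first criterion that fired wins
            self.keep[ch, epoch] = False
            self.reason[ch, epoch] = reason

    def surviving(self, ch: int) -> np.ndarray:
        return np.flatnonzero(self.candidate & self.keep[ch])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": lbl, "epoch_index": e,
             "keep": bool(self.keep[c, e]), "reason": self.reason[c, e]}
            for c, lbl in enumerate(self.channel_labels)
            for e in range(self.keep.shape[1])
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def condition_signal(rec: Recording) -> Recording:
    """Resample to 128 Hz (anti-aliased) and high-pass detrend at 0.25 Hz."""
    if rec.fs < TARGET_FS:
        raise ValueError(f"sampling rate {rec.fs} Hz below target {TARGET_FS} Hz")
    x = rec.samples
    if rec.fs != TARGET_FS:
        from fractions import Fraction
        frac = Fraction(TARGET_FS / rec.fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    sos = signal.butter(4, HP_CUTOFF_HZ, btype="highpass", fs=TARGET_FS,
                        output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    return Recording(samples=x, fs=TARGET_FS,
                     channel_labels=list(rec.channel_labels),
                     subject_id=rec.subject_id, family_id=rec.family_id,
                     group_label=rec.group_label)


# ---------------------------------------------------------------------------
# Rejection criteria
# ---------------------------------------------------------------------------

def _epochs_matrix(x: np.ndarray, fs: float, epoch_len_s: float) -> np.ndarray:
    spe = int(round(epoch_len_s * fs))
    n_ep = x.size // spe
    return x[:n_ep * spe].reshape(n_ep, spe)


def _band_power_db(epochs: np.ndarray, fs: float, band: tuple[float, float]
                   ) -> np.ndarray:
    """Per-epoch Welch band power (4-s Hann, 50% overlap) in decibels.

    The flanking statistics run on the dB scale, where band power across
    clean epochs is close to symmetric; on the linear scale the heavy right
    tail of delta power would trip the SD threshold on clean data.
    """
    f, p = signal.welch(epochs, fs=fs, window="hann", nperseg=int(4 * fs),
                        noverlap=int(2 * fs), detrend=False, axis=-1)
    sel = (f >= band[0]) & (f <= band[1])
    return 10.0 * np.log10(np.maximum(p[:, sel].mean(axis=1), 1e-30))


def new_mask(rec: Recording, h: Hypnogram) -> EpochMask:
    spe = int(round(h.epoch_len_s * rec.fs))
    n_ep = min(len(h), rec.n_samples // spe)
    candidate = np.zeros(n_ep, dtype=bool)
    stages = h.stage_array()[:n_ep]
    candidate[np.isin(stages, ["N2", "N3"])] = True
    return EpochMask(rec.channel_labels, n_ep, candidate)


def flanking_band_rejection(rec: Recording, h: Hypnogram,
                            mask: EpochMask) -> EpochMask:
    """Reject pooled-NREM epochs whose delta/beta power stands out from the
    flanking 14 pooled epochs (7 each side, fewer at the record edges)."""
    spe = int(round(h.epoch_len_s * rec.fs))
    for c in range(rec.n_channels):
        pooled = mask.surviving(c)
        if pooled.size == 0:
            continue
        epochs = np.stack([rec.samples[c, e * spe:(e + 1) * spe] for e in pooled])
        delta = _band_power_db(epochs, rec.fs, DELTA_BAND)
        beta = _band_power_db(epochs, rec.fs, BETA_BAND)
        for i, e in enumerate(pooled):
            flank = np.r_[delta[max(0, i - FLANK):i], delta[i + 1:i + 1 + FLANK]]
            flank_b = np.r_[beta[max(0, i - FLANK):i], beta[i + 1:i + 1 + FLANK]]
            if flank.size < MIN_FLANKERS:
                logger.warning("epoch %d on %s: only %d flankers, passing",
                               e, rec.channel_labels[c], flank.size)
                continue
            if delta[i] > flank.mean() + DELTA_SD * flank.std():
                mask.reject(c, e, "flank_delta")
            elif beta[i] > flank_b.mean() + BETA_SD * flank_b.std():
                mask.reject(c, e, "flank_beta")
    return mask


def clipping_rejection(rec: Recording, h: Hypnogram,
                       mask: EpochMask) -> EpochMask:
    """Reject epochs with > 5 % of samples pinned at the channel extremes."""
    spe = int(round(h.epoch_len_s * rec.fs))
    for c in range(rec.n_channels):
        x = rec.samples[c]
        gmin, gmax = x.min(), x.max()
        if gmin == gmax:
            logger.warning("channel %s is constant; rejecting all epochs",
                           rec.channel_labels[c])
            for e in mask.surviving(c):
                mask.reject(c, e, "clipping")
            continue
        for e in mask.surviving(c):
            seg = x[e * spe:(e + 1) * spe]
            frac = np.mean((seg == gmin) | (seg == gmax))
            if frac > CLIP_FRACTION:
                mask.reject(c, e, "clipping")
    return mask


def iterative_rejection(rec: Recording, h: Hypnogram,
                        mask: EpochMask) -> EpochMask:
    """Three cycles of outlier removal on RMS and the Hjorth parameters.

    An epoch is rejected when its RMS exceeds twice the standard deviation
    of the whole surviving signal (the epoch's own SD more than doubles the
    pooled one), or when a Hjorth score (sqrt-activity, mobility, complexity)
    more than doubles its whole-signal counterpart.  Whole-signal reference
    values are recomputed from the surviving epochs each cycle, so marginal
    epochs can fall in later cycles once gross outliers are gone.
    """
    spe = int(round(h.epoch_len_s * rec.fs))
    for c in range(rec.n_channels):
        for _cycle in range(ITER_CYCLES):
            surv = mask.surviving(c)
            if surv.size < MIN_SURVIVORS:
                logger.warning("channel %s: %d epochs left, stopping iterative "
                               "rejection early", rec.channel_labels[c], surv.size)
                break
            metrics = np.full((surv.size, 4), np.nan)
            for i, e in enumerate(surv):
                seg = rec.samples[c, e * spe:(e + 1) * spe]
                metrics[i, 0] = np.sqrt(np.mean(seg ** 2))
                try:
                    hp = hjorth(seg)
                    metrics[i, 1:] = (np.sqrt(hp.activity), hp.mobility,
                                      hp.complexity)
                except ValueError:
                    pass
            whole = np.concatenate(
                [rec.samples[c, e * spe:(e + 1) * spe] for e in surv])
            ref = np.array([np.sqrt(np.mean(whole ** 2)), np.nan, np.nan, np.nan])
            try:
                hw = hjorth(whole)
                ref[1:] = (np.sqrt(hw.activity), hw.mobility, hw.complexity)
            except ValueError:
                pass
            with np.errstate(invalid="ignore"):
                bad = metrics > ITER_SD * ref[None, :]
            rejected_any = False
            for i, e in enumerate(surv):
                if bad[i, 0] or bad[i, 1]:
                    mask.reject(c, e, "iter_rms")
                    rejected_any = True
                elif bad[i, 2] or bad[i, 3]:
                    mask.reject(c, e, "iter_hjorth")
                    rejected_any = True
            if not rejected_any:
                break
    return mask


def reject_artifacts(rec: Recording, h: Hypnogram) -> EpochMask:
    """Run the three criteria in their fixed order on pooled N2+N3 epochs."""
    mask = new_mask(rec, h)
    flanking_band_rejection(rec, h, mask)
    clipping_rejection(rec, h, mask)
    iterative_rejection(rec, h, mask)
    return mask


def apply_mask(rec: Recording, h: Hypnogram, mask: EpochMask
               ) -> dict[str, dict[str, np.ndarray]]:
    """Sample indices surviving per channel: ``{'nrem': ..., 'rem': ...}``.

    NREM indices are the kept N2+N3 epochs; REM indices are all REM epochs
    (the iterative criteria only police NREM, and ART is excluded by stage).
    """
    spe = int(round(h.epoch_len_s * rec.fs))
    stages = h.stage_array()
    out: dict[str, dict[str, np.ndarray]] = {}
    for c, lbl in enumerate(rec.channel_labels):
        nrem = mask.surviving(c)
        rem = np.flatnonzero(stages[:mask.keep.shape[1]] == "REM")
        def _samples(eps: np.ndarray) -> np.ndarray:
            if eps.size == 0:
                return np.empty(0, dtype=np.int64)
            return (eps[:, None] * spe + np.arange(spe)[None, :]).ravel()
        out[lbl] = {"nrem": _samples(nrem), "rem": _samples(rem)}
    return out


def stage_epoch_matrix(rec: Recording, h: Hypnogram, mask: EpochMask,
                       channel: int, stage: str) -> np.ndarray:
    """2-D (n_epochs, samples) matrix of surviving epochs of one stage."""
    spe = int(round(h.epoch_len_s * rec.fs))
    stages = h.stage_array()[:mask.keep.shape[1]]
    eps = np.flatnonzero((stages == stage) & mask.keep[channel])
    if eps.size == 0:
        return np.empty((0, spe))
    return np.stack([rec.samples[channel, e * spe:(e + 1) * spe] for e in eps])
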