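"""Power spectra, IRASA aperiodic/oscillatory decomposition and the
per-channel, per-stage spectral measures.

All PSDs use Welch's method with a 4-s Hann window advanced in 2-s steps,
averaged within 30-s epochs and then across epochs, at 0.25 Hz resolution on
[0.25, 20] Hz.  Power is kept linear (µV²/Hz) with a dB view (10·log10);
zero-power bins read a −300 dB floor sentinel.  IRASA resamples the signal by
irrational-pair factors h and 1/h, geometric-means each pair's PSD and takes
the median across the factor set to isolate the fractal (1/f) component; the
oscillatory component is the residual raw − fractal, which may be negative.
The aperiodic component is summarized by the slope β and intercept c of the
log-log line log P = c − β log f, i.e. P(f) = e^c f^(−β).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import Hypnogram, Recording
from .preprocess import EpochMask, stage_epoch_matrix

FMIN, FMAX = 0.25, 20.0
WELCH_WIN_S = 4.0
EPOCH_LEN_S = 30.0
DB_FLOOR = -300.0
SLOW_DELTA_BAND = (0.25, 1.5)   # Hz; the paper's methods use <1.5 Hz
SIGMA_BAND = (10.0, 16.0)
FIT_RANGE_HZ = (1.0, 20.0)
DEFAULT_HSET = np.round(np.arange(1.1, 1.9001, 0.05), 4)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray       # linear, µV²/Hz (may be negative for kind="oscillatory")
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be 1-D and equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def db(self) -> np.ndarray:
        """10·log10(power) with a −300 dB floor for non-positive bins."""
        out = np.full_like(self.power, DB_FLOOR)
        pos = self.power > 10 ** (DB_FLOOR / 10.0)
        out[pos] = 10.0 * np.log10(self.power[pos])
        return out

    def select(self, lo: float, hi: float) -> "PowerSpectrum":
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.freqs[sel], self.power[sel], self.kind)


@dataclass
class AperiodicFit:
    slope: float
    intercept: float
    fit_range_hz: tuple[float, float]
    rmse: float


@dataclass
class SigmaPeak:
    freq_hz: float
    fallback: bool = False


def _as_epochs(samples, fs: float, epoch_len_s: float = EPOCH_LEN_S) -> np.ndarray:
    """Coerce 1-D/2-D input into an (n_epochs, samples) matrix.

    1-D input longer than one epoch is cut into whole epochs (remainder
    dropped); shorter input becomes a single segment.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 2:
        return x
    spe = int(round(epoch_len_s * fs))
    if x.size < int(WELCH_WIN_S * fs):
        raise ValueError(f"need at least {WELCH_WIN_S} s of data")
    if x.size < spe:
        return x[None, :]
    n_ep = x.size // spe
    return x[:n_ep * spe].reshape(n_ep, spe)


def _welch_rows(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    f, p = signal.welch(epochs, fs=fs, window="hann",
                        nperseg=int(WELCH_WIN_S * fs),
                        noverlap=int(WELCH_WIN_S * fs / 2),
                        detrend=False, axis=-1)
    return f, p


def welch_psd(samples, fs: float, fmin: float = FMIN,
              fmax: float = FMAX) -> PowerSpectrum:
    """Welch PSD (4-s Hann, 50 % overlap) averaged per epoch then across
    epochs, restricted to [fmin, fmax]."""
    epochs = _as_epochs(samples, fs)
    f, p = _welch_rows(epochs, fs)
    mean_p = p.mean(axis=0)
    sel = (f >= fmin) & (f <= fmax)
    return PowerSpectrum(f[sel], mean_p[sel], kind="raw")


def welch_psd_zscored(samples, fs: float, fmin: float = FMIN,
                      fmax: float = FMAX) -> PowerSpectrum:
    """As :func:`welch_psd` after standardizing the signal in the time
    domain over all provided samples (removes broadband scale)."""
    epochs = _as_epochs(samples, fs)
    sd = epochs.std()
    if sd == 0:
        raise ValueError("zero-variance signal cannot be z-scored")
    z = (epochs - epochs.mean()) / sd
    ps = welch_psd(z, fs, fmin, fmax)
    return PowerSpectrum(ps.freqs, ps.power, kind="zscored")


def multitaper_spectrogram(samples, fs: float, win_s: float = 30.0,
                           step_s: float = 10.0, bandwidth_hz: float = 1.0,
                           fmin: float = FMIN, fmax: float = FMAX
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multitaper spectrogram: Slepian tapers with half-bandwidth
    bandwidth_hz/2 over win_s windows (NW = win_s·bandwidth/2, K = 2NW−1).

    Returns (freqs, window_centers_s, power[F, T]) in µV²/Hz.
    """
    x = np.asarray(samples, dtype=float).ravel()
    nwin = int(round(win_s * fs))
    step = int(round(step_s * fs))
    if x.size < nwin:
        raise ValueError(f"need at least {win_s} s of data")
    nw = win_s * bandwidth_hz / 2.0
    k = max(1, int(2 * nw - 1))
    tapers = signal.windows.dpss(nwin, nw, Kmax=k)
    tapers /= np.sqrt(np.sum(tapers ** 2, axis=1, keepdims=True))
    starts = np.arange(0, x.size - nwin + 1, step)
    f = np.fft.rfftfreq(nwin, 1.0 / fs)
    sel = (f >= fmin) & (f <= fmax)
    out = np.empty((sel.sum(), starts.size))
    for j, s in enumerate(starts):
        seg = x[s:s + nwin]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        psd = (np.abs(spec) ** 2).mean(axis=0) / fs
        psd[1:-1] *= 2.0
        out[:, j] = psd[sel]
    return f[sel], (starts + nwin / 2.0) / fs, out


def irasa(samples, fs: float, hset=None, fmin: float = FMIN,
          fmax: float = FMAX) -> tuple[PowerSpectrum, PowerSpectrum]:
    """IRASA decomposition into (fractal, oscillatory) spectra.

    For each resampling factor h the signal is stretched by h and compressed
    by 1/h (polyphase anti-aliased resampling); both PSDs are computed on the
    nominal frequency grid and geometric-mean-paired.  The median across the
    factor set estimates the fractal spectrum; oscillatory = raw − fractal.
    """
    if hset is None:
        hset = DEFAULT_HSET
    hset = np.asarray(hset, dtype=float)
    if hset.size == 0:
        raise ValueError("hset must not be empty")
    if np.any(hset <= 1):
        raise ValueError("all resampling factors must exceed 1")
    epochs = _as_epochs(samples, fs)
    if epochs.shape[0] * epochs.shape[1] < 60 * fs:
        raise ValueError("IRASA needs at least 60 s of data")
    f, raw_rows = _welch_rows(epochs, fs)
    raw = raw_rows.mean(axis=0)
    geo = np.empty((hset.size, f.size))
    for i, h in enumerate(hset):
        frac = Fraction(h).limit_denominator(100)
        up = signal.resample_poly(epochs, frac.numerator, frac.denominator, axis=1)
        dn = signal.resample_poly(epochs, frac.denominator, frac.numerator, axis=1)
        _, pu = _welch_rows(up, fs)
        _, pd_ = _welch_rows(dn, fs)
        geo[i] = np.sqrt(pu.mean(axis=0) * pd_.mean(axis=0))
    fractal = np.median(geo, axis=0)
    sel = (f >= fmin) & (f <= fmax)
    frac_ps = PowerSpectrum(f[sel], fractal[sel], kind="fractal")
    osc_ps = PowerSpectrum(f[sel], raw[sel] - fractal[sel], kind="oscillatory")
    return frac_ps, osc_ps


def fit_aperiodic(fractal: PowerSpectrum,
                  fit_range_hz: tuple[float, float] = FIT_RANGE_HZ
                  ) -> AperiodicFit:
    """Least-squares line on (log f, log P): log P = intercept − slope·log f."""
    lo, hi = fit_range_hz
    sel = (fractal.freqs >= lo) & (fractal.freqs <= hi)
    fr, pw = fractal.freqs[sel], fractal.power[sel]
    pos = pw > 0
    if pos.sum() < 5:
        raise ValueError("need at least 5 positive power values in fit range")
    lf, lp = np.log(fr[pos]), np.log(pw[pos])
    b, a = np.polyfit(lf, lp, 1)    # lp = b*lf + a
    resid = lp - (b * lf + a)
    return AperiodicFit(slope=-b, intercept=a, fit_range_hz=(lo, hi),
                        rmse=float(np.sqrt(np.mean(resid ** 2))))


def peak_sigma_frequency(oscillatory: PowerSpectrum,
                         band: tuple[float, float] = SIGMA_BAND,
                         fallback_hz: float = 13.0) -> SigmaPeak:
    """Frequency of maximum oscillatory power in the sigma band; falls back
    to 13 Hz (flagged) when no bin has positive oscillatory power."""
    sel = (oscillatory.freqs >= band[0]) & (oscillatory.freqs <= band[1])
    if not np.any(sel):
        raise ValueError("oscillatory spectrum does not cover the sigma band")
    pw = oscillatory.power[sel]
    if np.nanmax(pw) <= 0:
        return SigmaPeak(freq_hz=fallback_hz, fallback=True)
    return SigmaPeak(freq_hz=float(oscillatory.freqs[sel][np.argmax(pw)]))


def band_power(ps: PowerSpectrum, band_hz: tuple[float, float]) -> float:
    """Mean of the dB values across bins with lo ≤ f ≤ hi."""
    lo, hi = band_hz
    sel = (ps.freqs >= lo) & (ps.freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band_hz} contains no frequency bins")
    return float(ps.db[sel].mean())


def spectral_summary(rec: Recording, h: Hypnogram, mask: EpochMask,
                     slow_delta_band: tuple[float, float] = SLOW_DELTA_BAND
                     ) -> list[dict]:
    """The 12 spectral measures per channel: slow-delta power, sigma power
    and sigma peak (z-scored-input oscillatory spectrum) for N2 and N3;
    aperiodic slope and intercept (raw fractal fit) for N2, N3 and REM.
    """
    rows: list[dict] = []

    def add(ch: str, stage: str, measure: str, value: float) -> None:
        rows.append({"channel": ch, "stage": stage, "measure": measure,
                     "value": value})

    for c, lbl in enumerate(rec.channel_labels):
        for stage in ("N2", "N3"):
            epochs = stage_epoch_matrix(rec, h, mask, c, stage)
            if epochs.shape[0] * (epochs.shape[1] if epochs.ndim == 2 else 0) \
                    < 60 * rec.fs:
                for m in ("slow_delta_power_db", "sigma_power_db", "sigma_peak_hz"):
                    add(lbl, stage, m, np.nan)
                continue
            sd = epochs.std()
            z = (epochs - epochs.mean()) / sd if sd > 0 else epochs
            _, osc = irasa(z, rec.fs)
            add(lbl, stage, "slow_delta_power_db", band_power(osc, slow_delta_band))
            add(lbl, stage, "sigma_power_db", band_power(osc, SIGMA_BAND))
            add(lbl, stage, "sigma_peak_hz", peak_sigma_frequency(osc).freq_hz)
        for stage in ("N2", "N3", "REM"):
            epochs = stage_epoch_matrix(rec, h, mask, c, stage)
            if epochs.shape[0] * (epochs.shape[1] if epochs.ndim == 2 else 0) \
                    < 60 * rec.fs:
                add(lbl, stage, "aperiodic_slope", np.nan)
                add(lbl, stage, "aperiodic_intercept", np.nan)
                continue
            frac, _ = irasa(epochs, rec.fs)
            try:
                fit = fit_aperiodic(frac)
                add(lbl, stage, "aperiodic_slope", fit.slope)
                add(lbl, stage, "aperiodic_intercept", fit.intercept)
            except ValueError:
                add(lbl, stage, "aperiodic_slope", np.nan)
                add(lbl, stage, "aperiodic_intercept", np.nan)
    return rows
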