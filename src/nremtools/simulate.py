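"""Synthetic polysomnography with known ground truth.

Each channel is an independent realization of a 1/f (aperiodic) Gaussian
background with spectral exponent ``aperiodic_slope_true``, onto which
slow-wave negative half-waves and sigma-band spindle bursts are superposed in
N2/N3 epochs.  A configurable fraction of spindles is phase-coupled to a host
slow wave: the spindle peak sample is drawn from the ±1.5 s window around the
host trough with probability proportional to the von Mises density (preferred
angle ``mu_deg``, concentration ``kappa``) evaluated at the local slow-wave
phase (analysis convention: descending zero crossing = 0°, trough = 90°).
At ``kappa=0`` this reduces exactly to uniform-in-time placement — the same
distribution the coupling module's shuffle null draws from.  Injected
down-states carry flanking up-state lobes so the slow-oscillation phase
advances nearly uniformly around each trough.

The generator is the test bench for every downstream stage: it returns the
recording, the hypnogram it emulated, and per-event ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import Hypnogram, Recording, logger

MATCH_WINDOW_S = 1.5   # spindle peak vs SW trough overlap window
MIN_GAP_S = 1.0        # same-type inter-event gap, keeps truth matching unique
UPSTATE_FRACTION = 0.75  # amplitude of the flanking up-state lobes vs down-state


@dataclass
class SimParams:
    """Generative parameters; defaults describe a quiet, strongly coupled
    single-channel NREM recording (amplitudes in µV, rates per minute)."""

    fs: float = 128.0
    duration_s: float = 600.0
    n_channels: int = 1
    aperiodic_slope_true: float = 1.5
    aperiodic_intercept_true: float | None = None
    background_rms_uV: float = 45.0
    sw_density_per_min: float = 12.0
    sw_amp_mean_uV: float = 100.0
    sw_amp_sd_uV: float = 25.0
    sw_dur_lo_s: float = 0.8
    sw_dur_hi_s: float = 1.4
    sp_density_per_min: float = 3.0
    sp_freq_hz: float = 13.0
    sp_amp_uV: float = 15.0
    sp_dur_lo_s: float = 0.8
    sp_dur_hi_s: float = 1.2
    p_coupled: float = 0.5
    mu_deg: float = 30.0
    kappa: float = 3.0
    uncoupled_placement: str = "avoid"   # "avoid" SWs, or "uniform" in NREM
    stage_sequence: Hypnogram | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 60:
            raise ValueError("duration_s must be at least 60 s")
        if not (0 <= self.p_coupled <= 1):
            raise ValueError("p_coupled must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.sw_density_per_min < 0 or self.sp_density_per_min < 0:
            raise ValueError("densities must be non-negative")
        if self.uncoupled_placement not in ("avoid", "uniform"):
            raise ValueError("uncoupled_placement must be 'avoid' or 'uniform'")
        for lo, hi, b0, b1, name in [
                (self.sw_dur_lo_s, self.sw_dur_hi_s, 0.5, 2.0, "sw"),
                (self.sp_dur_lo_s, self.sp_dur_hi_s, 0.5, 3.0, "sp")]:
            if not (b0 <= lo <= hi <= b1):
                raise ValueError(f"{name} durations must satisfy "
                                 f"{b0} <= lo <= hi <= {b1}")


@dataclass
class GroundTruth:
    """Per-event truth tables: tuples are in seconds from record start."""

    sw_events: list[tuple] = field(default_factory=list)
    # (channel, start_s, trough_s, end_s, amp_uV)
    sp_events: list[tuple] = field(default_factory=list)
    # (channel, start_s, peak_s, end_s, freq_hz, coupled, true_phase_deg)


def default_hypnogram(duration_s: float, epoch_len_s: float = 30.0) -> Hypnogram:
    """A plain macro-structure: brief wake, descent into N2/N3, some REM."""
    cycle = (["W"] * 2 + ["N1"] * 2 + ["N2"] * 20 + ["N3"] * 20
             + ["N2"] * 10 + ["REM"] * 10)
    n = int(np.ceil(duration_s / epoch_len_s))
    stages = (cycle * (n // len(cycle) + 1))[:n]
    return Hypnogram(stages=stages, epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# Waveform kernels
# ---------------------------------------------------------------------------

def make_sw_kernel(amp_uV: float, dur_s: float, fs: float) -> np.ndarray:
    """Single negative half-sine: starts/ends at 0 µV, minimum −amp at dur/2."""
    if not 0.5 <= dur_s <= 2.0:
        raise ValueError("slow-wave duration must lie in [0.5, 2] s")
    if amp_uV <= 0:
        raise ValueError("amplitude must be positive")
    n = int(round(dur_s * fs))
    t = np.arange(n + 1) / fs
    return -amp_uV * np.sin(np.pi * t / dur_s)


def make_spindle_kernel(freq_hz: float, dur_s: float, amp_uV: float,
                        fs: float) -> np.ndarray:
    """Sinusoid under a raised-cosine (Hann) envelope peaking at amp_uV."""
    if not 10.0 <= freq_hz <= 16.0:
        raise ValueError("spindle frequency must lie in [10, 16] Hz")
    if not 0.5 <= dur_s <= 3.0:
        raise ValueError("spindle duration must lie in [0.5, 3] s")
    if amp_uV <= 0:
        raise ValueError("amplitude must be positive")
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))
    return amp_uV * env * np.cos(2 * np.pi * freq_hz * (t - dur_s / 2))


def draw_coupling_phase(mu_deg: float, kappa: float,
                        rng: np.random.Generator) -> float:
    """One angle (degrees, [0, 360)) from von Mises(mu, kappa); kappa=0 is
    circular-uniform."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return float(rng.uniform(0.0, 360.0))
    draw = sps.vonmises.rvs(kappa, loc=np.deg2rad(mu_deg), random_state=rng)
    return float(np.rad2deg(draw) % 360.0)


# ---------------------------------------------------------------------------
# Background and placement machinery
# ---------------------------------------------------------------------------

def _shaped_background(n: int, fs: float, beta: float, rng: np.random.Generator,
                       rms_uV: float, intercept: float | None) -> np.ndarray:
    """FFT-filtered white noise with amplitude profile f^(−beta/2)."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * amp, n)
    if intercept is not None:
        # unit white noise has one-sided PSD 2/fs, so the shaped series has
        # S(f) = (2/fs) f^(-beta); rescale to e^intercept * f^(-beta)
        x *= np.sqrt(np.exp(intercept) * fs / 2.0)
    else:
        x *= rms_uV / x.std()
    return x


def _nrem_runs(h: Hypnogram, fs: float, n_samples: int) -> list[tuple[int, int]]:
    """Contiguous [start, stop) sample runs of N2/N3 epochs."""
    spe = int(round(h.epoch_len_s * fs))
    mask = np.isin(h.stage_array(), ["N2", "N3"])
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            a, b = i * spe, min(j * spe, n_samples)
            if b > a:
                runs.append((a, b))
            i = j
        else:
            i += 1
    return runs


def _feasible_or_raise(density: float, dur_hi: float, label: str) -> None:
    max_density = 60.0 / (dur_hi + MIN_GAP_S)
    if density > max_density:
        raise ValueError(
            f"{label} density {density:g}/min infeasible under the {MIN_GAP_S} s "
            f"gap constraint; maximum feasible is {max_density:.2f}/min")


def _place_centers(rng: np.random.Generator, n_events: int,
                   runs: list[tuple[int, int]], half_span: int,
                   taken: list[tuple[int, int]], fs: float,
                   max_tries: int = 2000) -> list[int]:
    """Draw event centers uniformly over NREM runs, whole event inside one
    run, centers ≥ MIN_GAP_S + spans apart from ``taken`` intervals."""
    gap = int(MIN_GAP_S * fs)
    weights = np.array([b - a for a, b in runs], dtype=float)
    if not runs or weights.sum() == 0:
        return []
    weights /= weights.sum()
    placed: list[int] = []
    for _ in range(n_events):
        for _try in range(max_tries):
            ri = rng.choice(len(runs), p=weights)
            a, b = runs[ri]
            if b - a <= 2 * half_span + 2:
                continue
            c = int(rng.integers(a + half_span + 1, b - half_span - 1))
            lo, hi = c - half_span - gap, c + half_span + gap
            if all(hi < s or lo > e for s, e in taken):
                taken.append((c - half_span, c + half_span))
                placed.append(c)
                break
        else:
            logger.warning("could not place all requested events (placed %d/%d)",
                           len(placed), n_events)
            break
    return placed


def simulate_recording(p: SimParams) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Generate a multichannel recording, its hypnogram and ground truth.

    Deterministic for a fixed ``p.seed``; channels are independent
    realizations sharing the hypnogram and parameters.
    """
    # deferred import: coupling/events have no dependency on this module
    from .coupling import sw_phase_series
    from .events import sw_bandpass

    _feasible_or_raise(p.sw_density_per_min, p.sw_dur_hi_s, "slow-wave")
    _feasible_or_raise(p.sp_density_per_min, p.sp_dur_hi_s, "spindle")

    fs = p.fs
    n = int(round(p.duration_s * fs))
    h = p.stage_sequence or default_hypnogram(p.duration_s)
    runs = _nrem_runs(h, fs, n)
    nrem_minutes = sum(b - a for a, b in runs) / fs / 60.0

    rng = np.random.default_rng(p.seed)
    data = np.empty((p.n_channels, n))
    truth = GroundTruth()

    for ch in range(p.n_channels):
        label = f"EEG{ch + 1:03d}"
        x = _shaped_background(n, fs, p.aperiodic_slope_true, rng,
                               p.background_rms_uV, p.aperiodic_intercept_true)

        # --- slow waves -----------------------------------------------------
        n_sw = rng.poisson(p.sw_density_per_min * nrem_minutes)
        sw_taken: list[tuple[int, int]] = []
        sw_list: list[tuple[int, int, int, float]] = []  # start, trough, end, amp
        clean_sw = np.zeros(n)
        durs = rng.uniform(p.sw_dur_lo_s, p.sw_dur_hi_s, size=n_sw)
        if p.sw_amp_sd_uV > 0:
            s2 = np.log(1.0 + (p.sw_amp_sd_uV / p.sw_amp_mean_uV) ** 2)
            amps = rng.lognormal(np.log(p.sw_amp_mean_uV) - s2 / 2.0,
                                 np.sqrt(s2), size=n_sw)
        else:
            amps = np.full(n_sw, p.sw_amp_mean_uV)
        for k in range(n_sw):
            half = int(round(durs[k] * fs)) // 2 + 1
            centers = _place_centers(rng, 1, runs, half, sw_taken, fs)
            if not centers:
                continue
            kern = make_sw_kernel(amps[k], durs[k], fs)
            start = centers[0] - len(kern) // 2
            clean_sw[start:start + len(kern)] += kern
            # flanking up-states: half-amplitude positive lobes before and
            # after the down-state, giving the slow oscillation a continuous,
            # near-uniform phase advance across the trough's neighbourhood
            lobe = -UPSTATE_FRACTION * kern[:-1]
            a0 = start - lobe.size
            if a0 >= 0:
                clean_sw[a0:start] += lobe
            b0 = start + len(kern)
            if b0 + lobe.size <= n:
                clean_sw[b0:b0 + lobe.size] += lobe
            trough = start + int(np.argmin(kern))
            sw_list.append((start, trough, start + len(kern) - 1, amps[k]))
        sw_list.sort()

        # slow-wave phase of the pre-spindle signal (background + SW train)
        # under the analysis convention; spindles contribute nothing to the
        # 0.25-4 Hz band, so this is the phase the analysis will measure
        phase = (sw_phase_series(sw_bandpass(x + clean_sw, fs), fs)
                 if sw_list else None)

        # --- spindles -------------------------------------------------------
        n_sp = rng.poisson(p.sp_density_per_min * nrem_minutes)
        n_coupled = rng.binomial(n_sp, p.p_coupled) if n_sp else 0
        sp_taken: list[tuple[int, int]] = []
        sp_list: list[tuple[int, int, int, bool, float]] = []
        hosts = rng.permutation(len(sw_list))[:n_coupled] if sw_list else []
        win = int(MATCH_WINDOW_S * fs)
        for hi_idx in hosts:
            _, trough, _, _ = sw_list[hi_idx]
            dur = rng.uniform(p.sp_dur_lo_s, p.sp_dur_hi_s)
            half = int(round(dur * fs)) // 2 + 1
            lo = max(trough - win, half + 1)
            hi = min(trough + win, n - half - 1)
            if hi <= lo or phase is None:
                continue
            # phase-conditioned rate modulation: the peak sample is drawn
            # from the ±1.5 s window with probability proportional to the
            # von Mises density at the local slow-wave phase, so kappa=0
            # reduces exactly to uniform-in-time placement
            seg = phase[lo:hi + 1]
            w = np.exp(p.kappa * np.cos(np.deg2rad(seg - p.mu_deg)))
            w /= w.sum()
            peak = lo + int(rng.choice(seg.size, p=w))
            theta = float(phase[peak])
            gap = int(MIN_GAP_S * fs)
            span = (peak - half - gap, peak + half + gap)
            if not all(span[1] < s or span[0] > e for s, e in sp_taken):
                continue
            in_run = any(a <= peak - half and peak + half < b for a, b in runs)
            if not in_run:
                continue
            sp_taken.append((peak - half, peak + half))
            sp_list.append((peak, int(round(dur * fs)), 1, True, theta))
        n_uncoupled = n_sp - len(sp_list)
        for _ in range(n_uncoupled):
            dur = rng.uniform(p.sp_dur_lo_s, p.sp_dur_hi_s)
            half = int(round(dur * fs)) // 2 + 1
            for _try in range(200):
                centers = _place_centers(rng, 1, runs, half, sp_taken, fs)
                if not centers:
                    break
                c = centers[0]
                if p.uncoupled_placement == "avoid" and sw_list:
                    troughs = np.array([t for _, t, _, _ in sw_list])
                    if np.min(np.abs(troughs - c)) < (MATCH_WINDOW_S + 0.5) * fs:
                        sp_taken.pop()   # undo reservation, retry elsewhere
                        continue
                sp_list.append((c, int(round(dur * fs)), 1, False, np.nan))
                break

        for peak, ndur, _, coupled, theta in sp_list:
            kern = make_spindle_kernel(p.sp_freq_hz, ndur / fs, p.sp_amp_uV, fs)
            start = peak - len(kern) // 2
            x[start:start + len(kern)] += kern
            truth.sp_events.append(
                (label, start / fs, peak / fs, (start + len(kern) - 1) / fs,
                 p.sp_freq_hz, coupled, theta))
        x += clean_sw
        for start, trough, end, amp in sw_list:
            truth.sw_events.append(
                (label, start / fs, trough / fs, end / fs, amp))
        data[ch] = x

    rec = Recording(samples=data, fs=fs,
                    channel_labels=[f"EEG{c + 1:03d}" for c in range(p.n_channels)])
    truth.sw_events.sort(key=lambda e: (e[0], e[1]))
    truth.sp_events.sort(key=lambda e: (e[0], e[1]))
    return rec, h, truth


# ---------------------------------------------------------------------------
# Artifact injection (fixtures for the preprocessing criteria)
# ---------------------------------------------------------------------------

ARTIFACT_MODES = ("high_delta", "high_beta", "clipping", "high_rms")


def inject_artifact_epochs(rec: Recording, h: Hypnogram,
                           which_epochs: list[int], mode: str,
                           channel: int = 0, seed: int = 0,
                           clip_fraction: float = 0.06,
                           scale: float = 10.0) -> Recording:
    """Return a copy of ``rec`` with the selected epochs altered per mode.

    high_delta / high_beta add a large in-band sinusoid; clipping pins a
    fraction of samples to the channel's extreme value; high_rms multiplies
    the epoch by ``scale``.
    """
    if mode not in ARTIFACT_MODES:
        raise ValueError(f"unknown artifact mode {mode!r}; choose from {ARTIFACT_MODES}")
    spe = int(round(h.epoch_len_s * rec.fs))
    n_ep = rec.n_samples // spe
    for e in which_epochs:
        if not 0 <= e < n_ep:
            raise ValueError(f"epoch index {e} out of range (0..{n_ep - 1})")
    out = Recording(samples=rec.samples.copy(), fs=rec.fs,
                    channel_labels=list(rec.channel_labels),
                    subject_id=rec.subject_id, family_id=rec.family_id,
                    group_label=rec.group_label)
    rng = np.random.default_rng(seed)
    x = out.samples[channel]
    rms = np.sqrt(np.mean(x ** 2)) or 1.0
    for e in which_epochs:
        sl = slice(e * spe, (e + 1) * spe)
        t = np.arange(spe) / rec.fs
        if mode == "high_delta":
            x[sl] += 8.0 * rms * np.sin(2 * np.pi * 2.0 * t)
        elif mode == "high_beta":
            x[sl] += 8.0 * rms * np.sin(2 * np.pi * 20.0 * t)
        elif mode == "high_rms":
            x[sl] *= scale
        elif mode == "clipping":
            peak = np.max(np.abs(out.samples[channel]))
            idx = rng.choice(spe, size=int(np.ceil(clip_fraction * spe)),
                             replace=False)
            x[sl.start + idx] = peak
    return out
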