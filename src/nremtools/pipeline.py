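"""End-to-end orchestration: simulate → condition → reject → spectral →
detect → couple → feature table."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import events as ev
from . import preprocess as pp
from . import spectral as sp
from .io import (Hypnogram, Recording, logger, make_feature_table,
                 write_edf, write_feature_table, write_hypnogram)
from .simulate import GroundTruth, SimParams, simulate_recording


def analyze_recording(rec: Recording, h: Hypnogram, seed: int = 0,
                      cfg: ev.DetectorConfig | None = None,
                      condition: bool = True) -> dict:
    """Run the full analysis on one recording.

    Returns a dict with the feature table (``features``), the epoch mask,
    per-channel detected events and coupling summaries.  The spindle
    detector's center frequency is individualized per channel from the N2/N3
    oscillatory sigma peak unless ``cfg`` pins ``sp_center_hz``.
    """
    base_cfg = cfg
    if condition:
        rec = pp.condition_signal(rec)
    mask = pp.reject_artifacts(rec, h)
    idx = pp.apply_mask(rec, h, mask)
    spec_rows = sp.spectral_summary(rec, h, mask)
    spec_df = pd.DataFrame(spec_rows)

    rows = list(spec_rows)
    spindles: dict[str, list] = {}
    sws: dict[str, list] = {}
    summaries: dict[str, cpl.CouplingSummary] = {}
    for c, lbl in enumerate(rec.channel_labels):
        nrem = idx[lbl]["nrem"]
        minutes = nrem.size / rec.fs / 60.0
        x = rec.samples[c]
        if base_cfg is not None:
            ch_cfg = base_cfg
        else:
            peaks = spec_df.query("channel == @lbl and measure == 'sigma_peak_hz'")
            vals = peaks["value"].dropna()
            center = float(np.clip(vals.mean(), 10.0, 16.0)) if len(vals) else 13.0
            ch_cfg = ev.DetectorConfig(sp_center_hz=center)
        if minutes == 0:
            logger.warning("channel %s: no surviving N2/N3 data", lbl)
            spindles[lbl], sws[lbl] = [], []
            summaries[lbl] = cpl.CouplingSummary(0, 0, *([np.nan] * 5))
        else:
            sp_list = ev.detect_spindles(x, rec.fs, nrem, ch_cfg)
            sw_list = ev.detect_slow_waves(x, rec.fs, nrem, ch_cfg)
            for e in sp_list:
                e.channel = lbl
            for e in sw_list:
                e.channel = lbl
            spindles[lbl], sws[lbl] = sp_list, sw_list
            ch_seed = int(np.random.SeedSequence([seed, c]).generate_state(1)[0]
                          % (2 ** 31))
            summaries[lbl] = cpl.coupling_summary(
                x, rec.fs, nrem, sp_list, sw_list, seed=ch_seed,
                mrl_domain=ch_cfg.mrl_shuffle_domain)

        s = summaries[lbl]
        sp_list, sw_list = spindles[lbl], sws[lbl]

        def _mean(vals):
            vals = [v for v in vals if np.isfinite(v)]
            return float(np.mean(vals)) if vals else np.nan

        dens = (ev.event_density(sp_list, minutes) if minutes else np.nan,
                ev.event_density(sw_list, minutes) if minutes else np.nan)
        nrem_rows = {
            "spindle_density_per_min": dens[0],
            "spindle_amplitude_uv": _mean([e.amplitude_uV for e in sp_list]),
            "spindle_frequency_hz": _mean([e.frequency_hz for e in sp_list]),
            "sw_density_per_min": dens[1],
            "sw_amplitude_uv": _mean([e.amplitude_uV for e in sw_list]),
            "sw_duration_s": _mean([e.duration_s for e in sw_list]),
            "coupling_overlap_z": s.overlap_z,
            "coupling_mrl_z": s.mrl_z,
            "coupling_mean_angle_deg": s.mean_angle_deg,
        }
        rows.extend({"channel": lbl, "stage": "NREM", "measure": m, "value": v}
                    for m, v in nrem_rows.items())

    for r in rows:
        r["subject_id"] = rec.subject_id
    features = make_feature_table(rows)
    return {"features": features, "mask": mask, "spindles": spindles,
            "sws": sws, "coupling": summaries, "recording": rec}


def run_all(params: SimParams, outdir: str | Path, seed: int | None = None
            ) -> pd.DataFrame:
    """Simulate a recording, write its files, analyze it and write the
    feature table.  Deterministic for fixed params/seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        params = replace(params, seed=seed)
    rec, h, truth = simulate_recording(params)
    write_edf(rec, outdir / "recording.edf")
    write_hypnogram(h, outdir / "hypnogram.csv")
    write_ground_truth(truth, outdir)
    res = analyze_recording(rec, h, seed=params.seed, condition=True)
    write_feature_table(res["features"], outdir / "features.csv")
    res["mask"].to_frame().to_csv(outdir / "epoch_mask.csv", index=False)
    _write_events(res, outdir / "events.csv")
    return res["features"]


def write_ground_truth(truth: GroundTruth, outdir: Path) -> None:
    pd.DataFrame(truth.sw_events, columns=[
        "channel", "start_s", "trough_s", "end_s", "amp_uV"]).to_csv(
        outdir / "truth_sw.csv", index=False)
    pd.DataFrame(truth.sp_events, columns=[
        "channel", "start_s", "peak_s", "end_s", "freq_hz", "coupled",
        "true_phase_deg"]).to_csv(outdir / "truth_spindles.csv", index=False)


def _write_events(res: dict, path: Path) -> None:
    rows = []
    for lbl, evs in res["spindles"].items():
        rows += [{"channel": lbl, "type": "spindle", "start_s": e.start_s,
                  "peak_or_trough_s": e.peak_s, "end_s": e.end_s,
                  "amplitude_uV": e.amplitude_uV,
                  "frequency_hz": e.frequency_hz,
                  "duration_s": e.duration_s} for e in evs]
    for lbl, evs in res["sws"].items():
        rows += [{"channel": lbl, "type": "sw", "start_s": e.start_s,
                  "peak_or_trough_s": e.trough_s, "end_s": e.end_s,
                  "amplitude_uV": e.amplitude_uV, "frequency_hz": np.nan,
                  "duration_s": e.duration_s} for e in evs]
    pd.DataFrame(rows, columns=["channel", "type", "start_s",
                                "peak_or_trough_s", "end_s", "amplitude_uV",
                                "frequency_hz", "duration_s"]).to_csv(
        path, index=False)
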