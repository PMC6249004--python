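"""Stage runner tying the analysis modules into a reproducible pipeline.

Each stage reads the session container (and, where noted, the tabular
output of an earlier stage), writes TSV tables and a small JSON summary
into the output directory, and logs the configuration hash and seed so a
run is identified by (config, seed).  Stages:

``simulate``     write a synthetic session + ground-truth sidecar
``spectrogram``  per-trial normalized spectrograms, gamma envelopes,
                 switch-locked permutation test
``bursts``       burst detection and timing/amplitude statistics
                 (requires the envelope tables from ``spectrogram``)
``behavior``     scalar-timing fit and RT regression
``decode``       correct/error logistic decoding curves
``sta``          spike-triggered-average band powers + ANOVA
``coherence``    pairwise PLV vs electrode distance
``report``       collate stage summaries into ``summary.json``
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, bursts, coherence, decode, spectral, spikefield, synth
from .config import AnalysisConfig, TaskConfig
from .session import SessionData, read_session, write_session

log = logging.getLogger("metronome")

STAGES = ("simulate", "spectrogram", "bursts", "behavior", "decode", "sta",
          "coherence", "report")


class UsageError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    return str(o)


def _save_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default,
                               sort_keys=True) + "\n")


def _config_hash(task: TaskConfig, analysis: AnalysisConfig) -> str:
    blob = json.dumps([asdict(task), asdict(analysis)], sort_keys=True,
                      default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _envelope_path(out_dir: Path, tempo: float) -> Path:
    return out_dir / f"envelope_t{int(round(tempo))}.tsv"


def _save_envelopes(envs, tempo, out_dir: Path) -> None:
    # trials with earlier go-cues are shorter: pad to the longest with NaN
    longest = max(envs, key=lambda e: e.time_ms.size)
    n = longest.time_ms.size
    rows = [np.concatenate([e.amplitude,
                            np.full(n - e.amplitude.size, np.nan)])
            for e in envs]
    df = pd.DataFrame(rows, columns=[f"{t:.1f}" for t in longest.time_ms])
    df.insert(0, "trial_id", [e.trial_id for e in envs])
    df.to_csv(_envelope_path(out_dir, tempo), sep="\t", index=False)


def _load_envelopes(out_dir: Path, tempo: float, band):
    path = _envelope_path(out_dir, tempo)
    if not path.exists():
        raise DependencyError(
            f"{path.name} not found: run the 'spectrogram' stage first")
    df = pd.read_csv(path, sep="\t")
    time = np.array([float(c) for c in df.columns[1:]])
    out = []
    for _, row in df.iterrows():
        amp = row[1:].to_numpy(float)
        n = int(np.max(np.flatnonzero(np.isfinite(amp))) + 1)
        out.append(spectral.GammaEnvelope(amplitude=amp[:n], time_ms=time[:n],
                                          band_hz=band,
                                          method="spectrogram-average",
                                          trial_id=int(row.iloc[0])))
    return out


def _figure(path: Path, draw) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    draw(ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(task, analysis, session_path, out_dir, seed):
    session, truth = synth.simulate_session(task=task, seed=seed)
    write_session(session, session_path)
    _save_json({str(k): v for k, v in truth.items()},
               out_dir / "ground_truth.json")
    return {"n_trials": len(session.trials),
            "n_channels": session.n_channels,
            "n_units": len(session.spike_trains)}


def _session_by_tempo(session: SessionData):
    tempos = sorted({tr.tempo_ms for tr in session.trials})
    return {T: [tr for tr in session.trials if tr.tempo_ms == T]
            for T in tempos}


def stage_spectrogram(task, analysis, session, out_dir, seed):
    envs = spectral.trial_envelopes(session, analysis,
                                    baseline_ms=task.baseline_ms)
    by_id = {e.trial_id: e for e in envs}
    summary = {}
    for T, trials in _session_by_tempo(session).items():
        tempo_envs = [by_id[tr.trial_id] for tr in trials]
        _save_envelopes(tempo_envs, T, out_dir)
        summary[f"n_trials_t{int(T)}"] = len(tempo_envs)
    # permutation test on the fastest tempo, against the pre-trial baseline
    T0 = min(tr.tempo_ms for tr in session.trials)
    margin = analysis.spectrogram_window_ms / 2.0
    specs = []
    for tr in _session_by_tempo(session)[T0]:
        x = session.trial_slice(tr.trial_id, -task.baseline_ms - margin,
                                tr.epoch_bounds["maintenance"][1] + margin)
        specs.append(spectral.multitaper_spectrogram(
            x, session.sampling_rate_hz, analysis,
            t0_ms=-task.baseline_ms - margin))
    if len(specs) >= 2:
        p, t_axis, f_axis = spectral.permutation_test_bins(
            specs, (-task.baseline_ms, 0.0), analysis.n_permutations, seed)
        pd.DataFrame(p, index=t_axis, columns=f_axis).to_csv(
            out_dir / "permutation_p.tsv", sep="\t")
        gamma_rows = (f_axis >= analysis.gamma_band_hz[0]) \
            & (f_axis <= analysis.gamma_band_hz[1])
        summary["frac_gamma_bins_p<0.05"] = float(
            (p[:, gamma_rows] < 0.05).mean())
    env0 = [by_id[tr.trial_id] for tr in _session_by_tempo(session)[T0]]
    n_common = min(e.amplitude.size for e in env0)
    mean_env = np.mean([e.amplitude[:n_common] for e in env0], axis=0)
    _figure(out_dir / "mean_gamma_envelope.png",
            lambda ax: (ax.plot(env0[0].time_ms[:n_common] / 1000.0, mean_env),
                        ax.set_xlabel("time (s)"),
                        ax.set_ylabel("gamma amplitude (baseline = 1)")))
    return summary


def stage_bursts(task, analysis, session, out_dir, seed):
    summary = {}
    all_bursts = []
    for T, trials in _session_by_tempo(session).items():
        envs = _load_envelopes(out_dir, T, analysis.gamma_band_hz)
        evs = bursts.detect_session_bursts(
            envs, trials, analysis.burst_percentile, analysis.burst_min_dur_ms)
        all_bursts.extend(evs)
        ibi = bursts.interburst_intervals(evs).get(T, np.empty(0))
        summary[f"median_ibi_t{int(T)}"] = (float(np.median(ibi))
                                            if ibi.size else None)
        test = bursts.switch_vs_mid_test(envs, trials)
        summary[f"switch_vs_mid_p_t{int(T)}"] = test["p"]
    frame = bursts.bursts_to_frame(all_bursts)
    frame.to_csv(out_dir / "bursts.tsv", sep="\t", index=False)
    ent = [b for b in all_bursts if b.epoch == "entrainment"]
    if len(ent) >= 3:
        fit = bursts.fit_amplitude_growth(ent, "linear",
                                          aggregate="interval-mean")
        summary["entrainment_linear_r2"] = fit["r2"]
    full = [b for b in all_bursts if b.epoch in ("entrainment", "maintenance")]
    if len(full) >= 3:
        fit = bursts.fit_amplitude_growth(full, "exponential",
                                          aggregate="interval-mean")
        summary["growth_exponential_r2"] = fit["r2"]
    _figure(out_dir / "burst_amplitude_growth.png",
            lambda ax: (ax.scatter(frame["onset_ms"] / 1000.0,
                                   frame["mean_amp"], s=4),
                        ax.set_xlabel("burst onset (s)"),
                        ax.set_ylabel("mean burst amplitude")))
    return summary


def stage_behavior(task, analysis, session, out_dir, seed):
    fit = behavior.fit_scalar_model(session.trials)
    rts = np.array([tr.rt_ms for tr in session.trials])
    elapsed = np.array([tr.t_go_ms for tr in session.trials]) / 1000.0
    rt_fit = behavior.rt_regression(rts, elapsed)
    summary = {"weber_fraction": fit["weber_fraction"], "lapse": fit["lapse"],
               "w_ci": fit["w_ci"], "boundary": fit["boundary"],
               "rt_slope_ms_per_s": rt_fit["slope_ms_per_s"],
               "rt_r2": rt_fit["r2"]}
    rows = []
    for curve in fit["curves"]:
        for t, p in zip(curve.elapsed_s, curve.p_correct):
            rows.append({"tempo_ms": curve.tempo_ms, "elapsed_s": t,
                         "p_correct_model": p})
    pd.DataFrame(rows).to_csv(out_dir / "psychometric.tsv", sep="\t",
                              index=False)

    def draw(ax):
        for curve in fit["curves"]:
            ax.plot(curve.elapsed_s, curve.p_correct,
                    label=f"{curve.tempo_ms:.0f} ms")
        ax.axhline(0.5, ls="--", c="k")
        ax.set_xlabel("elapsed maintenance time (s)")
        ax.set_ylabel("P(correct)")
        ax.legend()
    _figure(out_dir / "psychometric.png", draw)
    return summary


def stage_decode(task, analysis, session, out_dir, seed):
    summary = {}
    rows = []
    envs = spectral.trial_envelopes(session, analysis,
                                    method="bandpass-analytic",
                                    baseline_ms=task.baseline_ms)
    by_id = {e.trial_id: e for e in envs}
    for T, trials in _session_by_tempo(session).items():
        labelled = [tr for tr in trials if tr.correct is not None]
        n_err = sum(not tr.correct for tr in labelled)
        if n_err < 4 or len(labelled) - n_err < 4:
            summary[f"skipped_t{int(T)}"] = "too few error trials"
            continue
        fm = decode.bin_gamma([by_id[tr.trial_id] for tr in labelled],
                              labelled, analysis.bins_per_interval)
        for scheme in ("cumulative", "sliding"):
            res = decode.classifier_accuracy_curves(
                fm, scheme, analysis.holdout_per_class,
                analysis.n_iterations, seed,
                sliding_bins=analysis.sliding_window_bins)
            for b, t, a, s in zip(res["bin"], res["time_s"],
                                  res["accuracy"], res["se"]):
                rows.append({"tempo_ms": T, "scheme": scheme, "bin": b,
                             "time_s": t, "accuracy": a, "se": s})
            if scheme == "cumulative":
                summary[f"final_accuracy_t{int(T)}"] = float(res["accuracy"][-1])
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "decoding_accuracy.tsv",
                                  sep="\t", index=False)
    return summary


def stage_sta(task, analysis, session, out_dir, seed):
    if not session.spike_trains:
        return {"skipped": "no spike trains in session"}
    fs = session.sampling_rate_hz
    rows = []
    for k, spikes in enumerate(session.spike_trains):
        parts = spikefield.spikes_by_epoch(spikes, session.trials,
                                           session.trial_onsets_ms)
        for epoch, sp in parts.items():
            if sp.size < 10:
                continue
            sta = spikefield.spike_triggered_average(
                sp, session.lfp[0].astype(float), fs,
                analysis.sta_halfwidth_ms, epoch, unit_id=k, cfg=analysis)
            for band, power in sta.band_power.items():
                rows.append({"unit": k, "condition": epoch, "band": band,
                             "power": power, "n_spikes": sta.n_spikes})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "sta_band_power.tsv", sep="\t", index=False)
    summary = {}
    try:
        anova = spikefield.sta_band_anova(df)
        summary["interaction_F"] = anova["interaction_F"]
        summary["interaction_p"] = anova["interaction_p"]
    except spectral.InputError as err:
        summary["anova_skipped"] = str(err)
    return summary


def stage_coherence(task, analysis, session, out_dir, seed):
    pairs = coherence.session_coherence_pairs(session,
                                              analysis.gamma_band_hz)
    pd.DataFrame([{"channel_a": p.channel_a, "channel_b": p.channel_b,
                   "distance_um": p.distance_um, "plv": p.plv,
                   "n_samples": p.n_samples} for p in pairs]).to_csv(
        out_dir / "coherence_pairs.tsv", sep="\t", index=False)
    fit = coherence.coherence_vs_distance(pairs,
                                          min(analysis.distance_bins,
                                              len(pairs)))
    pd.DataFrame({"distance_um": fit["bin_distance_um"],
                  "plv": fit["bin_plv"]}).to_csv(
        out_dir / "coherence_binned.tsv", sep="\t", index=False)
    return {"slope_per_um": fit["slope_per_um"], "r2": fit["r2"]}


def stage_report(task, analysis, session, out_dir, seed):
    collected = {}
    for stage in STAGES[:-1]:
        path = out_dir / f"{stage}.json"
        if path.exists():
            collected[stage] = json.loads(path.read_text())
    _save_json(collected, out_dir / "summary.json")
    return {"stages_collected": sorted(collected)}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "spectrogram": stage_spectrogram,
    "bursts": stage_bursts, "behavior": stage_behavior,
    "decode": stage_decode, "sta": stage_sta,
    "coherence": stage_coherence, "report": stage_report,
}


def run_pipeline(task: TaskConfig, analysis: AnalysisConfig,
                 session_path, stages: list[str], out_dir,
                 seed: int = 0) -> dict:
    """Run the requested stages in order; returns the combined summary."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise UsageError(f"unknown stage(s) {unknown}; valid stages are "
                         f"{list(STAGES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session_path = Path(session_path)
    cfg_hash = _config_hash(task, analysis)
    log.info("pipeline start: config=%s seed=%d stages=%s",
             cfg_hash, seed, stages)
    report = {"config_hash": cfg_hash, "seed": seed}
    session = None
    for stage in stages:
        fn = _STAGE_FUNCS[stage]
        if stage == "simulate":
            summary = fn(task, analysis, session_path, out_dir, seed)
            session = None
        else:
            if session is None:
                session = read_session(session_path)
            summary = fn(task, analysis, session, out_dir, seed)
        _save_json(summary, out_dir / f"{stage}.json")
        report[stage] = summary
        log.info("stage %s done", stage)
    return report
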