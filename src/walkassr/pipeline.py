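"""End-to-end orchestration: simulate → preprocess → select → parameterize →
turns → lateralization/perturbation/ERP → stats, with tabular outputs.

A run operates on one simulated participant.  Stage outputs are tidy CSV
tables plus a JSON provenance manifest (config, seeds, software versions,
per-stage counts).  Units: EEG µV, power µV², log-ratio dB, parameterized
power log10 over-aperiodic units; columns carry unit suffixes.  Epoch time
axes are in seconds with t = 0 at the lock sample.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .components import select_alpha_components, select_assr_components
from .dynamics import (lateralization_index, perturbation_response,
                       timeresolved_power, turn_locked_contrast)
from .erp import P1_WINDOW, P2_WINDOW, burst_erp, component_amplitude
from .motion import detect_turns, epoch_by_events, lowpass_yaw
from .preprocess import (FilterSpec, apply_filters, backproject,
                         component_spectra, decompose, rereference,
                         welch_spectrum)
from .recording import Recording, save_session
from .specparam import alpha_band_power, fit_parameterized, parameterized_power
from .stats import cluster_permutation_test
from .synth import (FRONTOCENTRAL, OCCIPITAL, BurstSchedule, SessionConfig,
                    schedule_bursts, simulate_eeg, simulate_gyro)

__all__ = ["RunConfig", "run_pipeline", "analyze_block", "clusters_to_bed"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (one simulated participant).

    ``experiment`` selects the block structure: "exp1" has stepping, walking
    and standing blocks (no bursts); "exp2" has standing and walking blocks
    with white-noise bursts (8 per kind standing, 32 per kind walking).
    Durations are controlled through laps (12 s each) per block.
    """

    experiment: str = "exp1"
    seed: int = 0
    out_dir: str = "walkassr_run"
    walk_laps: int = 40          # 480 s walking block
    stationary_laps: int = 10    # 120 s standing/stepping blocks
    lateral_gain: float = 1.5
    n_ica_dims: int = 16
    frontocentral: tuple[str, ...] = tuple(FRONTOCENTRAL)
    occipital: tuple[str, ...] = tuple(OCCIPITAL)
    run_ica: bool = True
    save_fixture: bool = False
    assr_hzs: tuple[float, float] = (39.0, 41.0)
    control_hzs: tuple[float, float] = (37.0, 44.0)
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for key in ("frontocentral", "occipital", "assr_hzs", "control_hzs"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


_STATE_SALT = {"stand": 1, "step": 2, "walk": 3}


def _session_config(run: RunConfig, state: str, block: int) -> SessionConfig:
    laps = run.walk_laps if state == "walk" else run.stationary_laps
    gain = run.lateral_gain if state == "walk" else 1.0
    return SessionConfig(movement_state=state, n_laps=laps,
                         lateral_gain=gain,
                         seed=run.seed * 1009 + block * 101 + _STATE_SALT[state])


def analyze_block(rec: Recording, run: RunConfig, seed: int) -> dict:
    """Preprocess one block and return selected-component power measures.

    Pipeline: rereference → filters → PCA+ICA → Welch component spectra →
    ASSR/alpha component selection → back-projection → sensor-space Welch →
    spectral parameterization on the frontocentral (ASSR) and occipital
    (alpha) electrode averages.
    """
    rec = apply_filters(rereference(rec), FilterSpec())
    out: dict = {"recording": rec}
    if run.run_ica:
        decomp = decompose(rec, n_dims=run.n_ica_dims, seed=seed)
        spectra = component_spectra(decomp)
        fits = [fit_parameterized(s) for s in spectra]
        assr_rep = select_assr_components(decomp, spectra,
                                          target_hzs=run.assr_hzs,
                                          parameterized=fits)
        alpha_rep = select_alpha_components(decomp, spectra)
        assr_ids = [r.component for r in assr_rep if r.accepted]
        alpha_ids = [r.component for r in alpha_rep if r.accepted]
        out.update(decomposition=decomp, assr_reports=assr_rep,
                   alpha_reports=alpha_rep, assr_components=assr_ids,
                   alpha_components=alpha_ids)
        assr_rec = (backproject(decomp, assr_ids, rec) if assr_ids else rec)
        alpha_rec = (backproject(decomp, alpha_ids, rec) if alpha_ids else rec)
    else:
        assr_rec = alpha_rec = rec
        out.update(assr_components=[], alpha_components=[])

    fc = assr_rec.get(list(run.frontocentral)).mean(axis=0)
    occ = alpha_rec.get(list(run.occipital)).mean(axis=0)
    ps_fc = fit_parameterized(welch_spectrum(fc, rec.fs))
    ps_occ = fit_parameterized(welch_spectrum(occ, rec.fs))
    out["assr_power_log10"] = {f: parameterized_power(ps_fc, f)
                               for f in run.assr_hzs}
    out["alpha_power_log10"] = alpha_band_power(ps_occ)
    out["aperiodic_fc"] = ps_fc.aperiodic
    return out


def _lateralization_stage(rec: Recording, motion, run: RunConfig,
                          freqs: tuple[float, float], seed: int) -> dict:
    """Hilbert power → LI → turn epochs (lap-paired) → cluster test."""
    turns = detect_turns(lowpass_yaw(motion))
    p_lo = timeresolved_power(rec, freqs[0], channel_labels=list(run.frontocentral))
    p_hi = timeresolved_power(rec, freqs[1], channel_labels=list(run.frontocentral))
    lat = lateralization_index(p_lo, p_hi)
    contrast = turn_locked_contrast(lat, turns)
    left, right = contrast["left"], contrast["right"]
    n = min(len(left), len(right))
    result = cluster_permutation_test(left[:n], right[:n],
                                      times=contrast["times"],
                                      n_perm=run.n_permutations, seed=seed)
    return {"turns": turns, "contrast": contrast, "cluster": result}


def clusters_to_bed(result, path: str | Path) -> None:
    """BED-like interval text: start_s, end_s, mass, p (tab-separated)."""
    lines = [f"{c.start_s:.4f}\t{c.end_s:.4f}\t{c.mass:.4f}\t{c.p:.4g}"
             for c in result.clusters]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def run_pipeline(run: RunConfig) -> Path:
    """Execute the configured experiment end to end; returns the run dir."""
    out_dir = Path(run.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    states = ["step", "walk", "stand"] if run.experiment == "exp1" else ["stand", "walk"]
    counts: dict = {}
    power_rows, perturb_rows, erp_rows = [], [], []
    cluster_results: dict[str, object] = {}

    for block, state in enumerate(states):
        cfg = _session_config(run, state, block)
        motion = simulate_gyro(cfg)
        schedule: BurstSchedule | None = None
        if run.experiment == "exp2":
            # one burst per ~15 s per kind — 32/kind for a full 480 s walking
            # block, 8/kind for a 120 s standing block
            n_bursts = max(2, int(cfg.duration_s / 15))
            schedule = schedule_bursts(cfg.duration_s, n_bursts,
                                       seed=cfg.seed + 7)
        rec = simulate_eeg(cfg, schedule=schedule,
                           motion=motion if state == "walk" else None)
        if run.save_fixture:
            save_session(out_dir / f"session_{state}.h5", rec, [motion])
        res = analyze_block(rec, run, seed=cfg.seed)
        counts[f"{state}_assr_components"] = len(res["assr_components"])
        counts[f"{state}_alpha_components"] = len(res["alpha_components"])
        for f in run.assr_hzs:
            power_rows.append({"state": state, "frequency_hz": f,
                               "assr_power_log10": res["assr_power_log10"][f]})
        power_rows.append({"state": state, "frequency_hz": "alpha_8_14",
                           "assr_power_log10": res["alpha_power_log10"]})

        prec = res["recording"]
        if state == "walk":
            for tag, freqs in (("assr", run.assr_hzs), ("control", run.control_hzs)):
                stage = _lateralization_stage(prec, motion, run, freqs,
                                              seed=cfg.seed + 11)
                cluster_results[tag] = stage["cluster"]
                counts["turns_detected"] = len(stage["turns"])
                clusters_to_bed(stage["cluster"], out_dir / f"clusters_{tag}.bed")

        if schedule is not None:
            for f in run.assr_hzs:
                pw = timeresolved_power(prec, f,
                                        channel_labels=list(run.frontocentral))
                series_rec = Recording(pw.values[None, :], ["p"], ["eeg"], prec.fs)
                for kind in schedule.kinds:
                    epochs = epoch_by_events(series_rec, schedule.onsets(kind),
                                             lock=f"burst_{kind}")
                    pr = perturbation_response(epochs, f,
                                               condition={"state": state,
                                                          "burst": kind})
                    perturb_rows.append({"state": state, "burst_kind": kind,
                                         "frequency_hz": f,
                                         "perturbation_db": pr.value_db,
                                         "n_trials": pr.n_trials})
            for kind in schedule.kinds:
                erp = burst_erp(prec, schedule.onsets(kind),
                                channel_labels=list(run.frontocentral),
                                condition=f"{state}_{kind}")
                erp_rows.append({"state": state, "burst_kind": kind,
                                 "p1_uv": component_amplitude(erp, P1_WINDOW),
                                 "p2_uv": component_amplitude(erp, P2_WINDOW),
                                 "n_trials": erp.n_trials})

    pd.DataFrame(power_rows).to_csv(out_dir / "parameterized_power.csv", index=False)
    if perturb_rows:
        pd.DataFrame(perturb_rows).to_csv(out_dir / "perturbation.csv", index=False)
    if erp_rows:
        pd.DataFrame(erp_rows).to_csv(out_dir / "erp_amplitudes.csv", index=False)

    cfg_json = json.dumps(asdict(run), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": run.seed,
        "versions": {"walkassr": __version__,
                     "numpy": np.__version__,
                     "python": platform.python_version()},
        "counts": counts,
        "clusters": {tag: [[c.start_s, c.end_s, c.mass, c.p]
                           for c in res.clusters]
                     for tag, res in cluster_results.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
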