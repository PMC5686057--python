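"""End-to-end pipeline: simulate -> preprocess -> QC -> segment -> spectra
-> cluster -> report, from a single config mapping.

The config is a nested mapping (typically loaded from YAML) whose defaults
reproduce the study's analysis settings: 1-50 Hz 4th-order zero-phase
band-pass, 0.5 s / 3 SD subspace cleaning calibrated on the baseline, CAR,
300 uV upper and 10x-resolution lower thresholds with 20% occupancy and
0.5 s padding, 4 s windows with 2 s overlap, NW=4 / 512-point multitaper
PSDs on 256 bins in 1-50 Hz, kernel screening over the standard sigma
ladder, eigenvalue-based k selection and 200-restart kernel K-means.

Every run writes a manifest (config, seeds, output hashes); deterministic
stages are bit-identical across reruns of the same config.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .cluster import (
    KernelSpec,
    cluster_composition,
    compute_kernel,
    default_kernel_specs,
    eigen_terms,
    kernel_kmeans,
    proportion_test,
    screen_kernels,
    select_k,
)
from .io import write_annotations, write_artifact_labels
from .preprocess import asr_clean, bandpass_filter, common_average_reference
from .profiles import BUILTIN_PROFILES, load_headset_profile
from .recording import Recording
from .segment import partition_conditions, slide_windows
from .spectral import (
    common_electrode_membership,
    feature_table,
    spectral_samples,
    standardize_features,
)
from .synth import ArtifactPlanItem, baseline_viewing_design, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "make_report",
           "process_session", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "headsets": ["M32", "BPG", "BPD"],
        "n_subjects": 2,
        "viewing_s": 180.0,
        # per-type events per minute; empty plan = clean sessions
        "artifact_rates": {"pop": 0.5, "wireless_loss": 0.2},
    },
    "filter": {"low_hz": 1.0, "high_hz": 50.0, "order": 4},
    "asr": {"window_s": 0.5, "cutoff_sd": 3.0, "calibration": "baseline"},
    "qc": {"upper_uv": 300.0, "lower_multiplier": 10.0,
           "occupancy": 0.20, "pad_s": 0.5, "on_filtered": True},
    "segment": {"window_s": 4.0, "overlap_s": 2.0},
    # k = 5 mirrors the study's "for consistency" choice across electrodes;
    # set k: auto to use the eigen-term gap rule instead
    "cluster": {"kernels": "default", "k": 5, "n_init": 200,
                "k_max": 10, "alpha": 0.01},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _stage_seed(seed: int, *names: str) -> int:
    h = hashlib.sha256(("/".join(map(str, names)) + f"#{seed}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass
class SessionResult:
    """Processed outputs of one simulated session."""

    recording_id: str
    headset: str
    qc: qc_mod.QCReport
    samples: list  # SpectralSample
    n_windows_total: int


def process_session(rec: Recording, track, profile, config: dict,
                    electrodes: list[str] | None = None,
                    gender: str = "U") -> SessionResult:
    """Filter, QC, clean, re-reference and spectrally summarize one session."""
    fcfg, qcfg = config["filter"], config["qc"]
    scfg, acfg = config["segment"], config["asr"]

    filtered = bandpass_filter(rec, fcfg["low_hz"], fcfg["high_hz"],
                               fcfg["order"])
    qc_input = filtered if qcfg.get("on_filtered", True) else rec

    upper, lower = qc_mod.thresholds_for(profile, qcfg["upper_uv"],
                                         qcfg["lower_multiplier"])
    decisions = qc_mod.reject_channels(qc_input, upper, lower,
                                       qcfg["occupancy"])
    retained = [d.channel for d in decisions if d.keep]
    if len(retained) < 2:
        raise ConfigError(
            f"session {rec.subject_id}: fewer than 2 channels survive QC")

    epochs = partition_conditions(rec, track)
    windows = [w for ep in epochs
               for w in slide_windows(ep, scfg["window_s"], scfg["overlap_s"])]

    picked = qc_input.pick(retained)
    mask = qc_mod.reject_windows(picked, windows, upper, qcfg["pad_s"])
    report = qc_mod.qc_report(decisions, mask)

    # subspace cleaning calibrated on the baseline condition
    cleaned = filtered.pick(retained)
    if acfg.get("calibration") == "baseline":
        base = next((ep for ep in epochs if ep.condition == "baseline"), None)
        if base is not None:
            i0 = cleaned.time_to_sample(base.start_s)
            i1 = cleaned.time_to_sample(base.end_s)
            calib = Recording(
                subject_id=rec.subject_id, headset=rec.headset,
                signal=cleaned.signal[:, i0:i1],
                sampling_rate=cleaned.sampling_rate,
                channel_labels=cleaned.channel_labels)
            try:
                cleaned = asr_clean(cleaned, calib, acfg["window_s"],
                                    acfg["cutoff_sd"])
            except ValueError as exc:
                logger.warning("ASR skipped for %s: %s", rec.subject_id, exc)
    cleaned = common_average_reference(cleaned)

    wanted = ([e for e in electrodes if e in retained]
              if electrodes is not None else retained)
    samples = spectral_samples(cleaned, mask.kept_windows(), wanted,
                               gender=gender)
    return SessionResult(recording_id=rec.subject_id, headset=profile.name,
                         qc=report, samples=samples,
                         n_windows_total=len(windows))


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Execute the full demo pipeline and write a run directory.

    Outputs: per-session QC reports and ground-truth labels, the pooled
    spectral feature table, per-electrode cluster models with composition
    tables and eigen-term sequences, and a manifest.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim = cfg["simulate"]

    montages = {name: BUILTIN_PROFILES[name].channel_labels
                for name in sim["headsets"]}
    membership = common_electrode_membership(montages)
    electrodes = list(membership)

    qc_rows = []
    all_samples = []
    rng_gender = np.random.default_rng(_stage_seed(seed, "gender"))
    for headset in sim["headsets"]:
        profile = load_headset_profile(headset)
        for s in range(int(sim["n_subjects"])):
            sid = f"{headset}-s{s:02d}"
            plan = tuple(
                ArtifactPlanItem(type=t, rate_per_min=float(r))
                for t, r in (sim.get("artifact_rates") or {}).items())
            design = baseline_viewing_design(
                profile, seed=_stage_seed(seed, "sim", sid),
                viewing_s=float(sim["viewing_s"]), artifact_plan=plan,
                subject_id=sid)
            rec, track, labels = simulate_session(design)
            write_annotations(track, out / f"{sid}.annotations.json")
            write_artifact_labels(labels, out / f"{sid}.labels.json")

            gender = "F" if rng_gender.random() < 0.5 else "M"
            result = process_session(rec, track, profile, cfg,
                                     electrodes=electrodes, gender=gender)
            qc_rows.append({"recording": sid, "headset": headset,
                            **result.qc.to_dict()})
            all_samples.extend(result.samples)
            logger.info("session %s: %d/%d windows kept, %d channels kept",
                        sid, len(result.qc.mask.windows) - result.qc.mask.n_rejected,
                        len(result.qc.mask.windows),
                        len(result.qc.retained_channels()))

    (out / "qc_reports.json").write_text(json.dumps(qc_rows, indent=2))
    table = feature_table(all_samples)
    table.to_csv(out / "features.tsv", sep="\t", index=False)

    ccfg = cfg["cluster"]
    cluster_summary = {}
    for electrode in electrodes:
        sub = table[table.electrode == electrode].reset_index(drop=True)
        if len(sub) < 10:
            logger.warning("electrode %s: too few samples, skipped", electrode)
            continue
        fcols = [c for c in sub.columns if c.startswith("f") and c[1:].isdigit()]
        X = standardize_features(sub[fcols].to_numpy(dtype=float))
        if ccfg["kernels"] == "default":
            Km, scores = screen_kernels(X)
        else:
            specs = [KernelSpec(**d) for d in ccfg["kernels"]]
            Km, scores = screen_kernels(X, specs)
        sel = eigen_terms(Km)
        k = (select_k(sel, k_max=ccfg["k_max"]) if ccfg["k"] == "auto"
             else int(ccfg["k"]))
        model = kernel_kmeans(Km, k, n_init=int(ccfg["n_init"]),
                              seed=_stage_seed(seed, "kmeans", electrode))
        comp = cluster_composition(model, sub)
        comp["proportions"].to_csv(
            out / f"composition_{electrode}.tsv", sep="\t", index=False)
        if "envelopes" in comp:
            comp["envelopes"].to_csv(
                out / f"envelopes_{electrode}.tsv", sep="\t", index=False)
        pd.DataFrame({"term": sel.terms}).to_csv(
            out / f"eigenterms_{electrode}.tsv", sep="\t", index=False)

        # condition-enrichment per cluster, against the pooled baseline share
        overall_p = float((sub.condition == "baseline").mean())
        tests = []
        for c in range(model.k):
            in_c = sub[model.assignments == c]
            n_b = int((in_c.condition == "baseline").sum())
            n_pv = len(in_c) - n_b
            p, sig = proportion_test((n_b, n_pv), overall_p,
                                     alpha=ccfg["alpha"])
            tests.append({"cluster": c, "n_baseline": n_b,
                          "n_piece_viewing": n_pv, "p_value": p,
                          "significant": sig})
        cluster_summary[electrode] = {
            "kernel": Km.spec.label(),
            "kernel_entropy_bits": float(scores.entropy_bits.iloc[0]),
            "k_selected": k,
            "objective": model.objective,
            "n_samples": len(sub),
            "assignments": model.assignments.tolist(),
            "proportion_tests": tests,
        }
    (out / "clusters.json").write_text(json.dumps(cluster_summary, indent=2))

    manifest = {
        "config": cfg,
        "electrodes": {e: list(m) for e, m in membership.items()},
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def make_report(run_dir: str | Path) -> dict[str, Path]:
    """Assemble plot-ready report tables from a completed run directory.

    Emits rejection rates per headset, per-cluster composition, mean +-
    5th/95th percentile PSD envelopes, and per-sample band-power triplets
    (delta/alpha/gamma) for 3-D scatter plots.
    """
    from .spectral import band_power

    run = Path(run_dir)
    missing = [f for f in ("qc_reports.json", "features.tsv", "clusters.json")
               if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"run directory {run} is incomplete; missing {missing}")

    outputs: dict[str, Path] = {}
    qc_rows = json.loads((run / "qc_reports.json").read_text())
    rej = pd.DataFrame([
        {"recording": r["recording"], "headset": r["headset"],
         "channel_rejection_rate": r["channel_rejection_rate"],
         "data_rejection_rate": r["data_rejection_rate"]}
        for r in qc_rows])
    path = run / "report_rejection_rates.tsv"
    rej.to_csv(path, sep="\t", index=False)
    outputs["rejection_rates"] = path

    table = pd.read_csv(run / "features.tsv", sep="\t")
    fcols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    P = table[fcols].to_numpy(dtype=float)
    bands = pd.DataFrame({
        "delta": [band_power(p, "delta") for p in P],
        "alpha": [band_power(p, "alpha") for p in P],
        "gamma": [band_power(p, "gamma") for p in P],
    })
    triplets = pd.concat(
        [table[["subject", "headset", "electrode", "condition"]], bands],
        axis=1)
    path = run / "report_band_triplets.tsv"
    triplets.to_csv(path, sep="\t", index=False)
    outputs["band_triplets"] = path

    clusters = json.loads((run / "clusters.json").read_text())
    rows = []
    for electrode, info in clusters.items():
        for t in info["proportion_tests"]:
            rows.append({"electrode": electrode, "kernel": info["kernel"],
                         "k": info["k_selected"], **t})
    path = run / "report_condition_tests.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    outputs["condition_tests"] = path
    return outputs
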