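"""End-to-end pipeline orchestration from a single config.

Stages run in dependency order; all cross-stage data flows through declared
files in the output directory, and a JSON run manifest records parameters,
seeds, QC counters and artifact digests. Identical config + seed yields
identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SessionConfig
from .decoding import decode, prepare_balanced_folds
from .gating import build_templates, gating_summary, label_trials
from .responses import build_trial_table, extract_responses
from .rsa import rsa_summary
from .scoring import awakening_stats, detect_spindles, score_session
from .subspace import condition_masks, cv_scree, inclusion_index, session_activity
from .synthetic import generate_physio, generate_session


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class DataError(Exception):
    """Invalid or missing data (CLI exit code 3)."""


STAGES = ("simulate", "score", "spindles", "responses",
          "rsa", "subspace", "decode", "gating")
DEPENDENCIES = {
    "simulate": (),
    "score": ("simulate",),
    "spindles": ("simulate", "score"),
    "responses": ("simulate", "score"),
    "rsa": ("responses",),
    "subspace": ("simulate", "responses"),
    "decode": ("responses",),
    "gating": ("responses",),
}


def default_config() -> dict:
    return dict(
        seed=0,
        stages=list(STAGES),
        session={},              # SessionConfig overrides
        rsa=dict(n_splits=20, states=["wake", "nrem"]),
        decode=dict(k=5, model="svc", C=1.0),
        gating=dict(top_frac=0.3, n_sounds=10, n_boot=1000),
        subspace=dict(state="nrem"),
        scoring=dict(channel="emg"),
    )


def validate_config(config: dict) -> dict:
    merged = default_config()
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(merged[key], dict) and isinstance(value, dict):
            merged[key] = {**merged[key], **value}
        else:
            merged[key] = value
    unknown = set(merged["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    enabled = set(merged["stages"])
    for stage in merged["stages"]:
        missing = set(DEPENDENCIES[stage]) - enabled
        if missing:
            raise ConfigError(
                f"stage {stage!r} requires {sorted(missing)} to be enabled")
    try:
        session = SessionConfig(seed=merged["seed"], **merged["session"])
        session.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid session config: {exc}") from exc
    merged["_session"] = session
    return merged


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: dict, out: str | Path) -> dict:
    """Execute all enabled stages and return the run manifest."""
    cfg = validate_config(config)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    session_cfg: SessionConfig = cfg["_session"]
    seed = cfg["seed"]
    enabled = cfg["stages"]
    manifest: dict = dict(seed=seed, stages=enabled, timing={}, qc={}, artifacts={},
                          parameters={k: v for k, v in cfg.items()
                                      if not k.startswith("_") and k != "stages"})
    manifest["parameters"]["session"] = dataclasses.asdict(session_cfg)

    state: dict = {}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = dict(path=str(path), sha256=_digest(path))

    for stage in STAGES:
        if stage not in enabled:
            continue
        t0 = time.monotonic()
        if stage == "simulate":
            raster, trials, truth = generate_session(session_cfg)
            physio = generate_physio(session_cfg, truth)
            state.update(raster=raster, trials=trials, truth=truth, physio=physio)
            io.save_raster(out / "raster.h5", raster, truth)
            io.save_trial_table(out / "trials.csv", trials)
            io.save_physio(out / "physio.bin", physio)
            record("raster", out / "raster.h5")
            record("trials", out / "trials.csv")
            record("physio", out / "physio.bin")
        elif stage == "score":
            hyp = score_session(state["physio"], channel=cfg["scoring"]["channel"])
            state["hypnogram"] = hyp
            io.save_hypnogram(out / "hypnogram.csv", hyp)
            record("hypnogram", out / "hypnogram.csv")
            stats = awakening_stats(hyp, state["trials"])
            manifest["qc"]["awakening"] = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                                           for k, v in stats.items()}
        elif stage == "spindles":
            events = detect_spindles(state["physio"]["ac"], state["physio"].rate,
                                     state["hypnogram"])
            state["spindles"] = events
            io.save_spindles(out / "spindles.csv", events)
            record("spindles", out / "spindles.csv")
            manifest["qc"]["n_spindles"] = len(events.events)
        elif stage == "responses":
            trials = build_trial_table(state["trials"].drop(columns=["state"]),
                                       state["hypnogram"])
            resp = extract_responses(state["raster"], trials)
            state["trials_scored"] = trials
            state["resp"] = resp
            io.save_trial_table(out / "trials_scored.csv", trials)
            io.save_responses(out / "responses.h5", resp)
            record("trials_scored", out / "trials_scored.csv")
            record("responses", out / "responses.h5")
            manifest["qc"]["dropped_trials"] = len(resp.dropped)
        elif stage == "rsa":
            states = tuple(cfg["rsa"]["states"])
            trials = state["trials_scored"]
            present = set(trials.state.unique())
            usable = tuple(s for s in states if s in present)
            if len(usable) == 2:
                res = rsa_summary(state["resp"], trials, mode="cross",
                                  states=usable, n_splits=cfg["rsa"]["n_splits"],
                                  seed=seed)
            elif len(usable) == 1:
                res = rsa_summary(state["resp"], trials, mode="within",
                                  states=usable, n_splits=cfg["rsa"]["n_splits"],
                                  seed=seed)
            else:
                raise DataError("no scored state has enough trials for RSA")
            io.save_similarity(out / "similarity.csv", res["matrix"])
            record("similarity", out / "similarity.csv")
            manifest["qc"]["rsa"] = dict(diag_mean=res["diag_mean"],
                                         diag_sd=res["diag_sd"],
                                         n_unreliable=res["matrix"].n_unreliable)
        elif stage == "subspace":
            target = cfg["subspace"]["state"]
            frame_states = np.array(
                [state["hypnogram"].state_at(min(t, state["hypnogram"].span[1] - 1e-9))
                 for t in state["raster"].frame_times()])
            spont_mask, evoked_mask = condition_masks(
                state["raster"], state["trials_scored"], frame_states, target)
            if spont_mask.sum() < 100 or evoked_mask.sum() < 100:
                raise DataError(f"too few {target} frames for subspace analysis")
            act = session_activity(state["raster"])
            result = inclusion_index(act[spont_mask], act[evoked_mask], seed=seed)
            scree = cv_scree(act[spont_mask], seed=seed)
            payload = dict(**result, spont_dimensionality=scree.dimensionality)
            (out / "subspace.json").write_text(json.dumps(payload, indent=2))
            record("subspace", out / "subspace.json")
            manifest["qc"]["subspace"] = payload
        elif stage == "decode":
            results = {}
            trials = state["trials_scored"]
            for st in sorted(trials[~trials.excluded].state.unique()):
                try:
                    folds = prepare_balanced_folds(state["resp"], trials, st,
                                                   k=cfg["decode"]["k"], seed=seed)
                except ValueError:
                    continue
                res = decode(folds, state["resp"], model=cfg["decode"]["model"],
                             C=cfg["decode"]["C"], seed=seed)
                results[st] = res.accuracy
                pd.DataFrame(res.confusion, index=res.sound_ids,
                             columns=res.sound_ids).to_csv(out / f"confusion_{st}.csv")
                record(f"confusion_{st}", out / f"confusion_{st}.csv")
            if not results:
                raise DataError("no state is decodable")
            (out / "decoding.json").write_text(json.dumps(results, indent=2))
            record("decoding", out / "decoding.json")
            manifest["qc"]["decoding"] = results
        elif stage == "gating":
            trials = state["trials_scored"]
            templates = build_templates(state["resp"], trials,
                                        top_frac=cfg["gating"]["top_frac"],
                                        n_sounds=cfg["gating"]["n_sounds"])
            labels = label_trials(state["resp"], trials, templates,
                                  n_boot=cfg["gating"]["n_boot"], seed=seed)
            state["labels"] = labels
            labels.to_csv(out / "gating.csv", index=False)
            record("gating", out / "gating.csv")
            summary = gating_summary(labels, state["resp"], trials, templates,
                                     seed=seed)
            manifest["qc"]["gating"] = summary["fraction_nonresponsive"]
        manifest["timing"][stage] = round(time.monotonic() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
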