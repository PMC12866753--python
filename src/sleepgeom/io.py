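"""Serialization of pipeline artifacts.

Rasters and response matrices go to HDF5; trial tables, hypnograms, spindle
events and similarity matrices to CSV; physiological traces to flat binary
float32 with a JSON sidecar describing channels and sampling rate.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .responses import ResponseMatrix
from .rsa import SimilarityMatrix
from .scoring import Hypnogram, SpindleEvents
from .signal import Raster
from .synthetic import PhysioRecord, SessionTruth


def save_raster(path: str | Path, raster: Raster, truth: SessionTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(track_times=False, name="raster", data=raster.counts, compression="gzip")
        d.attrs["frame_duration"] = raster.frame_duration
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset(track_times=False, name="tuning", data=truth.tuning)
            g.create_dataset(track_times=False, name="trial_gain", data=truth.trial_gain)
            g.create_dataset(track_times=False, name="gated", data=truth.gated)
            g.create_dataset(track_times=False, name="state_sequence",
                             data=np.array(truth.state_sequence, dtype="S8"))
            g.create_dataset(track_times=False, name="spont_loadings", data=truth.spont_loadings)
            g.create_dataset(track_times=False, name="spindle_intervals",
                             data=np.array(truth.spindle_intervals).reshape(-1, 2))
            g.attrs["baseline_rate"] = truth.baseline_rate
            g.attrs["frame_rate"] = truth.frame_rate
            g.attrs["seed"] = truth.seed


def load_raster(path: str | Path) -> Raster:
    with h5py.File(path, "r") as f:
        return Raster(counts=f["raster"][()],
                      frame_duration=float(f["raster"].attrs["frame_duration"]))


def save_trial_table(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    pd.DataFrame(hyp.intervals, columns=["start_s", "end_s", "state"]).to_csv(
        path, index=False)


def load_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    return Hypnogram(intervals=[(r.start_s, r.end_s, r.state)
                                for r in df.itertuples()])


def save_spindles(path: str | Path, events: SpindleEvents) -> None:
    pd.DataFrame(events.events, columns=["start_s", "end_s"]).to_csv(path, index=False)


def save_similarity(path: str | Path, matrix: SimilarityMatrix) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sound_ids, columns=matrix.sound_ids)
    df.to_csv(path)
    qc = dict(mode=matrix.mode, n_unreliable=matrix.n_unreliable,
              reliability=matrix.reliability.tolist())
    Path(str(path) + ".qc.json").write_text(json.dumps(qc, indent=2))


def save_responses(path: str | Path, resp: ResponseMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(track_times=False, name="responses", data=resp.responses, compression="gzip")
        f.create_dataset(track_times=False, name="baselines", data=resp.baselines, compression="gzip")
        f.create_dataset(track_times=False, name="trial_ids", data=resp.trial_ids)
        f.attrs["window"] = resp.window


def load_responses(path: str | Path) -> ResponseMatrix:
    with h5py.File(path, "r") as f:
        return ResponseMatrix(
            responses=f["responses"][()],
            baselines=f["baselines"][()],
            window=tuple(f.attrs["window"]),
            trial_ids=f["trial_ids"][()],
        )


def save_physio(path: str | Path, physio: PhysioRecord) -> None:
    path = Path(path)
    names = sorted(physio.channels)
    data = np.stack([physio.channels[k] for k in names]).astype(np.float32)
    data.tofile(path)
    sidecar = dict(channels=names, rate=physio.rate, n_samples=data.shape[1],
                   dtype="float32")
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_physio(path: str | Path) -> PhysioRecord:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    data = np.fromfile(path, dtype=np.float32).reshape(
        len(sidecar["channels"]), sidecar["n_samples"])
    channels = {k: data[i].astype(float) for i, k in enumerate(sidecar["channels"])}
    return PhysioRecord(channels=channels, rate=float(sidecar["rate"]))
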