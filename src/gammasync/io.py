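"""HDF5 container for sessions, trajectories and derived signals.

Layout
------
/lfp                    float32, (probes, contacts, trials, time)
/ground_truth/phases    float32, (probes, trials, time)
/ground_truth/omega     float64, (probes, conditions)
/ground_truth/epsilon   float64, (probes, probes)
/trial_condition        int, (trials,)
/spikes/p{i}/c{j}/times flattened spike times (s)
/spikes/p{i}/c{j}/trial trial index per spike
/derived/<name>         arrays written by the processing stages
/meta (attr)            JSON string: fs, geometry, conditions, sigma, seed
"""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np

from .oscillator import PairParams, PhaseDiffTrajectorySet
from .synthetic import ProbeGeometry, SessionRecording, StimulusCondition

__all__ = [
    "save_session",
    "load_session",
    "save_derived",
    "load_derived",
    "save_trajectories",
    "load_trajectories",
]


def _session_meta(session: SessionRecording) -> str:
    return json.dumps({
        "fs": session.fs,
        "seed": session.seed,
        "geometry": [
            {"n_contacts": g.n_contacts, "spacing": g.spacing,
             "position_mm": g.position_mm, "n_superficial": g.n_superficial}
            for g in session.geometry
        ],
        "conditions": [
            {"condition_id": c.condition_id, "contrasts": list(map(float, c.contrasts))}
            for c in session.conditions
        ],
        "sigma": float(session.ground_truth.get("sigma", np.nan)),
    })


def save_session(path, session: SessionRecording) -> None:
    """Write a session (including ground truth and spikes) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp, dtype="float32", compression="gzip")
        f.create_dataset("trial_condition", data=np.asarray(session.trial_condition))
        gt = f.create_group("ground_truth")
        gt.create_dataset("phases", data=session.ground_truth["phases"], dtype="float32")
        gt.create_dataset("omega", data=session.ground_truth["omega"])
        gt.create_dataset("epsilon", data=session.ground_truth["epsilon"])
        gt.create_dataset("positions_mm", data=session.ground_truth["positions_mm"])
        gt.create_dataset("condition_ids", data=session.ground_truth["condition_ids"])
        sp = f.create_group("spikes")
        for pi, probe_spikes in enumerate(session.spikes):
            for ci, trials in enumerate(probe_spikes):
                grp = sp.create_group(f"p{pi}/c{ci}")
                times = np.concatenate(trials) if trials else np.empty(0)
                index = np.concatenate([
                    np.full(len(tr), k) for k, tr in enumerate(trials)
                ]) if trials else np.empty(0, dtype=int)
                grp.create_dataset("times", data=times)
                grp.create_dataset("trial", data=index.astype(np.int32))
                grp.attrs["n_trials"] = len(trials)
        f.attrs["meta"] = _session_meta(session)


def load_session(path) -> SessionRecording:
    """Read a session written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        geometry = [ProbeGeometry(**g) for g in meta["geometry"]]
        conditions = [StimulusCondition(**c) for c in meta["conditions"]]
        lfp = f["lfp"][()]
        trial_condition = f["trial_condition"][()]
        gt = {
            "phases": f["ground_truth/phases"][()],
            "omega": f["ground_truth/omega"][()],
            "epsilon": f["ground_truth/epsilon"][()],
            "positions_mm": f["ground_truth/positions_mm"][()],
            "condition_ids": f["ground_truth/condition_ids"][()],
            "sigma": meta["sigma"],
        }
        spikes = []
        for pi in range(lfp.shape[0]):
            probe_spikes = []
            ci = 0
            while f"spikes/p{pi}/c{ci}" in f:
                grp = f[f"spikes/p{pi}/c{ci}"]
                times = grp["times"][()]
                index = grp["trial"][()]
                n_trials = int(grp.attrs["n_trials"])
                probe_spikes.append([times[index == k] for k in range(n_trials)])
                ci += 1
            spikes.append(probe_spikes)
        return SessionRecording(
            lfp=lfp, fs=meta["fs"], geometry=geometry, conditions=conditions,
            trial_condition=trial_condition, spikes=spikes, ground_truth=gt,
            seed=meta["seed"],
        )


def save_derived(path, name: str, arrays: dict, attrs: Optional[dict] = None) -> None:
    """Write derived arrays under /derived/<name> (overwrites the group)."""
    with h5py.File(path, "a") as f:
        key = f"derived/{name}"
        if key in f:
            del f[key]
        grp = f.create_group(key)
        for k, v in arrays.items():
            grp.create_dataset(k, data=np.asarray(v))
        if attrs:
            grp.attrs["meta"] = json.dumps(attrs)


def load_derived(path, name: str) -> dict:
    with h5py.File(path, "r") as f:
        grp = f[f"derived/{name}"]
        out = {k: grp[k][()] for k in grp}
        if "meta" in grp.attrs:
            out["_meta"] = json.loads(grp.attrs["meta"])
        return out


def save_trajectories(path, traj: PhaseDiffTrajectorySet,
                      params: Optional[PairParams] = None) -> None:
    """Write phase-difference trajectories (one dataset per trial)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("trajectories")
        for k in range(traj.n_trials):
            grp.create_dataset(f"trial{k:04d}", data=traj.theta[k])
        f.attrs["fs"] = traj.fs
        if params is not None:
            f.attrs["params"] = json.dumps({
                "delta_omega": params.delta_omega, "epsilon": params.epsilon,
                "sigma": params.sigma, "G": params.G.name, "fs": params.fs,
                "duration": params.duration, "n_trials": params.n_trials,
                "seed": params.seed,
            })


def load_trajectories(path) -> PhaseDiffTrajectorySet:
    with h5py.File(path, "r") as f:
        grp = f["trajectories"]
        keys = sorted(grp.keys())
        theta = np.vstack([grp[k][()] for k in keys])
        return PhaseDiffTrajectorySet(theta=theta, fs=float(f.attrs["fs"]))
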