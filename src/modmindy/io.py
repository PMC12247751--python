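"""HDF5 serialization of parameter bundles, recordings, and results."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .fit import FitResult
from .model import (
    LabeledRecording,
    ModelParameters,
    ModulationMatrix,
    StructuredConnectivity,
)
from .synthgen import GroundTruthBundle, SynthConfig

__all__ = [
    "save_params", "load_params",
    "save_recording", "load_recording",
    "save_bundle", "load_bundle",
    "save_fit_result", "load_fit_result",
    "params_scalars_json",
]


def _write_params(grp: h5py.Group, p: ModelParameters) -> None:
    grp.attrs["n_exc"] = p.n_exc
    grp.attrs["n_inh"] = p.n_inh
    grp.attrs["m"] = p.m
    grp.attrs["s_exc"] = p.s_exc
    grp.attrs["s_inh"] = p.s_inh
    for name in ("Wee", "Wie", "Wei", "Wii"):
        grp.create_dataset(name, data=getattr(p.W, name))
    grp.create_dataset("mask_ee", data=p.W.mask_ee.astype(np.uint8))
    grp.create_dataset("mask_ei", data=p.W.mask_ei.astype(np.uint8))
    grp.create_dataset("gamma_u", data=np.stack([g.u for g in p.gammas]))
    grp.create_dataset("gamma_v", data=np.stack([g.v for g in p.gammas]))
    grp.create_dataset("gamma_pinned",
                       data=np.array([g.pinned for g in p.gammas], dtype=np.uint8))
    for name in ("D", "V", "C", "H", "Q", "R"):
        grp.create_dataset(name, data=getattr(p, name))


def _read_params(grp: h5py.Group) -> ModelParameters:
    ne = int(grp.attrs["n_exc"])
    ni = int(grp.attrs["n_inh"])
    W = StructuredConnectivity(
        ne, ni, grp["Wee"][()], grp["Wie"][()], grp["Wei"][()], grp["Wii"][()],
        grp["mask_ee"][()].astype(bool), grp["mask_ei"][()].astype(bool))
    gu, gv = grp["gamma_u"][()], grp["gamma_v"][()]
    pinned = grp["gamma_pinned"][()].astype(bool)
    gammas = [ModulationMatrix(i + 1, gu[i], gv[i], pinned=bool(pinned[i]))
              for i in range(gu.shape[0])]
    return ModelParameters(
        W=W, gammas=gammas, D=grp["D"][()],
        s_exc=float(grp.attrs["s_exc"]), s_inh=float(grp.attrs["s_inh"]),
        V=grp["V"][()], C=grp["C"][()], H=grp["H"][()],
        Q=grp["Q"][()], R=grp["R"][()])


def _write_recording(grp: h5py.Group, rec: LabeledRecording) -> None:
    grp.create_dataset("y", data=rec.y)
    grp.create_dataset("labels", data=rec.labels)
    grp.attrs["fs"] = rec.fs
    if rec.channel_names:
        grp.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype()))
    grp.create_dataset("session_boundaries",
                       data=np.asarray(rec.session_boundaries, dtype=int))


def _read_recording(grp: h5py.Group) -> LabeledRecording:
    names = None
    if "channel_names" in grp:
        names = [s.decode() if isinstance(s, bytes) else str(s)
                 for s in grp["channel_names"][()]]
    return LabeledRecording(
        y=grp["y"][()], fs=float(grp.attrs["fs"]), labels=grp["labels"][()],
        channel_names=names,
        session_boundaries=list(grp["session_boundaries"][()]))


def save_params(path: str, params: ModelParameters) -> None:
    with h5py.File(path, "w") as f:
        _write_params(f.create_group("params"), params)


def load_params(path: str) -> ModelParameters:
    with h5py.File(path, "r") as f:
        return _read_params(f["params"])


def save_recording(path: str, rec: LabeledRecording) -> None:
    with h5py.File(path, "w") as f:
        _write_recording(f.create_group("recording"), rec)


def load_recording(path: str) -> LabeledRecording:
    with h5py.File(path, "r") as f:
        return _read_recording(f["recording"])


def save_bundle(path: str, bundle: GroundTruthBundle) -> None:
    with h5py.File(path, "w") as f:
        _write_params(f.create_group("params"), bundle.params)
        _write_recording(f.create_group("recording"), bundle.recording)
        f.create_dataset("labels", data=bundle.labels)
        f.create_dataset("states", data=bundle.states)
        if bundle.generator_seed is not None:
            f.attrs["generator_seed"] = int(bundle.generator_seed)
        f.attrs["config_json"] = json.dumps(
            {k: v for k, v in vars(bundle.config).items()
             if isinstance(v, (int, float, bool, str)) or v is None})


def load_bundle(path: str) -> GroundTruthBundle:
    with h5py.File(path, "r") as f:
        params = _read_params(f["params"])
        rec = _read_recording(f["recording"])
        labels = f["labels"][()]
        states = f["states"][()]
        seed = int(f.attrs["generator_seed"]) if "generator_seed" in f.attrs else None
        cfg_raw = json.loads(f.attrs["config_json"]) if "config_json" in f.attrs else {}
        cfg = SynthConfig(**{k: v for k, v in cfg_raw.items()
                             if k in SynthConfig.__dataclass_fields__})
    return GroundTruthBundle(params=params, labels=labels, states=states,
                             recording=rec, generator_seed=seed, config=cfg)


def save_fit_result(path: str, result: FitResult) -> None:
    with h5py.File(path, "w") as f:
        _write_params(f.create_group("params"), result.params)
        f.create_dataset("loss_trace", data=result.loss_trace)
        f.create_dataset("window_log", data=result.window_log)
        f.attrs["converged"] = bool(result.converged)
        f.attrs["n_iterations"] = int(result.n_iterations)


def load_fit_result(path: str) -> FitResult:
    with h5py.File(path, "r") as f:
        return FitResult(
            params=_read_params(f["params"]),
            loss_trace=f["loss_trace"][()],
            window_log=f["window_log"][()],
            converged=bool(f.attrs["converged"]),
            n_iterations=int(f.attrs["n_iterations"]))


def params_scalars_json(params: ModelParameters) -> str:
    """Human-readable JSON of the scalar parameters and shapes."""
    info = {
        "n_exc": params.n_exc, "n_inh": params.n_inh, "m": params.m,
        "n_channels": params.n_channels,
        "s_exc": params.s_exc, "s_inh": params.s_inh,
        "D_mean_exc": float(np.mean(params.D[:params.n_exc])),
        "D_mean_inh": float(np.mean(params.D[params.n_exc:])),
        "Q_diag_mean": float(np.mean(np.diag(params.Q))),
        "R_diag_mean": float(np.mean(np.diag(params.R))),
        "gamma_pinned": [g.pinned for g in params.gammas],
    }
    return json.dumps(info, indent=2)
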