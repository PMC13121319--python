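"""Sample and configuration I/O.

Samples travel as delimited text with header columns ``y,delta`` (and
optionally ``t_latent,c_latent`` when fixture mode retains the latent
hitting times); every write drops a JSON sidecar with provenance (seed,
config fingerprint, package version).  Configurations are YAML with a
``model`` block mirroring :class:`~cphit.model.ModelConfig` and optional
``theta`` / ``experiment`` blocks.

Delta coding follows the model definitions: Model I uses 1 = event
(T <= C), 0 = censored; Model II uses 0 = censored (T > C), 1 = event
(T < C) and 2 = tie (T = C).  The 2-code is nonstandard in survival files
and is rejected under Model I.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import ExperimentConfig
from .families import JumpFamily
from .model import ModelConfig, Theta, TruncationPolicy
from .simulate import CensoredSample

__all__ = ["read_sample", "write_sample", "family_from_dict",
           "config_from_dict", "theta_from_dict", "load_run_config"]


def read_sample(path, model_type: str) -> CensoredSample:
    """Load a censored sample from delimited text with columns y, delta."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"y", "delta"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    y = df["y"].to_numpy(dtype=float)
    bad = ~np.isfinite(y) | (y < 0)
    if bad.any():
        raise ValueError(f"{path}: invalid y at data row {int(np.flatnonzero(bad)[0]) + 1}")
    delta_raw = df["delta"].to_numpy()
    if not np.all(delta_raw == np.floor(delta_raw)):
        row = int(np.flatnonzero(delta_raw != np.floor(delta_raw))[0]) + 1
        raise ValueError(f"{path}: non-integer delta at data row {row}")
    delta = delta_raw.astype(np.int64)
    valid = (0, 1) if model_type == "I" else (0, 1, 2)
    bad = ~np.isin(delta, valid)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(
            f"{path}: delta={delta[np.flatnonzero(bad)[0]]} at data row {row} "
            f"invalid for Model {model_type}"
        )
    kw = {}
    if "t_latent" in df.columns and "c_latent" in df.columns:
        kw = {"t_latent": df["t_latent"].to_numpy(float),
              "c_latent": df["c_latent"].to_numpy(float)}
    return CensoredSample(y=y, delta=delta, model_type=model_type, **kw)


def write_sample(sample: CensoredSample, path, overwrite: bool = False) -> Path:
    """Write a sample as CSV (full double precision) plus a JSON sidecar."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    cols = {"y": sample.y, "delta": sample.delta}
    if sample.t_latent is not None:
        cols["t_latent"] = sample.t_latent
        cols["c_latent"] = sample.c_latent
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = dict(sample.provenance, n=int(sample.n),
                model_type=sample.model_type, cphit_version=__version__)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# configuration


def family_from_dict(d: dict) -> JumpFamily:
    """Build a jump family from a config mapping, e.g.
    ``{family: exponential, rate: 0.71}``."""
    d = dict(d)
    tag = d.pop("family")
    ctor = {
        "degenerate": JumpFamily.degenerate,
        "bernoulli": JumpFamily.bernoulli,
        "binomial": JumpFamily.binomial,
        "poisson": JumpFamily.poisson,
        "exponential": JumpFamily.exponential,
        "gamma": JumpFamily.gamma,
        "discrete_lattice": JumpFamily.lattice,
    }.get(tag)
    if ctor is None:
        raise ValueError(f"unknown jump family {tag!r}")
    return ctor(**d)


def config_from_dict(d: dict) -> ModelConfig:
    trunc = d.get("truncation", {})
    return ModelConfig(
        x_family=family_from_dict(d["x_family"]),
        z_family=family_from_dict(d["z_family"]),
        x_threshold=float(d["x_threshold"]),
        z_threshold=float(d["z_threshold"]),
        model_type=str(d.get("model_type", "I")),
        truncation=TruncationPolicy(
            N=int(trunc.get("N", 30)),
            lam_max=float(trunc.get("lam_max", 2.0)),
            tau=float(trunc.get("tau", 20.0)),
        ),
        bounds=tuple(map(tuple, d["bounds"])) if "bounds" in d else None,
    )


def theta_from_dict(d: dict) -> Theta:
    return Theta(float(d["lam"]),
                 tuple(d.get("alpha", ())), tuple(d.get("beta", ())))


def load_run_config(path):
    """Load a YAML run configuration; returns (ModelConfig, Theta | None,
    ExperimentConfig | None, raw dict)."""
    raw = yaml.safe_load(Path(path).read_text())
    config = config_from_dict(raw["model"])
    theta = theta_from_dict(raw["theta"]) if "theta" in raw else None
    exp = None
    if "experiment" in raw:
        e = raw["experiment"]
        if theta is None:
            raise ValueError("an experiment block requires a theta block")
        exp = ExperimentConfig(
            label=str(e.get("label", "custom")),
            theta_true=theta, config=config,
            n_list=tuple(e.get("n_list", (50, 100, 200))),
            M=int(e.get("M", 100)),
            base_seed=int(e.get("base_seed", 0)),
            chi2_levels=tuple(e.get("chi2_levels", (0.90, 0.95, 0.99))),
            grid=tuple(e.get("grid", np.linspace(0.0, 20.0, 81))),
        )
    return config, theta, exp, raw
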