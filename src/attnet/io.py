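"""Seeding, run manifests, HDF5 persistence, and a miniature test fixture.

Seed hierarchy: every stage derives its seed from the master seed and a
stage/condition counter through :func:`derive_seed`, so each stage (topology
construction, each task, each condition block) is independently replayable.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "derive_seed",
    "RunManifest",
    "save_rates",
    "load_rates",
    "save_experiment",
    "load_experiment",
    "make_fixture",
]

ARCHIVE_SCHEMA_VERSION = 1


def derive_seed(master: int, *keys: int) -> int:
    """Counter-based child seed: deterministic, collision-resistant, < 2**31."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunManifest:
    """Traceability record for a run archive."""

    config: dict
    master_seed: int
    derived_seeds: dict = field(default_factory=dict)
    version: str = "attnet 0.1.0"
    schema: int = ARCHIVE_SCHEMA_VERSION
    created: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )
    stages_complete: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def save_rates(group: h5py.Group, data) -> None:
    """Store a RateData (rates matrix + tidy metadata) in an HDF5 group."""
    group.create_dataset("rates", data=data.rates, compression="gzip", shuffle=True)
    meta = group.create_group("meta")
    for col in data.meta.columns:
        values = data.meta[col].to_numpy()
        if values.dtype == object:
            values = values.astype("S")
        meta.create_dataset(col, data=values)


def load_rates(group: h5py.Group):
    from .protocols import RateData  # local: avoids import cycle

    cols = {}
    for col in group["meta"]:
        v = group["meta"][col][...]
        if v.dtype.kind == "S":
            v = v.astype(str)
        cols[col] = v
    return RateData(group["rates"][...], pd.DataFrame(cols))


def save_experiment(result, path, manifest: RunManifest | None = None) -> None:
    from .topology import save_topology

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = ARCHIVE_SCHEMA_VERSION
        if manifest is not None:
            f.attrs["manifest"] = manifest.to_json()
        for k, v in result.params.to_dict().items():
            f.attrs[f"param_{k}"] = v
        for i, sr in enumerate(result.per_seed):
            g = f.create_group(f"init_{i}")
            g.attrs["seed"] = sr.seed
            save_rates(g.create_group("sensory"), sr.sensory)
            save_rates(g.create_group("attention"), sr.attention)
            tg = g.create_group("target_ids")
            for deg, ids in sr.target_ids.items():
                tg.create_dataset(str(deg), data=np.asarray(ids, dtype=int))


def load_experiment(path):
    from .params import ModelParams
    from .protocols import ExperimentResult, SeedResult

    defaults = ModelParams()
    with h5py.File(path, "r") as f:
        kw = {}
        for k, v in f.attrs.items():
            if k.startswith("param_"):
                name = k[len("param_"):]
                kw[name] = int(v) if isinstance(getattr(defaults, name), int) else float(v)
        params = ModelParams(**kw)
        result = ExperimentResult(params=params)
        for name in sorted(k for k in f if k.startswith("init_")):
            g = f[name]
            result.per_seed.append(
                SeedResult(
                    seed=int(g.attrs["seed"]),
                    conn=None,
                    sensory=load_rates(g["sensory"]),
                    target_ids={
                        float(d): g["target_ids"][d][...] for d in g["target_ids"]
                    },
                    attention=load_rates(g["attention"]),
                )
            )
    return result


def make_fixture(scale: int = 8, seed: int = 0, n_trials: int = 3,
                 duration_ms: float = 120.0, window_ms: float = 100.0):
    """Miniature network plus a handful of short trials for fast tests.

    All constants keep their published values; only the layer sizes shrink
    by ``scale`` (default: 8 -> 8x64 sensory neurons, 128 control neurons).
    Returns ``(conn, trials)`` where trials is a list of TrialRecord.
    """
    from .dynamics import run_trial
    from .params import ModelParams
    from .protocols import StimulusSpec
    from .topology import build_topology

    if 512 % scale or 1024 % scale:
        raise ValueError("scale must divide 512 and 1024")
    params = ModelParams(
        n_first_per_sub=512 // scale, n_second=1024 // scale, seed=seed
    )
    conn = build_topology(params, seed=derive_seed(seed, 0))
    trials = []
    for t in range(n_trials):
        trials.append(
            run_trial(
                conn,
                [StimulusSpec(subnetwork=0, mu_deg=90.0, strength=10.0)],
                duration_ms=duration_ms,
                params=params,
                seed=derive_seed(seed, 1, t),
                baseline_ms=20.0,
                window_ms=window_ms,
            )
        )
    return conn, trials
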