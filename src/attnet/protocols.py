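"""Task protocols: sensory task, attention targeting, attention-task grid.

The *sensory* task presents one of 16 stimuli (uniformly tiling the
circular feature space) in isolation to a single sub-network and records
windowed rates; ranking control-neuron responses to the to-be-attended
stimulus selects the top fraction (default 20%) as targets of top-down
modulation.  The *attention* task then presents two stimuli 180 degrees
apart to the same sub-network while driving the targeted control neurons,
over a grid of stimulus strengths and attentional modulation strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0

from .dynamics import _engine_for
from .params import ModelParams
from .topology import Connectivity, build_topology
from .io import derive_seed

__all__ = [
    "StimulusSpec",
    "AttentionSpec",
    "RateData",
    "stimulus_drive",
    "attention_drive",
    "run_sensory_task",
    "select_control_neurons",
    "run_attention_task",
    "run_experiment",
    "sensory_stimulus_set",
]

_MAX_BATCH = 640  # engine batch width cap; keeps per-run buffers ~100 MB


@dataclass(frozen=True)
class StimulusSpec:
    """External drive to one sensory sub-network: a von Mises bump."""

    subnetwork: int = 0
    mu_deg: float = 90.0
    strength: float = 10.0
    kappa_input: float | None = None  # falls back to params.kappa_input
    duration_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("stimulus strength must be >= 0")
        if not 0.0 < self.mu_deg <= 360.0:
            raise ValueError("stimulus angle must be in (0, 360]")


@dataclass(frozen=True)
class AttentionSpec:
    """Top-down modulation of targeted control neurons.

    In ``additive`` mode ``strength`` is added to the rate argument of each
    targeted control neuron during the stimulus epoch; in
    ``multiplicative`` mode the targeted neurons' summed feedforward input
    is scaled by ``strength`` (1 = no modulation).
    """

    target_deg: float = 90.0
    strength: float = 0.0
    proportion: float = 0.2
    mode: str = "additive"
    target_ids: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("proportion must be in (0, 1]")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown attention mode {self.mode!r}")
        if self.mode == "additive" and self.strength < 0:
            raise ValueError("additive attention strength must be >= 0")
        if self.mode == "multiplicative" and self.strength < 1:
            raise ValueError("multiplicative attention strength must be >= 1")


class RateData(NamedTuple):
    """Windowed rates (trials x neurons) with per-trial condition metadata."""

    rates: np.ndarray
    meta: pd.DataFrame


def stimulus_drive(spec: StimulusSpec, params: ModelParams) -> np.ndarray:
    """Per-sensory-neuron external drive vector for one stimulus.

    Neuron i of the target sub-network receives
    ``S_ext * exp(kappa*cos(theta_i - mu)) / (2*pi*I0(kappa))``, truncated
    to zero beyond three standard deviations (sigma = 1/sqrt(kappa) rad)
    from the stimulus angle; all other sub-networks receive zero.
    """
    if not 0 <= spec.subnetwork < params.n_subnetworks:
        raise ValueError(f"unknown sub-network index {spec.subnetwork}")
    kappa = spec.kappa_input if spec.kappa_input is not None else params.kappa_input
    n = params.n_first_per_sub
    theta = 2.0 * np.pi * np.arange(n) / n
    mu = np.deg2rad(spec.mu_deg)
    delta = theta - mu
    delta = delta - 2.0 * np.pi * np.round(delta / (2.0 * np.pi))
    drive = spec.strength * np.exp(kappa * np.cos(delta)) / (2.0 * np.pi * i0(kappa))
    sigma = 1.0 / np.sqrt(kappa)
    drive[np.abs(delta) > 3.0 * sigma] = 0.0
    full = np.zeros(params.n_first_total)
    lo = spec.subnetwork * n
    full[lo : lo + n] = drive
    return full


def attention_drive(
    spec: AttentionSpec, params: ModelParams
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-control-neuron (additive drive, multiplicative factor) pair."""
    add = np.zeros(params.n_second)
    mult = None
    ids = np.asarray(spec.target_ids, dtype=int)
    if spec.mode == "additive":
        add[ids] = spec.strength
    else:
        mult = np.ones(params.n_second)
        mult[ids] = spec.strength
    return add, mult


def sensory_stimulus_set(n_stimuli: int = 16) -> np.ndarray:
    """Stimulus angles uniformly tiling (0, 360]: {22.5, 45, ..., 360} deg."""
    return 360.0 * np.arange(1, n_stimuli + 1) / n_stimuli


def _run_condition_batches(
    conn: Connectivity,
    conditions: Sequence[dict],
    stim_ms: float,
    baseline_ms: float,
    window_ms: float,
    master_seed: int,
    stage: int,
    params: ModelParams | None = None,
) -> RateData:
    """Simulate a list of condition blocks, chunked to the batch cap.

    Each condition dict carries ``drive1`` (n1,), ``add2`` (n2,), optional
    ``mult2`` (n2,), ``n_trials`` and metadata columns; trials of one
    condition form one independently seeded column group.
    """
    if params is None:
        params = conn.params
    engine = _engine_for(conn)
    all_rates = []
    all_meta = []
    i = 0
    while i < len(conditions):
        chunk = []
        width = 0
        while i < len(conditions) and (
            not chunk or width + conditions[i]["n_trials"] <= _MAX_BATCH
        ):
            chunk.append((i, conditions[i]))
            width += conditions[i]["n_trials"]
            i += 1
        d1 = np.zeros((params.n_first_total, width), dtype=np.float32)
        d2 = np.zeros((params.n_second, width), dtype=np.float32)
        any_mult = any(c.get("mult2") is not None for _, c in chunk)
        m2 = np.ones((params.n_second, width), dtype=np.float32) if any_mult else None
        groups = []
        col = 0
        for ci, cond in chunk:
            nt = cond["n_trials"]
            sl = slice(col, col + nt)
            d1[:, sl] = cond["drive1"][:, None]
            d2[:, sl] = cond["add2"][:, None]
            if any_mult and cond.get("mult2") is not None:
                m2[:, sl] = cond["mult2"][:, None]
            groups.append((sl, derive_seed(master_seed, stage, ci)))
            for t in range(nt):
                all_meta.append({**cond["meta"], "trial": t})
            col += nt
        rates, _ = engine.run(
            d1,
            d2,
            seed_groups=groups,
            stim_ms=stim_ms,
            baseline_ms=baseline_ms,
            window_ms=window_ms,
            mult_second=m2,
            dt_ms=params.dt_ms,
        )
        all_rates.append(rates)
    return RateData(np.concatenate(all_rates, axis=0), pd.DataFrame(all_meta))


def run_sensory_task(
    conn: Connectivity,
    params: ModelParams | None = None,
    seed: int = 0,
    stimuli_deg: Iterable[float] | None = None,
    n_trials: int = 100,
    strength: float = 10.0,
    subnetwork: int = 0,
    duration_ms: float = 300.0,
    baseline_ms: float = 100.0,
    window_ms: float = 250.0,
) -> RateData:
    """Present each stimulus in isolation and record windowed rates.

    Defaults follow the published protocol: 16 stimuli uniformly tiling
    (0, 360], 100 trials each, 300 ms stimulus at strength 10 presented to
    sub-network 0.
    """
    if params is None:
        params = conn.params
    if stimuli_deg is None:
        stimuli_deg = sensory_stimulus_set()
    conditions = []
    for mu in stimuli_deg:
        spec = StimulusSpec(subnetwork=subnetwork, mu_deg=float(mu), strength=strength)
        conditions.append(
            {
                "drive1": stimulus_drive(spec, params),
                "add2": np.zeros(params.n_second),
                "n_trials": n_trials,
                "meta": {"stimulus_deg": float(mu), "strength": strength},
            }
        )
    return _run_condition_batches(
        conn, conditions, duration_ms, baseline_ms, window_ms, seed, stage=1,
        params=params,
    )


def select_control_neurons(
    sensory: RateData,
    target_deg: float,
    proportion: float = 0.2,
    params: ModelParams | None = None,
    n_second: int | None = None,
) -> np.ndarray:
    """Rank control neurons by mean rate to the target stimulus; keep the top.

    Returns the indices (into the control layer) of the
    ``floor(proportion * n_second)`` highest responders; rate ties are
    broken by neuron index for determinism.
    """
    if params is not None:
        n_second = params.n_second
    if n_second is None:
        raise ValueError("provide params or n_second")
    mask = sensory.meta["stimulus_deg"].to_numpy() == float(target_deg)
    if not mask.any():
        raise ValueError(f"{target_deg} deg is not among the sensory-task stimuli")
    n_first_total = sensory.rates.shape[1] - n_second
    mean_rates = sensory.rates[mask, n_first_total:].mean(axis=0)
    k = int(np.floor(proportion * n_second))
    order = np.argsort(-mean_rates, kind="stable")
    return np.sort(order[:k])


def run_attention_task(
    conn: Connectivity,
    target_ids_per_stimulus: dict[float, np.ndarray],
    params: ModelParams | None = None,
    seed: int = 0,
    stim_strengths: Iterable[float] = tuple(range(20)),
    att_strengths: Iterable[float] = tuple(range(0, 19, 2)),
    attended_degs: Iterable[float] = (90.0, 270.0),
    n_trials: int = 50,
    proportion: float = 0.2,
    mode: str = "additive",
    subnetwork: int = 0,
    duration_ms: float = 1000.0,
    baseline_ms: float = 100.0,
    window_ms: float = 250.0,
) -> RateData:
    """Two stimuli 180 degrees apart with concurrent top-down modulation.

    Runs the full condition grid (stimulus strength x attention strength x
    attended stimulus) with ``n_trials`` trials per condition; published
    grid: strengths 0-19 step 1, modulation 0-18 step 2, 50 trials.
    """
    if params is None:
        params = conn.params
    conditions = []
    for attended in attended_degs:
        if attended not in target_ids_per_stimulus:
            raise ValueError(f"no target ids resolved for attended {attended} deg")
        unattended = attended + 180.0 if attended <= 180.0 else attended - 180.0
        ids = tuple(int(i) for i in target_ids_per_stimulus[attended])
        for s_stim in stim_strengths:
            drive = stimulus_drive(
                StimulusSpec(subnetwork=subnetwork, mu_deg=attended, strength=s_stim),
                params,
            ) + stimulus_drive(
                StimulusSpec(subnetwork=subnetwork, mu_deg=unattended, strength=s_stim),
                params,
            )
            for s_att in att_strengths:
                spec = AttentionSpec(
                    target_deg=attended,
                    strength=s_att if mode == "additive" else max(1.0, s_att),
                    proportion=proportion,
                    mode=mode,
                    target_ids=ids,
                )
                add2, mult2 = attention_drive(spec, params)
                conditions.append(
                    {
                        "drive1": drive,
                        "add2": add2,
                        "mult2": mult2,
                        "n_trials": n_trials,
                        "meta": {
                            "stim_strength": float(s_stim),
                            "att_strength": float(s_att),
                            "attended_deg": float(attended),
                            "unattended_deg": float(unattended),
                            "mode": mode,
                        },
                    }
                )
    return _run_condition_batches(
        conn, conditions, duration_ms, baseline_ms, window_ms, seed, stage=2,
        params=params,
    )


@dataclass
class SeedResult:
    """All raw outputs of one network initialization."""

    seed: int
    conn: Connectivity
    sensory: RateData
    target_ids: dict[float, np.ndarray]
    attention: RateData


@dataclass
class ExperimentResult:
    params: ModelParams
    per_seed: list[SeedResult] = field(default_factory=list)

    def crf_summary(self) -> pd.DataFrame:
        """Across-seed mean and SEM of the contrast-response functions."""
        from .analysis import compute_crf  # local: avoids import cycle

        tables = []
        for sr in self.per_seed:
            t = compute_crf(sr.attention, self.params)
            t["seed"] = sr.seed
            tables.append(t)
        pooled = pd.concat(tables, ignore_index=True)
        g = pooled.groupby(["stim_strength", "att_strength"])
        out = g[["attended_rate", "unattended_rate"]].agg(["mean", "sem"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()


def run_experiment(
    params: ModelParams,
    n_inits: int = 10,
    master_seed: int = 0,
    keep_connectivity: bool = False,
    sensory_kwargs: dict | None = None,
    attention_kwargs: dict | None = None,
    proportion: float = 0.2,
    mode: str = "additive",
    attended_degs: Iterable[float] = (90.0, 270.0),
) -> ExperimentResult:
    """Multi-seed driver: topology -> sensory task -> targeting -> attention.

    Each initialization rebuilds the inter-layer connectivity from its own
    derived seed, so across-seed variability reflects the random wiring.
    """
    if n_inits < 1:
        raise ValueError("n_inits must be >= 1")
    sensory_kwargs = dict(sensory_kwargs or {})
    attention_kwargs = dict(attention_kwargs or {})
    result = ExperimentResult(params=params)
    for k in range(n_inits):
        topo_seed = derive_seed(master_seed, 0, k)
        conn = build_topology(params, seed=topo_seed)
        sensory = run_sensory_task(
            conn, params, seed=derive_seed(master_seed, 1, k), **sensory_kwargs
        )
        target_ids = {
            deg: select_control_neurons(sensory, deg, proportion, params=params)
            for deg in attended_degs
        }
        attention = run_attention_task(
            conn,
            target_ids,
            params,
            seed=derive_seed(master_seed, 2, k),
            proportion=proportion,
            mode=mode,
            attended_degs=attended_degs,
            **attention_kwargs,
        )
        result.per_seed.append(
            SeedResult(
                seed=topo_seed,
                conn=conn if keep_connectivity else None,
                sensory=sensory,
                target_ids=target_ids,
                attention=attention,
            )
        )
    return result
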