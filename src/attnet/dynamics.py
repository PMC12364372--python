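"""Poisson spiking dynamics of the two-layer network.

Each neuron carries a synaptic activation ``s`` that jumps toward its
saturation level (``s_max``, a gating-variable convention that bounds
reverberation in the reciprocal inter-layer loop) at each of its spikes and
decays exponentially with time constant tau between spikes.
The summed synaptic input ``g_i = sum_j W_ij s_j + drive_i`` is mapped
through a baseline-shifted tanh to an instantaneous rate (spikes/ms), and
spikes are drawn by Bernoulli thinning of the inhomogeneous Poisson process
at each step (at most one spike per neuron per step; valid because
``r*dt <= 0.08`` at the default step of 0.1 ms).

Update order within a step, fixed and documented: rates are computed from
the pre-decay activations, activations decay exactly by ``exp(-dt/tau)``,
spikes are drawn, and spiking neurons' activations are incremented.  Order
effects vanish as dt -> 0 (checked by a dt-refinement test).

The heavy path is a trial-batched float32 engine: with activations stored
as an (n_neurons x n_trials) matrix, the inter-layer input is a single
matrix product per layer per step, and the within-ring input is one
(n x n) product per sub-network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams
from .topology import Connectivity

__all__ = ["NetworkState", "TrialRecord", "transfer", "step", "SimEngine", "run_trial"]


def transfer(g, params: ModelParams | None = None):
    """Instantaneous firing rate (spikes/ms) from summed synaptic input.

    ``r = gain * (1 + tanh(slope*g - offset))``; strictly increasing,
    bounded in (0, 2*gain).  With the default constants the ceiling is
    0.8 spikes/ms and the quiescent rate transfer(0) is ~0.002 spikes/ms
    (~2 Hz).
    """
    if params is None:
        params = _DEFAULT_PARAMS
    g = np.asarray(g, dtype=float)
    r = params.transfer_gain * (
        1.0 + np.tanh(params.transfer_slope * g - params.transfer_offset)
    )
    return r if r.ndim else float(r)


_DEFAULT_PARAMS = ModelParams()


@dataclass
class NetworkState:
    """Synaptic activations of all neurons (sensory layer first) at time t."""

    s: np.ndarray
    t_ms: float = 0.0

    @classmethod
    def zeros(cls, params: ModelParams) -> "NetworkState":
        return cls(s=np.zeros(params.n_total), t_ms=0.0)


@dataclass
class TrialRecord:
    """Spikes and windowed mean rates for one simulated trial."""

    spikes: np.ndarray  # structured: neuron_id, t_ms
    rates_window: np.ndarray  # spikes/ms, per neuron
    stimulus_specs: tuple
    attention_spec: object
    seed: int
    duration_ms: float = 0.0
    window_ms: float = 250.0


def step(
    state: NetworkState,
    drives: np.ndarray,
    connectivity: Connectivity,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the network one integration step.

    ``drives`` is the per-neuron external input (stimulus drive for sensory
    neurons, attentional drive for control neurons) added to the recurrent
    input.  Returns the new state and the boolean spike vector.
    """
    engine = _engine_for(connectivity)
    s = state.s[:, None].astype(np.float32)
    g = engine._summed_input(s[: engine.n1], s[engine.n1 :], None)
    g += np.asarray(drives, dtype=np.float32)[:, None]
    r = transfer(g.ravel(), params)
    s_new = state.s * np.exp(-params.dt_ms / params.tau_ms)
    spikes = rng.random(params.n_total) < np.minimum(1.0, r * params.dt_ms)
    s_new = np.minimum(s_new + spikes, params.s_max)
    return NetworkState(s=s_new, t_ms=state.t_ms + params.dt_ms), spikes


def _engine_for(conn: Connectivity) -> "SimEngine":
    """Cache one engine per Connectivity (the float32 copies are large)."""
    engine = getattr(conn, "_engine", None)
    if engine is None:
        engine = SimEngine(conn)
        conn._engine = engine
    return engine


class SimEngine:
    """Trial-batched float32 simulation engine bound to one topology.

    The balanced inter-layer matrices are rank-one corrections of the
    scaled adjacency, so per step the engine computes
    ``g2 = (alpha/Nexc) * (A @ s1) - (alpha/N1) * sum(s1) + drive2`` and
    ``g1 = ring(s1) + (beta/Nexc_fb) * (A.T @ s2) - (beta/N2) * sum(s2)
    + drive1`` without materialising the dense weight matrices.
    """

    def __init__(self, conn: Connectivity):
        p = conn.params
        self.params = p
        self.n1 = p.n_first_total
        self.n2 = p.n_second
        self.n_sub = p.n_subnetworks
        self.n_ring = p.n_first_per_sub
        self.A = np.ascontiguousarray(conn.adjacency, dtype=np.float32)
        self.At = np.ascontiguousarray(conn.adjacency.T, dtype=np.float32)
        self.ff_scale = (p.alpha / conn.n_exc_ff).astype(np.float32)[:, None]
        self.ff_off = np.float32(p.alpha / self.n1)
        self.fb_scale = (p.beta / conn.n_exc_fb).astype(np.float32)[:, None]
        self.fb_off = np.float32(p.beta / self.n2)
        self.W_ring = conn.W_first.astype(np.float32)
        self.gain = np.float32(p.transfer_gain)
        self.slope = np.float32(p.transfer_slope)
        self.offset = np.float32(p.transfer_offset)
        self.s_max = np.float32(p.s_max)

    def _summed_input(self, s1: np.ndarray, s2: np.ndarray, mult2) -> np.ndarray:
        """Recurrent input g for the full population, shape (n_total, B)."""
        b = s1.shape[1]
        g1 = np.empty((self.n1, b), dtype=np.float32)
        s1_3d = s1.reshape(self.n_sub, self.n_ring, b)
        g1_3d = g1.reshape(self.n_sub, self.n_ring, b)
        for k in range(self.n_sub):
            np.matmul(self.W_ring, s1_3d[k], out=g1_3d[k])
        g1 += self.fb_scale * (self.At @ s2)
        g1 -= self.fb_off * s2.sum(axis=0, dtype=np.float32)[None, :]
        g2 = self.ff_scale * (self.A @ s1)
        g2 -= self.ff_off * s1.sum(axis=0, dtype=np.float32)[None, :]
        if mult2 is not None:
            g2 *= mult2
        return np.concatenate([g1, g2], axis=0)

    def _rate(self, g: np.ndarray) -> np.ndarray:
        return self.gain * (1.0 + np.tanh(self.slope * g - self.offset))

    def run(
        self,
        drive_first: np.ndarray,
        drive_second: np.ndarray,
        seed_groups: Sequence[tuple[slice, int]],
        stim_ms: float,
        baseline_ms: float = 100.0,
        window_ms: float = 250.0,
        mult_second: np.ndarray | None = None,
        record_spikes: bool = False,
        dt_ms: float | None = None,
    ):
        """Simulate a batch of trials sharing the topology.

        ``drive_first`` (n1 x B) and ``drive_second`` (n2 x B) are applied
        during the stimulus epoch only; the trial is ``baseline_ms`` of
        drive-free settling followed by ``stim_ms`` of stimulation, and the
        windowed rates average the last ``window_ms`` before stimulus
        offset.  ``seed_groups`` partitions the trial columns into
        independently seeded streams so each condition block is
        reproducible on its own.

        Returns ``(rates, spikes)``: rates is (B x n_total) in spikes/ms;
        spikes is a list per trial of (neuron_id, t_ms) arrays when
        ``record_spikes`` else None.
        """
        p = self.params
        b = drive_first.shape[1]
        dt = p.dt_ms if dt_ms is None else dt_ms
        if 2.0 * p.transfer_gain * dt > 0.1:
            raise ValueError(
                "dt too coarse for Bernoulli thinning: ceiling rate * dt > 0.1"
            )
        n_base = int(round(baseline_ms / dt))
        n_stim = int(round(stim_ms / dt))
        n_window = int(round(window_ms / dt))
        if n_window > n_base + n_stim:
            raise ValueError("analysis window longer than the trial")
        decay = np.float32(np.exp(-dt / p.tau_ms))
        d1 = np.ascontiguousarray(drive_first, dtype=np.float32)
        d2 = np.ascontiguousarray(drive_second, dtype=np.float32)
        m2 = None
        if mult_second is not None:
            m2 = np.ascontiguousarray(mult_second, dtype=np.float32)
        rngs = [(sl, np.random.default_rng(seed)) for sl, seed in seed_groups]
        s = np.zeros((p.n_total, b), dtype=np.float32)
        counts = np.zeros((p.n_total, b), dtype=np.float32)
        u = np.empty((p.n_total, b), dtype=np.float32)
        # preallocated work buffers; the loop below is allocation-free
        g = np.empty((p.n_total, b), dtype=np.float32)
        g1, g2 = g[: self.n1], g[self.n1 :]
        ring = np.empty((self.n1, b), dtype=np.float32)
        s1, s2 = s[: self.n1], s[self.n1 :]
        s1_3d = s1.reshape(self.n_sub, self.n_ring, b)
        ring_3d = ring.reshape(self.n_sub, self.n_ring, b)
        spk = np.empty((p.n_total, b), dtype=np.float32)
        spike_log: list[list] = [[] for _ in range(b)] if record_spikes else None
        n_steps = n_base + n_stim
        window_start = n_steps - n_window
        pdt = np.float32(dt * p.transfer_gain)
        for t in range(n_steps):
            in_stim = t >= n_base
            np.matmul(self.At, s2, out=g1)
            g1 *= self.fb_scale
            g1 -= self.fb_off * s2.sum(axis=0, dtype=np.float32)[None, :]
            for k in range(self.n_sub):
                np.matmul(self.W_ring, s1_3d[k], out=ring_3d[k])
            g1 += ring
            np.matmul(self.A, s1, out=g2)
            g2 *= self.ff_scale
            g2 -= self.ff_off * s1.sum(axis=0, dtype=np.float32)[None, :]
            if in_stim:
                if m2 is not None:
                    g2 *= m2
                g1 += d1
                g2 += d2
            # spike probability = gain*(1+tanh(slope*g - offset)) * dt, in place
            g *= self.slope
            g -= self.offset
            np.tanh(g, out=g)
            g += np.float32(1.0)
            g *= pdt
            s *= decay
            for sl, rng in rngs:
                u[:, sl] = rng.random((p.n_total, u[:, sl].shape[1]), dtype=np.float32)
            np.subtract(g, u, out=spk)  # spk > 0 iff u < p
            np.sign(spk, out=spk)
            np.maximum(spk, 0.0, out=spk)
            s += spk
            np.minimum(s, self.s_max, out=s)
            if t >= window_start:
                counts += spk
            if record_spikes:
                t_ms = (t + 1) * dt
                nz_n, nz_b = np.nonzero(spk)
                for nn, bb in zip(nz_n, nz_b):
                    spike_log[bb].append((nn, t_ms))
        rates = (counts / np.float32(n_window * dt)).T.astype(float)
        if record_spikes:
            spikes = [
                np.array(lst, dtype=[("neuron_id", int), ("t_ms", float)])
                for lst in spike_log
            ]
            return rates, spikes
        return rates, None


def run_trial(
    connectivity: Connectivity,
    stimulus_specs: Sequence,
    attention_spec=None,
    duration_ms: float = 300.0,
    params: ModelParams | None = None,
    seed: int = 0,
    baseline_ms: float = 100.0,
    window_ms: float = 250.0,
    record_spikes: bool = True,
) -> TrialRecord:
    """Simulate a single trial from stimulus/attention specifications.

    ``duration_ms`` is the stimulus-epoch length (300 ms in the sensory
    task, 1000 ms in the attention task); a drive-free baseline epoch
    precedes it and windowed rates average the last ``window_ms`` before
    stimulus offset.  Multiple simultaneous stimuli to one sub-network sum
    their drives; the attentional drive is applied only during the stimulus
    epoch.
    """
    from .protocols import attention_drive, stimulus_drive  # local: avoids cycle

    if params is None:
        params = connectivity.params
    d1 = np.zeros((params.n_first_total, 1), dtype=np.float32)
    for spec in stimulus_specs:
        d1[:, 0] += stimulus_drive(spec, params)
    d2 = np.zeros((params.n_second, 1), dtype=np.float32)
    m2 = None
    if attention_spec is not None:
        add, mult = attention_drive(attention_spec, params)
        d2[:, 0] = add
        if mult is not None:
            m2 = mult[:, None]
    engine = _engine_for(connectivity)
    rates, spikes = engine.run(
        d1,
        d2,
        seed_groups=[(slice(0, 1), seed)],
        stim_ms=duration_ms,
        baseline_ms=baseline_ms,
        window_ms=window_ms,
        mult_second=m2,
        record_spikes=record_spikes,
        dt_ms=params.dt_ms,
    )
    return TrialRecord(
        spikes=spikes[0] if spikes is not None else None,
        rates_window=rates[0],
        stimulus_specs=tuple(stimulus_specs),
        attention_spec=attention_spec,
        seed=seed,
        duration_ms=duration_ms,
        window_ms=window_ms,
    )
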