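"""Network topology: ring kernels and balanced inter-layer connectivity.

The sensory layer is a set of independent ring networks whose within-ring
weights follow a difference of circular normal (von Mises) kernels —
short-range excitation, longer-range suppression — so every neuron acquires
a circular tuning curve.  The control layer connects to the sensory layer
through reciprocal excitatory connections whose existence is either fully
random (kappa_structure = 0) or biased toward like-tuned sensory neurons
across sub-networks (kappa_structure > 0).  After the excitatory adjacency
is drawn, weights are balanced so every neuron receives zero net drive from
a uniformly active network: each excitatory connection onto neuron *i*
carries ``coupling / Nexc_i`` and every input additionally carries a broad
inhibitory offset ``-coupling / N_inputs``, making each row of the
inter-layer weight matrices sum to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import i0

from .params import ModelParams

__all__ = [
    "Connectivity",
    "ring_kernel",
    "build_ring_weights",
    "build_interlayer",
    "balance_weights",
    "build_topology",
    "save_topology",
    "load_topology",
]

logger = logging.getLogger("attnet")

_RESAMPLE_LIMIT = 100


def ring_kernel(theta_offset, params: ModelParams):
    """Within-ring weight as a function of preferred-angle offset (radians).

    ``w(theta) = lam + A*exp(k1*(cos(theta)-1)) - A*exp(k2*(cos(theta)-1))``
    with the self-connection override ``w(0) = 0``.  Accepts scalars or
    arrays; offsets are wrapped to (-pi, pi].
    """
    theta = np.asarray(theta_offset, dtype=float)
    wrapped = theta - 2.0 * np.pi * np.round(theta / (2.0 * np.pi))
    c = np.cos(wrapped) - 1.0
    w = params.lam + params.A * np.exp(params.k1 * c) - params.A * np.exp(params.k2 * c)
    w = np.where(wrapped == 0.0, 0.0, w)
    return w if w.ndim else float(w)


def preferred_angles_deg(n: int) -> np.ndarray:
    """Preferred angle of each ring neuron, degrees: theta_i = 360*i/n."""
    return 360.0 * np.arange(n) / n


def build_ring_weights(params: ModelParams) -> np.ndarray:
    """Dense within-sub-network weight matrix (circulant, zero diagonal).

    Entry (i, j) is ``ring_kernel(theta_i - theta_j)``.  The same matrix is
    shared by all sub-networks.
    """
    n = params.n_first_per_sub
    offsets = 2.0 * np.pi * np.arange(n) / n
    row = ring_kernel(offsets, params)  # w(theta_0 - theta_j) with theta in [0, 2pi)
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return row[idx]


@dataclass
class Connectivity:
    """Weight matrices and adjacency of a built network.

    ``W_first`` is the single ring block shared by all sub-networks.
    ``adjacency`` marks excitatory inter-layer connections
    (n_second x n_first_total); feedback adjacency is its transpose
    (reciprocity).  ``W_FF`` / ``W_FB`` are the dense balanced matrices.
    """

    params: ModelParams
    W_first: np.ndarray
    adjacency: np.ndarray
    W_FF: np.ndarray
    W_FB: np.ndarray
    n_exc_ff: np.ndarray  # per control neuron
    n_exc_fb: np.ndarray  # per sensory neuron
    mu_pref: np.ndarray  # per control neuron, degrees
    seed: int = 0
    theta_first_deg: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.theta_first_deg is None:
            self.theta_first_deg = np.tile(
                preferred_angles_deg(self.params.n_first_per_sub),
                self.params.n_subnetworks,
            )


def _draw_row(
    rng: np.random.Generator, params: ModelParams, mu_deg: float, bernoulli: bool
) -> np.ndarray:
    """Excitatory adjacency row (over all sensory neurons) for one control neuron."""
    n = params.n_first_per_sub
    kappa = params.kappa_structure
    row = np.zeros(params.n_first_total, dtype=bool)
    if bernoulli:
        if kappa > 0:
            raise ValueError("per-pair Bernoulli mode is defined for kappa_structure=0")
        row[:] = rng.random(params.n_first_total) < params.p_exc
        return row
    theta = np.deg2rad(preferred_angles_deg(n))
    if kappa > 0:
        w = np.exp(kappa * np.cos(theta - np.deg2rad(mu_deg)))
        p = w / w.sum()
    else:
        p = None
    for k in range(params.n_subnetworks):
        count = rng.binomial(n, params.p_exc)
        if count == 0:
            continue
        chosen = rng.choice(n, size=count, replace=False, p=p)
        row[k * n + chosen] = True
    return row


def build_interlayer(
    params: ModelParams, rng_seed: int, bernoulli: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the reciprocal excitatory inter-layer adjacency.

    For each control neuron and each sub-network the connection count is
    Binomial(n_first_per_sub, p_exc); partners are chosen without
    replacement, uniformly when kappa_structure = 0 and proportionally to
    ``exp(kappa*cos(theta - mu)) / (2*pi*I0(kappa))`` when kappa_structure
    > 0, where mu is that control neuron's preferred angle, drawn once
    uniformly from the 360 integer degrees.  With ``bernoulli=True``
    (kappa = 0 only) connection existence is instead drawn independently
    per pair with probability p_exc.

    Returns ``(adjacency, mu_pref)``.  Rows or columns left with no
    excitatory connection are resampled/repaired so the balancing formulas
    stay well-defined; each event is logged.
    """
    rng = np.random.default_rng(rng_seed)
    n2 = params.n_second
    mu_pref = rng.integers(1, 361, size=n2).astype(float)
    adjacency = np.zeros((n2, params.n_first_total), dtype=bool)
    for c in range(n2):
        row = _draw_row(rng, params, mu_pref[c], bernoulli)
        attempts = 0
        while not row.any():
            attempts += 1
            if attempts > _RESAMPLE_LIMIT:
                raise RuntimeError(
                    f"control neuron {c}: no excitatory connections after "
                    f"{_RESAMPLE_LIMIT} resamples"
                )
            logger.info("resampling empty adjacency row for control neuron %d", c)
            row = _draw_row(rng, params, mu_pref[c], bernoulli)
        adjacency[c] = row
    # A sensory neuron with zero connected control neurons would break the
    # feedback balancing; connect it to one random control neuron.
    empty_cols = np.flatnonzero(~adjacency.any(axis=0))
    for j in empty_cols:
        c = int(rng.integers(n2))
        adjacency[c, j] = True
        logger.info("repaired empty adjacency column for sensory neuron %d", j)
    return adjacency, mu_pref


def structured_selection_density(theta_rad, mu_rad, kappa: float):
    """Von Mises selection density (per radian) used for structured wiring."""
    return np.exp(kappa * np.cos(np.asarray(theta_rad) - mu_rad)) / (
        2.0 * np.pi * i0(kappa)
    )


def balance_weights(
    adjacency: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced feedforward and feedback weight matrices from the adjacency.

    Feedforward row i (control neuron): excitatory entries get
    ``alpha/Nexc_i - alpha/N_first_total`` and every entry (connected or
    not) carries the broad inhibition ``-alpha/N_first_total``; feedback row
    j (sensory neuron) analogously with beta and divisor n_second.  Every
    row of both matrices sums to zero.
    """
    n2, n1 = adjacency.shape
    if n1 != params.n_first_total or n2 != params.n_second:
        raise ValueError("adjacency shape does not match params")
    n_exc_ff = adjacency.sum(axis=1)
    n_exc_fb = adjacency.sum(axis=0)
    if (n_exc_ff == 0).any() or (n_exc_fb == 0).any():
        raise ValueError("adjacency has rows/columns with no excitatory connection")
    W_FF = np.where(adjacency, params.alpha / n_exc_ff[:, None], 0.0) - (
        params.alpha / n1
    )
    W_FB = np.where(adjacency.T, params.beta / n_exc_fb[:, None], 0.0) - (
        params.beta / n2
    )
    return W_FF, W_FB


def build_topology(
    params: ModelParams, seed: int | None = None, bernoulli: bool = False
) -> Connectivity:
    """Construct the full network: ring weights + balanced inter-layer weights."""
    if seed is None:
        seed = params.seed
    W_first = build_ring_weights(params)
    adjacency, mu_pref = build_interlayer(params, seed, bernoulli=bernoulli)
    W_FF, W_FB = balance_weights(adjacency, params)
    return Connectivity(
        params=params,
        W_first=W_first,
        adjacency=adjacency,
        W_FF=W_FF,
        W_FB=W_FB,
        n_exc_ff=adjacency.sum(axis=1),
        n_exc_fb=adjacency.sum(axis=0),
        mu_pref=mu_pref,
        seed=seed,
    )


def save_topology(conn: Connectivity, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W_first", data=conn.W_first, compression="gzip")
        f.create_dataset(
            "adjacency", data=conn.adjacency.astype(np.uint8), compression="gzip"
        )
        f.create_dataset("W_FF", data=conn.W_FF, compression="gzip")
        f.create_dataset("W_FB", data=conn.W_FB, compression="gzip")
        f.create_dataset("mu_pref", data=conn.mu_pref)
        meta = f.create_group("meta")
        meta.attrs["topology_seed"] = conn.seed
        for k, v in conn.params.to_dict().items():
            meta.attrs[k] = v


def load_topology(path) -> Connectivity:
    with h5py.File(path, "r") as f:
        meta = dict(f["meta"].attrs)
        seed = int(meta.pop("topology_seed"))
        defaults = ModelParams()
        # h5py returns numpy scalars; coerce through the dataclass field types
        params = ModelParams(**{
            k: (int(v) if isinstance(getattr(defaults, k), int) else float(v))
            for k, v in meta.items()
        })
        adjacency = f["adjacency"][...].astype(bool)
        return Connectivity(
            params=params,
            W_first=f["W_first"][...],
            adjacency=adjacency,
            W_FF=f["W_FF"][...],
            W_FB=f["W_FB"][...],
            n_exc_ff=adjacency.sum(axis=1),
            n_exc_fb=adjacency.sum(axis=0),
            mu_pref=f["mu_pref"][...],
            seed=seed,
        )
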