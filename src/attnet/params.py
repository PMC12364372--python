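"""Model parameters and configuration loading.

All scalar constants of the network live in :class:`ModelParams`.  The
defaults are the published operating point of the model: two layers of
Poisson spiking neurons, eight ring-structured sensory sub-networks of 512
neurons reciprocally coupled to 1024 mixed-selectivity control neurons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "load_config", "save_config"]


@dataclass(frozen=True)
class ModelParams:
    """All scalar constants of the network.

    Parameters
    ----------
    n_subnetworks
        Number of independent ring sub-networks in the sensory layer.
    n_first_per_sub
        Neurons per sensory ring; neuron i prefers ``360*i/N`` degrees.
    n_second
        Number of control-layer neurons.
    k1, k2
        Concentrations of the excitation / suppression kernels of the
        within-ring difference-of-von-Mises weight profile.
    A, lam
        Amplitude and baseline offset of the ring kernel.  With the default
        zero offset the kernel is a pure difference of von Mises lobes:
        zero at the center, mildly inhibitory at long range (w(pi) < 0), so
        the spontaneous state stays quiet while two stimulus bumps can
        coexist and weakly suppress each other.
    alpha, beta
        Total feedforward / feedback excitatory coupling; each excitatory
        inter-layer connection carries ``alpha/Nexc`` (resp. ``beta/Nexc``)
        before the broad inhibitory offset.
    p_exc
        Probability of an excitatory inter-layer connection.
    tau_ms
        Synaptic time constant of the exponential activation decay.
    transfer_gain, transfer_slope, transfer_offset
        Constants of the baseline-shifted tanh transfer function
        ``r = gain * (1 + tanh(slope * g - offset))`` (spikes/ms).
    dt_ms
        Euler / Poisson-thinning integration step.
    kappa_structure
        Concentration of the connection-probability profile linking
        like-tuned sensory neurons to common control neurons; 0 = fully
        random.
    kappa_input
        Concentration of the von Mises stimulus-drive profile.
    s_max
        Saturation level of the synaptic activation (gating-variable
        convention: a spike drives s toward s_max, never beyond).  Bounds
        the reverberation of the reciprocal inter-layer loop.
    seed
        Master seed for topology construction.
    """

    n_subnetworks: int = 8
    n_first_per_sub: int = 512
    n_second: int = 1024
    k1: float = 1.0
    k2: float = 0.83
    A: float = 2.0
    lam: float = 0.0
    alpha: float = 2100.0
    beta: float = 200.0
    p_exc: float = 0.35
    tau_ms: float = 10.0
    transfer_gain: float = 0.4
    transfer_slope: float = 0.25
    transfer_offset: float = 3.0
    dt_ms: float = 0.1
    kappa_structure: float = 0.0
    kappa_input: float = 14.0
    s_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subnetworks, self.n_first_per_sub, self.n_second) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if not 0.0 <= self.p_exc <= 1.0:
            raise ValueError(f"p_exc must be in [0, 1], got {self.p_exc}")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")
        if self.dt_ms <= 0 or self.dt_ms > self.tau_ms / 10.0:
            raise ValueError(
                f"dt_ms must satisfy 0 < dt <= tau/10 = {self.tau_ms / 10.0}"
            )
        if self.kappa_structure < 0:
            raise ValueError("kappa_structure must be >= 0")
        if self.kappa_input <= 0:
            raise ValueError("kappa_input must be > 0")
        if self.s_max <= 0:
            raise ValueError("s_max must be > 0")
        # Poisson thinning needs r*dt << 1; the transfer ceiling is 2*gain.
        if 2.0 * self.transfer_gain * self.dt_ms > 0.1:
            raise ValueError(
                "dt_ms too coarse: ceiling rate * dt exceeds 0.1, "
                "Poisson thinning would be inaccurate"
            )

    @property
    def n_first_total(self) -> int:
        return self.n_subnetworks * self.n_first_per_sub

    @property
    def n_total(self) -> int:
        return self.n_first_total + self.n_second

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}


def load_config(path: str | Path) -> tuple[ModelParams, dict[str, Any]]:
    """Load a YAML config into ModelParams plus any task-grid section.

    The ``model`` section (or the document root if no section is used)
    mirrors :class:`ModelParams` field names exactly; unknown keys are
    rejected.  Omitted fields fall back to the published defaults.  A
    ``grid`` section, if present, is returned untouched for the protocol
    drivers.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    grid = doc.pop("grid", {}) or {}
    model = doc.pop("model", None)
    if model is None:
        model = doc
    elif doc:
        raise ValueError(f"unknown top-level keys: {sorted(doc)}")
    unknown = sorted(set(model) - _FIELD_NAMES)
    if unknown:
        raise ValueError(f"unknown model parameter keys: {unknown}")
    return ModelParams(**model), grid


def save_config(params: ModelParams, path: str | Path, grid: dict | None = None) -> None:
    doc: dict[str, Any] = {"model": params.to_dict()}
    if grid:
        doc["grid"] = grid
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
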