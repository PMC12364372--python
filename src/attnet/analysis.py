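"""Analyses: contrast-response functions, gain fits, and decoding.

Gain changes are quantified by fitting Naka-Rushton functions
``R(c) = Gr * c^n / (c^n + Gc^n) + b`` to rate-versus-strength curves with
the response gain Gr and baseline b fixed from the data and the contrast
gain Gc (horizontal shift) and exponent n free; a leftward CRF shift shows
up as a drop in Gc.  Feature decoding uses a circular regression (two
chained empirical-Bayes ridge regressions on the sine and cosine of the
stimulus angle) scored by mean absolute circular error, and a linear SVM
classifying the attended stimulus, including cross-generalization between
unstimulated sub-networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.linear_model import BayesianRidge
from sklearn.multioutput import RegressorChain
from sklearn.svm import SVC

from .params import ModelParams
from .protocols import RateData

__all__ = [
    "NakaRushtonFit",
    "DecodeResult",
    "ring_slice",
    "control_slice",
    "nearest_ring_neurons",
    "circular_mae",
    "sincos_to_deg",
    "compute_crf",
    "attended_gain_percent",
    "naka_rushton",
    "fit_naka_rushton",
    "CircularRidgeDecoder",
    "fit_circular_ridge",
    "sensory_cv_mae",
    "decode_attention",
    "attention_mae_table",
    "svm_decode_cv",
    "svm_accuracy_table",
    "svm_cross_generalize",
    "attended_preferring_rates",
]


# ---------------------------------------------------------------------------
# indexing and circular helpers

def ring_slice(params: ModelParams, subnetwork: int) -> slice:
    """Columns of a rate matrix belonging to one sensory sub-network."""
    n = params.n_first_per_sub
    return slice(subnetwork * n, (subnetwork + 1) * n)


def control_slice(params: ModelParams) -> slice:
    return slice(params.n_first_total, params.n_first_total + params.n_second)


def nearest_ring_neurons(params: ModelParams, angle_deg: float, n: int = 2) -> np.ndarray:
    """Indices (within a ring) of the n neurons closest to an angle.

    Distance ties are broken by neuron index (argsort is stable).
    """
    theta = 360.0 * np.arange(params.n_first_per_sub) / params.n_first_per_sub
    d = np.abs((theta - angle_deg + 180.0) % 360.0 - 180.0)
    return np.sort(np.argsort(d, kind="stable")[:n])


def wrapped_diff_deg(a, b):
    """Signed circular difference a - b wrapped to (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circular_mae(pred_deg, true_deg) -> float:
    """Mean absolute circular error in degrees; 90 is chance on the circle."""
    return float(np.mean(np.abs(wrapped_diff_deg(pred_deg, true_deg))))


def sincos_to_deg(sin_pred, cos_pred) -> np.ndarray:
    """Angle from predicted (sin, cos), mapped to the (0, 360] convention."""
    deg = np.rad2deg(np.arctan2(sin_pred, cos_pred)) % 360.0
    deg = np.atleast_1d(deg)
    deg[deg == 0.0] = 360.0
    return deg


# ---------------------------------------------------------------------------
# contrast-response functions

def compute_crf(
    attention: RateData,
    params: ModelParams,
    subnetwork: int = 0,
    pool_attended: bool = True,
) -> pd.DataFrame:
    """Rate-vs-strength curves for attended- and unattended-tuned neurons.

    For every (stimulus strength, attention strength) cell, averages the
    windowed rates of the two ring neurons centered on the attended
    stimulus and, separately, on the unattended stimulus, over trials (and
    over the two attended-stimulus conditions when ``pool_attended``).
    """
    sl = ring_slice(params, subnetwork)
    meta = attention.meta
    rows = []
    group_cols = ["stim_strength", "att_strength"]
    if not pool_attended:
        group_cols.append("attended_deg")
    for key, idx in meta.groupby(group_cols).groups.items():
        idx = np.asarray(idx)
        att_rates, unatt_rates = [], []
        for attended, sub_idx in meta.loc[idx].groupby("attended_deg").groups.items():
            sub_idx = np.asarray(sub_idx)
            unattended = meta.loc[sub_idx[0], "unattended_deg"]
            ring = attention.rates[sub_idx][:, sl]
            att_rates.append(ring[:, nearest_ring_neurons(params, attended)].mean())
            unatt_rates.append(ring[:, nearest_ring_neurons(params, unattended)].mean())
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row["attended_rate"] = float(np.mean(att_rates))
        row["unattended_rate"] = float(np.mean(unatt_rates))
        rows.append(row)
    return pd.DataFrame(rows).sort_values(group_cols).reset_index(drop=True)


def attended_gain_percent(
    crf: pd.DataFrame,
    att_strengths: Iterable[float] = (2.0, 4.0),
    stim_strengths: Iterable[float] | None = None,
) -> float:
    """Mean percent increase of the attended-neuron rate versus no modulation.

    Each (stimulus strength, attention strength) cell is expressed as the
    percent change of the attended-neuron rate relative to the matched
    attention-0 cell, then averaged.
    """
    base = crf[crf["att_strength"] == 0.0].set_index("stim_strength")["attended_rate"]
    gains = []
    for a in att_strengths:
        cur = crf[crf["att_strength"] == float(a)].set_index("stim_strength")[
            "attended_rate"
        ]
        strengths = cur.index if stim_strengths is None else list(stim_strengths)
        for s in strengths:
            gains.append(100.0 * (cur.loc[s] - base.loc[s]) / base.loc[s])
    return float(np.mean(gains))


# ---------------------------------------------------------------------------
# Naka-Rushton fitting

@dataclass
class NakaRushtonFit:
    """Contrast-gain fit with Gr, b fixed from the curve and (Gc, n) free."""

    Gr: float
    Gc: float
    b: float
    n: float
    rmse: float
    c: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    skipped: bool = False


def naka_rushton(c, Gr: float, Gc: float, b: float, n: float):
    """Saturating CRF model; handles the c=0, n<0 limit (ratio -> 1)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        cn = np.power(c, n)
        gcn = np.power(float(Gc), n) if Gc >= 0 else np.nan
        ratio = np.where(np.isinf(cn), 1.0, cn / (cn + gcn))
    return Gr * ratio + b


_N_GRID = np.round(np.arange(-10.0, 10.0 + 1e-9, 0.1), 10)
_GC_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.01), 10)


def fit_naka_rushton(
    strengths: Sequence[float],
    rates: Sequence[float],
    max_strength: float = 19.0,
    Gr: float | None = None,
    b: float | None = None,
) -> NakaRushtonFit:
    """Two-stage Naka-Rushton fit: dense grid search then bounded local search.

    ``c = strength / max_strength`` (grid maximum 19).  Gr is fixed to the
    difference between the highest and lowest rate and b to the lowest
    rate (pass ``Gr``/``b`` to fix them elsewhere, e.g. at known generating
    values in a recovery check).  The grid spans n in [-10, 10] step 0.1
    and Gc in [-1, 1] step 0.01 minimizing RMSE; the grid optimum seeds an
    L-BFGS-B refinement within the same bounds.  Negative-Gc candidates
    with non-integer n have no real model value and are excluded by the
    non-finite guard.  A flat curve (Gr = 0) is flagged and skipped.
    """
    strengths = np.asarray(strengths, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if strengths.size < 4:
        raise ValueError("need at least 4 strength levels to fit")
    c = strengths / max_strength
    if b is None:
        b = float(rates.min())
    if Gr is None:
        Gr = float(rates.max() - rates.min())
    if Gr == 0.0:
        logging.getLogger("attnet").info("flat CRF (Gr=0): fit skipped")
        return NakaRushtonFit(Gr=0.0, Gc=np.nan, b=b, n=np.nan, rmse=np.nan,
                              c=c, skipped=True)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        cn = np.power(c[None, :], _N_GRID[:, None])  # (n, nc)
        gcn = np.power(_GC_GRID[None, :], _N_GRID[:, None])  # (n, ngc)
        ratio = cn[:, None, :] / (cn[:, None, :] + gcn[:, :, None])
        ratio = np.where(np.isinf(cn)[:, None, :], 1.0, ratio)
        resid = Gr * ratio + b - rates[None, None, :]
        rmse = np.sqrt(np.mean(resid**2, axis=-1))
    rmse = np.where(np.isfinite(rmse), rmse, np.inf)
    best = rmse.min()
    # for even integer n the sign of Gc is unidentifiable ((-Gc)^n = Gc^n);
    # break ties toward the physically meaningful non-negative branch
    ties = np.argwhere(rmse <= best + 1e-14)
    i, j = max(ties, key=lambda ij: _GC_GRID[ij[1]] >= 0)
    grid_rmse = float(rmse[i, j])
    gc0, n0 = float(_GC_GRID[j]), float(_N_GRID[i])

    def objective(x):
        r = naka_rushton(c, Gr, x[0], b, x[1]) - rates
        val = np.sqrt(np.mean(r**2))
        return val if np.isfinite(val) else 1e6

    res = optimize.minimize(
        objective, x0=[gc0, n0], method="L-BFGS-B", bounds=[(-1, 1), (-10, 10)]
    )
    if res.fun <= grid_rmse:
        gc, n, best = float(res.x[0]), float(res.x[1]), float(res.fun)
    else:  # local step failed to improve; keep the grid optimum
        gc, n, best = gc0, n0, grid_rmse
    return NakaRushtonFit(Gr=Gr, Gc=gc, b=b, n=n, rmse=best, c=c)


# ---------------------------------------------------------------------------
# circular ridge decoding

@dataclass
class DecodeResult:
    """Decoder output: per-trial predictions plus summary error/accuracy."""

    predicted_deg: np.ndarray | None
    mae_deg: float | None
    accuracy: float | None = None
    train_source: str = ""
    test_source: str = ""
    n_folds: int | None = None


class CircularRidgeDecoder:
    """Chained Bayesian ridge regression on (sin, cos) of the stimulus angle.

    Chain order is sin first, then cos (the cosine regression receives the
    sine prediction as an extra feature); predictions are mapped back to an
    angle with atan2 on the (0, 360] convention.
    """

    chain_order = ("sin", "cos")

    def __init__(self) -> None:
        self.chain = RegressorChain(BayesianRidge(), order=[0, 1])

    def fit(self, X: np.ndarray, angles_deg: np.ndarray) -> "CircularRidgeDecoder":
        angles_deg = np.asarray(angles_deg, dtype=float)
        if np.unique(angles_deg).size < 2:
            raise ValueError("need at least 2 distinct training angles")
        rad = np.deg2rad(angles_deg)
        self.chain.fit(np.asarray(X), np.column_stack([np.sin(rad), np.cos(rad)]))
        return self

    def predict_deg(self, X: np.ndarray) -> np.ndarray:
        y = self.chain.predict(np.asarray(X))
        return sincos_to_deg(y[:, 0], y[:, 1])


def fit_circular_ridge(train_rates: np.ndarray, train_deg) -> CircularRidgeDecoder:
    return CircularRidgeDecoder().fit(train_rates, train_deg)


def sensory_cv_mae(
    sensory: RateData,
    params: ModelParams,
    subnetwork: int = 0,
    n_folds: int | None = None,
) -> float:
    """Validate the circular decoder on the sensory task itself.

    Leave-one-trial-per-stimulus-out cross-validation on the stimulated
    sub-network's rates (with 100 trials per stimulus this gives 16 test
    and 1584 training trials per fold); returns the fold-averaged MAE.
    """
    X = sensory.rates[:, ring_slice(params, subnetwork)]
    y = sensory.meta["stimulus_deg"].to_numpy(dtype=float)
    per_stim = {s: np.flatnonzero(y == s) for s in np.unique(y)}
    max_folds = min(len(v) for v in per_stim.values())
    folds = max_folds if n_folds is None else min(n_folds, max_folds)
    maes = []
    for f in range(folds):
        test = np.array([v[f] for v in per_stim.values()])
        train = np.setdiff1d(np.arange(len(y)), test)
        dec = fit_circular_ridge(X[train], y[train])
        maes.append(circular_mae(dec.predict_deg(X[test]), y[test]))
    return float(np.mean(maes))


def decode_attention(
    decoder: CircularRidgeDecoder,
    rates: np.ndarray,
    attended_deg,
    train_source: str = "sensory",
    test_source: str = "attention",
) -> DecodeResult:
    """Predict the attended angle from attention-task rates.

    MAE is the wrapped absolute difference between each trial's predicted
    angle and that trial's attended angle, averaged over trials.
    """
    pred = decoder.predict_deg(rates)
    return DecodeResult(
        predicted_deg=pred,
        mae_deg=circular_mae(pred, attended_deg),
        train_source=train_source,
        test_source=test_source,
    )


def attention_mae_table(
    sensory: RateData,
    attention: RateData,
    params: ModelParams,
    subnetworks: Iterable[int] | None = None,
    stim_strengths: Iterable[float] | None = None,
    train_subnetwork: int = 0,
    train_on: str = "stimulated",
) -> pd.DataFrame:
    """Sensory-trained circular-decoder MAE per sub-network and condition.

    By default one decoder is trained on the stimulated sub-network's
    sensory-task rates — the stimulus-driven ring code — and tested on
    every sub-network's attention-task rates through the ring-position
    correspondence (neuron i of any ring prefers the same angle).  An
    unstimulated sub-network therefore only decodes above chance if
    attentional feedback evokes stimulus-like bumps there, which is the
    question the structured-wiring sweep asks.  ``train_on="matching"``
    instead trains each sub-network's decoder on its own sensory-task
    rates (which, for unstimulated sub-networks, are feedback traces: that
    variant probes the consistency of the feedback pattern rather than its
    resemblance to a stimulus).
    """
    if subnetworks is None:
        subnetworks = range(params.n_subnetworks)
    if train_on not in ("stimulated", "matching"):
        raise ValueError("train_on must be 'stimulated' or 'matching'")
    y_train = sensory.meta["stimulus_deg"].to_numpy(dtype=float)
    meta = attention.meta
    if stim_strengths is not None:
        keep = meta["stim_strength"].isin(list(stim_strengths))
    else:
        keep = pd.Series(True, index=meta.index)
    rows = []
    dec_stim = None
    if train_on == "stimulated":
        dec_stim = fit_circular_ridge(
            sensory.rates[:, ring_slice(params, train_subnetwork)], y_train
        )
    for k in subnetworks:
        sl = ring_slice(params, k)
        if train_on == "matching":
            dec = fit_circular_ridge(sensory.rates[:, sl], y_train)
        else:
            dec = dec_stim
        for (ss, sa), idx in meta[keep].groupby(
            ["stim_strength", "att_strength"]
        ).groups.items():
            idx = np.asarray(idx)
            res = decode_attention(
                dec,
                attention.rates[idx][:, sl],
                meta.loc[idx, "attended_deg"].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "subnetwork": k,
                    "stim_strength": ss,
                    "att_strength": sa,
                    "mae_deg": res.mae_deg,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SVM decoding

def svm_decode_cv(rates: np.ndarray, labels) -> DecodeResult:
    """Linear SVM with leave-one-trial-per-class-out cross-validation.

    With 50 trials per attended stimulus and 2 stimuli this yields 50 folds
    of 98 training and 2 test trials.  Features are the raw windowed rates
    (default SVC regularization, no standardization).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("expected exactly 2 classes")
    idx_a = np.flatnonzero(labels == classes[0])
    idx_b = np.flatnonzero(labels == classes[1])
    if idx_a.size != idx_b.size:
        raise ValueError("classes must be balanced")
    accs = []
    for f in range(idx_a.size):
        test = np.array([idx_a[f], idx_b[f]])
        train = np.setdiff1d(np.arange(labels.size), test)
        clf = SVC(kernel="linear")
        clf.fit(rates[train], labels[train])
        accs.append(np.mean(clf.predict(rates[test]) == labels[test]))
    return DecodeResult(
        predicted_deg=None,
        mae_deg=None,
        accuracy=float(np.mean(accs)),
        train_source="attention",
        test_source="attention",
        n_folds=len(accs),
    )


def svm_accuracy_table(
    attention: RateData,
    params: ModelParams,
    subnetworks: Iterable[int] | None = None,
    stim_strengths: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Within-sub-network SVM accuracy per condition cell."""
    if subnetworks is None:
        subnetworks = range(params.n_subnetworks)
    meta = attention.meta
    if stim_strengths is not None:
        meta_keep = meta[meta["stim_strength"].isin(list(stim_strengths))]
    else:
        meta_keep = meta
    rows = []
    for (ss, sa), idx in meta_keep.groupby(
        ["stim_strength", "att_strength"]
    ).groups.items():
        idx = np.asarray(idx)
        labels = meta.loc[idx, "attended_deg"].to_numpy(dtype=float)
        for k in subnetworks:
            res = svm_decode_cv(attention.rates[idx][:, ring_slice(params, k)], labels)
            rows.append(
                {
                    "subnetwork": k,
                    "stim_strength": ss,
                    "att_strength": sa,
                    "accuracy": res.accuracy,
                }
            )
    return pd.DataFrame(rows)


def svm_cross_generalize(
    attention: RateData,
    params: ModelParams,
    stimulated: int = 0,
    stim_strengths: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Train on one unstimulated sub-network, test on another.

    All ordered pairs of distinct unstimulated sub-networks (7x6 = 42 with
    8 sub-networks) per condition cell; the classifier is trained on all
    trials of the training sub-network and tested on all trials of the
    other.
    """
    unstim = [k for k in range(params.n_subnetworks) if k != stimulated]
    if len(unstim) < 2:
        raise ValueError("need at least 2 unstimulated sub-networks")
    meta = attention.meta
    if stim_strengths is not None:
        meta_keep = meta[meta["stim_strength"].isin(list(stim_strengths))]
    else:
        meta_keep = meta
    rows = []
    for (ss, sa), idx in meta_keep.groupby(
        ["stim_strength", "att_strength"]
    ).groups.items():
        idx = np.asarray(idx)
        labels = meta.loc[idx, "attended_deg"].to_numpy(dtype=float)
        sub_X = {k: attention.rates[idx][:, ring_slice(params, k)] for k in unstim}
        for a in unstim:
            clf = SVC(kernel="linear")
            clf.fit(sub_X[a], labels)
            for b_ in unstim:
                if b_ == a:
                    continue
                acc = float(np.mean(clf.predict(sub_X[b_]) == labels))
                rows.append(
                    {
                        "train_sub": a,
                        "test_sub": b_,
                        "stim_strength": ss,
                        "att_strength": sa,
                        "accuracy": acc,
                    }
                )
    return pd.DataFrame(rows)


def attended_preferring_rates(
    attention: RateData,
    params: ModelParams,
    subnetworks: Iterable[int],
) -> pd.DataFrame:
    """Mean rate of the neurons tuned to the attended angle, per condition.

    Used on unstimulated sub-networks to ask whether top-down modulation
    produces a feature-selective response where no stimulus is shown.
    """
    meta = attention.meta
    rows = []
    for (ss, sa, att), idx in meta.groupby(
        ["stim_strength", "att_strength", "attended_deg"]
    ).groups.items():
        idx = np.asarray(idx)
        nearest = nearest_ring_neurons(params, att)
        for k in subnetworks:
            ring = attention.rates[idx][:, ring_slice(params, k)]
            rows.append(
                {
                    "subnetwork": k,
                    "stim_strength": ss,
                    "att_strength": sa,
                    "attended_deg": att,
                    "rate": float(ring[:, nearest].mean()),
                }
            )
    return pd.DataFrame(rows)
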