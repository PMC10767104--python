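"""Levenberg-Marquardt-trained MLP surrogate for the wall heat-transfer rate.

A single-hidden-layer perceptron maps the six parameters
``(N_T, N_B, M, beta_e, beta_i, beta_F)`` to the Nusselt number.  The
architecture is fixed at 6 inputs, 5 tanh hidden units and one linear
output -- 41 trainable weights in total -- and is fitted by the
Levenberg-Marquardt (damped Gauss-Newton) algorithm on data generated by
the HPM solver, with a 70/15/15 train/validation/test split.

The trainer is written out in full here (analytic Jacobian, multiplicative
damping schedule, restart bookkeeping) because the fit report it produces
-- per-iteration accepted sum-of-squared-error trajectory, damping-factor
trajectory, best-of-restarts index -- is part of the surrogate's contract.
Accepted LM steps never increase the training SSE, and the whole procedure
is bitwise deterministic for a given seed.

A benchmark table of tabulated (parameters, Nu) evaluation rows with the
corresponding surrogate predictions is embedded for regression use; see
:func:`benchmark_table`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry, DimensionlessParams
from .hpm import HPMConfig
from .observables import nusselt

__all__ = [
    "FEATURES",
    "MinMaxScaler",
    "SurrogateDataset",
    "MLPModel",
    "TrainReport",
    "benchmark_table",
    "generate_dataset",
    "dataset_from_table",
    "train_lm",
    "predict",
    "evaluate",
]

FEATURES = ("N_T", "N_B", "M", "beta_e", "beta_i", "beta_F")

N_HIDDEN = 5
N_WEIGHTS = 6 * N_HIDDEN + N_HIDDEN + N_HIDDEN + 1  # 41

# Benchmark evaluation rows: six varied parameters, the solver-side Nusselt
# value, the tabulated surrogate prediction, and their difference.  Each
# block varies one parameter about the reference point
# (N_T=1, N_B=0.5, M=1, beta_e=0.1, beta_i=0.1, beta_F=1).
_BENCHMARK_ROWS = [
    # N_T   N_B   M    b_e  b_i  b_F  Nu        ANN       Error
    (1.5, 0.5, 1.0, 0.1, 0.1, 1.0, 0.315924, 0.315589, 0.000335),
    (2.0, 0.5, 1.0, 0.1, 0.1, 1.0, 0.235448, 0.235875, -0.00043),
    (2.5, 0.5, 1.0, 0.1, 0.1, 1.0, 0.138782, 0.171534, -0.032751),
    (1.0, 1.0, 1.0, 0.1, 0.1, 1.0, 0.353109, 0.360916, -0.00781),
    (1.0, 1.5, 1.0, 0.1, 0.1, 1.0, 0.317912, 0.31871, -0.0008),
    (1.0, 2.0, 1.0, 0.1, 0.1, 1.0, 0.274622, 0.272281, 0.00234),
    (1.0, 0.5, 1.5, 0.1, 0.1, 1.0, 0.375097, 0.375265, -0.00017),
    (1.0, 0.5, 2.0, 0.1, 0.1, 1.0, 0.35933, 0.360059, -0.00073),
    (1.0, 0.5, 2.5, 0.1, 0.1, 1.0, 0.324302, 0.324551, -0.00025),
    (1.0, 0.5, 1.0, 1.0, 0.1, 1.0, 0.38038, 0.376992, 0.003387),
    (1.0, 0.5, 1.0, 2.0, 0.1, 1.0, 0.3805, 0.380314, 0.000187),
    (1.0, 0.5, 1.0, 3.0, 0.1, 1.0, 0.380577, 0.338641, 0.041936),
    (1.0, 0.5, 1.0, 0.1, 1.0, 1.0, 0.380799, 0.381286, -0.00049),
    (1.0, 0.5, 1.0, 0.1, 2.0, 1.0, 0.380775, 0.383018, -0.00224),
    (1.0, 0.5, 1.0, 0.1, 3.0, 1.0, 0.38071, 0.380908, -0.0002),
    (1.0, 0.5, 1.0, 0.1, 0.1, 0.0, 0.370398, 0.370201, 0.000196),
    (1.0, 0.5, 1.0, 0.1, 0.1, 2.0, 0.390023, 0.389251, 0.000772),
    (1.0, 0.5, 1.0, 0.1, 0.1, 3.0, 0.399835, 0.399723, 0.000112),
]

#: tabulated mean-square error accompanying the benchmark table
BENCHMARK_MSE = 2.09144e-7


def benchmark_table() -> pd.DataFrame:
    """The embedded benchmark rows as a DataFrame (features, Nu, ANN, Error)."""
    return pd.DataFrame(_BENCHMARK_ROWS, columns=[*FEATURES, "Nu", "ANN", "Error"])


@dataclass
class MinMaxScaler:
    """Affine map of each column onto [-1, 1]; exactly invertible."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        hi = np.where(hi == lo, lo + 1.0, hi)  # constant column: identity-ish map
        return cls(lo=lo, hi=hi)

    def transform(self, X):
        return 2.0 * (np.asarray(X, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, Z):
        return (np.asarray(Z, dtype=float) + 1.0) * (self.hi - self.lo) / 2.0 + self.lo


@dataclass
class SurrogateDataset:
    """Training rows, per-feature scaling statistics and the split assignment."""

    frame: pd.DataFrame                 # columns FEATURES + ["Nu"]
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    split: np.ndarray                   # "train" / "val" / "test" per row
    seed: int

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURES)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["Nu"].to_numpy(float)

    def rows(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.split == which)


def _assign_split(n: int, seed: int) -> np.ndarray:
    """Random 70/15/15 assignment (+-1 row from rounding)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(0.70 * n))
    n_val = int(round(0.15 * n))
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_val]] = "val"
    split[order[n_train + n_val:]] = "test"
    return split.astype(str)


def _make_dataset(frame: pd.DataFrame, seed: int) -> SurrogateDataset:
    X = frame[list(FEATURES)].to_numpy(float)
    y = frame[["Nu"]].to_numpy(float)
    return SurrogateDataset(
        frame=frame.reset_index(drop=True),
        x_scaler=MinMaxScaler.fit(X),
        y_scaler=MinMaxScaler.fit(y),
        split=_assign_split(len(frame), seed),
        seed=seed,
    )


def generate_dataset(
    grid_spec: dict,
    baseline: DimensionlessParams | None = None,
    geom: ChannelGeometry | None = None,
    xi: float = 0.4,
    t: float = 0.2,
    seed: int = 0,
    config: HPMConfig | None = None,
    nu_wall: str = "h2",
    nu_sign: int = 1,
) -> SurrogateDataset:
    """Cartesian parameter grid -> one HPM Nusselt evaluation per grid point.

    ``grid_spec`` maps feature names (a subset of :data:`FEATURES`) to value
    lists; unlisted features stay at the baseline.  Solver failures abort
    with the offending grid point named.
    """
    unknown = set(grid_spec) - set(FEATURES)
    if unknown:
        raise ValueError(f"grid_spec keys not among surrogate features: {sorted(unknown)}")
    baseline = baseline or DimensionlessParams()
    geom = geom or ChannelGeometry()
    names = [f for f in FEATURES if f in grid_spec]
    meshes = np.meshgrid(*[np.asarray(grid_spec[f], float) for f in names], indexing="ij")
    points = np.stack([m.ravel() for m in meshes], axis=-1)
    records = []
    for values in points:
        overrides = dict(zip(names, values))
        params = baseline.replace(**overrides)
        try:
            nu = nusselt(params, geom, xi, t, wall=nu_wall, sign=nu_sign, config=config)
        except Exception as exc:
            raise RuntimeError(f"Nusselt evaluation failed at grid point {overrides}") from exc
        row = {f: getattr(params, f) for f in FEATURES}
        row["Nu"] = nu
        records.append(row)
    return _make_dataset(pd.DataFrame.from_records(records), seed)


def dataset_from_table(seed: int = 0) -> SurrogateDataset:
    """The embedded benchmark rows as a training dataset (features, Nu)."""
    frame = benchmark_table()[[*FEATURES, "Nu"]].copy()
    return _make_dataset(frame, seed)


@dataclass
class MLPModel:
    """6-5-1 perceptron: tanh hidden layer, linear output, stored scalers."""

    W1: np.ndarray            # (5, 6)
    b1: np.ndarray            # (5,)
    w2: np.ndarray            # (5,)
    b2: float
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Nusselt predictions for raw (unscaled) parameter rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(X < self.x_scaler.lo - 1e-12) or np.any(X > self.x_scaler.hi + 1e-12):
            warnings.warn("inputs outside the training box; extrapolating", stacklevel=2)
        z = self._forward_scaled(self.x_scaler.transform(X))
        return self.y_scaler.inverse(z[:, None]).ravel()

    def _forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return np.tanh(Xs @ self.W1.T + self.b1) @ self.w2 + self.b2

    # --- flat-vector view used by the trainer -------------------------------
    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    @staticmethod
    def unpack(w: np.ndarray, x_scaler, y_scaler, seed=0) -> "MLPModel":
        W1 = w[:30].reshape(N_HIDDEN, 6)
        b1 = w[30:35]
        w2 = w[35:40]
        b2 = float(w[40])
        return MLPModel(W1=W1, b1=b1, w2=w2, b2=b2,
                        x_scaler=x_scaler, y_scaler=y_scaler, seed=seed)

    def to_json(self) -> str:
        return json.dumps(
            {
                "W1": self.W1.tolist(), "b1": self.b1.tolist(),
                "w2": self.w2.tolist(), "b2": self.b2,
                "x_lo": self.x_scaler.lo.tolist(), "x_hi": self.x_scaler.hi.tolist(),
                "y_lo": self.y_scaler.lo.tolist(), "y_hi": self.y_scaler.hi.tolist(),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=float(d["b2"]),
            x_scaler=MinMaxScaler(np.array(d["x_lo"]), np.array(d["x_hi"])),
            y_scaler=MinMaxScaler(np.array(d["y_lo"]), np.array(d["y_hi"])),
            seed=int(d["seed"]),
        )


@dataclass
class TrainReport:
    """Fit diagnostics: SSE/damping trajectories and per-split errors."""

    sse_history: list = field(default_factory=list)       # accepted steps, best restart
    lambda_history: list = field(default_factory=list)
    mse: dict = field(default_factory=dict)               # split -> MSE (Nu units)
    best_restart: int = 0
    n_restarts: int = 0
    converged: bool = True
    seed: int = 0


def _forward_jac(w: np.ndarray, Xs: np.ndarray):
    """Network output and analytic Jacobian w.r.t. all 41 weights."""
    W1 = w[:30].reshape(N_HIDDEN, 6)
    b1 = w[30:35]
    w2 = w[35:40]
    b2 = w[40]
    Z = Xs @ W1.T + b1              # (n, 5)
    H = np.tanh(Z)
    out = H @ w2 + b2
    G = (1.0 - H**2) * w2           # (n, 5): d out / d z_j
    n = Xs.shape[0]
    J = np.empty((n, N_WEIGHTS))
    J[:, :30] = (G[:, :, None] * Xs[:, None, :]).reshape(n, 30)
    J[:, 30:35] = G
    J[:, 35:40] = H
    J[:, 40] = 1.0
    return out, J


def _lm_fit(w0, Xs, ys, max_iter, lambda0, lambda_factor, gtol=1e-12):
    """Core damped Gauss-Newton loop; returns weights and trajectories."""
    w = w0.copy()
    out, J = _forward_jac(w, Xs)
    r = out - ys
    sse = float(r @ r)
    lam = lambda0
    sse_hist = [sse]
    lam_hist = [lam]
    converged = False
    for _ in range(max_iter):
        A = J.T @ J
        g = J.T @ r
        if np.linalg.norm(g, np.inf) < gtol:
            converged = True
            break
        accepted = False
        for _inner in range(50):
            try:
                step = np.linalg.solve(A + lam * np.eye(N_WEIGHTS), -g)
            except np.linalg.LinAlgError:
                lam *= lambda_factor
                continue
            w_trial = w + step
            out_t, J_t = _forward_jac(w_trial, Xs)
            r_t = out_t - ys
            sse_t = float(r_t @ r_t)
            if sse_t < sse:         # accept: SSE strictly decreases
                w, r, J, sse = w_trial, r_t, J_t, sse_t
                lam = max(lam / lambda_factor, 1e-14)
                accepted = True
                break
            lam *= lambda_factor    # reject: raise damping, stay put
        sse_hist.append(sse)
        lam_hist.append(lam)
        if not accepted:            # fully damped and still no progress
            converged = True
            break
        if sse < 1e-28:
            converged = True
            break
    return w, sse_hist, lam_hist, converged


def train_lm(
    data: SurrogateDataset,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 200,
    lambda0: float = 1e-3,
    lambda_factor: float = 10.0,
) -> tuple[MLPModel, TrainReport]:
    """Fit the 6-5-1 network by Levenberg-Marquardt with random restarts.

    Each restart draws fresh initial weights from a child generator of
    ``seed`` and runs the damped Gauss-Newton loop on the training split
    (scaled features and target); the restart with the lowest final training
    SSE wins.  Non-convergence within ``max_iter`` is reported on the
    :class:`TrainReport`, not raised.
    """
    if len(data.frame) < 10:
        raise ValueError(f"need at least 10 rows to fit, got {len(data.frame)}")
    train_idx = data.rows("train")
    Xs = data.x_scaler.transform(data.X)[train_idx]
    ys = data.y_scaler.transform(data.y[:, None]).ravel()[train_idx]

    children = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        w0 = rng.normal(scale=0.5, size=N_WEIGHTS)
        w, sse_hist, lam_hist, conv = _lm_fit(w0, Xs, ys, max_iter, lambda0, lambda_factor)
        if best is None or sse_hist[-1] < best[1][-1]:
            best = (w, sse_hist, lam_hist, conv, i)

    w, sse_hist, lam_hist, conv, best_i = best
    model = MLPModel.unpack(w, data.x_scaler, data.y_scaler, seed=seed)
    report = TrainReport(
        sse_history=sse_hist, lambda_history=lam_hist,
        best_restart=best_i, n_restarts=restarts, converged=conv, seed=seed,
    )
    report.mse = {split: mse for split, mse in _split_mse(model, data).items()}
    if not conv:
        warnings.warn(
            f"LM did not meet its gradient tolerance within {max_iter} iterations",
            stacklevel=2,
        )
    return model, report


def _split_mse(model: MLPModel, data: SurrogateDataset) -> dict:
    pred = model.predict(data.X)
    out = {}
    for split in ("train", "val", "test"):
        idx = data.rows(split)
        if idx.size:
            out[split] = float(np.mean((pred[idx] - data.y[idx]) ** 2))
    return out


def predict(model: MLPModel, params_six) -> float:
    """Surrogate Nusselt prediction for one (N_T, N_B, M, b_e, b_i, b_F) point."""
    return float(model.predict(np.asarray(params_six, float)[None, :])[0])


def evaluate(model: MLPModel, data: SurrogateDataset) -> tuple[dict, pd.DataFrame]:
    """Per-split MSE plus a per-row error table (inputs, Nu, prediction, error)."""
    pred = model.predict(data.X)
    table = data.frame.copy()
    table["prediction"] = pred
    table["error"] = table["Nu"] - table["prediction"]
    table["split"] = data.split
    return _split_mse(model, data), table
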