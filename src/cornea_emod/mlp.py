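"""Three-layer backpropagation network for keratoconus staging.

A deliberately small feed-forward network — 12 inputs, 5 tanh hidden units,
1 linear output — trained to regress the group code (healthy = 1, forme
fruste keratoconus = 0, clinical keratoconus = -1) from twelve features:
eight dynamic corneal response parameters, three tomographic features and
the elastic modulus.  Training minimises the mean squared error with
Levenberg-Marquardt (damped Gauss-Newton on the residual Jacobian, the
"trainlm" semantics), stopping at a target MSE of 0.005 or 1000 iterations;
plain gradient descent with learning rate 0.01 is available as a fallback
optimizer.  Continuous predictions are mapped back to groups by
thresholding at +-0.5 consistently with the coding (value > 0.5 -> the
group coded 1).

Features are z-scored with statistics fitted on the training split only;
everything is deterministic given (data, config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synth import GROUP_CODES

#: the twelve input features, in canonical column order
DEFAULT_FEATURES = (
    "A1T", "A1V", "A2T", "A2V", "SP-A1", "PD", "DA", "ARTh",
    "B.Ele.Th", "Kmax", "Pachymin", "E",
)


@dataclass(frozen=True)
class MLPConfig:
    layer_sizes: Tuple[int, int, int] = (12, 5, 1)
    learning_rate: float = 0.01
    target_error: float = 0.005  # training MSE stopping criterion
    max_iter: int = 1000
    train_fraction: float = 0.70
    seed: int = 0
    optimizer: str = "levenberg_marquardt"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.optimizer not in ("levenberg_marquardt", "gradient_descent"):
            raise ValueError("unknown optimizer")


@dataclass
class MLPModel:
    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)
    feature_names: Tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    config: MLPConfig
    training_report: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "feature_names": list(self.feature_names),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "config": {
                "layer_sizes": list(self.config.layer_sizes),
                "learning_rate": self.config.learning_rate,
                "target_error": self.config.target_error,
                "max_iter": self.config.max_iter,
                "train_fraction": self.config.train_fraction,
                "seed": self.config.seed,
                "optimizer": self.config.optimizer,
            },
            "training_report": {
                k: v for k, v in self.training_report.items()
                if not isinstance(v, np.ndarray)
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        cfg = d["config"]
        return cls(
            W1=np.array(d["W1"]),
            b1=np.array(d["b1"]),
            W2=np.array(d["W2"]),
            b2=np.array(d["b2"]),
            feature_names=tuple(d["feature_names"]),
            x_mean=np.array(d["x_mean"]),
            x_sd=np.array(d["x_sd"]),
            config=MLPConfig(
                layer_sizes=tuple(cfg["layer_sizes"]),
                learning_rate=cfg["learning_rate"],
                target_error=cfg["target_error"],
                max_iter=cfg["max_iter"],
                train_fraction=cfg["train_fraction"],
                seed=cfg["seed"],
                optimizer=cfg["optimizer"],
            ),
            training_report=d.get("training_report", {}),
        )


def split_data(
    table: pd.DataFrame,
    train_fraction: float = 0.70,
    seed: int = 0,
    group_col: str = "group",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-group random train/validation split.

    The total training size is round(n * fraction), allocated across groups
    by largest remainder so each group's training share is within one
    subject of the requested fraction.  Deterministic given ``seed``; the
    original row indices are preserved in the returned frames.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_total = len(table)
    n_train_total = int(round(n_total * train_fraction))
    groups = list(table[group_col].unique())
    quotas = {}
    exact = {g: (table[group_col] == g).sum() * train_fraction for g in groups}
    base = {g: int(np.floor(exact[g])) for g in groups}
    remainder = n_train_total - sum(base.values())
    order = sorted(groups, key=lambda g: exact[g] - base[g], reverse=True)
    for g in groups:
        quotas[g] = base[g]
    for g in order[:remainder]:
        quotas[g] += 1
    train_idx: List[int] = []
    for g in groups:
        idx = table.index[table[group_col] == g].to_numpy()
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[: quotas[g]]].tolist())
        if quotas[g] == 0 or quotas[g] == len(idx):
            warnings.warn(
                f"group {g!r} absent from one side of the split", stacklevel=2
            )
    train_mask = table.index.isin(train_idx)
    return table[train_mask], table[~train_mask]


def _forward(
    X: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray
):
    h = np.tanh(X @ W1.T + b1)
    out = h @ W2.T + b2
    return out[:, 0], h


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta: np.ndarray, n_in: int, n_h: int):
    i = 0
    W1 = theta[i : i + n_h * n_in].reshape(n_h, n_in); i += n_h * n_in
    b1 = theta[i : i + n_h]; i += n_h
    W2 = theta[i : i + n_h].reshape(1, n_h); i += n_h
    b2 = theta[i : i + 1]
    return W1, b1, W2, b2


def _jacobian(X: np.ndarray, h: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """d out / d theta, shape (N, P); analytic backprop through the net."""
    N, n_in = X.shape
    n_h = h.shape[1]
    sech2 = 1.0 - h**2  # (N, n_h)
    dW1 = (W2[0][None, :] * sech2)[:, :, None] * X[:, None, :]  # (N, n_h, n_in)
    db1 = W2[0][None, :] * sech2
    dW2 = h
    db2 = np.ones((N, 1))
    return np.concatenate(
        [dW1.reshape(N, n_h * n_in), db1, dW2, db2], axis=1
    )


def train(
    table: pd.DataFrame,
    config: Optional[MLPConfig] = None,
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    target_col: str = "target",
) -> MLPModel:
    """Fit the network on a training table.

    ``table`` must contain the feature columns and ``target_col`` with the
    group codes.  Raises on missing columns or non-finite features.
    """
    config = config or MLPConfig()
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    n_in, n_h, n_out = config.layer_sizes
    if len(feature_names) != n_in:
        raise ValueError(
            f"{len(feature_names)} features but input layer expects {n_in}"
        )
    X_raw = table[list(feature_names)].to_numpy(dtype=float)
    y = table[target_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(X_raw)):
        raise ValueError("non-finite feature values")

    x_mean = X_raw.mean(axis=0)
    x_sd = X_raw.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0.0, 1.0, x_sd)
    X = (X_raw - x_mean) / x_sd
    N = X.shape[0]

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    W1 = rng.uniform(-0.5, 0.5, (n_h, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, n_h) / np.sqrt(n_in)
    W2 = rng.uniform(-0.5, 0.5, (1, n_h)) / np.sqrt(n_h)
    b2 = rng.uniform(-0.5, 0.5, 1) / np.sqrt(n_h)
    theta = _pack(W1, b1, W2, b2)

    def mse_of(th):
        W1_, b1_, W2_, b2_ = _unpack(th, n_in, n_h)
        out, h = _forward(X, W1_, b1_, W2_, b2_)
        r = y - out
        return float(np.mean(r**2)), r, h, W2_

    mse, r, h, W2_cur = mse_of(theta)
    lam = 1e-3
    n_iter = 0
    stop_reason = "max_iter"
    for n_iter in range(1, config.max_iter + 1):
        if mse <= config.target_error:
            stop_reason = "target_error"
            n_iter -= 1
            break
        if config.optimizer == "levenberg_marquardt":
            J = _jacobian(X, h, W2_cur)
            JtJ = J.T @ J
            Jtr = J.T @ r
            accepted = False
            for _ in range(30):
                try:
                    step = np.linalg.solve(
                        JtJ + lam * np.eye(JtJ.shape[0]), Jtr
                    )
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = theta + step
                mse_new, r_new, h_new, W2_new = mse_of(cand)
                if mse_new < mse:
                    theta, mse, r, h, W2_cur = cand, mse_new, r_new, h_new, W2_new
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                stop_reason = "stalled"
                break
        else:  # gradient descent with the stated learning rate
            J = _jacobian(X, h, W2_cur)
            grad = -(2.0 / N) * (J.T @ r)
            theta = theta - config.learning_rate * grad
            mse, r, h, W2_cur = mse_of(theta)
    else:
        n_iter = config.max_iter
    if mse <= config.target_error:
        stop_reason = "target_error"

    W1, b1, W2, b2 = _unpack(theta, n_in, n_h)
    return MLPModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        feature_names=tuple(feature_names),
        x_mean=x_mean, x_sd=x_sd,
        config=config,
        training_report={
            "final_mse": mse,
            "iterations": int(n_iter),
            "stop_reason": stop_reason,
            "n_train": int(N),
        },
    )


def predict(model: MLPModel, table: pd.DataFrame) -> np.ndarray:
    """Continuous network output for each row (typically within [-1.5, 1.5])."""
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X_raw = table[list(model.feature_names)].to_numpy(dtype=float)
    X = (X_raw - model.x_mean) / model.x_sd
    out, _ = _forward(X, model.W1, model.b1, model.W2, model.b2)
    return out


#: code -> group name, inverse of GROUP_CODES
CODE_TO_GROUP = {v: k for k, v in GROUP_CODES.items()}


def classify(values: Sequence[float]) -> List[str]:
    """Map continuous predictions to groups, consistent with the coding.

    value > 0.5 -> the group coded 1 (healthy); value < -0.5 -> the group
    coded -1 (KC); otherwise the middle group (FFKC).  Values exactly at
    +-0.5 deterministically fall to the middle group.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite predicted values")
    out = np.full(v.shape, "FFKC", dtype=object)
    out[v > 0.5] = "healthy"
    out[v < -0.5] = "KC"
    return out.tolist()


def accuracy(predicted_groups: Sequence[str], true_groups: Sequence[str]) -> float:
    pred = np.asarray(predicted_groups)
    true = np.asarray(true_groups)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    return float(np.mean(pred == true))


def add_target_column(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Return a copy with the numeric ``target`` coding column attached."""
    out = table.copy()
    out["target"] = out[group_col].map(GROUP_CODES)
    if out["target"].isna().any():
        raise ValueError("unknown group labels present")
    return out
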