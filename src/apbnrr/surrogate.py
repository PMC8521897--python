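"""Parameter-search-space reduction with a feedforward HD predictor.

A 14-input regressor maps 12 registration parameters plus two
patient-specific features — a lobe-wise tumor-location code and the rigid
registration error in mm (a proxy for the deformation magnitude) — to the
Hausdorff distance the adaptive registration would achieve with those
parameters. Trained on logged pipeline runs, it ranks candidate parameter
sets so only the most promising few need to be executed.

Architecture: four hidden fully-connected layers of 128 rectified-linear
units and a single linear output, optimized with stochastic gradient
descent with Nesterov momentum. Train/evaluation splits are by case id
and mutually exclusive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .core import RegistrationConfig

#: The 12 registration-parameter features fed to the network, in order.
PARAM_FEATURES = [
    "F_s", "B_s_x", "B_s_y", "B_s_z", "W_s_x", "W_s_y", "W_s_z",
    "delta", "E_ratio", "F_r", "N_rej", "c_min",
]
PATIENT_FEATURES = ["tumor_location", "rigid_error_mm"]
ALL_FEATURES = PARAM_FEATURES + PATIENT_FEATURES

#: Fixed lobe-wise tumor-location dictionary. Unknown strings are rejected.
LOBE_CODES = {
    "frontal": 0, "parietal": 1, "temporal": 2, "occipital": 3,
    "insular": 4, "perisylvian": 5, "fronto-temporal": 6,
    "parietal-occipital": 7, "deep": 8,
}


def encode_location(lobe: str | int) -> int:
    if isinstance(lobe, str):
        key = lobe.strip().lower()
        if key not in LOBE_CODES:
            raise ValueError(f"unknown tumor location {lobe!r}; known: {sorted(LOBE_CODES)}")
        return LOBE_CODES[key]
    code = int(lobe)
    if code not in LOBE_CODES.values():
        raise ValueError(f"unknown tumor-location code {code}")
    return code


def param_vector(config: RegistrationConfig, tumor_location: str | int,
                 rigid_error_mm: float) -> np.ndarray:
    """Encode a configuration + patient descriptors as the 14-feature vector."""
    vec = [
        config.F_s, *config.B_s, *config.W_s, config.delta,
        config.E_t / config.E_b, config.F_r, config.N_rej, config.c_min,
        float(encode_location(tumor_location)), float(rigid_error_mm),
    ]
    out = np.asarray(vec, dtype=float)
    assert len(out) == 14
    return out


class RunLog:
    """CSV-backed dataset of pipeline executions, keyed by an input hash."""

    COLUMNS = ["key", "case_id"] + ALL_FEATURES + ["hd"]

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if self.path.exists():
            self.df = pd.read_csv(self.path)
        else:
            self.df = pd.DataFrame(columns=self.COLUMNS)

    @staticmethod
    def _key(case_id: str, vector: np.ndarray) -> str:
        payload = case_id + "|" + ",".join(f"{v:.10g}" for v in vector)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def log_run(self, case_id: str, vector: np.ndarray, achieved_hd: float) -> bool:
        """Append one (parameter vector, HD) row; idempotent by input hash.

        Returns True if a new row was stored.
        """
        vector = np.asarray(vector, dtype=float).reshape(-1)
        if len(vector) != 14 or not np.all(np.isfinite(vector)):
            raise ValueError("parameter vector must be 14 finite numbers")
        if achieved_hd < 0:
            raise ValueError("achieved_hd must be >= 0")
        key = self._key(str(case_id), vector)
        if len(self.df) and (self.df["key"] == key).any():
            return False
        row = {"key": key, "case_id": str(case_id), "hd": float(achieved_hd)}
        row.update(dict(zip(ALL_FEATURES, vector)))
        self.df = pd.concat([self.df, pd.DataFrame([row])], ignore_index=True)
        self.df.to_csv(self.path, index=False)
        return True


@dataclass
class SurrogateModel:
    """Trained HD predictor: network weights plus standardization statistics."""

    mlp: MLPRegressor
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    seed: int
    train_rmse: float = float("nan")
    eval_rmse: float = float("nan")
    loss_curve: list = dc_field(default_factory=list)

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        """Predicted HD (mm) per row; batch and single-row results agree."""
        X = np.asarray(vectors, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != 14:
            raise ValueError(f"expected 14 features, got {X.shape[1]}")
        z = (X - self.x_mean) / self.x_std
        y = self.mlp.predict(z) * self.y_std + self.y_mean
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite prediction")
        return float(y[0]) if single else y

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean, "y_std": self.y_std, "seed": self.seed,
            "train_rmse": self.train_rmse, "eval_rmse": self.eval_rmse,
            "loss_curve": list(map(float, self.loss_curve)),
            "coefs": [w.tolist() for w in self.mlp.coefs_],
            "intercepts": [b.tolist() for b in self.mlp.intercepts_],
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        payload = json.loads(Path(path).read_text())
        coefs = [np.asarray(w) for w in payload["coefs"]]
        intercepts = [np.asarray(b) for b in payload["intercepts"]]
        mlp = _make_mlp(payload["seed"])
        # Minimal fit to initialize sklearn internals, then install weights.
        mlp.partial_fit(np.zeros((2, 14)), np.zeros(2))
        mlp.coefs_ = coefs
        mlp.intercepts_ = intercepts
        return cls(mlp, np.asarray(payload["x_mean"]), np.asarray(payload["x_std"]),
                   payload["y_mean"], payload["y_std"], payload["seed"],
                   payload["train_rmse"], payload["eval_rmse"], payload["loss_curve"])


def _make_mlp(seed: int, lr: float = 1e-2, momentum: float = 0.9,
              batch_size: int = 256, epochs: int = 200) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=(128, 128, 128, 128),
        activation="relu",
        solver="sgd",
        nesterovs_momentum=True,
        momentum=momentum,
        learning_rate_init=lr,
        batch_size=batch_size,
        max_iter=epochs,
        shuffle=True,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=epochs,
        alpha=1e-5,
    )


def train(dataset: pd.DataFrame, hyper: dict | None = None, seed: int = 0) -> SurrogateModel:
    """Train the HD predictor on logged runs; split by case id.

    ``hyper`` may set ``eval_cases`` (list of held-out case ids; default
    the last two unique ids), ``lr``, ``momentum``, ``batch_size`` and
    ``epochs``. Deterministic given the seed. Raises on non-finite loss.
    The default learning rate (1e-2) is set for full convergence within
    the fixed epoch budget on datasets of tens of thousands of rows.
    """
    hyper = dict(hyper or {})
    if len(dataset) < 100:
        raise ValueError("need at least 100 logged runs to train")
    missing = [c for c in ALL_FEATURES + ["case_id", "hd"] if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset missing columns {missing}")
    cases = list(dict.fromkeys(dataset["case_id"].astype(str)))
    eval_cases = [str(c) for c in hyper.pop("eval_cases", cases[-2:])]
    overlap_free = set(eval_cases) <= set(cases)
    if not overlap_free:
        raise ValueError("eval_cases not present in the dataset")
    is_eval = dataset["case_id"].astype(str).isin(eval_cases).to_numpy()
    if is_eval.all() or not is_eval.any():
        raise ValueError("case split must leave both partitions non-empty")

    X = dataset[ALL_FEATURES].to_numpy(dtype=float)
    y = dataset["hd"].to_numpy(dtype=float)
    x_mean = X[~is_eval].mean(axis=0)
    x_std = X[~is_eval].std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean = float(y[~is_eval].mean())
    y_std = float(y[~is_eval].std() or 1.0)

    mlp = _make_mlp(seed, **{k: hyper[k] for k in ("lr", "momentum", "batch_size", "epochs")
                             if k in hyper})
    Ztr = (X[~is_eval] - x_mean) / x_std
    ytr = (y[~is_eval] - y_mean) / y_std
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # convergence chatter at fixed epoch budget
        mlp.fit(Ztr, ytr)
    if not np.all(np.isfinite(mlp.loss_curve_)):
        raise ValueError(f"training diverged: loss curve {mlp.loss_curve_[-5:]}")

    model = SurrogateModel(mlp, x_mean, x_std, y_mean, y_std, seed,
                           loss_curve=list(mlp.loss_curve_))
    pred_tr = model.predict(X[~is_eval])
    model.train_rmse = float(np.sqrt(np.mean((pred_tr - y[~is_eval]) ** 2)))
    pred_ev = model.predict(X[is_eval])
    model.eval_rmse = float(np.sqrt(np.mean((pred_ev - y[is_eval]) ** 2)))
    return model


def rank(model: SurrogateModel, pool: pd.DataFrame | np.ndarray,
         top_n: int | None = None) -> pd.DataFrame:
    """Sort a pool of parameter sets by predicted HD ascending (stable).

    Returns the ``top_n`` rows (all, if None) with a ``predicted_hd``
    column; ties keep pool order.
    """
    if isinstance(pool, pd.DataFrame):
        if len(pool) == 0:
            raise ValueError("empty pool")
        X = pool[ALL_FEATURES].to_numpy(dtype=float)
        out = pool.copy().reset_index(drop=True)
    else:
        X = np.atleast_2d(np.asarray(pool, dtype=float))
        if len(X) == 0:
            raise ValueError("empty pool")
        out = pd.DataFrame(X, columns=ALL_FEATURES)
    pred = model.predict(X)
    out["predicted_hd"] = pred
    order = np.argsort(pred, kind="stable")
    out = out.iloc[order].reset_index(drop=True)
    return out if top_n is None else out.head(top_n)
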