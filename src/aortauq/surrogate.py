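"""Gaussian-process emulation of a scalar simulator output.

The emulator is an anisotropic squared-exponential GP with a small fixed
nugget, fitted by maximizing the log marginal likelihood with a seeded
multi-start; inputs are standardized to zero mean / unit variance and the
output is centered and scaled.  Accuracy is summarised by leave-one-out
cross-validation: each training run is excluded once and predicted by the
surrogate built from the remaining runs.  LOO RMSE, the coefficient of
determination R^2 of the LOO predictions, and the mean relative error (MRE,
%) are reported — the standard emulator-quality triplet.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = ["GPSurrogate", "GPSurrogateResults", "LOOMetrics"]


@dataclass(frozen=True)
class LOOMetrics:
    """Leave-one-out accuracy summary (loo_rmse in output units, mre in %)."""

    loo_rmse: float
    r2: float
    mre: float
    n: int

    def __post_init__(self) -> None:
        if self.loo_rmse < 0 or self.mre < 0:
            raise ValueError("loo_rmse and mre must be non-negative")
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")

    @staticmethod
    def from_predictions(y: np.ndarray, y_loo: np.ndarray) -> "LOOMetrics":
        y = np.asarray(y, dtype=float)
        y_loo = np.asarray(y_loo, dtype=float)
        e = y_loo - y
        sse = float(np.sum(e**2))
        sst = float(np.sum((y - y.mean()) ** 2))
        nonzero = y != 0
        if not np.all(nonzero):
            warnings.warn("zero-valued outputs excluded from MRE", stacklevel=2)
        mre = float(np.mean(np.abs(e[nonzero]) / np.abs(y[nonzero])) * 100.0)
        return LOOMetrics(
            loo_rmse=float(np.sqrt(np.mean(e**2))),
            r2=1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf),
            mre=mre,
            n=int(y.size),
        )

    def to_dict(self) -> dict:
        return {"loo_rmse": self.loo_rmse, "r2": self.r2, "mre_percent": self.mre, "n": self.n}


def _make_kernel(d: int, nugget: float, fixed: dict | None = None):
    if fixed is None:
        return ConstantKernel(1.0, (1e-4, 1e4)) * RBF(np.ones(d), (1e-2, 1e5)) + WhiteKernel(
            nugget, "fixed"
        )
    return ConstantKernel(fixed["signal_variance"], "fixed") * RBF(
        np.asarray(fixed["lengthscales"]), "fixed"
    ) + WhiteKernel(fixed["nugget"], "fixed")


class GPSurrogate:
    """GP emulator model over a simulation table.

    Parameters
    ----------
    X : DataFrame or (n, d) array
        Training inputs (one simulator run per row).
    y : sequence
        Scalar output per run (e.g. systolic diameter in mm).
    output_name : str
        Label used in summaries and persisted artifacts.
    """

    def __init__(self, X, y, output_name: str = "output"):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per output value")
        if X.shape[0] < 10:
            raise ValueError(f"need >= 10 training points, got {X.shape[0]}")
        col_sd = X.std(axis=0)
        degenerate = [self.feature_names[i] for i in np.where(col_sd == 0)[0]]
        if degenerate:
            raise ValueError(f"degenerate (constant) input columns: {degenerate}")
        self.X = X
        self.y = y
        self.output_name = output_name

    def fit(self, seed: int = 0, n_starts: int = 5, nugget: float = 1e-8) -> "GPSurrogateResults":
        """Maximize the log marginal likelihood from ``n_starts`` seeded
        starting points and return the fitted emulator."""
        x_mean, x_sd = self.X.mean(axis=0), self.X.std(axis=0)
        y_mean = float(self.y.mean())
        y_sd = float(self.y.std())
        constant_output = y_sd == 0.0
        if constant_output:
            y_sd = 1.0
        Z = (self.X - x_mean) / x_sd
        y_norm = (self.y - y_mean) / y_sd
        gpr = GaussianProcessRegressor(
            kernel=_make_kernel(Z.shape[1], nugget),
            normalize_y=False,
            n_restarts_optimizer=max(0, n_starts - 1),
            random_state=seed,
            optimizer=None if constant_output else "fmin_l_bfgs_b",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit(Z, y_norm)
        return GPSurrogateResults(
            model=self,
            gpr=gpr,
            x_mean=x_mean,
            x_sd=x_sd,
            y_mean=y_mean,
            y_sd=y_sd,
            constant_output=constant_output,
            nugget=nugget,
            seed=seed,
            n_starts=n_starts,
        )


class GPSurrogateResults:
    """Fitted emulator: predictions, LOO diagnostics, persistence."""

    def __init__(self, model, gpr, x_mean, x_sd, y_mean, y_sd, constant_output, nugget, seed, n_starts):
        self.model = model
        self.gpr = gpr
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_sd = np.asarray(x_sd, dtype=float)
        self.y_mean = y_mean
        self.y_sd = y_sd
        self.constant_output = constant_output
        self.nugget = nugget
        self.seed = seed
        self.n_starts = n_starts

    # -- prediction --------------------------------------------------------
    def _as_matrix(self, Xq) -> np.ndarray:
        if isinstance(Xq, pd.DataFrame):
            missing = [c for c in self.model.feature_names if c not in Xq.columns]
            if missing:
                raise ValueError(f"query is missing columns {missing}")
            Xq = Xq[self.model.feature_names].to_numpy(dtype=float)
        else:
            Xq = np.asarray(Xq, dtype=float)
            if Xq.ndim == 1:
                Xq = Xq[None, :]
            if Xq.shape[1] != len(self.model.feature_names):
                raise ValueError(
                    f"query has {Xq.shape[1]} columns, expected "
                    f"{len(self.model.feature_names)}"
                )
        return (Xq - self.x_mean) / self.x_sd

    def predict(self, Xq, return_sd: bool = False):
        """Predictive mean (and optionally sd) at the query rows."""
        Z = self._as_matrix(Xq)
        if self.constant_output:
            mean = np.full(Z.shape[0], self.y_mean)
            if return_sd:
                return mean, np.zeros(Z.shape[0])
            return mean
        if return_sd:
            m, s = self.gpr.predict(Z, return_std=True)
            return m * self.y_sd + self.y_mean, s * self.y_sd
        return self.gpr.predict(Z) * self.y_sd + self.y_mean

    @property
    def hyperparameters(self) -> dict:
        k = self.gpr.kernel_
        return {
            "signal_variance": float(k.k1.k1.constant_value),
            "lengthscales": np.atleast_1d(k.k1.k2.length_scale).astype(float).tolist(),
            "nugget": float(k.k2.noise_level),
        }

    # -- leave-one-out -----------------------------------------------------
    def loo(self, refit_hyperparameters: bool = False):
        """Literal leave-one-out: one refit per training point.

        With ``refit_hyperparameters=False`` (default) the maximized kernel
        and output scaling are frozen and only the GP posterior is rebuilt
        per fold — the fold prediction then agrees with the closed-form GP
        LOO identity to machine precision.  With ``True`` the
        hyperparameters are re-optimized from scratch per fold.

        Returns ``(LOOMetrics, loo_predictions)``.
        """
        X, y = self.model.X, self.model.y
        n = y.size
        preds = np.empty(n)
        if self.constant_output:
            preds[:] = self.y_mean
            return LOOMetrics.from_predictions(y, preds), preds
        Z = (X - self.x_mean) / self.x_sd
        y_norm = (y - self.y_mean) / self.y_sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n):
                mask = np.arange(n) != i
                if refit_hyperparameters:
                    sub = GPSurrogate(X[mask], y[mask], self.model.output_name)
                    res = sub.fit(seed=self.seed, n_starts=self.n_starts, nugget=self.nugget)
                    preds[i] = float(res.predict(X[i])[0])
                else:
                    gpr = GaussianProcessRegressor(
                        kernel=self.gpr.kernel_, optimizer=None, normalize_y=False
                    )
                    gpr.fit(Z[mask], y_norm[mask])
                    preds[i] = float(gpr.predict(Z[i][None, :])[0]) * self.y_sd + self.y_mean
        return LOOMetrics.from_predictions(y, preds), preds

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        hp = self.hyperparameters
        metrics, _ = self.loo()
        lines = [
            f"GP surrogate: {self.model.output_name}",
            "=" * 46,
            f"  n train        {self.model.y.size}",
            f"  signal var     {hp['signal_variance']:.4g}",
            f"  nugget         {hp['nugget']:.1e}",
            f"  LOO RMSE       {metrics.loo_rmse:.4g}",
            f"  R^2            {metrics.r2:.4f}",
            f"  MRE            {metrics.mre:.3f} %",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "output_name": self.model.output_name,
            "feature_names": self.model.feature_names,
            "X": self.model.X.tolist(),
            "y": self.model.y.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "constant_output": self.constant_output,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "training_data_sha256": hashlib.sha256(
                np.ascontiguousarray(self.model.X).tobytes()
                + np.ascontiguousarray(self.model.y).tobytes()
            ).hexdigest(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GPSurrogateResults":
        payload = json.loads(Path(path).read_text())
        X = pd.DataFrame(payload["X"], columns=payload["feature_names"])
        model = GPSurrogate(X, payload["y"], payload["output_name"])
        hp = payload["hyperparameters"]
        x_mean = np.array(payload["x_mean"])
        x_sd = np.array(payload["x_sd"])
        gpr = GaussianProcessRegressor(
            kernel=_make_kernel(model.X.shape[1], hp["nugget"], fixed=hp),
            optimizer=None,
            normalize_y=False,
        )
        y_norm = (model.y - payload["y_mean"]) / payload["y_sd"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit((model.X - x_mean) / x_sd, y_norm)
        return cls(
            model=model,
            gpr=gpr,
            x_mean=x_mean,
            x_sd=x_sd,
            y_mean=payload["y_mean"],
            y_sd=payload["y_sd"],
            constant_output=payload["constant_output"],
            nugget=hp["nugget"],
            seed=payload["seed"],
            n_starts=payload["n_starts"],
        )
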