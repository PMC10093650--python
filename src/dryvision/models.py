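"""Shrinkage-to-moisture regression models.

Two single-hidden-layer regressors map the area ratio AR_t (shrinkage) to the
moisture ratio MR_t:

* :class:`ShrinkageELM` — extreme learning machine: input-to-hidden weights
  and biases drawn once from uniform(-1, 1) and frozen, sigmoid hidden
  activation, output weights solved in closed form by the Moore-Penrose
  pseudoinverse (minimum-norm least squares).
* :class:`ShrinkageANN` — feedforward network with one tanh hidden layer and
  linear output, trained by Levenberg-Marquardt with weight decay and early
  stopping on a held-out validation split.

Both follow the statsmodels convention: a model object built from data whose
``fit()`` returns a results object carrying parameters, metrics, ``predict``
and ``summary()``. ``from_run`` constructors build a model directly from a
:class:`~dryvision.drying.DryingRun`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitMetrics",
    "evaluate",
    "ShrinkageELM",
    "ShrinkageANN",
    "ELMResults",
    "ANNResults",
    "train_predict_protocol",
]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class FitMetrics:
    """RMSE, MAE and R² of a prediction against measured values."""

    rmse: float
    mae: float
    r2: float
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "r2": self.r2, "n": self.n}

    def __str__(self) -> str:
        r2 = "nan" if np.isnan(self.r2) else f"{self.r2:.4f}"
        return f"RMSE={self.rmse:.4g}  MAE={self.mae:.4g}  R²={r2}  (n={self.n})"


def evaluate(y, yhat) -> FitMetrics:
    """Compute RMSE, MAE and the coefficient of determination R².

    RMSE = sqrt(mean((ŷ-y)²)), MAE = mean|ŷ-y|,
    R² = 1 - Σ(y-ŷ)²/Σ(y-ȳ)². With zero variance in y, R² is undefined and
    reported as NaN with a warning.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError("measured and predicted vectors must have equal length")
    if y.size == 0:
        raise ValueError("empty vectors")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero variance in measured values; R² undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return FitMetrics(rmse=rmse, mae=mae, r2=r2, n=int(y.size))


def _as_design(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("predictors must be 1-D or 2-D")
    return X


# ---------------------------------------------------------------------------
# ELM

class ShrinkageELM:
    """Extreme learning machine regressor MR = f(AR).

    Parameters
    ----------
    endog : array
        Target values (moisture ratio), shape (n,).
    exog : array
        Predictor values (area ratio), shape (n,) or (n, d).
    hidden : int
        Hidden node count L. The default 12 is the manually tuned optimum
        for the AR→MR mapping.
    seed : int
        Seeds the uniform(-1, 1) draw of the frozen input weights/biases.
    weights, biases : array, optional
        Explicit input-to-hidden weights (d×L) and biases (L,) overriding
        the random draw (test hook / reproducibility).
    """

    def __init__(self, endog, exog, hidden: int = 12, seed: int = 0,
                 weights=None, biases=None):
        self.endog = np.asarray(endog, dtype=np.float64).ravel()
        self.exog = _as_design(exog)
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog lengths differ")
        if self.endog.size < 2:
            raise ValueError("at least 2 samples required")
        if not (np.isfinite(self.endog).all() and np.isfinite(self.exog).all()):
            raise ValueError("non-finite values in training data")
        if hidden < 1:
            raise ValueError("hidden node count must be >= 1")
        self.hidden = int(hidden)
        self.seed = int(seed)
        d = self.exog.shape[1]
        rng = np.random.default_rng(seed)
        drawn_W = rng.uniform(-1.0, 1.0, size=(d, hidden))
        drawn_b = rng.uniform(-1.0, 1.0, size=hidden)
        self.W = drawn_W if weights is None else np.asarray(weights, dtype=np.float64)
        self.b = drawn_b if biases is None else np.asarray(biases, dtype=np.float64)
        if self.W.shape != (d, hidden) or self.b.shape != (hidden,):
            raise ValueError("weights must be (d, hidden) and biases (hidden,)")

    @classmethod
    def from_run(cls, run, **kwargs) -> "ShrinkageELM":
        ar, mr = run.modeling_pairs()
        return cls(mr, ar, **kwargs)

    def _hidden_matrix(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(X @ self.W + self.b)

    def fit(self) -> "ELMResults":
        """Solve the output weights beta = pinv(H) @ T (SVD least squares).

        The pseudoinverse uses the standard max(n, L)·eps relative
        singular-value cutoff, yielding the minimum-norm solution when the
        hidden matrix is (numerically) rank-deficient.
        """
        H = self._hidden_matrix(self.exog)
        rtol = max(H.shape) * np.finfo(np.float64).eps
        beta = np.linalg.pinv(H, rcond=rtol) @ self.endog
        return ELMResults(self, beta)


class _ResultsBase:
    """Shared results behaviour: prediction, metrics, summary."""

    model = None

    def predict(self, exog=None) -> np.ndarray:
        raise NotImplementedError

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.endog

    def metrics(self, endog=None, exog=None) -> FitMetrics:
        """Fit metrics on the training data, or on new (endog, exog)."""
        if endog is None:
            return evaluate(self.model.endog, self.fittedvalues)
        return evaluate(endog, self.predict(exog))

    def _summary_rows(self) -> list[tuple[str, str]]:
        return []

    def summary(self) -> str:
        m = self.metrics()
        rows = [("Model", type(self.model).__name__),
                ("No. observations", str(self.model.endog.size)),
                ("Hidden nodes", str(self.model.hidden)),
                *self._summary_rows(),
                ("Train RMSE", f"{m.rmse:.6f}"),
                ("Train MAE", f"{m.mae:.6f}"),
                ("Train R²", f"{m.r2:.6f}")]
        width = max(len(k) for k, _ in rows)
        lines = ["=" * (width + 22)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        lines.append("=" * (width + 22))
        return "\n".join(lines)


class ELMResults(_ResultsBase):
    """Fitted ELM: frozen random hidden layer plus solved output weights."""

    def __init__(self, model: ShrinkageELM, beta: np.ndarray):
        self.model = model
        self.beta = beta

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else _as_design(exog)
        return self.model._hidden_matrix(X) @ self.beta

    def _summary_rows(self):
        return [("Seed", str(self.model.seed)),
                ("‖beta‖", f"{np.linalg.norm(self.beta):.4g}")]


# ---------------------------------------------------------------------------
# ANN (Levenberg-Marquardt)

@dataclass
class ANNConfig:
    """Training configuration for the LM-trained network.

    weight decay ``lam`` multiplies ‖w‖² in the objective; ``mu0`` is the
    initial LM damping, adapted ×10 on rejection and ÷10 on acceptance;
    early stopping watches a held-out split of ``val_frac`` of the samples
    with the given patience.
    """

    max_epochs: int = 1000
    lam: float = 1e-4
    mu0: float = 1e-3
    mu_max: float = 1e10
    grad_tol: float = 1e-10
    val_frac: float = 0.2
    patience: int = 6


class ShrinkageANN:
    """One-hidden-layer feedforward network MR = f(AR), LM-trained.

    tanh hidden activation, linear output. The objective is
    Σ residual² + λ‖w‖²; training stops at max epochs, a vanishing
    gradient, or when validation error fails to improve for ``patience``
    epochs (the best-validation weights are restored).
    """

    def __init__(self, endog, exog, hidden: int = 10, seed: int = 0,
                 config: ANNConfig | None = None, **config_overrides):
        self.endog = np.asarray(endog, dtype=np.float64).ravel()
        self.exog = _as_design(exog)
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog lengths differ")
        if self.endog.size < 4:
            raise ValueError("at least 4 samples required for a validation split")
        if not (np.isfinite(self.endog).all() and np.isfinite(self.exog).all()):
            raise ValueError("non-finite values in training data")
        self.hidden = int(hidden)
        self.seed = int(seed)
        cfg = config or ANNConfig()
        for k, v in config_overrides.items():
            if not hasattr(cfg, k):
                raise TypeError(f"unknown config field {k!r}")
            setattr(cfg, k, v)
        self.config = cfg

    @classmethod
    def from_run(cls, run, **kwargs) -> "ShrinkageANN":
        ar, mr = run.modeling_pairs()
        return cls(mr, ar, **kwargs)

    # parameter vector layout: [W1 (d*H), b1 (H), w2 (H), b2]
    def _unpack(self, p):
        d, H = self.exog.shape[1], self.hidden
        i = 0
        W1 = p[i:i + d * H].reshape(d, H); i += d * H
        b1 = p[i:i + H]; i += H
        w2 = p[i:i + H]; i += H
        b2 = p[i]
        return W1, b1, w2, b2

    def _forward(self, X, p):
        W1, b1, w2, b2 = self._unpack(p)
        z = np.tanh(X @ W1 + b1)
        return z @ w2 + b2, z

    def _jacobian(self, X, p):
        """Analytic Jacobian of residuals wrt parameters, shape (n, P)."""
        W1, b1, w2, _ = self._unpack(p)
        z = np.tanh(X @ W1 + b1)           # (n, H)
        dz = (1.0 - z**2) * w2             # (n, H): dyhat/d(pre-activation)
        n, d, H = X.shape[0], X.shape[1], self.hidden
        J = np.empty((n, p.size))
        # dW1: outer product of inputs with dz
        J[:, :d * H] = (X[:, :, None] * dz[:, None, :]).reshape(n, d * H)
        J[:, d * H:d * H + H] = dz
        J[:, d * H + H:d * H + 2 * H] = z
        J[:, -1] = 1.0
        return J

    def fit(self) -> "ANNResults":
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        n = self.endog.size
        d = self.exog.shape[1]
        n_params = d * self.hidden + 2 * self.hidden + 1

        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_frac * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size < 2:
            raise ValueError("too few training samples after validation split")
        Xt, yt = self.exog[train_idx], self.endog[train_idx]
        Xv, yv = self.exog[val_idx], self.endog[val_idx]

        p = rng.uniform(-0.5, 0.5, size=n_params)
        lam, mu = cfg.lam, cfg.mu0
        eye = np.eye(n_params)

        def objective(params):
            r = self._forward(Xt, params)[0] - yt
            return float(r @ r + lam * params @ params), r

        F, r = objective(p)
        best_val = np.inf
        best_p = p.copy()
        stall = 0
        history = []
        stop_reason = "max_epochs"

        for epoch in range(cfg.max_epochs):
            J = self._jacobian(Xt, p)
            g = J.T @ r + lam * p
            if np.linalg.norm(2 * g) < cfg.grad_tol:
                stop_reason = "gradient"
                break
            A = J.T @ J + lam * eye
            accepted = False
            solved_any = False
            while mu <= cfg.mu_max:
                try:
                    step = np.linalg.solve(A + mu * eye, -g)
                    solved_any = True
                except np.linalg.LinAlgError:
                    mu *= 10
                    continue
                F_new, r_new = objective(p + step)
                if F_new < F:
                    p = p + step
                    F, r = F_new, r_new
                    mu = max(mu / 10, 1e-12)
                    accepted = True
                    break
                mu *= 10
            if not accepted:
                if not solved_any:
                    raise RuntimeError(
                        "singular damped Hessian: no solvable LM step up to "
                        f"mu={cfg.mu_max:g}")
                # no descent direction left: converged on the regularized objective
                stop_reason = "no_descent"
                mu = cfg.mu0
                break

            val_mse = float(np.mean((self._forward(Xv, p)[0] - yv) ** 2))
            history.append({"epoch": epoch, "objective": F, "val_mse": val_mse, "mu": mu})
            if val_mse < best_val - 1e-15:
                best_val = val_mse
                best_p = p.copy()
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    stop_reason = "early_stopping"
                    break

        final_p = best_p if np.isfinite(best_val) else p
        if not np.isfinite(final_p).all():
            raise RuntimeError("non-finite weights after training")
        return ANNResults(self, final_p, n_epochs=len(history),
                          stop_reason=stop_reason, history=history)


class ANNResults(_ResultsBase):
    """Fitted LM network: best-validation weights and training history."""

    def __init__(self, model: ShrinkageANN, params: np.ndarray,
                 n_epochs: int, stop_reason: str, history: list):
        self.model = model
        self.params = params
        self.n_epochs = n_epochs
        self.stop_reason = stop_reason
        self.history = history

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else _as_design(exog)
        return self.model._forward(X, self.params)[0]

    def _summary_rows(self):
        return [("Seed", str(self.model.seed)),
                ("Epochs", str(self.n_epochs)),
                ("Stop reason", self.stop_reason),
                ("Weight decay λ", f"{self.model.config.lam:g}")]


# ---------------------------------------------------------------------------
# protocol

_MODEL_KINDS = {"elm": ShrinkageELM, "ann": ShrinkageANN}


def train_predict_protocol(train_run, test_run, model_kind: str = "elm",
                           **model_kwargs) -> dict:
    """Fit on one run, predict a separate run.

    Fits the chosen model on the train run's (AR, MR) pairs and evaluates on
    both runs — the protocol of training on one drying experiment and
    verifying on a fresh one. AR and MR are already on a [0, 1] scale, so no
    further normalization is applied.

    Returns a dict with keys ``model`` (kind), ``results`` (fitted results
    object), ``train``/``test`` (:class:`FitMetrics`), and per-point
    ``test_predictions``.
    """
    if model_kind not in _MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {sorted(_MODEL_KINDS)}")
    ar_tr, mr_tr = train_run.modeling_pairs()
    ar_te, mr_te = test_run.modeling_pairs()
    if ar_tr.size < 4 or ar_te.size < 4:
        raise ValueError("fewer than 4 usable (AR, MR) pairs in a run")
    model = _MODEL_KINDS[model_kind](mr_tr, ar_tr, **model_kwargs)
    res = model.fit()
    yhat_te = res.predict(ar_te)
    return {
        "model": model_kind,
        "results": res,
        "train": res.metrics(),
        "test": evaluate(mr_te, yhat_te),
        "test_predictions": yhat_te,
    }
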