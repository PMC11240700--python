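"""Five survival learners behind one contract.

Every model implements ``fit(X, time, event)``, ``predict_risk(X)`` (higher =
worse prognosis) and ``predict_survival(X, times)`` returning S(t|x) on a
time grid with S(0|x) = 1 and S nonincreasing.

Learners: backward stepwise Cox (AIC), LASSO-penalized Cox, random survival
forest (1000 trees, log-rank splitting), gradient-boosted Cox (1000 trees,
partial-likelihood loss) and the numpy Deepsurv network from
:mod:`radsurv.deepsurv`.  Cox fitting goes through lifelines, the forest,
boosting and elastic-net paths through scikit-survival; survival curves for
score-based learners use a Breslow baseline fitted on the training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxfit import ConvergenceError, cox_newton_fit
from .deepsurv import DeepsurvConfig, DeepSurvNetwork

__all__ = [
    "ModelSpec",
    "one_hot_encode",
    "apply_one_hot",
    "BreslowBaseline",
    "StepwiseCoxModel",
    "LassoCoxModel",
    "RSFModel",
    "GBMModel",
    "DeepsurvModel",
    "make_model",
    "default_grid",
    "efron_null_loglik",
]

MODEL_LABELS = ("stepwise_cox", "lasso_cox", "rsf", "gbm", "deepsurv")


@dataclass
class ModelSpec:
    label: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in MODEL_LABELS:
            raise ValueError(f"unknown model label {self.label!r}")


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def one_hot_encode(
    df: pd.DataFrame, reference: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """One-hot encode categorical columns, dropping a reference level.

    Numeric columns pass through.  Returns (design matrix, encoding map);
    the map records levels and reference per variable and makes the encoding
    reusable (and checkable) at predict time via :func:`apply_one_hot`.
    """
    reference = reference or {}
    encoding: dict[str, dict] = {}
    out = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == object or str(s.dtype) == "category" or s.dtype == bool:
            levels = sorted(map(str, pd.unique(s.astype(str))))
            ref = str(reference.get(col, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            encoding[col] = {"levels": levels, "reference": ref}
            for lv in levels:
                if lv == ref:
                    continue
                out[f"{col}={lv}"] = (s.astype(str) == lv).astype(float).to_numpy()
        else:
            encoding[col] = {"numeric": True}
            out[col] = s.to_numpy(dtype=float)
    return pd.DataFrame(out, index=df.index), encoding


def apply_one_hot(df: pd.DataFrame, encoding: dict) -> pd.DataFrame:
    """Re-apply a fitted encoding; unseen categorical levels raise."""
    out = {}
    for col, enc in encoding.items():
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        s = df[col]
        if enc.get("numeric"):
            out[col] = s.to_numpy(dtype=float)
            continue
        seen = set(enc["levels"])
        unseen = set(map(str, pd.unique(s.astype(str)))) - seen
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(unseen)} in column {col!r}")
        for lv in enc["levels"]:
            if lv == enc["reference"]:
                continue
            out[f"{col}={lv}"] = (s.astype(str) == lv).astype(float).to_numpy()
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# Breslow baseline
# ---------------------------------------------------------------------------

class BreslowBaseline:
    """Nonparametric cumulative baseline hazard from (time, event, score)."""

    def fit(self, time: np.ndarray, event: np.ndarray, scores: np.ndarray):
        time = np.asarray(time, float)
        event = np.asarray(event).astype(bool)
        scores = np.asarray(scores, float)
        order = np.argsort(time, kind="stable")
        t, e, s = time[order], event[order], scores[order]
        exp_s = np.exp(s - s.max())
        rev = np.cumsum(exp_s[::-1])[::-1]
        first = np.searchsorted(t, t, side="left")
        ut, d = np.unique(t[e], return_counts=True)
        # risk-set denominator at each unique event time
        pos = np.searchsorted(t, ut, side="left")
        denom = rev[pos] * np.exp(s.max())
        self.event_times_ = ut
        self.cumhaz_ = np.cumsum(d / denom)
        return self

    def cumulative_hazard(self, times: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.event_times_, np.asarray(times, float), side="right")
        ch = np.concatenate([[0.0], self.cumhaz_])
        return ch[idx]

    def survival(self, scores: np.ndarray, times: np.ndarray) -> np.ndarray:
        """S(t|x) = exp(-H0(t))^exp(score); shape (n_subjects, n_times)."""
        h0 = self.cumulative_hazard(times)[None, :]
        return np.exp(-h0 * np.exp(np.asarray(scores, float))[:, None])


def efron_null_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood of the empty (no-covariate) Cox model."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ll = 0.0
    n = len(t)
    for ut in np.unique(t[e]):
        r = int((t >= ut).sum())
        d = int(((t == ut) & e).sum())
        ll -= sum(np.log(r - l) for l in range(d))
    return float(ll)


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

def _surv_y(time, event):
    from sksurv.util import Surv

    return Surv.from_arrays(np.asarray(event).astype(bool), np.asarray(time, float))


class _BaseModel:
    def fit(self, X: pd.DataFrame, time, event):  # pragma: no cover - interface
        raise NotImplementedError

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """Default: Breslow baseline on the training fit + risk scores."""
        return self.baseline_.survival(self.predict_risk(X), times)


class StepwiseCoxModel(_BaseModel):
    """Backward stepwise Cox regression minimizing the partial-likelihood AIC.

    Starts from the full multivariable model (Efron ties, Newton iteration)
    and repeatedly removes the variable whose removal most decreases AIC,
    allowing the empty model as a terminal state.  Candidate subsets whose
    fit fails to converge are treated as unavailable (AIC = inf); if the
    final non-empty fit itself fails, the last stable model is raised with
    the error.  Survival curves use the Breslow baseline.
    """

    def __init__(self, seed: int = 0):
        pass

    def _fit_subset(self, X: pd.DataFrame, time, event, cols: list[str]):
        fit = cox_newton_fit(X[cols].to_numpy(), time, event)
        return fit, fit.aic

    def fit(self, X: pd.DataFrame, time, event):
        time = np.asarray(time, float)
        event = np.asarray(event)
        if int(event.sum()) < 10:
            raise ValueError("backward stepwise Cox needs at least 10 events")
        cols = [c for c in X.columns if X[c].std() > 0]
        aic_empty = -2.0 * efron_null_loglik(time, event)
        cache: dict[tuple, float] = {(): aic_empty}

        def aic_of(subset: tuple) -> float:
            if subset not in cache:
                try:
                    cache[subset] = self._fit_subset(X, time, event, list(subset))[1]
                except ConvergenceError:
                    cache[subset] = np.inf
            return cache[subset]

        current = tuple(cols)
        cur_aic = aic_of(current)
        if not np.isfinite(cur_aic):
            raise ConvergenceError("full stepwise Cox model did not converge")
        while current:
            cands = [
                (aic_of(tuple(c2 for c2 in current if c2 != c)), tuple(c2 for c2 in current if c2 != c))
                for c in current
            ]
            best_aic, best_subset = min(cands)
            if best_aic >= cur_aic:
                break
            cur_aic, current = best_aic, best_subset
        self.selected_ = list(current)
        if self.selected_:
            fit, _ = self._fit_subset(X, time, event, self.selected_)
            self.coef_ = pd.Series(fit.beta, index=self.selected_)
        else:
            self.coef_ = pd.Series(dtype=float)
        self.baseline_ = BreslowBaseline().fit(time, event, self.predict_risk(X))
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        if not self.selected_:
            return np.zeros(len(X))
        return X[self.selected_].to_numpy() @ self.coef_.to_numpy()

    @property
    def coefficients(self) -> pd.Series:
        return self.coef_


class LassoCoxModel(_BaseModel):
    """L1-penalized Cox regression (coordinate-descent elastic net, l1=1).

    ``alpha`` (the λ hyperparameter) = 0 delegates to an unpenalized Cox fit.
    Expects a standardized design matrix.
    """

    def __init__(self, alpha: float = 0.01, seed: int = 0):
        if alpha < 0:
            raise ValueError("lambda must be nonnegative")
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, time, event):
        self.columns_ = list(X.columns)
        t = np.asarray(time, float)
        e = np.asarray(event)
        if self.alpha == 0:
            self.coef_ = cox_newton_fit(X.to_numpy(), t, e).beta
        else:
            from sksurv.linear_model import CoxnetSurvivalAnalysis

            alphas = np.geomspace(max(self.alpha * 50, 1e-4), self.alpha, 25)
            net = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, max_iter=100000, tol=1e-7
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(X.to_numpy(), _surv_y(t, e))
            self.coef_ = net.coef_[:, -1]
        scores = X.to_numpy() @ self.coef_
        self.baseline_ = BreslowBaseline().fit(t, e, scores)
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.columns_].to_numpy() @ self.coef_

    @property
    def excluded(self) -> list[str]:
        return [c for c, b in zip(self.columns_, self.coef_) if b == 0]


class RSFModel(_BaseModel):
    """Random survival forest: 1000 trees, log-rank splitting."""

    def __init__(self, mtry: int = 1, nodesize: int = 15, n_trees: int = 1000, seed: int = 0):
        self.mtry = mtry
        self.nodesize = nodesize
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X: pd.DataFrame, time, event):
        from sksurv.ensemble import RandomSurvivalForest

        if self.mtry > X.shape[1]:
            raise ValueError("mtry exceeds the number of covariates")
        self.model_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            min_samples_leaf=self.nodesize,
            random_state=self.seed,
            n_jobs=1,
        )
        self.model_.fit(X.to_numpy(), _surv_y(time, event))
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(X.to_numpy())

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        surv = self.model_.predict_survival_function(X.to_numpy(), return_array=True)
        grid = self.model_.unique_times_
        times = np.asarray(times, float)
        idx = np.searchsorted(grid, times, side="right") - 1
        out = np.ones((len(X), len(times)))
        inside = idx >= 0
        out[:, inside] = surv[:, idx[inside]]
        return out


class GBMModel(_BaseModel):
    """Gradient boosting on the Cox partial-likelihood gradient (1000 trees)."""

    def __init__(
        self,
        shrinkage: float = 0.05,
        depth: int = 2,
        mnotn: int = 8,
        n_trees: int = 1000,
        seed: int = 0,
    ):
        if shrinkage <= 0:
            raise ValueError("shrinkage must be positive")
        self.shrinkage = shrinkage
        self.depth = depth
        self.mnotn = mnotn
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X: pd.DataFrame, time, event):
        from sksurv.ensemble import GradientBoostingSurvivalAnalysis

        self.model_ = GradientBoostingSurvivalAnalysis(
            loss="coxph",
            n_estimators=self.n_trees,
            learning_rate=self.shrinkage,
            max_depth=self.depth,
            min_samples_leaf=self.mnotn,
            random_state=self.seed,
        )
        self.model_.fit(X.to_numpy(), _surv_y(time, event))
        self.baseline_ = BreslowBaseline().fit(
            np.asarray(time, float), np.asarray(event), self.model_.predict(X.to_numpy())
        )
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(X.to_numpy())


class DeepsurvModel(_BaseModel):
    """Cox partial-likelihood neural network (see :mod:`radsurv.deepsurv`)."""

    def __init__(self, config: DeepsurvConfig | None = None, seed: int | None = None, **kwargs):
        if config is None:
            config = DeepsurvConfig(**kwargs)
        if seed is not None:
            config.seed = seed
        self.config = config

    def fit(self, X: pd.DataFrame, time, event):
        self.columns_ = list(X.columns)
        self.net_ = DeepSurvNetwork(self.config)
        self.net_.fit(X.to_numpy(dtype=float), time, event)
        self.baseline_ = BreslowBaseline().fit(
            np.asarray(time, float),
            np.asarray(event),
            self.net_.predict_risk(X.to_numpy(dtype=float)),
        )
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return self.net_.predict_risk(X[self.columns_].to_numpy(dtype=float))


def make_model(spec: ModelSpec):
    """Instantiate a learner from a :class:`ModelSpec`."""
    hp = dict(spec.hyperparams)
    if spec.label == "stepwise_cox":
        return StepwiseCoxModel(**hp)
    if spec.label == "lasso_cox":
        return LassoCoxModel(seed=spec.seed, **hp)
    if spec.label == "rsf":
        return RSFModel(seed=spec.seed, **hp)
    if spec.label == "gbm":
        return GBMModel(seed=spec.seed, **hp)
    cfg = DeepsurvConfig(seed=spec.seed, **hp)
    return DeepsurvModel(config=cfg)


def default_grid(label: str, n_features: int) -> list[dict]:
    """Default hyperparameter grids; values cover the printed optima."""
    if label == "stepwise_cox":
        return [{}]
    if label == "lasso_cox":
        return [{"alpha": float(a)} for a in np.geomspace(1e-3, 1.0, 50)]
    if label == "rsf":
        mtries = range(1, int(np.ceil(np.sqrt(n_features))) + 1)
        return [
            {"mtry": m, "nodesize": ns}
            for m in mtries
            for ns in (5, 10, 15, 20, 22, 25)
        ]
    if label == "gbm":
        return [
            {"shrinkage": s, "depth": d, "mnotn": mn}
            for s in (0.005, 0.01, 0.05, 0.095, 0.1)
            for d in (1, 2, 3, 4)
            for mn in (5, 8, 11, 15)
        ]
    if label == "deepsurv":
        return [
            {
                "hidden_layers": nl,
                "hidden_nodes": nn,
                "activation": act,
                "optimizer": opt,
            }
            for nl in (1, 2, 3)
            for nn in range(8, 17)
            for act in ("relu", "selu")
            for opt in ("adam", "sgd")
        ]
    raise ValueError(f"unknown model label {label!r}")
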