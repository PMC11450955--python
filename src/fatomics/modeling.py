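"""Feature reduction and penalized Cox survival modeling.

Two scikit-learn estimators implement the modeling stage:

* :class:`MRMRSelector` — greedy maximum-relevance minimum-redundancy
  selection adapted to right-censored outcomes: relevance of a feature is
  the absolute z-statistic of its univariable Cox fit scaled to [0, 1]
  (divided by the largest |z|, so relevance and redundancy are commensurate),
  redundancy the mean absolute Pearson correlation with already-selected
  features, and each step picks ``argmax(relevance - redundancy)`` — an
  exact duplicate of an already-selected feature (redundancy 1) therefore
  defers below any informative uncorrelated candidate;
* :class:`CoxElasticNet` — Cox proportional-hazards elastic net
  (penalty lambda * sum(alpha*|b| + (1-alpha)*b^2/2), Breslow ties) fit on
  internally standardized columns over a log-spaced lambda path, with lambda
  chosen by k-fold cross-validated partial-likelihood deviance
  ("lambda.min") and then re-tightened along the path until the active set
  has at most ``max_features`` nonzero coefficients (default 15).

Both accept ``y`` as a scikit-survival structured array, a ``(time, event)``
tuple, or a DataFrame with ``time_days``/``event`` columns. The coordinate
descent path itself is scikit-survival's ``CoxnetSurvivalAnalysis``
(glmnet-family); the cross-validation, deviance and capping logic live here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxEnetModel",
    "MRMRSelector",
    "CoxElasticNet",
    "unpack_survival",
    "breslow_partial_loglik",
    "univariable_cox_z",
    "mrmr_select",
    "fit_cox_elastic_net",
    "risk_score",
    "univariable_cox",
    "filter_min_followup",
]


# ---------------------------------------------------------------------------
# survival containers


def unpack_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(time, event)`` float/int arrays from any accepted y format."""
    if isinstance(y, pd.DataFrame):
        tcol = "time_days" if "time_days" in y.columns else "time"
        return y[tcol].to_numpy(float), y["event"].to_numpy(int)
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        ev = next(n for n in names if y.dtype[n] == np.dtype(bool) or "event" in n or "cens" in n)
        tt = next(n for n in names if n != ev)
        return y[tt].astype(float), y[ev].astype(int)
    time, event = y
    return np.asarray(time, float), np.asarray(event, int)


def to_structured(y) -> np.ndarray:
    time, event = unpack_survival(y)
    return Surv.from_arrays(event=event.astype(bool), time=time)


def filter_min_followup(surv: pd.DataFrame, min_days: float = 10.0) -> pd.DataFrame:
    """Drop subjects with follow-up shorter than ``min_days`` (cohort rule)."""
    tcol = "time_days" if "time_days" in surv.columns else "time"
    return surv[surv[tcol] >= min_days].copy()


# ---------------------------------------------------------------------------
# Breslow partial likelihood and univariable Cox (Newton-Raphson)


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with the Breslow tie convention."""
    lp = np.asarray(lp, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], lp[order]
    # reverse log-cum-sum-exp of lp -> log sum over the risk set {j: t_j >= t}
    rev = np.logaddexp.accumulate(x[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ll = float(np.sum(x[e == 1] - rev[first][e == 1]))
    return ll


def _cox1_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 30):
    """Univariable Cox fit (Breslow): returns (beta, se, z)."""
    x = np.asarray(x, float)
    order = np.argsort(time, kind="stable")
    t, e, xs = np.asarray(time, float)[order], np.asarray(event, int)[order], x[order]
    first = np.searchsorted(t, t, side="left")
    ev = e == 1
    if ev.sum() == 0 or xs.std() == 0:
        return 0.0, np.inf, 0.0
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(np.clip(beta * xs, -500, 500))
        s0 = np.cumsum(w[::-1])[::-1][first]
        s1 = np.cumsum((w * xs)[::-1])[::-1][first]
        s2 = np.cumsum((w * xs**2)[::-1])[::-1][first]
        mu = s1 / s0
        U = float(np.sum(xs[ev] - mu[ev]))
        I = float(np.sum(s2[ev] / s0[ev] - mu[ev] ** 2))
        if I <= 1e-12:
            return beta, np.inf, 0.0
        step = U / I
        beta += np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-10:
            break
    se = 1.0 / np.sqrt(I)
    return beta, se, beta / se


def univariable_cox_z(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Absolute Wald z of a univariable Cox fit on the z-scored feature."""
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0 or not np.all(np.isfinite(x)):
        return 0.0
    _, _, z = _cox1_newton((x - x.mean()) / sd, time, event)
    return abs(z)


def univariable_cox(x, y) -> dict:
    """Single-covariate Cox fit on the standardized feature.

    Returns hazard ratio per SD with its Wald 95% CI and p-value, Harrell's
    C-index of the fitted predictor, and AIC = -2 logPL + 2.
    """
    from .evaluation import concordance_index  # local import: avoid cycle

    time, event = unpack_survival(y)
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("feature has zero variance")
    xs = (x - x.mean()) / sd
    beta, se, z = _cox1_newton(xs, time, event)
    ll = breslow_partial_loglik(beta * xs, time, event)
    from scipy import stats as sps

    p = 2 * sps.norm.sf(abs(z))
    return {
        "hr_per_sd": float(np.exp(beta)),
        "ci_lower": float(np.exp(beta - 1.96 * se)),
        "ci_upper": float(np.exp(beta + 1.96 * se)),
        "p": float(p),
        "c_index": concordance_index(xs if beta >= 0 else -xs, (time, event)),
        "aic": -2.0 * ll + 2.0,
        "beta": float(beta),
        "se": float(se),
    }


# ---------------------------------------------------------------------------
# mRMR


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy survival-aware maximum-relevance minimum-redundancy selection.

    Parameters
    ----------
    k : int
        Number of features to retain (default 50, the fat-omics reduction).

    Attributes
    ----------
    selected_features_ : list of str
        Names in selection order.
    relevance_ : ndarray
        |z| of the univariable Cox fit per input column.
    """

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        names = [str(c) for c in X_df.columns]
        A = X_df.to_numpy(float)
        n, p = A.shape
        if self.k > p:
            raise ValueError(f"k={self.k} exceeds the {p} available features")
        if not np.all(np.isfinite(A)):
            raise ValueError("feature table contains non-finite values")
        time, event = unpack_survival(y)
        raw_z = np.array([univariable_cox_z(A[:, j], time, event) for j in range(p)])
        relevance = raw_z / raw_z.max() if raw_z.max() > 0 else raw_z

        sd = A.std(axis=0)
        Z = (A - A.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        Z[:, sd == 0] = 0.0

        selected: list[int] = []
        remaining = list(range(p))
        redundancy = np.zeros(p)
        for _ in range(self.k):
            scores = relevance - redundancy
            best = max(remaining, key=lambda j: (scores[j], -j))
            selected.append(best)
            remaining.remove(best)
            if remaining:
                corr = np.abs(Z[:, remaining].T @ Z[:, best]) / n
                m = len(selected)
                idx = np.asarray(remaining)
                redundancy[idx] = (redundancy[idx] * (m - 1) + corr) / m

        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.relevance_ = raw_z
        self.selected_idx_ = selected
        self.selected_features_ = [names[j] for j in selected]
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        return self.support_


def mrmr_select(X: pd.DataFrame, surv, k: int = 50) -> list:
    """Names of the top-``k`` mRMR features, in selection order."""
    return MRMRSelector(k=k).fit(X, surv).selected_features_


# ---------------------------------------------------------------------------
# Cox elastic net


@dataclass
class CoxEnetModel:
    """Selected features and original-scale coefficients of the final model.

    ``log_features`` lists features entered on the natural-log scale (e.g.
    ``EAT_vol``); the risk score is sum(coef * transformed feature).
    """

    feature_names: list
    coefficients: list
    l1_ratio: float = 0.8
    lam: float = 0.0
    cv_folds: int = 10
    seed: int | None = None
    log_features: tuple = ()

    def __post_init__(self):
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("feature_names/coefficients length mismatch")

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "l1_ratio": self.l1_ratio,
            "lambda": self.lam,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "log_features": list(self.log_features),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoxEnetModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            feature_names=payload["feature_names"],
            coefficients=payload["coefficients"],
            l1_ratio=payload["l1_ratio"],
            lam=payload["lambda"],
            cv_folds=payload["cv_folds"],
            seed=payload.get("seed"),
            log_features=tuple(payload.get("log_features", ())),
        )


def risk_score(model: CoxEnetModel, x) -> float:
    """Linear risk score sum(coef * feature) of one study's feature vector."""
    total = 0.0
    for name, coef in zip(model.feature_names, model.coefficients):
        try:
            v = float(x[name])
        except (KeyError, ValueError, IndexError) as exc:
            raise KeyError(f"feature {name!r} missing from input vector") from exc
        if name in model.log_features:
            v = float(np.log(v))
        total += coef * v
    return float(total)


class CoxElasticNet(BaseEstimator):
    """Cox PH elastic net with CV lambda selection and an active-set cap.

    Parameters
    ----------
    l1_ratio : float
        Elastic-net mixing alpha (1 = lasso); default 0.8.
    cv : int
        Cross-validation folds for lambda (stratified by event); default 10.
    max_features : int or None
        If the CV-optimal lambda admits more nonzero coefficients than this,
        the penalty is re-tightened along the path until the active set fits
        the cap (default 15). ``None`` disables the cap.
    alphas : array-like or None
        Explicit lambda path (decreasing); default: a log-spaced path of
        ``n_alphas`` values chosen by the coordinate-descent backend.

    Attributes
    ----------
    coef_ : ndarray
        Original-scale coefficients for every input column (zeros included).
    alpha_ : float
        Selected penalty weight lambda.
    model_ : CoxEnetModel
        Nonzero-coefficient summary of the fit.
    """

    def __init__(
        self,
        l1_ratio: float = 0.8,
        cv: int = 10,
        max_features: int | None = 15,
        n_alphas: int = 50,
        alpha_min_ratio: float = 0.01,
        alphas=None,
        max_iter: int = 100000,
        tol: float = 1e-9,
        random_state: int | None = None,
    ):
        self.l1_ratio = l1_ratio
        self.cv = cv
        self.max_features = max_features
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.alphas = alphas
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _standardize(self, A):
        mean = A.mean(axis=0)
        sd = A.std(axis=0)
        safe = np.where(sd > 0, sd, 1.0)
        Z = (A - mean) / safe
        Z[:, sd == 0] = 0.0
        return Z, mean, sd

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        names = [str(c) for c in X_df.columns]
        A = X_df.to_numpy(float)
        if not np.all(np.isfinite(A)):
            raise ValueError("feature table contains non-finite values")
        time, event = unpack_survival(y)
        if event.sum() < 2:
            raise ValueError("need at least 2 events to fit a Cox model")
        Z, mean, sd = self._standardize(A)
        y_struct = Surv.from_arrays(event=event.astype(bool), time=time)

        kwargs = dict(l1_ratio=self.l1_ratio, max_iter=self.max_iter, normalize=False,
                      fit_baseline_model=False, tol=self.tol)
        if self.alphas is not None:
            path_est = CoxnetSurvivalAnalysis(alphas=np.sort(self.alphas)[::-1], **kwargs)
        else:
            path_est = CoxnetSurvivalAnalysis(
                n_alphas=self.n_alphas, alpha_min_ratio=self.alpha_min_ratio, **kwargs
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path_est.fit(Z, y_struct)
        alphas = np.asarray(path_est.alphas_)  # decreasing
        coef_path = path_est.coef_  # (p, n_alphas), standardized scale

        if len(alphas) == 1 or self.cv < 2:
            best_idx = len(alphas) - 1
            self.cv_deviance_ = None
        else:
            cv_dev = self._cv_deviance(Z, time, event, alphas, kwargs)
            best_idx = int(np.nanargmin(cv_dev))
            self.cv_deviance_ = cv_dev

        if self.max_features is not None:
            while best_idx > 0 and int(np.count_nonzero(coef_path[:, best_idx])) > self.max_features:
                best_idx -= 1
            if int(np.count_nonzero(coef_path[:, best_idx])) > self.max_features:
                warnings.warn(
                    "active set exceeds max_features even at the largest penalty",
                    stacklevel=2,
                )

        beta_std = coef_path[:, best_idx]
        beta = np.where(sd > 0, beta_std / np.where(sd > 0, sd, 1.0), 0.0)
        self.alphas_ = alphas
        self.coef_path_ = coef_path
        self.alpha_ = float(alphas[best_idx])
        self.coef_ = beta
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        nz = np.flatnonzero(beta_std)
        self.selected_features_ = [names[j] for j in nz]
        self.model_ = CoxEnetModel(
            feature_names=self.selected_features_,
            coefficients=[float(beta[j]) for j in nz],
            l1_ratio=self.l1_ratio,
            lam=self.alpha_,
            cv_folds=self.cv,
            seed=self.random_state,
        )
        return self

    def _cv_deviance(self, Z, time, event, alphas, kwargs):
        """-2 * test-fold Breslow partial log-likelihood summed per lambda."""
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        dev = np.zeros(len(alphas))
        used = np.zeros(len(alphas))
        for train_idx, test_idx in skf.split(Z, event):
            if event[train_idx].sum() < 2 or event[test_idx].sum() < 1:
                continue
            y_tr = Surv.from_arrays(event=event[train_idx].astype(bool), time=time[train_idx])
            est = CoxnetSurvivalAnalysis(alphas=alphas, **kwargs)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(Z[train_idx], y_tr)
            except (ArithmeticError, ValueError):
                continue
            fitted = {a: i for i, a in enumerate(est.alphas_)}
            for k, a in enumerate(alphas):
                if a not in fitted:
                    continue
                lp = Z[test_idx] @ est.coef_[:, fitted[a]]
                dev[k] += -2.0 * breslow_partial_loglik(lp, time[test_idx], event[test_idx])
                used[k] += 1
        full = used == used.max()
        dev = np.where(full, dev, np.nan)
        if not np.any(np.isfinite(dev)):
            raise RuntimeError("cross-validation failed on every fold")
        return dev

    def predict(self, X) -> np.ndarray:
        """Linear risk scores (original-scale coefficients)."""
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        A = X_df[list(self.feature_names_in_)].to_numpy(float) if isinstance(X, pd.DataFrame) \
            else X_df.to_numpy(float)
        return A @ self.coef_

    def score(self, X, y) -> float:
        from .evaluation import concordance_index

        return concordance_index(self.predict(X), y)


def fit_cox_elastic_net(
    X: pd.DataFrame,
    surv,
    alpha: float = 0.8,
    folds: int = 10,
    seed: int | None = None,
    max_features: int | None = 15,
    **kwargs,
) -> CoxEnetModel:
    """Fit the penalized Cox model; returns the nonzero-coefficient summary.

    The fitted estimator is attached as ``model.estimator_`` for callers that
    need predictions or the full path.
    """
    est = CoxElasticNet(
        l1_ratio=alpha, cv=folds, max_features=max_features, random_state=seed, **kwargs
    ).fit(X, surv)
    model = est.model_
    model.estimator_ = est
    return model
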