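"""Per-vessel-type ballast discharge models.

Two model families are fitted to curated voyage-level discharge volumes:

* ordinary multiple linear regression on calculated ballast capacity plus
  categorical covariates (destination port purpose, ports, ecoregions), with
  candidate predictor sets ranked by BIC — used for tankers, container
  vessels and the "other" class;

* a K-component mixture of linear regressions on calculated ballast capacity,
  fitted by expectation-maximisation (EM), for bulk carriers, whose discharge
  behaviour is multi-modal (minimal, partial, full and heavy-ballast
  discharge regimes).  Each observation with capacity ``x_i`` arises from
  component ``j`` with probability ``p_j``, under which
  ``y_i ~ beta1_j + beta2_j * x_i + N(0, sigma_j^2)``.  The number of
  components (1-5) is chosen by AIC, AIC3 and MDL, and validated by repeated
  random-subsampling cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "LinearDischargeModel",
    "MixtureDischargeModel",
    "SelectionReport",
    "CVResult",
    "fit_linear",
    "select_linear_by_bic",
    "em_fit_mixture",
    "information_criteria",
    "select_mixture",
    "cross_validate",
    "predict_discharge",
    "model_to_json",
    "model_from_json",
]

#: recognised predictors; "capacity" is numeric, the rest categorical
CATEGORICAL_PREDICTORS = (
    "purpose",
    "source_port",
    "dest_port",
    "source_ecoregion",
    "dest_ecoregion",
)
NUMERIC_PREDICTORS = ("capacity",)

#: column aliases accepted in input tables
_COLUMN_ALIASES = {
    "capacity": ("capacity", "capacity_m3"),
    "purpose": ("purpose", "dest_purpose"),
    "discharge": ("discharge", "discharge_m3"),
    "source_port": ("source_port",),
    "dest_port": ("dest_port",),
    "source_ecoregion": ("source_ecoregion",),
    "dest_ecoregion": ("dest_ecoregion",),
}


def _column(df: pd.DataFrame, name: str) -> pd.Series:
    for alias in _COLUMN_ALIASES.get(name, (name,)):
        if alias in df.columns:
            return df[alias]
    raise KeyError(f"no column for predictor {name!r} (tried {_COLUMN_ALIASES.get(name)})")


# ---------------------------------------------------------------------------
# linear models


@dataclass
class LinearDischargeModel:
    """OLS discharge model with Gaussian residuals.

    ``coefficients`` maps design-column names to values; ``levels`` stores
    the categorical levels seen in training (first level alphabetically is
    the reference).  ``bic = -2*loglik + k*ln(n)`` with ``k`` counting the
    coefficients plus one for sigma.
    """

    predictor_set: tuple[str, ...]
    coefficients: dict[str, float]
    sigma: float
    n: int
    loglik: float
    bic: float
    levels: dict[str, list] = field(default_factory=dict)

    @property
    def k_free(self) -> int:
        return len(self.coefficients) + 1

    def design(self, df: pd.DataFrame) -> np.ndarray:
        """Design matrix matching the training encoding; unseen categorical
        levels fall back to the level-marginal (mean) offset with a warning."""
        n = len(df)
        cols = []
        for name in self.coefficient_names():
            if name == "Intercept":
                cols.append(np.ones(n))
            elif name == "capacity":
                cols.append(_column(df, "capacity").to_numpy(float))
            else:
                factor, _, level = name.partition("=")
                vals = _column(df, factor).astype(str)
                known = set(map(str, self.levels[factor]))
                unseen = ~vals.isin(known)
                col = (vals == level).to_numpy(float)
                if unseen.any():
                    # marginal fallback: average offset over known levels
                    # (reference level contributes 0)
                    col = col.astype(float)
                    col[unseen.to_numpy()] = 1.0 / len(self.levels[factor])
                    logger.warning(
                        "%d rows with unseen %s level; using level-marginal offsets",
                        int(unseen.sum()), factor,
                    )
                cols.append(col)
        return np.column_stack(cols)

    def coefficient_names(self) -> list[str]:
        return list(self.coefficients)

    def predict_mean(self, df: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[c] for c in self.coefficient_names()])
        return self.design(df) @ beta


def _build_design(
    df: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    levels: dict[str, list] = {}
    for p in predictors:
        if p in NUMERIC_PREDICTORS:
            cols.append(_column(df, p).to_numpy(float))
            names.append(p)
        elif p in CATEGORICAL_PREDICTORS:
            vals = _column(df, p).astype(str)
            lv = sorted(vals.unique())
            levels[p] = lv
            for level in lv[1:]:  # reference = first level alphabetically
                cols.append((vals == level).to_numpy(float))
                names.append(f"{p}={level}")
        else:
            raise ValueError(f"unknown predictor {p!r}")
    return np.column_stack(cols), names, levels


def fit_linear(
    voyages: pd.DataFrame, predictor_set: Sequence[str] = ("capacity", "purpose")
) -> LinearDischargeModel:
    """Fit an OLS discharge model on the given predictor set.

    The response is per-voyage total discharge (m^3).  Raises ``ValueError``
    naming the offending term when the design is rank-deficient (e.g. a
    factor level perfectly confounded with another column).
    """
    import statsmodels.api as sm

    y = _column(voyages, "discharge").to_numpy(float)
    X, names, levels = _build_design(voyages, tuple(predictor_set))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a collinear column via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = names[int(np.argmin(diag))]
        raise ValueError(f"rank-deficient design: column {bad!r} is collinear")

    res = sm.OLS(y, X).fit()
    n = len(y)
    sigma2 = float(res.ssr / n)  # Gaussian MLE variance
    sigma = float(np.sqrt(sigma2))
    loglik = float(res.llf)
    k = X.shape[1] + 1  # coefficients + sigma
    bic = -2.0 * loglik + k * np.log(n)
    return LinearDischargeModel(
        predictor_set=tuple(predictor_set),
        coefficients=dict(zip(names, map(float, res.params))),
        sigma=sigma,
        n=n,
        loglik=loglik,
        bic=float(bic),
        levels=levels,
    )


def select_linear_by_bic(
    voyages: pd.DataFrame, candidate_sets: Sequence[Sequence[str]]
) -> tuple[LinearDischargeModel, pd.DataFrame]:
    """Fit every candidate predictor set and rank by BIC (ascending).

    Candidates whose fit fails are recorded as non-competing (infinite BIC).
    Ties break toward fewer free parameters.  Returns the best model and the
    ranked table.
    """
    if len(candidate_sets) < 2 and len(candidate_sets) != 1:
        raise ValueError("at least one candidate set is required")
    rows = []
    models: list[LinearDischargeModel | None] = []
    for cand in candidate_sets:
        cand = tuple(cand)
        try:
            m = fit_linear(voyages, cand)
            rows.append(
                {
                    "predictor_set": "+".join(cand) if cand else "(intercept)",
                    "k_free": m.k_free,
                    "loglik": m.loglik,
                    "bic": m.bic,
                    "error": "",
                }
            )
            models.append(m)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            rows.append(
                {
                    "predictor_set": "+".join(cand) if cand else "(intercept)",
                    "k_free": np.nan,
                    "loglik": np.nan,
                    "bic": np.inf,
                    "error": str(exc),
                }
            )
            models.append(None)
    table = pd.DataFrame(rows)
    order = np.lexsort((table["k_free"].fillna(np.inf), table["bic"]))
    table = table.iloc[order].reset_index(drop=True)
    best = models[order[0]]
    if best is None:
        raise ValueError("every candidate model failed to fit")
    return best, table


# ---------------------------------------------------------------------------
# mixture of linear regressions


@dataclass
class MixtureDischargeModel:
    """K-component mixture of linear regressions of discharge on capacity.

    Components are stored sorted by slope (identifiability).  ``loglik`` is
    the maximised observed-data log-likelihood.
    """

    K: int
    weights: tuple[float, ...]
    intercepts: tuple[float, ...]
    slopes: tuple[float, ...]
    sigmas: tuple[float, ...]
    loglik: float
    n: int
    n_iter: int = 0
    converged: bool = True

    def component_means(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.asarray(self.intercepts) + np.outer(x, np.asarray(self.slopes))

    def predict_mean(self, x) -> np.ndarray:
        """Predictive mean ``sum_j p_j (beta1_j + beta2_j x)`` (untruncated)."""
        mu = self.component_means(np.atleast_1d(x))
        return mu @ np.asarray(self.weights)

    def predict_variance(self, x) -> np.ndarray:
        """Predictive variance by the law of total variance."""
        w = np.asarray(self.weights)
        mu = self.component_means(np.atleast_1d(x))
        mean = mu @ w
        second = (mu**2 + np.asarray(self.sigmas) ** 2) @ w
        return second - mean**2


def _wls_line(r: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Responsibility-weighted per-component line fits, vectorised over components.

    ``r`` is (n, K); returns (intercepts, slopes), each length K.
    """
    sw = r.sum(axis=0)
    swx = r.T @ x
    swy = r.T @ y
    swxx = r.T @ (x * x)
    swxy = r.T @ (x * y)
    denom = sw * swxx - swx**2
    denom = np.where(np.abs(denom) < 1e-300, np.nan, denom)
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    return intercept, slope


class _DegenerateFit(RuntimeError):
    pass


def _em_once(
    x: np.ndarray,
    y: np.ndarray,
    K: int,
    resp0: np.ndarray,
    tol: float,
    max_iter: int,
    sigma_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int]:
    n = len(x)
    r = resp0
    ll_old = -np.inf
    floor_streak = np.zeros(K, dtype=int)
    for it in range(1, max_iter + 1):
        # M-step
        w = r.sum(axis=0) / n
        if np.any(w < 1.0 / n):
            raise _DegenerateFit("component weight collapsed")
        b1, b2 = _wls_line(r, x, y)
        if np.any(~np.isfinite(b1)) or np.any(~np.isfinite(b2)):
            raise _DegenerateFit("singular component regression")
        resid = y[:, None] - (b1 + np.outer(x, b2))
        s2 = (r * resid**2).sum(axis=0) / (n * w)
        sig = np.sqrt(np.maximum(s2, sigma_floor**2))
        at_floor = sig <= sigma_floor * (1 + 1e-12)
        floor_streak = np.where(at_floor, floor_streak + 1, 0)
        if np.any(floor_streak >= 10):
            raise _DegenerateFit("component variance pinned at floor")

        # E-step
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2.0 * np.pi * sig**2)[None, :]
            - 0.5 * (resid / sig[None, :]) ** 2
        )
        lse = logsumexp(logp, axis=1)
        ll = float(lse.sum())
        if ll < ll_old - 1e-8 * (1.0 + abs(ll_old)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll_old:.6f} -> {ll:.6f}); "
                "this indicates a numerical fault"
            )
        r = np.exp(logp - lse[:, None])
        if ll - ll_old <= tol * (1.0 + abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return w, b1, b2, sig, ll_old, it


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    sigma2 = (resid**2).sum() / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return intercept, slope, float(np.sqrt(sigma2)), float(ll)


def em_fit_mixture(
    x,
    y,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureDischargeModel:
    """Fit a K-component mixture of linear regressions by EM.

    Runs ``n_restarts`` initialisations (one deterministic, splitting the OLS
    residuals into K quantile bins; the rest by random responsibility
    assignment) and keeps the fit with the highest final log-likelihood.
    The observed-data log-likelihood is checked to be non-decreasing on every
    iteration.  ``K=1`` reduces exactly to OLS.  Component variances are
    floored at ``1e-6 * sd(y)``; restarts where a component collapses are
    discarded, and an error is raised if every restart degenerates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not 1 <= K <= 5:
        raise ValueError("K must lie in 1..5")
    if n <= 5 * (3 * K - 1):
        raise ValueError(f"need more than {5 * (3 * K - 1)} observations for K={K}")

    if K == 1:
        b1, b2, sig, ll = _ols_line(x, y)
        return MixtureDischargeModel(
            K=1, weights=(1.0,), intercepts=(b1,), slopes=(b2,), sigmas=(sig,),
            loglik=ll, n=n, n_iter=1, converged=True,
        )

    rng = np.random.default_rng(seed)
    sigma_floor = 1e-6 * float(np.std(y))
    if sigma_floor == 0.0:
        sigma_floor = 1e-12

    def _quantile_bins(v: np.ndarray) -> np.ndarray:
        edges = np.quantile(v, np.linspace(0, 1, K + 1)[1:-1])
        return np.eye(K)[np.searchsorted(edges, v, side="right")]

    # deterministic inits: slope-proxy (y/x) quantile bins separate components
    # differing in slope; pooled-OLS residual bins separate intercept shifts
    b1, b2, _, _ = _ols_line(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_proxy = np.where(np.abs(x) > 1e-12, y / np.where(x == 0, 1.0, x), y)
    inits = [_quantile_bins(slope_proxy), _quantile_bins(y - b1 - b2 * x)]
    for _ in range(max(0, n_restarts - 2)):
        inits.append(np.eye(K)[rng.integers(K, size=n)])
    inits = inits[: max(2, n_restarts)]

    best = None
    failures: list[str] = []
    for resp0 in inits:
        try:
            w, i1, s1, sg, ll, it = _em_once(x, y, K, resp0, tol, max_iter, sigma_floor)
        except _DegenerateFit as exc:
            failures.append(str(exc))
            continue
        if best is None or ll > best[4]:
            best = (w, i1, s1, sg, ll, it)
    if best is None:
        raise RuntimeError(
            f"all {len(inits)} EM restarts degenerated for K={K}: {failures[-1]}"
        )
    w, i1, s1, sg, ll, it = best
    order = np.argsort(s1)  # identifiability: sort components by slope
    return MixtureDischargeModel(
        K=K,
        weights=tuple(float(v) for v in w[order]),
        intercepts=tuple(float(v) for v in i1[order]),
        slopes=tuple(float(v) for v in s1[order]),
        sigmas=tuple(float(v) for v in sg[order]),
        loglik=float(ll),
        n=n,
        n_iter=it,
        converged=it < max_iter,
    )


def information_criteria(loglik: float, K: int, n: int) -> dict[str, float]:
    """AIC, AIC3, BIC and MDL for a K-component regression mixture.

    Free parameters: intercept, slope and sigma per component plus K-1
    weights, ``k = 4K - 1``.  ``AIC = -2l + 2k``; ``AIC3 = -2l + 3k``;
    ``BIC = -2l + k ln n``; ``MDL = -l + (k/2) ln n`` (the BIC/2 form common
    in the mixtures literature).
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    k = 4 * K - 1
    return {
        "aic": -2.0 * loglik + 2.0 * k,
        "aic3": -2.0 * loglik + 3.0 * k,
        "bic": -2.0 * loglik + k * np.log(n),
        "mdl": -loglik + 0.5 * k * np.log(n),
    }


@dataclass
class SelectionReport:
    """Component-count selection table for the bulker mixture."""

    table: pd.DataFrame
    chosen: dict[str, int]
    models: dict[int, MixtureDischargeModel]

    def best(self, criterion: str = "aic") -> MixtureDischargeModel:
        return self.models[self.chosen[criterion]]


def select_mixture(
    x,
    y,
    k_range: Iterable[int] = range(1, 6),
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SelectionReport:
    """Fit mixtures across ``k_range`` and choose K by each criterion."""
    rows = []
    models: dict[int, MixtureDischargeModel] = {}
    n = len(np.asarray(x))
    for K in k_range:
        m = em_fit_mixture(x, y, K, seed=seed + K, n_restarts=n_restarts,
                           tol=tol, max_iter=max_iter)
        crit = information_criteria(m.loglik, K, n)
        rows.append({"K": K, "k_free": 4 * K - 1, "loglik": m.loglik, **crit})
        models[K] = m
    table = pd.DataFrame(rows)
    chosen = {c: int(table.loc[table[c].idxmin(), "K"]) for c in ("aic", "aic3", "bic", "mdl")}
    return SelectionReport(table=table, chosen=chosen, models=models)


# ---------------------------------------------------------------------------
# prediction and cross-validation


def predict_discharge(
    model,
    capacity,
    purpose=None,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    dwt=None,
    frame: pd.DataFrame | None = None,
):
    """Predict discharge volume (m^3) from a fitted model.

    ``mode="expected"`` returns ``(mean, variance)`` with the mean truncated
    below at 0 and, when ``dwt`` is supplied, capped at ``1.2 * DWT`` (the
    curation feasibility bound); the variance follows the mixture law of
    total variance (or ``sigma^2`` for a linear model).  ``mode="sample"``
    draws a component then Gaussian noise, with the same truncation.

    For linear models with categorical predictors beyond purpose, pass the
    full covariate ``frame``; otherwise ``capacity`` and ``purpose`` suffice.
    """
    capacity = np.atleast_1d(np.asarray(capacity, dtype=float))
    if np.any(capacity < 0):
        raise ValueError("capacity must be non-negative")
    cap_hi = None if dwt is None else 1.2 * np.atleast_1d(np.asarray(dwt, dtype=float))

    if isinstance(model, MixtureDischargeModel):
        if mode == "expected":
            mean = model.predict_mean(capacity)
            var = model.predict_variance(capacity)
        elif mode == "sample":
            if rng is None:
                rng = np.random.default_rng()
            comp = rng.choice(model.K, size=len(capacity), p=list(model.weights))
            mu = np.asarray(model.intercepts)[comp] + np.asarray(model.slopes)[comp] * capacity
            draw = mu + rng.normal(0.0, np.asarray(model.sigmas)[comp])
            out = np.clip(draw, 0.0, cap_hi) if cap_hi is not None else np.maximum(draw, 0.0)
            return out
        else:
            raise ValueError("mode must be 'expected' or 'sample'")
    elif isinstance(model, LinearDischargeModel):
        if frame is None:
            frame = pd.DataFrame({"capacity": capacity})
            if purpose is not None:
                frame["purpose"] = np.broadcast_to(np.asarray(purpose, dtype=object),
                                                   capacity.shape)
        mean = model.predict_mean(frame)
        var = np.full_like(mean, model.sigma**2)
        if mode == "sample":
            if rng is None:
                rng = np.random.default_rng()
            draw = mean + rng.normal(0.0, model.sigma, size=len(mean))
            return np.clip(draw, 0.0, cap_hi) if cap_hi is not None else np.maximum(draw, 0.0)
        if mode != "expected":
            raise ValueError("mode must be 'expected' or 'sample'")
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    mean = np.clip(mean, 0.0, cap_hi) if cap_hi is not None else np.maximum(mean, 0.0)
    return mean, var


@dataclass
class CVResult:
    """Repeated random-subsampling cross-validation summary."""

    per_repeat: pd.DataFrame
    r2_mean: float
    r2_sd: float
    total_error_mean: float
    total_error_sd: float
    abs_total_error_mean: float


def cross_validate(
    model_spec: tuple,
    voyages: pd.DataFrame,
    train_fraction: float = 0.7,
    n_repeats: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Repeated random-subsampling CV of a discharge model.

    ``model_spec`` is ``("linear", predictor_set)`` or ``("mixture", K)``.
    Each repeat fits on a random ``train_fraction`` split and scores held-out
    R^2 and total-discharge error (predicted minus true); mixture predictions
    use the predictive mean.  Identical seeds give identical splits.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(voyages)
    n_train = int(round(train_fraction * n))
    if n_train in (0, n):
        raise ValueError("split leaves an empty train or test set")
    kind, arg = model_spec
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        train = voyages.iloc[perm[:n_train]]
        test = voyages.iloc[perm[n_train:]]
        y_test = _column(test, "discharge").to_numpy(float)
        if kind == "linear":
            m = fit_linear(train, arg)
            pred = np.maximum(m.predict_mean(test), 0.0)
        elif kind == "mixture":
            m = em_fit_mixture(
                _column(train, "capacity").to_numpy(float),
                _column(train, "discharge").to_numpy(float),
                K=arg,
                seed=int(rng.integers(2**31)),
                **fit_kwargs,
            )
            pred, _ = predict_discharge(m, _column(test, "capacity").to_numpy(float))
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        ss_res = float(((y_test - pred) ** 2).sum())
        ss_tot = float(((y_test - y_test.mean()) ** 2).sum())
        rows.append(
            {
                "repeat": rep,
                "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
                "total_error": float(pred.sum() - y_test.sum()),
            }
        )
    per = pd.DataFrame(rows)
    return CVResult(
        per_repeat=per,
        r2_mean=float(per["r2"].mean()),
        r2_sd=float(per["r2"].std(ddof=1)) if n_repeats > 1 else 0.0,
        total_error_mean=float(per["total_error"].mean()),
        total_error_sd=float(per["total_error"].std(ddof=1)) if n_repeats > 1 else 0.0,
        abs_total_error_mean=float(per["total_error"].abs().mean()),
    )


# ---------------------------------------------------------------------------
# serialisation

_SCHEMA_VERSION = 1


def model_to_json(model) -> dict:
    """Serialise a fitted model to a JSON-compatible document."""
    if isinstance(model, MixtureDischargeModel):
        return {
            "version": _SCHEMA_VERSION,
            "type": "mixture",
            "K": model.K,
            "weights": list(model.weights),
            "intercepts": list(model.intercepts),
            "slopes": list(model.slopes),
            "sigmas": list(model.sigmas),
            "loglik": model.loglik,
            "n": model.n,
        }
    if isinstance(model, LinearDischargeModel):
        return {
            "version": _SCHEMA_VERSION,
            "type": "linear",
            "predictor_set": list(model.predictor_set),
            "coefficients": model.coefficients,
            "sigma": model.sigma,
            "n": model.n,
            "loglik": model.loglik,
            "bic": model.bic,
            "levels": model.levels,
        }
    raise TypeError(f"unsupported model type {type(model).__name__}")


def model_from_json(doc: dict):
    if doc.get("version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {doc.get('version')!r}")
    if doc["type"] == "mixture":
        return MixtureDischargeModel(
            K=int(doc["K"]),
            weights=tuple(doc["weights"]),
            intercepts=tuple(doc["intercepts"]),
            slopes=tuple(doc["slopes"]),
            sigmas=tuple(doc["sigmas"]),
            loglik=float(doc["loglik"]),
            n=int(doc["n"]),
        )
    if doc["type"] == "linear":
        return LinearDischargeModel(
            predictor_set=tuple(doc["predictor_set"]),
            coefficients=dict(doc["coefficients"]),
            sigma=float(doc["sigma"]),
            n=int(doc["n"]),
            loglik=float(doc["loglik"]),
            bic=float(doc["bic"]),
            levels={k: list(v) for k, v in doc.get("levels", {}).items()},
        )
    raise ValueError(f"unknown model type {doc['type']!r}")
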