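"""PLS1 regression and the randomized leave-k-out validation protocol.

A single physicochemical response (melting point, degC) is regressed on the
preprocessed spectra with NIPALS PLS1 (X and y deflation). Validation draws
random k-subsets as test sets over many iterations; prediction errors are
aggregated per sample into the mean absolute error e_hat, the mean relative
error e_hat_R (percent), and the extreme errors e_alpha (max) and e_omega
(min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidStateError

ComponentRule = int | Literal["auto"]


@dataclass
class PlsModel:
    """A fitted NIPALS PLS1 model with per-component deflation history."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, A)
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    x_scores: np.ndarray     # (n, A)
    regression_coefficients: np.ndarray  # (p,)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict y for new rows, optionally truncated to fewer components."""
        Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        if n_components is None or n_components == self.n_components:
            b = self.regression_coefficients
        else:
            b = self.coefficients_for(n_components)
        return self.y_mean + Xc @ b

    def coefficients_for(self, a: int) -> np.ndarray:
        """Regression coefficients using only the first ``a`` components."""
        if not 1 <= a <= self.n_components:
            raise InvalidArgumentError(f"a must be in [1, {self.n_components}]")
        W = self.weights[:, :a]
        P = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)


@dataclass
class PredictionReport:
    """Per-sample leave-k-out error statistics.

    ``per_sample`` is indexed by sample id with columns ``e_hat`` (mean
    absolute error, units of y), ``e_hat_R`` (mean relative error, percent),
    ``e_alpha`` (max absolute error), ``e_omega`` (min absolute error) and
    ``times_held_out``.
    """

    per_sample: pd.DataFrame
    mean_relative_error: float
    k: int
    iterations: int
    seed: int
    iteration_log: pd.DataFrame | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "protocol": {"k": self.k, "iterations": self.iterations, "seed": self.seed},
            "global_mean_relative_error_pct": self.mean_relative_error,
            "per_sample": self.per_sample.reset_index().to_dict(orient="records"),
        }


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """NIPALS PLS1 with X- and y-deflation.

    Each component takes the weight vector w = X'y / |X'y| of the deflated
    data, scores t = Xw, loadings p = X't/t't and q = y't/t't, then deflates
    X := X - t p' and y := y - t q. The compact regression coefficients
    b = W (P'W)^-1 q reproduce the deflation-path training fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise InvalidArgumentError("X and y sample counts differ")
    if not 1 <= n_components <= min(n - 1, p):
        raise InvalidArgumentError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    if np.std(y) == 0.0:
        raise InvalidArgumentError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0.0:
            # residual y is orthogonal to residual X; stop extracting
            W = W[:, :a]
            P = P[:, :a]
            q = q[:a]
            T = T[:, :a]
            n_components = a
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        p_vec = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_vec)
        yd = yd - t * q_a
        W[:, a], P[:, a], q[a], T[:, a] = w, p_vec, q_a, t

    if n_components == 0:
        raise InvalidArgumentError("could not extract any PLS component")
    b = W @ np.linalg.solve(P.T @ W, q)
    return PlsModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        regression_coefficients=b,
    )


def _train_mre_by_components(model: PlsModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Training mean relative error (percent) for 1..A components, incrementally."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.full(y.size, model.y_mean)
    mre = np.empty(model.n_components)
    for a in range(model.n_components):
        yhat = yhat + model.x_scores[:, a] * model.y_loadings[a]
        mre[a] = float(np.mean(np.abs(yhat - y) / np.abs(y))) * 100.0
    return mre


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    target_train_mre: float = 10.0,
) -> int:
    """Smallest component count whose training MRE is at or below the target.

    The stopping rule guards against over-fitting: the model keeps only as
    many latent components as needed to reach roughly the target mean
    relative error (percent) on the training set itself; if no count up to
    ``max_components`` qualifies, ``max_components`` is returned.
    """
    if max_components < 1:
        raise InvalidArgumentError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    cap = min(max_components, min(X.shape[0] - 1, X.shape[1]))
    model = pls_fit(X, y, cap)
    mre = _train_mre_by_components(model, X, y)
    hits = np.nonzero(mre <= target_train_mre)[0]
    if hits.size:
        return int(hits[0]) + 1
    return max_components


def leave_k_out(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    iterations: int,
    seed: int,
    selection: ComponentRule = "auto",
    max_components: int = 10,
    target_train_mre: float = 10.0,
    sample_ids: list[str] | None = None,
    log_iterations: bool = False,
) -> PredictionReport:
    """Randomized leave-k-out PLS validation.

    Each iteration draws a uniform random k-subset (without replacement
    within the iteration; subsets may repeat across iterations) as the test
    set, fits PLS1 on the remaining samples — with the component count fixed
    (integer ``selection``) or chosen by the training-error rule
    (``selection="auto"``) — and predicts the held-out samples. Statistics
    aggregate per sample over all iterations in which it was held out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if not 1 <= k < n:
        raise InvalidArgumentError("k must satisfy 1 <= k < n_samples")
    if iterations < 1:
        raise InvalidArgumentError("iterations must be >= 1")
    ids = sample_ids if sample_ids is not None else [f"S{i + 1:02d}" for i in range(n)]

    rng = np.random.default_rng(seed)
    abs_errors: list[list[float]] = [[] for _ in range(n)]
    rel_errors: list[list[float]] = [[] for _ in range(n)]
    log_rows: list[dict[str, Any]] = []

    for it in range(iterations):
        test_idx = rng.choice(n, size=k, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        X_tr, y_tr = X[mask], y[mask]
        if selection == "auto":
            a = select_components(X_tr, y_tr, max_components, target_train_mre)
        else:
            a = min(int(selection), min(X_tr.shape[0] - 1, X_tr.shape[1]))
        model = pls_fit(X_tr, y_tr, a)
        y_hat = model.predict(X[test_idx])
        err = np.abs(y_hat - y[test_idx])
        rel = err / np.abs(y[test_idx]) * 100.0
        for j, idx in enumerate(test_idx):
            abs_errors[idx].append(float(err[j]))
            rel_errors[idx].append(float(rel[j]))
        if log_iterations:
            log_rows.append(
                {
                    "iteration": it,
                    "test_indices": tuple(int(i) for i in test_idx),
                    "abs_errors": tuple(float(e) for e in err),
                    "rel_errors": tuple(float(e) for e in rel),
                    "n_components": a,
                }
            )

    rows = []
    for i in range(n):
        ae = np.asarray(abs_errors[i])
        re = np.asarray(rel_errors[i])
        if ae.size:
            rows.append(
                {
                    "sample_id": ids[i],
                    "e_hat": float(ae.mean()),
                    "e_hat_R": float(re.mean()),
                    "e_alpha": float(ae.max()),
                    "e_omega": float(ae.min()),
                    "times_held_out": int(ae.size),
                }
            )
        else:
            rows.append(
                {
                    "sample_id": ids[i],
                    "e_hat": np.nan,
                    "e_hat_R": np.nan,
                    "e_alpha": np.nan,
                    "e_omega": np.nan,
                    "times_held_out": 0,
                }
            )
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    global_mre = float(per_sample["e_hat_R"].mean(skipna=True))
    log_df = pd.DataFrame(log_rows) if log_iterations else None
    return PredictionReport(
        per_sample=per_sample,
        mean_relative_error=global_mre,
        k=k,
        iterations=iterations,
        seed=seed,
        iteration_log=log_df,
    )


def training_set_influence(report: PredictionReport) -> pd.DataFrame:
    """Rank samples by the test error their presence in the training set induces.

    For each sample s, compares the mean relative test error of iterations
    whose training set contains s against iterations where s itself was held
    out. In the held-out case s's own prediction error is excluded from the
    iteration mean, so the ratio reflects s's influence purely as a training
    member. Returns a DataFrame sorted by ``ratio`` descending.
    """
    if report.iteration_log is None:
        raise InvalidStateError("leave_k_out must be run with log_iterations=True")
    ids = list(report.per_sample.index)
    n = len(ids)
    in_train: list[list[float]] = [[] for _ in range(n)]
    out_train: list[list[float]] = [[] for _ in range(n)]
    for row in report.iteration_log.itertuples(index=False):
        test = set(row.test_indices)
        rels = np.asarray(row.rel_errors)
        mean_all = float(rels.mean())
        for s in range(n):
            if s in test:
                others = [
                    r for i, r in zip(row.test_indices, row.rel_errors) if i != s
                ]
                if others:
                    out_train[s].append(float(np.mean(others)))
            else:
                in_train[s].append(mean_all)
    rows = []
    for s in range(n):
        m_in = float(np.mean(in_train[s])) if in_train[s] else np.nan
        m_out = float(np.mean(out_train[s])) if out_train[s] else np.nan
        ratio = m_in / m_out if (m_out and not np.isnan(m_out)) else np.nan
        rows.append(
            {
                "sample_id": ids[s],
                "mre_with_sample_in_training": m_in,
                "mre_with_sample_excluded": m_out,
                "ratio": ratio,
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    return df.sort_values("ratio", ascending=False)
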