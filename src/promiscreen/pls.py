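"""Partial least squares (NIPALS) fitting of the pairwise-coupling model.

The activity of a library variant is modelled as

    A^k(delta) = const^k + sum_i delta_i p_i^k + sum_{i<j} delta_ij p_ij^k

with binary mutation indicators delta_i, main-effect coefficients p_i^k and
pairwise coupling coefficients p_ij^k for each objective k.  With M = 10
mutations and two objectives this has 110 coefficients, typically far more
than the number of measured variants, so the fit is regularized by partial
least squares: latent vectors (orthogonal combinations of the predictor
columns chosen to maximize covariance with the responses) are extracted by
the NIPALS algorithm and the number retained is chosen by leave-one-out
cross-validation.

Conventions
-----------
* Responses (log10 activities) are auto-scaled per objective: mean
  subtraction followed by division by the standard deviation.
* Predictors are mean-centered but *not* variance-scaled: they are binary
  indicators, and variance scaling would overweight rare pair columns.
* The model as written has no intercept; mean-centering supplies one
  implicitly, and the back-transformed model reports it explicitly.
* By default one joint multi-response model covers all objectives; a
  per-objective mode fits each response separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import ActivityTable
from .genotypes import as_genotype, design_matrix

_EPS = 1e-14


class DegenerateScalingError(ValueError):
    """A response has zero variance; auto-scaling is undefined."""


class InsufficientDataError(ValueError):
    """Too few rows to fit and cross-validate."""


def _nipals(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract NIPALS latent vectors from centered X and scaled Y.

    Returns weights W (p, L), X-loadings P (p, L) and Y-loadings C (K, L),
    with L <= n_components (extraction stops early once the residual
    covariance is exhausted).
    """
    X = X.copy()
    Y = Y.copy()
    n, p = X.shape
    k = Y.shape[1]
    ws, ps, cs = [], [], []
    for _ in range(n_components):
        # start from the response column with the largest remaining variance
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
        if u @ u < _EPS:
            break
        w = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw < _EPS:
                w = None
                break
            w /= nw
            t = X @ w
            tt = t @ t
            if tt < _EPS:
                w = None
                break
            q = Y.T @ t
            nq = np.linalg.norm(q)
            if nq < _EPS:
                break  # X structure left but no Y covariance: accept w
            q /= nq
            u_new = Y @ q
            if np.linalg.norm(u_new - u) <= tol * max(1.0, np.linalg.norm(u_new)):
                u = u_new
                break
            u = u_new
        if w is None:
            break
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_l = X.T @ t / tt
        c_l = Y.T @ t / tt
        X -= np.outer(t, p_l)
        Y -= np.outer(t, c_l)
        ws.append(w)
        ps.append(p_l)
        cs.append(c_l)
    if not ws:
        return np.zeros((p, 0)), np.zeros((p, 0)), np.zeros((k, 0))
    return np.column_stack(ws), np.column_stack(ps), np.column_stack(cs)


def _coefficient_path(
    W: np.ndarray, P: np.ndarray, C: np.ndarray
) -> list[np.ndarray]:
    """Regression coefficients B_L = W (P'W)^-1 C' for every L = 1..L_max.

    Uses the rotation recursion (P'W is unit upper triangular for NIPALS
    components), giving the whole nested coefficient path in one pass.
    """
    p, n_lv = W.shape
    k = C.shape[0]
    R = np.zeros((p, n_lv))
    B = np.zeros((p, k))
    path = []
    for l in range(n_lv):
        r = W[:, l] - R[:, :l] @ (P[:, :l].T @ W[:, l])
        R[:, l] = r
        B = B + np.outer(r, C[:, l])
        path.append(B.copy())
    return path


@dataclass
class PlsModel:
    """A fitted PLS model of the pairwise-coupling activity equation.

    ``coef`` holds the back-transformed coefficients on the original
    log-activity scale, one column per objective: M main effects p_i^k
    followed by the M(M-1)/2 pair couplings p_ij^k (lexicographic order)
    when the pairwise design is used.  ``cv_curve`` is the mean leave-one-
    out squared error (auto-scaled response units, averaged over
    objectives) at each candidate latent-variable count.
    """

    m: int
    objectives: list
    include_pairs: bool
    n_components: int
    coef: np.ndarray  # (p, K) original scale
    intercept: np.ndarray  # (K,)
    x_mean: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    cv_curve: np.ndarray
    weights: np.ndarray = field(default=None, repr=False)
    x_loadings: np.ndarray = field(default=None, repr=False)
    y_loadings: np.ndarray = field(default=None, repr=False)
    training_genotypes: list = field(default_factory=list, repr=False)

    @property
    def n_coefficients(self) -> int:
        return self.coef.size

    def main_effects(self) -> np.ndarray:
        """(M, K) main-effect coefficients p_i^k."""
        return self.coef[: self.m]

    def pair_couplings(self) -> np.ndarray:
        """(M(M-1)/2, K) pairwise coupling coefficients p_ij^k."""
        if not self.include_pairs:
            raise ValueError("model was fitted without pair columns")
        return self.coef[self.m :]

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "objectives": list(self.objectives),
            "include_pairs": self.include_pairs,
            "n_components": int(self.n_components),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_sd": self.y_sd.tolist(),
            "cv_curve": self.cv_curve.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        return cls(
            m=d["m"],
            objectives=list(d["objectives"]),
            include_pairs=d["include_pairs"],
            n_components=int(d["n_components"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            y_sd=np.asarray(d["y_sd"], dtype=float),
            cv_curve=np.asarray(d["cv_curve"], dtype=float),
        )


def autoscale(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-subtract and divide by the (ddof=1) standard deviation."""
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    if np.any(sd < _EPS):
        raise DegenerateScalingError("a response has zero variance")
    return (y - mean) / sd, mean, sd


def _fit_scaled(
    X: np.ndarray, Y: np.ndarray, max_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center X, autoscale Y, run NIPALS; return pieces for prediction."""
    x_mean = X.mean(axis=0)
    ys, y_mean, y_sd = autoscale(Y)
    W, P, C = _nipals(X - x_mean, ys, max_lv)
    return W, P, C, x_mean, (y_mean, y_sd)


def _loo_groups(genotypes: list) -> list[np.ndarray]:
    """Row-index groups for leave-one-genotype-out cross-validation.

    Rows sharing a genotype (bootstrap duplicates) are left out together to
    avoid leakage.
    """
    seen: dict = {}
    for i, g in enumerate(genotypes):
        seen.setdefault(g, []).append(i)
    return [np.array(v) for v in seen.values()]


def pls_fit(
    table: ActivityTable,
    max_lv: int | None = None,
    cv: str = "loo",
    include_pairs: bool = True,
    joint: bool = True,
    n_components: int | None = None,
) -> PlsModel:
    """Fit the pairwise-coupling model by NIPALS PLS with LOO-CV.

    The latent-variable count minimizing the mean leave-one-out squared
    prediction error (auto-scaled response units, averaged over objectives)
    is retained; coefficients are back-transformed to the original log10
    activity scale.  ``joint=False`` fits each objective independently and
    keeps its own optimal latent count per objective.  Passing
    ``n_components`` fixes the latent-variable count and skips the
    cross-validation.
    """
    if cv != "loo":
        raise ValueError("only leave-one-out cross-validation is supported")
    n = len(table)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 rows, got {n}")
    genotypes = list(table.genotypes)
    X = design_matrix(genotypes, include_pairs=include_pairs)
    Y = table.values()
    p = X.shape[1]

    if not joint:
        subs = []
        for k, obj in enumerate(table.objectives):
            sub_table = ActivityTable(
                genotypes=genotypes,
                activities=table.activities[[obj]].reset_index(drop=True),
                objectives=[obj],
            )
            subs.append(
                pls_fit(sub_table, max_lv=max_lv, include_pairs=include_pairs)
            )
        max_curve = max(len(s.cv_curve) for s in subs)
        curve = np.full((max_curve,), np.nan)
        return PlsModel(
            m=table.m,
            objectives=list(table.objectives),
            include_pairs=include_pairs,
            n_components=max(s.n_components for s in subs),
            coef=np.column_stack([s.coef[:, 0] for s in subs]),
            intercept=np.array([s.intercept[0] for s in subs]),
            x_mean=subs[0].x_mean,
            y_mean=np.array([s.y_mean[0] for s in subs]),
            y_sd=np.array([s.y_sd[0] for s in subs]),
            cv_curve=curve,
            training_genotypes=genotypes,
        )

    groups = _loo_groups(genotypes)
    if max_lv is None:
        max_lv = min(n - 2, 15)
    max_lv = max(1, min(max_lv, n - 1, p))

    if n_components is not None:
        n_fixed = max(1, min(int(n_components), n - 1, p))
        W, P, C, x_mean, (y_mean, y_sd) = _fit_scaled(X, Y, n_fixed)
        n_comp = min(n_fixed, W.shape[1])
        path = _coefficient_path(W[:, :n_comp], P[:, :n_comp], C[:, :n_comp])
        b_scaled = path[-1] if path else np.zeros((p, Y.shape[1]))
        coef = b_scaled * y_sd
        return PlsModel(
            m=table.m,
            objectives=list(table.objectives),
            include_pairs=include_pairs,
            n_components=n_comp,
            coef=coef,
            intercept=y_mean - x_mean @ coef,
            x_mean=x_mean,
            y_mean=y_mean,
            y_sd=y_sd,
            cv_curve=np.full(n_comp, np.nan),
            weights=W[:, :n_comp],
            x_loadings=P[:, :n_comp],
            y_loadings=C[:, :n_comp],
            training_genotypes=genotypes,
        )

    # leave-one-genotype-out CV over the nested component path
    press = np.zeros(max_lv)
    counts = np.zeros(max_lv)
    _, y_mean_all, y_sd_all = autoscale(Y)
    for grp in groups:
        mask = np.ones(n, dtype=bool)
        mask[grp] = False
        if mask.sum() < 2:
            continue
        try:
            W, P, C, x_mean, (y_mean, y_sd) = _fit_scaled(
                X[mask], Y[mask], max_lv
            )
        except DegenerateScalingError:
            continue
        path = _coefficient_path(W, P, C)
        xc = X[grp] - x_mean
        y_true_scaled = (Y[grp] - y_mean_all) / y_sd_all
        for l, B in enumerate(path):
            pred = xc @ B * y_sd + y_mean  # original scale
            pred_scaled = (pred - y_mean_all) / y_sd_all
            press[l] += ((pred_scaled - y_true_scaled) ** 2).sum()
            counts[l] += grp.size
        # components beyond the fold's path reuse its last coefficients
        for l in range(len(path), max_lv):
            if path:
                pred = xc @ path[-1] * y_sd + y_mean
                pred_scaled = (pred - y_mean_all) / y_sd_all
                press[l] += ((pred_scaled - y_true_scaled) ** 2).sum()
                counts[l] += grp.size
    valid = counts > 0
    cv_curve = np.full(max_lv, np.inf)
    cv_curve[valid] = press[valid] / (counts[valid] * Y.shape[1])
    best_l = int(np.argmin(cv_curve)) + 1

    W, P, C, x_mean, (y_mean, y_sd) = _fit_scaled(X, Y, max_lv)
    n_comp = min(best_l, W.shape[1])
    path = _coefficient_path(W[:, :n_comp], P[:, :n_comp], C[:, :n_comp])
    b_scaled = path[-1] if path else np.zeros((p, Y.shape[1]))
    coef = b_scaled * y_sd  # back to original response scale
    intercept = y_mean - x_mean @ coef
    return PlsModel(
        m=table.m,
        objectives=list(table.objectives),
        include_pairs=include_pairs,
        n_components=n_comp,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        y_sd=y_sd,
        cv_curve=cv_curve,
        weights=W[:, :n_comp],
        x_loadings=P[:, :n_comp],
        y_loadings=C[:, :n_comp],
        training_genotypes=genotypes,
    )


def pls_predict(model: PlsModel, genotypes) -> np.ndarray:
    """Predict log10 activities for genotypes; (n, K) on the original scale."""
    gts = [as_genotype(g) for g in genotypes]
    if any(len(g) != model.m for g in gts):
        raise ValueError(f"genotype length must be {model.m}")
    X = design_matrix(gts, include_pairs=model.include_pairs)
    return X @ model.coef + model.intercept
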