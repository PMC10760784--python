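"""Sparse linear modeling of pri-miRNA expression.

The model for one pri-miRNA is the L1-penalized least-squares problem

    minimize_w  sum_i (y_i - sum_j x_ij w_j)^2 + alpha * sum_j |w_j|

where y is the pri-miRNA expression across samples, the columns of X are
mRNA expression profiles, and both sides have been standardized to mean 0
and standard deviation 1.  Note the objective carries *no* 1/(2n) factor:
penalties from conventions that include one map via

    alpha_here = 2 * n_samples * alpha_scaled.

The solver is cyclic coordinate descent with soft-thresholding, run on the
Gram matrix so each coordinate update is O(m).  The mRNAs left with a
nonzero coefficient are the pri-miRNA's "associated mRNAs".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AssociatedGeneSet,
    ConfigError,
    ExpressionMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def soft_threshold(z: float, lam: float) -> float:
    """S(z, lam) = sign(z) * max(|z| - lam, 0)."""
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


class LassoCD:
    """Cyclic coordinate-descent solver for the unnormalized LASSO objective.

    Parameters
    ----------
    alpha : float
        L1 penalty weight on the scale of the objective above (no sample-size
        normalization).
    tol : float
        Convergence tolerance: iteration stops once both the largest
        coefficient change in a sweep and the largest KKT violation
        |x_j'(y - Xw)| - alpha/2 (zero coefficients) /
        |x_j'(y - Xw) - (alpha/2) sign(w_j)| (active coefficients)
        fall below ``tol``.
    max_sweeps : int
        Hard cap on full coordinate sweeps.

    Fitted attributes
    -----------------
    coef_ : (m,) coefficient vector
    n_sweeps_ : sweeps actually run
    converged_ : whether the tolerance was met
    objective_ : final objective value
    objective_path_ : objective after each sweep (non-increasing)
    kkt_violation_ : largest KKT residual at the solution
    """

    def __init__(self, alpha: float = 1.0, tol: float = 1e-6,
                 max_sweeps: int = 1000):
        self.alpha = alpha
        self.tol = tol
        self.max_sweeps = max_sweeps

    # -- sklearn-style plumbing ------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "tol": self.tol,
                "max_sweeps": self.max_sweeps}

    def set_params(self, **params) -> "LassoCD":
        for key, value in params.items():
            if key not in ("alpha", "tol", "max_sweeps"):
                raise ConfigError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, coef_init=None) -> "LassoCD":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        n, m = X.shape
        if y.shape != (n,):
            raise ValidationError(f"y has shape {y.shape}, expected ({n},)")
        if n < 2:
            raise ValidationError("need at least 2 samples")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValidationError("non-finite values in X or y")
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")

        G = X.T @ X
        b = X.T @ y
        yy = float(y @ y)
        diag = np.diag(G).copy()
        half_alpha = self.alpha / 2.0

        w = np.zeros(m) if coef_init is None else np.array(coef_init, dtype=float)
        if w.shape != (m,):
            raise ValidationError("coef_init has wrong length")
        Gw = G @ w

        path: list[float] = []
        converged = False
        sweeps = 0
        for sweeps in range(1, self.max_sweeps + 1):
            max_delta = 0.0
            for j in range(m):
                if diag[j] <= 0.0:
                    continue  # zero-variance column: coefficient stays 0
                cj = b[j] - Gw[j] + diag[j] * w[j]
                wj_new = soft_threshold(cj, half_alpha) / diag[j]
                delta = wj_new - w[j]
                if delta != 0.0:
                    Gw += G[:, j] * delta
                    w[j] = wj_new
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            path.append(yy - 2.0 * (b @ w) + float(w @ Gw)
                        + self.alpha * np.abs(w).sum())
            kkt = self._kkt_violation(b - Gw, w, half_alpha, diag)
            if max_delta < self.tol and kkt <= self.tol:
                converged = True
                break

        if not converged:
            logger.warning(
                "coordinate descent did not converge in %d sweeps "
                "(last coefficient change tolerance %.3g)",
                self.max_sweeps, self.tol,
            )
        self.coef_ = w
        self.n_features_in_ = m
        self.n_sweeps_ = sweeps
        self.converged_ = converged
        self.objective_path_ = np.array(path)
        self.objective_ = path[-1] if path else yy
        self.kkt_violation_ = self._kkt_violation(b - G @ w, w, half_alpha, diag)
        return self

    @staticmethod
    def _kkt_violation(c: np.ndarray, w: np.ndarray, half_alpha: float,
                       diag: np.ndarray) -> float:
        """Largest violation of the subgradient optimality conditions."""
        live = diag > 0.0
        zero = (w == 0.0) & live
        active = (w != 0.0) & live
        viol = 0.0
        if zero.any():
            viol = max(viol, float(np.max(np.abs(c[zero]) - half_alpha, initial=0.0)))
        if active.any():
            viol = max(viol, float(np.max(
                np.abs(c[active] - half_alpha * np.sign(w[active])))))
        return max(viol, 0.0)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features, model was fit with "
                f"{self.n_features_in_}"
            )
        return X @ self.coef_


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class Standardizer:
    """Column-wise standardization (mean 0, sd 1, population sd, divisor n).

    Zero-variance columns cannot be standardized; they are dropped from the
    transformed output and recorded in ``dropped_``.
    """

    def fit(self, A) -> "Standardizer":
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] < 2:
            raise ValidationError("need a 2-d array with >= 2 rows")
        self.mean_ = A.mean(axis=0)
        self.scale_ = A.std(axis=0)  # ddof=0
        self.kept_ = self.scale_ > 0.0
        self.dropped_ = np.flatnonzero(~self.kept_)
        self.n_features_in_ = A.shape[1]
        if not self.kept_.any():
            raise ValidationError("all features have zero variance")
        if len(self.dropped_):
            logger.warning("dropping %d zero-variance feature(s)",
                           len(self.dropped_))
        return self

    def transform(self, A) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.shape[1] != self.n_features_in_:
            raise ValidationError("feature count mismatch in transform")
        return (A[:, self.kept_] - self.mean_[self.kept_]) / self.scale_[self.kept_]

    def fit_transform(self, A) -> np.ndarray:
        return self.fit(A).transform(A)


@dataclass
class StandardizationParams:
    """Per-gene training mean/sd plus the ids of dropped constant genes."""

    means: dict[str, float]
    sds: dict[str, float]
    dropped: list[str] = field(default_factory=list)


def standardize(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, StandardizationParams]:
    """Standardize each gene (row) to mean 0, sd 1 (population sd).

    Constant rows are dropped (logged and recorded in the returned params);
    an all-constant matrix raises.
    """
    if expr.shape[1] < 2:
        raise ValidationError("standardization needs at least 2 samples")
    values = expr.values
    means = values.mean(axis=1)
    sds = values.std(axis=1)
    kept = sds > 0.0
    if not kept.any():
        raise ValidationError("all genes have zero variance")
    dropped = [g for g, k in zip(expr.gene_ids, kept) if not k]
    if dropped:
        logger.warning("standardize: dropping %d constant gene(s)", len(dropped))
    data = expr.data.loc[kept].sub(means[kept], axis=0).div(sds[kept], axis=0)
    params = StandardizationParams(
        means={g: float(mu) for g, mu in zip(expr.gene_ids, means)},
        sds={g: float(sd) for g, sd in zip(expr.gene_ids, sds)},
        dropped=dropped,
    )
    return ExpressionMatrix(data, transform="standardized"), params


# ---------------------------------------------------------------------------
# Penalty selection
# ---------------------------------------------------------------------------

def default_alpha_grid(X, y, n_alphas: int = 16, eps: float = 1e-4) -> np.ndarray:
    """Logarithmic grid on [alpha_max * eps, alpha_max].

    alpha_max = 2 * max_j |x_j' y| is the smallest penalty for which the
    all-zero coefficient vector is optimal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha_max = 2.0 * float(np.max(np.abs(X.T @ y)))
    if alpha_max <= 0.0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max * eps), np.log10(alpha_max), n_alphas)


def lasso_path(X, y, alphas, tol: float = 1e-6,
               max_sweeps: int = 1000) -> dict[float, np.ndarray]:
    """Warm-started coefficient path over a descending alpha sequence."""
    alphas = sorted(np.asarray(alphas, dtype=float), reverse=True)
    coefs: dict[float, np.ndarray] = {}
    w = None
    for a in alphas:
        est = LassoCD(alpha=a, tol=tol, max_sweeps=max_sweeps).fit(X, y, coef_init=w)
        w = est.coef_.copy()
        coefs[a] = w
    return coefs


def select_alpha(X, y, grid, k_folds: int = 5, seed: int = 0,
                 tol: float = 1e-6, max_sweeps: int = 1000,
                 rule: str = "min", cv_slack: float = 1.5) -> float:
    """Pick a penalty from the grid by k-fold cross-validation.

    rule="min" returns the grid alpha minimizing mean CV squared prediction
    error, ties broken toward the larger alpha (the sparser model).
    rule="sparse" returns the largest alpha whose mean CV error is within
    ``cv_slack`` times the minimum; prediction-optimal penalties overselect
    predictors, so support identification trades a bounded CV-error increase
    for a much sparser model.  The fold assignment is a seeded permutation
    split into k contiguous blocks, so the choice is deterministic given the
    seed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("alpha grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ConfigError("alpha grid must be sorted ascending")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k_folds > n:
        raise ConfigError(f"k_folds={k_folds} exceeds n={n}")
    if k_folds < 2:
        raise ConfigError("k_folds must be >= 2")
    if rule not in ("min", "sparse"):
        raise ConfigError(f"unknown alpha selection rule {rule!r}")
    if cv_slack < 1.0:
        raise ConfigError("cv_slack must be >= 1")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)

    errs = np.zeros(grid.size)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te, y_te = X[test_idx], y[test_idx]
        coefs = lasso_path(X_tr, y_tr, grid, tol=tol, max_sweeps=max_sweeps)
        for i, a in enumerate(grid):
            resid = y_te - X_te @ coefs[a]
            errs[i] += float(resid @ resid) / len(test_idx)
    errs /= k_folds

    best = errs.min()
    ceiling = best if rule == "min" else cv_slack * best
    # scan from the largest alpha down; first within the ceiling wins
    for i in range(grid.size - 1, -1, -1):
        if errs[i] <= ceiling:
            return float(grid[i])
    return float(grid[-1])  # pragma: no cover


# ---------------------------------------------------------------------------
# Per-pri-miRNA model wrapper
# ---------------------------------------------------------------------------

@dataclass
class LassoModel:
    """A fitted sparse model for one pri-miRNA.

    Coefficients live on the standardized scale; ``x_standardizer`` together
    with ``y_mean``/``y_sd`` let predictions be mapped back to the original
    expression scale.
    """

    pri_mirna_id: str
    gene_ids: list[str]          # predictors retained after standardization
    coef: np.ndarray             # same order as gene_ids
    alpha: float
    n_sweeps: int
    converged: bool
    objective: float
    kkt_violation: float
    x_standardizer: Standardizer
    y_mean: float
    y_sd: float


def fit_pri_mirna(pri_mirna_id: str, X, gene_ids, y, alpha: float,
                  tol: float = 1e-6, max_sweeps: int = 1000) -> LassoModel:
    """Standardize (X columns and y) on the given data, then solve the LASSO.

    X is samples x genes on the observation scale; y is the pri-miRNA's
    expression over the same samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y disagree on the number of samples")
    if len(gene_ids) != X.shape[1]:
        raise ValidationError("gene_ids length does not match X columns")
    scaler = Standardizer().fit(X)
    X_std = scaler.transform(X)
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd == 0.0:
        raise ValidationError(
            f"pri-miRNA {pri_mirna_id!r} has constant expression; cannot fit"
        )
    y_std = (y - y_mean) / y_sd
    est = LassoCD(alpha=alpha, tol=tol, max_sweeps=max_sweeps).fit(X_std, y_std)
    kept_ids = [g for g, k in zip(gene_ids, scaler.kept_) if k]
    return LassoModel(
        pri_mirna_id=pri_mirna_id,
        gene_ids=kept_ids,
        coef=est.coef_,
        alpha=alpha,
        n_sweeps=est.n_sweeps_,
        converged=est.converged_,
        objective=est.objective_,
        kkt_violation=est.kkt_violation_,
        x_standardizer=scaler,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def predict(model: LassoModel, X_new, destandardize: bool = False) -> np.ndarray:
    """Predict the pri-miRNA response for new samples.

    X_new is on the observation scale with the same feature columns the model
    was trained on (before standardization); it is standardized with the
    *training* parameters.  With ``destandardize`` the prediction is mapped
    back to the training response scale.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.x_standardizer.n_features_in_:
        raise ValidationError(
            f"X_new has {X_new.shape[1]} features, model expects "
            f"{model.x_standardizer.n_features_in_}"
        )
    pred = model.x_standardizer.transform(X_new) @ model.coef
    if destandardize:
        pred = pred * model.y_sd + model.y_mean
    return pred


def associated_genes(model: LassoModel, zero_tol: float = 1e-8) -> AssociatedGeneSet:
    """The mRNAs whose coefficient magnitude exceeds ``zero_tol``."""
    coefficients = {
        g: float(w)
        for g, w in zip(model.gene_ids, model.coef)
        if abs(w) > zero_tol
    }
    return AssociatedGeneSet(pri_mirna_id=model.pri_mirna_id,
                             coefficients=coefficients)
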