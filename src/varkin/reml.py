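"""Multi-kernel REML: average-information updates with EM fallback, BLUP, delta-method SEs.

The model is  y = Xβ + Σ_k u_k + e  with  u_k ~ N(0, σ²_k K_k)  for an
arbitrary set of symmetric PSD kernels K_k (a genomic relationship matrix,
or Z Zᵀ for an identity covariance over a grouping factor such as dams) and
e ~ N(0, σ²_e I). The residual log-likelihood convention omits the n·log 2π
constant:

    −2 logL = log|V| + log|XᵀV⁻¹X| + yᵀPy,

which is fixed across models on the same data, so likelihood-ratio
differences between nested models are valid.

Estimation maximizes logL over the non-negative orthant: average-information
(AI) steps with step-halving, an EM-REML fallback when an AI step leaves the
feasible region or decreases the likelihood, and components pinned to the
boundary (zero) when updates push them negative while the gradient points
outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

__all__ = ["ModelSpec", "FitResult", "KernelREML", "reml_logL", "reml_fit", "ratio_se"]


@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``random_terms`` maps a term name to either an n×n kernel reference (a
    :class:`~varkin.kernels.RelationshipMatrix` / array) or the name of a
    grouping column (identity covariance over its levels, e.g. dams).
    """

    response: str
    fixed_factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    random_terms: list[tuple[str, object]] = field(default_factory=list)
    include_homozygosity: bool = True

    def __post_init__(self) -> None:
        names = [name for name, _ in self.random_terms]
        if len(set(names)) != len(names):
            raise ValueError("random-term names must be unique")


@dataclass
class FitResult:
    """REML output: components, likelihood, AI matrix, solutions and BLUPs."""

    components: dict[str, float]
    logL: float
    ai_matrix: np.ndarray
    ai_terms: list[str]
    fixed_solutions: pd.DataFrame
    blups: dict[str, pd.Series]
    converged: bool
    boundary_terms: set[str]
    n_obs: int
    n_iter: int
    degenerate: bool = False

    def component_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Inverse AI matrix over the non-boundary terms (component covariance)."""
        free = [t for t in self.ai_terms if t not in self.boundary_terms]
        if not free:
            raise ValueError("all components on the boundary; covariance undefined")
        rows = [self.ai_terms.index(t) for t in free]
        sub = self.ai_matrix[np.ix_(rows, rows)]
        return np.linalg.inv(sub), free

    def to_dict(self) -> dict:
        cov_se: dict[str, float] = {}
        try:
            C, free = self.component_covariance()
            cov_se = {t: float(np.sqrt(max(C[i, i], 0.0))) for i, t in enumerate(free)}
        except (ValueError, np.linalg.LinAlgError):
            pass
        return {
            "components": {k: float(v) for k, v in self.components.items()},
            "component_se": cov_se,
            "logL": float(self.logL),
            "converged": bool(self.converged),
            "boundary_terms": sorted(self.boundary_terms),
            "n_obs": int(self.n_obs),
            "n_iter": int(self.n_iter),
            "fixed_solutions": {
                str(r["term"]): {"estimate": float(r["estimate"]), "se": float(r["se"])}
                for _, r in self.fixed_solutions.iterrows()
            },
        }


def _groups_to_kernel(labels: Sequence) -> tuple[np.ndarray, np.ndarray, list]:
    """Z Zᵀ kernel for an identity covariance over the levels of a factor."""
    codes, levels = pd.factorize(pd.Series(list(labels)), sort=True)
    if (codes < 0).any():
        raise ValueError("missing level in grouping factor")
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z @ Z.T, Z, list(levels)


class KernelREML(BaseEstimator):
    """Linear mixed model with kernel-structured random effects, fit by AI-REML.

    Parameters
    ----------
    kernels
        Mapping term name → n×n symmetric PSD kernel aligned with the rows
        of ``X``/``y``.
    groups
        Mapping term name → length-n label vector; each becomes an identity
        covariance over its levels (kernel Z Zᵀ).
    max_iter, tol_logl, tol_theta
        Iteration cap and convergence thresholds (|ΔlogL| and max relative
        component change).
    jitter
        Added to kernel diagonals inside the solver only (never to stored
        matrices).

    Attributes (after ``fit``)
    --------------------------
    variance_components_ : dict term → σ² (includes ``"residual"``)
    logL_ : REML log-likelihood at convergence
    ai_matrix_, ai_terms_ : average-information matrix and its term order
    beta_, beta_se_, beta_names_ : fixed-effect solutions
    converged_, boundary_terms_, n_iter_, degenerate_
    """

    def __init__(
        self,
        kernels: Mapping[str, np.ndarray] | None = None,
        groups: Mapping[str, Sequence] | None = None,
        max_iter: int = 100,
        tol_logl: float = 1e-8,
        tol_theta: float = 1e-6,
        jitter: float = 1e-8,
        floor_frac: float = 1e-10,
        verbose: int = 0,
    ) -> None:
        self.kernels = kernels
        self.groups = groups
        self.max_iter = max_iter
        self.tol_logl = tol_logl
        self.tol_theta = tol_theta
        self.jitter = jitter
        self.floor_frac = floor_frac
        self.verbose = verbose

    # ---------------------------------------------------------------- setup
    def _materialize(self, n: int) -> tuple[list[str], list[np.ndarray]]:
        names: list[str] = []
        Ks: list[np.ndarray] = []
        self._group_Z_: dict[str, tuple[np.ndarray, list]] = {}
        for name, K in (self.kernels or {}).items():
            vals = getattr(K, "values", K)
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n, n):
                raise ValueError(f"kernel {name!r} has shape {vals.shape}, need ({n},{n})")
            if not np.allclose(vals, vals.T, atol=1e-8):
                raise ValueError(f"kernel {name!r} is not symmetric")
            Kj = vals + self.jitter * np.eye(n)
            names.append(name)
            Ks.append(Kj)
        for name, labels in (self.groups or {}).items():
            if len(labels) != n:
                raise ValueError(f"grouping {name!r} has length {len(labels)}, need {n}")
            ZZt, Z, levels = _groups_to_kernel(labels)
            names.append(name)
            Ks.append(ZZt + self.jitter * np.eye(n))
            self._group_Z_[name] = (Z, levels)
        if len(set(names)) != len(names):
            raise ValueError("random-term names must be unique across kernels and groups")
        return names, Ks

    @staticmethod
    def _check_design(X: np.ndarray, names: list[str] | None) -> None:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify confounded columns by pivoted QR
            _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
            dropped = sorted(piv[rank:])
            labels = [names[j] if names else str(j) for j in dropped]
            raise ValueError(
                f"fixed-effects design is rank deficient (rank {rank} < {X.shape[1]}); "
                f"confounded columns: {labels}"
            )

    # ------------------------------------------------------------- likelihood
    @staticmethod
    def _logL_at(theta: np.ndarray, Ks: list[np.ndarray], X: np.ndarray, y: np.ndarray):
        """Return (logL, P, Py, Vinv) at the given component vector."""
        n = y.shape[0]
        V = theta[-1] * np.eye(n)
        for th, K in zip(theta[:-1], Ks):
            if th != 0.0:
                V += th * K
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf, None, None, None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        ViX = Vinv @ X
        XtViX = X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, None, None, None
        P = Vinv - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = P @ y
        logL = -0.5 * (logdetV + logdetX + float(y @ Py))
        return logL, P, Py, Vinv

    # ------------------------------------------------------------------- fit
    def fit(self, X: np.ndarray, y: np.ndarray, theta0: np.ndarray | None = None):
        """Fit by AI-REML. ``X`` must be the full fixed-effects design (with intercept)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be n×p aligned with y")
        n = y.shape[0]
        names, Ks = self._materialize(n)
        self._check_design(X, getattr(self, "feature_names_", None))
        k = len(Ks)
        terms = names + ["residual"]
        vy = float(np.var(y))

        self.term_names_ = terms
        self.n_obs_ = n
        self._X_, self._y_, self._Ks_ = X, y, Ks

        if vy < 1e-12:
            # no variation to partition: all components zero, flagged degenerate
            self.variance_components_ = {t: 0.0 for t in terms}
            self.logL_ = np.nan
            self.ai_matrix_ = np.zeros((k + 1, k + 1))
            self.ai_terms_ = terms
            self.boundary_terms_ = set(terms)
            self.converged_ = True
            self.degenerate_ = True
            self.n_iter_ = 0
            self._solve_fixed(np.zeros(k + 1))
            self._Py_ = np.zeros(n)
            return self

        floor = self.floor_frac * vy
        if theta0 is not None:
            theta = np.maximum(np.asarray(theta0, dtype=float), floor)
            if theta.shape != (k + 1,):
                raise ValueError(f"theta0 must have length {k + 1}")
        else:
            theta = np.full(k + 1, vy / (k + 1))

        logL, P, Py, _ = self._logL_at(theta, Ks, X, y)
        if not np.isfinite(logL):
            raise ValueError("non-finite likelihood at starting values")

        converged = False
        it = 0
        score = np.zeros(k + 1)
        AI = np.eye(k + 1)
        for it in range(1, self.max_iter + 1):
            # score and AI at current point
            q = [K @ Py for K in Ks] + [Py]
            trPK = [float(np.sum(P * K)) for K in Ks] + [float(np.trace(P))]
            yPKPy = [float(Py @ qi) for qi in q]
            score = np.array([-0.5 * (t - s) for t, s in zip(trPK, yPKPy)])
            Pq = [P @ qi for qi in q]
            AI = 0.5 * np.array([[float(qi @ Pqj) for Pqj in Pq] for qi in q])

            # components are clamped at a small positive floor rather than
            # pinned: a term parked at the floor rejoins the updates as soon
            # as its gradient turns inward, so a bad early step cannot freeze
            # it at zero. Boundary classification happens at convergence.
            # active set for the AI step: terms stuck at the floor with an
            # outward gradient are held there for this step (they rejoin as
            # soon as their gradient turns inward); the residual is always
            # active. Solving the full AI system with a boundary term present
            # is ill-conditioned and stalls the other components.
            at_floor = theta <= floor * (1 + 1e-9)
            active = ~(at_floor & (score < 0.0))
            active[-1] = True

            new_theta = None
            # EM first iteration for robustness, then AI with step halving
            if it > 1 and active.any():
                try:
                    delta = np.zeros(k + 1)
                    delta[active] = np.linalg.solve(
                        AI[np.ix_(active, active)], score[active]
                    )
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None and np.isfinite(delta).all():
                    step = 1.0
                    for _ in range(6):
                        cand = np.maximum(theta + step * delta, floor)
                        cl, cP, cPy, _ = self._logL_at(cand, Ks, X, y)
                        if np.isfinite(cl) and cl >= logL - 1e-10:
                            new_theta, new_logL, P2, Py2 = cand, cl, cP, cPy
                            break
                        step *= 0.5
            if new_theta is None:
                # EM-REML update: θ ← θ + θ² (yᵀPKPy − tr(PK)) / n
                cand = theta + theta**2 * (np.array(yPKPy) - np.array(trPK)) / n
                cand = np.maximum(cand, floor)
                new_logL, P2, Py2, _ = self._logL_at(cand, Ks, X, y)
                if not np.isfinite(new_logL):
                    break
                new_theta = cand

            d_logl = abs(new_logL - logL)
            denom = np.maximum(np.abs(theta), vy * 1e-6)
            d_theta = float(np.max(np.abs(new_theta - theta) / denom))
            theta, logL, P, Py = new_theta, new_logL, P2, Py2
            if self.verbose:
                print(f"iter {it}: logL={logL:.8f} theta={theta}")
            at_floor = theta <= floor * (1 + 1e-9)
            if d_logl < self.tol_logl and d_theta < self.tol_theta:
                # a floor component with an outward gradient is a boundary
                # solution; one with an inward gradient still needs updates
                if not (at_floor[:-1] & (score[:-1] > 1e-6)).any():
                    converged = True
                    break

        pinned = theta <= floor * (1 + 1e-9)
        pinned[-1] = False  # residual reported as estimated even when tiny
        theta = np.where(pinned, 0.0, theta)
        self.variance_components_ = {t: float(v) for t, v in zip(terms, theta)}
        self.logL_ = float(logL)
        self.ai_matrix_ = AI
        self.ai_terms_ = terms
        self.boundary_terms_ = {t for t, pin in zip(terms, pinned) if pin}
        self.converged_ = converged
        self.degenerate_ = False
        self.n_iter_ = it
        self._P_, self._Py_ = P, Py
        self._theta_ = theta
        self._solve_fixed(theta)
        return self

    def _solve_fixed(self, theta: np.ndarray) -> None:
        X, y, Ks = self._X_, self._y_, self._Ks_
        n = y.shape[0]
        resid = theta[-1] if theta[-1] > 0 else 1.0
        V = resid * np.eye(n)
        for th, K in zip(theta[:-1], Ks):
            if th != 0.0:
                V += th * K
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        ViX = linalg.cho_solve((c, low), X, check_finite=False)
        XtViX = X.T @ ViX
        cov = np.linalg.inv(XtViX)
        self.beta_ = cov @ (ViX.T @ y)
        self.beta_se_ = np.sqrt(np.maximum(np.diag(cov), 0.0))
        self.beta_cov_ = cov

    # ------------------------------------------------------------------ blup
    def blup(self) -> dict[str, pd.Series]:
        """Best linear unbiased predictions per random term.

        Kernel terms: û = σ² K P y (one value per observation). Grouping
        terms: per-level effects σ² Zᵀ P y, indexed by level.
        """
        self._require_fitted()
        out: dict[str, pd.Series] = {}
        Py = self._Py_
        for name, K in zip(self.term_names_[:-1], self._Ks_):
            sig = self.variance_components_[name]
            if sig == 0.0:
                vals = np.zeros(self.n_obs_)
            else:
                vals = sig * (K @ Py)
            if name in self._group_Z_:
                Z, levels = self._group_Z_[name]
                lev_vals = (
                    np.zeros(len(levels)) if sig == 0.0 else sig * (Z.T @ Py)
                )
                out[name] = pd.Series(lev_vals, index=levels, name=name)
            else:
                out[name] = pd.Series(vals, name=name)
        return out

    def _require_fitted(self) -> None:
        if not hasattr(self, "variance_components_"):
            raise ValueError("call fit first")

    def result(self, feature_names: list[str] | None = None) -> FitResult:
        self._require_fitted()
        names = feature_names or [f"x{j}" for j in range(self._X_.shape[1])]
        fixed = pd.DataFrame(
            {"term": names, "estimate": self.beta_, "se": self.beta_se_}
        )
        return FitResult(
            components=dict(self.variance_components_),
            logL=self.logL_,
            ai_matrix=self.ai_matrix_,
            ai_terms=list(self.ai_terms_),
            fixed_solutions=fixed,
            blups={} if self.degenerate_ else self.blup(),
            converged=self.converged_,
            boundary_terms=set(self.boundary_terms_),
            n_obs=self.n_obs_,
            n_iter=self.n_iter_,
            degenerate=self.degenerate_,
        )


def reml_logL(
    kernels: Mapping[str, np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    theta: Mapping[str, float],
    jitter: float = 1e-8,
) -> float:
    """Evaluate the REML log-likelihood at a given component vector.

    ``theta`` maps every kernel name plus ``"residual"`` to a non-negative
    variance (residual strictly positive). The constant convention omits
    n·log 2π, fixed across models on the same data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    names = list(kernels)
    missing = set(names) - set(theta)
    if missing or "residual" not in theta:
        raise ValueError(f"theta must cover {names + ['residual']}")
    if theta["residual"] <= 0:
        raise ValueError("residual component must be positive")
    if any(theta[name] < 0 for name in names):
        raise ValueError("components must be non-negative")
    Ks = []
    for name in names:
        vals = np.asarray(getattr(kernels[name], "values", kernels[name]), dtype=float)
        Ks.append(vals + jitter * np.eye(n))
    vec = np.array([theta[name] for name in names] + [theta["residual"]])
    logL, _, _, _ = KernelREML._logL_at(vec, Ks, X, y)
    return float(logL)


def reml_fit(
    kernels: Mapping[str, np.ndarray] | None,
    X: np.ndarray,
    y: np.ndarray,
    groups: Mapping[str, Sequence] | None = None,
    feature_names: list[str] | None = None,
    theta0: np.ndarray | None = None,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`KernelREML`."""
    est = KernelREML(kernels=kernels, groups=groups, **kwargs)
    if feature_names is not None:
        est.feature_names_ = feature_names
    est.fit(X, y, theta0=theta0)
    return est.result(feature_names)


def ratio_se(
    components: Mapping[str, float],
    covariance: np.ndarray,
    cov_terms: Sequence[str],
    numerator_terms: Sequence[str],
    denominator_terms: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Delta-method SE for a ratio of variance components.

    The ratio is Σ(numerator terms) / Σ(denominator terms; all components by
    default). ``covariance``/``cov_terms`` give the sampling covariance of
    the *free* components (typically the inverse AI matrix); terms absent
    from ``cov_terms`` (boundary or omitted) are treated as fixed constants.
    """
    terms = list(components)
    den_terms = list(denominator_terms) if denominator_terms is not None else terms
    s = sum(components[t] for t in den_terms)
    if s <= 0:
        raise ValueError("denominator of ratio is non-positive")
    num = sum(components[t] for t in numerator_terms)
    r = num / s
    grad = []
    for t in cov_terms:
        w = 1.0 if t in numerator_terms else 0.0
        d = 1.0 if t in den_terms else 0.0
        grad.append((w - r * d) / s)
    g = np.asarray(grad)
    C = np.asarray(covariance, dtype=float)
    if C.shape != (len(cov_terms), len(cov_terms)):
        raise ValueError("covariance shape does not match cov_terms")
    var = float(g @ C @ g)
    return r, float(np.sqrt(max(var, 0.0)))
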