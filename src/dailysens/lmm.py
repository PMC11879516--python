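"""Maximum-likelihood random-intercept linear mixed models.

The marginal model is y = Xβ + u + e with a random intercept u_i per subject,
so each subject's covariance is σ_u²·J + σ_e²·I (compound symmetry).  The
likelihood is maximized by profiling: for a fixed variance ratio
λ = σ_u²/σ_e², GLS gives β̂ and σ̂_e² in closed form, leaving a 1-D search
over log λ.  Everything is plain ML (never REML) so that AICs are comparable
across models with different fixed effects — the requirement of the
crossover-model competition built on top of this engine.

Per-group algebra uses the Sherman–Morrison identity
(I + λJ)⁻¹ = I − λ/(1 + n_g λ)·J, reducing each likelihood evaluation to
group sums: cost O(G·p² + p³) after a single O(n·p²) precomputation, which
is what makes the bootstrap stages affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "DesignSpec",
    "LmmFit",
    "RandomInterceptML",
    "fit_ml",
    "wald_tests",
    "trim_covariates",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_LAMBDA_BOUNDS = (1e-8, 1e8)


@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effect design for a lagged multilevel model.

    ``fixed`` lists column names of the analysis table (an intercept is
    always included and is not listed); ``group`` is the clustering column.
    """

    outcome: str
    fixed: tuple[str, ...]
    group: str = "subject_id"

    def with_fixed(self, fixed) -> "DesignSpec":
        return DesignSpec(self.outcome, tuple(fixed), self.group)


@dataclass
class LmmFit:
    params: pd.Series
    bse: pd.Series
    sigma_u2: float
    sigma_e2: float
    loglik: float
    n_params: int
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    lambda_hat: float = 0.0
    spec: DesignSpec | None = None

    @property
    def fe_names(self) -> list[str]:
        return list(self.params.index)


class RandomInterceptML:
    """Profiled-ML engine bound to one design (X, groups); refits per y.

    Splitting the design from the response lets parametric-bootstrap loops
    reuse X'X and the per-group design sums, which do not depend on y.
    """

    def __init__(self, X: np.ndarray, group_codes: np.ndarray, names: list[str]):
        X = np.asarray(X, dtype=float)
        codes = np.asarray(group_codes)
        order = np.argsort(codes, kind="stable")
        self._order = order
        self.X = X[order]
        codes = codes[order]
        self.names = list(names)
        self.n, self.p = self.X.shape
        if self.n == 0:
            raise ValueError("empty design")
        # group boundaries on the sorted rows
        change = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        self.starts = change
        self.n_g = np.diff(np.r_[change, self.n]).astype(float)
        self.G = len(change)
        if self.G < 2:
            raise ValueError("need at least 2 groups")
        self._check_rank()
        self.XtX = self.X.T @ self.X
        self.SX = np.add.reduceat(self.X, self.starts, axis=0)  # G × p

    def _check_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.p:
            # identify offending columns via pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(self.X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(self.X.shape) * np.finfo(float).eps
            bad = [self.names[piv[j]] for j in range(self.p) if j >= rank or diag[j] < tol]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    # --- profiled likelihood pieces -------------------------------------
    def _suff(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)[self._order]
        Xty = self.X.T @ y
        yty = float(y @ y)
        Sy = np.add.reduceat(y, self.starts)
        return y, Xty, yty, Sy

    def _profile(self, lam: float, Xty, yty, Sy):
        """Profiled loglik at λ plus GLS pieces; returns (ll, beta, sigma_e2, A)."""
        c = lam / (1.0 + self.n_g * lam)  # per-group shrinkage weight
        A = self.XtX - (self.SX * c[:, None]).T @ self.SX
        b = Xty - self.SX.T @ (c * Sy)
        q = yty - float(c @ (Sy * Sy))
        beta = np.linalg.solve(A, b)
        rss = q - float(b @ beta)
        rss = max(rss, 1e-300)
        sigma_e2 = rss / self.n
        ll = -0.5 * (
            self.n * (_LOG_2PI + 1.0 + np.log(sigma_e2))
            + float(np.log1p(self.n_g * lam).sum())
        )
        return ll, beta, sigma_e2, A

    def fit(self, y: np.ndarray, names: list[str] | None = None) -> LmmFit:
        y_s, Xty, yty, Sy = self._suff(y)

        def neg(t: float) -> float:
            return -self._profile(np.exp(t), Xty, yty, Sy)[0]

        lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9}
        )
        lam = float(np.exp(res.x))
        ll_opt = -float(res.fun)
        ll0 = self._profile(0.0, Xty, yty, Sy)[0]
        if ll0 >= ll_opt:  # boundary: no between-subject variance
            lam, ll = 0.0, ll0
        else:
            ll = ll_opt
        _, beta, sigma_e2, A = self._profile(lam, Xty, yty, Sy)
        cov = sigma_e2 * np.linalg.inv(A)
        bse = np.sqrt(np.diag(cov))
        names = list(names or self.names)
        n_params = self.p + 2
        fit = LmmFit(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            sigma_u2=lam * sigma_e2,
            sigma_e2=sigma_e2,
            loglik=float(ll),
            n_params=n_params,
            aic=2.0 * n_params - 2.0 * float(ll),
            n_obs=self.n,
            n_groups=self.G,
            converged=bool(res.success or lam == 0.0),
            lambda_hat=lam,
        )
        return fit

    def fitted_mean(self, fit: LmmFit) -> np.ndarray:
        """Xβ̂ on the engine's (sorted) row order."""
        return self.X @ fit.params.to_numpy()

    def simulate(self, fit: LmmFit, rng: np.random.Generator) -> np.ndarray:
        """Draw one parametric-bootstrap response on the sorted row order."""
        mu = self.fitted_mean(fit)
        u = rng.normal(0.0, np.sqrt(fit.sigma_u2), size=self.G)
        e = rng.normal(0.0, np.sqrt(fit.sigma_e2), size=self.n)
        return mu + np.repeat(u, self.n_g.astype(int)) + e

    def refit(self, y: np.ndarray, presorted: bool = False) -> LmmFit:
        """Fit a new response vector.

        ``presorted=True`` declares y already on the engine's sorted row
        order (as returned by :meth:`simulate`).
        """
        if presorted:
            saved = self._order
            try:
                self._order = np.arange(self.n)
                return self.fit(y)
            finally:
                self._order = saved
        return self.fit(y)


def build_design(
    data: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, group codes, names) from an analysis table."""
    missing = [c for c in (spec.outcome, *spec.fixed, spec.group) if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent from data: {missing}")
    sub = data[[spec.outcome, *spec.fixed, spec.group]].dropna()
    y = sub[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in spec.fixed]
    )
    codes = pd.factorize(sub[spec.group])[0]
    return X, y, codes, ["const", *spec.fixed]


def fit_ml(data: pd.DataFrame, spec: DesignSpec) -> LmmFit:
    """ML fit of a random-intercept model defined by ``spec``."""
    X, y, codes, names = build_design(data, spec)
    engine = RandomInterceptML(X, codes, names)
    fit = engine.fit(y)
    fit.spec = spec
    return fit


def wald_tests(fit: LmmFit) -> pd.DataFrame:
    """Per-coefficient Wald z and two-sided normal p-values."""
    if not fit.converged:
        raise ValueError("fit did not converge; Wald tests unavailable")
    se = fit.bse.to_numpy()
    if np.any(se == 0):
        raise ValueError("zero standard error; Wald p undefined")
    z = fit.params.to_numpy() / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({"z": z, "p": p}, index=fit.params.index)


def trim_covariates(
    data: pd.DataFrame,
    spec: DesignSpec,
    candidates: tuple[str, ...] = ("PC1", "PC2"),
    alpha: float = 0.05,
) -> DesignSpec:
    """Drop screening covariates whose Wald p ≥ alpha.

    Used between the screening phase and the confirmatory crossover stage:
    ancestry components that contribute nothing are removed from the
    confirmatory models.
    """
    fit = fit_ml(data, spec)
    tests = wald_tests(fit)
    drop = {
        c for c in candidates if c in spec.fixed and tests.loc[c, "p"] >= alpha
    }
    if not drop:
        return spec
    return spec.with_fixed(c for c in spec.fixed if c not in drop)
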