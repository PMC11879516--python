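"""Competitive-confirmatory G×E classification via crossover models.

All six candidate models share the mean structure

    y = b0 + u_i + Σ γ_k·cov_k + (s0 + s1·G)·(E − c) + e

where G is the person-level sensitivity score, E the momentary environment
rating, and c the crossover point: the environment value at which the
regression lines for different G levels intersect.  The candidates differ in
where c lives and whether a baseline environmental slope is allowed:

* differential susceptibility (DS): c is a free parameter — sensitive people
  do worse in adverse contexts *and* better in favourable ones;
* diathesis-stress: c fixed at the favourable extreme (max observed E) —
  sensitivity only amplifies harm;
* vantage sensitivity: c fixed at the unfavourable extreme (min observed E)
  — sensitivity only amplifies benefit;
* "strong" variants additionally constrain s0 = 0 (no environmental effect
  at G = 0); "weak" variants leave s0 free.

Models are fit by ML (via the random-intercept engine) and compared by AIC;
a DS winner is only labelled DS when the 95% parametric-bootstrap interval
of ĉ lies within the observed range of E.

Fixed-c models are linear given c.  The free-c models are exact
reparameterizations of ordinary interaction models (weak:
{1, G, E, G·E}; strong: {1, G, G·E}) with ĉ = −β̂_G/β̂_{G·E}, which is used
whenever the interaction coefficient is identifiable and the implied c lies
in the representable window (observed E range extended by 50% on each side);
otherwise the profile likelihood over c is maximized on a grid plus local
refinement inside that window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .lmm import LmmFit, RandomInterceptML

__all__ = [
    "GxeModelSpec",
    "CrossoverFit",
    "GxeClassification",
    "six_specs",
    "fit_crossover",
    "crossover_ci",
    "classify",
]

FRAMEWORKS = ("differential_susceptibility", "diathesis_stress", "vantage_sensitivity")
_SHORT = {
    "differential_susceptibility": "DS",
    "diathesis_stress": "Diathesis-stress",
    "vantage_sensitivity": "Vantage-sensitivity",
}
_IDENT_TOL = 1e-10
_GRID_POINTS = 61
_WINDOW_EXTENSION = 0.5  # fraction of the observed E range added on each side


@dataclass(frozen=True)
class GxeModelSpec:
    """One of the six candidate G×E models."""

    framework: str
    strength: str  # "weak" | "strong"
    crossover: str  # "free" | "fixed_at_max" | "fixed_at_min"

    def __post_init__(self):
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.strength not in ("weak", "strong"):
            raise ValueError(f"unknown strength {self.strength!r}")
        expected = {
            "differential_susceptibility": "free",
            "diathesis_stress": "fixed_at_max",
            "vantage_sensitivity": "fixed_at_min",
        }[self.framework]
        if self.crossover != expected:
            raise ValueError(
                f"{self.framework} requires crossover={expected!r}, got {self.crossover!r}"
            )

    @classmethod
    def make(cls, framework: str, strength: str) -> "GxeModelSpec":
        crossover = {
            "differential_susceptibility": "free",
            "diathesis_stress": "fixed_at_max",
            "vantage_sensitivity": "fixed_at_min",
        }[framework]
        return cls(framework, strength, crossover)

    @property
    def label(self) -> str:
        return f"{_SHORT[self.framework]} {'S' if self.strength == 'strong' else 'W'}"


def six_specs() -> list[GxeModelSpec]:
    return [
        GxeModelSpec.make(fw, st) for fw in FRAMEWORKS for st in ("weak", "strong")
    ]


@dataclass
class CrossoverFit:
    spec: GxeModelSpec
    b0: float
    s0: float
    s1: float
    c: float
    cov_coefs: pd.Series
    sigma_u2: float
    sigma_e2: float
    loglik: float
    n_params: int
    aic: float
    identifiable: bool
    converged: bool
    c_ci: tuple[float, float] | None = None
    linear_fit: LmmFit | None = None


@dataclass
class GxeClassification:
    aic_table: pd.DataFrame
    best: GxeModelSpec
    fits: dict[str, CrossoverFit]
    c_hat: float
    c_ci: tuple[float, float] | None
    e_bounds: tuple[float, float]
    within_bounds: bool | None
    label: str


def _columns(data: pd.DataFrame, covariates) -> tuple[np.ndarray, ...]:
    y = data["y"].to_numpy(dtype=float)
    e = data["E"].to_numpy(dtype=float)
    g = data["G"].to_numpy(dtype=float)
    covs = [data[c].to_numpy(dtype=float) for c in covariates]
    codes = pd.factorize(data["subject_id"])[0]
    return y, e, g, covs, codes


def _window(e: np.ndarray) -> tuple[float, float, float, float]:
    emin, emax = float(e.min()), float(e.max())
    r = emax - emin
    return emin, emax, emin - _WINDOW_EXTENSION * r, emax + _WINDOW_EXTENSION * r


def _fixed_c_fit(y, e, g, covs, codes, covariates, c, strength):
    ec = e - c
    if strength == "weak":
        cols = [np.ones_like(e), ec, g * ec, *covs]
        names = ["const", "E_c", "GxE_c", *covariates]
    else:
        cols = [np.ones_like(e), g * ec, *covs]
        names = ["const", "GxE_c", *covariates]
    engine = RandomInterceptML(np.column_stack(cols), codes, names)
    return engine.fit(y)


def fit_crossover(
    data: pd.DataFrame,
    spec: GxeModelSpec,
    covariates: tuple[str, ...] = (),
    e_bounds: tuple[float, float] | None = None,
) -> CrossoverFit:
    """Fit one crossover-reparameterized G×E mixed model by ML.

    ``data`` is a lagged pair table with columns ``subject_id``, ``E``
    (environment at t), ``y`` (outcome at t+1), ``G`` and any covariates.
    """
    y, e, g, covs, codes = _columns(data, covariates)
    if e_bounds is None:
        emin, emax, wlo, whi = _window(e)
    else:
        emin, emax = e_bounds
        r = emax - emin
        wlo, whi = emin - _WINDOW_EXTENSION * r, emax + _WINDOW_EXTENSION * r

    if spec.crossover in ("fixed_at_max", "fixed_at_min"):
        c = emax if spec.crossover == "fixed_at_max" else emin
        lf = _fixed_c_fit(y, e, g, covs, codes, covariates, c, spec.strength)
        s0 = float(lf.params.get("E_c", 0.0))
        return CrossoverFit(
            spec=spec,
            b0=float(lf.params["const"]),
            s0=s0,
            s1=float(lf.params["GxE_c"]),
            c=float(c),
            cov_coefs=lf.params[list(covariates)],
            sigma_u2=lf.sigma_u2,
            sigma_e2=lf.sigma_e2,
            loglik=lf.loglik,
            n_params=lf.n_params,
            aic=lf.aic,
            identifiable=True,
            converged=lf.converged,
            linear_fit=lf,
        )

    # free crossover: exact linear reparameterization
    if spec.strength == "weak":
        cols = [np.ones_like(e), g, e, g * e, *covs]
        names = ["const", "G", "E", "GxE", *covariates]
    else:
        cols = [np.ones_like(e), g, g * e, *covs]
        names = ["const", "G", "GxE", *covariates]
    engine = RandomInterceptML(np.column_stack(cols), codes, names)
    lf = engine.fit(y)
    s1 = float(lf.params["GxE"])
    identifiable = abs(s1) >= _IDENT_TOL
    c_hat = -float(lf.params["G"]) / s1 if identifiable else float("nan")
    s0 = float(lf.params.get("E", 0.0))
    b0 = float(lf.params["const"]) + s0 * (c_hat if identifiable else 0.0)

    if spec.strength == "weak":
        if not identifiable:
            warnings.warn(
                "interaction coefficient ~0: crossover point non-identifiable",
                stacklevel=2,
            )
        return CrossoverFit(
            spec=spec,
            b0=b0,
            s0=s0,
            s1=s1,
            c=c_hat,
            cov_coefs=lf.params[list(covariates)],
            sigma_u2=lf.sigma_u2,
            sigma_e2=lf.sigma_e2,
            loglik=lf.loglik,
            n_params=lf.n_params,
            aic=lf.aic,
            identifiable=identifiable,
            converged=lf.converged,
            linear_fit=lf,
        )

    # strong + free c
    if identifiable and wlo <= c_hat <= whi:
        # unconstrained optimum lies in the representable window: the linear
        # fit *is* the profile maximum (same span, same parameter count)
        return CrossoverFit(
            spec=spec,
            b0=float(lf.params["const"]),
            s0=0.0,
            s1=s1,
            c=c_hat,
            cov_coefs=lf.params[list(covariates)],
            sigma_u2=lf.sigma_u2,
            sigma_e2=lf.sigma_e2,
            loglik=lf.loglik,
            n_params=lf.n_params,
            aic=lf.aic,
            identifiable=True,
            converged=lf.converged,
            linear_fit=lf,
        )

    # profile the likelihood over c on the window
    grid = np.linspace(wlo, whi, _GRID_POINTS)

    def ll_at(c: float) -> float:
        return _fixed_c_fit(y, e, g, covs, codes, covariates, c, "strong").loglik

    lls = np.array([ll_at(c) for c in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda c: -ll_at(c), bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    c_best = float(res.x) if -res.fun >= lls[k] else float(grid[k])
    best = _fixed_c_fit(y, e, g, covs, codes, covariates, c_best, "strong")
    n_params = best.n_params + 1  # the free crossover point
    return CrossoverFit(
        spec=spec,
        b0=float(best.params["const"]),
        s0=0.0,
        s1=float(best.params["GxE_c"]),
        c=c_best,
        cov_coefs=best.params[list(covariates)],
        sigma_u2=best.sigma_u2,
        sigma_e2=best.sigma_e2,
        loglik=best.loglik,
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * best.loglik,
        identifiable=abs(float(best.params["GxE_c"])) >= _IDENT_TOL,
        converged=best.converged,
        linear_fit=best,
    )


def crossover_ci(
    data: pd.DataFrame,
    fit: CrossoverFit,
    covariates: tuple[str, ...] = (),
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """95% parametric-bootstrap interval for the crossover point.

    Responses are resimulated from the fitted model (fresh random intercepts
    and residuals), refit in the free-crossover linear representation, and
    ĉ* = −β̂*_G/β̂*_{G·E} collected; the interval is the 2.5/97.5 percentile.
    Deterministic under ``seed``.
    """
    if fit.spec.crossover != "free":
        raise ValueError("crossover CI requires a free-crossover fit")
    if not fit.identifiable:
        raise ValueError("crossover point is non-identifiable; no CI")
    y, e, g, covs, codes = _columns(data, covariates)
    if fit.spec.strength == "weak":
        cols = [np.ones_like(e), g, e, g * e, *covs]
        names = ["const", "G", "E", "GxE", *covariates]
    else:
        cols = [np.ones_like(e), g, g * e, *covs]
        names = ["const", "G", "GxE", *covariates]
    engine = RandomInterceptML(np.column_stack(cols), codes, names)

    # simulate from the crossover-form mean of the chosen fit
    gamma = fit.cov_coefs.to_numpy() if len(covariates) else np.zeros(0)
    mu = (
        fit.b0
        + (np.column_stack(covs) @ gamma if len(covariates) else 0.0)
        + (fit.s0 + fit.s1 * g) * (e - fit.c)
    )
    mu_sorted = np.asarray(mu, dtype=float)[engine._order]
    rng = np.random.default_rng(seed)
    n_g = engine.n_g.astype(int)
    c_stars = []
    n_bad = 0
    for _ in range(n_boot):
        u = rng.normal(0.0, np.sqrt(fit.sigma_u2), size=engine.G)
        eps = rng.normal(0.0, np.sqrt(fit.sigma_e2), size=engine.n)
        y_star = mu_sorted + np.repeat(u, n_g) + eps
        bf = engine.refit(y_star, presorted=True)
        s1 = float(bf.params["GxE"])
        if abs(s1) < _IDENT_TOL:
            n_bad += 1
            continue
        c_stars.append(-float(bf.params["G"]) / s1)
    if n_bad > 0.1 * n_boot:
        warnings.warn(
            f"{n_bad}/{n_boot} bootstrap refits non-identifiable; CI unreliable",
            stacklevel=2,
        )
    lo, hi = np.percentile(c_stars, [2.5, 97.5])
    return float(lo), float(hi)


def classify(
    data: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    n_boot: int = 500,
    seed: int = 0,
) -> GxeClassification:
    """Fit all six crossover models, pick the AIC winner, and label it.

    AIC ties are broken toward fewer parameters, then fixed-crossover before
    free-crossover.  A differential-susceptibility winner keeps the "DS"
    label only when the 95% CI of ĉ lies within the observed E range.
    """
    e = data["E"].to_numpy(dtype=float)
    e_bounds = (float(e.min()), float(e.max()))
    fits: dict[str, CrossoverFit] = {}
    for spec in six_specs():
        try:
            f = fit_crossover(data, spec, covariates, e_bounds=e_bounds)
        except Exception as exc:  # noqa: BLE001 - excluded with warning per contract
            warnings.warn(f"{spec.label} failed to fit: {exc}", stacklevel=2)
            continue
        if not f.converged:
            warnings.warn(f"{spec.label} did not converge; excluded", stacklevel=2)
            continue
        fits[spec.label] = f
    if len(fits) < 2:
        raise RuntimeError("fewer than 2 crossover models converged; cannot classify")

    rows = []
    for label, f in fits.items():
        rows.append(
            {
                "model": label,
                "framework": f.spec.framework,
                "strength": f.spec.strength,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "aic": f.aic,
            }
        )
    table = pd.DataFrame(rows).set_index("model")

    def sort_key(label: str):
        f = fits[label]
        return (f.aic, f.n_params, 0 if f.spec.crossover != "free" else 1, label)

    best_label = min(fits, key=sort_key)
    best = fits[best_label]

    c_ci = None
    within = None
    label = best.spec.label
    if best.spec.framework == "differential_susceptibility":
        if best.identifiable:
            c_ci = crossover_ci(data, best, covariates, n_boot=n_boot, seed=seed)
            within = e_bounds[0] <= c_ci[0] and c_ci[1] <= e_bounds[1]
            if not within:
                label = "unclassified DS (out-of-bounds)"
        else:
            within = False
            label = "unclassified DS (non-identifiable)"
    return GxeClassification(
        aic_table=table,
        best=best.spec,
        fits=fits,
        c_hat=best.c,
        c_ci=c_ci,
        e_bounds=e_bounds,
        within_bounds=within,
        label=label,
    )
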