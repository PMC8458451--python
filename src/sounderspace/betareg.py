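"""Beta-likelihood regression of overlap responses with AICc model selection.

Overlap responses (directional 2D overlap, VI) are proportions, so they are
modeled with a beta likelihood: mean mu = inverse-logit(X beta), shape
parameters (mu * phi, (1 - mu) * phi) with a single precision phi.  Models
are ranked by the small-sample Akaike criterion AICc and effects reported as
odds ratios per standardized covariate unit with 90% Wald intervals.

The study's random intercepts for sow and sample period are rendered as
fixed-effects beta regression (see docs/methods.md); the likelihood, score
and information are implemented here rather than delegated, so the model can
be verified against an independent implementation in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import shapely

from .overlap import IsoplethRegion
from .tracks import AnimalAttributes, StudyPolygons

log = logging.getLogger(__name__)

Z90 = 1.6449  # standard-normal 95th percentile -> two-sided 90% interval


def transform_boundary(y: np.ndarray, n: int) -> np.ndarray:
    """Shrink proportions off the boundary: y' = (y (n - 1) + 0.5) / n.

    Applied only when any response sits exactly at 0 or 1 (the beta
    likelihood is undefined there); n is the sample size.
    """
    y = np.asarray(y, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    if ((y == 0.0) | (y == 1.0)).any():
        log.info("boundary response values present; applying (y(n-1)+0.5)/n")
        return (y * (n - 1) + 0.5) / n
    return y


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _is_continuous(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return len(vals) > 2


def build_design(
    table: pd.DataFrame,
    terms: Sequence[str],
    scalers: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, tuple[float, float]]]:
    """Design matrix with intercept for main-effect and ':'-interaction terms.

    Continuous covariates (more than two distinct values) are standardized to
    mean 0, SD 1 *before* interaction products are formed; the (mean, SD)
    scalers are returned so new data can be placed on the fitted scale.
    """
    scalers = dict(scalers) if scalers else {}
    base_cols: dict[str, np.ndarray] = {}
    for term in terms:
        for name in term.split(":"):
            if name in base_cols:
                continue
            if name not in table.columns:
                raise ValueError(f"covariate {name!r} not in table")
            col = table[name]
            v = col.to_numpy(dtype=float)
            if _is_continuous(col):
                if name not in scalers:
                    sd = v.std(ddof=0)
                    scalers[name] = (float(v.mean()), float(sd if sd > 0 else 1.0))
                m, s = scalers[name]
                v = (v - m) / s
            base_cols[name] = v
    cols = [np.ones(len(table))]
    names = ["(Intercept)"]
    for term in terms:
        parts = term.split(":")
        if len(parts) > 3:
            raise ValueError(f"interactions limited to the third order: {term!r}")
        v = base_cols[parts[0]].copy()
        for p in parts[1:]:
            v = v * base_cols[p]
        cols.append(v)
        names.append(term)
    X = np.column_stack(cols)
    return X, names, scalers


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, R, piv = _qr_pivot(X)
        keep = set(piv[: r])
        aliased = [names[j] for j in range(X.shape[1]) if j not in keep]
        raise ValueError(f"design matrix rank deficient; aliased terms: {aliased}")


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


# ---------------------------------------------------------------------------
# Beta likelihood
# ---------------------------------------------------------------------------

@dataclass
class BetaRegressionModel:
    terms: list[str]
    response: str
    coef_names: list[str]
    beta: np.ndarray
    phi: float
    se: np.ndarray           # Wald SEs of beta (logit scale)
    se_log_phi: float
    loglik: float
    k: int                   # parameter count including phi
    n: int
    converged: bool
    scalers: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def formula(self) -> str:
        return f"{self.response} ~ " + (" + ".join(self.terms) if self.terms else "1")


def _beta_negloglik_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray):
    beta, log_phi = params[:-1], params[-1]
    phi = np.exp(log_phi)
    eta = X @ beta
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a, b = mu * phi, (1.0 - mu) * phi
    ll = np.sum(
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
    )
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(a) - special.digamma(b)
    dmu = mu * (1.0 - mu)
    g_beta = phi * (X.T @ ((ystar - mustar) * dmu))
    g_phi = np.sum(
        special.digamma(phi) - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * np.log(y) + (1.0 - mu) * np.log1p(-y)
    )
    g = np.concatenate([g_beta, [g_phi * phi]])  # chain rule for log phi
    return -ll, -g


def _numeric_hessian(fun_grad, params, X, y, eps=1e-5):
    p = len(params)
    H = np.zeros((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(params[j]))
        up = params.copy(); up[j] += step
        dn = params.copy(); dn[j] -= step
        _, gu = fun_grad(up, X, y)
        _, gd = fun_grad(dn, X, y)
        H[:, j] = (gu - gd) / (2.0 * step)
    return 0.5 * (H + H.T)


def fit_beta_regression(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    *,
    scalers: Mapping[str, tuple[float, float]] | None = None,
) -> BetaRegressionModel:
    """Maximum-likelihood beta regression with logit mean link.

    The response must lie strictly inside (0, 1) (apply
    :func:`transform_boundary` first if needed).  Continuous covariates are
    standardized before fitting and the scalers stored on the model.  Wald
    standard errors come from the inverse observed information at the
    optimum.
    """
    y = table[response].to_numpy(dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("response must lie strictly in (0, 1); "
                         "use transform_boundary")
    X, names, scalers = build_design(table, terms, scalers)
    _check_full_rank(X, names)
    n, p = X.shape

    # start values: OLS on the logit scale, phi by moments of the residuals
    z = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu0 = special.expit(np.clip(X @ beta0, -30, 30))
    resid_var = max(np.var(y - mu0), 1e-6)
    phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
    x0 = np.concatenate([beta0, [np.log(phi0)]])

    bounds = [(None, None)] * p + [(np.log(1e-3), np.log(1e8))]
    x0[-1] = np.clip(x0[-1], *bounds[-1])
    res = optimize.minimize(
        _beta_negloglik_grad, x0, args=(X, y), jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    params = res.x
    H = _numeric_hessian(_beta_negloglik_grad, params, X, y)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov).copy()
        ok = np.all(diag > 0)
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        diag = np.full(p + 1, np.nan)
    se = np.sqrt(diag[:p])
    # L-BFGS-B can abort its line search at the optimum; a small gradient is
    # the operative convergence criterion
    _, g = _beta_negloglik_grad(params, X, y)
    converged = (bool(res.success) or float(np.abs(g).max()) < 1e-3 * n) and ok
    if not converged:
        log.warning("beta regression %s did not converge cleanly", terms)
    return BetaRegressionModel(
        terms=list(terms), response=response, coef_names=names,
        beta=params[:p], phi=float(np.exp(params[-1])), se=se,
        se_log_phi=float(np.sqrt(diag[p])), loglik=float(-res.fun),
        k=p + 1, n=n, converged=converged, scalers=scalers,
    )


def beta_loglik(model: BetaRegressionModel, table: pd.DataFrame) -> float:
    """Log-likelihood of a fitted model on (possibly new) data."""
    X, _, _ = build_design(table, model.terms, model.scalers)
    y = table[model.response].to_numpy(dtype=float)
    nll, _ = _beta_negloglik_grad(
        np.concatenate([model.beta, [np.log(model.phi)]]), X, y
    )
    return -nll


# ---------------------------------------------------------------------------
# Model selection and effect reporting
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); +inf when n <= k + 1."""
    if n - k - 1 <= 0:
        log.warning("AICc undefined for k=%d, n=%d; returning +inf", k, n)
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc_rank(models: Sequence[BetaRegressionModel]) -> pd.DataFrame:
    """Rank converged models by AICc; plausible when delta AICc < 2.

    All models must be fit to the same rows; non-converged models are
    excluded with a warning.
    """
    ns = {m.n for m in models}
    if len(ns) > 1:
        raise ValueError(f"models fit to different sample sizes: {sorted(ns)}")
    usable = []
    for m in models:
        if not m.converged:
            log.warning("excluding non-converged model: %s", m.formula)
            continue
        usable.append(m)
    rows = [
        {
            "formula": m.formula,
            "k": m.k,
            "n": m.n,
            "loglik": m.loglik,
            "aicc": aicc(m.loglik, m.k, m.n),
        }
        for m in usable
    ]
    df = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    if len(df):
        df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
        df["plausible"] = df["delta_aicc"] < 2.0
    return df


def odds_ratios(model: BetaRegressionModel, level: float = 0.90) -> pd.DataFrame:
    """Odds ratios per standardized unit with Wald confidence intervals.

    The ``excludes_one`` flag marks terms whose interval does not overlap 1
    (the table convention of the study's effect reporting).
    """
    if not model.converged:
        raise ValueError("odds ratios require a converged model")
    z = Z90 if abs(level - 0.90) < 1e-9 else float(stats.norm.ppf(0.5 + level / 2.0))
    rows = []
    for name, b, s in zip(model.coef_names, model.beta, model.se):
        if name == "(Intercept)":
            continue
        lo, hi = np.exp(b - z * s), np.exp(b + z * s)
        rows.append(
            {
                "term": name, "beta": b, "se": s, "or": float(np.exp(b)),
                "ci_lo": float(lo), "ci_hi": float(hi),
                "excludes_one": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariate construction
# ---------------------------------------------------------------------------

def _region_cell_centers(region: IsoplethRegion) -> tuple[np.ndarray, np.ndarray]:
    g = region.grid
    rows, cols = np.divmod(region.cells, g.ncols)
    return g.x0 + (cols + 0.5) * g.cell, g.y0 + (rows + 0.5) * g.cell


def _boundary_cells(region: IsoplethRegion) -> np.ndarray:
    """Flat indices of region cells with at least one 4-neighbour outside."""
    g = region.grid
    mask = region.mask()
    padded = np.pad(mask, 1, constant_values=False)
    core = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~core
    rr, cc = np.nonzero(boundary)
    return rr * g.ncols + cc


def percent_in_polygon(region: IsoplethRegion, poly) -> float:
    """Percent of region cells whose centres fall inside the polygon."""
    x, y = _region_cell_centers(region)
    if len(x) == 0:
        return 0.0
    inside = shapely.covers(poly, shapely.points(x, y))
    return 100.0 * inside.sum() / len(x)


def distance_to_polygon_km(region: IsoplethRegion, poly) -> float:
    """Min distance (km) from region boundary cells to the polygon; 0 if touching."""
    g = region.grid
    bcells = _boundary_cells(region)
    rows, cols = np.divmod(bcells, g.ncols)
    x = g.x0 + (cols + 0.5) * g.cell
    y = g.y0 + (rows + 0.5) * g.cell
    pts = shapely.points(x, y)
    if shapely.covers(poly, pts).any():
        return 0.0
    d = shapely.distance(poly, pts)
    return float(d.min()) / 1000.0


def build_covariates(
    regions: Sequence[IsoplethRegion],
    polygons: StudyPolygons,
    attributes: Mapping[str, AnimalAttributes],
    weather: pd.DataFrame | None = None,
    cohort_of: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-(sow, period, UD level) covariate table for the overlap models.

    Columns follow the study's predictor set: ``Dist.WC`` (km from the region
    boundary to the waste cells), ``%UD.LF`` / ``%UD.BLHW`` (percent of region
    cells inside the landfill / habitat polygons), sow attributes (``Mass``,
    ``Age`` with adult = 1, ``Sounder``), period-mean weather (``Temp``,
    ``Press``) and the ``UD.lev`` (core area = 1) and ``Year`` indicators.
    """
    if weather is not None:
        weather = weather.copy()
        weather["date"] = pd.to_datetime(weather["date"], utc=True)
    rows = []
    for region in regions:
        sow = region.animal_id
        if sow not in attributes:
            raise ValueError(f"no attribute row for sow {sow!r}")
        attr = attributes[sow]
        row = {
            "animal_id": sow,
            "scale": region.period.scale if region.period else "",
            "period": region.period.label if region.period else "",
            "ud_level": region.level,
            "area_ha": region.area_ha,
            "Dist.WC": distance_to_polygon_km(region, polygons.waste_cells),
            "%UD.LF": percent_in_polygon(region, polygons.landfill),
            "%UD.BLHW": (
                percent_in_polygon(region, polygons.habitat_blhw)
                if polygons.habitat_blhw is not None else 0.0
            ),
            "Mass": attr.mass_kg,
            "Age": 1.0 if attr.age_class == "adult" else 0.0,
            "Sounder": float(attr.sounder_size),
            "UD.lev": 1.0 if region.level == 0.50 else 0.0,
            "Year": float(cohort_of.get(sow, 0)) if cohort_of else 0.0,
        }
        if weather is not None and region.period is not None:
            w = weather[
                (weather["date"] >= region.period.start)
                & (weather["date"] < region.period.end)
            ]
            row["Temp"] = float(w["temp_c"].mean()) if len(w) else np.nan
            row["Press"] = float(w["pressure_mb"].mean()) if len(w) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def default_candidate_models(scale: str) -> list[list[str]]:
    """Config-style default candidate sets built from the covariate groups.

    Groups: landfill (Dist.WC, %UD.LF), sow (Mass, Age, Sounder), cover
    (%UD.BLHW) and weather (Temp, Press), plus the UD.lev and Year
    indicators.  Weather and Year enter only sub-season models (the season
    scale has too few periods to identify them), and interactions never
    involve Year or weather.
    """
    lf = ["Dist.WC", "%UD.LF"]
    sow = ["Mass", "Age", "Sounder"]
    cover = ["%UD.BLHW"]
    base = ["UD.lev"]
    extra = [] if scale == "season" else ["Year"]
    sets = [
        base + extra,
        base + extra + lf,
        base + extra + sow,
        base + extra + lf + cover,
        base + extra + lf + sow,
        base + extra + lf + ["UD.lev:Dist.WC", "UD.lev:%UD.LF"],
        base + extra + lf + sow + cover
        + ["UD.lev:Dist.WC", "UD.lev:%UD.LF", "UD.lev:Mass"],
    ]
    return sets
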