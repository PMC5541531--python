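"""Spatial modelling of range-contraction likelihood.

The modelling unit is a species × coarse-grid-cell observation: for every
coarse cell inside a species' historic range, a binary indicator of
whether the species' range has contracted from that cell.  Contraction
likelihood is regressed on standardized anthropogenic covariates with a
logistic generalized linear mixed model (random intercepts by species,
optionally random intercepts and slopes by geographical region), fitted by
maximum likelihood under the Laplace approximation.

Residual spatial autocorrelation is absorbed with a residuals
auto-covariate (RAC): deviance residuals of the non-spatial fit are
collapsed to one value per cell, averaged over all cells within a fixed
great-circle radius (default 300 km) of each cell, standardized, and added
to the model as an extra fixed covariate before refitting.

The mixed-model machinery here is self-contained: an inner penalized
iteratively-reweighted least-squares (Newton) solve for the joint mode of
fixed effects and spherical random effects, and an outer profile
optimization of the relative random-effect standard deviations.  With all
variance components pinned to zero it reduces exactly to ordinary logistic
regression.  Random-effect terms within a factor are modelled as
independent (diagonal covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .grid import GridSpec, neighbors_within

__all__ = [
    "ModelParams",
    "CovariateSpec",
    "RandomEffect",
    "GlmmFit",
    "R2Summary",
    "build_observation_table",
    "transform_standardize",
    "fit_logistic_glmm",
    "fit_rac_model",
    "deviance_residuals",
    "rac_covariate",
    "odds_effect_summary",
    "pseudo_r2",
    "region_effect_profiles",
    "compare_models",
]

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0  # latent-scale distribution variance


@dataclass
class ModelParams:
    """Settings of the observation-building and RAC stages.

    rac_radius_km
        Great-circle radius of the residual-averaging neighborhood.
    coarse_membership_threshold
        Minimum fraction of a coarse cell's fine *land* cells the historic
        range must cover for the cell to count as within the range.
    contraction_threshold
        The cell is scored contracted (y = 1) when the current range
        covers less than this fraction of the cell's historic fine cells.
    include_self_in_rac
        Whether the focal cell's own residual enters its RAC average.
    rac_collapse
        ``"cell"``: average observation residuals to one value per cell
        before neighborhood averaging (each cell weighs equally);
        ``"observation"``: average over all observation residuals in
        neighboring cells (multi-species cells weigh more).
    """

    rac_radius_km: float = 300.0
    coarse_membership_threshold: float = 0.5
    contraction_threshold: float = 0.5
    include_self_in_rac: bool = False
    rac_collapse: str = "cell"

    def __post_init__(self):
        if self.rac_radius_km <= 0:
            raise ValueError("rac_radius_km must be positive")
        for name in ("coarse_membership_threshold", "contraction_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.rac_collapse not in ("cell", "observation"):
            raise ValueError("rac_collapse must be 'cell' or 'observation'")


@dataclass
class CovariateSpec:
    """One model covariate: units, optional log1p transform, and the
    post-transform mean/s.d. recorded at standardization time (needed to
    back-transform effect sizes to natural units)."""

    name: str
    units: str = ""
    transform: str = "none"  # none | log1p
    mean: float | None = None
    sd: float | None = None  # sample s.d. (n−1 denominator)

    def __post_init__(self):
        if self.transform not in ("none", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")


# ---------------------------------------------------------------------------
# Observation table
# ---------------------------------------------------------------------------

def _block_sum(arr: np.ndarray, f: int) -> np.ndarray:
    nr, nc = arr.shape
    return arr.reshape(nr // f, f, nc // f, f).sum(axis=(1, 3))


def build_observation_table(
    pairs,
    covariates: dict[str, np.ndarray],
    land: np.ndarray,
    fine_grid: GridSpec,
    coarse_factor: int,
    regions: np.ndarray | None = None,
    params: ModelParams | None = None,
) -> tuple[pd.DataFrame, GridSpec]:
    """Aggregate fine rasters to the coarse model grid and score contraction.

    A coarse cell belongs to a species' historic range when the historic
    raster covers at least ``coarse_membership_threshold`` of the cell's
    fine land cells; the contraction indicator is 1 when the current range
    covers less than ``contraction_threshold`` of those historic fine
    cells.  Covariates are aggregated by their mean over fine land cells;
    the region code is the (land-area) majority zone of the cell.

    Returns the observation table and the coarse :class:`GridSpec`.
    """
    params = params or ModelParams()
    land = land.astype(bool)
    coarse = fine_grid.coarsen(coarse_factor)
    n_land = _block_sum(land.astype(float), coarse_factor)
    valid = n_land > 0

    cov_means = {}
    for name, ras in covariates.items():
        if ras.shape != fine_grid.shape:
            raise ValueError(f"covariate {name!r}: shape mismatch with fine grid")
        with np.errstate(invalid="ignore"):
            cov_means[name] = np.where(
                valid, _block_sum(np.where(land, ras, 0.0), coarse_factor) / np.where(valid, n_land, 1), np.nan
            )

    if regions is not None:
        zone_codes = np.unique(regions[land])
        counts = np.stack(
            [_block_sum(((regions == z) & land).astype(float), coarse_factor) for z in zone_codes]
        )
        region_coarse = zone_codes[np.argmax(counts, axis=0)]
    else:
        region_coarse = None

    rows_idx, cols_idx = np.meshgrid(
        np.arange(coarse.n_rows), np.arange(coarse.n_cols), indexing="ij"
    )
    lon, lat = coarse.cell_centroid(rows_idx, cols_idx)
    cell_id = rows_idx * coarse.n_cols + cols_idx

    frames = []
    for sp_id, pair in enumerate(pairs):
        hist = pair.historic.astype(bool) & land
        curr = pair.current.astype(bool) & land
        n_hist = _block_sum(hist.astype(float), coarse_factor)
        with np.errstate(invalid="ignore", divide="ignore"):
            member = valid & (n_hist / np.where(valid, n_land, 1) >= params.coarse_membership_threshold)
        if not member.any():
            warnings.warn(
                f"{pair.traits.name}: no coarse cells meet the historic-range "
                "membership threshold; species dropped from the model"
            )
            continue
        n_curr = _block_sum((curr & hist).astype(float), coarse_factor)
        with np.errstate(invalid="ignore", divide="ignore"):
            cover = np.where(n_hist > 0, n_curr / np.where(n_hist > 0, n_hist, 1), 0.0)
        y = (cover < params.contraction_threshold).astype(int)
        sel = member
        frame = {
            "species_id": sp_id,
            "species": pair.traits.name,
            "cell_id": cell_id[sel],
            "row": rows_idx[sel],
            "col": cols_idx[sel],
            "lon": lon[sel],
            "lat": lat[sel],
            "y": y[sel],
        }
        if region_coarse is not None:
            frame["region"] = region_coarse[sel]
        for name in covariates:
            frame[name] = cov_means[name][sel]
        frames.append(pd.DataFrame(frame))
    if not frames:
        raise ValueError("no species produced model observations")
    return pd.concat(frames, ignore_index=True), coarse


def transform_standardize(
    table: pd.DataFrame, specs: list[CovariateSpec], suffix: str = "_z"
) -> pd.DataFrame:
    """Apply per-covariate transforms and z-score to mean 0, s.d. 1.

    The sample standard deviation (n−1 denominator) is used and recorded,
    with the mean, on each spec for back-transformation.  Adds a
    ``<name><suffix>`` column per spec; raises on constant covariates.
    """
    out = table.copy()
    for spec in specs:
        x = out[spec.name].to_numpy(dtype=float)
        if spec.transform == "log1p":
            if (x < 0).any():
                raise ValueError(f"{spec.name}: negative values under log1p")
            x = np.log1p(x)
        sd = float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {spec.name!r} is constant; cannot standardize")
        spec.mean = float(np.mean(x))
        spec.sd = sd
        out[spec.name + suffix] = (x - spec.mean) / sd
    return out


# ---------------------------------------------------------------------------
# Logistic GLMM (Laplace maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class RandomEffect:
    """A random-effect factor with intercept and/or slope terms.

    ``terms`` lists model columns; ``"1"`` denotes the intercept.  Terms
    within the factor are independent (diagonal covariance).
    """

    factor: str
    terms: tuple = ("1",)


@dataclass
class GlmmFit:
    """Fitted logistic (mixed) model."""

    fixed_names: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    vcov_beta: np.ndarray
    variance_components: dict  # (factor, term) -> variance on logit scale
    random_effects: dict  # factor -> DataFrame(level, term, mode, cond_sd)
    fitted: np.ndarray  # conditional P(y=1)
    eta_fixed: np.ndarray  # fixed-effect linear predictor
    y: np.ndarray
    loglik: float
    converged: bool
    n_obs: int = 0

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se_beta

    @property
    def p_values(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.wald_z))


def _log1pexp(eta):
    return np.logaddexp(0.0, eta)


def _build_design(table, fixed, re_spec, add_intercept):
    n = len(table)
    cols = []
    names = []
    if add_intercept:
        cols.append(np.ones(n))
        names.append("(Intercept)")
    for name in fixed:
        cols.append(table[name].to_numpy(dtype=float))
        names.append(name)
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    z_cols, col_theta, theta_labels = [], [], []
    re_layout = {}  # factor -> (levels, [(term, col_slice)])
    for re in re_spec:
        codes, levels = pd.factorize(table[re.factor], sort=True)
        if len(levels) < 2:
            raise ValueError(f"random factor {re.factor!r} needs >= 2 groups")
        term_slices = []
        for term in re.terms:
            v = np.ones(n) if term == "1" else table[term].to_numpy(dtype=float)
            block = np.zeros((n, len(levels)))
            block[np.arange(n), codes] = v
            start = sum(c.shape[1] for c in z_cols)
            z_cols.append(block)
            col_theta.extend([len(theta_labels)] * len(levels))
            term_slices.append((term, slice(start, start + len(levels))))
            theta_labels.append((re.factor, term))
        re_layout[re.factor] = (list(levels), term_slices)
    Z = np.hstack(z_cols) if z_cols else np.empty((n, 0))
    return X, names, Z, np.asarray(col_theta, dtype=int), theta_labels, re_layout


def _pirls(y, X, Z, lam_cols, delta0, max_iter=100, tol=1e-9):
    """Joint Newton solve for (beta, u) at fixed relative s.d.s.

    Maximizes sum[y*eta - log(1+e^eta)] - u'u/2 with eta = X b + (Z Lam) u.
    Returns (delta, H, penalized loglik, converged).
    """
    n, p = X.shape
    q = Z.shape[1]
    A = np.hstack([X, Z * lam_cols]) if q else X
    pen = np.concatenate([np.zeros(p), np.ones(q)])
    delta = delta0.copy()

    def objective(d):
        eta = A @ d
        u = d[p:]
        return float(np.sum(y * eta - _log1pexp(eta)) - 0.5 * u @ u)

    f = objective(delta)
    converged = False
    for _ in range(max_iter):
        eta = A @ delta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = A.T @ (y - mu) - pen * delta
        H = (A * w[:, None]).T @ A
        H[np.diag_indices_from(H)] += pen
        try:
            c = cho_factor(H + 1e-10 * np.eye(p + q))
            step = cho_solve(c, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - ridge fallback
            step = np.linalg.lstsq(H + 1e-6 * np.eye(p + q), grad, rcond=None)[0]
        if np.max(np.abs(grad)) < 1e-8:
            converged = True
            break
        t = 1.0
        for _ in range(30):
            f_new = objective(delta + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        delta = delta + t * step
        if abs(f_new - f) < tol * (1.0 + abs(f)):
            f = f_new
            converged = True
            break
        f = f_new
    eta = A @ delta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (A * w[:, None]).T @ A
    H[np.diag_indices_from(H)] += pen
    return delta, H, f, converged


def _laplace_loglik(y, X, Z, col_theta, theta, delta0):
    p = X.shape[1]
    q = Z.shape[1]
    lam_cols = theta[col_theta] if q else np.empty(0)
    delta, H, f_pen, conv = _pirls(y, X, Z, lam_cols, delta0)
    if q:
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        ll = f_pen - 0.5 * logdet
    else:
        ll = f_pen
    return ll, delta, H, conv


def fit_logistic_glmm(
    table: pd.DataFrame,
    fixed,
    re_spec=(),
    response: str = "y",
    add_intercept: bool = True,
    fix_theta=None,
) -> GlmmFit:
    """Fit a logistic regression with independent Gaussian random effects.

    Maximum likelihood under the Laplace approximation: for trial values
    of the relative random-effect standard deviations, the joint mode of
    fixed effects and spherical random effects is found by penalized
    Newton iterations; the profiled Laplace log-likelihood is then
    maximized over the standard deviations.  ``fix_theta`` pins the
    relative s.d.s (e.g. all zeros recovers ordinary logistic
    regression).  Non-convergence is flagged on the result, not raised.
    """
    y = table[response].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response is degenerate (all 0 or all 1)")
    X, names, Z, col_theta, theta_labels, re_layout = _build_design(
        table, tuple(fixed), tuple(re_spec), add_intercept
    )
    n, p = X.shape
    q = Z.shape[1]
    k = len(theta_labels)
    delta_ws = {"d": np.zeros(p + q)}

    def neg_ll(theta_vec):
        theta_vec = np.clip(np.atleast_1d(np.asarray(theta_vec, dtype=float)), 0.0, None)
        ll, delta, _, _ = _laplace_loglik(y, X, Z, col_theta, theta_vec, delta_ws["d"])
        delta_ws["d"] = delta
        return -ll

    outer_ok = True
    if k == 0 or (fix_theta is not None):
        theta = (
            np.zeros(k)
            if fix_theta is None
            else np.clip(np.atleast_1d(np.asarray(fix_theta, dtype=float)), 0.0, None)
        )
    elif k == 1:
        res = optimize.minimize_scalar(
            neg_ll, bounds=(0.0, 15.0), method="bounded", options={"xatol": 1e-5}
        )
        theta = np.atleast_1d(res.x)
    else:
        res = optimize.minimize(
            neg_ll,
            x0=np.full(k, 0.7),
            method="L-BFGS-B",
            bounds=[(0.0, 15.0)] * k,
            options={"maxiter": 200, "ftol": 1e-11},
        )
        theta = np.asarray(res.x)
        outer_ok = bool(res.success)

    ll, delta, H, inner_ok = _laplace_loglik(y, X, Z, col_theta, theta, delta_ws["d"])
    beta, u = delta[:p], delta[p:]
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:  # degenerate design (e.g. all-zero covariate)
        Hinv = np.linalg.pinv(H)
    se_beta = np.sqrt(np.clip(np.diag(Hinv)[:p], 0.0, None))
    if np.abs(beta).max(initial=0.0) > 30:
        warnings.warn("very large coefficients: possible complete separation")

    lam_cols = theta[col_theta] if q else np.empty(0)
    eta = X @ beta + (Z * lam_cols) @ u if q else X @ beta

    var_comp = {lab: float(theta[i] ** 2) for i, lab in enumerate(theta_labels)}
    rand = {}
    diag_u = np.diag(Hinv)[p:] if q else np.empty(0)
    for factor, (levels, term_slices) in re_layout.items():
        recs = []
        for term, sl in term_slices:
            t_idx = theta_labels.index((factor, term))
            lam = theta[t_idx]
            modes = lam * u[sl]
            csd = lam * np.sqrt(np.clip(diag_u[sl], 0.0, None))
            for lev, m, s in zip(levels, modes, csd):
                recs.append({"level": lev, "term": term, "mode": float(m), "cond_sd": float(s)})
        rand[factor] = pd.DataFrame(recs)

    return GlmmFit(
        fixed_names=names,
        beta=beta,
        se_beta=se_beta,
        vcov_beta=Hinv[:p, :p],
        variance_components=var_comp,
        random_effects=rand,
        fitted=expit(eta),
        eta_fixed=X @ beta,
        y=y.astype(int),
        loglik=float(ll),
        converged=bool(inner_ok and outer_ok),
        n_obs=n,
    )


def fit_rac_model(table: pd.DataFrame, fixed, re_spec=(), rac_column: str = "rac_z", **kw) -> GlmmFit:
    """Refit the model with the standardized RAC term as an extra fixed
    covariate (same contract as :func:`fit_logistic_glmm`)."""
    if rac_column not in table.columns:
        raise ValueError(f"table has no {rac_column!r} column; compute the RAC first")
    return fit_logistic_glmm(table, tuple(fixed) + (rac_column,), re_spec, **kw)


# ---------------------------------------------------------------------------
# Residuals and the spatial auto-covariate
# ---------------------------------------------------------------------------

def deviance_residuals(fit: GlmmFit | None = None, y=None, p=None) -> np.ndarray:
    """Signed square-root deviance contributions of binary observations.

    d = sign(y − p̂)·sqrt(−2[y ln p̂ + (1−y) ln(1−p̂)]); fitted
    probabilities are clamped to [1e-12, 1−1e-12].
    """
    if fit is not None:
        y, p = fit.y, fit.fitted
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    dev = -2.0 * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return np.sign(y - p) * np.sqrt(np.clip(dev, 0.0, None))


def rac_covariate(
    table: pd.DataFrame,
    residuals: np.ndarray,
    params: ModelParams | None = None,
) -> tuple[np.ndarray, dict]:
    """Residuals auto-covariate: distance-band average of cell residuals.

    Observation residuals are first collapsed to one value per coarse cell
    (mean across the species present, or kept at observation level — see
    ``ModelParams.rac_collapse``); each cell's RAC is then the average
    over all cells whose centroid lies within ``rac_radius_km`` great-
    circle distance (focal cell excluded unless ``include_self_in_rac``).
    Cells with no neighbor in the band get RAC 0; their count is reported.

    Returns per-observation RAC values aligned with ``table`` rows, plus
    an info dict (n_cells, n_isolated, collapse mode).
    """
    params = params or ModelParams()
    if len(table) == 0:
        raise ValueError("empty observation table")
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(table):
        raise ValueError("residuals length does not match table")

    df = pd.DataFrame(
        {
            "cell_id": table["cell_id"].to_numpy(),
            "lon": table["lon"].to_numpy(dtype=float),
            "lat": table["lat"].to_numpy(dtype=float),
            "resid": residuals,
        }
    )
    g = df.groupby("cell_id", sort=True)
    cells = g.agg(
        lon=("lon", "first"),
        lat=("lat", "first"),
        rsum=("resid", "sum"),
        n=("resid", "size"),
    ).reset_index()
    nbrs = neighbors_within(
        cells["lon"].to_numpy(),
        cells["lat"].to_numpy(),
        params.rac_radius_km,
        include_self=params.include_self_in_rac,
    )
    rsum = cells["rsum"].to_numpy()
    cnt = cells["n"].to_numpy().astype(float)
    cell_mean = rsum / cnt
    rac = np.zeros(len(cells))
    n_isolated = 0
    for i, idx in enumerate(nbrs):
        if len(idx) == 0:
            n_isolated += 1
            continue
        if params.rac_collapse == "cell":
            rac[i] = cell_mean[idx].mean()
        else:  # observation-level averaging
            rac[i] = rsum[idx].sum() / cnt[idx].sum()
    if n_isolated:
        warnings.warn(
            f"{n_isolated} cells have no neighbor within "
            f"{params.rac_radius_km} km; their RAC is set to 0"
        )
    lookup = pd.Series(rac, index=cells["cell_id"])
    info = {
        "n_cells": len(cells),
        "n_isolated": n_isolated,
        "collapse": params.rac_collapse,
        "radius_km": params.rac_radius_km,
    }
    return lookup.loc[table["cell_id"]].to_numpy(), info


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def odds_effect_summary(fit: GlmmFit, terms=None) -> pd.DataFrame:
    """Percent change in contraction odds per 1 s.d. covariate increase.

    100·(e^β − 1) with Wald 95% CI 100·(e^{β±1.96·se} − 1) and two-sided
    Wald p-values.  The intercept is excluded unless listed explicitly.
    """
    if terms is None:
        terms = [n for n in fit.fixed_names if n != "(Intercept)"]
    rows = []
    pvals = fit.p_values
    for name in terms:
        i = fit.fixed_names.index(name)
        b, se = fit.beta[i], fit.se_beta[i]
        rows.append(
            {
                "term": name,
                "beta": b,
                "se": se,
                "pct_odds_change": 100.0 * (np.exp(b) - 1.0),
                "ci_low": 100.0 * (np.exp(b - 1.96 * se) - 1.0),
                "ci_high": 100.0 * (np.exp(b + 1.96 * se) - 1.0),
                "p_value": pvals[i],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class R2Summary:
    """Latent-scale variance-partition pseudo-R² for a logistic mixed model."""

    marginal: float
    conditional: float
    var_fixed: float
    var_random: float
    var_resid: float = LOGIT_RESIDUAL_VARIANCE


def pseudo_r2(fit: GlmmFit) -> R2Summary:
    """Marginal and conditional pseudo-R² on the latent logit scale.

    marginal = σ²_f / (σ²_f + Σσ²_r + π²/3), conditional adds Σσ²_r to
    the numerator; σ²_f is the variance of the fixed-effect linear
    predictor across observations.
    """
    var_f = float(np.var(fit.eta_fixed, ddof=1)) if fit.n_obs > 1 else 0.0
    var_r = float(sum(fit.variance_components.values()))
    denom = var_f + var_r + LOGIT_RESIDUAL_VARIANCE
    return R2Summary(
        marginal=var_f / denom,
        conditional=(var_f + var_r) / denom,
        var_fixed=var_f,
        var_random=var_r,
    )


def region_effect_profiles(fit: GlmmFit, factor: str = "region") -> pd.DataFrame:
    """Per-group combined effects: fixed estimate + conditional mode.

    95% prediction intervals assume independence of the fixed-effect
    estimate and the conditional mode: half-width
    1.96·sqrt(se_fixed² + cond_sd²).  With a zero variance component the
    combined effect collapses to the fixed estimate and the PI to its CI.
    """
    if factor not in fit.random_effects:
        raise ValueError(f"fit has no random effects for factor {factor!r}")
    re = fit.random_effects[factor]
    rows = []
    for _, r in re.iterrows():
        term = r["term"]
        name = "(Intercept)" if term == "1" else term
        i = fit.fixed_names.index(name)
        b, se = fit.beta[i], fit.se_beta[i]
        combined = b + r["mode"]
        half = 1.96 * np.sqrt(se**2 + r["cond_sd"] ** 2)
        rows.append(
            {
                "level": r["level"],
                "term": name,
                "fixed": b,
                "mode": r["mode"],
                "combined": combined,
                "pi_low": combined - half,
                "pi_high": combined + half,
            }
        )
    return pd.DataFrame(rows)


def compare_models(fit_base: GlmmFit, fit_extended: GlmmFit) -> dict:
    """Pseudo-R² comparison of two fits on the same observations.

    Reports marginal/conditional R² of both models, their differences,
    and the (conditional − marginal) share — the variability attributed
    to the random effects — per fit.
    """
    if fit_base.n_obs != fit_extended.n_obs or not np.array_equal(
        fit_base.y, fit_extended.y
    ):
        raise ValueError("fits are not on the same observations")
    r2b = pseudo_r2(fit_base)
    r2e = pseudo_r2(fit_extended)
    return {
        "base": r2b,
        "extended": r2e,
        "delta_marginal": r2e.marginal - r2b.marginal,
        "delta_conditional": r2e.conditional - r2b.conditional,
        "random_share_base": r2b.conditional - r2b.marginal,
        "random_share_extended": r2e.conditional - r2e.marginal,
    }
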