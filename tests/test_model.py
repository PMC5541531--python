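"""Observation building, GLMM estimation, RAC term, effect summaries."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from carnrange.grid import great_circle_distance, make_grid
from carnrange.harmonize import SpeciesRangePair, SpeciesTraits
from carnrange.model import (
    LOGIT_RESIDUAL_VARIANCE,
    CovariateSpec,
    GlmmFit,
    ModelParams,
    RandomEffect,
    build_observation_table,
    compare_models,
    deviance_residuals,
    fit_logistic_glmm,
    fit_rac_model,
    odds_effect_summary,
    pseudo_r2,
    rac_covariate,
    region_effect_profiles,
    transform_standardize,
)
from carnrange.synthetic import simulate_observation_table


# -- observation table ------------------------------------------------------

def _toy_fine_world():
    """8x8 fine grid, coarse factor 2, hand-checkable coverage fractions."""
    grid = make_grid(1.0, (0, 8, 0, 8))
    land = np.ones(grid.shape, dtype=bool)
    land[0, 0] = False  # one ocean cell in coarse cell (0,0)
    return grid, land


def test_observation_table_matches_threshold_scan(rng):
    grid, land = _toy_fine_world()
    f = 2
    pairs = []
    for i in range(2):
        h = (rng.random(grid.shape) > 0.35) & land
        c = h & (rng.random(grid.shape) > 0.4)
        pairs.append(
            SpeciesRangePair(traits=SpeciesTraits(name=f"s{i}"), historic=h, current=c, grid=grid)
        )
    cov = {"x": rng.uniform(0, 10, grid.shape)}
    params = ModelParams(coarse_membership_threshold=0.5, contraction_threshold=0.5)
    table, coarse = build_observation_table(pairs, cov, land, grid, f, params=params)

    # brute-force scan over every species and coarse cell
    expected_rows = set()
    for sp, p in enumerate(pairs):
        for R in range(coarse.n_rows):
            for C in range(coarse.n_cols):
                blk = np.s_[R * f : (R + 1) * f, C * f : (C + 1) * f]
                n_land = land[blk].sum()
                if n_land == 0:
                    continue
                n_hist = (p.historic & land)[blk].sum()
                if n_hist / n_land < 0.5:
                    continue
                n_curr = (p.current & land)[blk].sum()
                y = int(n_curr / n_hist < 0.5)
                xbar = cov["x"][blk][land[blk]].mean()
                expected_rows.add((sp, R * coarse.n_cols + C, y, round(xbar, 9)))
    got = {
        (r.species_id, r.cell_id, r.y, round(r.x, 9)) for r in table.itertuples()
    }
    assert got == expected_rows


def test_observation_table_degenerate_species(rng):
    grid, land = _toy_fine_world()
    h = land.copy()
    full = SpeciesRangePair(traits=SpeciesTraits(name="keep"), historic=h, current=h.copy(), grid=grid)
    gone = SpeciesRangePair(
        traits=SpeciesTraits(name="gone"), historic=h, current=np.zeros_like(h), grid=grid
    )
    cov = {"x": rng.uniform(0, 1, grid.shape)}
    table, _ = build_observation_table([full, gone], cov, land, grid, 2)
    assert (table.loc[table.species == "keep", "y"] == 0).all()
    assert (table.loc[table.species == "gone", "y"] == 1).all()
    # species with no coarse membership is dropped with a warning
    tiny = np.zeros_like(h)
    tiny[3, 3] = True  # 1 of 4 land cells -> below 0.5 membership
    sliver = SpeciesRangePair(traits=SpeciesTraits(name="sliver"), historic=tiny, current=tiny, grid=grid)
    with pytest.warns(UserWarning, match="membership threshold"):
        t2, _ = build_observation_table([full, sliver], cov, land, grid, 2)
    assert set(t2.species) == {"keep"}


# -- standardization --------------------------------------------------------

def test_standardize_mean_zero_unit_sd(rng):
    t = pd.DataFrame({"a": rng.uniform(0, 50, 300), "b": rng.exponential(5, 300)})
    specs = [CovariateSpec("a"), CovariateSpec("b", transform="log1p")]
    out = transform_standardize(t, specs)
    for c in ("a_z", "b_z"):
        assert abs(out[c].mean()) < 1e-8
        assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-8)
    assert specs[1].mean == pytest.approx(np.log1p(t["b"]).mean())


def test_standardize_hand_arithmetic_sample_sd():
    # log1p maps {0, e-1} to {0, 1}; sample s.d. (n-1) of {0,1} is 1/sqrt(2)
    t = pd.DataFrame({"x": [0.0, np.e - 1.0]})
    spec = CovariateSpec("x", transform="log1p")
    out = transform_standardize(t, [spec])
    assert out["x_z"].to_list() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])
    assert spec.sd == pytest.approx(np.sqrt(0.5))


def test_standardize_rejects_constant_column():
    t = pd.DataFrame({"x": np.ones(10)})
    with pytest.raises(ValueError, match="'x' is constant"):
        transform_standardize(t, [CovariateSpec("x")])


# -- GLMM -------------------------------------------------------------------

def _sm_logit(y, X):
    import statsmodels.api as sm

    return sm.GLM(y, X, family=sm.families.Binomial()).fit()


def test_pinned_variance_reproduces_irls(rng):
    tab = simulate_observation_table(5, side=10, n_species=4, sigma_species=0.8)
    fit = fit_logistic_glmm(tab, ("x1", "x2", "x3"), (RandomEffect("species"),), fix_theta=[0.0])
    X = np.column_stack([np.ones(len(tab)), tab.x1, tab.x2, tab.x3])
    ref = _sm_logit(tab.y.to_numpy(), X)
    assert np.abs(fit.beta - ref.params).max() < 1e-6
    assert np.abs(fit.se_beta - ref.bse).max() < 1e-6
    # no-random-effect path gives the same answer
    fit2 = fit_logistic_glmm(tab, ("x1", "x2", "x3"))
    assert np.abs(fit2.beta - ref.params).max() < 1e-6


def test_null_slope_coverage(rng):
    """With y independent of x the Wald CI covers 0 at its nominal rate."""
    hits = 0
    reps = 200
    for rep in range(reps):
        r = np.random.default_rng(50_000 + rep)
        x = r.standard_normal(2000)
        y = r.integers(0, 2, 2000)
        t = pd.DataFrame({"x": x, "y": y})
        fit = fit_logistic_glmm(t, ("x",))
        b, se = fit.beta[1], fit.se_beta[1]
        assert abs(b) < 0.5
        hits += b - 1.96 * se <= 0.0 <= b + 1.96 * se
    assert 0.90 <= hits / reps <= 0.99


def test_glmm_matches_lme4_reference():
    """Independent oracle: lme4::glmer on the same data, Laplace (nAGQ=1)."""
    tab = simulate_observation_table(42, side=12, n_species=8, sigma_species=1.0)
    fit = fit_logistic_glmm(tab, ("x1", "x2", "x3"), (RandomEffect("species"),))
    with open("/tmp/carnrange_lme4.csv", "w") as fh:
        tab.to_csv(fh, index=False)
    rscript = textwrap.dedent(
        """
        suppressMessages(library(lme4))
        d <- read.csv("/tmp/carnrange_lme4.csv")
        m <- glmer(y ~ x1 + x2 + x3 + (1|species), data=d, family=binomial)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    vals = [float(v) for v in out.stdout.split()]
    ref_beta, ref_sd, ref_ll = np.array(vals[:4]), vals[4], vals[5]
    assert np.abs(fit.beta - ref_beta).max() < 0.02
    sd_hat = np.sqrt(fit.variance_components[("species", "1")])
    assert sd_hat == pytest.approx(ref_sd, rel=0.05)
    assert fit.loglik == pytest.approx(ref_ll, abs=0.5)


def test_degenerate_response_rejected():
    t = pd.DataFrame({"y": np.ones(20, dtype=int), "x": np.arange(20.0)})
    with pytest.raises(ValueError, match="degenerate"):
        fit_logistic_glmm(t, ("x",))


def test_separation_warns_but_returns():
    t = pd.DataFrame({"y": ([0] * 20 + [1] * 20), "x": np.r_[np.zeros(20), np.ones(20)]})
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_logistic_glmm(t, ("x",))
    assert np.isfinite(fit.beta).all()


# -- deviance residuals -----------------------------------------------------

def test_deviance_residual_closed_forms():
    d = deviance_residuals(y=[1, 1, 0], p=[1.0, 0.5, 0.5])
    assert d[0] == pytest.approx(0.0, abs=1e-5)  # y=1, p=1 (clamped)
    assert d[1] == pytest.approx(np.sqrt(-2 * np.log(0.5)), abs=1e-9)  # +1.17741
    assert d[2] == pytest.approx(-np.sqrt(-2 * np.log(0.5)), abs=1e-9)
    assert np.isfinite(deviance_residuals(y=[0, 1], p=[1.0, 0.0])).all()


# -- RAC --------------------------------------------------------------------

def test_rac_two_cells_swap_residuals():
    t = pd.DataFrame(
        {"cell_id": [0, 1], "lon": [0.0, 0.9], "lat": [0.0, 0.0], "y": [0, 1]}
    )
    rac, info = rac_covariate(t, np.array([0.4, -0.2]), ModelParams(rac_radius_km=300))
    assert rac == pytest.approx([-0.2, 0.4])
    assert info["n_isolated"] == 0


def test_rac_isolated_cell_defaults_to_zero():
    t = pd.DataFrame(
        {"cell_id": [0, 1], "lon": [0.0, 100.0], "lat": [0.0, 0.0], "y": [0, 1]}
    )
    with pytest.warns(UserWarning, match="no neighbor"):
        rac, info = rac_covariate(t, np.array([0.4, -0.2]), ModelParams(rac_radius_km=300))
    assert rac == pytest.approx([0.0, 0.0])
    assert info["n_isolated"] == 2


def test_rac_matches_brute_force_double_loop(rng):
    # 25-cell toy grid, multiple species per cell
    side = 5
    rows, cols = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    cells = pd.DataFrame(
        {"cell_id": np.arange(side * side), "lon": cols.ravel() * 1.5, "lat": rows.ravel() * 1.5}
    )
    obs = pd.concat([cells] * 3, ignore_index=True).sample(60, random_state=2).reset_index(drop=True)
    resid = rng.standard_normal(len(obs))
    params = ModelParams(rac_radius_km=300.0)
    rac, _ = rac_covariate(obs, resid, params)

    # brute force: per-cell means, all-pairs distance filter
    obs2 = obs.assign(resid=resid)
    per_cell = obs2.groupby("cell_id").agg(
        lon=("lon", "first"), lat=("lat", "first"), m=("resid", "mean")
    )
    for i, row in obs.iterrows():
        c = row.cell_id
        vals = []
        for c2, r2 in per_cell.iterrows():
            if c2 == c:
                continue
            d = great_circle_distance(
                per_cell.loc[c, "lon"], per_cell.loc[c, "lat"], r2["lon"], r2["lat"]
            )
            if d <= 300.0:
                vals.append(r2["m"])
        expected = np.mean(vals) if vals else 0.0
        assert rac[i] == pytest.approx(expected, abs=1e-12)


def test_rac_observation_collapse_weights_by_observations(rng):
    t = pd.DataFrame(
        {
            "cell_id": [0, 0, 0, 1],  # cell 0 hosts 3 species, cell 1 one
            "lon": [0.0, 0.0, 0.0, 0.9],
            "lat": [0.0, 0.0, 0.0, 0.0],
        }
    )
    resid = np.array([1.0, 2.0, 3.0, 10.0])
    rac_cell, _ = rac_covariate(t, resid, ModelParams(rac_radius_km=300, rac_collapse="cell"))
    rac_obs, _ = rac_covariate(
        t, resid, ModelParams(rac_radius_km=300, rac_collapse="observation")
    )
    # neighbor of cell 1 is cell 0: mean-of-cell 2.0 either way here;
    # neighbor of cell 0 is cell 1 with a single observation
    assert rac_cell[:3] == pytest.approx([10.0] * 3)
    assert rac_cell[3] == pytest.approx(2.0)
    assert rac_obs[3] == pytest.approx((1 + 2 + 3) / 3)


def test_rac_zero_column_leaves_base_coefficients(rng):
    tab = simulate_observation_table(9, side=10, n_species=5)
    base = fit_logistic_glmm(tab, ("x1", "x2", "x3"), (RandomEffect("species"),))
    tab["rac_z"] = 0.0
    ext = fit_rac_model(tab, ("x1", "x2", "x3"), (RandomEffect("species"),))
    i = [ext.fixed_names.index(n) for n in base.fixed_names]
    assert np.abs(ext.beta[i] - base.beta).max() < 1e-6


def test_rac_detects_strong_spatial_field():
    from scipy.ndimage import gaussian_filter

    n_sig = 0
    for rep in range(5):
        r = np.random.default_rng(300 + rep)
        side = 14
        field = gaussian_filter(r.standard_normal((side, side)), 2.0, mode="wrap")
        field = 1.5 * (field - field.mean()) / field.std()
        tab = simulate_observation_table(300 + rep, side=side, spatial_field=field)
        fit = fit_logistic_glmm(tab, ("x1", "x2", "x3"), (RandomEffect("species"),))
        resid = deviance_residuals(fit)
        tab["rac"], _ = rac_covariate(tab, resid, ModelParams(rac_radius_km=300))
        tab = transform_standardize(tab, [CovariateSpec("rac")])
        ext = fit_rac_model(tab, ("x1", "x2", "x3"), (RandomEffect("species"),))
        i = ext.fixed_names.index("rac_z")
        n_sig += ext.beta[i] / ext.se_beta[i] > 1.96
    assert n_sig >= 4


def test_fit_rac_model_requires_rac_column():
    tab = simulate_observation_table(9, side=8, n_species=4)
    with pytest.raises(ValueError, match="rac"):
        fit_rac_model(tab, ("x1",), (RandomEffect("species"),))


# -- summaries --------------------------------------------------------------

def _stub_fit(beta, se, names, eta=None, varcomp=None):
    n = 2 if eta is None else len(eta)
    eta = np.zeros(n) if eta is None else np.asarray(eta, dtype=float)
    return GlmmFit(
        fixed_names=list(names),
        beta=np.asarray(beta, dtype=float),
        se_beta=np.asarray(se, dtype=float),
        vcov_beta=np.diag(np.asarray(se, dtype=float) ** 2),
        variance_components=varcomp or {},
        random_effects={},
        fitted=expit(eta),
        eta_fixed=eta,
        y=np.zeros(n, dtype=int),
        loglik=0.0,
        converged=True,
        n_obs=n,
    )


def test_odds_summary_closed_forms():
    fit = _stub_fit([0.0, np.log(2.0), 0.2], [0.1, 0.0, 0.015], ["a", "b", "c"])
    out = odds_effect_summary(fit, terms=["a", "b", "c"])
    assert out.loc[0, "pct_odds_change"] == pytest.approx(0.0)
    assert out.loc[1, "pct_odds_change"] == pytest.approx(100.0)
    assert out.loc[1, "ci_low"] == pytest.approx(100.0)  # degenerate CI
    assert out.loc[2, "pct_odds_change"] == pytest.approx(22.14, abs=0.005)
    assert out.loc[2, "ci_low"] == pytest.approx(18.60, abs=0.01)
    assert out.loc[2, "ci_high"] == pytest.approx(25.78, abs=0.01)
    # CI brackets the estimate; sign agreement
    assert (out.ci_low <= out.pct_odds_change).all()
    assert (out.pct_odds_change <= out.ci_high).all()


def test_pseudo_r2_closed_forms():
    # no explained variance at all
    z = _stub_fit([0.0], [1.0], ["a"], eta=np.zeros(10))
    r = pseudo_r2(z)
    assert r.marginal == 0.0 and r.conditional == 0.0
    # fixed-effect variance equal to the logistic distribution variance
    a = np.sqrt(LOGIT_RESIDUAL_VARIANCE / 2.0)
    r2 = pseudo_r2(_stub_fit([1.0], [0.1], ["a"], eta=[-a, a]))
    assert r2.marginal == pytest.approx(0.5, abs=1e-12)
    assert r2.conditional == pytest.approx(0.5, abs=1e-12)
    # var_f = 1, var_r = 2
    fit3 = _stub_fit(
        [1.0], [0.1], ["a"], eta=[-np.sqrt(0.5), np.sqrt(0.5)],
        varcomp={("species", "1"): 2.0},
    )
    r3 = pseudo_r2(fit3)
    assert r3.marginal == pytest.approx(0.1590, abs=1e-4)
    assert r3.conditional == pytest.approx(0.4770, abs=1e-4)
    assert 0.0 <= r3.marginal <= r3.conditional <= 1.0


def test_region_profiles_zero_variance_collapse_to_fixed():
    tab = simulate_observation_table(21, side=10, n_species=6)
    tab["region"] = (tab.cell_id % 3).astype(int)
    fit = fit_logistic_glmm(
        tab, ("x1", "x2", "x3"),
        (RandomEffect("species"), RandomEffect("region", terms=("1", "x1"))),
        fix_theta=[1.0, 0.0, 0.0],  # region variances pinned to zero
    )
    prof = region_effect_profiles(fit)
    for _, r in prof.iterrows():
        i = fit.fixed_names.index(r.term)
        assert r.combined == pytest.approx(fit.beta[i], abs=1e-9)
        assert r.pi_high - r.pi_low == pytest.approx(2 * 1.96 * fit.se_beta[i], rel=1e-9)


def test_region_profiles_pi_wider_than_fixed_ci_and_sign_recovery():
    hits, total = 0, 0
    for rep in range(8):
        r = np.random.default_rng(900 + rep)
        n = 2500
        x1 = r.standard_normal(n)
        sp = r.integers(0, 8, n)
        reg = r.integers(0, 4, n)
        offs = np.array([0.5, -0.5, 0.5, -0.5])
        eta = -0.2 + (0.3 + offs[reg]) * x1 + r.normal(0, 1, 8)[sp]
        y = (r.random(n) < expit(eta)).astype(int)
        t = pd.DataFrame({"y": y, "x1": x1, "species": sp, "region": reg})
        fit = fit_logistic_glmm(
            t, ("x1",), (RandomEffect("species"), RandomEffect("region", terms=("1", "x1")))
        )
        prof = region_effect_profiles(fit)
        slopes = prof[prof.term == "x1"].sort_values("level")
        hits += int((np.sign(slopes["mode"].to_numpy()) == np.sign(offs)).sum())
        total += 4
        for _, row in prof.iterrows():
            i = fit.fixed_names.index(row.term)
            assert row.pi_high - row.pi_low >= 2 * 1.96 * fit.se_beta[i] - 1e-9
    assert hits / total >= 0.90


def test_compare_models_identity_and_mismatch():
    tab = simulate_observation_table(31, side=10, n_species=6)
    fit = fit_logistic_glmm(tab, ("x1", "x2", "x3"), (RandomEffect("species"),))
    cmp_same = compare_models(fit, fit)
    assert cmp_same["delta_marginal"] == 0.0
    assert cmp_same["delta_conditional"] == 0.0
    other = simulate_observation_table(32, side=9, n_species=6)
    fit2 = fit_logistic_glmm(other, ("x1", "x2", "x3"), (RandomEffect("species"),))
    with pytest.raises(ValueError, match="same observations"):
        compare_models(fit, fit2)


def test_compare_models_region_truth_increases_conditional_r2():
    deltas = []
    for rep in range(5):
        r = np.random.default_rng(700 + rep)
        n = 3000
        x1 = r.standard_normal(n)
        sp = r.integers(0, 8, n)
        reg = r.integers(0, 5, n)
        offs = r.normal(0, 0.6, 5)
        eta = -0.2 + 0.4 * x1 + r.normal(0, 1, 8)[sp] + offs[reg]
        y = (r.random(n) < expit(eta)).astype(int)
        t = pd.DataFrame({"y": y, "x1": x1, "species": sp, "region": reg})
        base = fit_logistic_glmm(t, ("x1",), (RandomEffect("species"),))
        ext = fit_logistic_glmm(
            t, ("x1",), (RandomEffect("species"), RandomEffect("region"))
        )
        deltas.append(compare_models(base, ext)["delta_conditional"])
    assert np.mean(deltas) > 0.0
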