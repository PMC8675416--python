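"""Per-site vertex-wise GLM: design construction, OLS, effect sizes."""

import numpy as np
import pytest
from scipy import stats as sps

from shapemeta.mesh_io import SubjectRecord
from shapemeta.shape_measures import VertexMeasureMap
from shapemeta.site_glm import (
    MODELS,
    DesignError,
    VertexwiseGLM,
    build_design_matrix,
    effect_size_from_t,
    fit_vertexwise,
    t_pvalues,
)


def _records(n, rng, site="s0", dx_split=0.5, with_cpz=True):
    out = []
    for i in range(n):
        dx = int(i < n * dx_split)
        out.append(SubjectRecord(
            subject_id=f"sub{i:03d}", site_id=site, dx=dx,
            age=float(rng.uniform(18, 60)), sex=int(rng.random() < 0.5),
            icv=float(rng.normal(1.5e6, 1.5e5)),
            cpz=float(rng.lognormal(5.7, 0.5)) if dx and with_cpz else None,
            saps_total=float(rng.uniform(0, 40)) if dx else None))
    return out


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def test_design_has_eight_labeled_columns(rng):
    X, labels, used, info = build_design_matrix(_records(20, rng),
                                                MODELS["m1_dx_thickness"])
    assert labels == ["intercept", "predictor", "sex", "age", "age_x_sex",
                      "age2", "age2_x_sex", "icv"]
    assert X.shape == (20, 8)
    assert set(np.unique(X[:, 1])) <= {0.0, 1.0}
    assert info["usable"] and info["rank_ok"]
    # age centred at the site mean before powers
    assert abs(X[:, 3].mean()) < 1e-9


def test_single_sex_site_flagged_rank_deficient(rng):
    records = _records(20, rng)
    records = [SubjectRecord(r.subject_id, r.site_id, r.dx, r.age, 1, r.icv)
               for r in records]
    X, _, _, info = build_design_matrix(records, MODELS["m1_dx_thickness"])
    assert not info["usable"] and not info["rank_ok"]


def test_patients_only_filter_excludes_controls(rng):
    records = _records(40, rng)
    X, _, used, info = build_design_matrix(records, MODELS["m5_cpz"])
    assert all(r.dx == 1 for r in used)
    assert info["n2"] == 0 and info["n1"] == len(used)


def test_missing_cpz_rows_dropped_and_counted(rng):
    records = _records(40, rng, with_cpz=False)
    # give cpz to only 12 patients
    for r in records[:12]:
        r.cpz = 300.0
    X, _, used, info = build_design_matrix(records, MODELS["m5_cpz"])
    assert info["n_dropped"] == 8  # 20 patients - 12 with dose
    assert len(used) == 12


def test_small_sites_unusable(rng):
    X, _, _, info = build_design_matrix(_records(8, rng),
                                        MODELS["m1_dx_thickness"])
    assert not info["usable"]
    X, _, _, info = build_design_matrix(_records(20, rng, dx_split=0.1),
                                        MODELS["m1_dx_thickness"])
    assert not info["usable"] and "group" in info["reason"]


# ---------------------------------------------------------------------------
# vertex-wise OLS
# ---------------------------------------------------------------------------


def test_exact_recovery_with_zero_noise(rng):
    records = _records(50, rng)
    spec = MODELS["m1_dx_thickness"]
    X, _, used, info = build_design_matrix(records, spec)
    true_beta = np.array([2.0, -0.4, 0.1, 0.02, -0.01, 1e-3, -5e-4, 1e-7])
    Y = (X @ true_beta)[:, None]
    stats = fit_vertexwise(X, Y, spec, n1=info["n1"], n2=info["n2"])
    assert abs(stats.beta[0] - true_beta[1]) < 1e-10


def test_matches_independent_normal_equations_oracle(rng):
    """200 subjects x 100 vertices vs an explicit per-vertex solver."""
    records = _records(200, rng)
    spec = MODELS["m1_dx_thickness"]
    X, _, used, info = build_design_matrix(records, spec)
    Y = 2.0 + 0.1 * X[:, 1:2] + rng.normal(size=(200, 100))
    stats = fit_vertexwise(X, Y, spec, n1=info["n1"], n2=info["n2"])

    for v in range(Y.shape[1]):  # brute-force oracle, one vertex at a time
        beta_v = np.linalg.solve(X.T @ X, X.T @ Y[:, v])
        resid = Y[:, v] - X @ beta_v
        sigma2 = resid @ resid / (200 - 8)
        se_v = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(stats.beta[v] - beta_v[1]) < 1e-8
        assert abs(stats.se_beta[v] - se_v) < 1e-8
        assert abs(stats.t[v] - beta_v[1] / se_v) < 1e-8


def test_matches_statsmodels_ols(rng):
    sm = pytest.importorskip("statsmodels.api")
    records = _records(60, rng)
    spec = MODELS["m1_dx_thickness"]
    X, _, used, info = build_design_matrix(records, spec)
    y = rng.normal(size=60) + 0.3 * X[:, 1]
    stats = fit_vertexwise(X, y[:, None], spec, n1=info["n1"], n2=info["n2"])
    fit = sm.OLS(y, X).fit()
    assert abs(stats.beta[0] - fit.params[1]) < 1e-10
    assert abs(stats.t[0] - fit.tvalues[1]) < 1e-10
    assert abs(t_pvalues(stats)[0] - fit.pvalues[1]) < 1e-12


def test_null_pvalues_uniform_and_calibrated(rng):
    """Null simulation: p-values uniform (KS) and type-I error in bounds."""
    records = _records(100, rng)
    spec = MODELS["m1_dx_thickness"]
    X, _, used, info = build_design_matrix(records, spec)
    n_fits = 2500
    Y = rng.normal(size=(100, n_fits))  # outcome independent of dx
    stats = fit_vertexwise(X, Y, spec, n1=info["n1"], n2=info["n2"])
    p = t_pvalues(stats)
    assert sps.kstest(p, "uniform").pvalue > 0.01
    alpha = (p < 0.05).mean()
    bound = 2.5758 * np.sqrt(0.05 * 0.95 / n_fits)  # binomial 99%
    assert abs(alpha - 0.05) < bound


def test_outcome_shift_and_icv_rescale_invariance(rng):
    records = _records(80, rng)
    spec = MODELS["m1_dx_thickness"]
    X, _, used, info = build_design_matrix(records, spec)
    y = rng.normal(size=(80, 1))
    s0 = fit_vertexwise(X, y, spec, n1=info["n1"], n2=info["n2"])
    s1 = fit_vertexwise(X, y + 7.5, spec, n1=info["n1"], n2=info["n2"])
    assert abs(s0.t[0] - s1.t[0]) < 1e-9 and abs(s0.d[0] - s1.d[0]) < 1e-9
    X2 = X.copy()
    X2[:, 7] *= 1e-6  # ICV in different units
    s2 = fit_vertexwise(X2, y, spec, n1=info["n1"], n2=info["n2"])
    assert abs(s0.t[0] - s2.t[0]) < 1e-8


def test_subject_alignment_by_id(rng, toy_atlas):
    records = _records(30, rng)
    n = toy_atlas.n_vertices("hippocampus")
    maps = [VertexMeasureMap(r.subject_id, "hippocampus", "L", "thickness",
                             np.full(n, 2.0) + 0.3 * r.dx)
            for r in records]
    res = VertexwiseGLM(records, maps[::-1], MODELS["m1_dx_thickness"]).fit()
    assert res.stats.usable
    assert np.allclose(res.stats.beta, 0.3, atol=1e-10)
    with pytest.raises(DesignError, match="no measure map"):
        VertexwiseGLM(records, maps[:-1], MODELS["m1_dx_thickness"]).fit()


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------


def test_effect_size_zero_t():
    d, var_d = effect_size_from_t(0.0, 50, 50, 92)
    assert d == 0.0
    assert var_d == pytest.approx(100 / 2500)


def test_effect_size_two_group_formula():
    d, var_d = effect_size_from_t(2.0, 50, 50, 92)
    expected_d = 2.0 * 100 / (np.sqrt(2500) * np.sqrt(92))
    assert d == pytest.approx(expected_d, rel=1e-12)
    assert var_d == pytest.approx(100 / 2500 + expected_d ** 2 / 200, rel=1e-12)


def test_effect_size_matches_adjusted_mean_difference(rng):
    """Monte-Carlo oracle: d-from-t agrees with the covariate-adjusted
    standardized mean difference computed directly on simulated data."""
    true_delta = 0.5  # standardized group difference
    ds = []
    for rep in range(200):
        records = _records(100, rng)
        spec = MODELS["m1_dx_thickness"]
        X, _, used, info = build_design_matrix(records, spec)
        y = true_delta * X[:, 1] + 0.1 * X[:, 2] + rng.normal(size=100)
        s = fit_vertexwise(X, y[:, None], spec, n1=info["n1"], n2=info["n2"])
        ds.append(s.d[0])
    mc_se = np.std(ds, ddof=1) / np.sqrt(len(ds))
    assert abs(np.mean(ds) - true_delta) < 4 * mc_se + 0.02


def test_effect_size_sign_preservation(rng):
    t = rng.normal(scale=3.0, size=200)
    d2, _ = effect_size_from_t(t, 30, 40, 60)
    dc, _ = effect_size_from_t(t, 70, 0, 60)
    assert np.all(np.sign(d2) == np.sign(t))
    assert np.all(np.sign(dc) == np.sign(t))


def test_effect_size_continuous_conversion():
    t, df = 2.5, 100
    r = t / np.sqrt(t ** 2 + df)
    d, var_d = effect_size_from_t(t, 100, 0, df)
    assert d == pytest.approx(2 * r / np.sqrt(1 - r ** 2), rel=1e-12)
    assert var_d == pytest.approx(4 / (df + 2) * (1 / (1 - r ** 2)) ** 2,
                                  rel=1e-12)


def test_effect_size_df_validation():
    with pytest.raises(ValueError):
        effect_size_from_t(1.0, 10, 10, 0)


from hypothesis import given, settings  # noqa: E402
from hypothesis import strategies as st  # noqa: E402


@settings(derandomize=True, max_examples=200)
@given(st.floats(-50, 50), st.integers(2, 500), st.integers(0, 500),
       st.integers(2, 900))
def test_effect_size_properties(t, n1, n2, df):
    """Properties of the d-from-t conversion: sign preservation, positive
    variance, and monotonicity in t."""
    d, var_d = effect_size_from_t(t, n1, n2, df)
    assert np.sign(d) == np.sign(t)
    assert var_d > 0
    d2, _ = effect_size_from_t(t + 1.0, n1, n2, df)
    assert d2 > d
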