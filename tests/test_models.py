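"""Model layer: OLS against a normal-equations oracle, type II LR tests
against brute-force refits, relative likelihood algebra, and the within-study
slope machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pstfst.models import (
    CongruenceModel,
    fit_global_models,
    fit_method_models,
    fit_proportion_model,
    fit_within_study_model,
    fst_congruence_report,
    relative_likelihood,
    winnow_combos,
)
from pstfst.studydb import within_study_rows
from pstfst.synthetic import DatabaseGenConfig, simulate_study_database

# -- independent oracles ------------------------------------------------------


def normal_equations_fit(X: np.ndarray, y: np.ndarray):
    """Solve X'X beta = X'y directly; return beta and the Gaussian ML llf."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    llf = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0)
    return beta, llf


def brute_force_type2(data, response, terms):
    """Type II LR chi-squared per term by explicitly refitting both models
    through raw design matrices (patsy only used to build columns)."""
    import patsy

    out = {}
    for term in terms:
        term_parts = set(term.split(":"))
        background = [
            t for t in terms if not term_parts <= set(t.split(":"))
        ]
        chis = []
        for sub in (background + [term], background):
            formula = f"{response} ~ " + (" + ".join(sub) if sub else "1")
            y, X = patsy.dmatrices(formula, data)
            _, llf = normal_equations_fit(np.asarray(X), np.asarray(y).ravel())
            chis.append(llf)
        out[term] = 2.0 * (chis[0] - chis[1])
    return out


# -- CongruenceModel ----------------------------------------------------------


def test_fit_matches_normal_equations_oracle(six_row_table):
    terms = ["logit_fst_nonneutral", "logit_prop_nonneutral"]
    fit = CongruenceModel(six_row_table, "logit_pst", terms).fit()
    X = np.column_stack(
        [
            np.ones(6),
            six_row_table.logit_fst_nonneutral,
            six_row_table.logit_prop_nonneutral,
        ]
    )
    beta, llf = normal_equations_fit(X, six_row_table.logit_pst.to_numpy())
    assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
    assert fit.log_likelihood == pytest.approx(llf, abs=1e-10)
    assert fit.aic == pytest.approx(2 * 4 - 2 * llf, abs=1e-10)
    assert fit.n_parameters == 4  # intercept + 2 slopes + error variance


def test_perfect_fit_recovers_identity(six_row_table):
    data = six_row_table.assign(logit_pst=six_row_table.logit_fst_nonneutral)
    fit = CongruenceModel(data, "logit_pst", ["logit_fst_nonneutral"]).fit()
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.params["logit_fst_nonneutral"] == pytest.approx(1.0, abs=1e-10)


def test_null_predictor_slope_within_three_se():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        {"logit_pst": rng.normal(size=500), "logit_fst_nonneutral": rng.normal(size=500)}
    )
    fit = CongruenceModel(data, "logit_pst", ["logit_fst_nonneutral"]).fit()
    slope, se = fit.params["logit_fst_nonneutral"], fit.bse["logit_fst_nonneutral"]
    assert abs(slope) < 3 * se


def test_rank_deficiency_and_small_n_errors(six_row_table):
    dup = six_row_table.assign(dup_col=six_row_table.logit_fst_nonneutral)
    with pytest.raises(ValueError, match="aliased"):
        CongruenceModel(dup, "logit_pst", ["logit_fst_nonneutral", "dup_col"]).fit()
    tiny = six_row_table.head(2)
    with pytest.raises(ValueError, match="too few rows"):
        CongruenceModel(tiny, "logit_pst", ["logit_fst_nonneutral", "logit_prop_nonneutral"]).fit()


def test_from_formula_matches_explicit_terms(six_row_table):
    a = CongruenceModel.from_formula(
        "logit_pst ~ logit_fst_nonneutral + logit_prop_nonneutral", six_row_table
    ).fit()
    b = CongruenceModel(
        six_row_table, "logit_pst", ["logit_fst_nonneutral", "logit_prop_nonneutral"]
    ).fit()
    assert a.params.equals(b.params)


# -- type II LR tests ---------------------------------------------------------


def test_type2_single_predictor_reduces_to_nested_lr(six_row_table):
    model = CongruenceModel(six_row_table, "logit_pst", ["logit_fst_nonneutral"])
    fit = model.fit()
    (test,) = model.lr_test_type2()
    null = model.fit_intercept_only()
    assert test.chi_squared == pytest.approx(
        2 * (fit.log_likelihood - null.log_likelihood), abs=1e-10
    )
    assert test.df == 1


@pytest.mark.parametrize(
    "terms",
    [
        ["logit_fst_nonneutral", "logit_prop_nonneutral",
         "logit_fst_nonneutral:logit_prop_nonneutral"],
        ["C(marker)", "logit_fst_nonneutral", "C(marker):logit_fst_nonneutral"],
    ],
)
def test_type2_matches_brute_force_refits(default_db_rows, terms):
    model = CongruenceModel(default_db_rows, "logit_pst", terms)
    tests = {t.term: t for t in model.lr_test_type2()}
    oracle = brute_force_type2(model.data, "logit_pst", terms)
    for term, expected in oracle.items():
        assert tests[term].chi_squared == pytest.approx(expected, abs=1e-8)
        assert tests[term].chi_squared >= -1e-8


def test_type2_orthogonal_null_term_is_zero():
    # orthogonal design: y = 2*x1 + e with e orthogonal to x2 (and x1), so the
    # x2 coefficient is exactly zero and adding x2 changes the likelihood not at all
    x1 = np.array([-1.0, -1.0, 1.0, 1.0] * 2)
    x2 = np.array([-1.0, 1.0, -1.0, 1.0] * 2)
    e = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
    data = pd.DataFrame({"y": 2 * x1 + e, "x1": x1, "x2": x2})
    tests = {t.term: t for t in CongruenceModel(data, "y", ["x1", "x2"]).lr_test_type2()}
    assert tests["x2"].chi_squared == pytest.approx(0.0, abs=1e-8)


def test_nested_likelihood_monotonicity(default_db_rows):
    terms = ["logit_fst_nonneutral", "logit_prop_nonneutral",
             "logit_fst_nonneutral:logit_prop_nonneutral"]
    model = CongruenceModel(default_db_rows, "logit_pst", terms)
    llf_by_size: dict[int, list[tuple[set, float]]] = {}
    for k in range(len(terms) + 1):
        for sub in itertools.combinations(terms, k):
            llf_by_size.setdefault(k, []).append(
                (set(sub), model._fit_terms(list(sub)).log_likelihood)
            )
    for k in range(len(terms)):
        for sub, llf_sub in llf_by_size[k]:
            for sup, llf_sup in llf_by_size[k + 1]:
                if sub <= sup:
                    assert llf_sup >= llf_sub - 1e-8


def test_order_invariance(default_db_rows):
    shuffled = default_db_rows.sample(frac=1.0, random_state=7).reset_index(drop=True)
    a = fit_global_models(default_db_rows)
    b = fit_global_models(shuffled)
    assert a.nonneutral_slope == pytest.approx(b.nonneutral_slope, abs=1e-10)
    assert a.relative_likelihood_neutral == pytest.approx(
        b.relative_likelihood_neutral, rel=1e-10
    )


# -- relative likelihood ------------------------------------------------------


def test_relative_likelihood_algebra(six_row_table, default_db_rows):
    fit = CongruenceModel(six_row_table, "logit_pst", ["logit_fst_nonneutral"]).fit()
    assert relative_likelihood(fit, fit) == pytest.approx(1.0)

    nn = CongruenceModel(default_db_rows, "logit_pst", ["logit_fst_nonneutral"]).fit()
    neu = CongruenceModel(default_db_rows, "logit_pst", ["logit_fst_neutral"]).fit()
    ab = relative_likelihood(nn, neu)
    ba = relative_likelihood(neu, nn)
    assert ab * ba == pytest.approx(1.0, rel=1e-12)
    # equal parameter counts: reduces to exp(llf_b - llf_a)
    assert ab == pytest.approx(math.exp(neu.log_likelihood - nn.log_likelihood), rel=1e-12)

    with pytest.raises(ValueError, match="not comparable"):
        relative_likelihood(fit, nn)


def test_relative_likelihood_ln200_identity(six_row_table):
    # two equal-complexity fits with llf difference ln 200 give ratio 1/200
    fit = CongruenceModel(six_row_table, "logit_pst", ["logit_fst_nonneutral"]).fit()
    import dataclasses

    other = dataclasses.replace(fit, log_likelihood=fit.log_likelihood - math.log(200),
                                aic=fit.aic + 2 * math.log(200))
    assert relative_likelihood(fit, other) == pytest.approx(0.005, rel=1e-12)


# -- meta-analytic fits -------------------------------------------------------


def test_global_models_drop_missing_neutral_per_model(default_db_rows):
    rows = default_db_rows.copy()
    rows.loc[rows.index[:5], "logit_fst_neutral"] = np.nan
    report = fit_global_models(rows)
    assert report.nonneutral_fit.n_rows_used == len(rows)
    assert report.neutral_fit.n_rows_used == len(rows) - 5
    assert report.n_common == len(rows) - 5


def test_proportion_model_interaction_flow(default_db_rows):
    report = fit_proportion_model(default_db_rows)
    assert {t.term for t in report.term_tests} == {
        "logit_fst_nonneutral",
        "logit_prop_nonneutral",
        "logit_fst_nonneutral:logit_prop_nonneutral",
    }
    if not report.interaction_significant:
        assert report.reduced_fit is not None
        assert report.r_squared_without_interaction <= report.r_squared_with_interaction + 1e-12


def test_method_models_structure(default_db_rows):
    reports = fit_method_models(default_db_rows)
    assert set(reports) == {"common_garden", "marker", "method", "analysis_group"}
    marker = reports["marker"]
    # haplotype/window fold into snp: marker factor has <= 4 levels
    tested_terms = [t.term for t in marker.term_tests]
    assert "C(marker)" in tested_terms and "logit_prop_nonneutral" in tested_terms
    factor_test = next(t for t in marker.term_tests if t.term == "C(marker)")
    assert factor_test.df == marker.fit.model.data["marker"].nunique() - 1


def test_method_factor_power_under_null_and_alternative():
    """Factor tests: quiet when levels share one intercept, loud when marker
    classes shift the intercept by +/-0.5 (simulation, 200 replicates each)."""
    null_sig, alt_sig = 0, 0
    n_rep = 200
    for i in range(n_rep):
        null_cfg = DatabaseGenConfig(seed=10_000 + i)
        alt_cfg = DatabaseGenConfig(
            seed=50_000 + i,
            factor_effects={
                "marker": {"aflp": 0.5, "msat": -0.5, "qtl": 0.5, "snp": -0.5}
            },
        )
        for cfg, bucket in ((null_cfg, "null"), (alt_cfg, "alt")):
            from pstfst.studydb import average_per_comparison, to_model_rows

            rows = to_model_rows(average_per_comparison(simulate_study_database(cfg)))
            rep = fit_method_models(rows, factors=["marker"])["marker"]
            p = next(t for t in rep.term_tests if t.term == "C(marker)").p_value
            if bucket == "null" and p <= 0.05:
                null_sig += 1
            if bucket == "alt" and p < 0.05:
                alt_sig += 1
    assert null_sig <= 0.10 * n_rep  # p > 0.05 in >= 90% of null replicates
    assert alt_sig >= 0.90 * n_rep  # significant in >= 90% under the alternative


# -- within-study analysis ----------------------------------------------------


def make_within_rows(n_combos=4, n_points=6, seed=0):
    cfg = DatabaseGenConfig(
        n_papers=n_combos, comparisons_per_paper=n_points, seed=seed, slope_sd=0.1
    )
    return within_study_rows(simulate_study_database(cfg))


def test_winnow_combos_threshold():
    rows = make_within_rows(n_combos=3, n_points=5)
    short = rows.groupby("combo_id").head(4)  # every combo cut to 4 points
    kept, n = winnow_combos(short, min_points=5)
    assert n == 0 and kept.empty
    kept, n = winnow_combos(rows, min_points=5)
    assert n == 3 and len(kept) == 15


def test_within_study_model_slopes_and_r2():
    rows = make_within_rows(n_combos=6, n_points=8, seed=2)
    winnowed, n = winnow_combos(rows)
    report = fit_within_study_model(winnowed)
    assert len(report.slopes) == n == report.summary.n_combos
    for s in report.slopes:
        assert s.n_points == 8
        assert s.df == report.fit.df_resid
        assert s.t == pytest.approx(s.beta / s.se)
    betas = [s.beta for s in report.slopes]
    assert report.summary.mean_slope == pytest.approx(np.mean(betas))
    assert report.summary.se_of_slopes == pytest.approx(
        np.std(betas, ddof=1) / math.sqrt(n)
    )


def test_within_study_detects_collinear_combo():
    rows = make_within_rows(n_combos=2, n_points=5)
    combo = rows.combo_id.iloc[0]
    rows.loc[rows.combo_id == combo, "logit_fst_nonneutral"] = -2.0
    with pytest.raises(ValueError, match="no variation"):
        fit_within_study_model(rows)


# -- F_ST congruence ----------------------------------------------------------


def test_fst_congruence_identical_and_independent_columns():
    rng = np.random.default_rng(3)
    x = rng.normal(size=400)
    same = pd.DataFrame({"logit_fst_neutral": x, "logit_fst_nonneutral": x})
    assert fst_congruence_report(same).pearson_r == pytest.approx(1.0)
    indep = pd.DataFrame(
        {"logit_fst_neutral": x, "logit_fst_nonneutral": rng.normal(size=400)}
    )
    assert abs(fst_congruence_report(indep).pearson_r) < 0.15
    with pytest.raises(ValueError, match="fewer than 3"):
        fst_congruence_report(same.head(2))


def test_fst_congruence_with_shared_latent_divergence(default_db_rows):
    # generator couples the two F_ST kinds through a shared latent logit
    assert fst_congruence_report(default_db_rows).pearson_r > 0.8
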