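"""Linear models of P_ST - F_ST congruence on the logit scale.

The central object is :class:`CongruenceModel`, a Gaussian identity-link
ordinary-least-squares model over the logit-transformed modeling table, whose
:meth:`~CongruenceModel.fit` returns a :class:`CongruenceResults` carrying
coefficients, standard errors, the maximum (Gaussian) log-likelihood, AIC,
R-squared, and marginality-respecting type II likelihood-ratio term tests.

On top of the Model/Results pair sit the four meta-analytic fits:

* :func:`fit_global_models` — logit(P_ST) on logit(nnF_ST) and, separately,
  on logit(neutral F_ST), compared by relative likelihood;
* :func:`fit_proportion_model` — adds the logit proportion of non-neutral
  loci and its interaction with logit(nnF_ST);
* :func:`fit_method_models` — one model per methodological factor
  (common-garden rearing, marker type, method, software group) with
  factor-specific intercepts and slopes;
* :func:`fit_within_study_model` — combo-specific (paper x phenotype x
  method) intercepts and slopes with a single shared proportion-of-loci
  slope, plus per-combo t tests and the slope-distribution summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CongruenceModel",
    "CongruenceResults",
    "TermTest",
    "SlopeEstimate",
    "WithinStudySummary",
    "GlobalModelsReport",
    "ProportionModelReport",
    "MethodModelReport",
    "WithinStudyReport",
    "FstCongruenceReport",
    "DEFAULT_MARKER_MAP",
    "METHOD_FACTORS",
    "relative_likelihood",
    "fit_global_models",
    "fit_proportion_model",
    "fit_method_models",
    "winnow_combos",
    "fit_within_study_model",
    "fst_congruence_report",
]

#: Marker-class mapping applied before the marker factor enters a model:
#: microhaplotypes and sliding-window aggregates are SNP-based assays, so the
#: marker factor has the four levels {aflp, msat, qtl, snp}.
DEFAULT_MARKER_MAP: dict[str, str] = {"haplotype": "snp", "window": "snp"}

#: The methodological covariates, each tested in its own model.
METHOD_FACTORS = ("common_garden", "marker", "method", "analysis_group")


@dataclass(frozen=True)
class TermTest:
    """Type II likelihood-ratio test for one model term."""

    term: str
    chi_squared: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class SlopeEstimate:
    """One combo-specific P_ST - nnF_ST slope from the within-study model."""

    combo_id: str
    beta: float
    se: float
    t: float
    df: int
    p_value: float
    n_points: int
    r_squared: float  # about the combo's own response mean; may be negative


@dataclass(frozen=True)
class WithinStudySummary:
    """Distribution of the within-study slopes: unweighted mean and its SE."""

    mean_slope: float
    se_of_slopes: float
    n_combos: int


def _term_components(term: str) -> frozenset[str]:
    return frozenset(part.strip() for part in term.split(":"))


def _contains(container: str, contained: str) -> bool:
    """True if term ``container`` is a (possibly equal) superset of ``contained``."""
    return _term_components(contained) <= _term_components(container)


class CongruenceModel:
    """Gaussian OLS model of a logit response on main effects and interactions.

    Parameters
    ----------
    data:
        Modeling table (one row per comparison or per observation).
    response:
        Column name of the response (e.g. ``"logit_pst"``).
    terms:
        Patsy term strings — continuous columns, ``C(factor)`` for
        categorical covariates, and ``a:b`` interactions.  Terms may only
        interact with other declared terms' variables.
    include_intercept:
        If False the model is fit without a global intercept (used by the
        within-study model, where the combo factor supplies the intercepts).

    Rows with a missing value in any variable used by any term are dropped
    once, up front, so every nested sub-fit (intercept-only and the type II
    reduced models) is computed on exactly the same rows.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        terms: Sequence[str],
        include_intercept: bool = True,
    ):
        if response not in data.columns:
            raise ValueError(f"response column {response!r} not in data")
        self.response = response
        self.terms = list(terms)
        self.include_intercept = include_intercept
        # Complete cases over everything the full model touches
        full_formula = self._formula(self.terms)
        y, X = patsy.dmatrices(full_formula, data, return_type="dataframe")
        self.data = data.loc[X.index].copy()
        self.n_rows_used = len(self.data)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "CongruenceModel":
        """Build from an R-style formula, e.g. ``"logit_pst ~ logit_fst_nonneutral"``."""
        lhs, rhs = formula.split("~", 1)
        terms = [t.strip() for t in rhs.split("+")]
        include_intercept = True
        clean: list[str] = []
        for t in terms:
            if t in ("0", "-1"):
                include_intercept = False
            elif t == "1":
                pass
            else:
                clean.append(t)
        return cls(data, lhs.strip(), clean, include_intercept=include_intercept)

    # -- design construction ------------------------------------------------

    def _formula(self, terms: Sequence[str]) -> str:
        rhs = " + ".join(terms) if terms else "1"
        prefix = "" if self.include_intercept else "0 + "
        return f"{self.response} ~ {prefix}{rhs}"

    def _design(self, terms: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame]:
        y, X = patsy.dmatrices(
            self._formula(terms),
            self.data,
            return_type="dataframe",
            NA_action=patsy.NAAction(on_NA="raise"),
        )
        return np.asarray(y).ravel(), X

    @staticmethod
    def _check_rank(X: pd.DataFrame) -> None:
        arr = np.asarray(X, dtype=float)
        rank = np.linalg.matrix_rank(arr)
        if rank < arr.shape[1]:
            # name the columns whose addition does not increase the rank
            aliased = []
            r = 0
            for j in range(arr.shape[1]):
                rj = np.linalg.matrix_rank(arr[:, : j + 1])
                if rj == r:
                    aliased.append(X.columns[j])
                r = rj
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    def _fit_terms(self, terms: Sequence[str]) -> "CongruenceResults":
        y, X = self._design(terms)
        if len(y) <= X.shape[1]:
            raise ValueError(
                f"too few rows ({len(y)}) for {X.shape[1]} parameters"
            )
        self._check_rank(X)
        ols = sm.OLS(y, X).fit()
        resid = y - ols.fittedvalues
        sse = float(np.sum(resid**2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else float("nan")
        k_mean = X.shape[1]
        llf = float(ols.llf)  # Gaussian ML log-likelihood
        n_parameters = k_mean + 1  # + the error variance
        aic = 2.0 * n_parameters - 2.0 * llf
        return CongruenceResults(
            model=self,
            terms=list(terms),
            params=pd.Series(ols.params, index=X.columns),
            bse=pd.Series(ols.bse, index=X.columns),
            log_likelihood=llf,
            n_parameters=n_parameters,
            aic=aic,
            r_squared=r2,
            fittedvalues=pd.Series(ols.fittedvalues, index=X.index),
            resid=pd.Series(resid, index=X.index),
            n_rows_used=len(y),
            df_resid=int(len(y) - k_mean),
            design_columns=list(X.columns),
        )

    def fit(self) -> "CongruenceResults":
        """Fit the full model by maximum likelihood (OLS)."""
        return self._fit_terms(self.terms)

    def fit_intercept_only(self) -> "CongruenceResults":
        """Fit the null (grand-mean) model on the same rows."""
        if not self.include_intercept:
            raise ValueError("intercept-only null undefined for a no-intercept model")
        return self._fit_terms([])

    # -- type II likelihood-ratio tests --------------------------------------

    def lr_test_type2(self) -> list[TermTest]:
        """Marginality-respecting per-term likelihood-ratio tests.

        For each term T, the background model contains every term that does
        not contain T (so a main effect is never tested in the presence of
        its own interactions); chi-squared = 2 (llf(background + T) -
        llf(background)), df = number of design columns removed.
        """
        tests = []
        for term in self.terms:
            background = [t for t in self.terms if not _contains(t, term)]
            full = self._fit_terms(background + [term])
            reduced = self._fit_terms(background)
            chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
            if -1e-10 < chi2 < 0.0:  # pure rounding in a null term
                chi2 = 0.0
            df = len(full.design_columns) - len(reduced.design_columns)
            tests.append(
                TermTest(
                    term=term,
                    chi_squared=chi2,
                    df=df,
                    p_value=float(stats.chi2.sf(max(chi2, 0.0), df)),
                )
            )
        return tests


@dataclass
class CongruenceResults:
    """Fitted-model container: estimates, uncertainty, fit statistics.

    ``aic`` counts the Gaussian error variance as a parameter
    (AIC = 2(k+1) - 2 llf for k mean parameters); ``r_squared`` is
    1 - SSE/SST about the response mean.
    """

    model: CongruenceModel
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    log_likelihood: float
    n_parameters: int
    aic: float
    r_squared: float
    fittedvalues: pd.Series
    resid: pd.Series
    n_rows_used: int
    df_resid: int
    design_columns: list[str]

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index,
        )

    def lr_test_type2(self) -> list[TermTest]:
        return self.model.lr_test_type2()

    def lr_test_vs_null(self) -> TermTest:
        """Likelihood-ratio test of the whole model against intercept-only."""
        null = self.model.fit_intercept_only()
        chi2 = max(0.0, 2.0 * (self.log_likelihood - null.log_likelihood))
        df = len(self.design_columns) - 1
        return TermTest(
            term="model",
            chi_squared=chi2,
            df=df,
            p_value=float(stats.chi2.sf(chi2, df)),
        )

    def summary(self) -> str:
        lines = [
            f"Gaussian OLS: {self.model.response} ~ "
            + (" + ".join(self.terms) if self.terms else "1"),
            f"n = {self.n_rows_used}, parameters = {self.n_parameters} "
            f"(incl. error variance), df_resid = {self.df_resid}",
            f"log-likelihood = {self.log_likelihood:.4f}, AIC = {self.aic:.4f}, "
            f"R^2 = {self.r_squared:.4f}",
            "",
            f"{'coefficient':<50}{'estimate':>12}{'SE':>12}{'t':>10}{'p':>10}",
        ]
        pv = self.pvalues
        for name in self.params.index:
            lines.append(
                f"{name:<50}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{self.tvalues[name]:>10.3f}{pv[name]:>10.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.model.response,
            "terms": self.terms,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "r_squared": self.r_squared,
            "n": self.n_rows_used,
        }


def relative_likelihood(fit_a: CongruenceResults, fit_b: CongruenceResults) -> float:
    """Evidence for model B relative to model A: exp((AIC_a - AIC_b) / 2).

    Used to compare non-nested models fit to the same rows; when the two
    models have equal parameter counts this reduces to exp(llf_b - llf_a).
    """
    if fit_a.n_rows_used != fit_b.n_rows_used:
        raise ValueError(
            "models not comparable: fitted to different row counts "
            f"({fit_a.n_rows_used} vs {fit_b.n_rows_used})"
        )
    return float(math.exp((fit_a.aic - fit_b.aic) / 2.0))


# ---------------------------------------------------------------------------
# Meta-analytic fits
# ---------------------------------------------------------------------------


@dataclass
class GlobalModelsReport:
    """The two single-predictor baselines and their relative likelihood."""

    nonneutral_fit: CongruenceResults
    neutral_fit: CongruenceResults
    nonneutral_slope: float
    neutral_slope: float
    nonneutral_chi2: TermTest
    neutral_chi2: TermTest
    relative_likelihood_neutral: float  # of the neutral model w.r.t. the nn model
    n_common: int

    def to_dict(self) -> dict:
        return {
            "nonneutral": self.nonneutral_fit.to_dict(),
            "neutral": self.neutral_fit.to_dict(),
            "nonneutral_slope": self.nonneutral_slope,
            "neutral_slope": self.neutral_slope,
            "nonneutral_chi2": self.nonneutral_chi2.chi_squared,
            "neutral_chi2": self.neutral_chi2.chi_squared,
            "relative_likelihood_neutral": self.relative_likelihood_neutral,
            "n_common": self.n_common,
        }


def fit_global_models(rows: pd.DataFrame) -> GlobalModelsReport:
    """Fit logit(P_ST) on logit(nnF_ST) and on logit(neutral F_ST).

    Each baseline is fit on its own complete cases (missing neutral F_ST
    drops rows from the neutral model only); the relative likelihood is
    computed from refits on the rows where both predictors are observed, the
    only footing on which non-nested AICs are comparable.
    """
    nn_model = CongruenceModel(rows, "logit_pst", ["logit_fst_nonneutral"])
    neu_model = CongruenceModel(rows, "logit_pst", ["logit_fst_neutral"])
    nn_fit = nn_model.fit()
    neu_fit = neu_model.fit()

    common = rows.dropna(
        subset=["logit_pst", "logit_fst_nonneutral", "logit_fst_neutral"]
    )
    nn_common = CongruenceModel(common, "logit_pst", ["logit_fst_nonneutral"]).fit()
    neu_common = CongruenceModel(common, "logit_pst", ["logit_fst_neutral"]).fit()

    return GlobalModelsReport(
        nonneutral_fit=nn_fit,
        neutral_fit=neu_fit,
        nonneutral_slope=float(nn_fit.params["logit_fst_nonneutral"]),
        neutral_slope=float(neu_fit.params["logit_fst_neutral"]),
        nonneutral_chi2=nn_fit.lr_test_vs_null(),
        neutral_chi2=neu_fit.lr_test_vs_null(),
        relative_likelihood_neutral=relative_likelihood(nn_common, neu_common),
        n_common=len(common),
    )


@dataclass
class ProportionModelReport:
    """logit(P_ST) ~ logit(nnF_ST) * logit(prop non-neutral), with type II tests."""

    full_fit: CongruenceResults
    term_tests: list[TermTest]
    interaction_significant: bool
    reduced_fit: Optional[CongruenceResults]  # without the interaction, if dropped
    r_squared_with_interaction: float
    r_squared_without_interaction: float

    @property
    def final_fit(self) -> CongruenceResults:
        return self.reduced_fit if self.reduced_fit is not None else self.full_fit

    def to_dict(self) -> dict:
        return {
            "full": self.full_fit.to_dict(),
            "term_tests": [
                {"term": t.term, "chi2": t.chi_squared, "df": t.df, "p": t.p_value}
                for t in self.term_tests
            ],
            "interaction_significant": self.interaction_significant,
            "reduced": None if self.reduced_fit is None else self.reduced_fit.to_dict(),
            "r_squared_with_interaction": self.r_squared_with_interaction,
            "r_squared_without_interaction": self.r_squared_without_interaction,
        }


_NN = "logit_fst_nonneutral"
_PROP = "logit_prop_nonneutral"


def fit_proportion_model(
    rows: pd.DataFrame,
    with_interaction: bool = True,
    alpha: float = 0.05,
) -> ProportionModelReport:
    """Add the proportion of non-neutral loci to the nnF_ST baseline.

    Fits the full model with the nnF_ST x proportion interaction and runs
    type II LR tests on all three terms; if the interaction is not
    significant at ``alpha`` it is removed and the model refit, mirroring the
    analysis flow in which only first-order effects were retained.
    """
    terms = [_NN, _PROP] + ([f"{_NN}:{_PROP}"] if with_interaction else [])
    model = CongruenceModel(rows, "logit_pst", terms)
    full_fit = model.fit()
    tests = model.lr_test_type2()

    reduced_fit = None
    interaction_sig = True
    if with_interaction:
        inter = next(t for t in tests if ":" in t.term)
        interaction_sig = inter.p_value < alpha
        if not interaction_sig:
            reduced_fit = CongruenceModel(rows, "logit_pst", [_NN, _PROP]).fit()
    r2_without = (
        reduced_fit.r_squared
        if reduced_fit is not None
        else CongruenceModel(rows, "logit_pst", [_NN, _PROP]).fit().r_squared
    )
    return ProportionModelReport(
        full_fit=full_fit,
        term_tests=tests,
        interaction_significant=interaction_sig,
        reduced_fit=reduced_fit,
        r_squared_with_interaction=full_fit.r_squared if with_interaction else r2_without,
        r_squared_without_interaction=r2_without,
    )


@dataclass
class MethodModelReport:
    """One methodological factor's model: factor intercepts and slopes plus
    the shared proportion-of-loci effect."""

    factor: str
    fit: CongruenceResults
    term_tests: list[TermTest]
    sparse_levels: list[str]  # levels observed in < 2 rows, flagged not dropped

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "fit": self.fit.to_dict(),
            "term_tests": [
                {"term": t.term, "chi2": t.chi_squared, "df": t.df, "p": t.p_value}
                for t in self.term_tests
            ],
            "sparse_levels": self.sparse_levels,
        }


def fit_method_models(
    rows: pd.DataFrame,
    factors: Sequence[str] = METHOD_FACTORS,
    marker_map: Mapping[str, str] = DEFAULT_MARKER_MAP,
) -> dict[str, MethodModelReport]:
    """Fit one model per methodological covariate, each tested separately.

    Each model has factor-specific intercepts, a logit(nnF_ST) slope, a
    factor x logit(nnF_ST) interaction (factor-specific slopes), and the
    shared logit proportion-of-non-neutral-loci effect; all four terms get
    type II LR tests.  Marker classes are collapsed through ``marker_map``
    (SNP-based assays pooled) before entering the marker model.
    """
    out: dict[str, MethodModelReport] = {}
    for factor in factors:
        data = rows.copy()
        if factor == "marker":
            data["marker"] = data["marker"].map(lambda m: marker_map.get(m, m))
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has < 2 observed levels")
        counts = data[factor].value_counts()
        sparse = sorted(str(lvl) for lvl in counts[counts < 2].index)
        terms = [f"C({factor})", _NN, f"C({factor}):{_NN}", _PROP]
        model = CongruenceModel(data, "logit_pst", terms)
        out[factor] = MethodModelReport(
            factor=factor,
            fit=model.fit(),
            term_tests=model.lr_test_type2(),
            sparse_levels=sparse,
        )
    return out


def winnow_combos(
    within_rows: pd.DataFrame, min_points: int = 5
) -> tuple[pd.DataFrame, int]:
    """Keep paper x phenotype x method combos with at least ``min_points`` rows.

    Returns the filtered table and the number of combos retained; an empty
    result is permitted (no combo had enough population-pair datapoints).
    """
    counts = within_rows.groupby("combo_id")["logit_pst"].size()
    keep = counts[counts >= min_points].index
    filtered = within_rows[within_rows["combo_id"].isin(keep)].reset_index(drop=True)
    return filtered, len(keep)


@dataclass
class WithinStudyReport:
    """Joint within-study fit, per-combo slopes, and their distribution."""

    fit: CongruenceResults
    slopes: list[SlopeEstimate]
    summary: WithinStudySummary

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "slopes": [
                {
                    "combo_id": s.combo_id,
                    "beta": s.beta,
                    "se": s.se,
                    "t": s.t,
                    "df": s.df,
                    "p": s.p_value,
                    "n_points": s.n_points,
                    "r_squared": s.r_squared,
                }
                for s in self.slopes
            ],
            "mean_slope": self.summary.mean_slope,
            "se_of_slopes": self.summary.se_of_slopes,
            "n_combos": self.summary.n_combos,
        }


def fit_within_study_model(winnowed: pd.DataFrame) -> WithinStudyReport:
    """One joint model with combo-specific intercepts and nnF_ST slopes.

    Every paper x phenotype x method combo gets its own intercept and its own
    logit(nnF_ST) slope; a single shared slope is fit for the logit proportion
    of non-neutral loci.  Slopes are t-tested against zero on the joint fit's
    residual degrees of freedom (one shared error variance), and summarised by
    their unweighted mean and standard error (SD / sqrt(n_combos)).  Per-combo
    R-squared is computed about each combo's own response mean and may be
    negative when the shared proportion effect works against that combo.
    """
    if winnowed.empty:
        raise ValueError("no combos to fit (empty winnowed table)")
    for combo, grp in winnowed.groupby("combo_id"):
        if grp[_NN].nunique() < 2:
            raise ValueError(
                f"combo {combo!r}: no variation in logit(nnF_ST); "
                "slope collinear with its intercept"
            )
    model = CongruenceModel(
        winnowed,
        "logit_pst",
        ["C(combo_id)", f"C(combo_id):{_NN}", _PROP],
        include_intercept=False,
    )
    fit = model.fit()

    slopes: list[SlopeEstimate] = []
    pv = fit.pvalues
    for combo, grp in winnowed.groupby("combo_id"):
        col = next(
            c
            for c in fit.params.index
            if c.startswith("C(combo_id)[") and f"[{combo}]" in c and c.endswith(_NN)
        )
        beta = float(fit.params[col])
        se = float(fit.bse[col])
        resid_c = fit.resid.loc[grp.index]
        y_c = winnowed.loc[grp.index, "logit_pst"]
        sst_c = float(np.sum((y_c - y_c.mean()) ** 2))
        sse_c = float(np.sum(resid_c**2))
        r2_c = 1.0 - sse_c / sst_c if sst_c > 0 else float("nan")
        slopes.append(
            SlopeEstimate(
                combo_id=str(combo),
                beta=beta,
                se=se,
                t=beta / se,
                df=fit.df_resid,
                p_value=float(pv[col]),
                n_points=len(grp),
                r_squared=r2_c,
            )
        )
    betas = np.array([s.beta for s in slopes])
    n_combos = len(betas)
    se_of_mean = float(betas.std(ddof=1) / math.sqrt(n_combos)) if n_combos > 1 else float("nan")
    return WithinStudyReport(
        fit=fit,
        slopes=slopes,
        summary=WithinStudySummary(
            mean_slope=float(betas.mean()),
            se_of_slopes=se_of_mean,
            n_combos=n_combos,
        ),
    )


@dataclass
class FstCongruenceReport:
    """How tightly non-neutral F_ST tracks neutral F_ST across comparisons."""

    pearson_r: float
    slope: float
    n: int

    def to_dict(self) -> dict:
        return {"pearson_r": self.pearson_r, "slope": self.slope, "n": self.n}


def fst_congruence_report(rows: pd.DataFrame) -> FstCongruenceReport:
    """Pearson correlation and OLS slope of logit(nnF_ST) on logit(neutral F_ST)."""
    complete = rows.dropna(subset=["logit_fst_nonneutral", "logit_fst_neutral"])
    if len(complete) < 3:
        raise ValueError("fewer than 3 rows with both F_ST kinds present")
    r, _ = stats.pearsonr(
        complete["logit_fst_neutral"], complete["logit_fst_nonneutral"]
    )
    fit = CongruenceModel(
        complete, "logit_fst_nonneutral", ["logit_fst_neutral"]
    ).fit()
    return FstCongruenceReport(
        pearson_r=float(r),
        slope=float(fit.params["logit_fst_neutral"]),
        n=len(complete),
    )
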