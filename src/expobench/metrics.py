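"""The 13 performance measures comparing a selection to the true model.

Term-level measures (Sens, FDP, RMS) compare term sets exactly; variable
measures (Sensvar, FDPvar, RNV) compare the exposures involved; the
*alternative* measures credit (or discount) selected proxies through the
data-generating correlation matrix:

    AltSens  = (1/n_A) sum_{i in A} max_{j in B} |corr(X_i, X_j)|
    AltFDP   = 1 - (1/n_B) sum_{i in B} max_{j in A} |corr(X_i, X_j)|

and analogously AltSens2/AltFDP2 over the variables involved in
interaction terms (sets A2, B2).  R^2_rel is the ratio of the
out-of-sample R^2 of the fitted model to that of the true-term model on an
independent validation set.

Measures that a method cannot produce (no term set for BRT, no single
model for the two-step screen, no interaction search for LASSO/DSA1) are
reported as NaN, as is any measure whose defining set is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationModel
from .scenarios import SimulatedStudy, TrueModel
from .terms import SelectedModel, ols_fit

__all__ = [
    "SelectionComparison",
    "PerformanceReport",
    "METRIC_NAMES",
    "relative_model_size",
    "relative_number_of_variables",
    "sensitivity_terms",
    "sensitivity_variables",
    "sensitivity_interactions",
    "alt_sensitivity",
    "alt_sensitivity_interactions",
    "fdp_terms",
    "fdp_variables",
    "fdp_interactions",
    "alt_fdp",
    "alt_fdp_interactions",
    "r2_relative",
    "evaluate",
]

METRIC_NAMES = ("rms", "rnv", "r2_rel", "sens", "alt_sens", "sens_var",
                "sens2", "alt_sens2", "fdp", "alt_fdp", "fdp_var",
                "fdp2", "alt_fdp2")


@dataclass
class SelectionComparison:
    """True-vs-fitted sets plus the correlation lookup for Alt measures."""

    true_terms: frozenset
    fitted_terms: frozenset
    A: frozenset                 # true predictors
    B: frozenset                 # variables in the fitted model
    A2: frozenset                # true predictors in interaction terms
    B2: frozenset                # fitted variables in interaction terms
    corr: np.ndarray | None = None

    @classmethod
    def from_models(cls, selected: SelectedModel, true_model: TrueModel,
                    corr: CorrelationModel | np.ndarray | None = None):
        mat = corr.matrix if isinstance(corr, CorrelationModel) else corr
        return cls(
            true_terms=frozenset(true_model.terms),
            fitted_terms=frozenset(selected.terms),
            A=frozenset(true_model.predictor_indices),
            B=selected.variables,
            A2=true_model.interaction_variables,
            B2=frozenset(v for t in selected.interaction_terms
                         for v in t.variables),
            corr=None if mat is None else np.asarray(mat, float),
        )

    def _absmax_corr(self, targets, pool) -> float:
        """Mean over targets of the largest |corr| with any pool member."""
        if self.corr is None:
            raise ValueError("Alt measures need a correlation matrix")
        pool = sorted(pool)
        vals = [np.max(np.abs(self.corr[i, pool])) for i in sorted(targets)]
        return float(np.mean(vals))


@dataclass
class PerformanceReport:
    rms: float
    rnv: float
    r2_rel: float
    sens: float
    alt_sens: float
    sens_var: float
    sens2: float
    alt_sens2: float
    fdp: float
    alt_fdp: float
    fdp_var: float
    fdp2: float
    alt_fdp2: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


# -- size measures ----------------------------------------------------------

def relative_model_size(fitted: SelectedModel, true_model: TrueModel) -> float:
    """Fitted term count over true term count (intercepts excluded)."""
    n_true = len(true_model.terms)
    if n_true == 0:
        raise ValueError("true model has no terms")
    return len(fitted.terms) / n_true


def relative_number_of_variables(fitted: SelectedModel,
                                 true_model: TrueModel) -> float:
    return len(fitted.variables) / len(true_model.predictor_indices)


# -- sensitivity ------------------------------------------------------------

def sensitivity_terms(cmp: SelectionComparison) -> float:
    """Fraction of true terms present in the fitted term set."""
    if not cmp.true_terms:
        return np.nan
    return len(cmp.true_terms & cmp.fitted_terms) / len(cmp.true_terms)


def sensitivity_variables(cmp: SelectionComparison) -> float:
    """Fraction of true predictors involved in any fitted term."""
    if not cmp.A:
        return np.nan
    return len(cmp.A & cmp.B) / len(cmp.A)


def sensitivity_interactions(cmp: SelectionComparison) -> float:
    true2 = {t for t in cmp.true_terms if t.kind == "inter"}
    if not true2:
        return np.nan
    fit2 = {t for t in cmp.fitted_terms if t.kind == "inter"}
    return len(true2 & fit2) / len(true2)


def alt_sensitivity(cmp: SelectionComparison) -> float:
    if not cmp.A or not cmp.B:
        return np.nan
    return cmp._absmax_corr(cmp.A, cmp.B)


def alt_sensitivity_interactions(cmp: SelectionComparison) -> float:
    if not cmp.A2 or not cmp.B2:
        return np.nan
    return cmp._absmax_corr(cmp.A2, cmp.B2)


# -- false discovery --------------------------------------------------------

def fdp_terms(cmp: SelectionComparison) -> float:
    """Fraction of fitted terms not in the true model (0 when none fitted)."""
    if not cmp.fitted_terms:
        return 0.0
    return len(cmp.fitted_terms - cmp.true_terms) / len(cmp.fitted_terms)


def fdp_variables(cmp: SelectionComparison) -> float:
    if not cmp.B:
        return 0.0
    return len(cmp.B - cmp.A) / len(cmp.B)


def fdp_interactions(cmp: SelectionComparison) -> float:
    fit2 = {t for t in cmp.fitted_terms if t.kind == "inter"}
    if not fit2:
        return 0.0
    true2 = {t for t in cmp.true_terms if t.kind == "inter"}
    return len(fit2 - true2) / len(fit2)


def alt_fdp(cmp: SelectionComparison) -> float:
    if not cmp.B or not cmp.A:
        return np.nan
    return 1.0 - cmp._absmax_corr(cmp.B, cmp.A)


def alt_fdp_interactions(cmp: SelectionComparison) -> float:
    if not cmp.B2 or not cmp.A2:
        return np.nan
    return 1.0 - cmp._absmax_corr(cmp.B2, cmp.A2)


# -- predictive ability -----------------------------------------------------

def _oos_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("validation outcome has zero variance")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def r2_relative(results, study: SimulatedStudy) -> float:
    """Out-of-sample R^2 of the fit over that of the true-term model.

    ``results`` is a SelectionResults (its native predictor is used for the
    numerator); the denominator refits the true terms by OLS on the
    training data.  The ratio can exceed 1 or go negative.
    """
    if not results.model.predicts or results.predictor is None:
        return np.nan
    y_va = study.valid_outcome
    num = _oos_r2(y_va, results.predict(study.valid_exposures))
    true_fit = ols_fit(study.train_exposures, study.train_outcome,
                       study.true_model.terms)
    den = _oos_r2(y_va, true_fit.predict(study.valid_exposures))
    if den == 0:
        return np.nan
    return num / den


# -- aggregation ------------------------------------------------------------

def evaluate(results, study: SimulatedStudy,
             corr: CorrelationModel | np.ndarray) -> PerformanceReport:
    """All applicable measures of one fit against one simulated truth.

    ``results`` may be a SelectionResults or a bare SelectedModel (then
    r2_rel is only computed when the model carries coefficients).
    """
    from .selectors.base import SelectionResults

    if isinstance(results, SelectedModel):
        results = SelectionResults(results, predictor=None)
    selected = results.model
    tm = study.true_model
    cmp = SelectionComparison.from_models(selected, tm, corr)

    has_terms = selected.has_terms
    rms = relative_model_size(selected, tm) if has_terms else np.nan
    sens = sensitivity_terms(cmp) if has_terms else np.nan
    fdp = fdp_terms(cmp) if has_terms else np.nan

    if selected.searches_interactions and has_terms:
        sens2 = sensitivity_interactions(cmp)
        fdp2 = fdp_interactions(cmp)
        alt_sens2 = alt_sensitivity_interactions(cmp)
        alt_fdp2 = alt_fdp_interactions(cmp)
    else:
        sens2 = fdp2 = alt_sens2 = alt_fdp2 = np.nan

    if results.predictor is not None and selected.predicts:
        r2rel = r2_relative(results, study)
    else:
        r2rel = np.nan

    return PerformanceReport(
        rms=rms,
        rnv=relative_number_of_variables(selected, tm),
        r2_rel=r2rel,
        sens=sens,
        alt_sens=alt_sensitivity(cmp),
        sens_var=sensitivity_variables(cmp),
        sens2=sens2,
        alt_sens2=alt_sens2,
        fdp=fdp,
        alt_fdp=alt_fdp(cmp),
        fdp_var=fdp_variables(cmp),
        fdp2=fdp2,
        alt_fdp2=alt_fdp2,
    )
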