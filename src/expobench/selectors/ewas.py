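"""Two-step exposome-wide association screening (EWAS2).

Step 1 tests every exposure marginally (simple linear regression) and
keeps the survivors of a Benjamini-Yekutieli correction at alpha.  Step 2
fits, for every unordered pair of survivors, a linear model with both
mains and their product, collects the interaction p-values, corrects them
again (BY, same alpha) and keeps the surviving products.  The output is a
*set* of marginally associated terms, not a single fitted model, and it
yields no predictor.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as _st

from ..terms import SelectedModel, benjamini_yekutieli, inter, main, ols_fit
from .base import SelectionResults, SelectorModel

__all__ = ["EWAS2", "ewas2"]


def _marginal_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the slope in each simple regression."""
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * _st.t.sf(np.abs(t), df)
    p[~np.isfinite(p)] = 1.0
    return p


class EWAS2(SelectorModel):
    """Two-step EWAS bound to a training set."""

    method_name = "EWAS2"

    def __init__(self, E, Y, *, alpha: float = 0.05):
        super().__init__(E, Y)
        if self.X.shape[0] <= 4:
            raise ValueError("EWAS2 needs N > 4")
        self.alpha = float(alpha)

    def fit(self) -> SelectionResults:
        X, y = self.X, self.Y
        p1 = _marginal_pvalues(X, y)
        keep1 = benjamini_yekutieli(p1, self.alpha)
        survivors = [int(i) for i in np.flatnonzero(keep1)]

        inter_terms: list = []
        pairs = list(combinations(survivors, 2)) if len(survivors) > 1 else []
        p2 = np.empty(len(pairs))
        for idx, (i, j) in enumerate(pairs):
            fit = ols_fit(X, y, [main(i), main(j), inter(i, j)])
            p2[idx] = fit.pvalue(inter(i, j))
        if pairs:
            p2 = np.nan_to_num(p2, nan=1.0)
            keep2 = benjamini_yekutieli(p2, self.alpha)
            inter_terms = [inter(i, j)
                           for (i, j), k in zip(pairs, keep2) if k]

        terms = frozenset(main(i) for i in survivors) | frozenset(inter_terms)
        model = SelectedModel(
            method=self.method_name, terms=terms,
            coefficients=None, intercept=None,
            has_single_model=False, predicts=False,
            searches_interactions=True, has_terms=True)
        diag = {"n_step1": len(survivors), "n_pairs_tested": len(pairs),
                "n_step2": len(inter_terms)}
        return SelectionResults(model, predictor=None, diagnostics=diag)


def ewas2(E, Y, alpha: float = 0.05) -> SelectedModel:
    """Functional wrapper; see :class:`EWAS2`."""
    return EWAS2(E, Y, alpha=alpha).fit().model
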