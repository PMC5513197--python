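"""Three-step screen -> tree -> DSA selection.

Step 1 (collinearity screen): within each exposure family, exposures whose
pairwise sample |r| exceeds a threshold (default 0.60) are grouped
(connected components of the threshold graph); each group keeps only the
member with the smallest univariate regression p-value.  Step 2 fits a
regression tree (CART) on the survivors and prunes it to the subtree with
minimum cross-validated error; the variables used in any split survive.
Step 3 runs DSA (order 2: quadratics and pairwise interactions) restricted
to those variables; its output is the final model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from ..terms import SelectedModel
from .base import SelectionResults, SelectorModel
from .dsa import DSA, DSAConfig
from .ewas import _marginal_pvalues

__all__ = ["Sun3StepConfig", "Sun3Step", "sun3step"]


@dataclass(frozen=True)
class Sun3StepConfig:
    r_threshold: float = 0.60
    tree_cv_folds: int = 5
    min_samples_leaf: int = 5
    seed: int = 0
    dsa: DSAConfig = field(default_factory=lambda: DSAConfig(maxorder=2))

    def validate(self):
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.dsa.maxorder != 2:
            raise ValueError("the final DSA stage searches order-2 terms")


def screen_correlated(X: np.ndarray, y: np.ndarray, families,
                      r_threshold: float) -> list:
    """Step 1: per family, keep one exposure per highly correlated group."""
    families = np.asarray(families)
    p = X.shape[1]
    if families.shape != (p,):
        raise ValueError("family labels must cover all exposures")
    pvals = _marginal_pvalues(X, y)
    keep: list = []
    for fam in np.unique(families):
        idx = np.flatnonzero(families == fam)
        if idx.size == 1:
            keep.append(int(idx[0]))
            continue
        sub = np.corrcoef(X[:, idx], rowvar=False)
        adj = (np.abs(sub) > r_threshold) & ~np.eye(idx.size, dtype=bool)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            keep.append(int(members[np.argmin(pvals[members])]))
    return sorted(keep)


def tree_screen(X: np.ndarray, y: np.ndarray, variables, *,
                cv_folds: int = 5, min_samples_leaf: int = 5,
                seed: int = 0) -> list:
    """Step 2: CART with minimum-CV cost-complexity pruning.

    Returns the surviving variable indices (those used in any split of the
    pruned tree); an empty list when the best subtree is the root.
    """
    variables = sorted(variables)
    if not variables:
        return []
    Xs = X[:, variables]
    base = DecisionTreeRegressor(random_state=seed,
                                 min_samples_leaf=min_samples_leaf)
    path = base.cost_complexity_pruning_path(Xs, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    cv_err = np.zeros(alphas.size)
    for ai, a in enumerate(alphas):
        errs = []
        for tr, te in splits:
            t = DecisionTreeRegressor(random_state=seed, ccp_alpha=a,
                                      min_samples_leaf=min_samples_leaf)
            t.fit(Xs[tr], y[tr])
            errs.append(np.mean((y[te] - t.predict(Xs[te])) ** 2))
        cv_err[ai] = np.mean(errs)
    # minimum CV error; ties resolved toward heavier pruning
    best = alphas[np.max(np.flatnonzero(cv_err <= cv_err.min() + 1e-12))]
    tree = DecisionTreeRegressor(random_state=seed, ccp_alpha=best,
                                 min_samples_leaf=min_samples_leaf)
    tree.fit(Xs, y)
    used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
    return sorted(int(variables[u]) for u in used)


class Sun3Step(SelectorModel):
    """Screen -> tree -> DSA pipeline bound to a training set."""

    method_name = "Sun3step"

    def __init__(self, E, Y, families=None, *,
                 config: Sun3StepConfig | None = None, **kwargs):
        super().__init__(E, Y)
        self.config = config or Sun3StepConfig(**kwargs)
        self.config.validate()
        if families is None:
            families = np.zeros(self.X.shape[1], dtype=int)
        self.families = np.asarray(families)

    def fit(self) -> SelectionResults:
        cfg = self.config
        step1 = screen_correlated(self.X, self.Y, self.families,
                                  cfg.r_threshold)
        step2 = tree_screen(self.X, self.Y, step1,
                            cv_folds=cfg.tree_cv_folds,
                            min_samples_leaf=cfg.min_samples_leaf,
                            seed=cfg.seed)
        diag = {"n_step1": len(step1), "n_step2": len(step2)}
        if not step2:
            mu = float(self.Y.mean())
            model = SelectedModel(
                method=self.method_name, terms=frozenset(),
                coefficients={}, intercept=mu,
                has_single_model=True, predicts=True,
                searches_interactions=True, has_terms=True)
            return SelectionResults(
                model,
                predictor=lambda E: np.full(
                    (E.values if hasattr(E, "values")
                     else np.asarray(E)).shape[0], mu),
                diagnostics=diag)
        final = DSA(self.X, self.Y, config=cfg.dsa, variables=step2).fit()
        model = SelectedModel(
            method=self.method_name, terms=final.model.terms,
            coefficients=final.model.coefficients,
            intercept=final.model.intercept,
            has_single_model=True, predicts=True,
            searches_interactions=True, has_terms=True)
        diag.update(final.diagnostics)
        return SelectionResults(model, predictor=final.predictor,
                                diagnostics=diag)


def sun3step(E, Y, families=None, config: Sun3StepConfig | None = None,
             **kwargs) -> SelectedModel:
    """Functional wrapper; see :class:`Sun3Step`."""
    return Sun3Step(E, Y, families, config=config, **kwargs).fit().model
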