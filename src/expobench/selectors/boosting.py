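"""Boosted regression trees with backward variable elimination.

The base learner is stage-wise squared-error gradient boosting of shallow
trees (depth 4 by default -- the depth bounds the interaction order the
ensemble can represent) with shrinkage and row subsampling; the number of
trees is chosen by the error minimum on a held-out fraction of the
training rows (up to 5000 trees).  Variable importance is the split-count
weighted by the squared improvement of each split, averaged over trees.

BRT does not select variables by itself, so a backward elimination wrapper
makes it comparable to the other selectors: repeatedly fit, record the
holdout error, and drop the fraction ``f`` of variables with the smallest
importance (at least one) until a single variable remains; the final set
is the smallest recorded set minimizing the holdout error (the empty
"null" model competes too).  The result is a set of *variables* -- the
ensemble has no regression equation, so term-level measures do not apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from ..terms import SelectedModel, main
from .base import SelectionResults, SelectorModel

__all__ = ["BRTConfig", "BRTResult", "BRT", "fit_brt",
           "brt_variable_selection", "elimination_sizes"]


@dataclass(frozen=True)
class BRTConfig:
    max_trees: int = 5000
    depth: int = 4
    learning_rate: float = 0.01
    bag_fraction: float = 0.5
    elimination_fraction: float = 0.5
    holdout_fraction: float = 0.25
    seed: int = 0

    def validate(self):
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination fraction must lie in (0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout fraction must lie in (0, 1)")


@dataclass
class BRTResult:
    """A fitted ensemble restricted to a variable subset."""

    variables: tuple            # column indices the ensemble was fit on
    n_trees: int                # chosen by the holdout-error minimum
    holdout_error: float        # MSE on the holdout at n_trees
    importances: np.ndarray     # per-variable, aligned with ``variables``
    ensemble: GradientBoostingRegressor | None
    train_mean: float

    def predict(self, E) -> np.ndarray:
        X = E.values if hasattr(E, "values") else np.asarray(E, float)
        if self.ensemble is None or self.n_trees == 0:
            return np.full(X.shape[0], self.train_mean)
        preds = self.train_mean * 0.0
        # staged prediction truncated at the selected tree count
        it = self.ensemble.staged_predict(X[:, list(self.variables)])
        for k, pred in enumerate(it, start=1):
            preds = pred
            if k == self.n_trees:
                break
        return preds


def elimination_sizes(p: int, f: float) -> list:
    """The backward-elimination schedule: keep ceil((1-f) n), drop >= 1."""
    sizes = [p]
    while sizes[-1] > 1:
        nxt = min(int(np.ceil((1.0 - f) * sizes[-1])), sizes[-1] - 1)
        sizes.append(max(nxt, 1))
    return sizes


def _raw_importances(est: GradientBoostingRegressor, n_trees: int,
                     n_features: int) -> np.ndarray:
    """Split-count x squared-improvement importances, averaged over trees."""
    total = np.zeros(n_features)
    trees = est.estimators_[:n_trees]
    for row in trees:
        for t in row:
            total += t.tree_.compute_feature_importances(normalize=False)
    return total / max(len(trees), 1)


class BRT(SelectorModel):
    """Boosted-tree selector bound to a training set."""

    method_name = "BRT"

    def __init__(self, E, Y, *, config: BRTConfig | None = None, **kwargs):
        super().__init__(E, Y)
        self.config = config or BRTConfig(**kwargs)
        self.config.validate()
        if self.X.shape[0] < 50:
            raise ValueError("BRT needs N >= 50")

    # -- single fit ------------------------------------------------------
    def fit_ensemble(self, variables=None, holdout=None) -> BRTResult:
        """Fit boosting on a variable subset; trees chosen on the holdout."""
        cfg = self.config
        X, y = self.X, self.Y
        variables = tuple(range(X.shape[1])) if variables is None \
            else tuple(int(v) for v in variables)
        if holdout is None:
            holdout = _holdout_mask(X.shape[0], cfg.holdout_fraction, cfg.seed)
        tr = ~holdout
        ytr = y[tr]
        mu = float(ytr.mean())
        if np.var(y) < 1e-24:
            return BRTResult(variables, 0, 0.0,
                             np.zeros(len(variables)), None, mu)
        est = GradientBoostingRegressor(
            loss="squared_error", n_estimators=cfg.max_trees,
            learning_rate=cfg.learning_rate, max_depth=cfg.depth,
            subsample=cfg.bag_fraction, random_state=cfg.seed)
        est.fit(X[np.ix_(tr, variables)], ytr)
        yte = y[holdout]
        errs = np.array([np.mean((yte - pred) ** 2) for pred in
                         est.staged_predict(X[np.ix_(holdout, variables)])])
        n_trees = int(np.argmin(errs)) + 1
        imps = _raw_importances(est, n_trees, len(variables))
        return BRTResult(variables, n_trees, float(errs[n_trees - 1]),
                         imps, est, mu)

    # -- backward elimination -------------------------------------------
    def fit(self) -> SelectionResults:
        cfg = self.config
        X, y = self.X, self.Y
        holdout = _holdout_mask(X.shape[0], cfg.holdout_fraction, cfg.seed)
        null_err = float(np.mean((y[holdout] - y[~holdout].mean()) ** 2))
        current = list(range(X.shape[1]))
        trace = [{"variables": (), "error": null_err, "result": None}]
        while True:
            res = self.fit_ensemble(current, holdout)
            trace.append({"variables": tuple(current),
                          "error": res.holdout_error, "result": res})
            if len(current) == 1:
                break
            keep = int(np.ceil((1.0 - cfg.elimination_fraction)
                               * len(current)))
            keep = min(keep, len(current) - 1)
            order = np.argsort(res.importances)[::-1]
            current = sorted(current[i] for i in order[:keep])

        errors = np.array([t["error"] for t in trace])
        sizes = np.array([len(t["variables"]) for t in trace])
        candidates = np.flatnonzero(errors <= errors.min())
        best = candidates[np.argmin(sizes[candidates])]
        chosen = trace[best]
        variables = chosen["variables"]
        result = chosen["result"]

        model = SelectedModel(
            method=self.method_name,
            terms=frozenset(main(v) for v in variables),
            coefficients=None, intercept=None,
            has_single_model=True, predicts=True,
            searches_interactions=False, has_terms=False)
        if result is None:
            mu = float(y[~holdout].mean())
            predictor = lambda E: np.full(
                (E.values if hasattr(E, "values")
                 else np.asarray(E)).shape[0], mu)
            importances = None
        else:
            predictor = result.predict
            importances = dict(zip(result.variables, result.importances))
        diag = {"trace": [(len(t["variables"]), t["error"]) for t in trace],
                "n_eliminations": len(trace) - 1,
                "importances": importances,
                "n_trees": None if result is None else result.n_trees}
        return SelectionResults(model, predictor=predictor, diagnostics=diag)


def _holdout_mask(n: int, fraction: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD4]))
    k = max(1, int(round(fraction * n)))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def fit_brt(E, Y, config: BRTConfig | None = None, **kwargs) -> BRTResult:
    """Fit one boosted ensemble on all variables (no elimination)."""
    return BRT(E, Y, config=config, **kwargs).fit_ensemble()


def brt_variable_selection(E, Y, config: BRTConfig | None = None,
                           **kwargs) -> SelectedModel:
    """Backward-elimination BRT selector; see :class:`BRT`."""
    return BRT(E, Y, config=config, **kwargs).fit().model
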