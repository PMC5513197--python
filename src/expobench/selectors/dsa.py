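"""Deletion/Substitution/Addition model search.

The search maintains, for every model size k = 0..maxsize, the best
residual sum of squares found so far.  Repeated sweeps propose, from each
per-size incumbent, all deletions (one term removed), substitutions (one
in-model term swapped for one out-of-model term) and additions (one term
appended); a move replaces the incumbent of its *target* size whenever it
strictly lowers that size's RSS.  Sweeps repeat until no move improves any
size.  The final size is chosen by cross-validating the whole search:
the search is re-run inside each training fold and its per-size incumbents
are scored on the held-out fold; the size with minimum mean RMSE wins
(ties favour the smaller model) and the full-data incumbent of that size
is refitted by OLS on all data.

With ``maxorder=1`` the candidate terms are the main effects only; with
``maxorder=2`` quadratics and all pairwise products join the universe, and
no hierarchy is imposed (an interaction may enter without its mains).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.model_selection import KFold

from ..terms import (SelectedModel, canonical_order, design_columns, inter,
                     main, ols_fit, quad)
from .base import SelectionResults, SelectorModel

__all__ = ["DSAConfig", "DSA", "dsa", "term_universe"]


@dataclass(frozen=True)
class DSAConfig:
    maxorder: int = 2
    maxsize: int = 10
    folds: int = 5
    seed: int = 0
    max_sweeps: int = 50
    rss_tol: float = 1e-12

    def validate(self):
        if self.maxorder not in (1, 2):
            raise ValueError("maxorder must be 1 or 2")
        if self.maxsize < 1:
            raise ValueError("maxsize must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def term_universe(p: int, maxorder: int,
                  variables=None) -> list:
    """Candidate terms: mains, plus quads and pairwise products at order 2."""
    idx = sorted(variables) if variables is not None else range(p)
    terms = [main(i) for i in idx]
    if maxorder == 2:
        terms += [quad(i) for i in idx]
        terms += [inter(i, j) for i, j in combinations(idx, 2)]
    return terms


class _SearchState:
    """Best-RSS incumbent per model size over a fixed candidate matrix."""

    def __init__(self, C: np.ndarray, y: np.ndarray, maxsize: int, tol: float):
        self.C = C
        self.y = y
        self.tol = tol
        self.n, self.T = C.shape
        self.colnorm2 = np.einsum("ij,ij->j", C, C)
        self.valid = self.colnorm2 > 1e-10 * max(1.0, self.colnorm2.max())
        sizes = maxsize + 1
        self.sets: list = [None] * sizes
        self.rss = np.full(sizes, np.inf)
        self.sets[0] = []
        self.rss[0] = float(y @ y)

    def _qr_resid(self, S: list):
        """Orthonormal basis of the span of columns S and the y-residual."""
        if not S:
            return None, self.y.copy()
        Q, _ = np.linalg.qr(self.C[:, S])
        r = self.y - Q @ (Q.T @ self.y)
        return Q, r

    def _rss_of(self, S: list) -> float:
        _, r = self._qr_resid(S)
        return float(r @ r)

    def _best_addition(self, S: list, Q, r):
        """Best single column to append: (rss_after, column index)."""
        rc = r @ self.C
        if Q is not None and Q.shape[1] > 0:
            W = Q.T @ self.C
            W2 = np.einsum("ij,ij->j", W, W)
        else:
            W2 = np.zeros(self.T)
        perp = self.colnorm2 - W2
        ok = self.valid & (perp > 1e-10 * np.maximum(self.colnorm2, 1.0))
        if S:
            ok[S] = False
        if not np.any(ok):
            return np.inf, -1
        gain = np.where(ok, rc * rc / np.where(ok, perp, 1.0), -np.inf)
        j = int(np.argmax(gain))
        rss_now = float(r @ r)
        return rss_now - float(gain[j]), j

    def _maybe_update(self, size: int, rss: float, S: list) -> bool:
        if size >= len(self.rss):
            return False
        cur = self.rss[size]
        if rss < (cur - self.tol * (1.0 + abs(cur)) if np.isfinite(cur)
                  else np.inf):
            self.rss[size] = rss
            self.sets[size] = sorted(S)
            return True
        return False

    def sweep(self) -> bool:
        """One full pass of deletion/substitution/addition moves."""
        updated = False
        for k in range(len(self.sets)):
            S = self.sets[k]
            if S is None:
                continue
            Q, r = self._qr_resid(S)
            # additions -> size k+1
            if k + 1 < len(self.sets):
                rss_new, j = self._best_addition(S, Q, r)
                if j >= 0:
                    updated |= self._maybe_update(k + 1, rss_new, S + [j])
            # deletions -> size k-1
            if k >= 1:
                for pos in range(k):
                    S_minus = S[:pos] + S[pos + 1:]
                    rss_minus = self._rss_of(S_minus)
                    updated |= self._maybe_update(k - 1, rss_minus, S_minus)
            # substitutions -> size k
            if k >= 1:
                for pos in range(k):
                    S_minus = S[:pos] + S[pos + 1:]
                    Qm, rm = self._qr_resid(S_minus)
                    rss_new, j = self._best_addition(S, Qm, rm)
                    # exclude re-adding any current member (handled in
                    # _best_addition via the full set S)
                    if j >= 0:
                        updated |= self._maybe_update(k, rss_new, S_minus + [j])
        return updated


class DSA(SelectorModel):
    """DSA search bound to a training set."""

    method_name = "DSA"

    def __init__(self, E, Y, *, config: DSAConfig | None = None,
                 variables=None, **kwargs):
        super().__init__(E, Y)
        self.config = config or DSAConfig(**kwargs)
        self.config.validate()
        if self.X.shape[0] <= self.config.maxsize + 1:
            raise ValueError("need N > maxsize + 1")
        self.variables = variables
        self.universe = term_universe(self.X.shape[1], self.config.maxorder,
                                      variables)

    @property
    def _method_label(self) -> str:
        return f"DSA{self.config.maxorder}"

    @staticmethod
    def _search(C: np.ndarray, y: np.ndarray, maxsize: int, tol: float,
                max_sweeps: int):
        yc = y - y.mean()
        Cc = C - C.mean(axis=0, keepdims=True)
        state = _SearchState(Cc, yc, maxsize, tol)
        sweeps = 0
        for sweeps in range(1, max_sweeps + 1):
            if not state.sweep():
                break
        return state, sweeps

    def fit(self) -> SelectionResults:
        cfg = self.config
        C_raw = design_columns(self.X, self.universe)
        ordered = canonical_order(self.universe)

        maxsize = min(cfg.maxsize, len(ordered))
        state, sweeps = self._search(C_raw, self.Y, maxsize, cfg.rss_tol,
                                     cfg.max_sweeps)

        # The model size is chosen by honest cross-validation of the whole
        # search: within each training fold the DSA search is re-run, its
        # per-size incumbents are refitted on the fold and scored on the
        # held-out part, and the size minimising the mean RMSE wins (ties
        # favour the smaller model).  The final model is the full-data
        # incumbent of the chosen size.
        kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        splits = list(kf.split(self.X))
        y = self.Y
        cv_rmse = np.zeros((len(splits), maxsize + 1))
        for f, (tr, te) in enumerate(splits):
            fold_state, _ = self._search(C_raw[tr], y[tr], maxsize,
                                         cfg.rss_tol, cfg.max_sweeps)
            for size, S in enumerate(fold_state.sets):
                if S is None:
                    cv_rmse[f, size] = np.inf
                    continue
                Xtr = np.column_stack([np.ones(len(tr)), C_raw[np.ix_(tr, S)]])
                Xte = np.column_stack([np.ones(len(te)), C_raw[np.ix_(te, S)]])
                beta, *_ = np.linalg.lstsq(Xtr, y[tr], rcond=None)
                cv_rmse[f, size] = np.sqrt(np.mean((y[te] - Xte @ beta) ** 2))
        mean_rmse = cv_rmse.mean(axis=0)
        best_size = int(np.argmin(mean_rmse))   # first minimum = smaller size
        while state.sets[best_size] is None and best_size > 0:
            best_size -= 1
        cv_rmse = mean_rmse

        chosen = [ordered[j] for j in (state.sets[best_size] or [])]
        diag = {"n_sweeps": sweeps, "chosen_size": best_size,
                "cv_rmse": cv_rmse.tolist(),
                "best_rss_per_size": state.rss.tolist()}

        if not chosen:
            mu = float(self.Y.mean())
            model = SelectedModel(
                method=self._method_label, terms=frozenset(),
                coefficients={}, intercept=mu,
                has_single_model=True, predicts=True,
                searches_interactions=cfg.maxorder == 2, has_terms=True)
            return SelectionResults(model, predictor=lambda E: np.full(
                (E.values if hasattr(E, "values") else np.asarray(E)).shape[0],
                mu), diagnostics=diag)

        fit = ols_fit(self.X, self.Y, chosen)
        coefs = {t: float(b) for t, b in zip(fit.terms, fit.coefficients)}
        model = SelectedModel(
            method=self._method_label, terms=frozenset(chosen),
            coefficients=coefs, intercept=fit.intercept,
            has_single_model=True, predicts=True,
            searches_interactions=cfg.maxorder == 2, has_terms=True)
        return SelectionResults(model, predictor=fit.predict, diagnostics=diag)


def dsa(E, Y, config: DSAConfig | None = None, **kwargs) -> SelectedModel:
    """Functional wrapper; see :class:`DSA`."""
    return DSA(E, Y, config=config, **kwargs).fit().model
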