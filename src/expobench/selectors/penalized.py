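"""Penalized selectors: LASSO (mains only) and a hierarchical group lasso.

The group-lasso selector fits linear pairwise-interaction models under
*strong hierarchy* via the overlapped group lasso: besides the singleton
coefficients alpha_i, every candidate pair (i, j) owns a 3-vector group
theta^(ij) = (theta_i, theta_j, theta_int) penalized by its Euclidean norm,

    (1/2N) || y - X alpha - sum_g (X_i th_i + X_j th_j + (X_i o X_j) th_int) ||^2
        + lambda ( sum_i |alpha_i| + w sum_g ||theta^(ij)||_2 ),

with w = sqrt(3) so group size does not bias selection.  A nonzero
interaction can only appear inside a nonzero group, which also activates
its two main-effect components -- hierarchy holds by construction.  The
solver is FISTA (proximal gradient with momentum) on a fixed lambda path
with warm starts; the penalty level is chosen by minimum cross-validated
squared error on a shared fold split (3 folds by default).

Exposures are standardized internally before products are formed; product
columns are then centered but not rescaled.  Main-effect coefficients are
reported on the original scale; interaction coefficients refer to products
of standardized exposures (selection and prediction are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from ..terms import SelectedModel, inter, main
from .base import SelectionResults, SelectorModel

__all__ = [
    "PenalizedConfig",
    "Lasso",
    "GroupLassoInteractions",
    "lasso_select",
    "glinternet_select",
    "cv_curve",
]


@dataclass(frozen=True)
class PenalizedConfig:
    folds: int = 3
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    tol: float = 1e-5
    max_iter: int = 2000
    seed: int = 0
    interaction_universe: str = "all"      # all | none
    screen_pairs_above_p: int = 100        # sure-screen when p exceeds this
    screen_q: int = 5000                   # pairs kept by the screen
    zero_tol: float = 1e-8

    def validate(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.interaction_universe not in ("all", "none"):
            raise ValueError("interaction_universe must be 'all' or 'none'")


def _standardize(X: np.ndarray, y: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd
    ybar = float(y.mean())
    return Xs, y - ybar, mu, sd, ybar


def _lambda_grid(lam_max: float, n: int, ratio: float) -> np.ndarray:
    return lam_max * np.logspace(0.0, np.log10(ratio), n)


def cv_curve(E, Y, fit_at_lambda, config: PenalizedConfig,
             lambdas: np.ndarray):
    """Cross-validated error curve over a fixed penalty path.

    ``fit_at_lambda(X_train, y_train, X_test, lambdas)`` must return an
    (n_test, n_lambda) prediction matrix.  The same seeded fold partition
    is used for every lambda; returns (mean_error, se_error, best_index).
    """
    X = E.values if hasattr(E, "values") else np.asarray(E, float)
    y = np.asarray(Y, float).ravel()
    n = X.shape[0]
    folds = min(config.folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=config.seed)
    errs = np.zeros((folds, len(lambdas)))
    for f, (tr, te) in enumerate(kf.split(X)):
        if te.size < 1 or tr.size < 2:
            raise ValueError("cross-validation fold too small")
        preds = fit_at_lambda(X[tr], y[tr], X[te], lambdas)
        errs[f] = np.mean((y[te][:, None] - preds) ** 2, axis=0)
    mean = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(folds) if folds > 1 else 0 * mean
    return mean, se, int(np.argmin(mean))


# ---------------------------------------------------------------------------
# LASSO (main effects only)
# ---------------------------------------------------------------------------

class Lasso(SelectorModel):
    """Main-effects LASSO with CV-selected penalty (coordinate descent)."""

    method_name = "LASSO"

    def __init__(self, E, Y, *, config: PenalizedConfig | None = None,
                 **kwargs):
        super().__init__(E, Y)
        self.config = config or PenalizedConfig(**kwargs)
        self.config.validate()

    def fit(self) -> SelectionResults:
        cfg = self.config
        X, y = self.X, self.Y
        n = X.shape[0]
        Xs, yc, mu, sd, ybar = _standardize(X, y)
        lam_max = np.max(np.abs(Xs.T @ yc)) / n
        if lam_max <= 0:
            lam_max = 1.0
        lambdas = _lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)

        def handle(Xtr, ytr, Xte, lams):
            Xtr_s = (Xtr - mu) / sd
            Xte_s = (Xte - mu) / sd
            ytr_c = ytr - ytr.mean()
            _, coefs, _ = lasso_path(Xtr_s, ytr_c, alphas=lams,
                                     tol=1e-7, max_iter=100000)
            return ytr.mean() + Xte_s @ coefs

        mean_err, se_err, best = cv_curve(X, y, handle, cfg, lambdas)
        _, coefs, _ = lasso_path(Xs, yc, alphas=lambdas,
                                 tol=1e-8, max_iter=200000)
        beta_std = coefs[:, best]
        nz = np.flatnonzero(np.abs(beta_std) > cfg.zero_tol)
        beta_orig = beta_std / sd
        intercept = ybar - float(beta_orig[nz] @ mu[nz]) if nz.size else ybar
        terms = frozenset(main(int(i)) for i in nz)
        coef_map = {main(int(i)): float(beta_orig[i]) for i in nz}

        def predictor(E):
            Xn = E.values if hasattr(E, "values") else np.asarray(E, float)
            return intercept + Xn[:, nz] @ beta_orig[nz] if nz.size \
                else np.full(Xn.shape[0], intercept)

        model = SelectedModel(
            method=self.method_name, terms=terms, coefficients=coef_map,
            intercept=intercept, has_single_model=True, predicts=True,
            searches_interactions=False, has_terms=True)
        diag = {"lambda_index": best, "lambdas": lambdas,
                "cv_mean": mean_err, "cv_se": se_err}
        return SelectionResults(model, predictor=predictor, diagnostics=diag)


def lasso_select(E, Y, config: PenalizedConfig | None = None,
                 **kwargs) -> SelectedModel:
    """Functional wrapper; see :class:`Lasso`."""
    return Lasso(E, Y, config=config, **kwargs).fit().model


# ---------------------------------------------------------------------------
# Overlapped group lasso with strong hierarchy
# ---------------------------------------------------------------------------

class _GroupProblem:
    """Design data for the overlapped group-lasso objective."""

    def __init__(self, Xs: np.ndarray, pairs_i: np.ndarray,
                 pairs_j: np.ndarray):
        self.X = Xs
        self.n, self.p = Xs.shape
        self.pi = pairs_i
        self.pj = pairs_j
        self.q = len(pairs_i)
        if self.q:
            P = Xs[:, pairs_i] * Xs[:, pairs_j]
            self.P = P - P.mean(axis=0, keepdims=True)
        else:
            self.P = np.zeros((self.n, 0))
        self.w = np.sqrt(3.0)

    def effective_main(self, alpha: np.ndarray, theta: np.ndarray):
        eff = alpha.copy()
        if self.q:
            np.add.at(eff, self.pi, theta[:, 0])
            np.add.at(eff, self.pj, theta[:, 1])
        return eff

    def predict_centered(self, alpha, theta):
        out = self.X @ self.effective_main(alpha, theta)
        if self.q:
            out += self.P @ theta[:, 2]
        return out

    def gradient(self, resid):
        g = self.X.T @ resid / self.n
        if self.q:
            gp = self.P.T @ resid / self.n
            gtheta = np.column_stack([g[self.pi], g[self.pj], gp])
        else:
            gtheta = np.zeros((0, 3))
        return g, gtheta

    def objective(self, alpha, theta, y, lam):
        r = y - self.predict_centered(alpha, theta)
        pen = np.sum(np.abs(alpha))
        if self.q:
            pen += self.w * np.sum(np.linalg.norm(theta, axis=1))
        return 0.5 * float(r @ r) / self.n + lam * pen

    def lipschitz(self, n_iter: int = 30, seed: int = 0) -> float:
        """Largest eigenvalue of A'A/n for the stacked design (power iter)."""
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(self.p)
        th = rng.standard_normal((self.q, 3))
        lam = 1.0
        for _ in range(n_iter):
            z = self.predict_centered(a, th)
            g, gt = self.gradient(z)          # A' z / n
            norm = np.sqrt(np.sum(g * g) + np.sum(gt * gt))
            if norm < 1e-30:
                return 1.0
            lam = norm
            scale = 1.0 / norm
            a = g * scale
            th = gt * scale
        return float(lam) * 1.05


def _group_soft(theta: np.ndarray, thresh: float) -> np.ndarray:
    norms = np.linalg.norm(theta, axis=1, keepdims=True)
    scale = np.clip(1.0 - thresh / np.maximum(norms, 1e-300), 0.0, None)
    return theta * scale


def _fista_path(problem: _GroupProblem, y: np.ndarray, lambdas: np.ndarray,
                tol: float, max_iter: int):
    """Warm-started FISTA over a decreasing penalty path."""
    L = problem.lipschitz()
    step = 1.0 / L
    alpha = np.zeros(problem.p)
    theta = np.zeros((problem.q, 3))
    out_alpha = np.zeros((problem.p, len(lambdas)))
    out_theta = np.zeros((problem.q, 3, len(lambdas)))
    n_iters = []
    for li, lam in enumerate(lambdas):
        za, zt = alpha.copy(), theta.copy()
        t_m = 1.0
        obj_prev = problem.objective(alpha, theta, y, lam)
        it = 0
        for it in range(1, max_iter + 1):
            r = problem.predict_centered(za, zt) - y
            ga, gt = problem.gradient(r)
            a_new = za - step * ga
            a_new = np.sign(a_new) * np.maximum(np.abs(a_new) - step * lam, 0.0)
            if problem.q:
                t_new_mat = zt - step * gt
                th_new = _group_soft(t_new_mat, step * lam * problem.w)
            else:
                th_new = zt
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_m * t_m))
            za = a_new + (t_m - 1.0) / t_next * (a_new - alpha)
            zt = th_new + (t_m - 1.0) / t_next * (th_new - theta)
            alpha, theta, t_m = a_new, th_new, t_next
            if it % 10 == 0 or it == max_iter:
                obj = problem.objective(alpha, theta, y, lam)
                if abs(obj_prev - obj) <= tol * (1.0 + abs(obj)):
                    break
                obj_prev = obj
        n_iters.append(it)
        out_alpha[:, li] = alpha
        out_theta[:, :, li] = theta
    return out_alpha, out_theta, n_iters


def kkt_violation(problem: _GroupProblem, y, alpha, theta, lam,
                  zero_tol: float = 1e-8) -> float:
    """Maximum violation of the subgradient optimality conditions."""
    r = y - problem.predict_centered(alpha, theta)
    ga, gt = problem.gradient(-r)
    viol = 0.0
    for i in range(problem.p):
        if abs(alpha[i]) > zero_tol:
            viol = max(viol, abs(ga[i] + lam * np.sign(alpha[i])))
        else:
            viol = max(viol, max(abs(ga[i]) - lam, 0.0))
    for g in range(problem.q):
        ng = np.linalg.norm(theta[g])
        if ng > zero_tol:
            viol = max(viol, float(np.linalg.norm(
                gt[g] + lam * problem.w * theta[g] / ng)))
        else:
            viol = max(viol, max(float(np.linalg.norm(gt[g]))
                                 - lam * problem.w, 0.0))
    return viol


def _candidate_pairs(Xs: np.ndarray, yc: np.ndarray,
                     cfg: PenalizedConfig):
    p = Xs.shape[1]
    if cfg.interaction_universe == "none" or p < 2:
        return np.zeros(0, int), np.zeros(0, int)
    all_pairs = np.array(list(combinations(range(p), 2)))
    if p <= cfg.screen_pairs_above_p or len(all_pairs) <= cfg.screen_q:
        return all_pairs[:, 0], all_pairs[:, 1]
    # Sure screen: keep the q product columns most correlated with y.
    scores = np.empty(len(all_pairs))
    block = 20000
    for s in range(0, len(all_pairs), block):
        sub = all_pairs[s:s + block]
        P = Xs[:, sub[:, 0]] * Xs[:, sub[:, 1]]
        P = P - P.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(P, axis=0)
        norms[norms < 1e-12] = np.inf
        scores[s:s + block] = np.abs(P.T @ yc) / norms
    keep = np.argsort(scores)[::-1][:cfg.screen_q]
    keep.sort()
    sub = all_pairs[keep]
    return sub[:, 0], sub[:, 1]


class GroupLassoInteractions(SelectorModel):
    """Hierarchical pairwise-interaction selector (overlapped group lasso)."""

    method_name = "GLINTERNET"

    def __init__(self, E, Y, *, config: PenalizedConfig | None = None,
                 **kwargs):
        super().__init__(E, Y)
        self.config = config or PenalizedConfig(**kwargs)
        self.config.validate()

    def fit(self) -> SelectionResults:
        cfg = self.config
        X, y = self.X, self.Y
        n = X.shape[0]
        Xs, yc, mu, sd, ybar = _standardize(X, y)
        pi, pj = _candidate_pairs(Xs, yc, cfg)
        problem = _GroupProblem(Xs, pi, pj)

        g0 = np.abs(Xs.T @ yc) / n
        lam_max = float(np.max(g0)) if g0.size else 1.0
        if problem.q:
            gp0 = np.abs(problem.P.T @ yc) / n
            gnorm = np.sqrt(g0[pi] ** 2 + g0[pj] ** 2 + gp0 ** 2) / problem.w
            lam_max = max(lam_max, float(np.max(gnorm)))
        if lam_max <= 0:
            lam_max = 1.0
        lambdas = _lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)

        def handle(Xtr, ytr, Xte, lams):
            Xtr_s = (Xtr - mu) / sd
            Xte_s = (Xte - mu) / sd
            ytr_c = ytr - ytr.mean()
            prob = _GroupProblem(Xtr_s, pi, pj)
            oa, ot, _ = _fista_path(prob, ytr_c, lams, cfg.tol, cfg.max_iter)
            preds = np.empty((Xte.shape[0], len(lams)))
            if prob.q:
                Pte = Xte_s[:, pi] * Xte_s[:, pj]
                Pte = Pte - (Xtr_s[:, pi] * Xtr_s[:, pj]).mean(axis=0)
            for li in range(len(lams)):
                eff = prob.effective_main(oa[:, li], ot[:, :, li])
                pred = Xte_s @ eff
                if prob.q:
                    pred = pred + Pte @ ot[:, 2, li]
                preds[:, li] = ytr.mean() + pred
            return preds

        mean_err, se_err, best = cv_curve(X, y, handle, cfg, lambdas)
        oa, ot, n_iters = _fista_path(problem, yc, lambdas, cfg.tol,
                                      cfg.max_iter)
        alpha, theta = oa[:, best], ot[:, :, best]
        eff = problem.effective_main(alpha, theta)
        # Structural activity: a main effect is active through its
        # singleton or any group containing the variable.
        active_main = np.abs(alpha) > cfg.zero_tol
        if problem.q:
            for col in (0, 1):
                idx = (pi, pj)[col]
                np.add.at(active_main, idx,
                          np.abs(theta[:, col]) > cfg.zero_tol)
        active_inter = (np.abs(theta[:, 2]) > cfg.zero_tol) if problem.q \
            else np.zeros(0, bool)
        # strong hierarchy by construction: an active product sits inside a
        # nonzero group, which activates both main components
        for g in np.flatnonzero(active_inter):
            active_main[pi[g]] = True
            active_main[pj[g]] = True

        terms = {main(int(i)) for i in np.flatnonzero(active_main)}
        coef_map = {main(int(i)): float(eff[i] / sd[i])
                    for i in np.flatnonzero(active_main)}
        for g in np.flatnonzero(active_inter):
            t = inter(int(pi[g]), int(pj[g]))
            terms.add(t)
            coef_map[t] = float(theta[g, 2])

        Pmeans = (Xs[:, pi] * Xs[:, pj]).mean(axis=0) if problem.q else None

        def predictor(E):
            Xn = E.values if hasattr(E, "values") else np.asarray(E, float)
            Xn_s = (Xn - mu) / sd
            pred = Xn_s @ eff
            if problem.q:
                Pn = Xn_s[:, pi] * Xn_s[:, pj] - Pmeans
                pred = pred + Pn @ theta[:, 2]
            return ybar + pred

        model = SelectedModel(
            method=self.method_name, terms=frozenset(terms),
            coefficients=coef_map, intercept=ybar,
            has_single_model=True, predicts=True,
            searches_interactions=cfg.interaction_universe != "none",
            has_terms=True)
        diag = {"lambda_index": best, "lambdas": lambdas,
                "cv_mean": mean_err, "cv_se": se_err,
                "n_pairs": problem.q, "fista_iters": n_iters,
                "alpha": alpha, "theta": theta, "problem": problem}
        return SelectionResults(model, predictor=predictor, diagnostics=diag)


def glinternet_select(E, Y, config: PenalizedConfig | None = None,
                      **kwargs) -> SelectedModel:
    """Functional wrapper; see :class:`GroupLassoInteractions`."""
    return GroupLassoInteractions(E, Y, config=config, **kwargs).fit().model
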