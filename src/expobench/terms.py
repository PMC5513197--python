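"""Term algebra and OLS plumbing shared by the selectors and the metrics.

A fitted selection is a set of *terms* over exposure columns: main effects
``X_i``, quadratics ``X_i^2`` and unordered pairwise products ``X_i X_j``.
A model with terms {X1, X2, X1^2, X1X2} involves two *variables* and four
*terms*; several performance measures depend on that distinction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Term",
    "main",
    "quad",
    "inter",
    "canonical_order",
    "SelectedModel",
    "FitResult",
    "design_columns",
    "ols_fit",
    "benjamini_yekutieli",
    "count_terms",
    "count_variables",
]

_KIND_RANK = {"main": 0, "quad": 1, "inter": 2}


@dataclass(frozen=True, order=False)
class Term:
    """A single model term: ``main``/``quad`` on index i, or ``inter`` (i, j).

    Interaction terms are unordered; they are normalised to i < j at
    construction so that ``inter(5, 2) == inter(2, 5)``.
    """

    kind: str
    i: int
    j: int | None = None

    def __post_init__(self):
        if self.kind not in _KIND_RANK:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "inter":
            if self.j is None or self.j == self.i:
                raise ValueError("inter terms need two distinct indices")
            if self.j < self.i:
                lo, hi = self.j, self.i
                object.__setattr__(self, "i", lo)
                object.__setattr__(self, "j", hi)
        elif self.j is not None:
            raise ValueError(f"{self.kind} terms take a single index")

    @property
    def variables(self) -> tuple:
        return (self.i,) if self.j is None else (self.i, self.j)

    def sort_key(self):
        return (_KIND_RANK[self.kind], self.i, -1 if self.j is None else self.j)

    def __repr__(self):
        if self.kind == "main":
            return f"X{self.i}"
        if self.kind == "quad":
            return f"X{self.i}^2"
        return f"X{self.i}*X{self.j}"


def main(i: int) -> Term:
    return Term("main", int(i))


def quad(i: int) -> Term:
    return Term("quad", int(i))


def inter(i: int, j: int) -> Term:
    return Term("inter", int(i), int(j))


def canonical_order(terms: Iterable[Term]) -> list:
    """Mains by index, then quads, then interactions lexicographically."""
    return sorted(terms, key=Term.sort_key)


@dataclass
class SelectedModel:
    """The output of a variable-selection method.

    ``has_single_model`` is False for screening procedures that return sets
    of marginally associated terms rather than one fitted equation;
    ``predicts`` is True when the method yields a usable predictor
    function; ``searches_interactions`` records whether the method's
    candidate space contained interaction terms at all (it drives which
    interaction-level performance measures apply).
    """

    method: str
    terms: frozenset
    coefficients: Mapping | None = None
    intercept: float | None = None
    has_single_model: bool = True
    predicts: bool = True
    searches_interactions: bool = False
    has_terms: bool = True

    def __post_init__(self):
        self.terms = frozenset(self.terms)
        if self.coefficients is not None:
            extra = set(self.coefficients) - set(self.terms)
            if extra:
                raise ValueError(f"coefficients for unknown terms: {extra}")

    @property
    def variables(self) -> frozenset:
        return frozenset(v for t in self.terms for v in t.variables)

    @property
    def interaction_terms(self) -> frozenset:
        return frozenset(t for t in self.terms if t.kind == "inter")

    # -- line-oriented text serialization --------------------------------
    def to_text(self, path: str | Path | None = None) -> str:
        lines = [f"# method {self.method}",
                 f"# flags single={int(self.has_single_model)} "
                 f"predicts={int(self.predicts)} "
                 f"inter={int(self.searches_interactions)} "
                 f"terms={int(self.has_terms)}"]
        if self.intercept is not None:
            lines.append(f"intercept {self.intercept:.12g}")
        for t in canonical_order(self.terms):
            part = f"{t.kind} {t.i}" if t.j is None else f"{t.kind} {t.i} {t.j}"
            if self.coefficients is not None and t in self.coefficients:
                part += f" {self.coefficients[t]:.12g}"
            lines.append(part)
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_text(cls, source: str | Path) -> "SelectedModel":
        text = Path(source).read_text() if isinstance(source, Path) else source
        method, flags = "unknown", {}
        terms, coefs, intercept = [], {}, None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# method"):
                method = line.split(None, 2)[2]
                continue
            if line.startswith("# flags"):
                flags = dict(kv.split("=") for kv in line.split()[2:])
                continue
            parts = line.split()
            if parts[0] == "intercept":
                intercept = float(parts[1])
                continue
            kind = parts[0]
            if kind == "inter":
                t = inter(int(parts[1]), int(parts[2]))
                rest = parts[3:]
            else:
                t = Term(kind, int(parts[1]))
                rest = parts[2:]
            terms.append(t)
            if rest:
                coefs[t] = float(rest[0])
        return cls(
            method=method, terms=frozenset(terms),
            coefficients=coefs or None, intercept=intercept,
            has_single_model=bool(int(flags.get("single", 1))),
            predicts=bool(int(flags.get("predicts", 1))),
            searches_interactions=bool(int(flags.get("inter", 0))),
            has_terms=bool(int(flags.get("terms", 1))),
        )


@dataclass
class FitResult:
    """OLS fit of a fixed term set: coefficients, SEs and t-test p-values."""

    terms: tuple
    intercept: float
    coefficients: np.ndarray
    std_errors: np.ndarray
    pvalues: np.ndarray
    residual_var: float
    df_resid: int
    rank_deficient: bool = False

    def coef(self, t: Term) -> float:
        return float(self.coefficients[self.terms.index(t)])

    def pvalue(self, t: Term) -> float:
        return float(self.pvalues[self.terms.index(t)])

    def predict(self, E) -> np.ndarray:
        X = design_columns(E, self.terms)
        return self.intercept + X @ self.coefficients


def _values(E) -> np.ndarray:
    return E.values if hasattr(E, "values") else np.asarray(E, dtype=float)


def design_columns(E, terms: Sequence[Term]) -> np.ndarray:
    """N x k design matrix in canonical term order (no intercept)."""
    X = _values(E)
    ordered = canonical_order(terms)
    cols = []
    for t in ordered:
        if t.i >= X.shape[1] or (t.j is not None and t.j >= X.shape[1]):
            raise IndexError(f"term {t} out of range for p={X.shape[1]}")
        if t.kind == "main":
            cols.append(X[:, t.i])
        elif t.kind == "quad":
            cols.append(X[:, t.i] ** 2)
        else:
            cols.append(X[:, t.i] * X[:, t.j])
    if not cols:
        return np.empty((X.shape[0], 0))
    return np.column_stack(cols)


def ols_fit(E, Y, terms: Iterable[Term]) -> FitResult:
    """Least-squares fit with intercept; two-sided t-tests, N - k - 1 df.

    Rank-deficient designs are fitted by pseudo-inverse and flagged; the
    affected p-values are reported as NaN.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    ordered = tuple(canonical_order(terms))
    Xt = design_columns(E, ordered)
    n, k = Xt.shape
    if n <= k + 1:
        raise ValueError(f"need N > k+1 (N={n}, k={k})")
    X = np.column_stack([np.ones(n), Xt])
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - k - 1
    rss = float(resid @ resid)
    sigma2 = rss / df if df > 0 else np.nan
    deficient = rank < k + 1
    if deficient:
        xtx_inv = np.linalg.pinv(X.T @ X)
    else:
        xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv), 0, None) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * _st.t.sf(np.abs(tvals), df)
    if deficient:
        pvals = np.full_like(pvals, np.nan)
    return FitResult(
        terms=ordered,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        std_errors=se[1:],
        pvalues=pvals[1:],
        residual_var=sigma2,
        df_resid=df,
        rank_deficient=deficient,
    )


def benjamini_yekutieli(pvals, alpha: float = 0.05) -> np.ndarray:
    """Step-up FDR control valid under arbitrary dependence.

    Thresholds are ``i * alpha / (m * c(m))`` with ``c(m) = sum_{l<=m} 1/l``;
    all p-values up to the largest i satisfying the rule are declared
    significant.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_by")
    return reject


def count_terms(model: SelectedModel) -> int:
    """Number of terms excluding the intercept."""
    return len(model.terms)


def count_variables(model: SelectedModel) -> int:
    """Number of distinct exposures appearing in any term."""
    return len(model.variables)
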