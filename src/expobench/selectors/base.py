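"""Model/Results surface shared by all selectors.

Every selector is a model object constructed from training data
(`E`, `Y`, plus a config); ``fit()`` runs the selection and returns a
:class:`SelectionResults` carrying the selected term set, native
coefficients where the method has them, a prediction rule, and per-stage
diagnostics.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..terms import SelectedModel, canonical_order


class SelectorModel:
    """Abstract base: a variable-selection method bound to training data."""

    method_name: str = "abstract"

    def __init__(self, E, Y):
        self.E = E
        self.Y = np.asarray(Y, dtype=float).ravel()
        X = E.values if hasattr(E, "values") else np.asarray(E, float)
        if X.shape[0] != self.Y.shape[0]:
            raise ValueError("E and Y have different numbers of rows")
        self.X = X

    def fit(self) -> "SelectionResults":   # pragma: no cover - interface
        raise NotImplementedError


class SelectionResults:
    """Outcome of one selector fit.

    Attributes
    ----------
    model : SelectedModel
        The selected terms with capability flags.
    predictor : callable or None
        Maps an exposure matrix to predictions (the method's *native*
        predictor: penalized coefficients, OLS refit, tree ensemble...).
    diagnostics : dict
        Per-stage counts, CV curves, traces.
    """

    def __init__(self, model: SelectedModel,
                 predictor: Callable | None = None,
                 diagnostics: dict | None = None):
        self.model = model
        self.predictor = predictor
        self.diagnostics = diagnostics or {}

    def predict(self, E) -> np.ndarray:
        if self.predictor is None:
            raise ValueError(
                f"method {self.model.method} does not provide a predictor")
        return self.predictor(E)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Selection by {m.method}",
            "=" * 32,
            f"terms selected     : {len(m.terms)}",
            f"variables involved : {len(m.variables)}",
            f"interaction terms  : {len(m.interaction_terms)}",
            f"single fitted model: {m.has_single_model}",
            f"provides predictor : {m.predicts}",
        ]
        for key in ("n_step1", "n_step2", "n_sweeps", "chosen_size",
                    "lambda_index", "n_trees", "n_eliminations"):
            if key in self.diagnostics:
                lines.append(f"{key:19s}: {self.diagnostics[key]}")
        if m.terms:
            lines.append("terms:")
            for t in canonical_order(m.terms):
                coef = ""
                if m.coefficients is not None and t in m.coefficients:
                    coef = f"  {m.coefficients[t]: .5g}"
                lines.append(f"  {t!r}{coef}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<SelectionResults {self.model.method}: "
                f"{len(self.model.terms)} terms>")
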