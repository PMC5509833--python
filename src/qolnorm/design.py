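"""Model formulas and design matrices.

Formulas use the familiar Wilkinson mini-language, e.g.::

    vas ~ age + I(age**2) + child*sick + C(education)

parsed by patsy.  A :class:`DesignSpec` stores the expanded term list (so
``child*sick`` becomes three droppable terms) together with the names of
forced-in terms that model selection must never remove (the age polynomial
and the questionnaire-block indicators).  Building against a dataset
returns a :class:`Design` that keeps patsy's design info, so bootstrap
refits can resample rows of the built matrix and predictions on new data
reuse the training factor levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import ModelDesc, build_design_matrices, dmatrix

from ._util import ValidationError


def _normalize(name: str) -> str:
    return name.replace(" ", "")


@dataclass(frozen=True)
class Design:
    """A built design matrix with term bookkeeping."""

    X: np.ndarray
    columns: tuple[str, ...]
    term_slices: dict[str, slice]
    design_info: object

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def matrix_for(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for new rows using the training encoding."""
        (mat,) = build_design_matrices([self.design_info], data)
        return np.asarray(mat)

    def check_full_rank(self):
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.k:
            # name the aliased columns via pivoted QR
            from scipy.linalg import qr

            _, r, piv = qr(self.X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            bad = piv[rank:] if diag[rank:].size else []
            names = [self.columns[j] for j in bad]
            raise ValidationError(f"design is rank-deficient; aliased columns: {names}")


@dataclass(frozen=True)
class DesignSpec:
    """An outcome name, a list of RHS terms, and forced-in term names."""

    outcome: str
    terms: tuple[str, ...]
    forced: tuple[str, ...] = ()

    @classmethod
    def from_formula(cls, formula: str, forced: tuple[str, ...] = ()) -> "DesignSpec":
        desc = ModelDesc.from_formula(formula)
        if desc.lhs_termlist:
            outcome = desc.lhs_termlist[0].name()
        else:
            outcome = ""
        terms = tuple(
            t.name() for t in desc.rhs_termlist if t.name() not in ("Intercept", "1")
        )
        missing = [f for f in forced if _normalize(f) not in {_normalize(t) for t in terms}]
        if missing:
            raise ValidationError(f"forced terms not in formula: {missing}")
        return cls(outcome=outcome, terms=terms, forced=tuple(forced))

    @property
    def rhs(self) -> str:
        return "1 + " + " + ".join(self.terms) if self.terms else "1"

    def drop(self, term: str) -> "DesignSpec":
        key = _normalize(term)
        if key in {_normalize(f) for f in self.forced}:
            raise ValidationError(f"term {term!r} is forced-in and cannot be dropped")
        kept = tuple(t for t in self.terms if _normalize(t) != key)
        if len(kept) == len(self.terms):
            raise ValidationError(f"term {term!r} not in design")
        return DesignSpec(outcome=self.outcome, terms=kept, forced=self.forced)

    def removable(self) -> tuple[str, ...]:
        forced = {_normalize(f) for f in self.forced}
        return tuple(t for t in self.terms if _normalize(t) not in forced)

    def build(self, data: pd.DataFrame) -> Design:
        mat = dmatrix(self.rhs, data, NA_action="raise")
        di = mat.design_info
        slices = {}
        for term_name, slc in di.term_name_slices.items():
            if term_name == "Intercept":
                slices["Intercept"] = slc
                continue
            # map patsy's normalised term names back to ours
            match = [t for t in self.terms if _normalize(t) == _normalize(term_name)]
            slices[match[0] if match else term_name] = slc
        return Design(
            X=np.asarray(mat),
            columns=tuple(di.column_names),
            term_slices=slices,
            design_info=di,
        )
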