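"""Design-matrix terms for the propensity models.

A *term* is a named block of one or more design columns built from the
cohort table: a binary/categorical factor (dummy coded against a reference
level), a continuous variable under a chosen functional form, or a two-way
interaction (elementwise products of two parents' bases).  Stepwise
selection enters and removes whole term blocks, so the joint Wald test for
a term needs to know which columns belong to it.

Categorical levels are *frozen* from the estimation data before fitting
(:func:`freeze_terms`); prediction and bootstrap refits then reuse the same
dummy coding even if a rare level is absent from a resample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, Sequence, Union

import numpy as np
import pandas as pd

from .forms import FormSpec, expand_terms


class Term(Protocol):
    name: str

    def columns(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]: ...

    def required_columns(self) -> set[str]: ...

    def width(self) -> int: ...


@dataclass(frozen=True)
class CategoricalTerm:
    """Dummy-coded factor; the first level (lexicographic, or the explicit
    ``levels`` tuple's head) is the reference."""

    column: str
    levels: tuple[str, ...] | None = None

    @property
    def name(self) -> str:
        return self.column

    def _levels(self, data: pd.DataFrame) -> tuple[str, ...]:
        if self.levels is not None:
            return self.levels
        return tuple(sorted(pd.unique(data[self.column].astype(str))))

    def columns(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        levels = self._levels(data)
        values = data[self.column].astype(str).to_numpy()
        others = levels[1:]
        if not others:
            return np.empty((len(values), 0)), []
        cols = np.column_stack([(values == lv).astype(float) for lv in others])
        return cols, [f"{self.column}[{lv}]" for lv in others]

    def required_columns(self) -> set[str]:
        return {self.column}

    def width(self) -> int:
        if self.levels is None:
            raise ValueError(f"term {self.column!r} has unfrozen levels")
        return len(self.levels) - 1


@dataclass(frozen=True)
class NumericTerm:
    """A column used as-is (already numeric, e.g. a questionnaire score)."""

    column: str

    @property
    def name(self) -> str:
        return self.column

    def columns(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        return data[self.column].to_numpy(dtype=float)[:, None], [self.column]

    def required_columns(self) -> set[str]:
        return {self.column}

    def width(self) -> int:
        return 1


@dataclass(frozen=True)
class FormTerm:
    """A continuous variable expanded under a functional form."""

    form: FormSpec

    @property
    def name(self) -> str:
        return self.form.label()

    def columns(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        return expand_terms(data[self.form.variable].to_numpy(), self.form)

    def required_columns(self) -> set[str]:
        return {self.form.variable}

    def width(self) -> int:
        return self.form.n_terms


SimpleTerm = Union[CategoricalTerm, NumericTerm, FormTerm]


@dataclass(frozen=True)
class InteractionTerm:
    """All pairwise products of two parent terms' basis columns."""

    left: SimpleTerm
    right: SimpleTerm

    @property
    def name(self) -> str:
        return f"{self.left.name}*{self.right.name}"

    def columns(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        lc, ln = self.left.columns(data)
        rc, rn = self.right.columns(data)
        cols = (lc[:, :, None] * rc[:, None, :]).reshape(len(data), -1)
        names = [f"{a}*{b}" for a in ln for b in rn]
        return cols, names

    def required_columns(self) -> set[str]:
        return self.left.required_columns() | self.right.required_columns()

    def width(self) -> int:
        return self.left.width() * self.right.width()


def freeze_terms(data: pd.DataFrame, terms: Sequence[Term]) -> list[Term]:
    """Pin categorical levels (including inside interactions) to the levels
    observed in ``data``."""

    def _freeze(t: Term) -> Term:
        if isinstance(t, CategoricalTerm) and t.levels is None:
            return replace(t, levels=t._levels(data))
        if isinstance(t, InteractionTerm):
            return InteractionTerm(_freeze(t.left), _freeze(t.right))
        return t

    return [_freeze(t) for t in terms]


def build_design(
    data: pd.DataFrame, terms: Sequence[Term]
) -> tuple[np.ndarray, list[str]]:
    """Stack term blocks into a design matrix (no intercept column)."""
    if not terms:
        return np.empty((len(data), 0)), []
    blocks, names = [], []
    for t in terms:
        cols, nm = t.columns(data)
        blocks.append(cols)
        names.extend(nm)
    return np.column_stack(blocks), names


def term_slices(terms: Sequence[Term]) -> list[slice]:
    """Column slice of each (frozen) term's block in the stacked design."""
    slices, start = [], 0
    for t in terms:
        k = t.width()
        slices.append(slice(start, start + k))
        start += k
    return slices


def required_columns(terms: Sequence[Term]) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= t.required_columns()
    return out
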