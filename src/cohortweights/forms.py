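"""Functional-form search for continuous design covariates.

The log-odds of each selection outcome may depend non-linearly on the
continuous covariates (age in years, IMD decile).  The candidate menu is

* linear,
* categorical (pre-specified cut points),
* linear + quadratic,
* fractional polynomials (FP) of degree 1 or 2 over the Royston-Altman
  power set ``P = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}``,

and the winner is the form whose logistic fit (alongside the other design
terms) has the lowest AIC.  Power 0 denotes the natural log; a repeated
FP2 power ``(p, p)`` contributes the pair ``x**p`` and ``x**p * log(x)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: default age-band cut points (inclusive bounds, in years)
AGE_CUTS: tuple[tuple[int, int], ...] = ((11, 13), (14, 15), (16, 17))
#: IMD quintile bands derived from deciles
IMD_CUTS: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6), (7, 8), (9, 10))

FAMILIES = ("linear", "categorical", "quadratic", "FP1", "FP2")


@dataclass(frozen=True)
class FormSpec:
    """One candidate functional form for a continuous variable.

    ``shift`` and ``scale`` are applied before powering
    (``z = (x + shift) / scale``); they keep the working variable strictly
    positive and of order one so that cubes and logs stay well conditioned.
    """

    variable: str
    family: str
    powers: tuple[float, ...] = ()
    cuts: tuple[tuple[float, float], ...] = ()
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown form family {self.family!r}")
        if self.family == "FP1" and len(self.powers) != 1:
            raise ValueError("FP1 requires exactly one power")
        if self.family == "FP2" and len(self.powers) != 2:
            raise ValueError("FP2 requires exactly two powers")
        if self.family == "categorical" and not self.cuts:
            raise ValueError("categorical form requires cut points")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_terms(self) -> int:
        if self.family == "linear":
            return 1
        if self.family == "quadratic":
            return 2
        if self.family == "categorical":
            return len(self.cuts) - 1
        return len(self.powers)

    def label(self) -> str:
        if self.family in ("FP1", "FP2"):
            pw = ",".join(f"{p:g}" for p in self.powers)
            return f"{self.variable}:{self.family}({pw})"
        return f"{self.variable}:{self.family}"


def _fp_basis(z: np.ndarray, p: float) -> np.ndarray:
    if p == 0.0:
        return np.log(z)
    return z**p


def expand_terms(values: Sequence[float], form: FormSpec) -> tuple[np.ndarray, list[str]]:
    """Expand a variable into its design columns under ``form``.

    Returns an ``(n, k)`` array and the column names.  Pure function:
    identical inputs give identical columns.
    """
    x = np.asarray(values, dtype=float)
    z = (x + form.shift) / form.scale
    v = form.variable

    if form.family == "categorical":
        cols, names = [], []
        for lo, hi in form.cuts[1:]:  # first band is the reference level
            cols.append(((x >= lo) & (x <= hi)).astype(float))
            names.append(f"{v}[{lo:g}-{hi:g}]")
        return np.column_stack(cols), names

    if form.family in ("FP1", "FP2"):
        fractional_or_log = any(p != int(p) or p <= 0 for p in form.powers) or (
            form.family == "FP2" and form.powers[0] == form.powers[1]
        )
        if fractional_or_log and np.any(z <= 0):
            bad = int(np.flatnonzero(z <= 0)[0])
            raise ValueError(
                f"non-positive value for {v!r} at row {bad} "
                f"(z={z[bad]:g}) cannot enter a log/fractional power"
            )

    if form.family == "linear":
        return z[:, None], [v]
    if form.family == "quadratic":
        return np.column_stack([z, z**2]), [v, f"{v}^2"]
    if form.family == "FP1":
        (p,) = form.powers
        name = f"{v}^{p:g}" if p != 0 else f"log({v})"
        return _fp_basis(z, p)[:, None], [name]
    # FP2
    p1, p2 = form.powers
    if p1 == p2:
        b = _fp_basis(z, p1)
        return np.column_stack([b, b * np.log(z)]), [
            f"{v}^{p1:g}" if p1 != 0 else f"log({v})",
            f"{v}^{p1:g}*log({v})" if p1 != 0 else f"log({v})^2",
        ]
    cols = np.column_stack([_fp_basis(z, p1), _fp_basis(z, p2)])
    names = [f"{v}^{p:g}" if p != 0 else f"log({v})" for p in (p1, p2)]
    return cols, names


def candidate_forms(
    variable: str,
    cuts: tuple[tuple[float, float], ...],
    shift: float = 0.0,
    scale: float = 1.0,
) -> list[FormSpec]:
    """The full candidate menu for one variable, in the canonical order
    linear, categorical, quadratic, FP1 (8), FP2 (36)."""
    forms = [
        FormSpec(variable, "linear", shift=shift, scale=scale),
        FormSpec(variable, "categorical", cuts=cuts, shift=shift, scale=scale),
        FormSpec(variable, "quadratic", shift=shift, scale=scale),
    ]
    for p in FP_POWERS:
        forms.append(FormSpec(variable, "FP1", powers=(p,), shift=shift, scale=scale))
    for p1, p2 in itertools.combinations_with_replacement(FP_POWERS, 2):
        forms.append(
            FormSpec(variable, "FP2", powers=(p1, p2), shift=shift, scale=scale)
        )
    return forms


def default_form_menu(variable: str) -> list[FormSpec]:
    """Candidate menu with the package's cut points and scaling for the
    two continuous design variables."""
    if variable == "age_years":
        return candidate_forms("age_years", AGE_CUTS, shift=0.0, scale=10.0)
    if variable == "imd_decile":
        return candidate_forms("imd_decile", IMD_CUTS, shift=0.0, scale=10.0)
    raise ValueError(f"no default form menu for variable {variable!r}")


@dataclass
class FormSearchRecord:
    """One row of the AIC search log."""

    form: FormSpec
    aic: float
    converged: bool
    n_terms: int


def select_form_by_aic(
    data: pd.DataFrame,
    outcome: str,
    baseline_terms: Sequence,
    variable: str,
    candidates: Sequence[FormSpec] | None = None,
) -> tuple[FormSpec, list[FormSearchRecord]]:
    """Pick the minimum-AIC functional form for ``variable``.

    Each candidate is fitted as a logistic regression of ``outcome`` on the
    candidate's columns plus ``baseline_terms`` (term objects from
    :mod:`cohortweights.design`).  Ties are broken by fewer basis terms,
    then by position in the candidate list.  Candidates whose fit fails to
    converge are skipped with a warning; if all fail an error is raised.
    """
    from .modelfit import fit_logit
    from .design import build_design

    if candidates is None:
        candidates = default_form_menu(variable)

    y = data[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} is constant; no model possible")

    X_base, base_names = build_design(data, baseline_terms)
    records: list[FormSearchRecord] = []
    for form in candidates:
        cols, names = expand_terms(data[variable].to_numpy(), form)
        X = np.column_stack([np.ones(len(data)), cols, X_base])
        try:
            res = fit_logit(y, X)
            records.append(FormSearchRecord(form, float(res.aic), True, form.n_terms))
        except Exception as exc:  # noqa: BLE001 - any fit failure skips the form
            warnings.warn(
                f"form {form.label()} failed to converge and was skipped: {exc}",
                stacklevel=2,
            )
            records.append(FormSearchRecord(form, np.inf, False, form.n_terms))
    converged = [r for r in records if r.converged]
    if not converged:
        raise RuntimeError(f"no candidate form converged for {variable!r}")
    order = {id(r): i for i, r in enumerate(records)}
    best = min(converged, key=lambda r: (r.aic, r.n_terms, order[id(r)]))
    return best.form, records


def search_log_frame(records: Sequence[FormSearchRecord]) -> pd.DataFrame:
    """Tabulate a form-search log (for the CSV search record)."""
    return pd.DataFrame(
        {
            "variable": [r.form.variable for r in records],
            "family": [r.form.family for r in records],
            "powers": [",".join(f"{p:g}" for p in r.form.powers) for r in records],
            "n_terms": [r.n_terms for r in records],
            "aic": [r.aic for r in records],
            "converged": [r.converged for r in records],
        }
    )
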