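"""Data-collection sweeps and the month-of-test → sweep-availability rule.

Follow-up questionnaires were scheduled 3, 6 and 12 months after the index
PCR test, but which sweeps exist for a person depends on when they tested:

* tested January–March 2021   → 3-, 6- and 12-month sweeps
* tested October–December 2020 → 6- and 12-month sweeps
* tested September 2020        → 12-month sweep only

A response counts as *timely* if it arrived strictly before 24 weeks
post-testing at the 3-month sweep, and within (≤) 34 and 60 weeks at the
6- and 12-month sweeps.  For December-2020 testers only a portion were
contacted at 6 months; the generator carries a ``contacted_6m`` flag for
them (default: everyone contacted).
"""

from __future__ import annotations

from dataclasses import dataclass

MONTHS: tuple[str, ...] = (
    "2020-09",
    "2020-10",
    "2020-11",
    "2020-12",
    "2021-01",
    "2021-02",
    "2021-03",
)

_THREE_MONTH = ("2021-01", "2021-02", "2021-03")
_SIX_MONTH = ("2020-10", "2020-11", "2020-12") + _THREE_MONTH


@dataclass(frozen=True)
class SweepDefinition:
    """One data-collection sweep and its timeliness rule."""

    months_after_test: int
    cutoff_weeks: float
    strict: bool  # True: timely iff weeks < cutoff; False: weeks <= cutoff
    eligible_months: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.months_after_test}m"

    def is_timely(self, weeks_to_response):
        import numpy as np

        w = np.asarray(weeks_to_response, dtype=float)
        return w < self.cutoff_weeks if self.strict else w <= self.cutoff_weeks


SWEEPS: dict[int, SweepDefinition] = {
    3: SweepDefinition(3, 24.0, strict=True, eligible_months=_THREE_MONTH),
    6: SweepDefinition(6, 34.0, strict=False, eligible_months=_SIX_MONTH),
    12: SweepDefinition(12, 60.0, strict=False, eligible_months=MONTHS),
}

SWEEP_ORDER: tuple[int, ...] = (3, 6, 12)


def sweep_availability(month_of_test: str, contacted_6m: bool = True) -> frozenset[int]:
    """Sweeps available to a person given their month of index test."""
    if month_of_test not in MONTHS:
        raise ValueError(f"unknown month of test {month_of_test!r}")
    out = {12}
    if month_of_test in _SIX_MONTH:
        if month_of_test != "2020-12" or contacted_6m:
            out.add(6)
    if month_of_test in _THREE_MONTH:
        out.add(3)
    return frozenset(out)
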