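"""Reading and writing the package's CSV interchange formats.

Cohort files are long format — one row per person per *available* sweep —
with the person-level design covariates repeated on every row; empty
cells encode missing values.  Sweep availability is not stored: it is a
deterministic function of month of test (and the December-2020 contact
flag) and is recomputed on read.  The stored timeliness indicator is
cross-checked against weeks-to-response under each sweep's strict/≤
cutoff rule; disagreement is an error naming the rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .sweeps import SWEEPS, SWEEP_ORDER, sweep_availability

PERSON_COLUMNS = [
    "id", "index_status", "sex", "age_years", "region", "imd_decile",
    "ethnicity", "month_of_test", "contacted_6m",
]

SWEEP_COLUMNS = [
    "responded", "weeks_to_response", "timely", "reinfected",
    "vacc", "phealth", "lonely", "nsympt", "tired", "breathless",
    "swemws", "eqvas", "eq5dy", "sdq", "ucla", "cfs",
]

_SWEEP_COL_MAP = {"weeks_to_response": "weeks"}

ORACLE_PREFIXES = ("true_",)
OBSERVED_PREFIXES = ("obs_",)


def _oracle_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(ORACLE_PREFIXES)]


def _observed_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(OBSERVED_PREFIXES)]


def write_cohort(cohort: pd.DataFrame, path, include_oracle: bool = True
                 ) -> None:
    """Write a wide cohort table as a long person-sweep CSV.

    ``include_oracle=False`` drops the generator-only ``true_*`` latent
    columns (real-data mode must never carry them)."""
    person_cols = PERSON_COLUMNS + _observed_columns(cohort)
    if include_oracle:
        person_cols += _oracle_columns(cohort)
    frames = []
    for s in SWEEP_ORDER:
        avail = cohort[f"available_{s}m"].astype(bool)
        sub = cohort.loc[avail, person_cols].copy()
        sub.insert(len(PERSON_COLUMNS), "sweep", s)
        for col in SWEEP_COLUMNS:
            src = _SWEEP_COL_MAP.get(col, col)
            sub[col] = cohort.loc[avail, f"{src}_{s}m"]
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True).sort_values(["id", "sweep"])
    long.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a long person-sweep CSV back into the wide in-memory layout.

    Validates: unique (id, sweep) rows, consistent person-level fields
    across a person's rows, and agreement of the stored timeliness
    indicator with weeks-to-response under the sweep cutoff rules.
    """
    long = pd.read_csv(path)
    dup = long.duplicated(subset=["id", "sweep"])
    if dup.any():
        raise ValueError(
            f"duplicate (id, sweep) rows at file rows {list(long.index[dup])}")

    extra = [c for c in long.columns
             if c.startswith(ORACLE_PREFIXES + OBSERVED_PREFIXES)]
    person = long[PERSON_COLUMNS + extra].drop_duplicates(subset="id")
    inconsistent = long.groupby("id")[
        [c for c in PERSON_COLUMNS if c != "id"]].nunique(dropna=False)
    bad = inconsistent[(inconsistent > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValueError(f"person-level fields differ across rows for ids {bad}")

    wide = person.reset_index(drop=True).copy()
    wide["contacted_6m"] = wide["contacted_6m"].astype(bool)
    wide["age_years"] = wide["age_years"].astype(int)
    for s in SWEEP_ORDER:
        wide[f"available_{s}m"] = [
            s in sweep_availability(m, c)
            for m, c in zip(wide["month_of_test"], wide["contacted_6m"])
        ]
        rows = long[long["sweep"] == s].set_index("id")
        stray = set(rows.index) - set(
            wide.loc[wide[f"available_{s}m"], "id"])
        if stray:
            raise ValueError(
                f"rows at sweep {s} for persons without that sweep: "
                f"{sorted(stray)[:10]}")
        for col in SWEEP_COLUMNS:
            dst = f"{_SWEEP_COL_MAP.get(col, col)}_{s}m"
            wide[dst] = rows[col].reindex(wide["id"]).to_numpy()

        sweep = SWEEPS[s]
        weeks = wide[f"weeks_{s}m"]
        responded = wide[f"responded_{s}m"] == 1
        if (responded & weeks.isna()).any() or (~responded & weeks.notna()).any():
            bad_ids = wide.loc[(responded & weeks.isna())
                               | (~responded & weeks.notna()), "id"]
            raise ValueError(
                f"weeks_to_response presence disagrees with responded at "
                f"sweep {s} for ids {bad_ids.tolist()[:10]}")
        has = weeks.notna()
        recomputed = sweep.is_timely(weeks[has].to_numpy())
        stored = wide.loc[has, f"timely_{s}m"].to_numpy() == 1
        if (recomputed != stored).any():
            bad_ids = wide.loc[has, "id"].to_numpy()[recomputed != stored]
            raise ValueError(
                f"stored timeliness disagrees with weeks_to_response at "
                f"sweep {s} for ids {bad_ids.tolist()[:10]}")
    return wide


def write_margins(margins: pd.DataFrame, path) -> None:
    margins.to_csv(path, index=False)


def read_margins(path) -> pd.DataFrame:
    margins = pd.read_csv(path)
    needed = {"sex", "age_band", "region", "count"}
    missing = needed - set(margins.columns)
    if missing:
        raise ValueError(f"margins file lacks columns {sorted(missing)}")
    if margins[["sex", "age_band", "region"]].duplicated().any():
        raise ValueError("duplicate cells in margins file")
    if (margins["count"] < 0).any():
        raise ValueError("negative census counts")
    return margins


def write_results(estimates: pd.DataFrame, path) -> None:
    estimates.to_csv(path, index=False)


def write_weightset_csv(weightsets: dict, path) -> None:
    """Per-person per-sweep weights (raw and trimmed) with exclusion flags."""
    frames = []
    for sweep, ws in weightsets.items():
        f = ws.frame.reset_index()
        f.insert(1, "sweep", sweep)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_model_report(model, path) -> None:
    """Coefficient table with a comment header carrying the model's
    identity and diagnostics."""
    path = Path(path)
    header = (
        f"# outcome={model.outcome} sweep={model.sweep}m "
        f"c_statistic={model.c_statistic:.4f} n={model.n_used} "
        f"dropped_for_separation={','.join(model.dropped_for_separation) or 'none'} "
        f"selected={','.join(model.selected_candidates) or 'none'}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        model.report_frame().to_csv(fh, index=False)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
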