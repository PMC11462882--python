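"""CSV schemas for the four claims tables, with validation.

Schemas (all day counts are integers since index discharge = day 0):

* patients.csv: patient_id, entity_id, age, sex (F/M), index_year,
  discharge_day (= 0), censor_day, plus any number of ``cf_`` confounder
  columns.
* prescriptions.csv: patient_id, fill_day, n_packages, package_size,
  dose_per_unit, daily_dose.
* stays.csv: patient_id, admit_day, discharge_day (half-open interval).
* terminal_events.csv: patient_id, event_day, event_type (death/recurrent).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import ClaimsBundle

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "entity_id", "age", "sex", "index_year",
                 "discharge_day", "censor_day"],
    "prescriptions": ["patient_id", "fill_day", "n_packages", "package_size",
                      "dose_per_unit", "daily_dose"],
    "stays": ["patient_id", "admit_day", "discharge_day"],
    "terminal_events": ["patient_id", "event_day", "event_type"],
}

TABLE_FILES = {name: f"{name}.csv" for name in REQUIRED_COLUMNS}


def write_bundle(bundle: ClaimsBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in REQUIRED_COLUMNS:
        path = outdir / TABLE_FILES[name]
        getattr(bundle, name).to_csv(path, index=False)
        paths[name] = path
    return paths


def read_bundle(indir: str | Path) -> ClaimsBundle:
    indir = Path(indir)
    tables = {name: pd.read_csv(indir / TABLE_FILES[name]) for name in REQUIRED_COLUMNS}
    return ClaimsBundle(tables["patients"], tables["prescriptions"],
                        tables["stays"], tables["terminal_events"],
                        meta={"source": str(indir)})


def validate_tables(indir: str | Path) -> list[str]:
    """Schema, referential-integrity and sanity checks; returns a list of
    human-readable problems (empty when the bundle is well-formed)."""
    indir = Path(indir)
    problems: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in REQUIRED_COLUMNS.items():
        path = indir / TABLE_FILES[name]
        if not path.exists():
            problems.append(f"{path.name}: file missing")
            continue
        df = pd.read_csv(path)
        tables[name] = df
        for c in cols:
            if c not in df.columns:
                problems.append(f"{path.name}: missing column {c!r}")
    if "patients" not in tables:
        return problems

    pat = tables["patients"]
    if "patient_id" in pat and pat["patient_id"].duplicated().any():
        dups = pat.loc[pat["patient_id"].duplicated(), "patient_id"].tolist()
        problems.append(f"patients.csv: duplicate patient_id {dups[:5]}")
    if "censor_day" in pat:
        for row in pat.index[pat["censor_day"] < 0]:
            problems.append(f"patients.csv row {row}: negative censor_day")
    known = set(pat.get("patient_id", pd.Series(dtype=int)))
    for name in ("prescriptions", "stays", "terminal_events"):
        df = tables.get(name)
        if df is None or "patient_id" not in df:
            continue
        orphans = df.index[~df["patient_id"].isin(known)]
        for row in orphans:
            problems.append(f"{name}.csv row {row}: unknown patient_id "
                            f"{df.loc[row, 'patient_id']}")
    rx = tables.get("prescriptions")
    if rx is not None and set(REQUIRED_COLUMNS["prescriptions"]) <= set(rx.columns):
        bad = rx.index[(rx["fill_day"] < 0) | (rx["n_packages"] <= 0)
                       | (rx["package_size"] <= 0) | (rx["dose_per_unit"] <= 0)
                       | (rx["daily_dose"] <= 0)]
        for row in bad:
            problems.append(f"prescriptions.csv row {row}: non-positive quantity "
                            "or negative fill_day")
    st = tables.get("stays")
    if st is not None and {"admit_day", "discharge_day"} <= set(st.columns):
        bad = st.index[(st["admit_day"] < 0) | (st["discharge_day"] <= st["admit_day"])]
        for row in bad:
            problems.append(f"stays.csv row {row}: invalid interval "
                            f"[{st.loc[row, 'admit_day']}, {st.loc[row, 'discharge_day']})")
    te = tables.get("terminal_events")
    if te is not None and "event_day" in te.columns:
        for row in te.index[te["event_day"] < 0]:
            problems.append(f"terminal_events.csv row {row}: negative event_day")
    return problems
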