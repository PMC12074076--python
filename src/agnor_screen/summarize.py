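"""Aggregation of per-cell NOR counts into per-patient and per-group tables.

The unit of analysis is the patient: each patient contributes a mean
AgNORs/nucleus over their analyzable cells plus the percentage of cells
in the count classes 1, 2, 3, 4 and 5+.  Group tables then report the
mean ± SD of patient means (SD across patients, n−1 denominator) and the
mean of each class percentage, marking the most frequent class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import MAX_NORS

__all__ = [
    "PatientSummary",
    "patient_summary",
    "summarize_cohort",
    "group_table",
    "write_report",
]

CLASS_COLS = ["pct_1", "pct_2", "pct_3", "pct_4", "pct_5plus"]


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    group_id: str
    n_cells: int
    mean_nors: float
    pct_class: tuple[float, float, float, float, float]


def patient_summary(
    counts, patient_id: str = "", group_id: str = ""
) -> PatientSummary:
    """Mean count and class percentages (1..4 and 5+) for one patient."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("patient has no cells")
    if counts.min() < 1 or counts.max() > MAX_NORS:
        raise ValueError(f"counts must lie in [1, {MAX_NORS}]")
    n = counts.size
    pct = [100.0 * np.count_nonzero(counts == k) / n for k in (1, 2, 3, 4)]
    pct.append(100.0 * np.count_nonzero(counts >= 5) / n)
    return PatientSummary(patient_id, group_id, n, float(counts.mean()), tuple(pct))


def summarize_cohort(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-patient summaries for a long-format cell table.

    Returns columns ``patient_id, group_id, n_cells, mean_nors,
    pct_1..pct_5plus``, one row per patient, patient order preserved.
    """
    rows = []
    for (pid, gid), sub in cells.groupby(["patient_id", "group_id"], sort=False):
        s = patient_summary(sub["nor_count"].to_numpy(), pid, gid)
        rows.append((s.patient_id, s.group_id, s.n_cells, s.mean_nors, *s.pct_class))
    return pd.DataFrame(
        rows, columns=["patient_id", "group_id", "n_cells", "mean_nors", *CLASS_COLS]
    )


def group_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Group-level table: mean ± SD of patient means, mean class percentages.

    SD uses the n−1 denominator across patients; a group with fewer than
    two patients gets a missing SD (with a warning).  The most frequent
    class (highest mean percentage; ties to the lower class) is marked in
    ``top_class``.
    """
    rows = []
    for gid, sub in patients.groupby("group_id", sort=False):
        means = sub["mean_nors"].to_numpy()
        if len(sub) < 2:
            warnings.warn(f"group {gid}: fewer than 2 patients, SD undefined")
            sd = np.nan
        else:
            sd = float(means.std(ddof=1))
        pct_means = [float(sub[c].mean()) for c in CLASS_COLS]
        top = int(np.argmax(pct_means)) + 1  # argmax takes the first (lower class) on ties
        rows.append((gid, len(sub), float(means.mean()), sd, *pct_means, top))
    return pd.DataFrame(
        rows,
        columns=["group_id", "n_patients", "mean_nors", "sd_nors", *CLASS_COLS, "top_class"],
    )


def write_report(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, excel: bool = False
) -> list[Path]:
    """Write each table as ``<name>.csv`` (means 2 dp, percentages 1 dp).

    With ``excel=True`` an additional workbook ``report.xlsx`` holds one
    sheet per table.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rounded: dict[str, pd.DataFrame] = {}
    for name, table in tables.items():
        t = table.copy()
        for col in t.columns:
            if col.startswith("pct_"):
                t[col] = t[col].astype(float).round(1)
            elif col in ("mean_nors", "sd_nors"):
                t[col] = t[col].astype(float).round(2)
        rounded[name] = t
        path = out_dir / f"{name}.csv"
        t.to_csv(path, index=False)
        written.append(path)
    if excel:
        xlsx = out_dir / "report.xlsx"
        with pd.ExcelWriter(xlsx) as writer:
            for name, t in rounded.items():
                t.to_excel(writer, sheet_name=name[:31], index=False)
        written.append(xlsx)
    return written
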