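"""Readers and writers for the pipeline's file formats.

Canonical dialect is TSV (UTF-8, '.' decimal); CSV is accepted on read.
Cohorts are ``subject_id<TAB>outcome<TAB>predictor...`` tables; fitted
categorizations serialize to JSON; association and subsample results are
tidy TSVs.  Also packaged here: the 20 published case-control summary
tables (top AMC-categorized NLP variables from the emulated VA suicide
cohort, 4990 cases vs 20,352 controls), transcribed as count fixtures with
their printed thresholds and chi-square -log10 p-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .amc import Categorization
from .stats import ContingencyTable
from .synthetic import CohortTable

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_dictionary_map",
    "read_dictionary_map",
    "write_categorizations",
    "read_categorizations",
    "PublishedTable",
    "load_published_tables",
]


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    cohort.to_frame().to_csv(path, sep=sep, index=False)


def read_cohort(path: str | Path, dictionary_map: dict[str, str] | None = None) -> CohortTable:
    """Read a cohort table, validating header, outcome codes and values.

    Errors are addressed by row (1-based data rows) and column so malformed
    files can be fixed without guesswork.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if list(df.columns[:2]) != ["subject_id", "outcome"]:
        raise ValueError(
            f"{path}: header must start with 'subject_id', 'outcome' "
            f"(got {list(df.columns[:2])})"
        )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: no predictor columns")
    ids = df["subject_id"].astype(str).to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate subject_id at row {int(dup.idxmax()) + 1}")
    outcome = df["outcome"].to_numpy()
    bad = ~np.isin(outcome, (0, 1))
    if bad.any():
        raise ValueError(
            f"{path}: outcome must be 0/1; offending row {int(np.flatnonzero(bad)[0]) + 1}"
        )
    pred_cols = list(df.columns[2:])
    values = np.empty((len(df), len(pred_cols)))
    for j, col in enumerate(pred_cols):
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        nan = ~np.isfinite(v)
        if nan.any():
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"row {int(np.flatnonzero(nan)[0]) + 1}"
            )
        if (v < 0).any():
            raise ValueError(
                f"{path}: negative value in column {col!r}, "
                f"row {int(np.flatnonzero(v < 0)[0]) + 1}"
            )
        values[:, j] = v
    return CohortTable(
        subject_id=ids,
        outcome=outcome.astype(np.int64),
        values=values,
        predictor_names=tuple(pred_cols),
        dictionary_map=dictionary_map,
    )


def write_dictionary_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"predictor": list(mapping), "dictionary": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_dictionary_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["predictor", "dictionary"]:
        raise ValueError(f"{path}: expected columns 'predictor', 'dictionary'")
    return dict(zip(df["predictor"].astype(str), df["dictionary"].astype(str)))


def write_categorizations(cats: list[Categorization], path: str | Path) -> None:
    payload = [
        {
            "predictor": c.predictor_name,
            "method": c.method,
            "thresholds": list(c.thresholds),
            "k": c.k,
            "counts": list(c.category_counts),
            "selection_minus_log10_p": (
                None
                if np.isnan(c.selection_minus_log10_p)
                else _round4(c.selection_minus_log10_p)
            ),
            "degenerate": c.degenerate,
        }
        for c in cats
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _round4(x: float) -> float | str:
    if np.isinf(x):
        return "inf"
    return float(f"{x:.4g}")


def read_categorizations(path: str | Path) -> list[Categorization]:
    payload = json.loads(Path(path).read_text())
    out = []
    for rec in payload:
        sel = rec.get("selection_minus_log10_p")
        sel = float("nan") if sel is None else float(sel)
        out.append(
            Categorization(
                predictor_name=rec["predictor"],
                thresholds=tuple(rec["thresholds"]),
                category_counts=tuple(rec["counts"]),
                method=rec["method"],
                selection_minus_log10_p=sel,
                degenerate=bool(rec.get("degenerate", False)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Published summary-table fixtures
# ---------------------------------------------------------------------------

_CASE_TOTAL = 4990
_CONTROL_TOTAL = 20352


@dataclass(frozen=True)
class PublishedTable:
    """One published AMC categorization of an NLP variable, with its
    case/control counts per category and the printed chi-square result."""

    name: str
    dictionary: str
    form: str  # "positive" | "negative"
    thresholds: tuple[float, ...]
    table: ContingencyTable
    published_minus_log10_p: float

    @property
    def label(self) -> str:
        return f"{self.name} ({self.dictionary}), {self.form}"


def load_published_tables() -> list[PublishedTable]:
    """Load the 20 packaged case-control summary tables.

    Each table's case column must sum to 4990 and control column to 20,352;
    a mismatch means the packaged transcription is corrupt and raises.
    """
    raw = (
        resources.files("amcsuite.data")
        .joinpath("published_top20_tables.json")
        .read_text()
    )
    out = []
    for rec in json.loads(raw):
        cases = np.asarray(rec["case_counts"], dtype=np.int64)
        controls = np.asarray(rec["control_counts"], dtype=np.int64)
        if cases.sum() != _CASE_TOTAL or controls.sum() != _CONTROL_TOTAL:
            raise ValueError(
                f"fixture {rec['name']} ({rec['form']}): column sums "
                f"{cases.sum()}/{controls.sum()} != {_CASE_TOTAL}/{_CONTROL_TOTAL}"
            )
        out.append(
            PublishedTable(
                name=rec["name"],
                dictionary=rec["dictionary"],
                form=rec["form"],
                thresholds=tuple(rec["thresholds"]),
                table=ContingencyTable(
                    np.column_stack([cases, controls]),
                    name=f"{rec['name']}|{rec['form']}",
                ),
                published_minus_log10_p=float(rec["published_minus_log10_p"]),
            )
        )
    return out
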