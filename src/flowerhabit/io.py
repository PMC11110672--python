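"""Readers and writers for every table the pipeline touches.

All files are UTF-8 CSV/TSV with a mandatory header.  Required columns are
validated by name; unknown columns are preserved but never interpreted.
Writers are deterministic: identical inputs produce byte-identical files.
Percentages in summaries are kept at full precision internally and rendered
to 2 decimals with half-away-from-zero rounding.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from ._utils import round_half_away
from .ontology import CollectionSummary
from .phenotyping import SCORE_LEVELS

__all__ = [
    "SchemaError",
    "read_plot_records",
    "write_plot_records",
    "read_raw_records",
    "write_raw_records",
    "read_truth_labels",
    "write_truth_labels",
    "read_phenotypes",
    "write_phenotypes",
    "read_calls",
    "write_calls",
    "read_summary",
    "write_summary",
    "load_config",
    "save_config",
]


class SchemaError(ValueError):
    """A table violated its required schema."""


_SCHEMAS = {
    "plot_records": ("accession_id", "year", "block", "pct60", "pct100"),
    "raw_records": ("accession_id", "year", "block", "n_plants", "frac60", "frac100"),
    "truth_labels": ("accession_id", "true_category", "p_early_annual", "p_late_annual", "p_biennial"),
    "phenotypes": ("accession_id", "scope", "emm60", "emm100", "n_plots_used"),
    "calls": ("accession_id", "scheme", "category", "subcategory", "emm60", "emm100"),
}

#: printed row order of collection summaries
SUMMARY_ROWS = (
    ("Biennial", "category", "biennial"),
    ("Mixture", "category", "mixture"),
    ("Predominantly biennial", "subcategory", "predominantly_biennial"),
    ("All other mixtures", "subcategory", "other_mixture"),
    ("Annual", "category", "annual"),
    ("Annual (non-uniform)", "subcategory", "non_uniform_annual"),
    ("Uniformly-early annual", "subcategory", "uniformly_early_annual"),
    ("Uniformly-late annual", "subcategory", "uniformly_late_annual"),
    ("Flowering 60 DAS", "flowering", "60"),
    ("Flowering 100 DAS", "flowering", "100"),
)


def _validate(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for {kind}")
    return df


def _check_duplicates(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=["accession_id", "year", "block"])
    if dup.any():
        row = int(dup.idxmax())
        raise SchemaError(f"{path}: duplicate (accession_id, year, block) at row {row}")


def read_plot_records(path, strict: bool = False) -> pd.DataFrame:
    """Read scored plot observations; reject duplicates and, in strict mode,
    scores off the 5-point scale (error names the row and column)."""
    df = _validate(pd.read_csv(path), "plot_records", path)
    _check_duplicates(df, path)
    for col in ("pct60", "pct100"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {row}")
        if ((vals < 0) | (vals > 100)).any():
            row = int(((vals < 0) | (vals > 100)).idxmax())
            raise SchemaError(f"{path}: score out of [0,100] in column {col!r} at row {row}")
        if strict:
            bad = ~vals.isin(SCORE_LEVELS)
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{path}: score {vals[row]} not on the 5-point scale in "
                    f"column {col!r} at row {row}"
                )
        df[col] = vals.astype(float)
    return df


def write_plot_records(df: pd.DataFrame, path) -> None:
    _validate(df, "plot_records", path)
    df.to_csv(path, index=False, lineterminator="\n")


def read_raw_records(path) -> pd.DataFrame:
    """Read simulator output: per-plot flowering fractions in [0, 1]."""
    df = _validate(pd.read_csv(path), "raw_records", path)
    _check_duplicates(df, path)
    for col in ("frac60", "frac100"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise SchemaError(f"{path}: column {col!r} must lie in [0, 1]")
    return df


def write_raw_records(df: pd.DataFrame, path) -> None:
    _validate(df, "raw_records", path)
    df.to_csv(path, index=False, lineterminator="\n")


def read_truth_labels(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), "truth_labels", path)


def write_truth_labels(df: pd.DataFrame, path) -> None:
    _validate(df, "truth_labels", path)
    df.to_csv(path, index=False, lineterminator="\n")


def read_phenotypes(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), "phenotypes", path)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    _validate(df, "phenotypes", path)
    df.to_csv(path, index=False, lineterminator="\n")


def read_calls(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path), "calls", path)


def write_calls(df: pd.DataFrame, path) -> None:
    _validate(df, "calls", path)
    df.to_csv(path, index=False, lineterminator="\n")


def write_summary(summary: CollectionSummary, path) -> None:
    """Write a collection summary as TSV in the printed row order."""
    rows = []
    for label, kind, key in SUMMARY_ROWS:
        if kind == "category":
            n = summary.category_counts.get(key, 0)
        elif kind == "subcategory":
            n = summary.subcategory_counts.get(key, 0)
        else:
            n = summary.n_flowering_60 if key == "60" else summary.n_flowering_100
        rows.append(
            {
                "row": label,
                "n": n,
                "percent": f"{round_half_away(100.0 * n / summary.denominator, 2):.2f}",
                "scheme": summary.scheme,
                "denominator": summary.denominator,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_summary(path) -> CollectionSummary:
    df = pd.read_csv(path, sep="\t")
    for col in ("row", "n", "scheme", "denominator"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r} in summary")
    by_row = dict(zip(df["row"], df["n"].astype(int)))
    label_of = {label: (kind, key) for label, kind, key in SUMMARY_ROWS}
    s = CollectionSummary(
        scheme=str(df["scheme"].iloc[0]), denominator=int(df["denominator"].iloc[0])
    )
    for label, n in by_row.items():
        kind, key = label_of[label]
        if kind == "category":
            s.category_counts[key] = n
        elif kind == "subcategory":
            s.subcategory_counts[key] = n
        elif key == "60":
            s.n_flowering_60 = n
        else:
            s.n_flowering_100 = n
    return s


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: run config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False), encoding="utf-8"
    )
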