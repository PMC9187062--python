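"""Series-matrix-style file I/O and auxiliary tables.

The dialect is a simplified series matrix: "!"-prefixed header lines carry
per-sample annotations ("!Sample_title" plus one "!Sample_characteristics"
line each for class, cancer_type and batch), and the probe x sample value
table sits between ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
markers.  Fields are tab-separated; strings are double-quoted; empty value
cells encode absent measurements.  ``write_series_matrix`` and
``read_series_matrix`` are exact inverses on valid matrices.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig, SplitPlan
from .matrix import ANNOTATION_COLUMNS, ExpressionMatrix, ValidationError
from .simulate import SyntheticTruth

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when a series-matrix file cannot be parsed."""


def _quote(s: str) -> str:
    return '"' + str(s) + '"'


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


def write_series_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    """Write a matrix in the series-matrix dialect (re-readable exactly)."""
    if matrix.n_probes == 0:
        raise ValidationError("refusing to write a matrix with no probes")
    if matrix.n_samples == 0:
        raise ValidationError("refusing to write a matrix with no samples")
    lines = []
    ids = matrix.sample_ids
    lines.append("!Sample_title\t" + "\t".join(_quote(s) for s in ids))
    for key in ANNOTATION_COLUMNS:
        vals = matrix.samples[key]
        lines.append("!Sample_characteristics\t" + "\t".join(
            _quote(f"{key}: {vals[s]}") for s in ids))
    lines.append(TABLE_BEGIN)
    lines.append('"ID_REF"\t' + "\t".join(_quote(s) for s in ids))
    values = matrix.values
    for probe in matrix.probe_ids:
        row = values.loc[probe]
        cells = ["" if (isinstance(v, float) and math.isnan(v)) else repr(float(v))
                 for v in row.to_numpy()]
        lines.append(_quote(probe) + "\t" + "\t".join(cells))
    lines.append(TABLE_END)
    Path(path).write_text("\n".join(lines) + "\n")


def read_series_matrix(path: PathLike) -> ExpressionMatrix:
    """Parse a series-matrix dialect file into an :class:`ExpressionMatrix`.

    Tolerates CR/LF line endings and trailing blank lines; requires exactly
    one table block with both delimiters.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip("\r") for ln in text.split("\n")]
    while lines and lines[-1] == "":
        lines.pop()
    try:
        begin = lines.index(TABLE_BEGIN)
    except ValueError:
        raise ParseError(f"{path}: missing {TABLE_BEGIN} marker") from None
    try:
        end = lines.index(TABLE_END)
    except ValueError:
        raise ParseError(f"{path}: missing {TABLE_END} marker") from None
    if end <= begin:
        raise ParseError(f"{path}: table end marker precedes begin marker")
    if TABLE_BEGIN in lines[begin + 1:]:
        raise ParseError(f"{path}: more than one table block")

    sample_ids = None
    characteristics: dict = {}
    for ln in lines[:begin]:
        if not ln.startswith("!"):
            continue
        parts = ln.split("\t")
        tag = parts[0]
        if tag == "!Sample_title":
            sample_ids = [_unquote(c) for c in parts[1:]]
        elif tag == "!Sample_characteristics":
            cells = [_unquote(c) for c in parts[1:]]
            keys = set()
            vals = []
            for c in cells:
                if ":" not in c:
                    raise ParseError(
                        f"{path}: malformed characteristics cell {c!r}")
                k, v = c.split(":", 1)
                keys.add(k.strip())
                vals.append(v.strip())
            if len(keys) != 1:
                raise ParseError(f"{path}: mixed keys in one "
                                 f"characteristics line: {sorted(keys)}")
            characteristics[keys.pop()] = vals

    header = [_unquote(c) for c in lines[begin + 1].split("\t")]
    table_samples = header[1:]
    if sample_ids is None:
        sample_ids = table_samples
    if table_samples != sample_ids:
        raise ParseError(f"{path}: table columns disagree with !Sample_title")
    if len(set(sample_ids)) != len(sample_ids):
        dup = [s for s in sample_ids if sample_ids.count(s) > 1][0]
        raise ValidationError(f"{path}: duplicated sample ID {dup!r}")

    probe_ids = []
    rows = []
    for ln in lines[begin + 2:end]:
        cells = ln.split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}: row {_unquote(cells[0])!r} has {len(cells) - 1} "
                f"values, expected {len(sample_ids)}")
        probe = _unquote(cells[0])
        vals = []
        for sample, cell in zip(sample_ids, cells[1:]):
            cell = cell.strip()
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {probe!r}, "
                    f"column {sample!r}: {cell!r}") from None
        probe_ids.append(probe)
        rows.append(vals)
    if not probe_ids:
        raise ParseError(f"{path}: empty table block")

    frame = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    missing = [k for k in ANNOTATION_COLUMNS if k not in characteristics]
    if missing:
        raise ParseError(f"{path}: missing sample characteristics: {missing}")
    samples = pd.DataFrame(
        {k: characteristics[k] for k in ANNOTATION_COLUMNS}, index=sample_ids)
    return ExpressionMatrix(frame, samples)


# ----------------------------------------------------------------------
# auxiliary tables
# ----------------------------------------------------------------------
def write_truth(truth: SyntheticTruth, path: PathLike) -> None:
    rows = []
    for p in sorted(truth.pan_marker_ids):
        rows.append((p, "pan", "", truth.direction[p], truth.effect_delta))
    for p, t in sorted(truth.type_marker_ids.items()):
        rows.append((p, "type", t, truth.direction[p], truth.effect_delta))
    pd.DataFrame(rows, columns=["probe_id", "role", "type", "direction",
                                "delta"]).to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "type": str},
                     keep_default_na=False)
    truth = SyntheticTruth()
    for _, row in df.iterrows():
        if row["role"] == "pan":
            truth.pan_marker_ids.add(row["probe_id"])
        else:
            truth.type_marker_ids[row["probe_id"]] = row["type"]
        truth.direction[row["probe_id"]] = row["direction"]
        truth.effect_delta = float(row["delta"])
    return truth


def read_split_plan(path: PathLike, seed: int = 0) -> SplitPlan:
    """Read a split plan TSV (columns: type, fraction); a row with type
    ``non_cancer`` sets the control fraction."""
    df = pd.read_csv(path, sep="\t")
    fractions = dict(zip(df["type"].astype(str), df["fraction"].astype(float)))
    non_cancer = fractions.pop("non_cancer", 0.7997)
    return SplitPlan(fraction_by_type=fractions, non_cancer_fraction=non_cancer,
                     seed=seed)


def write_split_plan(plan: SplitPlan, path: PathLike) -> None:
    rows = sorted(plan.fraction_by_type.items())
    rows.append(("non_cancer", plan.non_cancer_fraction))
    pd.DataFrame(rows, columns=["type", "fraction"]).to_csv(
        path, sep="\t", index=False)


def load_config(path: PathLike) -> PipelineConfig:
    """Load a flat YAML key/value file mirroring PipelineConfig field names."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    field_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - field_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
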