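"""Delimited-text formats for drug tables and stopped-flow trace sessions.

All files are comma-separated UTF-8 with a header row and '.' decimal
separator.  A trace *session* is a directory containing a
``manifest.csv`` (columns: file, mix_type, replicate_id) and one
two-column trace file (time_s, fluorescence) per mixing reaction.
Writers format floats with a fixed repr so fixed-seed pipelines are
byte-identical across runs.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .cohort import DrugRecord
from .fitting import FluorescenceTrace, TraceFitResult

__all__ = [
    "SchemaError",
    "SessionError",
    "read_drug_table",
    "write_drug_table",
    "read_trace_session",
    "write_trace_session",
    "write_fit_report",
]

CC20_TRUNCATION_UM = 80.0

MANDATORY_COLUMNS = ("id", "alogp", "psa", "qed", "pscore", "cc20", "normrate")
OPTIONAL_FLOAT_COLUMNS = ("fu_mouse", "fu_mic", "normrate_disp")


class SchemaError(ValueError):
    """A table or manifest does not match the documented schema."""


class SessionError(ValueError):
    """A trace-session directory is missing or unreadable."""


def _parse_float(raw: str, column: str, line: int, path) -> float | None:
    raw = raw.strip()
    if raw == "" or raw.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"{path}: line {line}: malformed number {raw!r} in column {column!r}"
        ) from None


def read_drug_table(path) -> list[DrugRecord]:
    """Read a per-drug library table into typed records.

    Blank CC20 fields become missing values; CC20 values above the
    80 µM assay truncation are clamped with a warning.  Unknown columns
    are ignored (preserved by round-tripping through pandas if needed).
    Missing mandatory columns raise `SchemaError` naming them.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns: {missing}")
        records = []
        for line_no, row in enumerate(reader, start=2):
            vals = {
                c: _parse_float(row[c], c, line_no, path)
                for c in ("alogp", "psa", "qed", "pscore", "cc20", "normrate")
            }
            for c in ("alogp", "psa", "qed", "pscore", "normrate"):
                if vals[c] is None:
                    raise SchemaError(
                        f"{path}: line {line_no}: column {c!r} must not be blank"
                    )
            cc20 = vals["cc20"]
            if cc20 is not None and cc20 > CC20_TRUNCATION_UM:
                warnings.warn(
                    f"{path}: line {line_no}: CC20 {cc20:g} µM clamped to the "
                    f"{CC20_TRUNCATION_UM:g} µM assay truncation",
                    stacklevel=2,
                )
                cc20 = CC20_TRUNCATION_UM
            opt = {}
            for c in OPTIONAL_FLOAT_COLUMNS:
                opt[c] = _parse_float(row[c], c, line_no, path) if c in row and row[c] is not None else None
            records.append(
                DrugRecord(
                    id=row["id"],
                    alogp=vals["alogp"],
                    psa=vals["psa"],
                    qed=vals["qed"],
                    pscore=vals["pscore"],
                    normrate=vals["normrate"],
                    cc20=cc20,
                    fu_mouse=opt["fu_mouse"],
                    fu_mic=opt["fu_mic"],
                    normrate_disp=opt["normrate_disp"] or 0.0,
                    disp_kind=(row.get("disp_kind") or "half_range"),
                )
            )
    return records


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def write_drug_table(drugs: Sequence, path) -> None:
    """Write drug records (DrugRecord or SyntheticDrug) as CSV."""
    path = Path(path)
    extra = ["true_normrate"] if hasattr(drugs[0], "true_normrate") else []
    cols = ["id", "alogp", "psa", "qed", "pscore", "cc20", "fu_mouse",
            "fu_mic", "normrate", "normrate_disp", "disp_kind", *extra]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for d in drugs:
            row = []
            for c in cols:
                v = getattr(d, c, None)
                row.append(v if c in ("id", "disp_kind") else _fmt(v))
            writer.writerow(row)


def write_trace_session(traces: Sequence[FluorescenceTrace], path) -> None:
    """Write traces plus manifest.csv into a session directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tr in enumerate(traces):
        fname = f"trace_{i:03d}_{tr.mix_type}.csv"
        df = pd.DataFrame({"time_s": tr.time, "fluorescence": tr.signal})
        df.to_csv(path / fname, index=False, float_format="%.10g")
        rows.append({"file": fname, "mix_type": tr.mix_type,
                     "replicate_id": tr.replicate_id})
    pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)


def read_trace_session(path) -> list[FluorescenceTrace]:
    """Read a session directory of stopped-flow traces.

    Requires a manifest distinguishing buffer from quencher mixes;
    non-monotone time columns and truncated files are rejected with the
    offending file named.
    """
    path = Path(path)
    manifest = path / "manifest.csv"
    if not path.is_dir() or not manifest.exists():
        raise SessionError(f"{path}: not a trace session (manifest.csv missing)")
    mdf = pd.read_csv(manifest)
    required = {"file", "mix_type", "replicate_id"}
    if not required.issubset(mdf.columns):
        raise SchemaError(f"{manifest}: manifest needs columns {sorted(required)}")
    if len(mdf) == 0:
        raise SessionError(f"{path}: empty session")
    traces = []
    for _, row in mdf.iterrows():
        fpath = path / row["file"]
        try:
            df = pd.read_csv(fpath)
        except (FileNotFoundError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
            raise SessionError(f"{fpath}: unreadable trace file: {e}") from e
        if not {"time_s", "fluorescence"}.issubset(df.columns):
            raise SchemaError(f"{fpath}: needs columns time_s, fluorescence")
        t = df["time_s"].to_numpy(float)
        s = df["fluorescence"].to_numpy(float)
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(s)):
            raise SessionError(f"{fpath}: non-finite values (truncated file?)")
        try:
            traces.append(
                FluorescenceTrace(time=t, signal=s,
                                  mix_type=str(row["mix_type"]),
                                  replicate_id=str(row["replicate_id"]))
            )
        except ValueError as e:
            raise SessionError(f"{fpath}: {e}") from e
    return traces


def write_fit_report(results: Sequence[TraceFitResult], path) -> None:
    """Per-trace fit report: replicate id, rate, model params, r², flags."""
    rows = []
    for r in results:
        rows.append({
            "replicate_id": r.replicate_id,
            "rate0": r.rate0,
            "beta": r.params.beta,
            "tau0": r.params.tau0,
            "f0q": r.params.f0q,
            "finfq": r.params.finfq,
            "r2": r.r2,
            "converged": r.converged,
            "qc_flags": ";".join(sorted(r.qc_flags)),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
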