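"""Reading, validating and writing event-onset sequences.

The only input to every rhythm computation in this package is an ordered
list of element start times in seconds ("onsets"), typically exported from
an annotation tool.  Two plain-text dialects are supported: a single-column
CSV of onset times, and tab-separated label files in the Audacity dialect
(``start<TAB>end[<TAB>label]``) where only the start column enters the
analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, UgofError, ValidationError

logger = logging.getLogger("ugof")

#: significant digits used when rendering floats in reports
REPORT_PRECISION = 6


@dataclass
class OnsetSequence:
    """An ordered sequence of event-onset times in seconds.

    Parameters
    ----------
    id
        Text label identifying the sequence (file stem, individual, ...).
    onsets
        Strictly increasing, finite, nonnegative times in seconds.
    labels
        Optional per-element text tags (same length as ``onsets``).
    source
        Originating file path, or ``"synthetic"``.
    meta
        Free-form metadata; synthetic generators record ground truth here.
    """

    id: str
    onsets: np.ndarray
    labels: list[str] | None = None
    source: str = "synthetic"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1 or self.onsets.size < 1:
            raise ValidationError(f"sequence {self.id!r}: need >= 1 onset")
        if not np.all(np.isfinite(self.onsets)):
            raise ValidationError(f"sequence {self.id!r}: non-finite onset")
        if np.any(self.onsets < 0):
            raise ValidationError(f"sequence {self.id!r}: negative onset")
        d = np.diff(self.onsets)
        if np.any(d == 0):
            raise ValidationError(
                f"sequence {self.id!r}: duplicate onset times "
                "(two events at identical time break interval analysis)"
            )
        if np.any(d < 0):
            raise ValidationError(
                f"sequence {self.id!r}: onsets not sorted; use from_times() "
                "to sort on construction"
            )
        if self.labels is not None and len(self.labels) != self.onsets.size:
            raise ValidationError(
                f"sequence {self.id!r}: {len(self.labels)} labels for "
                f"{self.onsets.size} onsets"
            )

    @classmethod
    def from_times(
        cls,
        times: Sequence[float],
        id: str = "sequence",
        labels: Sequence[str] | None = None,
        source: str = "synthetic",
        meta: dict[str, Any] | None = None,
    ) -> "OnsetSequence":
        """Build a sequence, sorting unordered input with a warning.

        Duplicate timestamps are always a hard error: two events at the
        same instant produce a zero interonset interval.
        """
        arr = np.asarray(times, dtype=float)
        labs = list(labels) if labels is not None else None
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            logger.warning("WARN sequence %r: onsets unsorted, sorting", id)
            order = np.argsort(arr, kind="stable")
            arr = arr[order]
            if labs is not None:
                labs = [labs[i] for i in order]
        return cls(id=id, onsets=arr, labels=labs, source=source,
                   meta=meta or {})

    def __len__(self) -> int:
        return int(self.onsets.size)

    @property
    def duration(self) -> float:
        """Time from first to last onset, seconds."""
        return float(self.onsets[-1] - self.onsets[0])


def read_onsets_csv(path: str | Path, column: str | int = 0) -> OnsetSequence:
    """Read one onset sequence from a CSV column.

    ``column`` may be a header name or a 0-based index.  A header row is
    detected automatically (a first cell that does not parse as a number).
    Unsorted rows are sorted with a warning; duplicates raise
    :class:`~ugof.exceptions.ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: int | None = 0
    try:
        first = pd.read_csv(path, nrows=1, header=None)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file")
    if isinstance(column, int):
        try:
            float(first.iloc[0, column])
            header = None  # first row is data
        except (ValueError, TypeError, IndexError):
            header = 0
    df = pd.read_csv(path, header=header)
    if isinstance(column, int):
        if column >= df.shape[1]:
            raise ParseError(f"{path}: no column {column}")
        col = df.iloc[:, column]
    else:
        if column not in df.columns:
            raise ParseError(f"{path}: no column named {column!r}")
        col = df[column]
    values = pd.to_numeric(col, errors="coerce")
    bad = values.isna() & col.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {col.iloc[row]!r}",
            line=row + 1 + (1 if header == 0 else 0),
        )
    values = values.dropna()
    if values.empty:
        raise ParseError(f"{path}: no onset values")
    return OnsetSequence.from_times(
        values.to_numpy(), id=path.stem, source=str(path)
    )


def read_label_file(path: str | Path) -> OnsetSequence:
    """Read an Audacity-style label track: ``start<TAB>end[<TAB>label]``.

    Only the start column becomes an onset; end times are discarded because
    rhythm analysis here operates on element starts alone.  Labels, when
    present on every line, are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    onsets: list[float] = []
    labels: list[str] = []
    any_label = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: expected >= 2 tab-separated fields, got "
                    f"{len(fields)}", line=lineno)
            try:
                start = float(fields[0])
                float(fields[1])  # end must parse even though unused
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric start/end in {line!r}", line=lineno)
            onsets.append(start)
            if len(fields) >= 3:
                any_label = True
                labels.append(fields[2])
            else:
                labels.append("")
    if not onsets:
        raise ParseError(f"{path}: no label lines")
    return OnsetSequence.from_times(
        onsets, id=path.stem, labels=labels if any_label else None,
        source=str(path))


def _sig(x: float, digits: int = REPORT_PRECISION) -> float:
    """Round to ``digits`` significant digits (report rendering rule)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _as_record(obj: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        rec = dataclasses.asdict(obj)
    elif isinstance(obj, dict):
        rec = dict(obj)
    else:
        raise UgofError(f"cannot serialize {type(obj).__name__}")
    out: dict[str, Any] = {}
    for key, val in rec.items():
        if isinstance(val, np.ndarray):
            val = val.tolist()
        if isinstance(val, (list, tuple)):
            val = [_sig(v) if isinstance(v, (float, np.floating)) else v
                   for v in val]
        elif isinstance(val, (float, np.floating)):
            val = _sig(float(val))
        elif isinstance(val, (np.integer,)):
            val = int(val)
        out[key] = val
    return out


def write_report(
    results: Iterable[Any], path: str | Path, format: str = "csv"
) -> None:
    """Write analysis results (dataclasses or dicts) to CSV or JSON.

    Field order is deterministic (declaration order); floats are rendered
    with 6 significant digits.  An empty collection is an error.
    """
    records = [_as_record(r) for r in results]
    if not records:
        raise UgofError("write_report: empty result collection")
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        rows = []
        for rec in records:
            # per-element lists explode into one row per element
            listcols = {k: v for k, v in rec.items() if isinstance(v, list)}
            scalars = {k: v for k, v in rec.items() if k not in listcols}
            if listcols:
                n = max(len(v) for v in listcols.values())
                for i in range(n):
                    row = dict(scalars)
                    row["element"] = i
                    for k, v in listcols.items():
                        row[k] = v[i] if i < len(v) else ""
                    rows.append(row)
            else:
                rows.append(scalars)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise UgofError(f"unknown report format {format!r}")


def write_onsets_csv(seq: OnsetSequence, path: str | Path) -> None:
    """Write a sequence back to single-column CSV (header ``onset_s``)."""
    pd.DataFrame({"onset_s": seq.onsets}).to_csv(path, index=False)
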