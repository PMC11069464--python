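"""File formats: archive-dialect series files, token streams, reports.

The series dialect is the one the public classification archives
distribute: one series per line, tab-separated, the first field an
integer class label and the remaining fields the values.  Labels are
retained for evaluation only — training code paths receive bare value
matrices.  Comma-separated files are accepted via ``delimiter=","``.
"""

from __future__ import annotations

import json

import numpy as np

from .exceptions import EmptyInputError, FormatError
from .series import Dataset

__all__ = [
    "read_ucr",
    "write_ucr",
    "read_tokens",
    "write_assignments",
    "write_umatrix",
]


def read_ucr(path, delimiter: str = "\t") -> Dataset:
    """Read a label-first, delimiter-separated series file.

    Rows of differing lengths are rejected outright (variable-length
    series are outside the scope of equal-length DTW comparison).
    """
    rows, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need a label and at least one value")
            try:
                label = int(float(fields[0]))
                values = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if rows and len(values) != len(rows[0]):
                raise FormatError(
                    f"{path}:{lineno}: ragged row (length {len(values)} vs "
                    f"{len(rows[0])}); variable-length series are not supported"
                )
            rows.append(values)
            labels.append(label)
    if not rows:
        raise EmptyInputError(f"{path}: no series found")
    return Dataset(values=np.asarray(rows), labels=np.asarray(labels), name=str(path))


def write_ucr(dataset: Dataset, path, delimiter: str = "\t") -> None:
    """Write a dataset in the label-first dialect (label 0 when absent)."""
    labels = dataset.labels if dataset.labels is not None else np.zeros(dataset.n, dtype=int)
    with open(path, "w") as fh:
        for i in range(dataset.n):
            fields = [str(int(labels[i]))] + [repr(float(v)) for v in dataset.values[i]]
            fh.write(delimiter.join(fields) + "\n")


def read_tokens(path, delimiter: str = "\t") -> dict[str, list[tuple[int, str]]]:
    """Read tagged-token streams: ``conversation_id  position  tag`` rows.

    Returns a mapping of conversation id to its (position, tag) list in
    file order.
    """
    streams: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'id position tag'")
            conv, pos, tag = fields
            try:
                pos = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position") from None
            streams.setdefault(conv, []).append((pos, tag))
    return streams


def write_assignments(ids, labels, path) -> None:
    """Comma-separated assignment table: series id, cluster label."""
    with open(path, "w") as fh:
        fh.write("id,label\n")
        for sid, lab in zip(ids, labels):
            fh.write(f"{sid},{int(lab)}\n")


def write_umatrix(umatrix: np.ndarray, path, delimiter: str = "\t") -> None:
    """Tab-separated U-matrix grid, one mesh row per line."""
    with open(path, "w") as fh:
        for row in np.atleast_2d(umatrix):
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
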