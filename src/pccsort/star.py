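"""Minimal STAR-dialect reader/writer for particle tables.

Supports exactly the subset emitted by symmetry-expansion tooling: one
``data_`` block, one ``loop_`` with ``_tag`` column headers, whitespace-
delimited rows, ``#`` comments and blank lines.  Multi-block files and
quoted strings are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .simulate import ALPHA_MISSING, ALPHA_PRESENT, ExpandedRecord, GroundTruth
from .symmetry import OccupancyConfig

__all__ = [
    "StarParseError",
    "StarTable",
    "read_star",
    "write_star",
    "records_to_table",
    "table_to_records",
    "write_truth_tsv",
    "read_truth_tsv",
]

PARTICLE_COLUMNS = ("_pccParticleId", "_pccCopyIndex", "_pccClassLabel")
_LABEL_TO_STAR = {ALPHA_PRESENT: "present", ALPHA_MISSING: "missing"}
_STAR_TO_LABEL = {v: k for k, v in _LABEL_TO_STAR.items()}


class StarParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True)
class StarTable:
    block_name: str
    columns: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column tags")
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError(
                    f"row arity {len(row)} != column count {len(self.columns)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def read_star(path) -> StarTable:
    """Parse one data block with a loop_ header; raises with line numbers."""
    path = Path(path)
    block_name: str | None = None
    columns: list[str] = []
    rows: list[tuple[str, ...]] = []
    state = "preamble"  # -> block -> loop -> body
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if state == "preamble":
                if line.startswith("data_"):
                    block_name = line
                    state = "block"
                else:
                    raise StarParseError(path, line_no, f"expected data_ block, got {line!r}")
            elif state == "block":
                if line == "loop_":
                    state = "loop"
                elif line.startswith("data_"):
                    raise StarParseError(path, line_no, "multiple data blocks not supported")
                else:
                    raise StarParseError(path, line_no, f"expected loop_, got {line!r}")
            elif state == "loop":
                if line.startswith("_"):
                    tag = line.split()[0]
                    if tag in columns:
                        raise StarParseError(path, line_no, f"duplicate tag {tag}")
                    columns.append(tag)
                elif columns:
                    state = "body"
                    _append_row(path, line_no, line, columns, rows)
                else:
                    raise StarParseError(path, line_no, "loop_ with no column tags")
            else:  # body
                if line.startswith("data_"):
                    raise StarParseError(path, line_no, "multiple data blocks not supported")
                _append_row(path, line_no, line, columns, rows)
    if block_name is None:
        raise StarParseError(path, 0, "no data_ block found")
    if not columns:
        raise StarParseError(path, 0, "data block has no loop_ columns")
    return StarTable(block_name=block_name, columns=tuple(columns), rows=tuple(rows))


def _append_row(path, line_no, line, columns, rows) -> None:
    values = tuple(line.split())
    if len(values) != len(columns):
        raise StarParseError(
            path,
            line_no,
            f"row has {len(values)} fields, expected {len(columns)}",
        )
    rows.append(values)


def write_star(table: StarTable, path, header_comments: Iterable[str] = ()) -> None:
    """Deterministic serialization: fixed order, LF newlines, no locale formatting."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            fh.write(f"{table.block_name}\n\nloop_\n")
            for i, col in enumerate(table.columns, start=1):
                fh.write(f"{col} #{i}\n")
            for row in table.rows:
                fh.write("\t".join(row) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing STAR table to {path}: {exc}") from exc


def records_to_table(records: Sequence[ExpandedRecord]) -> StarTable:
    rows = tuple(
        (str(r.particle_id), str(r.copy_index), _LABEL_TO_STAR[r.class_label])
        for r in records
    )
    return StarTable(block_name="data_particles", columns=PARTICLE_COLUMNS, rows=rows)


def table_to_records(table: StarTable) -> list[ExpandedRecord]:
    missing = [c for c in PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing columns: {missing}")
    idx = [table.columns.index(c) for c in PARTICLE_COLUMNS]
    records = []
    for row in table.rows:
        pid, copy_idx, label = (row[i] for i in idx)
        if label not in _STAR_TO_LABEL:
            raise ValueError(f"unknown class label {label!r} (expected present/missing)")
        records.append(
            ExpandedRecord(
                particle_id=int(pid),
                copy_index=int(copy_idx),
                class_label=_STAR_TO_LABEL[label],
            )
        )
    return records


def write_truth_tsv(truth: Sequence[GroundTruth], path, header_comments: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("particle_id\tbits\n")
        for gt in truth:
            fh.write(f"{gt.particle_id}\t{gt.true_config.as_string()}\n")


def read_truth_tsv(path) -> list[GroundTruth]:
    path = Path(path)
    truth = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("particle_id"):
                continue
            pid, bits = line.split("\t")
            truth.append(
                GroundTruth(particle_id=int(pid), true_config=OccupancyConfig.from_string(bits))
            )
    return truth
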