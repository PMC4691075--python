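"""Differential-expression tables and the significance filter.

The experiment behind this package compares a planthopper-resistant rice
line (R) with its susceptible parent (S) before (0 h) and after (6 h)
infestation.  Four pairwise contrasts are analysed:

* ``R6_R0`` and ``S6_S0`` — 6 h vs 0 h within one genotype ("temporal");
* ``R0_S0`` and ``R6_S6`` — resistant vs susceptible at one timepoint
  ("genotype").

Fold changes are positive ratios oriented first-named-over-second (R6/R0,
R/S).  A gene is differentially expressed when its ratio is at least 2 (or
at most 1/2) and its false-discovery q-value is strictly below 0.05; q is
produced upstream and consumed here, never computed.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .errors import FormatError

#: Default significance thresholds: ratio >= 2 (or <= 1/2), q < 0.05.
FOLD_CHANGE_MIN = 2.0
Q_MAX = 0.05


class ContrastKind(enum.Enum):
    TEMPORAL = "temporal"
    GENOTYPE = "genotype"


class Contrast(enum.Enum):
    """One of the four pairwise comparisons."""

    S6_S0 = "S6_S0"
    R6_R0 = "R6_R0"
    R0_S0 = "R0_S0"
    R6_S6 = "R6_S6"

    @property
    def kind(self) -> ContrastKind:
        if self in (Contrast.S6_S0, Contrast.R6_R0):
            return ContrastKind.TEMPORAL
        return ContrastKind.GENOTYPE

    @classmethod
    def parse(cls, label: str) -> "Contrast":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise FormatError(
                f"unknown contrast label {label!r} (expected one of {valid})"
            ) from None


#: Canonical contrast order used for pattern columns and Venn categories.
CONTRAST_ORDER: tuple[Contrast, ...] = (
    Contrast.S6_S0,
    Contrast.R6_R0,
    Contrast.R0_S0,
    Contrast.R6_S6,
)


class GeneDirection(enum.Enum):
    """Direction of a single significant gene within one contrast."""

    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression evidence in one contrast.

    ``fold_change`` is the positive expression ratio of the first-named
    condition of the contrast over the second; ``direction`` is set by
    :func:`filter_significant` and is ``None`` on raw records.
    """

    contrast: Contrast
    gene_id: str
    fold_change: float
    q_value: float
    direction: GeneDirection | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("empty gene_id")
        if not self.fold_change > 0:
            raise FormatError(
                f"fold change must be positive, got {self.fold_change!r} "
                f"for {self.gene_id}"
            )
        if not 0.0 <= self.q_value <= 1.0:
            raise FormatError(
                f"q-value must lie in [0, 1], got {self.q_value!r} "
                f"for {self.gene_id}"
            )


_Source = Union[str, Path, TextIO]


def _open_text(source: _Source):
    """Return (stream, needs_close) for a path or an already-open stream."""
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def read_de_table(
    source: _Source,
    contrast: Contrast | str | None = None,
) -> list[DERecord]:
    """Read a per-contrast DE table and canonicalize fold changes.

    The TSV header is ``gene_id  fold_change  q_value`` (ratios) or
    ``gene_id  log2fc  q_value`` (signed log2, converted to ratios via
    ``2**x``), optionally followed by a ``contrast`` column.  If the file
    has no contrast column, ``contrast`` must be supplied by the caller.
    """
    if contrast is not None and not isinstance(contrast, Contrast):
        contrast = Contrast.parse(contrast)
    stream, needs_close = _open_text(source)
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty DE table: missing header") from None
        header = [h.strip() for h in header]
        if header[:1] != ["gene_id"] or len(header) < 3:
            raise FormatError(f"malformed DE header: {header!r}")
        fc_col = header[1]
        if fc_col not in ("fold_change", "log2fc"):
            raise FormatError(
                f"second column must be 'fold_change' or 'log2fc', got {fc_col!r}"
            )
        if header[2] != "q_value":
            raise FormatError(f"third column must be 'q_value', got {header[2]!r}")
        has_contrast_col = len(header) > 3 and header[3] == "contrast"
        if not has_contrast_col and contrast is None:
            raise FormatError(
                "DE table has no 'contrast' column and no contrast was supplied"
            )
        is_log2 = fc_col == "log2fc"
        records: list[DERecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            expected = 4 if has_contrast_col else 3
            if len(row) < expected:
                raise FormatError(f"line {lineno}: expected {expected} columns")
            gene_id = row[0].strip()
            try:
                value = float(row[1])
                q = float(row[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            ratio = 2.0 ** value if is_log2 else value
            row_contrast = (
                Contrast.parse(row[3].strip()) if has_contrast_col else contrast
            )
            try:
                records.append(
                    DERecord(
                        contrast=row_contrast,
                        gene_id=gene_id,
                        fold_change=ratio,
                        q_value=q,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
        return records
    finally:
        if needs_close:
            stream.close()


def is_significant(
    record: DERecord,
    fold_change_min: float = FOLD_CHANGE_MIN,
    q_max: float = Q_MAX,
) -> bool:
    """Apply the fold-change/q filter: ratio >= t or <= 1/t, and q < q_max.

    Both fold-change bounds are inclusive (a ratio of exactly 2 — or
    exactly 0.5 — is differentially expressed); the q bound is strict.
    """
    fc = record.fold_change
    return (fc >= fold_change_min or fc <= 1.0 / fold_change_min) and (
        record.q_value < q_max
    )


def filter_significant(
    records: Iterable[DERecord],
    fold_change_min: float = FOLD_CHANGE_MIN,
    q_max: float = Q_MAX,
) -> list[DERecord]:
    """Keep significant records, annotated with their direction.

    Direction is ``UP`` for ratio >= ``fold_change_min`` and ``DOWN`` for
    ratio <= 1/``fold_change_min``.  Idempotent: re-filtering the output
    returns it unchanged.
    """
    kept: list[DERecord] = []
    for record in records:
        if is_significant(record, fold_change_min, q_max):
            direction = (
                GeneDirection.UP
                if record.fold_change >= fold_change_min
                else GeneDirection.DOWN
            )
            kept.append(replace(record, direction=direction))
    return kept


def write_de_table(records: Sequence[DERecord], dest: _Source) -> None:
    """Write records as a ratio-dialect TSV with a contrast column."""
    stream: TextIO
    if isinstance(dest, (str, Path)):
        stream = open(dest, "w", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = dest, False
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "fold_change", "q_value", "contrast"])
        for r in records:
            writer.writerow(
                [r.gene_id, f"{r.fold_change:.6g}", f"{r.q_value:.6g}", r.contrast.value]
            )
    finally:
        if needs_close:
            stream.close()
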