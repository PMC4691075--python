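"""Free-amino-acid percent-change analysis.

Concentrations (µg per g fresh weight) of free amino acids measured in
the resistant (R) and susceptible (S) rice lines before (0 h) and after
(6 h) planthopper infestation.  The within-genotype response of each
analyte is the percent change of its mean concentration,

    100 × (after − before) / before,

reported to one decimal with ties rounded half away from zero (the
convention that reproduces the published values, e.g. −46.97 → −47.0 and
895.65 → 895.7).

The packaged reference table also carries the percent changes as
originally printed; for a handful of analytes those printed values are
not reproducible from the printed concentrations.  Such rows are flagged
as discrepant rather than silently reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import TextIO, Union

import pandas as pd

from .errors import DomainError, FormatError

_Source = Union[str, Path, TextIO]

#: Condition columns, in fixed order: susceptible/resistant × 0 h/6 h.
CONDITIONS = ("S0", "R0", "S6", "R6")

#: Row label of the column-sum row in the reference table.
TOTAL_LABEL = "Total"

#: |recomputed − printed| above this is a discrepancy (half of the last
#: printed decimal place).
DISCREPANCY_TOLERANCE = 0.05


def percent_change(before: float, after: float) -> float:
    """Percent change of a concentration, rounded to one decimal.

    Rounding is half away from zero.  ``before`` must be positive.
    """
    before, after = float(before), float(after)
    if before <= 0:
        raise DomainError(f"baseline concentration must be positive, got {before!r}")
    raw = 100.0 * (after - before) / before
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AminoAcidTable:
    """Mean concentrations (and standard errors) per analyte and condition.

    ``frame`` is indexed by analyte name with columns S0, R0, S6, R6 and
    optionally their ``_se`` companions and printed percent-change columns
    ``printed_pct_S6_S0`` / ``printed_pct_R6_R0``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"amino-acid table lacks condition columns {missing}")
        conc = self.frame[list(CONDITIONS)]
        if not (conc > 0).all().all():
            raise FormatError("all concentrations must be positive")

    @property
    def analytes(self) -> list[str]:
        return [name for name in self.frame.index if name != TOTAL_LABEL]

    @property
    def has_printed_changes(self) -> bool:
        return {"printed_pct_S6_S0", "printed_pct_R6_R0"} <= set(self.frame.columns)


def read_amino_acid_table(source: _Source) -> AminoAcidTable:
    frame = pd.read_csv(source, sep="\t", index_col="analyte")
    return AminoAcidTable(frame=frame)


def load_reference_table() -> AminoAcidTable:
    """The packaged concentration table from the rice–planthopper study."""
    path = resources.files("hopperpath").joinpath("data/sbph_free_amino_acids.tsv")
    with resources.as_file(path) as fp:
        return read_amino_acid_table(fp)


@dataclass(frozen=True)
class AminoAcidChanges:
    """Recomputed percent changes plus rankings and totals.

    ``frame`` has one row per analyte (Total excluded) with columns
    ``pct_S6_S0`` and ``pct_R6_R0`` and — when the input carried printed
    changes — their printed counterparts and a ``discrepant`` flag that is
    True when either recomputed change differs from the printed one by
    more than :data:`DISCREPANCY_TOLERANCE`.

    ``total_from_row`` recomputes the Total row's changes from its printed
    concentrations; ``total_from_sum`` recomputes them from the column
    sums of the individual analytes.  Rankings order analytes by signed
    change, largest increase first.
    """

    frame: pd.DataFrame
    total_from_row: dict[str, float]
    total_from_sum: dict[str, float]
    resistant_ranking: tuple[str, ...]
    susceptible_ranking: tuple[str, ...]


def table_changes(table: AminoAcidTable) -> AminoAcidChanges:
    """Recompute both within-genotype percent-change columns."""
    data = table.frame
    analytes = table.analytes
    rows = []
    for name in analytes:
        row = data.loc[name]
        entry = {
            "analyte": name,
            "pct_S6_S0": percent_change(row["S0"], row["S6"]),
            "pct_R6_R0": percent_change(row["R0"], row["R6"]),
        }
        if table.has_printed_changes:
            entry["printed_pct_S6_S0"] = row["printed_pct_S6_S0"]
            entry["printed_pct_R6_R0"] = row["printed_pct_R6_R0"]
            entry["discrepant"] = bool(
                abs(entry["pct_S6_S0"] - row["printed_pct_S6_S0"])
                > DISCREPANCY_TOLERANCE
                or abs(entry["pct_R6_R0"] - row["printed_pct_R6_R0"])
                > DISCREPANCY_TOLERANCE
            )
        rows.append(entry)
    frame = pd.DataFrame(rows).set_index("analyte")

    if TOTAL_LABEL in data.index:
        total_row = data.loc[TOTAL_LABEL]
        total_from_row = {
            "pct_S6_S0": percent_change(total_row["S0"], total_row["S6"]),
            "pct_R6_R0": percent_change(total_row["R0"], total_row["R6"]),
        }
    else:
        total_from_row = {}
    sums = data.loc[analytes, list(CONDITIONS)].sum()
    total_from_sum = {
        "pct_S6_S0": percent_change(sums["S0"], sums["S6"]),
        "pct_R6_R0": percent_change(sums["R0"], sums["R6"]),
    }

    resistant_ranking = tuple(
        frame["pct_R6_R0"].sort_values(ascending=False, kind="stable").index
    )
    susceptible_ranking = tuple(
        frame["pct_S6_S0"].sort_values(ascending=False, kind="stable").index
    )
    return AminoAcidChanges(
        frame=frame,
        total_from_row=total_from_row,
        total_from_sum=total_from_sum,
        resistant_ranking=resistant_ranking,
        susceptible_ranking=susceptible_ranking,
    )


def write_changes_table(changes: AminoAcidChanges, dest: _Source) -> None:
    """Side-by-side recomputed/printed changes with the discrepancy flag."""
    changes.frame.to_csv(dest, sep="\t")
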