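"""Four-contrast Venn partition and the Class I–III pathway rules.

Called pathways are partitioned into the 15 non-empty subsets of the four
contrasts — the cells of a four-set Venn diagram.  On top of the
per-pathway regulation patterns, rule-based classes nominate pathways as
candidate resistance or susceptibility factors:

Resistance classes (induced-defense logic, resistant line R):

* **Class I** — regulated after infestation in R (R6_R0) but not in S
  (S6_S0); the genotypes differ after attack (R6_S6) but not before
  (R0_S0): a defence switched on only in the resistant line.
* **Class II** — as Class I, except the genotypes already differ before
  attack (R0_S0 present as well as R6_S6): a constitutive difference that
  is also infestation-responsive in R.
* **Class III** — regulated in both genotypes with strictly opposing pure
  directions (up in one, down in the other), and the genotypes differ
  after attack (R6_S6); the before-attack contrast is unconstrained.

Susceptibility classes swap the roles of R6_R0 and S6_S0 in Classes I and
II; Class III is symmetric, so a pathway is resistance Class III exactly
when it is susceptibility Class III.

A MIXED (up/down) call counts as "differentially regulated" for every
presence/absence test, but never satisfies the opposing-direction test of
Class III.
"""

from __future__ import annotations

import csv
import enum
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TextIO, Union

import pandas as pd

from .de_input import CONTRAST_ORDER, Contrast
from .errors import ConsistencyError
from .pathway_calls import PathwayDirection, RegulationPattern
from .pathway_db import PathwayDatabase

_Source = Union[str, Path, TextIO]


class ClassLabel(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    NONE = "none"


@dataclass(frozen=True)
class ClassAssignment:
    """Resistance and susceptibility class labels for one pathway."""

    pathway_id: str
    resistance_class: ClassLabel
    susceptibility_class: ClassLabel


#: All 15 non-empty contrast subsets in canonical order.
VENN_CATEGORIES: tuple[tuple[Contrast, ...], ...] = tuple(
    subset
    for size in range(1, 5)
    for subset in itertools.combinations(CONTRAST_ORDER, size)
)


def category_label(category: tuple[Contrast, ...]) -> str:
    return "+".join(c.value for c in category)


def venn_partition(
    patterns: Sequence[RegulationPattern],
) -> dict[tuple[Contrast, ...], frozenset[str]]:
    """Assign each pathway to the subset of contrasts it is called in.

    Returns all 15 categories (possibly with empty sets) keyed by
    canonical contrast order.  The category sets are pairwise disjoint and
    together cover every input pathway — asserted on every run.
    """
    buckets: dict[tuple[Contrast, ...], set[str]] = {c: set() for c in VENN_CATEGORIES}
    seen: set[str] = set()
    for pattern in patterns:
        if pattern.pathway_id in seen:
            raise ConsistencyError(f"duplicate pattern for {pattern.pathway_id!r}")
        seen.add(pattern.pathway_id)
        key = tuple(c for c in CONTRAST_ORDER if pattern.get(c) is not None)
        # RegulationPattern guarantees >=1 call, so key is never empty.
        buckets[key].add(pattern.pathway_id)
    covered: set[str] = set()
    for members in buckets.values():
        assert not (covered & members), "Venn categories must be disjoint"
        covered |= members
    assert covered == seen, "Venn categories must cover all called pathways"
    return {category: frozenset(buckets[category]) for category in VENN_CATEGORIES}


def _is_opposing(
    a: PathwayDirection | None, b: PathwayDirection | None
) -> bool:
    """Strictly opposing pure directions; MIXED never opposes."""
    return {a, b} == {PathwayDirection.UP, PathwayDirection.DOWN}


def _classify(pattern: RegulationPattern, focal: Contrast, other: Contrast) -> ClassLabel:
    """Shared rule body; focal/other = (R6_R0, S6_S0) for resistance."""
    focal_call = pattern.get(focal)
    other_call = pattern.get(other)
    before = pattern.get(Contrast.R0_S0)
    after = pattern.get(Contrast.R6_S6)
    if focal_call is not None and other_call is None and after is not None:
        return ClassLabel.I if before is None else ClassLabel.II
    if _is_opposing(focal_call, other_call) and after is not None:
        return ClassLabel.III
    return ClassLabel.NONE


def classify_resistance(pattern: RegulationPattern) -> ClassLabel:
    """Resistance class of one regulation pattern (NONE if no rule fires)."""
    return _classify(pattern, focal=Contrast.R6_R0, other=Contrast.S6_S0)


def classify_susceptibility(pattern: RegulationPattern) -> ClassLabel:
    """Susceptibility class: the resistance rules with R and S roles swapped."""
    return _classify(pattern, focal=Contrast.S6_S0, other=Contrast.R6_R0)


def classify_patterns(
    patterns: Sequence[RegulationPattern],
) -> list[ClassAssignment]:
    return [
        ClassAssignment(
            pathway_id=p.pathway_id,
            resistance_class=classify_resistance(p),
            susceptibility_class=classify_susceptibility(p),
        )
        for p in patterns
    ]


def class_counts(assignments: Sequence[ClassAssignment]) -> pd.DataFrame:
    """Class-by-axis count table (rows I, II, III, any; columns axes)."""
    rows = {}
    for label in (ClassLabel.I, ClassLabel.II, ClassLabel.III):
        rows[label.value] = {
            "resistance": sum(1 for a in assignments if a.resistance_class is label),
            "susceptibility": sum(
                1 for a in assignments if a.susceptibility_class is label
            ),
        }
    rows["any"] = {
        "resistance": sum(
            1 for a in assignments if a.resistance_class is not ClassLabel.NONE
        ),
        "susceptibility": sum(
            1 for a in assignments if a.susceptibility_class is not ClassLabel.NONE
        ),
    }
    return pd.DataFrame(rows).T


def network_table(
    assignments: Sequence[ClassAssignment],
    db: PathwayDatabase,
    patterns: Mapping[str, RegulationPattern] | None = None,
) -> pd.DataFrame:
    """Group classed pathways under their category-hierarchy branches.

    A tabular stand-in for a hierarchy-derived pathway network figure: one
    row per classed pathway with its top-level branch, full class path,
    class labels and (when ``patterns`` is given) the within-genotype
    direction that motivated the class — R6_R0 for resistance-classed
    pathways, S6_S0 otherwise.
    """
    rows = []
    for assignment in assignments:
        if (
            assignment.resistance_class is ClassLabel.NONE
            and assignment.susceptibility_class is ClassLabel.NONE
        ):
            continue
        record = db.get(assignment.pathway_id)
        if record is None:
            raise ConsistencyError(
                f"classed pathway {assignment.pathway_id!r} not in database"
            )
        direction = ""
        if patterns is not None and assignment.pathway_id in patterns:
            pattern = patterns[assignment.pathway_id]
            source = (
                Contrast.R6_R0
                if assignment.resistance_class is not ClassLabel.NONE
                else Contrast.S6_S0
            )
            call = pattern.get(source)
            if call is not None:
                direction = call.render(source)
        rows.append(
            {
                "branch": record.class_path[0],
                "class_path": "|".join(record.class_path),
                "pathway_id": record.pathway_id,
                "pathway_name": record.name,
                "resistance_class": assignment.resistance_class.value,
                "susceptibility_class": assignment.susceptibility_class.value,
                "direction": direction,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "branch",
            "class_path",
            "pathway_id",
            "pathway_name",
            "resistance_class",
            "susceptibility_class",
            "direction",
        ],
    )
    return frame.sort_values(["branch", "class_path", "pathway_id"]).reset_index(
        drop=True
    )


def write_venn_table(
    partition: Mapping[tuple[Contrast, ...], frozenset[str]], dest: _Source
) -> None:
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = dest, False
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "count", "pathway_ids"])
        for category in VENN_CATEGORIES:
            members = sorted(partition.get(category, frozenset()))
            writer.writerow([category_label(category), len(members), ",".join(members)])
    finally:
        if needs_close:
            stream.close()


def write_classes_table(
    assignments: Sequence[ClassAssignment],
    patterns: Mapping[str, RegulationPattern],
    dest: _Source,
    db: PathwayDatabase | None = None,
) -> None:
    """Classed-pathway listing in the four-direction-column layout."""
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = dest, False
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["pathway_id", "name", "resistance_class", "susceptibility_class"]
            + [c.value for c in CONTRAST_ORDER]
        )
        for assignment in assignments:
            name = assignment.pathway_id
            if db is not None:
                record = db.get(assignment.pathway_id)
                if record is not None:
                    name = record.name
            pattern = patterns.get(assignment.pathway_id)
            cells = []
            for contrast in CONTRAST_ORDER:
                call = pattern.get(contrast) if pattern is not None else None
                cells.append("" if call is None else call.render(contrast))
            writer.writerow(
                [
                    assignment.pathway_id,
                    name,
                    assignment.resistance_class.value,
                    assignment.susceptibility_class.value,
                ]
                + cells
            )
    finally:
        if needs_close:
            stream.close()
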