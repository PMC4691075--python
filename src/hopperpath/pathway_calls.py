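"""Pathway-level direction calls and cross-contrast regulation patterns.

A pathway is *called* in a contrast as soon as one significant gene maps
to it.  The call direction aggregates the member-gene directions: UP if
every significant member gene is up-regulated, DOWN if every one is
down-regulated, MIXED otherwise.  For the genotype contrasts the same
three states are rendered "higher" / "lower" / "higher/lower" (resistant
over susceptible), mirroring how pathway-level omics viewers report them.

A pathway's calls across the four contrasts form its *regulation
pattern*, the input to the resistance/susceptibility classifier.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import pandas as pd

from .de_input import CONTRAST_ORDER, Contrast, ContrastKind, DERecord, GeneDirection
from .errors import ConsistencyError, FormatError
from .pathway_db import PathwayDatabase

_Source = Union[str, Path, TextIO]


class PathwayDirection(enum.Enum):
    """Aggregated direction of one pathway in one contrast."""

    UP = "up"
    DOWN = "down"
    MIXED = "mixed"

    def render(self, contrast: Contrast) -> str:
        """Human-readable direction in the vocabulary of the contrast kind."""
        if contrast.kind is ContrastKind.TEMPORAL:
            return {"up": "up", "down": "down", "mixed": "up/down"}[self.value]
        return {"up": "higher", "down": "lower", "mixed": "higher/lower"}[self.value]


_DIRECTION_SYNONYMS = {
    "up": PathwayDirection.UP,
    "higher": PathwayDirection.UP,
    "down": PathwayDirection.DOWN,
    "lower": PathwayDirection.DOWN,
    "mixed": PathwayDirection.MIXED,
    "up/down": PathwayDirection.MIXED,
    "higher/lower": PathwayDirection.MIXED,
}


def parse_direction(text: str) -> PathwayDirection | None:
    """Parse a rendered direction cell; empty cell means no call."""
    text = text.strip()
    if not text:
        return None
    try:
        return _DIRECTION_SYNONYMS[text.lower()]
    except KeyError:
        raise FormatError(f"unknown direction {text!r}") from None


@dataclass(frozen=True)
class PathwayCall:
    """One pathway's aggregated direction in one contrast, with evidence."""

    pathway_id: str
    contrast: Contrast
    direction: PathwayDirection
    evidence: tuple[tuple[str, GeneDirection], ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ConsistencyError(
                f"pathway call {self.pathway_id}/{self.contrast.value} without evidence"
            )


def _aggregate(directions: Iterable[GeneDirection]) -> PathwayDirection:
    kinds = {d for d in directions}
    if kinds == {GeneDirection.UP}:
        return PathwayDirection.UP
    if kinds == {GeneDirection.DOWN}:
        return PathwayDirection.DOWN
    return PathwayDirection.MIXED


def call_pathways(
    records: Sequence[DERecord],
    db: PathwayDatabase,
    contrast: Contrast | str,
) -> list[PathwayCall]:
    """Aggregate significant locus-keyed records into per-pathway calls.

    Records from other contrasts are ignored; records must carry a
    direction (i.e. have passed the significance filter).  A locus seen
    with conflicting directions (e.g. via two probes) contributes both,
    which forces the pathway to MIXED.  Output order is deterministic
    (sorted by pathway id) and independent of the input record order.
    """
    if not isinstance(contrast, Contrast):
        contrast = Contrast.parse(contrast)
    evidence: dict[str, set[tuple[str, GeneDirection]]] = {}
    for record in records:
        if record.contrast is not contrast:
            continue
        if record.direction is None:
            raise ConsistencyError(
                f"record {record.gene_id} lacks a direction; filter before calling"
            )
        for pathway_id in db.pathways_of_locus(record.gene_id):
            evidence.setdefault(pathway_id, set()).add(
                (record.gene_id, record.direction)
            )
    calls = []
    for pathway_id in sorted(evidence):
        pairs = tuple(sorted(evidence[pathway_id], key=lambda p: (p[0], p[1].value)))
        calls.append(
            PathwayCall(
                pathway_id=pathway_id,
                contrast=contrast,
                direction=_aggregate(d for _, d in pairs),
                evidence=pairs,
            )
        )
    return calls


@dataclass
class RegulationPattern:
    """A pathway's direction across the four contrasts (absent = no call)."""

    pathway_id: str
    calls: dict[Contrast, PathwayDirection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.calls:
            raise ConsistencyError(
                f"pattern for {self.pathway_id!r} has no calls in any contrast"
            )

    def get(self, contrast: Contrast) -> PathwayDirection | None:
        return self.calls.get(contrast)

    @property
    def contrasts(self) -> frozenset[Contrast]:
        return frozenset(self.calls)


def build_patterns(calls: Iterable[PathwayCall]) -> list[RegulationPattern]:
    """Collate per-contrast calls into one pattern per pathway.

    Two calls for the same (pathway, contrast) — even identical ones —
    indicate an upstream bookkeeping fault and raise.
    """
    by_pathway: dict[str, dict[Contrast, PathwayDirection]] = {}
    for call in calls:
        slots = by_pathway.setdefault(call.pathway_id, {})
        if call.contrast in slots:
            raise ConsistencyError(
                f"duplicate call for ({call.pathway_id}, {call.contrast.value})"
            )
        slots[call.contrast] = call.direction
    return [
        RegulationPattern(pathway_id=pid, calls=by_pathway[pid])
        for pid in sorted(by_pathway)
    ]


def tabulate_by_category(
    patterns: Sequence[RegulationPattern],
    db: PathwayDatabase,
    level: int = 1,
) -> pd.DataFrame:
    """Count called pathways per category hierarchy label per contrast.

    ``level`` indexes the class_path from the root (clamped for shallow
    paths); level 1 reproduces the subclass rows of the published
    per-category tabulation.  A pathway counts once in every contrast it
    is called in.
    """
    rows = []
    for pattern in patterns:
        record = db.get(pattern.pathway_id)
        if record is None:
            raise ConsistencyError(
                f"pathway {pattern.pathway_id!r} in patterns but not in database"
            )
        for contrast in pattern.contrasts:
            rows.append({"category": record.category(level), "contrast": contrast.value})
    columns = [c.value for c in CONTRAST_ORDER]
    if not rows:
        return pd.DataFrame(columns=columns, dtype=int)
    frame = pd.DataFrame(rows)
    table = (
        frame.groupby(["category", "contrast"]).size().unstack("contrast", fill_value=0)
    )
    table = table.reindex(columns=columns, fill_value=0).sort_index()
    table.columns.name = None
    return table.astype(int)


@dataclass(frozen=True)
class SharedUniqueCounts:
    """Shared/unique pure-direction pathway sets between R6_R0 and S6_S0.

    MIXED calls belong to neither the up nor the down tally; the
    per-category tabulation still counts them as differentially regulated.
    """

    shared_up: frozenset[str]
    unique_up_r: frozenset[str]
    unique_up_s: frozenset[str]
    shared_down: frozenset[str]
    unique_down_r: frozenset[str]
    unique_down_s: frozenset[str]

    @property
    def n_shared(self) -> int:
        """Pathways with the same pure direction in both genotypes."""
        return len(self.shared_up) + len(self.shared_down)


def shared_unique_counts(patterns: Sequence[RegulationPattern]) -> SharedUniqueCounts:
    """Set algebra over the two temporal contrasts' pure up/down calls."""
    r_up = {
        p.pathway_id for p in patterns if p.get(Contrast.R6_R0) is PathwayDirection.UP
    }
    s_up = {
        p.pathway_id for p in patterns if p.get(Contrast.S6_S0) is PathwayDirection.UP
    }
    r_down = {
        p.pathway_id for p in patterns if p.get(Contrast.R6_R0) is PathwayDirection.DOWN
    }
    s_down = {
        p.pathway_id for p in patterns if p.get(Contrast.S6_S0) is PathwayDirection.DOWN
    }
    return SharedUniqueCounts(
        shared_up=frozenset(r_up & s_up),
        unique_up_r=frozenset(r_up - s_up),
        unique_up_s=frozenset(s_up - r_up),
        shared_down=frozenset(r_down & s_down),
        unique_down_r=frozenset(r_down - s_down),
        unique_down_s=frozenset(s_down - r_down),
    )


def mapped_gene_ratio(
    records: Sequence[DERecord], db: PathwayDatabase, contrast: Contrast
) -> float:
    """Fraction of distinct DE loci in ``contrast`` that map to a pathway.

    The pathway-mapping coverage statistic reported alongside this kind of
    analysis as a QC figure; 0.0 for a contrast without records.
    """
    loci = {r.gene_id for r in records if r.contrast is contrast}
    if not loci:
        return 0.0
    mapped = {locus for locus in loci if db.pathways_of_locus(locus)}
    return len(mapped) / len(loci)


def write_calls_table(calls: Sequence[PathwayCall], dest: _Source) -> None:
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = dest, False
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["pathway_id", "contrast", "direction", "n_genes", "genes"])
        for call in calls:
            loci = sorted({locus for locus, _ in call.evidence})
            writer.writerow(
                [
                    call.pathway_id,
                    call.contrast.value,
                    call.direction.render(call.contrast),
                    len(loci),
                    ",".join(loci),
                ]
            )
    finally:
        if needs_close:
            stream.close()


PATTERN_HEADER = ["pathway"] + [c.value for c in CONTRAST_ORDER]


def write_patterns_table(
    patterns: Sequence[RegulationPattern], dest: _Source
) -> None:
    """One row per pathway, one rendered direction column per contrast."""
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = dest, False
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(PATTERN_HEADER)
        for pattern in patterns:
            row = [pattern.pathway_id]
            for contrast in CONTRAST_ORDER:
                direction = pattern.get(contrast)
                row.append("" if direction is None else direction.render(contrast))
            writer.writerow(row)
    finally:
        if needs_close:
            stream.close()


def load_reference_patterns() -> list[RegulationPattern]:
    """The packaged direction grid of the 25 classed pathways.

    Curated per-contrast regulation calls for the metabolic pathways
    nominated as resistance- or susceptibility-associated in the
    rice–planthopper infestation study this package models (resistant
    introgression line Pf9279-4 vs susceptible parent 02428).
    """
    from importlib import resources

    path = resources.files("hopperpath").joinpath("data/sbph_pathway_patterns.tsv")
    with resources.as_file(path) as fp:
        return read_patterns_table(fp)


def read_patterns_table(source: _Source) -> list[RegulationPattern]:
    """Read a pattern grid; accepts up/down and higher/lower synonyms."""
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, "r", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = source, False
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise FormatError("empty pattern table: missing header") from None
        if len(header) != 5 or header[0] not in ("pathway", "pathway_id"):
            raise FormatError(f"malformed pattern header {header!r}")
        contrasts = [Contrast.parse(h) for h in header[1:]]
        patterns: list[RegulationPattern] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            pathway_id = row[0].strip()
            if pathway_id in seen:
                raise ConsistencyError(f"line {lineno}: duplicate pathway {pathway_id!r}")
            seen.add(pathway_id)
            cells = list(row[1:]) + [""] * (4 - (len(row) - 1))
            calls: dict[Contrast, PathwayDirection] = {}
            for contrast, cell in zip(contrasts, cells):
                direction = parse_direction(cell)
                if direction is not None:
                    calls[contrast] = direction
            if not calls:
                raise FormatError(
                    f"line {lineno}: pathway {pathway_id!r} has no call in any contrast"
                )
            patterns.append(RegulationPattern(pathway_id=pathway_id, calls=calls))
        return patterns
    finally:
        if needs_close:
            stream.close()
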