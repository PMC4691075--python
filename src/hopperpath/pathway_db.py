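"""Pathway–gene association database and probe→locus translation.

A metabolic-pathway database in the BioCyc tradition (RiceCyc for rice)
links each pathway to the gene loci encoding its enzymes and places it in
a category hierarchy ("Biosynthesis" → "Secondary metabolites
biosynthesis" → …).  This module reads and writes a flat one-row-per-
(pathway, gene) TSV emulation of such a database, maintains the inverted
locus→pathways index used to map expression data onto pathways, and
translates microarray probe-set ids to locus ids.

Locus identifiers are opaque, case-sensitive strings (TIGR-style ids are
case-stable; treating them opaquely avoids silent collisions).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

from .de_input import DERecord
from .errors import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

_Source = Union[str, Path, TextIO]

PATHWAY_HEADER = ["pathway_id", "pathway_name", "class_path", "gene_id"]
PROBE_MAP_HEADER = ["probe_id", "locus_id"]

#: Separator for category-hierarchy levels inside the class_path column.
CLASS_PATH_SEP = "|"


@dataclass(frozen=True)
class PathwayRecord:
    """One metabolic pathway: identity, hierarchy placement, member loci.

    ``gene_ids`` may be empty — such a pathway exists in the database but
    can never be called differentially regulated.
    """

    pathway_id: str
    name: str
    class_path: tuple[str, ...]
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise FormatError("empty pathway_id")
        if len(self.class_path) < 1 or any(not c for c in self.class_path):
            raise FormatError(
                f"pathway {self.pathway_id}: class_path needs >=1 non-empty level"
            )

    def category(self, level: int) -> str:
        """Hierarchy label at ``level`` (0 = root), clamped to the deepest."""
        return self.class_path[min(level, len(self.class_path) - 1)]


class PathwayDatabase:
    """Lookup by pathway_id plus an inverted locus→pathways index."""

    def __init__(self, records: Iterable[PathwayRecord]):
        self._records: dict[str, PathwayRecord] = {}
        for record in records:
            if record.pathway_id in self._records:
                raise ConsistencyError(f"duplicate pathway_id {record.pathway_id!r}")
            self._records[record.pathway_id] = record
        self._by_locus: dict[str, set[str]] = {}
        for record in self._records.values():
            for locus in record.gene_ids:
                self._by_locus.setdefault(locus, set()).add(record.pathway_id)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PathwayRecord]:
        return iter(self._records.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._records

    def __getitem__(self, pathway_id: str) -> PathwayRecord:
        return self._records[pathway_id]

    def get(self, pathway_id: str) -> PathwayRecord | None:
        return self._records.get(pathway_id)

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(self._by_locus)

    def pathways_of_locus(self, locus_id: str) -> frozenset[str]:
        """All pathways containing ``locus_id``; empty for unknown loci."""
        return frozenset(self._by_locus.get(locus_id, ()))


def _open_reader(source: _Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def read_pathway_table(source: _Source) -> PathwayDatabase:
    """Parse the flat pathway–gene TSV into a :class:`PathwayDatabase`.

    One row per (pathway, gene) link; a row with an empty ``gene_id``
    declares a pathway without member genes.  Duplicate (pathway, gene)
    rows are deduplicated; a pathway_id reappearing with a different name
    or class_path is a consistency error.
    """
    stream, needs_close = _open_reader(source)
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise FormatError("empty pathway table: missing header") from None
        if header != PATHWAY_HEADER:
            raise FormatError(
                f"malformed pathway header {header!r}, expected {PATHWAY_HEADER!r}"
            )
        meta: dict[str, tuple[str, tuple[str, ...]]] = {}
        genes: dict[str, set[str]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) == 3:
                row = row + [""]  # trailing gene column may be omitted
            if len(row) < 4:
                raise FormatError(f"line {lineno}: expected 4 columns, got {len(row)}")
            pathway_id, name, class_path_raw, gene_id = (c.strip() for c in row[:4])
            if not pathway_id:
                raise FormatError(f"line {lineno}: empty pathway_id")
            class_path = tuple(
                level.strip() for level in class_path_raw.split(CLASS_PATH_SEP)
            )
            if any(not level for level in class_path):
                raise FormatError(f"line {lineno}: empty class_path level")
            key = (name, class_path)
            if pathway_id in meta and meta[pathway_id] != key:
                raise ConsistencyError(
                    f"line {lineno}: pathway {pathway_id!r} redefined with "
                    f"conflicting name/class_path"
                )
            meta.setdefault(pathway_id, key)
            genes.setdefault(pathway_id, set())
            if gene_id:
                genes[pathway_id].add(gene_id)
        records = [
            PathwayRecord(
                pathway_id=pid,
                name=meta[pid][0],
                class_path=meta[pid][1],
                gene_ids=frozenset(genes[pid]),
            )
            for pid in meta
        ]
        return PathwayDatabase(records)
    finally:
        if needs_close:
            stream.close()


def write_pathway_table(db: PathwayDatabase, dest: _Source) -> None:
    """Inverse of :func:`read_pathway_table` up to row order."""
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", encoding="utf-8", newline="")
        needs_close = True
    else:
        stream, needs_close = dest, False
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(PATHWAY_HEADER)
        for record in sorted(db, key=lambda r: r.pathway_id):
            class_path = CLASS_PATH_SEP.join(record.class_path)
            if record.gene_ids:
                for gene in sorted(record.gene_ids):
                    writer.writerow([record.pathway_id, record.name, class_path, gene])
            else:
                writer.writerow([record.pathway_id, record.name, class_path, ""])
    finally:
        if needs_close:
            stream.close()


@dataclass(frozen=True)
class ProbeLocusMap:
    """Many-to-one probe-set-id → locus-id translation table."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for probe, locus in self.mapping.items():
            if not probe or not locus:
                raise FormatError(f"empty probe or locus id in map: {probe!r}->{locus!r}")

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mapping

    def get(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)


def read_probe_map(source: _Source) -> ProbeLocusMap:
    stream, needs_close = _open_reader(source)
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise FormatError("empty probe map: missing header") from None
        if header != PROBE_MAP_HEADER:
            raise FormatError(
                f"malformed probe map header {header!r}, expected {PROBE_MAP_HEADER!r}"
            )
        mapping: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            probe, locus = row[0].strip(), row[1].strip()
            if not probe or not locus:
                raise FormatError(f"line {lineno}: empty probe or locus id")
            if probe in mapping and mapping[probe] != locus:
                raise ConsistencyError(
                    f"line {lineno}: probe {probe!r} mapped to two loci"
                )
            mapping[probe] = locus
        return ProbeLocusMap(mapping)
    finally:
        if needs_close:
            stream.close()


@dataclass(frozen=True)
class TranslationReport:
    """Bookkeeping for a probe→locus translation pass."""

    n_input: int
    n_mapped: int
    unmapped_probes: tuple[str, ...]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped_probes)


def translate_probes(
    records: Sequence[DERecord], probe_map: ProbeLocusMap
) -> tuple[list[DERecord], TranslationReport]:
    """Rekey DE records from probe ids to locus ids.

    Probes absent from the map are dropped (translation is expected to be
    lossy) and surfaced through the report and a logged warning.  Several
    probes of one locus stay as separate evidence rows.
    """
    from dataclasses import replace

    translated: list[DERecord] = []
    unmapped: list[str] = []
    for record in records:
        locus = probe_map.get(record.gene_id)
        if locus is None:
            unmapped.append(record.gene_id)
        else:
            translated.append(replace(record, gene_id=locus))
    report = TranslationReport(
        n_input=len(records),
        n_mapped=len(translated),
        unmapped_probes=tuple(unmapped),
    )
    if report.n_unmapped:
        logger.warning(
            "%d of %d probes had no locus mapping and were dropped",
            report.n_unmapped,
            report.n_input,
        )
    return translated, report
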