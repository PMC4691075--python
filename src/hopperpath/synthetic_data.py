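"""Synthetic pathway databases and DE tables with planted regulation.

The microarray data behind the analysis this package implements are not
publicly deposited, so end-to-end behaviour is exercised on simulated
input bundles instead: a pathway–gene database, a probe→locus map and
four per-contrast DE tables in which chosen pathways carry *planted*
regulation patterns.

Planting is exact with respect to the significance filter: a pathway
planted UP in a contrast has every member gene at ratio ≥ 2 with
q < 0.05 there; DOWN is symmetric (ratio ≤ 1/2); MIXED receives at least
one gene of each direction; a contrast absent from the plant leaves every
member gene non-significant.  Effect magnitudes are drawn on the log2
scale with a floor at |log2 ratio| = 1 so the significance filter — not
the generator — is the binding constraint.  Unplanted ("background")
genes become significant independently with a configurable probability,
which is what creates false pathway calls downstream.

The generator also emits a ground-truth table: each planted pattern plus
the resistance/susceptibility class it implies under the published
Class I–III rules, evaluated by a self-contained truth-table oracle that
is independent of the classifier in :mod:`hopperpath.venn_classify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .de_input import CONTRAST_ORDER, Contrast, DERecord, write_de_table
from .errors import ConfigError, ConsistencyError
from .pathway_calls import PathwayDirection
from .pathway_db import PathwayDatabase, PathwayRecord, write_pathway_table
from .venn_classify import ClassAssignment

import csv

#: Plausible two-level category branches for generated pathways.
_CLASS_PATHS = (
    ("Biosynthesis", "Secondary metabolites biosynthesis"),
    ("Biosynthesis", "Amino acids biosynthesis"),
    ("Biosynthesis", "Carbohydrates biosynthesis"),
    ("Degradation/Utilization/Assimilation", "Amino acids degradation"),
    ("Degradation/Utilization/Assimilation", "Carbohydrates degradation"),
    ("Generation of Precursor Metabolites and Energy", "Fermentation"),
)


@dataclass(frozen=True)
class PlantedPattern:
    """A pathway index with its target per-contrast directions."""

    pathway_index: int
    pattern: Mapping[Contrast, PathwayDirection]

    @classmethod
    def from_dict(cls, data: Mapping) -> "PlantedPattern":
        pattern = {
            Contrast.parse(label): PathwayDirection(direction)
            for label, direction in dict(data["pattern"]).items()
        }
        return cls(pathway_index=int(data["pathway_index"]), pattern=pattern)


@dataclass
class SimulationConfig:
    """Study-shaped simulation settings.

    Defaults emulate the scale at which pathway-level calling behaves like
    the real analysis while staying desk-sized: 30 pathways of ~4 genes,
    200 extra background genes, DE effect sizes centred at log2 ratio 1.5
    (ratio ≈ 2.8) with spread 0.5 and a floor at |log2| = 1, DE q-values
    uniform below 0.05 and non-DE q-values uniform above it.
    """

    n_pathways: int = 30
    genes_per_pathway_mean: float = 4.0
    min_genes_per_pathway: int = 1
    n_background_genes: int = 200
    planted: list[PlantedPattern] = field(default_factory=list)
    background_de_prob: float = 0.0
    log2fc_loc: float = 1.5
    log2fc_spread: float = 0.5
    duplicate_probe_fraction: float = 0.0
    conflicting_duplicates: bool = False
    unmapped_probe_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ConfigError("n_pathways must be >= 1")
        if self.min_genes_per_pathway < 1:
            raise ConfigError("min_genes_per_pathway must be >= 1")
        if not 0.0 <= self.background_de_prob <= 1.0:
            raise ConfigError("background_de_prob must lie in [0, 1]")
        for plant in self.planted:
            if not 0 <= plant.pathway_index < self.n_pathways:
                raise ConfigError(
                    f"planted pathway index {plant.pathway_index} out of range"
                )
            if not plant.pattern:
                raise ConfigError("planted pattern must name >=1 contrast")
        indices = [p.pathway_index for p in self.planted]
        if len(indices) != len(set(indices)):
            raise ConfigError("a pathway may carry at most one planted pattern")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        planted = [PlantedPattern.from_dict(p) for p in data.pop("planted", [])]
        return cls(planted=planted, **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, Mapping):
            raise ConfigError(f"config {path} must contain a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Independent class-rule oracle.
#
# Evaluated as an explicit truth table over presence/direction states,
# written directly from the published class definitions and deliberately
# separate from the classifier implementation so it can serve as ground
# truth for recovery tests.


def _implied_classes(
    pattern: Mapping[Contrast, PathwayDirection],
) -> tuple[str, str]:
    """(resistance, susceptibility) class implied by a planted pattern."""
    s = pattern.get(Contrast.S6_S0)
    r = pattern.get(Contrast.R6_R0)
    g0 = pattern.get(Contrast.R0_S0)
    g6 = pattern.get(Contrast.R6_S6)
    opposing = (
        r is not None
        and s is not None
        and {r.value, s.value} == {"up", "down"}
    )
    resistance = "none"
    susceptibility = "none"
    if r is not None and s is None and g6 is not None:
        resistance = "I" if g0 is None else "II"
    if s is not None and r is None and g6 is not None:
        susceptibility = "I" if g0 is None else "II"
    if opposing and g6 is not None:
        resistance = susceptibility = "III"
    return resistance, susceptibility


@dataclass(frozen=True)
class GroundTruth:
    """Planted patterns and the class labels they imply."""

    patterns: Mapping[str, Mapping[Contrast, PathwayDirection]]
    resistance: Mapping[str, str]
    susceptibility: Mapping[str, str]

    @property
    def pathway_ids(self) -> frozenset[str]:
        return frozenset(self.resistance)


TRUTH_HEADER = (
    ["pathway_id"]
    + [c.value for c in CONTRAST_ORDER]
    + ["resistance_class", "susceptibility_class"]
)


def write_truth_table(truth: GroundTruth, dest: str | Path) -> None:
    with open(dest, "w", encoding="utf-8", newline="") as stream:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_HEADER)
        for pathway_id in sorted(truth.resistance):
            pattern = truth.patterns.get(pathway_id, {})
            row = [pathway_id]
            for contrast in CONTRAST_ORDER:
                direction = pattern.get(contrast)
                row.append("" if direction is None else direction.value)
            row += [truth.resistance[pathway_id], truth.susceptibility[pathway_id]]
            writer.writerow(row)


def read_truth_table(source: str | Path) -> GroundTruth:
    patterns: dict[str, dict[Contrast, PathwayDirection]] = {}
    resistance: dict[str, str] = {}
    susceptibility: dict[str, str] = {}
    with open(source, "r", encoding="utf-8", newline="") as stream:
        reader = csv.reader(stream, delimiter="\t")
        header = next(reader)
        if header != TRUTH_HEADER:
            raise ConsistencyError(f"unexpected truth header {header!r}")
        for row in reader:
            pathway_id = row[0]
            pattern = {}
            for contrast, cell in zip(CONTRAST_ORDER, row[1:5]):
                if cell:
                    pattern[contrast] = PathwayDirection(cell)
            if pattern:
                patterns[pathway_id] = pattern
            resistance[pathway_id] = row[5]
            susceptibility[pathway_id] = row[6]
    return GroundTruth(
        patterns=patterns, resistance=resistance, susceptibility=susceptibility
    )


# ---------------------------------------------------------------------------
# Generation


def _draw_magnitude(rng: np.random.Generator, config: SimulationConfig) -> float:
    """|log2 ratio| for a DE gene: normal draw floored at 1."""
    return max(1.0, rng.normal(config.log2fc_loc, config.log2fc_spread))


def _de_value(
    rng: np.random.Generator, config: SimulationConfig, up: bool
) -> tuple[float, float]:
    magnitude = _draw_magnitude(rng, config)
    ratio = 2.0 ** (magnitude if up else -magnitude)
    q = rng.uniform(0.0, 0.0499)
    return ratio, q


def _non_de_value(rng: np.random.Generator) -> tuple[float, float]:
    # Ratio strictly inside (1/2, 2) AND q >= 0.05: both filter arms fail.
    ratio = 2.0 ** rng.uniform(-0.9, 0.9)
    q = rng.uniform(0.05, 1.0)
    return ratio, q


def generate(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Write a complete input bundle under ``outdir`` and return the truth.

    Files written: ``pathways.tsv``, ``probe_map.tsv``,
    ``de_<contrast>.tsv`` for the four contrasts, and ``truth.tsv``.
    Identical configs (including seed) produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    planted_by_index = {p.pathway_index: p.pattern for p in config.planted}

    # Pathway sizes; a planted MIXED direction needs two genes to realize,
    # so such pathways are grown to at least two members.
    sizes = [
        max(config.min_genes_per_pathway, int(rng.poisson(config.genes_per_pathway_mean)))
        for _ in range(config.n_pathways)
    ]
    for index, pattern in planted_by_index.items():
        need = 2 if PathwayDirection.MIXED in pattern.values() else 1
        sizes[index] = max(sizes[index], need)
        if sizes[index] < 1:
            raise ConfigError(f"planted pathway {index} has no member genes")

    # Disjoint gene membership keeps every planted pattern realizable.
    records: list[PathwayRecord] = []
    gene_pathway: dict[str, int | None] = {}
    counter = 0
    for index in range(config.n_pathways):
        members = []
        for _ in range(sizes[index]):
            counter += 1
            locus = f"LOC_Syn{counter:05d}"
            gene_pathway[locus] = index
            members.append(locus)
        records.append(
            PathwayRecord(
                pathway_id=f"PWY-S{index:04d}",
                name=f"synthetic pathway {index}",
                class_path=_CLASS_PATHS[index % len(_CLASS_PATHS)],
                gene_ids=frozenset(members),
            )
        )
    for _ in range(config.n_background_genes):
        counter += 1
        gene_pathway[f"LOC_Syn{counter:05d}"] = None
    db = PathwayDatabase(records)

    loci = sorted(gene_pathway)

    # Probes: one per locus, plus optional duplicates; a fraction of probes
    # is left out of the map to exercise lossy translation.
    probe_of: list[tuple[str, str, bool]] = []  # (probe, locus, is_duplicate)
    for i, locus in enumerate(loci, start=1):
        probe_of.append((f"Syn.{i:05d}.S1_at", locus, False))
    if config.duplicate_probe_fraction > 0:
        n_dup = int(round(config.duplicate_probe_fraction * len(loci)))
        dup_loci = rng.choice(len(loci), size=n_dup, replace=False)
        for j, k in enumerate(sorted(int(x) for x in dup_loci), start=1):
            probe_of.append((f"Syn.{k + 1:05d}.S2_at", loci[k], True))
    mapped_mask = [True] * len(probe_of)
    if config.unmapped_probe_fraction > 0:
        n_unmapped = int(round(config.unmapped_probe_fraction * len(probe_of)))
        drop = set(
            int(x)
            for x in rng.choice(len(probe_of), size=n_unmapped, replace=False)
        )
        mapped_mask = [i not in drop for i in range(len(probe_of))]

    with open(outdir / "probe_map.tsv", "w", encoding="utf-8", newline="") as stream:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", "locus_id"])
        for (probe, locus, _), keep in zip(probe_of, mapped_mask):
            if keep:
                writer.writerow([probe, locus])

    write_pathway_table(db, outdir / "pathways.tsv")

    # Per-contrast values per locus, then expanded to probes.
    de_records: dict[Contrast, list[DERecord]] = {c: [] for c in CONTRAST_ORDER}
    locus_direction: dict[tuple[str, Contrast], bool | None] = {}
    for contrast in CONTRAST_ORDER:
        mixed_toggle: dict[int, bool] = {}
        for locus in loci:
            index = gene_pathway[locus]
            pattern = planted_by_index.get(index) if index is not None else None
            up: bool | None
            if pattern is not None:
                direction = pattern.get(contrast)
                if direction is None:
                    up = None  # must stay non-significant
                elif direction is PathwayDirection.MIXED:
                    # Alternate directions within the pathway, starting up,
                    # so both directions are always present.
                    first = mixed_toggle.get(index, True)
                    mixed_toggle[index] = not first
                    up = first
                else:
                    up = direction is PathwayDirection.UP
            else:
                if rng.uniform() < config.background_de_prob:
                    up = bool(rng.uniform() < 0.5)
                else:
                    up = None
            locus_direction[(locus, contrast)] = up
            if up is None:
                ratio, q = _non_de_value(rng)
            else:
                ratio, q = _de_value(rng, config, up)
            de_records[contrast].append(
                DERecord(
                    contrast=contrast,
                    gene_id=locus,  # replaced by probe id below
                    fold_change=ratio,
                    q_value=q,
                )
            )

    value_of = {
        (r.gene_id, c): (r.fold_change, r.q_value)
        for c, recs in de_records.items()
        for r in recs
    }
    for contrast in CONTRAST_ORDER:
        rows: list[DERecord] = []
        for probe, locus, is_duplicate in probe_of:
            ratio, q = value_of[(locus, contrast)]
            if is_duplicate and config.conflicting_duplicates:
                up = locus_direction[(locus, contrast)]
                if up is not None:
                    # Conflicting evidence: duplicate probe flips direction.
                    ratio = 1.0 / ratio
            rows.append(
                DERecord(contrast=contrast, gene_id=probe, fold_change=ratio, q_value=q)
            )
        write_de_table(rows, outdir / f"de_{contrast.value}.tsv")

    patterns = {
        records[index].pathway_id: dict(pattern)
        for index, pattern in planted_by_index.items()
    }
    resistance: dict[str, str] = {}
    susceptibility: dict[str, str] = {}
    for record in records:
        pattern = patterns.get(record.pathway_id, {})
        resistance[record.pathway_id], susceptibility[record.pathway_id] = (
            _implied_classes(pattern)
        )
    truth = GroundTruth(
        patterns=patterns, resistance=resistance, susceptibility=susceptibility
    )
    write_truth_table(truth, outdir / "truth.tsv")
    return truth


# ---------------------------------------------------------------------------
# Recovery scoring


def recovery_report(
    assignments: Sequence[ClassAssignment], truth: GroundTruth
) -> "pd.DataFrame":
    """Per-class precision/recall of classifier output against the truth.

    Pathways absent from ``assignments`` are treated as predicted
    class-none (an uncalled pathway never reaches the classifier).  An
    assignment for a pathway outside the truth universe is an error.
    """
    import pandas as pd

    predicted_res: dict[str, str] = {pid: "none" for pid in truth.resistance}
    predicted_sus: dict[str, str] = {pid: "none" for pid in truth.susceptibility}
    for assignment in assignments:
        if assignment.pathway_id not in truth.resistance:
            raise ConsistencyError(
                f"assignment for {assignment.pathway_id!r} outside the truth universe"
            )
        predicted_res[assignment.pathway_id] = assignment.resistance_class.value
        predicted_sus[assignment.pathway_id] = assignment.susceptibility_class.value

    rows = []
    for axis, predicted, actual in (
        ("resistance", predicted_res, truth.resistance),
        ("susceptibility", predicted_sus, truth.susceptibility),
    ):
        for label in ("I", "II", "III"):
            pred = {pid for pid, cls in predicted.items() if cls == label}
            true = {pid for pid, cls in actual.items() if cls == label}
            tp = len(pred & true)
            fp = len(pred - true)
            fn = len(true - pred)
            rows.append(
                {
                    "axis": axis,
                    "class": label,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": 1.0 if tp + fp == 0 else tp / (tp + fp),
                    "recall": 1.0 if tp + fn == 0 else tp / (tp + fn),
                }
            )
    return pd.DataFrame(rows)
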