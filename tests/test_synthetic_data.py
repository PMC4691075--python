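import hashlib
from pathlib import Path

import pytest

from hopperpath.de_input import (
    CONTRAST_ORDER,
    Contrast,
    filter_significant,
    is_significant,
    read_de_table,
)
from hopperpath.errors import ConfigError, ConsistencyError
from hopperpath.pathway_calls import (
    PathwayDirection,
    build_patterns,
    call_pathways,
)
from hopperpath.pathway_db import read_pathway_table, read_probe_map, translate_probes
from hopperpath.synthetic_data import (
    GroundTruth,
    PlantedPattern,
    SimulationConfig,
    generate,
    read_truth_table,
    recovery_report,
)
from hopperpath.venn_classify import ClassAssignment, ClassLabel, classify_patterns

U, D, M = PathwayDirection.UP, PathwayDirection.DOWN, PathwayDirection.MIXED


def run_pipeline(bundle: Path):
    """Read a generated bundle and return recovered patterns."""
    db = read_pathway_table(bundle / "pathways.tsv")
    probe_map = read_probe_map(bundle / "probe_map.tsv")
    calls = []
    for contrast in CONTRAST_ORDER:
        records = read_de_table(bundle / f"de_{contrast.value}.tsv")
        records, _ = translate_probes(records, probe_map)
        calls.extend(call_pathways(filter_significant(records), db, contrast))
    return build_patterns(calls)


def plant(index, **kwargs):
    mapping = {
        "s": Contrast.S6_S0,
        "r": Contrast.R6_R0,
        "g0": Contrast.R0_S0,
        "g6": Contrast.R6_S6,
    }
    return PlantedPattern(index, {mapping[k]: v for k, v in kwargs.items()})


class TestConfigValidation:
    def test_planted_index_out_of_range(self):
        with pytest.raises(ConfigError, match="out of range"):
            SimulationConfig(n_pathways=3, planted=[plant(3, r=U)])

    def test_empty_planted_pattern_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(planted=[PlantedPattern(0, {})])

    def test_two_plants_on_one_pathway_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(planted=[plant(0, r=U), plant(0, s=D)])

    def test_from_dict_parses_labels(self):
        config = SimulationConfig.from_dict(
            {
                "n_pathways": 4,
                "seed": 9,
                "planted": [
                    {"pathway_index": 1, "pattern": {"R6_R0": "down", "R6_S6": "down"}}
                ],
            }
        )
        assert config.planted[0].pattern == {Contrast.R6_R0: D, Contrast.R6_S6: D}


class TestGenerate:
    def test_reproducible_byte_identical(self, tmp_path):
        config = dict(n_pathways=8, planted=[plant(0, r=U, g6=U)], seed=11,
                      background_de_prob=0.1)
        hashes = []
        for sub in ("a", "b"):
            outdir = tmp_path / sub
            generate(SimulationConfig(**config), outdir)
            digest = {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(outdir.iterdir())
            }
            hashes.append(digest)
        assert hashes[0] == hashes[1]
        assert set(hashes[0]) == {
            "pathways.tsv", "probe_map.tsv", "truth.tsv",
            "de_S6_S0.tsv", "de_R6_R0.tsv", "de_R0_S0.tsv", "de_R6_S6.tsv",
        }

    def test_threshold_coherence(self, tmp_path):
        config = SimulationConfig(
            n_pathways=6,
            planted=[plant(0, r=U, g6=U), plant(1, s=M)],
            background_de_prob=0.2,
            seed=3,
        )
        truth = generate(config, tmp_path)
        db = read_pathway_table(tmp_path / "pathways.tsv")
        planted_loci = {
            locus
            for pid in truth.patterns
            for locus in db[pid].gene_ids
        }
        probe_map = read_probe_map(tmp_path / "probe_map.tsv")
        for contrast in CONTRAST_ORDER:
            records = read_de_table(tmp_path / f"de_{contrast.value}.tsv")
            records, _ = translate_probes(records, probe_map)
            for record in records:
                ratio, q = record.fold_change, record.q_value
                if is_significant(record):
                    assert (ratio >= 2.0 or ratio <= 0.5) and q < 0.05
                else:
                    assert (0.5 < ratio < 2.0) or q >= 0.05
                if record.gene_id in planted_loci:
                    pattern = None
                    for pid, pat in truth.patterns.items():
                        if record.gene_id in db[pid].gene_ids:
                            pattern = pat
                    if contrast not in pattern:
                        assert not is_significant(record)

    def test_zero_plants_zero_background_gives_zero_calls(self, tmp_path):
        generate(SimulationConfig(n_pathways=5, seed=1), tmp_path)
        assert run_pipeline(tmp_path) == []

    def test_single_class_i_plant_recovered(self, tmp_path):
        config = SimulationConfig(
            n_pathways=1, planted=[plant(0, r=D, g6=D)], seed=2
        )
        truth = generate(config, tmp_path)
        patterns = run_pipeline(tmp_path)
        (assignment,) = classify_patterns(patterns)
        assert assignment.resistance_class is ClassLabel.I
        assert truth.resistance[assignment.pathway_id] == "I"

    def test_mixed_plant_realized_via_both_directions(self, tmp_path):
        config = SimulationConfig(
            n_pathways=2, genes_per_pathway_mean=1.0, planted=[plant(0, s=M)], seed=4
        )
        generate(config, tmp_path)
        (pattern,) = run_pipeline(tmp_path)
        assert pattern.get(Contrast.S6_S0) is M

    def test_conflicting_duplicate_probes_force_mixed(self, tmp_path):
        config = SimulationConfig(
            n_pathways=1,
            n_background_genes=0,
            planted=[plant(0, r=U, g6=U)],
            duplicate_probe_fraction=1.0,
            conflicting_duplicates=True,
            seed=6,
        )
        generate(config, tmp_path)
        (pattern,) = run_pipeline(tmp_path)
        assert pattern.get(Contrast.R6_R0) is M

    def test_noise_free_truth_recovered_verbatim(self, tmp_path):
        config = SimulationConfig(
            n_pathways=12,
            planted=[
                plant(0, r=D, g6=D),          # resistance I
                plant(1, r=U, g0=U, g6=U),    # resistance II
                plant(2, s=U, r=D, g6=D),     # III on both axes
                plant(3, s=D, g0=D, g6=D),    # susceptibility II
                plant(4, s=U, g6=U),          # susceptibility I
                plant(5, r=M, g6=M),          # resistance I via MIXED
                plant(6, s=U, r=U, g0=U, g6=U),  # same direction: no class
            ],
            seed=8,
        )
        truth = generate(config, tmp_path)
        patterns = run_pipeline(tmp_path)
        recovered = {p.pathway_id: p.calls for p in patterns}
        assert recovered == {pid: dict(pat) for pid, pat in truth.patterns.items()}
        report = recovery_report(classify_patterns(patterns), truth)
        assert (report["precision"] == 1.0).all()
        assert (report["recall"] == 1.0).all()

    def test_truth_table_round_trip(self, tmp_path):
        config = SimulationConfig(
            n_pathways=4, planted=[plant(0, r=U, g6=U), plant(1, s=M)], seed=5
        )
        truth = generate(config, tmp_path)
        again = read_truth_table(tmp_path / "truth.tsv")
        assert dict(again.resistance) == dict(truth.resistance)
        assert dict(again.susceptibility) == dict(truth.susceptibility)
        assert {k: dict(v) for k, v in again.patterns.items()} == {
            k: dict(v) for k, v in truth.patterns.items()
        }


class TestRecoveryReport:
    def test_perfect_assignment_scores_one(self):
        truth = GroundTruth(
            patterns={}, resistance={"P": "I"}, susceptibility={"P": "none"}
        )
        report = recovery_report(
            [ClassAssignment("P", ClassLabel.I, ClassLabel.NONE)], truth
        )
        assert (report["precision"] == 1.0).all() and (report["recall"] == 1.0).all()

    def test_missed_class_i_pathway_has_zero_recall(self):
        truth = GroundTruth(
            patterns={}, resistance={"P": "I"}, susceptibility={"P": "none"}
        )
        report = recovery_report([], truth)
        row = report[(report["axis"] == "resistance") & (report["class"] == "I")]
        assert float(row["recall"].iloc[0]) == 0.0 and int(row["fn"].iloc[0]) == 1

    def test_foreign_pathway_is_universe_error(self):
        truth = GroundTruth(patterns={}, resistance={}, susceptibility={})
        with pytest.raises(ConsistencyError):
            recovery_report(
                [ClassAssignment("X", ClassLabel.NONE, ClassLabel.NONE)], truth
            )

    def test_counts_equal_brute_force_recount_under_noise(self, tmp_path):
        # Stochastic background; recount the confusion table by hand.
        total = {"tp": 0, "fn": 0}
        for seed in range(5):
            outdir = tmp_path / str(seed)
            config = SimulationConfig(
                n_pathways=20,
                planted=[plant(0, r=D, g6=D), plant(1, s=U, r=D, g6=D)],
                background_de_prob=0.05,
                seed=seed,
            )
            truth = generate(config, outdir)
            assignments = classify_patterns(run_pipeline(outdir))
            report = recovery_report(assignments, truth)
            predicted = {
                a.pathway_id: a.resistance_class.value for a in assignments
            }
            for label in ("I", "II", "III"):
                true_set = {
                    pid for pid, cls in truth.resistance.items() if cls == label
                }
                pred_set = {pid for pid, cls in predicted.items() if cls == label}
                row = report[
                    (report["axis"] == "resistance") & (report["class"] == label)
                ]
                assert int(row["tp"].iloc[0]) == len(true_set & pred_set)
                assert int(row["fn"].iloc[0]) == len(true_set - pred_set)
                total["tp"] += len(true_set & pred_set)
                total["fn"] += len(true_set - pred_set)
        assert total["tp"] + total["fn"] == 10  # two planted classes x five seeds
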