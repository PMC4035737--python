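import logging

import numpy as np
import pytest

from pmiscale.discrimination import SP, TM, evaluate_discrimination
from pmiscale.optimizer import (
    OptimizerConfig,
    OptimizerError,
    _TrainingMatrix,
    enumerate_neighbors,
    optimize_scale,
    steepest_step,
)
from pmiscale.scales import CANONICAL_RESIDUES, builtin_scale
from pmiscale.synthetic import GeneratorConfig, generate_dataset
from pmiscale.windowing import WindowingParams
from tests.conftest import make_example


@pytest.fixture(scope="module")
def kd():
    return builtin_scale("KD")


@pytest.fixture(scope="module")
def tiny_training():
    train = [make_example(f"t{i}", TM, "S" * 5 + "I" * 23 + "S" * 5, ((6, 28),)) for i in range(3)]
    train += [make_example(f"s{i}", SP, "K" + "L" * 8 + "S" * 40) for i in range(4)]
    return train


@pytest.mark.parametrize("k,count", [(1, 2), (2, 8), (7, 2186)])
def test_neighborhood_size_is_3_to_k_minus_1(kd, k, count):
    group = list(CANONICAL_RESIDUES[:k])
    assert len(enumerate_neighbors(kd, group, 1.0)) == count


def test_neighbors_exclude_identity_and_leave_other_residues_untouched(kd):
    neighbors = enumerate_neighbors(kd, ["A", "C"], 0.5)
    for nb in neighbors:
        assert dict(nb.values) != dict(kd.values)
        for aa in CANONICAL_RESIDUES[2:]:
            assert nb.values[aa] == kd.values[aa]
    # deterministic order: unchanged < -delta < +delta, alphabetical residues
    first = neighbors[0]
    assert first.values["A"] == kd.values["A"] and first.values["C"] == kd.values["C"] - 0.5
    assert enumerate_neighbors(kd, ["C", "A"], 0.5)[0].values == first.values


def test_enumerate_neighbors_validates_arguments(kd):
    with pytest.raises(ValueError):
        enumerate_neighbors(kd, [], 1.0)
    with pytest.raises(ValueError):
        enumerate_neighbors(kd, ["A"], 0.0)


def test_no_improvement_when_training_is_perfectly_separated(kd, tiny_training):
    res, _ = evaluate_discrimination(tiny_training, kd)
    assert res.auc == 1.0
    assert steepest_step(kd, ["I", "L"], 1.0, tiny_training) is None


def test_no_improvement_when_group_residues_absent_from_training(kd, tiny_training):
    # moving a residue that never occurs leaves every score unchanged
    assert steepest_step(kd, ["W"], 3.0, tiny_training) is None


def graded_inverted_training():
    """Tiny hand-built set with inverted hydropathy and graded overlap:
    TM cores are mostly-D with increasing I content, SP h-regions are
    I-rich, so the initial K&D AUC is low but not on a flat plateau."""
    train = [
        make_example(f"t{i}", TM, "G" * 5 + "D" * (23 - i) + "I" * i + "G" * 5, ((6, 28),))
        for i in (0, 3, 6, 9, 12)
    ]
    train += [make_example(f"s{j}", SP, "K" + "I" * (6 + j) + "S" * (40 - j)) for j in range(5)]
    return train


def test_steepest_step_picks_the_exhaustively_best_neighbor(kd):
    train = graded_inverted_training()
    group, delta = ["D", "I"], 3.0
    result = steepest_step(kd, group, delta, train)
    assert result is not None
    best_scale, best_auc, moves = result
    # oracle: evaluate every neighbor directly
    aucs = []
    for nb in enumerate_neighbors(kd, group, delta):
        r, _ = evaluate_discrimination(train, nb)
        aucs.append(r.auc)
    r0, _ = evaluate_discrimination(train, kd)
    assert best_auc == pytest.approx(max(aucs), abs=1e-9)
    assert best_auc > r0.auc
    direct, _ = evaluate_discrimination(train, best_scale)
    assert direct.auc == pytest.approx(best_auc, abs=1e-9)


def test_training_matrix_scores_match_direct_evaluation(kd):
    dataset = generate_dataset(25, 40, GeneratorConfig(seed=3))
    matrix = _TrainingMatrix(dataset, WindowingParams())
    _, scored = evaluate_discrimination(dataset, kd)
    np.testing.assert_allclose(
        matrix.example_scores(kd.as_array()),
        [e.score for e in scored],
        atol=1e-9,
    )


def test_training_matrix_requires_both_classes(kd, tiny_training):
    with pytest.raises(ValueError, match="both"):
        _TrainingMatrix([ex for ex in tiny_training if ex.label == TM], WindowingParams())


def test_config_validates_groups_and_deltas(kd):
    with pytest.raises(ValueError, match="cover"):
        OptimizerConfig(groups=(("A",), ("C",)))
    with pytest.raises(ValueError, match="positive"):
        OptimizerConfig(delta_schedule=(1.0, -0.5))
    with pytest.raises(ValueError, match="non-increasing"):
        OptimizerConfig(delta_schedule=(1.0, 2.0))


def test_optimizer_returns_initial_scale_on_separated_training(kd, tiny_training):
    scale, trace = optimize_scale(tiny_training, OptimizerConfig(delta_schedule=(3.0, 1.0)))
    assert trace.initial_auc == 1.0 and trace.final_auc == 1.0
    assert trace.steps == []
    assert dict(scale.values) == dict(kd.values)


def test_single_residue_group_reaches_local_optimum_of_value_grid(kd):
    """With one residue and one delta, steepest ascent must end on a grid
    value whose neighbors do not improve the AUC, matching exhaustive
    search over the monotone reachable grid."""
    train = graded_inverted_training()
    delta = 2.0
    scale = kd
    while True:
        step = steepest_step(scale, ["D"], delta, train)
        if step is None:
            break
        scale = step[0]
    final_auc = evaluate_discrimination(train, scale)[0].auc
    # exhaustive oracle over the reachable grid around the endpoint
    for k in (-1, 1):
        nb = scale.replace_values({"D": scale.values["D"] + k * delta})
        assert evaluate_discrimination(train, nb)[0].auc <= final_auc + 1e-12
    # and the endpoint beats the start
    assert final_auc >= evaluate_discrimination(train, kd)[0].auc


def test_optimizer_trace_is_strictly_increasing_and_deterministic(inverted_config):
    train = generate_dataset(20, 20, inverted_config)
    config = OptimizerConfig(delta_schedule=(3.0, 1.0))
    scale1, trace1 = optimize_scale(train, config)
    scale2, trace2 = optimize_scale(train, config)
    assert dict(scale1.values) == dict(scale2.values)
    assert [(s.group, s.delta, s.moves, s.auc) for s in trace1.steps] == [
        (s.group, s.delta, s.moves, s.auc) for s in trace2.steps
    ]
    aucs = [trace1.initial_auc] + [s.auc for s in trace1.steps]
    assert all(b > a for a, b in zip(aucs, aucs[1:]))
    assert trace1.final_auc > trace1.initial_auc


def test_returned_scale_differs_only_in_traced_residues(inverted_config, kd):
    train = generate_dataset(15, 15, inverted_config)
    scale, trace = optimize_scale(train, OptimizerConfig(delta_schedule=(3.0,)))
    moved = {aa for step in trace.steps for aa, _ in step.moves}
    for aa in CANONICAL_RESIDUES:
        if aa not in moved:
            assert scale.values[aa] == kd.values[aa]


def test_step_cap_raises_with_trace_attached(inverted_config):
    train = generate_dataset(30, 30, inverted_config)
    with pytest.raises(OptimizerError) as exc:
        optimize_scale(train, OptimizerConfig(max_steps_per_phase=1))
    assert len(exc.value.trace.steps) >= 1


def test_oversized_group_falls_back_to_single_coordinate_moves(kd, tiny_training, caplog):
    big = tuple(CANONICAL_RESIDUES[:8])
    with caplog.at_level(logging.WARNING):
        result = steepest_step(kd, big, 3.0, tiny_training)
    assert "single-coordinate" in caplog.text
    assert result is None  # tiny training is already separated


def test_trace_tsv_export(tmp_path, inverted_config):
    from pmiscale.optimizer import write_trace_tsv

    train = generate_dataset(15, 15, inverted_config)
    _, trace = optimize_scale(train, OptimizerConfig(delta_schedule=(3.0,)))
    out = tmp_path / "trace.tsv"
    write_trace_tsv(trace, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "step\tgroup\tdelta\tmove\tauc"
    assert len(lines) == 2 + len(trace.steps)
    aucs = [float(l.split("\t")[4]) for l in lines[1:]]
    assert aucs == sorted(aucs)
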