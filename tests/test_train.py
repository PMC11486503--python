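"""Training loop, metrics and the repeated-split / ablation / sweep harnesses."""

import numpy as np
import pytest

import oracles
from dualddi import (
    TrainConfig,
    evaluate,
    run_ablation,
    run_cv,
    run_sweep,
    scaled_synthetic_config,
    train,
)
from dualddi.pairs import stratified_split
from dualddi.training import SPLIT_SCHEMES, MetricsReport, metrics_from_scores


def micro_config(**kw):
    base = dict(
        epochs=2, phase_boundary=1, batch_size=32, d=8, n_patterns=3,
        n_gin_layers=2, head_hidden=(16,), lam=0.25, seed=0,
    )
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def tiny_split(tiny_benchmark):
    records, pairs, _ = tiny_benchmark
    split = stratified_split(pairs, (0.6, 0.2, 0.2), seed=0)
    return records, split


def balanced_subset(pairs, n):
    pos = [p for p in pairs if p.label == 1][: n // 2]
    neg = [p for p in pairs if p.label == 0][: n // 2]
    return pos + neg


def test_phase_boundary_beyond_epochs_rejected():
    with pytest.raises(ValueError, match="boundary"):
        TrainConfig(epochs=10, phase_boundary=20)


def test_single_class_training_set_rejected(tiny_split):
    records, split = tiny_split
    positives = [p for p in split.partition("train") if p.label == 1]
    with pytest.raises(ValueError, match="both classes"):
        train(records, positives, split.partition("valid"), micro_config())


def test_learning_rate_switches_at_phase_boundary(tiny_split):
    records, split = tiny_split
    config = micro_config(epochs=3, phase_boundary=2)
    result = train(records, balanced_subset(split.partition("train"), 64),
                   balanced_subset(split.partition("valid"), 32), config)
    lrs = result.history["lr"].tolist()
    assert lrs == [config.lr_phase1, config.lr_phase1, config.lr_phase2]


def test_same_seed_reproduces_first_epoch_loss(tiny_split):
    records, split = tiny_split
    tr = balanced_subset(split.partition("train"), 64)
    va = balanced_subset(split.partition("valid"), 32)
    h1 = train(records, tr, va, micro_config(epochs=1, phase_boundary=1)).history
    h2 = train(records, tr, va, micro_config(epochs=1, phase_boundary=1)).history
    assert h1["train_loss"][0] == h2["train_loss"][0]


def test_small_separable_set_is_memorized(tiny_benchmark):
    records, pairs, _ = tiny_benchmark
    subset = sorted(pairs, key=lambda p: p.label)[:32] + \
        sorted(pairs, key=lambda p: -p.label)[:32]
    config = scaled_synthetic_config(
        epochs=100, phase_boundary=100, batch_size=32, seed=0, eval_every=100,
    )
    result = train(records, subset, [], config)
    report = evaluate(result.model, records, subset)
    assert result.history["train_loss"].iloc[-1] < 0.1
    assert report.repeats[0]["auroc"] >= 0.99


def test_perfect_separation_metrics():
    row = metrics_from_scores(np.array([1, 1, 0, 0]),
                              np.array([0.9, 0.8, 0.2, 0.1]))
    assert row["auroc"] == 1.0 and row["ap"] == 1.0 and row["acc"] == 1.0


def test_auroc_matches_concordance_oracle(rng):
    labels = np.array([0, 1, 1, 0])
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    row = metrics_from_scores(labels, scores)
    assert row["auroc"] == pytest.approx(0.5)
    labels = rng.integers(0, 2, size=150)
    labels[:2] = [0, 1]
    scores = rng.random(150)
    row = metrics_from_scores(labels, scores)
    assert row["auroc"] == pytest.approx(
        oracles.auroc(labels.tolist(), scores.tolist()), abs=1e-12
    )


def test_single_class_input_flags_ranking_metrics():
    row = metrics_from_scores(np.ones(5), np.linspace(0.1, 0.9, 5))
    assert row["auroc"] is None and row["ap"] is None
    assert row["ranking_undefined"] is True
    assert 0.0 <= row["acc"] <= 1.0


def test_run_cv_single_repeat_reports_and_aggregates(tiny_benchmark):
    records, pairs, _ = tiny_benchmark
    report, results = run_cv(records, pairs, "three_fold_622",
                             micro_config(), repeats=2)
    assert len(report.repeats) == 2
    for metric in MetricsReport.METRICS:
        values = [r[metric] for r in report.repeats]
        assert min(values) <= report.mean(metric) <= max(values)
    assert report.sd("auroc") >= 0.0
    assert {r["split_seed"] for r in report.repeats} == {0, 1}


def test_split_schemes_expose_documented_ratios():
    assert SPLIT_SCHEMES["three_fold_622"] == (0.6, 0.2, 0.2)
    assert SPLIT_SCHEMES["five_fold_811"] == (0.8, 0.1, 0.1)


def test_run_ablation_emits_all_variants_with_expected_widths(tiny_benchmark):
    records, pairs, _ = tiny_benchmark
    table = run_ablation(records, pairs, micro_config(), repeats=1)
    widths = dict(zip(table["variant"], table["head_input_width"]))
    d, m = 8, 3
    assert widths == {
        "full": 2 * d + m * m,
        "no_cross_attention": m * m,
        "no_normalization": 2 * d + m * m,
        "no_similarity": 2 * d,
    }
    assert table[["auroc", "ap", "f1", "acc"]].notna().all().all()


def test_run_sweep_long_format(tiny_benchmark):
    records, pairs, _ = tiny_benchmark
    table = run_sweep(records, pairs, "lam", [0.0, 1.5], micro_config(), repeats=1)
    assert len(table) == 2 * len(MetricsReport.METRICS)
    assert set(table["value"]) == {0.0, 1.5}
    with pytest.raises(ValueError, match="sweepable"):
        run_sweep(records, pairs, "epochs", [1], micro_config())
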