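"""Training and evaluation harness.

Implements the full protocol: mini-batch Adam optimization of the BCE loss
with a two-phase learning-rate schedule (high rate for the first half of
training, one tenth of it afterwards), model selection on validation AUROC,
repeated stratified-split evaluation at 6:2:2 or 8:1:1 ratios, ablation
variants and one-parameter sweeps.

Metrics are AUROC, average precision (step-wise precision-recall area), F1
and accuracy at a 0.5 probability threshold, computed with scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from .chem import DrugRecord, MolecularGraph
from .model import DDIModel, ModelConfig
from .nn import Adam
from .pairs import LabeledPair, stratified_split

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TrainResult",
    "train",
    "evaluate",
    "run_cv",
    "run_ablation",
    "run_sweep",
    "scaled_synthetic_config",
    "SPLIT_SCHEMES",
]

log = logging.getLogger(__name__)

SPLIT_SCHEMES = {
    "three_fold_622": (0.6, 0.2, 0.2),
    "five_fold_811": (0.8, 0.1, 0.1),
}


@dataclass
class TrainConfig:
    epochs: int = 300
    lr_phase1: float = 1e-3
    lr_phase2: float = 1e-4
    phase_boundary: int = 150        # last epoch trained at lr_phase1
    batch_size: int = 512
    d: int = 128
    n_patterns: int = 60             # M
    n_gin_layers: int = 5
    lam: float = 0.75
    seed: int = 0
    use_gsat: bool = True
    use_giat: bool = True
    use_normalization: bool = True
    head_hidden: tuple[int, ...] = (512, 128)
    attn_scale: str = "sqrt_d"
    scheme: str = "atoms-v1"
    optimizer: str = "adam"
    eval_every: int = 1              # validation cadence in epochs

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.phase_boundary <= self.epochs:
            raise ValueError(
                f"phase boundary {self.phase_boundary} outside 0..{self.epochs}"
            )
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        self.head_hidden = tuple(self.head_hidden)

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            d=self.d,
            n_patterns=self.n_patterns,
            n_gin_layers=self.n_gin_layers,
            lam=self.lam,
            attn_scale=self.attn_scale,
            scheme=self.scheme,
            head_hidden=self.head_hidden,
            use_gsat=self.use_gsat,
            use_giat=self.use_giat,
            use_normalization=self.use_normalization,
        )


def scaled_synthetic_config(**overrides) -> TrainConfig:
    """CPU-sized defaults for the synthetic planted-rule benchmarks.

    Width, pattern count, depth and epochs are scaled down from the
    full-size defaults; the learning-rate drop keeps its half-way position.
    """
    # The full protocol drops the learning rate at epoch 150; a 60-epoch
    # scaled run ends before that point, so no drop occurs within it.
    base = dict(
        epochs=60, phase_boundary=60, batch_size=64,
        d=32, n_patterns=16, n_gin_layers=3, head_hidden=(128, 64),
        eval_every=5,
    )
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class MetricsReport:
    """Per-repeat metric values plus their mean and standard deviation."""

    repeats: list[dict] = field(default_factory=list)
    conventions: dict = field(
        default_factory=lambda: {
            "ap": "step-wise precision-recall area",
            "threshold": 0.5,
        }
    )

    METRICS = ("auroc", "ap", "f1", "acc")

    def add(self, row: dict) -> None:
        self.repeats.append(row)

    def mean(self, metric: str) -> float:
        vals = [r[metric] for r in self.repeats if r.get(metric) is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def sd(self, metric: str) -> float:
        vals = [r[metric] for r in self.repeats if r.get(metric) is not None]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m)} for m in self.METRICS
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.repeats)


def _pair_graphs(
    pairs: list[LabeledPair], graphs: dict[str, MolecularGraph]
) -> tuple[list[MolecularGraph], list[MolecularGraph], np.ndarray]:
    ga = [graphs[p.drug_a] for p in pairs]
    gb = [graphs[p.drug_b] for p in pairs]
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return ga, gb, y


def _graph_index(library: list[DrugRecord]) -> dict[str, MolecularGraph]:
    return {r.drug_id: r.graph for r in library}


@dataclass
class TrainResult:
    model: DDIModel
    history: pd.DataFrame
    best_epoch: int
    best_valid_auroc: float


def train(
    library: list[DrugRecord],
    pairs_train: list[LabeledPair],
    pairs_valid: list[LabeledPair],
    config: TrainConfig,
) -> TrainResult:
    """Mini-batch BCE training with the two-phase learning-rate schedule.

    Logs per-epoch loss and validation metrics; the parameters of the best
    validation-AUROC epoch are restored before returning.  Reproducible
    given the config seed.
    """
    labels = {p.label for p in pairs_train}
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    graphs = _graph_index(library)
    model = DDIModel(config.model_config(), seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr_phase1)
    rng = np.random.default_rng(config.seed + 10_000)
    ga, gb, y = _pair_graphs(pairs_train, graphs)
    n = len(pairs_train)
    history_rows = []
    best_auroc, best_epoch, best_state = -np.inf, -1, model.state_arrays()
    for epoch in range(1, config.epochs + 1):
        opt.lr = config.lr_phase1 if epoch <= config.phase_boundary else config.lr_phase2
        order = rng.permutation(n)
        epoch_loss, n_batches, density = 0.0, 0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, diag = model.loss(
                [ga[i] for i in idx], [gb[i] for i in idx], y[idx]
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.data.item()
            density += diag.get("mask_density", 0.0)
            n_batches += 1
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": epoch_loss / n_batches,
            "mask_density": density / n_batches,
        }
        if pairs_valid and (epoch % config.eval_every == 0 or epoch == config.epochs):
            valid = evaluate(model, library, pairs_valid)
            row.update(
                valid_auroc=valid.repeats[0]["auroc"], valid_ap=valid.repeats[0]["ap"]
            )
            if row["valid_auroc"] is not None and row["valid_auroc"] > best_auroc:
                best_auroc, best_epoch = row["valid_auroc"], epoch
                best_state = model.state_arrays()
        history_rows.append(row)
        log.info(
            "epoch %d lr %.2g loss %.4f valid_auroc %s mask_density %.3f",
            epoch, row["lr"], row["train_loss"],
            f"{row['valid_auroc']:.4f}" if row.get("valid_auroc") is not None else "-",
            row["mask_density"],
        )
    if pairs_valid:
        model.load_state_arrays(best_state)
    else:
        best_epoch, best_auroc = config.epochs, float("nan")
    return TrainResult(
        model=model,
        history=pd.DataFrame(history_rows),
        best_epoch=best_epoch,
        best_valid_auroc=best_auroc,
    )


def evaluate(
    model: DDIModel, library: list[DrugRecord], pairs: list[LabeledPair]
) -> MetricsReport:
    """AUROC / AP / F1 / ACC on labeled pairs (single round).

    With a single-class input, AUROC and AP are undefined and reported as
    None with a flag; the threshold metrics are still computed.
    """
    if not pairs:
        raise ValueError("no pairs to evaluate")
    graphs = _graph_index(library)
    ga, gb, y = _pair_graphs(pairs, graphs)
    scores = model.predict_proba(ga, gb)
    report = MetricsReport()
    report.add(metrics_from_scores(y, scores))
    return report


def metrics_from_scores(y: np.ndarray, scores: np.ndarray) -> dict:
    y = np.asarray(y)
    predicted = (scores >= 0.5).astype(int)
    row = {
        "n_pairs": int(len(y)),
        "f1": float(f1_score(y, predicted, zero_division=0)),
        "acc": float(accuracy_score(y, predicted)),
    }
    if len(np.unique(y)) < 2:
        row.update(auroc=None, ap=None, ranking_undefined=True)
    else:
        row.update(
            auroc=float(roc_auc_score(y, scores)),
            ap=float(average_precision_score(y, scores)),
            ranking_undefined=False,
        )
    return row


def run_cv(
    library: list[DrugRecord],
    pairs: list[LabeledPair],
    scheme: str = "three_fold_622",
    config: TrainConfig | None = None,
    repeats: int = 5,
) -> tuple[MetricsReport, list[TrainResult]]:
    """Repeated random stratified splits at the scheme's ratios.

    Each repeat re-splits with seed ``config.seed + repeat``, trains on the
    train partition, selects on validation AUROC and reports test metrics;
    the report aggregates mean and standard deviation over repeats.
    """
    if scheme not in SPLIT_SCHEMES:
        raise ValueError(f"scheme must be one of {sorted(SPLIT_SCHEMES)}")
    config = config or TrainConfig()
    ratios = SPLIT_SCHEMES[scheme]
    report = MetricsReport()
    results = []
    for repeat in range(repeats):
        split_seed = config.seed + repeat
        split = stratified_split(pairs, ratios, seed=split_seed)
        repeat_config = replace(config, seed=split_seed)
        result = train(
            library, split.partition("train"), split.partition("valid"), repeat_config
        )
        test_report = evaluate(result.model, library, split.partition("test"))
        row = dict(test_report.repeats[0])
        row.update(repeat=repeat, split_seed=split_seed, best_epoch=result.best_epoch)
        report.add(row)
        results.append(result)
        log.info("repeat %d: %s", repeat,
                 {k: row[k] for k in ("auroc", "ap", "f1", "acc")})
    return report, results


ABLATION_VARIANTS = {
    "full": {},
    "no_cross_attention": {"use_giat": False},
    "no_normalization": {"use_normalization": False},
    "no_similarity": {"use_gsat": False},
}


def run_ablation(
    library: list[DrugRecord],
    pairs: list[LabeledPair],
    config: TrainConfig,
    scheme: str = "three_fold_622",
    repeats: int = 1,
) -> pd.DataFrame:
    """Train the full model and the three single-module-removed variants.

    All variants share the config seed, hence identical splits; returns a
    tidy table of mean/sd metrics per variant.
    """
    rows = []
    for name, flags in ABLATION_VARIANTS.items():
        variant = replace(config, **flags)
        report, _ = run_cv(library, pairs, scheme, variant, repeats)
        row = {"variant": name,
               "head_input_width": variant.model_config().head_input_width}
        for metric in MetricsReport.METRICS:
            row[metric] = report.mean(metric)
            row[f"{metric}_sd"] = report.sd(metric)
        rows.append(row)
    return pd.DataFrame(rows)


def run_sweep(
    library: list[DrugRecord],
    pairs: list[LabeledPair],
    parameter: str,
    values: list,
    config: TrainConfig,
    scheme: str = "three_fold_622",
    repeats: int = 1,
) -> pd.DataFrame:
    """One run_cv per parameter value, everything else fixed (long format)."""
    if parameter not in {"batch_size", "lam", "n_gin_layers"}:
        raise ValueError("sweepable parameters: batch_size, lam, n_gin_layers")
    if not values:
        raise ValueError("no sweep values given")
    rows = []
    for value in values:
        swept = replace(config, **{parameter: value})
        report, _ = run_cv(library, pairs, scheme, swept, repeats)
        for metric in MetricsReport.METRICS:
            rows.append({
                "parameter": parameter,
                "value": value,
                "metric": metric,
                "mean": report.mean(metric),
                "sd": report.sd(metric),
            })
    return pd.DataFrame(rows)
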