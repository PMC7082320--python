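"""Experiment driver: epoch loops, evaluation, rule comparison, CSV logs.

Runs scaled-down analogues of rate-coded classification experiments on the
synthetic task: per-example online training (no mini-batching), prediction
by argmax of output firing counts (ties resolve to the lowest neuron index),
and fully seed-deterministic execution — every source of randomness (data,
weight init, feedback matrices, optional shuffling) derives from the seeds
recorded in the result.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .data import RateDataset, RateTaskSpec, make_rate_task
from .learning import TrainConfig, init_network, train_example
from .neuron import Network, NeuronParams, forward_pass

__all__ = [
    "ExperimentResult",
    "evaluate",
    "run_experiment",
    "compare_rules",
    "write_results_csv",
]

#: Feedback variant used by each learning rule.
RULE_FEEDBACK = {
    "stdfa": "real-uniform",
    "stdfa2": "power-of-2-set",
    "bp-baseline": "power-of-2-set",  # unused by the rule, kept for parity
    "frozen": "power-of-2-set",
}


@dataclass
class ExperimentResult:
    """Per-epoch training curve and final accuracies of one run."""

    rule: str
    seed: int
    epoch_losses: list[float]
    epoch_accuracies: list[float]  # percent, online training accuracy
    final_train_accuracy: float  # percent
    test_accuracy: float  # percent
    epochs_run: int
    data_hash: str
    config: dict = field(default_factory=dict)

    def epochs_to_accuracy(self, target_pct: float) -> int | None:
        """First epoch (1-based) whose training accuracy reaches the target."""
        for i, acc in enumerate(self.epoch_accuracies):
            if acc >= target_pct:
                return i + 1
        return None


def _dataset_hash(ds: RateDataset) -> str:
    h = hashlib.sha256()
    for ex in ds.examples:
        h.update(np.packbits(ex).tobytes())
    h.update(ds.labels.tobytes())
    return h.hexdigest()[:16]


def evaluate(net: Network, dataset: RateDataset, quantized: bool = False) -> float:
    """Classification accuracy (percent) by argmax of output spike counts."""
    correct = 0
    for raster, label in zip(dataset.examples, dataset.labels):
        counts = forward_pass(net, raster, quantized=quantized).output_counts
        if int(np.argmax(counts)) == int(label):
            correct += 1
    return 100.0 * correct / len(dataset)


def run_experiment(
    cfg: TrainConfig,
    task: RateTaskSpec,
    layer_sizes,
    params: NeuronParams | None = None,
    stop_at_train_acc: float | None = None,
    log_path=None,
    n_test_per_class: int | None = None,
) -> ExperimentResult:
    """Train one network with the configured rule and measure accuracies.

    The training accuracy of an epoch is the online accuracy: the fraction
    of examples whose forward pass (before that example's update) predicted
    the correct class. ``stop_at_train_acc`` (percent) stops early once an
    epoch reaches it — useful because converged runs change little after.
    Test accuracy is measured on a freshly sampled dataset from the same
    task specification but an independent seed.
    """
    if cfg.rule not in RULE_FEEDBACK:
        raise ValueError(f"unknown rule {cfg.rule!r}")
    dataset = make_rate_task(task)
    net = init_network(
        layer_sizes,
        seed=cfg.seed,
        params=params,
        feedback_variant=RULE_FEEDBACK[cfg.rule],
    )
    rng = np.random.default_rng(cfg.seed + 1)

    losses: list[float] = []
    accs: list[float] = []
    rows: list[tuple[int, float, float]] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset)) if cfg.shuffle else np.arange(len(dataset))
        total_loss = 0.0
        correct = 0
        for i in order:
            report = train_example(net, dataset.examples[i], int(dataset.labels[i]), cfg)
            total_loss += report.loss
            correct += report.correct
        acc = 100.0 * correct / len(dataset)
        losses.append(total_loss / len(dataset))
        accs.append(acc)
        rows.append((epoch + 1, losses[-1], acc))
        if stop_at_train_acc is not None and acc >= stop_at_train_acc:
            break

    test_task = replace(
        task,
        seed=task.seed + 986533,
        n_per_class=n_test_per_class or task.n_per_class,
    )
    test_acc = evaluate(net, make_rate_task(test_task), quantized=cfg.quantize)

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss", "train_accuracy_pct"])
            writer.writerows(rows)

    snapshot = {**asdict(cfg), "layer_sizes": list(layer_sizes), "task": asdict(task)}
    snapshot["weight_format"] = (
        cfg.weight_format.total_bits, cfg.weight_format.frac_bits,
        cfg.weight_format.signed,
    )
    return ExperimentResult(
        rule=cfg.rule,
        seed=cfg.seed,
        epoch_losses=losses,
        epoch_accuracies=accs,
        final_train_accuracy=accs[-1],
        test_accuracy=test_acc,
        epochs_run=len(accs),
        data_hash=_dataset_hash(dataset),
        config=snapshot,
    )


def compare_rules(
    cfg: TrainConfig,
    task: RateTaskSpec,
    layer_sizes,
    rules: list[str],
    **kwargs,
) -> list[ExperimentResult]:
    """Run several rules on identical data and seeds, one result per rule.

    All runs share the task specification and training seed, so datasets are
    identical across rows (verifiable via ``data_hash``).
    """
    if not rules:
        raise ValueError("need at least one rule")
    return [run_experiment(replace(cfg, rule=r), task, layer_sizes, **kwargs) for r in rules]


def write_results_csv(results: list[ExperimentResult], path) -> None:
    """Summary table, one row per run."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["rule", "seed", "epochs_run", "final_train_accuracy_pct",
             "test_accuracy_pct", "final_mean_loss", "data_hash"]
        )
        for r in results:
            writer.writerow(
                [r.rule, r.seed, r.epochs_run, f"{r.final_train_accuracy:.2f}",
                 f"{r.test_accuracy:.2f}", f"{r.epoch_losses[-1]:.4f}", r.data_hash]
            )
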