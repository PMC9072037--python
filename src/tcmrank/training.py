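"""Seeded training loop and multi-run experiment driver.

Training follows the reference protocol: Adam with learning rate 5e-4,
batches of 5000 samples, truncated-normal initialization, and -- because
random initialization makes single runs fluctuate -- every experiment is
trained several times (default 5, seeds ``base_seed .. base_seed+n_runs-1``)
and each evaluation metric is averaged across runs.  Batches are scaled
down proportionally (floor 64) when a corpus yields fewer than 20 batches,
so desk-scale synthetic corpora still see a sensible number of updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .corpus import FIELDS, MedicalCase, Vocabulary, build_samples, split_cases
from .evaluation import MetricsReport, evaluate_scores
from .model import Batch, MMOEMatchModel, ModelConfig, batch_from_samples, make_model
from .stat_features import CooccurrenceStats, FeatureConfig, case_feature_vector, compute_stats

MIN_BATCH = 64
TARGET_BATCHES = 20


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 5000
    epochs: int = 10
    n_runs: int = 5
    base_seed: int = 0
    shuffle: bool = True
    patience: int | None = None       # early stop on held-out AUC, optional
    negative_policy: str = "all"
    n_negatives: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.n_runs < 1 or self.epochs < 1:
            raise ValueError("batch_size, epochs and n_runs must be >= 1")


class Adam:
    """Standard Adam over a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def effective_batch_size(n_samples: int, batch_size: int) -> int:
    """Scale the batch down (floor 64) when there would be < 20 batches."""
    if n_samples >= TARGET_BATCHES * batch_size:
        return batch_size
    return max(MIN_BATCH, n_samples // TARGET_BATCHES)


def train(
    batch: Batch | Sequence,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
    vocab: Vocabulary | None = None,
) -> tuple[MMOEMatchModel, list[dict[str, float]]]:
    """Train one model; deterministic given ``seed``.

    ``batch`` is either a packed :class:`Batch` or a sequence of
    ``LabeledSample``.  The seed drives initialization and epoch shuffling.
    Returns the fitted model and a per-epoch history of mean loss
    components.  A non-finite loss aborts with a diagnostic naming the
    epoch.
    """
    if not isinstance(batch, Batch):
        batch = batch_from_samples(batch)
    n = len(batch)
    if n == 0:
        raise ValueError("no training samples")
    rng = np.random.default_rng(seed)
    if vocab is not None:
        model = make_model(model_config, vocab, rng=rng)
    else:
        vocab_sizes = {f: int(batch.field_ids[f].max()) for f in FIELDS}
        n_elements = int(batch.element_ids.max())
        model = MMOEMatchModel(model_config, vocab_sizes, n_elements, rng=rng)
    history = fit_model(model, batch, train_config, rng)
    model.history = history  # type: ignore[attr-defined]
    return model, history


def fit_model(
    model: MMOEMatchModel, batch: Batch, train_config: TrainConfig, rng: np.random.Generator
) -> list[dict[str, float]]:
    """Run the optimization loop on an existing model; returns the history."""
    n = len(batch)
    bs = effective_batch_size(n, train_config.batch_size)
    opt = Adam(model.params, train_config.learning_rate)
    history: list[dict[str, float]] = []
    monitor = None
    if train_config.patience is not None:
        # hold out 10% of the training batch for the early-stop AUC
        held = rng.permutation(n)[: max(MIN_BATCH, n // 10)]
        monitor = batch.take(held)
        best_auc, best_epoch = -np.inf, 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(n) if train_config.shuffle else np.arange(n)
        sums = {"total": 0.0, "main": 0.0, "match": 0.0, "mimic_u": 0.0, "mimic_v": 0.0}
        weight = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            try:
                losses, grads = model.loss_and_grads(batch.take(idx))
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch + 1}"
                ) from exc
            if train_config.learning_rate > 0:
                opt.step(model.params, grads)
            for k in sums:
                sums[k] += losses[k] * len(idx)
            weight += len(idx)
        epoch_losses = {k: v / weight for k, v in sums.items()}
        epoch_losses["epoch"] = epoch + 1
        history.append(epoch_losses)
        if not np.isfinite(epoch_losses["total"]):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch + 1}")
        if monitor is not None:
            from .evaluation import auc as _auc

            try:
                held_auc = _auc(monitor.labels, model.predict(monitor))
            except ValueError:  # single-class holdout; skip monitoring
                continue
            epoch_losses["held_out_auc"] = held_auc
            if held_auc > best_auc:
                best_auc, best_epoch = held_auc, epoch
            elif epoch - best_epoch >= train_config.patience:
                break
    return history


def attach_stat_features(
    samples, cases: Sequence[MedicalCase], stats: CooccurrenceStats, feat_cfg: FeatureConfig
) -> None:
    """Fill ``extra_features`` of each sample from the co-occurrence tables.

    Feature vectors are cached per (case, element) since all samples of a
    case share the fields.
    """
    by_id = {c.case_id: c for c in cases}
    cache: dict[tuple[str, int], np.ndarray] = {}
    for s in samples:
        key = (s.case_id, s.element_id)
        if key not in cache:
            cache[key] = case_feature_vector(by_id[s.case_id], s.element_id, stats, feat_cfg)
        s.extra_features = cache[key]


def evaluate_model(model: MMOEMatchModel, test_batch: Batch) -> MetricsReport:
    """Score a packed test cross-product and compute all ranking metrics."""
    scores = model.predict(test_batch)
    return evaluate_scores(test_batch.case_ids, test_batch.element_ids, test_batch.labels, scores)


def run_experiment(
    cases: Sequence[MedicalCase],
    vocab: Vocabulary,
    model_config: ModelConfig,
    train_config: TrainConfig,
    test_fraction: float = 0.2,
    feature_config: FeatureConfig | None = None,
    shuffle_train_labels: bool = False,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Split, train ``n_runs`` seeded models, evaluate, and average.

    ``shuffle_train_labels`` permutes training labels (seeded) and serves
    as the no-signal control: the resulting test AUC hovers at 0.5.
    Returns the averaged report plus the per-run reports.
    """
    train_cases, test_cases = split_cases(cases, test_fraction, seed=train_config.base_seed)
    train_samples = build_samples(
        train_cases, vocab, train_config.negative_policy,
        n_negatives=train_config.n_negatives, seed=train_config.base_seed,
    )
    test_samples = build_samples(test_cases, vocab, "all")
    stat_dim = 0
    if feature_config is not None:
        stats = compute_stats(train_cases, vocab)
        attach_stat_features(train_samples, train_cases, stats, feature_config)
        attach_stat_features(test_samples, test_cases, stats, feature_config)
        stat_dim = feature_config.width
    if model_config.stat_dim != stat_dim:
        raise ValueError(
            f"model_config.stat_dim={model_config.stat_dim} does not match "
            f"feature width {stat_dim}"
        )
    train_batch = batch_from_samples(train_samples)
    test_batch = batch_from_samples(test_samples)
    if shuffle_train_labels:
        ctrl_rng = np.random.default_rng(train_config.base_seed + 10_007)
        train_batch.labels = ctrl_rng.permutation(train_batch.labels)
    reports = []
    for run in range(train_config.n_runs):
        seed = train_config.base_seed + run
        rng = np.random.default_rng(seed)
        model = make_model(model_config, vocab, rng=rng)
        history = fit_model(model, train_batch, train_config, rng)
        report = evaluate_model(model, test_batch)
        report.per_run = None
        report.history = history  # type: ignore[attr-defined]
        reports.append(report)
    return MetricsReport.from_runs(reports), reports
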