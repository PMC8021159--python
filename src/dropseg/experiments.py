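"""Evaluation protocols: unshuffled k-fold cross-validation and
training-set-size sweeps.

Cross-validation splits the image list into k contiguous folds (no
shuffling), trains on k-1 folds and scores the hold-out, reporting the
six segmentation metrics per fold and their across-fold means.  The
sweep draws nested training subsets of increasing size from a pool,
always scoring against one fixed held-out test set, and reports the
median per-test-image Dice for each size.

Per-fold scores are per-image means; undefined (NaN) per-image scores
are excluded from averages with the exclusion count reported.  Pooled
confusion counts across a fold's images are also emitted for anyone who
prefers pixel-pooled scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classic_models import PixelClassifier
from .filters import FilterBank, FilterBankFeaturizer, PixelMatrix, build_default_bank, flatten_dataset
from .io import BinaryMask, normalize_to_uint8
from .metrics import (
    METRIC_NAMES,
    MetricsReport,
    compute_metrics,
    confusion_counts,
    mean_defined,
    score_masks,
)
from .nn.unet import UNetSegmenter
from .synthetic import SyntheticPair

CLASSIC_METHODS = ("rf", "xgb", "svm", "mlp", "lda")
ALL_METHODS = CLASSIC_METHODS + ("cnn",)


@dataclass
class ExperimentConfig:
    """Shared knobs for both protocols."""

    k_folds: int = 5
    training_sizes: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000)
    methods: tuple[str, ...] = ("rf",)
    seed: int = 0
    epochs: int = 30          # CNN only
    batch_size: int = 2       # CNN only
    unet_widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    unet_bottleneck: int = 128
    canvas: int = 64

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if any(s <= 0 for s in self.training_sizes):
            raise ValueError("training sizes must be positive")
        bad = [m for m in self.methods if m.lower() not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {ALL_METHODS}")


def kfold_split(n: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous, unshuffled k-fold partition of ``range(n)``.

    Hold-out folds are disjoint, cover every index, and differ in size by
    at most one, with the larger folds first when n is not divisible by k.
    Returns (train_indices, validation_indices) per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    splits = []
    start = 0
    all_idx = np.arange(n)
    for size in sizes:
        val = all_idx[start : start + size]
        train = np.concatenate([all_idx[:start], all_idx[start + size :]])
        splits.append((train, val))
        start += size
    return splits


@dataclass
class CVResult:
    """Per-fold reports plus across-fold means for one method."""

    method: str
    fold_reports: list[list[MetricsReport]]   # per fold: per-image reports
    fold_means: list[dict[str, float]]        # per fold: metric -> mean
    means: dict[str, float]                   # metric -> mean over folds
    excluded: dict[str, int]                  # metric -> NaN images excluded
    pooled_counts: list                       # per fold: pooled ConfusionCounts

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, **m) for i, m in enumerate(self.fold_means)]
        rows.append(dict(fold="mean", **self.means))
        return pd.DataFrame(rows)


def _predict_masks_classic(
    model: PixelClassifier, stacks
) -> list[BinaryMask]:
    return [model.segment_stack(s)[1] for s in stacks]


def _score_images(pred_masks, truth_masks) -> list[MetricsReport]:
    return [score_masks(p, t) for p, t in zip(pred_masks, truth_masks)]


def _fold_summary(reports: list[MetricsReport]) -> tuple[dict[str, float], dict[str, int]]:
    means, excluded = {}, {}
    for name in METRIC_NAMES:
        m, ex = mean_defined([getattr(r, name) for r in reports])
        means[name] = m
        excluded[name] = ex
    return means, excluded


def _train_eval_classic(
    method: str,
    train_pairs: list[SyntheticPair],
    test_pairs: list[SyntheticPair],
    cfg: ExperimentConfig,
    bank: FilterBank,
    stacks_cache: dict,
) -> list[MetricsReport]:
    feat = FilterBankFeaturizer(bank=bank).fit([])

    def stacks_for(pairs):
        out = []
        for p in pairs:
            key = id(p)
            if key not in stacks_cache:
                stacks_cache[key] = feat.transform_stacks(
                    [normalize_to_uint8(p.image)]
                )[0]
            out.append(stacks_cache[key])
        return out

    train_stacks = stacks_for(train_pairs)
    matrix = flatten_dataset(
        [(s, p.mask) for s, p in zip(train_stacks, train_pairs)]
    )
    model = PixelClassifier(method=method, seed=cfg.seed).fit(matrix, None)
    test_stacks = stacks_for(test_pairs)
    preds = _predict_masks_classic(model, test_stacks)
    return _score_images(preds, [p.mask for p in test_pairs])


def _train_eval_cnn(
    train_pairs, test_pairs, cfg: ExperimentConfig
) -> list[MetricsReport]:
    seg = UNetSegmenter(
        canvas=cfg.canvas, encoder_widths=cfg.unet_widths,
        bottleneck_width=cfg.unet_bottleneck, epochs=cfg.epochs,
        batch_size=cfg.batch_size, seed=cfg.seed,
    )
    seg.fit([p.image for p in train_pairs], [p.mask for p in train_pairs])
    preds = seg.predict([p.image for p in test_pairs])
    return _score_images(preds, [p.mask for p in test_pairs])


def cross_validate(
    dataset: list[SyntheticPair],
    method: str,
    cfg: ExperimentConfig | None = None,
    bank: FilterBank | None = None,
) -> CVResult:
    """Unshuffled k-fold cross-validation of one method over image pairs."""
    cfg = cfg or ExperimentConfig()
    method = method.lower()
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}")
    bank = bank or build_default_bank()
    splits = kfold_split(len(dataset), cfg.k_folds)
    if method in CLASSIC_METHODS:
        for f, (train_idx, _) in enumerate(splits):
            labels = np.concatenate(
                [dataset[i].mask.pixels.ravel() for i in train_idx]
            )
            if np.unique(labels).size < 2:
                raise ValueError(
                    f"training fold {f} contains a single class; both lipid "
                    "and non-lipid pixels are required"
                )
    stacks_cache: dict = {}
    fold_reports, fold_means, pooled = [], [], []
    excluded_total = {name: 0 for name in METRIC_NAMES}
    for train_idx, val_idx in splits:
        train_pairs = [dataset[i] for i in train_idx]
        val_pairs = [dataset[i] for i in val_idx]
        if method == "cnn":
            reports = _train_eval_cnn(train_pairs, val_pairs, cfg)
        else:
            reports = _train_eval_classic(
                method, train_pairs, val_pairs, cfg, bank, stacks_cache
            )
        means, excluded = _fold_summary(reports)
        fold_reports.append(reports)
        fold_means.append(means)
        for k, v in excluded.items():
            excluded_total[k] += v
        counts = [r.counts for r in reports]
        pooled.append(
            compute_metrics(
                type(counts[0])(
                    tp=sum(c.tp for c in counts), tn=sum(c.tn for c in counts),
                    fp=sum(c.fp for c in counts), fn=sum(c.fn for c in counts),
                )
            ).counts
        )
    means = {}
    for name in METRIC_NAMES:
        m, ex = mean_defined([fm[name] for fm in fold_means])
        means[name] = m
        excluded_total[name] += ex
    return CVResult(
        method=method, fold_reports=fold_reports, fold_means=fold_means,
        means=means, excluded=excluded_total, pooled_counts=pooled,
    )


def training_size_sweep(
    pool: list[SyntheticPair],
    test_set: list[SyntheticPair],
    sizes,
    methods,
    cfg: ExperimentConfig | None = None,
    bank: FilterBank | None = None,
) -> pd.DataFrame:
    """Median held-out Dice as a function of training-set size.

    For each size, a subset is drawn from ``pool`` without replacement
    (seeded), each listed method is trained on it, and the median
    per-image Dice over the fixed ``test_set`` is reported.  The test set
    must be disjoint from the pool.
    """
    cfg = cfg or ExperimentConfig()
    bank = bank or build_default_bank()
    sizes = list(sizes)
    if any(s <= 0 for s in sizes):
        raise ValueError("training sizes must be positive")
    if max(sizes) > len(pool):
        raise ValueError(
            f"largest size {max(sizes)} exceeds the training pool ({len(pool)})"
        )
    pool_ids = {id(p) for p in pool}
    if any(id(t) in pool_ids for t in test_set):
        raise ValueError("test set must be disjoint from the training pool")
    rng = np.random.default_rng(cfg.seed)
    stacks_cache: dict = {}
    rows = []
    for size in sizes:
        subset_idx = rng.choice(len(pool), size=size, replace=False)
        subset = [pool[i] for i in subset_idx]
        for method in methods:
            method = method.lower()
            if method == "cnn":
                reports = _train_eval_cnn(subset, test_set, cfg)
            else:
                reports = _train_eval_classic(
                    method, subset, test_set, cfg, bank, stacks_cache
                )
            dices = [r.dice for r in reports]
            defined = [d for d in dices if not math.isnan(d)]
            median = float(np.median(defined)) if defined else math.nan
            rows.append(
                {"method": method, "size": size, "median_dice": median,
                 "n_test": len(test_set),
                 "n_undefined": len(dices) - len(defined)}
            )
    return pd.DataFrame(rows)
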