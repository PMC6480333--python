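"""Evaluation artifacts: confusion matrix, per-class metrics, probability-bin
summaries, high-confidence metrics, and repeated gene-disjoint cross-validation
with grid search over the (Conv, Pool, Drop) architecture grid.

Metrics are reported as percentages rounded half-even to two decimals.
Per-repetition cross-validation accuracy is the unweighted mean over the k
fold rotations; a configuration's score is the median over T repetitions,
with the sample (n-1) standard deviation as a stability measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GenePairKFold, LabeledFusion, _groups_of, _labels_of
from .encoding import OneHotProteinEncoder
from .model import (
    NOTONCO,
    ONCO,
    ZONE_UNCERTAIN,
    FusionCNNClassifier,
    ModelConfig,
    TrainConfig,
    confidence_zone,
)

_CLASSES = (ONCO, NOTONCO)


@dataclass
class ConfusionMatrix:
    """Counts indexed as counts[predicted][actual] over {Onco, NotOnco}."""

    counts: dict[str, dict[str, int]]

    @classmethod
    def from_counts(cls, onco_onco: int, onco_notonco: int, notonco_onco: int, notonco_notonco: int):
        """Build from the four cells: rows are predictions, columns actual classes."""
        return cls(
            counts={
                ONCO: {ONCO: onco_onco, NOTONCO: onco_notonco},
                NOTONCO: {ONCO: notonco_onco, NOTONCO: notonco_notonco},
            }
        )

    @property
    def total(self) -> int:
        return sum(v for row in self.counts.values() for v in row.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts).T.reindex(index=_CLASSES, columns=_CLASSES)


def confusion_matrix(preds, truths) -> ConfusionMatrix:
    """Tally predicted-vs-actual label counts."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths) or not preds:
        raise ValueError(f"need equal, non-empty label lists (got {len(preds)} vs {len(truths)})")
    bad = (set(preds) | set(truths)) - set(_CLASSES)
    if not set(preds) <= set(_CLASSES) or not set(truths) <= set(_CLASSES):
        raise ValueError(f"labels must be in {_CLASSES}, got {sorted(bad)}")
    counts = {p: {a: 0 for a in _CLASSES} for p in _CLASSES}
    for p, a in zip(preds, truths):
        counts[p][a] += 1
    return ConfusionMatrix(counts=counts)


@dataclass
class MetricsReport:
    """Percent accuracy plus per-class precision/recall; None marks an undefined ratio."""

    accuracy: float | None
    precision_onco: float | None
    recall_onco: float | None
    precision_notonco: float | None
    recall_notonco: float | None
    n: int

    def to_dict(self) -> dict:
        def r2(x):
            return None if x is None else round(x, 2)

        return {
            "accuracy": r2(self.accuracy),
            "precision_onco": r2(self.precision_onco),
            "recall_onco": r2(self.recall_onco),
            "precision_notonco": r2(self.precision_notonco),
            "recall_notonco": r2(self.recall_notonco),
            "n": self.n,
        }


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy and per-class precision/recall (percent) from a confusion matrix.

    A ratio with a zero denominator is reported as undefined (None), never as 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    c = cm.counts
    diag = c[ONCO][ONCO] + c[NOTONCO][NOTONCO]
    return MetricsReport(
        accuracy=_pct(diag, cm.total),
        precision_onco=_pct(c[ONCO][ONCO], c[ONCO][ONCO] + c[ONCO][NOTONCO]),
        recall_onco=_pct(c[ONCO][ONCO], c[ONCO][ONCO] + c[NOTONCO][ONCO]),
        precision_notonco=_pct(c[NOTONCO][NOTONCO], c[NOTONCO][ONCO] + c[NOTONCO][NOTONCO]),
        recall_notonco=_pct(c[NOTONCO][NOTONCO], c[ONCO][NOTONCO] + c[NOTONCO][NOTONCO]),
        n=cm.total,
    )


@dataclass
class ProbabilityBinSummary:
    """Per-bin class counts over equal-width probability ranges (the stacked-bar table)."""

    table: pd.DataFrame  # columns: bin_lo, bin_hi, n_onco, n_notonco
    n_bins: int = 10
    zone_boundaries: tuple[float, float] = (0.2, 0.8)

    @property
    def n(self) -> int:
        return int(self.table[["n_onco", "n_notonco"]].to_numpy().sum())


def bin_probabilities(probs, truths, n_bins: int = 10) -> ProbabilityBinSummary:
    """Count instances per class in equal-width probability bins.

    Bin i covers [i/n, (i+1)/n), with the last bin right-closed so that a
    probability of exactly 1 is counted.
    """
    probs = np.asarray(probs, dtype=float)
    truths = np.asarray(truths)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        rows.append(
            {
                "bin_lo": b / n_bins,
                "bin_hi": (b + 1) / n_bins,
                "n_onco": int((in_bin & (truths == ONCO)).sum()),
                "n_notonco": int((in_bin & (truths == NOTONCO)).sum()),
            }
        )
    return ProbabilityBinSummary(table=pd.DataFrame(rows), n_bins=n_bins)


def high_confidence_metrics(probs, truths) -> tuple[MetricsReport | None, float]:
    """Metrics restricted to the high-confidence zones (< 0.2 or > 0.8).

    Returns the restricted report (None when every instance is uncertain) and
    the fraction of instances falling in a high-confidence zone.
    """
    probs = np.asarray(probs, dtype=float)
    truths = np.asarray(truths)
    zones = np.asarray(confidence_zone(probs))
    keep = zones != ZONE_UNCERTAIN
    fraction = float(keep.mean()) if len(probs) else 0.0
    if not keep.any():
        return None, 0.0
    from .model import label_from_prob

    preds = np.asarray(label_from_prob(probs[keep]))
    return metrics(confusion_matrix(preds, truths[keep])), fraction


def plot_probability_bins(summary: ProbabilityBinSummary, path=None):
    """Stacked-bar rendering of a bin summary with shaded confidence zones."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summary.table
    centers = (t["bin_lo"] + t["bin_hi"]) / 2
    fig, ax = plt.subplots(figsize=(7, 4))
    lo, hi = summary.zone_boundaries
    ax.axvspan(0, lo, color="honeydew")
    ax.axvspan(hi, 1, color="honeydew")
    ax.axvspan(lo, hi, color="0.92")
    width = 0.8 / summary.n_bins
    ax.bar(centers, t["n_notonco"], width=width, label="actual NotOnco", color="tab:blue")
    ax.bar(centers, t["n_onco"], width=width, bottom=t["n_notonco"], label="actual Onco", color="tab:orange")
    ax.set_xlabel("oncogenic probability")
    ax.set_ylabel("instances")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


# -- cross-validation and grid search ------------------------------------------
@dataclass
class CVResult:
    """T repeated cross-validation accuracies for one configuration."""

    name: str
    config: ModelConfig
    accuracies: list[float]
    median: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        self.median = float(np.median(self.accuracies))
        self.std = float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def _classifier_for(cfg: ModelConfig, tcfg: TrainConfig, seed: int) -> FusionCNNClassifier:
    return FusionCNNClassifier(
        conv_kernel=cfg.conv_kernel,
        pool_kernel=cfg.pool_kernel,
        dropout=cfg.dropout,
        n_filters=cfg.n_filters,
        dense_units=cfg.dense_units,
        learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size,
        max_epochs=tcfg.max_epochs,
        patience=tcfg.patience,
        momentum=tcfg.momentum,
        validation_fraction=tcfg.validation_fraction,
        random_state=seed,
    )


def cross_validate(
    train: list[LabeledFusion],
    cfg: ModelConfig,
    tcfg: TrainConfig,
    k: int = 4,
    T: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified, gene-disjoint k-fold cross-validation.

    Each of the T repetitions re-draws the k bins (fresh seed), rotates each
    bin out as the validation fold, trains a fresh network on the remainder
    and averages the k fold accuracies into one repetition accuracy.
    """
    groups = _groups_of(train)
    y = _labels_of(train)
    encoder = OneHotProteinEncoder(seq_len=cfg.input_spec.n).fit([])
    X = encoder.transform([f.aa_seq for f in train])
    rng = np.random.default_rng(seed)
    accuracies = []
    for _t in range(T):
        rep_seed = int(rng.integers(2**31 - 1))
        kf = GenePairKFold(n_splits=k, random_state=rep_seed)
        fold_accs = []
        for j, (tr, va) in enumerate(kf.split(X, y, groups)):
            est = _classifier_for(cfg, tcfg, seed=rep_seed + j)
            est.fit(X[tr], y[tr], groups=groups[tr])
            fold_accs.append(float((est.predict(X[va]) == y[va]).mean()))
        accuracies.append(float(np.mean(fold_accs)))
    return CVResult(name=cfg.name or "config", config=cfg, accuracies=accuracies)


def table_grid(input_spec=None) -> list[ModelConfig]:
    """The 12-configuration architecture grid: four (Conv, Pool) pairs crossed
    with dropout in {0.1, 0.3, 0.5}, named Conf_1 .. Conf_12."""
    from .encoding import EncodingSpec

    spec = input_spec or EncodingSpec()
    grid = []
    i = 1
    for conv, pool in [(3, 2), (5, 2), (5, 3), (10, 5)]:
        for drop in (0.1, 0.3, 0.5):
            grid.append(
                ModelConfig(
                    conv_kernel=conv, pool_kernel=pool, dropout=drop,
                    input_spec=spec, name=f"Conf_{i}",
                )
            )
            i += 1
    return grid


def grid_search(
    train: list[LabeledFusion],
    grid: list[ModelConfig],
    tcfg: TrainConfig,
    k: int = 4,
    T: int = 10,
    seed: int = 0,
    std_cap: float | None = None,
) -> tuple[list[CVResult], CVResult]:
    """Cross-validate every configuration and pick the best compromise.

    Selection: discard configurations whose accuracy standard deviation over
    the T repetitions exceeds ``std_cap`` (default: the grid-wide median of
    the stds), then take the highest median accuracy; ties go to the lower
    std.  Returns all results ranked plus the selected one.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    results = [cross_validate(train, cfg, tcfg, k=k, T=T, seed=seed + i) for i, cfg in enumerate(grid)]
    cap = float(np.median([r.std for r in results])) if std_cap is None else std_cap
    eligible = [r for r in results if r.std <= cap] or results
    ranked = sorted(results, key=lambda r: (-r.median, r.std))
    selected = sorted(eligible, key=lambda r: (-r.median, r.std))[0]
    return ranked, selected


def cv_report_frame(results: list[CVResult]) -> pd.DataFrame:
    """Grid report table: name, Conv, Pool, Drop, median accuracy (%), std."""
    return pd.DataFrame(
        {
            "Name": [r.name for r in results],
            "Conv": [r.config.conv_kernel for r in results],
            "Pool": [r.config.pool_kernel for r in results],
            "Drop": [r.config.dropout for r in results],
            "CrossValidationAccuracy": [round(100 * r.median, 2) for r in results],
            "StandardDeviation": [round(100 * r.std, 2) for r in results],
        }
    )
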