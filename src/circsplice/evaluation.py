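"""Classification metrics, cross-validation and the BN ablation harness.

Five metrics summarize each evaluation: accuracy, AUC, Matthews
correlation coefficient, sensitivity (TPR) and specificity (TNR).  AUC
is the rank-based probability that a random positive outscores a random
negative, with ties contributing 1/2 (midrank convention); it equals
trapezoidal ROC integration.  Hard calls use a 0.5 threshold unless
stated otherwise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .model import ModelConfig, TrainedModel, build_model, predict, train
from .seqdata import SamplePair, FoldSplit, kfold_split

VARIANTS = ("default", "no_bn", "bn_to_dropout")


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    acc: float
    auc: float
    mcc: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class CVResult:
    folds: tuple[MetricsReport, ...]
    split: FoldSplit

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def best_fold(self, metric: str = "auc") -> int:
        """Index of the best-performing fold (highest value of ``metric``)."""
        return int(np.argmax([getattr(f, metric) for f in self.folds]))

    def summary(self) -> dict:
        out = {}
        for m in ("auc", "acc", "mcc", "sensitivity", "specificity"):
            out[f"mean_{m}"] = self.mean(m)
            out[f"best_{m}"] = float(max(getattr(f, m) for f in self.folds))
        return out


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC with the midrank tie convention.

    NaN when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """All five metrics plus confusion counts at the given threshold.

    MCC uses the convention 0 when any marginal factor of its denominator
    is 0; sensitivity/specificity are NaN when their class is absent, and
    so is AUC (single-class input leaves AUC undefined).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    calls = p >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    tn = int(np.sum(~calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    n = len(y)
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(
        acc=float(acc),
        auc=auc_score(y, p),
        mcc=float(mcc),
        sensitivity=float(sens),
        specificity=float(spec),
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )


def cross_validate(
    pairs: Sequence[SamplePair],
    cfg: ModelConfig,
    k: int = 7,
    seed: int = 0,
    threshold: float = 0.5,
    split: FoldSplit | None = None,
    keep_models: bool = False,
    verbose: bool = False,
):
    """Stratified k-fold cross-validation of the classifier.

    Every sample is tested exactly once.  Each fold's model trains on the
    other k-1 folds, with an internal stratified validation split for
    early stopping.  Returns a CVResult; with ``keep_models`` a list of
    the per-fold TrainedModel objects is returned alongside it.
    """
    # canonical order makes the result invariant to input ordering
    pairs = sorted(pairs, key=lambda p: p.id)
    if split is None:
        split = kfold_split(pairs, k=k, seed=seed)
    by_id = {p.id: p for p in pairs}
    reports = []
    models = []
    for fold in range(split.k):
        test_ids = set(split.fold_ids(fold))
        train_pairs = [p for p in pairs if p.id not in test_ids]
        test_pairs = [by_id[i] for i in sorted(test_ids)]
        model = build_model(cfg, seed=cfg.seed + fold)
        train(model, train_pairs, verbose=verbose)
        prob = predict(model, test_pairs)
        y = [p.label for p in test_pairs]
        reports.append(compute_metrics(y, prob, threshold=threshold))
        if keep_models:
            models.append(model)
    result = CVResult(folds=tuple(reports), split=split)
    return (result, models) if keep_models else result


def ablation_suite(
    pairs: Sequence[SamplePair],
    cfg: ModelConfig,
    variants: Sequence[str] = VARIANTS,
    k: int = 7,
    seed: int = 0,
    verbose: bool = False,
) -> dict[str, CVResult]:
    """Run the BN ablation: identical folds, one CVResult per variant.

    Variants: 'default' (batch normalization after concatenation),
    'no_bn' (the layer removed), 'bn_to_dropout' (replaced by dropout).
    """
    pairs = list(pairs)
    split = kfold_split(pairs, k=k, seed=seed)
    out: dict[str, CVResult] = {}
    for name in variants:
        out[name] = cross_validate(
            pairs, cfg.variant(name), k=k, seed=seed, split=split, verbose=verbose
        )
    return out

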