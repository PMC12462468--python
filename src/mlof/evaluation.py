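"""Performance metrics and resampling procedures.

Scores are oriented so that larger means more positive-class-like (the
positive class is LOF by convention); callers evaluating a metric whose
LOF-like direction is low (e.g. EDC) negate or otherwise pre-orient their
scores.  A positive call is made at score >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from mlof.errors import DataError


@dataclass(frozen=True)
class LabelledScore:
    unit_id: str
    score: float
    label: int  # 1 = positive (LOF)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")


@dataclass
class EvalReport:
    auroc: float
    aubprc: float
    t_optimal: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_statistic: str | None = None
    n_boot: int | None = None
    seed: int | None = None


def _split(data: Sequence[LabelledScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([d.score for d in data if d.label == 1], dtype=float)
    neg = np.array([d.score for d in data if d.label == 0], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both classes must be present")
    return pos, neg


def auroc(data: Sequence[LabelledScore]) -> float:
    """AUROC via the Mann-Whitney U statistic, ties counted half."""
    pos, neg = _split(data)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus +/-inf sentinels."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _rates(pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    return tpr, fpr


def optimal_threshold(data: Sequence[LabelledScore]) -> float:
    """Threshold minimising Euclidean distance to the ROC (0, 1) corner.

    Candidates are midpoints between adjacent distinct scores plus
    sentinel thresholds below/above all scores; ties break toward higher
    specificity, then the lower threshold.
    """
    pos, neg = _split(data)
    cand = _candidate_thresholds(np.concatenate([pos, neg]))
    tpr, fpr = _rates(pos, neg, cand)
    dist = np.hypot(1.0 - tpr, fpr)
    order = np.lexsort((cand, fpr, dist))  # dist, then spec (low FPR), then low t
    return float(cand[order[0]])


def threshold_metrics(data: Sequence[LabelledScore], t: float) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and F1 at a positive call of score >= t."""
    pos, neg = _split(data)
    tp = float((pos >= t).sum())
    fn = pos.size - tp
    fp = float((neg >= t).sum())
    tn = neg.size - fp
    sens = tp / pos.size
    spec = tn / neg.size
    acc = (tp + tn) / (pos.size + neg.size)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc, "f1": f1}


def balanced_pr(data: Sequence[LabelledScore]) -> float:
    """Area under the balanced precision-recall curve (AUBPRC).

    Balanced precision rescales precision to a notional 1:1 class balance:
    TPR/(TPR+FPR).  The curve is swept over descending distinct-score
    thresholds, truncated at the first threshold reaching full recall, and
    integrated over recall by the trapezoid rule with a (0, bp_first)
    anchor.
    """
    pos, neg = _split(data)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr, fpr = _rates(pos, neg, thresholds)
    keep = tpr + fpr > 0
    tpr, fpr = tpr[keep], fpr[keep]
    bp = tpr / (tpr + fpr)
    full = np.nonzero(tpr >= 1.0)[0]
    if full.size:
        end = full[0] + 1
        tpr, bp = tpr[:end], bp[:end]
    recall = np.concatenate([[0.0], tpr])
    bp = np.concatenate([[bp[0]], bp])
    return float(np.trapezoid(bp, recall))


def bootstrap_ci(
    statistic: Callable,
    data: Sequence,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    max_retries: int = 100,
    return_samples: bool = False,
):
    """Seeded percentile bootstrap interval of ``statistic`` over ``data``.

    Resampling is at the unit level (whatever the elements of ``data``
    are: genes, phenotypes).  A resample on which the statistic raises
    (e.g. single-class) is redrawn, up to ``max_retries`` times each.
    """
    data = list(data)
    if not data:
        raise DataError("empty data")
    rng = np.random.default_rng(seed)
    n = len(data)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            try:
                stats[b] = statistic([data[i] for i in idx])
                break
            except (DataError, ZeroDivisionError):
                if attempt == max_retries:
                    raise DataError(
                        f"statistic undefined on {max_retries} consecutive resamples"
                    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    if return_samples:
        return float(lo), float(hi), stats
    return float(lo), float(hi)


def evaluate(
    data: Sequence[LabelledScore],
    n_boot: int = 1000,
    seed: int | None = None,
    ci_statistic: str = "auroc",
) -> EvalReport:
    """Full evaluation: AUROC, AUBPRC, ROC-optimal threshold and its metrics."""
    t = optimal_threshold(data)
    m = threshold_metrics(data, t)
    stat_fn = {"auroc": auroc, "aubprc": balanced_pr, "t_optimal": optimal_threshold}[ci_statistic]
    lo, hi = bootstrap_ci(stat_fn, data, n_boot=n_boot, seed=seed)
    return EvalReport(
        auroc=auroc(data),
        aubprc=balanced_pr(data),
        t_optimal=t,
        ci_low=lo,
        ci_high=hi,
        ci_statistic=ci_statistic,
        n_boot=n_boot,
        seed=seed,
        **m,
    )


def classify_by_sd(
    scores: dict,
    reference: Sequence[float],
    k: float,
    direction: str = "two_sided",
) -> dict:
    """Flag scores lying k reference-SDs beyond the reference mean.

    The reference is typically the synonymous-variant score distribution
    of a multiplexed assay; ``direction`` selects the tail(s) considered
    (``above``, ``below`` or ``two_sided``).  Returns variant -> bool.
    """
    ref = np.asarray(list(reference), dtype=float)
    if ref.size < 2:
        raise DataError("reference needs >= 2 values")
    mu, sd = ref.mean(), ref.std(ddof=1)
    if sd == 0:
        raise DataError("zero-SD reference")
    if direction not in ("above", "below", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    out = {}
    for key, score in scores.items():
        z = (score - mu) / sd
        if direction == "above":
            out[key] = z > k
        elif direction == "below":
            out[key] = z < -k
        else:
            out[key] = abs(z) > k
    return out


def set_relationship(a, b) -> str:
    """Overlap class of two variant sets on (position, wt, mut) triples.

    ``identical`` (A = B), ``subset`` (strict containment either way),
    ``distinct`` (no overlap) or ``intersect`` (partial overlap).
    """
    ta, tb = a.triples(), b.triples()
    if ta == tb:
        return "identical"
    if ta < tb or tb < ta:
        return "subset"
    if not ta & tb:
        return "distinct"
    return "intersect"
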