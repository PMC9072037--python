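"""Ranking metrics: AUC, RelaImpr, Hits@10, MeanRank, MRR.

AUC is pooled over all (case, element) samples; Hits@10, MeanRank and MRR
are computed per case by ranking the full element vocabulary by predicted
score and averaged over cases.  MeanRank uses a piecewise rank-penalty:
with y = |true ∩ top-10|, s = |true| and i the 1-based rank of the deepest
true element found in the top 10, the per-case score is y/s when i < 5,
(y + i − 3)/s when 5 ≤ i ≤ 10, and (11 − s)/s when no true element is in
the top 10.  MRR is the reciprocal of MeanRank within a run; across runs
each metric is averaged independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

TOP_K = 10


def auc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    """Probability that a random positive outranks a random negative.

    Rank-sum (Mann-Whitney) computation; tied scores receive half credit.
    Raises ``ValueError`` when only one class is present.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same shape")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both a positive and a negative sample")
    ranks = rankdata(s)  # average ranks handle ties with 0.5 credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rela_impr(auc_new: float, auc_base: float) -> float:
    """Relative AUC improvement over a baseline, in percent.

    Measured above the 0.5 random-ranking floor:
    ((AUC_new − 0.5) / (AUC_base − 0.5) − 1) × 100.
    """
    if auc_base == 0.5:
        raise ValueError("RelaImpr is undefined for a baseline AUC of exactly 0.5")
    return ((auc_new - 0.5) / (auc_base - 0.5) - 1.0) * 100.0


def hits_at_10(true_elements: Iterable, ranked_elements: Sequence) -> float:
    """Fraction of a case's true elements appearing in the top 10."""
    true_set = set(true_elements)
    if not true_set:
        raise ValueError("true element set must be non-empty")
    top = set(ranked_elements[:TOP_K])
    return len(true_set & top) / len(true_set)


def mean_rank_score(true_elements: Iterable, ranked_elements: Sequence) -> float:
    """Piecewise per-case rank penalty (see module docstring); smaller is better."""
    true_set = set(true_elements)
    if not true_set:
        raise ValueError("true element set must be non-empty")
    s = len(true_set)
    top = list(ranked_elements[:TOP_K])
    hit_ranks = [r + 1 for r, e in enumerate(top) if e in true_set]
    y = len(hit_ranks)
    if y == 0:
        return (TOP_K + 1 - s) / s
    i = max(hit_ranks)  # deepest true element found in the top 10
    if i < 5:
        return y / s
    return (y + i - 3) / s


def mrr_from_mean_rank(mean_rank: float) -> float:
    """Reciprocal of MeanRank (single-run identity)."""
    return 1.0 / mean_rank


@dataclass
class MetricsReport:
    """Metrics for one evaluation run, or the average of several runs.

    Within a single run ``mrr == 1 / mean_rank`` exactly; averaged reports
    average each metric independently across runs, so reciprocity need not
    hold at the mean level.
    """

    auc: float
    hits_at_10: float
    mean_rank: float
    mrr: float
    n_runs: int = 1
    per_run: dict[str, list[float]] | None = field(default=None, repr=False)
    rela_impr: float | None = None

    @classmethod
    def from_runs(cls, runs: Sequence["MetricsReport"]) -> "MetricsReport":
        if not runs:
            raise ValueError("no runs to average")
        per_run = {
            name: [getattr(r, name) for r in runs]
            for name in ("auc", "hits_at_10", "mean_rank", "mrr")
        }
        return cls(
            auc=float(np.mean(per_run["auc"])),
            hits_at_10=float(np.mean(per_run["hits_at_10"])),
            mean_rank=float(np.mean(per_run["mean_rank"])),
            mrr=float(np.mean(per_run["mrr"])),
            n_runs=len(runs),
            per_run=per_run,
        )

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "hits_at_10": self.hits_at_10,
            "mean_rank": self.mean_rank,
            "mrr": self.mrr,
            "n_runs": self.n_runs,
        }
        if self.rela_impr is not None:
            out["rela_impr"] = self.rela_impr
        if self.per_run is not None:
            out["per_run"] = self.per_run
        return out

    def summary_table(self) -> str:
        """Plain-text one-row table mirroring the published column layout."""
        header = "Hits@10\tMeanRank\tMRR\tAUC"
        row = f"{self.hits_at_10:.4f}\t{self.mean_rank:.4f}\t{self.mrr:.4f}\t{self.auc:.4f}"
        if self.rela_impr is not None:
            header += "\tRelaImpr"
            row += f"\t{self.rela_impr:+.3f}%"
        return header + "\n" + row


def rank_elements(scores: np.ndarray, element_ids: np.ndarray) -> np.ndarray:
    """Order element ids by descending score; ties broken by ascending id."""
    order = np.lexsort((element_ids, -scores))
    return element_ids[order]


def evaluate_scores(
    case_ids: Sequence,
    element_ids: np.ndarray,
    labels: np.ndarray,
    scores: np.ndarray,
) -> MetricsReport:
    """Metrics from flat per-sample arrays covering >= 2 cases.

    Samples are grouped by case id; every case is ranked over its own
    candidate list.  Cases without candidates or without any true element
    are skipped with a warning.
    """
    case_ids = np.asarray(case_ids)
    element_ids = np.asarray(element_ids)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pooled_auc = auc(labels, scores)
    hits, ranks = [], []
    for cid in np.unique(case_ids):
        m = case_ids == cid
        true_set = set(element_ids[m][labels[m] == 1].tolist())
        if not true_set:
            warnings.warn(f"case {cid!r} has no true elements; skipped", stacklevel=2)
            continue
        ranked = rank_elements(scores[m], element_ids[m])
        hits.append(hits_at_10(true_set, ranked.tolist()))
        ranks.append(mean_rank_score(true_set, ranked.tolist()))
    if not hits:
        raise ValueError("no rankable cases")
    mean_rank = float(np.mean(ranks))
    return MetricsReport(
        auc=pooled_auc,
        hits_at_10=float(np.mean(hits)),
        mean_rank=mean_rank,
        mrr=mrr_from_mean_rank(mean_rank),
    )
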