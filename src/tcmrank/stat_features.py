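"""Hand-crafted co-occurrence statistics between symptoms and elements.

For a symptom token ``zz`` (in one of the four fields) and a syndrome
element ``zs``, with case-level co-occurrence count ``N(zz, zs)``:

* confidence  F1 = N / T_zz   (fraction of zz-cases that carry zs)
* confidence  F2 = N / T_zs   (fraction of zs-cases that carry zz)
* lift        L  = F2 / (T_zs / T_total)  -- 1 under independence
* TF-IDF      TF = N / S_zz,  IDF = log(Y_zz / (H_zs + 1))

where T_zz / T_zs count cases containing the token / element, S_zz is the
token's total co-occurrence mass across all elements, Y_zz the number of
distinct tokens observed in the field, and H_zs the number of *other*
elements co-occurring with zs in at least one case.  All counts are
case-level (a case contributes at most 1 to any N) and are computed on the
training split only, per field independently.

Per-case aggregation follows the published convention: per statistic a sum
and an average over all contributing tokens of the four fields, plus a
length-10 "padding" vector -- the first 7 engraving values (-1-filled,
truncated beyond 7) followed by the tongue, moss and pulse field averages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import FIELDS, MedicalCase, Vocabulary

STAT_NAMES = ("F1", "F2", "L", "TFIDF")

ENGRAVING_SLOTS = 7
PAD_FILL = -1.0


@dataclass
class CooccurrenceStats:
    """All count tables backing the co-occurrence statistics.

    Arrays are indexed by vocabulary ids (row/column 0 is the reserved
    padding id and stays zero).
    """

    vocab: Vocabulary
    t_total: int
    t_element: np.ndarray                    # (E+1,) cases containing each element
    h_element: np.ndarray                    # (E+1,) distinct co-occurring other elements
    n_co: dict[str, np.ndarray]              # field -> (V_f+1, E+1) co-occurrence counts
    t_token: dict[str, np.ndarray]           # field -> (V_f+1,) cases containing token
    y_tokens: dict[str, int] = dc_field(default_factory=dict)  # distinct observed tokens

    @property
    def s_token(self) -> dict[str, np.ndarray]:
        """Total co-occurrence mass of each token across all elements."""
        return {f: self.n_co[f].sum(axis=1) for f in FIELDS}


def compute_stats(train_cases: Sequence[MedicalCase], vocab: Vocabulary) -> CooccurrenceStats:
    """Count case-level co-occurrences on the training split.

    A case contributes at most one count to any (token, element) cell
    regardless of how its tokens repeat; tokens unknown to the vocabulary
    (id 0) are ignored.
    """
    if not train_cases:
        raise ValueError("cannot compute statistics on an empty training corpus")
    n_elem = vocab.n_elements
    t_element = np.zeros(n_elem + 1, dtype=np.int64)
    elem_co = np.zeros((n_elem + 1, n_elem + 1), dtype=bool)
    n_co = {f: np.zeros((vocab.field_size(f) + 1, n_elem + 1), dtype=np.int64) for f in FIELDS}
    t_token = {f: np.zeros(vocab.field_size(f) + 1, dtype=np.int64) for f in FIELDS}
    for case in train_cases:
        eids = np.array(
            sorted({vocab.element_map[e] for e in case.syndrome_elements if e in vocab.element_map}),
            dtype=np.int64,
        )
        if eids.size:
            t_element[eids] += 1
            elem_co[np.ix_(eids, eids)] = True
        for f in FIELDS:
            tids = np.array(
                sorted({i for i in vocab.encode_field(f, case.field_tokens(f)) if i > 0}),
                dtype=np.int64,
            )
            if tids.size:
                t_token[f][tids] += 1
                if eids.size:
                    n_co[f][np.ix_(tids, eids)] += 1
    h_element = (elem_co & ~np.eye(n_elem + 1, dtype=bool)).sum(axis=1)
    h_element[t_element == 0] = 0
    y_tokens = {f: int((t_token[f] > 0).sum()) for f in FIELDS}
    return CooccurrenceStats(
        vocab=vocab,
        t_total=len(train_cases),
        t_element=t_element,
        h_element=h_element,
        n_co=n_co,
        t_token=t_token,
        y_tokens=y_tokens,
    )


def _resolve(stats: CooccurrenceStats, field_name: str, zz: str | int, zs: str | int) -> tuple[int, int]:
    if field_name not in FIELDS:
        raise KeyError(field_name)
    tid = zz if isinstance(zz, int) else stats.vocab.field_maps[field_name].get(zz, 0)
    eid = zs if isinstance(zs, int) else stats.vocab.encode_element(zs)
    return tid, eid


def _zero_denominator(what: str) -> float:
    warnings.warn(f"zero denominator in {what}; returning 0", stacklevel=3)
    return 0.0


def confidence_f1(stats: CooccurrenceStats, field_name: str, zz: str | int, zs: str | int) -> float:
    """Confidence of zz -> zs: N(zz, zs) / T_zz."""
    tid, eid = _resolve(stats, field_name, zz, zs)
    t = stats.t_token[field_name][tid]
    if t == 0:
        return _zero_denominator("F1")
    return float(stats.n_co[field_name][tid, eid] / t)


def confidence_f2(stats: CooccurrenceStats, field_name: str, zz: str | int, zs: str | int) -> float:
    """Confidence of zs -> zz: N(zz, zs) / T_zs."""
    tid, eid = _resolve(stats, field_name, zz, zs)
    t = stats.t_element[eid]
    if t == 0:
        return _zero_denominator("F2")
    return float(stats.n_co[field_name][tid, eid] / t)


def lift(
    stats: CooccurrenceStats, field_name: str, zz: str | int, zs: str | int, scale: float = 1.0
) -> float:
    """Promotion degree: F2 / (element marginal frequency), times ``scale``.

    Equals ``scale`` exactly when token and element are independent.
    ``scale`` defaults to 1, which reproduces the published worked-example
    values (F2 / L is constant across a sample's tokens at the element's
    corpus frequency).
    """
    _, eid = _resolve(stats, field_name, zz, zs)
    if stats.t_total == 0 or stats.t_element[eid] == 0:
        return _zero_denominator("lift")
    marginal = stats.t_element[eid] / stats.t_total
    return confidence_f2(stats, field_name, zz, zs) / marginal * scale


def tfidf(
    stats: CooccurrenceStats,
    field_name: str,
    zz: str | int,
    zs: str | int,
    log_base: float | None = None,
) -> float:
    """TF-IDF association: (N / S_zz) * log(Y_zz / (H_zs + 1)).

    Natural log by default; ``log_base`` switches the base.  S_zz = 0
    (token never co-occurs with any element) yields 0 with a warning.
    """
    tid, eid = _resolve(stats, field_name, zz, zs)
    s = stats.n_co[field_name][tid].sum()
    if s == 0:
        return _zero_denominator("TF-IDF")
    tf = stats.n_co[field_name][tid, eid] / s
    idf = math.log(stats.y_tokens[field_name] / (stats.h_element[eid] + 1))
    if log_base is not None:
        idf /= math.log(log_base)
    return float(tf * idf)


_STAT_FUNCS = {
    "F1": confidence_f1,
    "F2": confidence_f2,
    "L": lift,
    "TFIDF": tfidf,
}


@dataclass
class AggregatedFeatures:
    """Sum / average / padding aggregation of one statistic over one case."""

    sum: float
    average: float
    padding: np.ndarray  # length 10

    def __post_init__(self) -> None:
        self.padding = np.asarray(self.padding, dtype=float)
        if self.padding.shape != (ENGRAVING_SLOTS + 3,):
            raise ValueError("padding vector must have length 10")


def aggregate_case_features(
    per_field_values: Mapping[str, Sequence[float]],
) -> AggregatedFeatures:
    """Aggregate per-token statistic values of one case into fixed features.

    ``per_field_values`` maps each of the four fields to the statistic
    values of that field's tokens.  The padding layout keeps the first 7
    engraving values (-1 when fewer, truncated when more) and one average
    per short field; an absent short field contributes 0 to its slot.
    """
    values = [v for f in FIELDS for v in per_field_values.get(f, ())]
    if not values:
        raise ValueError("no statistic values to aggregate")
    total = float(np.sum(values))
    average = total / len(values)
    eng = list(per_field_values.get("engraving_symptoms", ()))[:ENGRAVING_SLOTS]
    pad = eng + [PAD_FILL] * (ENGRAVING_SLOTS - len(eng))
    for f in ("tongue", "moss", "pulse"):
        vals = per_field_values.get(f, ())
        pad.append(float(np.mean(vals)) if len(vals) else 0.0)
    return AggregatedFeatures(sum=total, average=average, padding=np.array(pad))


@dataclass
class FeatureConfig:
    """Which statistics and aggregations enter a sample's feature vector.

    The fixed order is [sum, average] per included statistic followed by
    the 10-slot padding vector per included statistic (when
    ``include_padding``), giving 2*k + 10*k entries for k statistics.
    """

    statistics: tuple[str, ...] = STAT_NAMES
    include_padding: bool = True
    lift_scale: float = 1.0

    @property
    def width(self) -> int:
        k = len(self.statistics)
        return 2 * k + (10 * k if self.include_padding else 0)


def case_statistic_values(
    case: MedicalCase, element: str | int, stats: CooccurrenceStats, stat: str,
    lift_scale: float = 1.0,
) -> dict[str, list[float]]:
    """Per-field lists of one statistic for every token of a case."""
    func = _STAT_FUNCS[stat]
    kwargs = {"scale": lift_scale} if stat == "L" else {}
    out: dict[str, list[float]] = {}
    for f in FIELDS:
        out[f] = [func(stats, f, tok, element, **kwargs) for tok in case.field_tokens(f)]
    return out


def case_feature_vector(
    case: MedicalCase, element: str | int, stats: CooccurrenceStats, config: FeatureConfig
) -> np.ndarray:
    """Assemble a case-element statistical feature vector in the fixed order."""
    parts: list[np.ndarray] = []
    aggs = []
    for stat in config.statistics:
        vals = case_statistic_values(case, element, stats, stat, config.lift_scale)
        aggs.append(aggregate_case_features(vals))
    for a in aggs:
        parts.append(np.array([a.sum, a.average]))
    if config.include_padding:
        for a in aggs:
            parts.append(a.padding)
    return np.concatenate(parts)


def stats_to_frame(stats: CooccurrenceStats) -> pd.DataFrame:
    """Long-format table of every observed (field, token, element) pair."""
    rows = []
    inv_elem = {i: t for t, i in stats.vocab.element_map.items()}
    for f in FIELDS:
        inv_tok = {i: t for t, i in stats.vocab.field_maps[f].items()}
        tok_idx, elem_idx = np.nonzero(stats.n_co[f])
        for tid, eid in zip(tok_idx, elem_idx):
            rows.append(
                {
                    "field": f,
                    "symptom_token": inv_tok[tid],
                    "element_token": inv_elem[eid],
                    "N": int(stats.n_co[f][tid, eid]),
                    "T_zz": int(stats.t_token[f][tid]),
                    "T_zs": int(stats.t_element[eid]),
                    "F1": confidence_f1(stats, f, int(tid), int(eid)),
                    "F2": confidence_f2(stats, f, int(tid), int(eid)),
                    "L": lift(stats, f, int(tid), int(eid)),
                    "TFIDF": tfidf(stats, f, int(tid), int(eid)),
                }
            )
    return pd.DataFrame(rows)


def write_stats(stats: CooccurrenceStats, path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)
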