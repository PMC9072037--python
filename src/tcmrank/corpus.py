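"""Domain types and corpus plumbing for syndrome-element ranking.

A medical case carries four observed symptom fields -- the engraving
(chief) symptoms, tongue body, tongue coating ("moss"), and pulse -- each a
short list of phrase-level tokens, plus the set of ground-truth syndrome
elements assigned by the physician.  Ranking models score every
(case, candidate element) pair, so the labeled-sample construction is a
full cross product of cases with the element vocabulary: a pair is positive
iff the element belongs to the case's true set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: The four observed symptom fields, in canonical order.
FIELDS = ("engraving_symptoms", "tongue", "moss", "pulse")

#: Reserved integer id for padding / unknown tokens in every vocabulary map.
PAD_ID = 0


@dataclass
class MedicalCase:
    """One patient record: four symptom fields plus true syndrome elements.

    Tokens are whole phrases ("abdominal distension"); no sub-word
    splitting is performed anywhere in the package.
    """

    case_id: str
    engraving_symptoms: list[str]
    tongue: list[str]
    moss: list[str]
    pulse: list[str]
    syndrome_elements: set[str]

    def __post_init__(self) -> None:
        if not self.engraving_symptoms:
            raise ValueError(f"case {self.case_id!r}: engraving_symptoms must be non-empty")
        if not self.syndrome_elements:
            raise ValueError(f"case {self.case_id!r}: syndrome_elements must be non-empty")
        self.syndrome_elements = set(self.syndrome_elements)
        for f in FIELDS:
            toks = getattr(self, f)
            if len(toks) != len(set(toks)):
                raise ValueError(f"case {self.case_id!r}: duplicate tokens in field {f!r}")

    def field_tokens(self, field_name: str) -> list[str]:
        if field_name not in FIELDS:
            raise KeyError(field_name)
        return getattr(self, field_name)


@dataclass
class Vocabulary:
    """Per-field token->id maps; id 0 is reserved for padding/unknown.

    Real tokens get dense positive ids assigned in lexicographic token
    order, which makes vocabulary construction independent of corpus order.
    """

    field_maps: dict[str, dict[str, int]]
    element_map: dict[str, int]

    def field_size(self, field_name: str) -> int:
        return len(self.field_maps[field_name])

    @property
    def n_elements(self) -> int:
        return len(self.element_map)

    @property
    def element_tokens(self) -> list[str]:
        """Element tokens ordered by id."""
        return sorted(self.element_map, key=self.element_map.get)

    def encode_field(self, field_name: str, tokens: Iterable[str]) -> list[int]:
        """Map tokens to ids; unknown tokens map to the reserved id 0."""
        m = self.field_maps[field_name]
        return [m.get(t, PAD_ID) for t in tokens]

    def encode_element(self, token: str) -> int:
        try:
            return self.element_map[token]
        except KeyError:
            raise KeyError(f"element token {token!r} not in vocabulary") from None

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write all maps as a three-column (field, token, id) table."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("field\ttoken\tid\n")
            for f in FIELDS:
                for tok, i in sorted(self.field_maps[f].items(), key=lambda kv: kv[1]):
                    fh.write(f"{f}\t{tok}\t{i}\n")
            for tok, i in sorted(self.element_map.items(), key=lambda kv: kv[1]):
                fh.write(f"syndrome_elements\t{tok}\t{i}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        field_maps: dict[str, dict[str, int]] = {f: {} for f in FIELDS}
        element_map: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("field\t"):
                raise ValueError("not a vocabulary TSV (missing header)")
            for line in fh:
                f, tok, i = line.rstrip("\n").split("\t")
                if f == "syndrome_elements":
                    element_map[tok] = int(i)
                else:
                    field_maps[f][tok] = int(i)
        return cls(field_maps=field_maps, element_map=element_map)


@dataclass
class LabeledSample:
    """One (case, candidate element) pair.

    ``label`` is 1 iff the element is one of the case's true syndrome
    elements.  ``field_id_lists`` holds the integer-encoded symptom fields;
    ``extra_features`` optionally carries hand-crafted statistical features
    (and/or a fused match-network output) as a fixed-length vector.
    """

    case_id: str
    element_id: int
    label: int
    field_id_lists: dict[str, list[int]]
    extra_features: np.ndarray | None = field(default=None, repr=False)


def build_vocabulary(cases: Sequence[MedicalCase]) -> Vocabulary:
    """Build per-field vocabularies over a corpus.

    Tokens are sorted lexicographically before id assignment, so the result
    is invariant to corpus order and idempotent under union.
    """
    if not cases:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    field_maps: dict[str, dict[str, int]] = {}
    for f in FIELDS:
        toks = sorted({t for c in cases for t in c.field_tokens(f)})
        field_maps[f] = {t: i + 1 for i, t in enumerate(toks)}
    elems = sorted({e for c in cases for e in c.syndrome_elements})
    element_map = {t: i + 1 for i, t in enumerate(elems)}
    return Vocabulary(field_maps=field_maps, element_map=element_map)


def build_samples(
    cases: Sequence[MedicalCase],
    vocab: Vocabulary,
    negative_policy: str = "all",
    n_negatives: int = 10,
    seed: int | None = None,
) -> list[LabeledSample]:
    """Construct labeled (case, element) samples by cross-product labeling.

    Under policy ``"all"`` every case is paired with every element in the
    vocabulary, giving exactly ``len(cases) * vocab.n_elements`` samples
    (e.g. 130,000 cases x 62 elements = 8.06 M training samples at the full
    corpus scale).  Policy ``"sampled"`` keeps all positives plus
    ``n_negatives`` negatives drawn per case without replacement -- a speed
    knob for desk-scale experiments.

    Raises ``KeyError`` if a case's true element is missing from the
    vocabulary (unknown *symptoms* are tolerated and encoded as id 0).
    """
    if negative_policy not in ("all", "sampled"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    rng = np.random.default_rng(seed)
    elem_ids = np.array([vocab.element_map[t] for t in vocab.element_tokens])
    samples: list[LabeledSample] = []
    for case in cases:
        pos_ids = {vocab.encode_element(e) for e in case.syndrome_elements}
        encoded = {f: vocab.encode_field(f, case.field_tokens(f)) for f in FIELDS}
        if negative_policy == "all":
            cand = elem_ids
        else:
            neg_pool = np.array([i for i in elem_ids if i not in pos_ids])
            k = min(n_negatives, len(neg_pool))
            negs = rng.choice(neg_pool, size=k, replace=False)
            cand = np.concatenate([sorted(pos_ids), np.sort(negs)])
        for eid in cand:
            samples.append(
                LabeledSample(
                    case_id=case.case_id,
                    element_id=int(eid),
                    label=int(eid in pos_ids),
                    field_id_lists=encoded,
                )
            )
    return samples


def split_cases(
    cases: Sequence[MedicalCase], test_fraction: float, seed: int
) -> tuple[list[MedicalCase], list[MedicalCase]]:
    """Seeded case-level train/test split (no case appears in both halves).

    Splitting at the case level (never the sample level) prevents label
    leakage: all 62 samples of one case land on the same side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_test = int(round(len(cases) * test_fraction))
    test_idx = set(order[:n_test].tolist())
    train = [c for i, c in enumerate(cases) if i not in test_idx]
    test = [c for i, c in enumerate(cases) if i in test_idx]
    return train, test


# -- record I/O (JSONL, one case per line) ----------------------------------

def write_cases(cases: Iterable[MedicalCase], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in cases:
            rec = {
                "case_id": c.case_id,
                "engraving_symptoms": c.engraving_symptoms,
                "tongue": c.tongue,
                "moss": c.moss,
                "pulse": c.pulse,
                "syndrome_elements": sorted(c.syndrome_elements),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_cases(path: str | Path) -> list[MedicalCase]:
    """Read a JSONL corpus; malformed records raise with their line number."""
    cases: list[MedicalCase] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                cases.append(
                    MedicalCase(
                        case_id=str(rec["case_id"]),
                        engraving_symptoms=list(rec["engraving_symptoms"]),
                        tongue=list(rec["tongue"]),
                        moss=list(rec["moss"]),
                        pulse=list(rec["pulse"]),
                        syndrome_elements=set(rec["syndrome_elements"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
    if not cases:
        warnings.warn(f"{path}: empty corpus", stacklevel=2)
    return cases
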