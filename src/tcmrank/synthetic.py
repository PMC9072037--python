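"""Synthetic medical-case corpora with planted symptom-element structure.

The real laboratory corpus (hundreds of thousands of physician-annotated
records) is private, so experiments run on generated corpora that emulate
its shape: ~62 syndrome elements, 3-7 engraving symptoms per case drawn
from a few hundred phrases, and 1-2 tokens each for tongue / moss / pulse.
Each syndrome element owns a small "characteristic" token set per field;
case tokens are drawn from a mixture of the case's elements' characteristic
distributions and uniform noise, which plants exactly the kind of
co-occurrence signal the statistical features (confidence, lift, TF-IDF)
and the learned models are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .corpus import FIELDS, MedicalCase


@dataclass
class GeneratorConfig:
    """Sampling parameters for one synthetic corpus.

    ``affinity_strength`` is the probability mass an element's per-field
    token distribution places on its own characteristic set;
    ``noise_rate`` is the per-token probability of ignoring the elements
    entirely and drawing uniformly from the field vocabulary.  With
    ``affinity_strength=0`` or ``noise_rate=1`` symptoms are independent of
    elements and every association statistic degenerates to its
    independence value.
    """

    n_cases: int = 5000
    n_elements: int = 62
    field_vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "engraving_symptoms": 500,
            "tongue": 20,
            "moss": 20,
            "pulse": 25,
        }
    )
    elements_per_case: tuple[int, int] = (1, 4)
    tokens_per_case: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "engraving_symptoms": (3, 7),
            "tongue": (1, 2),
            "moss": (1, 2),
            "pulse": (1, 2),
        }
    )
    characteristic_set_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "engraving_symptoms": 6,
            "tongue": 2,
            "moss": 2,
            "pulse": 2,
        }
    )
    affinity_strength: float = 0.8
    noise_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_elements <= 0:
            raise ValueError("n_cases and n_elements must be positive")
        if not 0.0 <= self.affinity_strength <= 1.0:
            raise ValueError("affinity_strength must be in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        lo, hi = self.elements_per_case
        if not 1 <= lo <= hi <= self.n_elements:
            raise ValueError("invalid elements_per_case range")
        for f in FIELDS:
            lo, hi = self.tokens_per_case[f]
            vsize = self.field_vocab_sizes[f]
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid tokens_per_case range for {f}")
            if hi > vsize:
                raise ValueError(
                    f"field {f}: vocabulary size {vsize} smaller than "
                    f"tokens-per-case upper bound {hi}"
                )
            if self.characteristic_set_sizes[f] > vsize:
                raise ValueError(f"field {f}: characteristic set larger than vocabulary")


@dataclass
class PlantedTruth:
    """Ground truth of the generator: which tokens characterize which element."""

    characteristic_sets: dict[str, dict[str, list[str]]]  # element -> field -> tokens
    config: GeneratorConfig

    def is_planted(self, field_name: str, token: str, element: str) -> bool:
        return token in self.characteristic_sets[element][field_name]

    def to_dict(self) -> dict:
        return {
            "characteristic_sets": self.characteristic_sets,
            "config": asdict(self.config),
        }


def _token_name(field_name: str, idx: int) -> str:
    prefix = {"engraving_symptoms": "sym", "tongue": "tong", "moss": "moss", "pulse": "puls"}
    return f"{prefix[field_name]}_{idx:03d}"


def _element_name(idx: int) -> str:
    return f"elem_{idx:02d}"


def generate_corpus(config: GeneratorConfig) -> tuple[list[MedicalCase], PlantedTruth]:
    """Sample a corpus of medical cases with planted associations.

    Per case: draw an element count uniformly over ``elements_per_case``,
    then that many distinct elements uniformly.  Per field, draw the target
    token count uniformly over its range, then fill the field one token at
    a time: with probability ``noise_rate`` uniform over the field
    vocabulary, otherwise via a uniformly chosen case element whose
    distribution puts ``affinity_strength`` mass (uniform) on its
    characteristic set and the rest uniform on the whole vocabulary.
    Duplicate draws are rejected so field lengths land exactly in range.
    Fully deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    elements = [_element_name(i) for i in range(config.n_elements)]
    vocab = {f: [_token_name(f, i) for i in range(config.field_vocab_sizes[f])] for f in FIELDS}

    # Characteristic sets: partition the vocabulary when it is large enough
    # (disjoint sets), otherwise sample per element with replacement across
    # elements (overlap allowed) but without replacement within an element.
    char_sets: dict[str, dict[str, list[str]]] = {e: {} for e in elements}
    for f in FIELDS:
        size = config.characteristic_set_sizes[f]
        vsize = config.field_vocab_sizes[f]
        if size * config.n_elements <= vsize:
            perm = rng.permutation(vsize)
            for i, e in enumerate(elements):
                idx = perm[i * size : (i + 1) * size]
                char_sets[e][f] = [vocab[f][j] for j in sorted(idx)]
        else:
            for e in elements:
                idx = rng.choice(vsize, size=size, replace=False)
                char_sets[e][f] = [vocab[f][j] for j in sorted(idx)]

    cases: list[MedicalCase] = []
    elem_lo, elem_hi = config.elements_per_case
    for ci in range(config.n_cases):
        n_elem = int(rng.integers(elem_lo, elem_hi + 1))
        case_elems = [elements[j] for j in rng.choice(config.n_elements, n_elem, replace=False)]
        fields_out: dict[str, list[str]] = {}
        for f in FIELDS:
            lo, hi = config.tokens_per_case[f]
            target = int(rng.integers(lo, hi + 1))
            toks: list[str] = []
            seen: set[str] = set()
            attempts = 0
            while len(toks) < target:
                attempts += 1
                if attempts > 200 * target:
                    # pathological configs only; fill deterministically
                    for t in vocab[f]:
                        if t not in seen:
                            toks.append(t)
                            seen.add(t)
                        if len(toks) == target:
                            break
                    break
                if rng.random() < config.noise_rate:
                    t = vocab[f][int(rng.integers(config.field_vocab_sizes[f]))]
                else:
                    e = case_elems[int(rng.integers(n_elem))]
                    if rng.random() < config.affinity_strength:
                        cs = char_sets[e][f]
                        t = cs[int(rng.integers(len(cs)))]
                    else:
                        t = vocab[f][int(rng.integers(config.field_vocab_sizes[f]))]
                if t not in seen:
                    toks.append(t)
                    seen.add(t)
            fields_out[f] = toks
        cases.append(
            MedicalCase(
                case_id=f"case_{ci:06d}",
                engraving_symptoms=fields_out["engraving_symptoms"],
                tongue=fields_out["tongue"],
                moss=fields_out["moss"],
                pulse=fields_out["pulse"],
                syndrome_elements=set(case_elems),
            )
        )
    return cases, PlantedTruth(characteristic_sets=char_sets, config=config)


def table3_fixture() -> dict[str, dict[str, list[float]]]:
    """Published per-field statistic values for one worked example.

    One sample (five engraving symptoms, one tongue token, two moss tokens,
    one pulse token, all co-occurring with a single syndrome element) with
    its per-token confidence (F1, F2), lift (L) and TF-IDF values.  Used as
    the input of aggregation tests: summing / averaging / padding these
    nine values per statistic must reproduce the published feature rows.
    """
    return {
        "F1": {
            "engraving_symptoms": [0.0821, 0.0698, 0.0850, 0.0855, 0.0575],
            "tongue": [0.0653],
            "moss": [0.0840, 0.1049],
            "pulse": [0.0985],
        },
        "F2": {
            "engraving_symptoms": [0.3343, 0.2703, 0.3099, 0.3379, 0.2497],
            "tongue": [0.2805],
            "moss": [0.3415, 0.4384],
            "pulse": [0.3960],
        },
        "L": {
            "engraving_symptoms": [1.0938, 0.8844, 1.0139, 1.1056, 0.8170],
            "tongue": [0.9178],
            "moss": [1.1172, 1.4345],
            "pulse": [1.2958],
        },
        "TFIDF": {
            "engraving_symptoms": [0.1823, 0.1550, 0.1888, 0.1900, 0.1277],
            "tongue": [0.0910],
            "moss": [0.0943, 0.1179],
            "pulse": [0.1366],
        },
    }
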