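"""MMOE main network, two-tower match network, mimic mechanism, and losses.

The main network scores one (case, candidate element) pair: each of the
five fields (four symptom fields plus the candidate element) is embedded
by mean-pooling its token embeddings, the concatenated vector E feeds a
multi-gate mixture-of-experts (shared expert MLPs combined per task by a
softmax gate) and a per-task tower ending in a sigmoid.

The auxiliary match network re-uses the same embeddings.  In *concat* head
mode the symptom-side and element-side vectors are concatenated and pushed
through an MLP to a matching probability; in *cosine* head mode each side
has its own tower ending in L2 normalization, and the match score is a
scaled cosine of the two unit vectors.  Fusion modes couple the two
networks: an auxiliary BCE loss on the match output, the match probability
appended to the main input features (gradient-detached by default), and a
mimic mechanism in which learned augmentation vectors a_u / a_v are
concatenated to each tower's input and trained (on positive pairs only,
with the opposing tower stop-gradiented) to approximate the opposing
tower's normalized output.

Everything is plain NumPy.  Gradients are analytic, written by hand, and
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import expit as sigmoid

from .corpus import FIELDS, LabeledSample, Vocabulary

FUSION_MODES = ("none", "auxiliary_loss", "match_as_feature", "mimic", "full")
_EPS_NORM = 1e-12


@dataclass
class ModelConfig:
    """Architecture and loss hyperparameters.

    Defaults follow the reference setting: 8 experts of two dense layers
    (256 then 128 rectified units), one 64-unit tower layer per task, a
    three-layer match tower (256/128/64), Adam-friendly truncated-normal
    initialization with std 0.05.  ``fusion`` selects how the match network
    couples to the main network; ``match_head`` is derived from the fusion
    mode when left ``None`` (concat for pure auxiliary-loss/feature modes,
    cosine whenever the mimic mechanism needs per-side unit vectors).
    """

    embedding_dim: int = 64
    n_experts: int = 8
    expert_layer_sizes: tuple[int, ...] = (256, 128)
    n_tasks: int = 1
    tower_layer_sizes: tuple[int, ...] = (64,)
    match_tower_sizes: tuple[int, ...] = (256, 128, 64)
    match_head: str | None = None
    fusion: str = "none"
    lambda1: float = 1.0
    lambda_u: float = 0.5
    lambda_v: float = 0.5
    init_std: float = 0.05
    stat_dim: int = 0
    detach_match_feature: bool = True
    per_element_augment: bool = False

    def __post_init__(self) -> None:
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.n_tasks < 1 or self.n_experts < 1:
            raise ValueError("n_tasks and n_experts must be >= 1")
        if min(self.lambda1, self.lambda_u, self.lambda_v) < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def resolved_head(self) -> str | None:
        if self.fusion == "none":
            return None
        if self.match_head is not None:
            return self.match_head
        return "concat" if self.fusion in ("auxiliary_loss", "match_as_feature") else "cosine"

    @property
    def uses_match_feature(self) -> bool:
        return self.fusion in ("match_as_feature", "full")

    @property
    def uses_mimic(self) -> bool:
        return self.fusion in ("mimic", "full")


@dataclass
class Batch:
    """Dense arrays for a set of samples (token ids 0-padded on the right)."""

    field_ids: dict[str, np.ndarray]      # field -> (N, L_f) int
    element_ids: np.ndarray               # (N,)
    labels: np.ndarray                    # (N,) float in {0, 1}
    extra: np.ndarray | None = None       # (N, stat_dim)
    case_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.element_ids)

    def take(self, idx: np.ndarray) -> "Batch":
        return Batch(
            field_ids={f: a[idx] for f, a in self.field_ids.items()},
            element_ids=self.element_ids[idx],
            labels=self.labels[idx],
            extra=None if self.extra is None else self.extra[idx],
            case_ids=None if self.case_ids is None else self.case_ids[idx],
        )


MAX_ENGRAVING_TOKENS = 7  # engraving symptom lists beyond 7 tokens are truncated


def batch_from_samples(samples: Sequence[LabeledSample]) -> Batch:
    """Pack samples into padded id matrices (one row per sample)."""
    if not samples:
        raise ValueError("empty sample collection")
    field_ids = {}
    for f in FIELDS:
        lists = [s.field_id_lists[f] for s in samples]
        if f == "engraving_symptoms":
            lists = [ids[:MAX_ENGRAVING_TOKENS] for ids in lists]
        width = max(1, max(len(ids) for ids in lists))
        arr = np.zeros((len(samples), width), dtype=np.int64)
        for i, ids in enumerate(lists):
            arr[i, : len(ids)] = ids
        field_ids[f] = arr
    extra = None
    if samples[0].extra_features is not None:
        extra = np.stack([np.asarray(s.extra_features, dtype=float) for s in samples])
    return Batch(
        field_ids=field_ids,
        element_ids=np.array([s.element_id for s in samples], dtype=np.int64),
        labels=np.array([s.label for s in samples], dtype=float),
        extra=extra,
        case_ids=np.array([s.case_id for s in samples]),
    )


# -- small numeric helpers ---------------------------------------------------

def _truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations (by redraw)."""
    out = rng.standard_normal(shape)
    for _ in range(6):
        bad = np.abs(out) > 2.0
        if not bad.any():
            break
        out[bad] = rng.standard_normal(int(bad.sum()))
    np.clip(out, -2.0, 2.0, out=out)
    return out * std


def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed stably from logits."""
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def bce(prob: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy from probabilities (clipped at ``eps``)."""
    p = np.clip(np.asarray(prob, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))


def l2_normalize(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unit vectors; zero rows are passed through with a warning."""
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    zero = norms[:, 0] < _EPS_NORM
    if zero.any():
        warnings.warn("zero vector fed to L2 normalization; left unnormalized", stacklevel=2)
    safe = np.where(zero[:, None], 1.0, norms)
    return h / safe, safe


def fuse_match_feature(
    E: np.ndarray, y_match: np.ndarray | None, extra: np.ndarray | None = None
) -> np.ndarray:
    """Concatenate the main input E with statistical features and the match output."""
    parts = [E]
    if extra is not None:
        parts.append(extra)
    if y_match is not None:
        parts.append(np.asarray(y_match, dtype=float).reshape(-1, 1))
    return np.concatenate(parts, axis=1)


def mimic_augment(
    symptom_embedding: np.ndarray,
    element_embedding: np.ndarray,
    a_u: np.ndarray,
    a_v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Append the augmentation vectors to each tower's input.

    ``a_u`` is a single global vector broadcast to the batch; ``a_v`` may be
    global ``(m,)`` or already gathered per sample ``(N, m)``.
    """
    n = symptom_embedding.shape[0]
    a_u = np.asarray(a_u, dtype=float)
    a_v = np.asarray(a_v, dtype=float)
    c_u = np.concatenate([symptom_embedding, np.broadcast_to(a_u, (n, a_u.shape[-1]))], axis=1)
    if a_v.ndim == 1:
        a_v = np.broadcast_to(a_v, (n, a_v.shape[-1]))
    if a_v.shape[0] != n:
        raise ValueError("a_v batch dimension mismatch")
    c_v = np.concatenate([element_embedding, a_v], axis=1)
    return c_u, c_v


def total_loss(
    labels: np.ndarray,
    y_main: np.ndarray,
    y_match: np.ndarray | None,
    a_u: np.ndarray | None,
    a_v: np.ndarray | None,
    p_u: np.ndarray | None,
    p_v: np.ndarray | None,
    config: ModelConfig,
) -> dict[str, float]:
    """Combined objective from predicted probabilities (reference form).

    Returns the components and their weighted sum:
    ``total = main + λ1·match + λu·mimic_u + λv·mimic_v`` where the mimic
    terms are positives-only squared distances between an augmentation
    vector and the opposing tower's unit output, normalized by batch size.
    With all three weights at zero the total equals the main cross-entropy
    exactly.  The training path computes the same quantities from logits.
    """
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("empty batch")
    out = {"main": bce(y_main, y), "match": 0.0, "mimic_u": 0.0, "mimic_v": 0.0}
    if y_match is not None:
        out["match"] = bce(y_match, y)
    n = y.size
    if a_u is not None and p_v is not None:
        diff = np.atleast_2d(a_u) - p_v
        out["mimic_u"] = float((y @ (diff**2).sum(axis=1)) / n)
    if a_v is not None and p_u is not None:
        diff = np.atleast_2d(a_v) - p_u
        out["mimic_v"] = float((y @ (diff**2).sum(axis=1)) / n)
    out["total"] = (
        out["main"]
        + config.lambda1 * out["match"]
        + config.lambda_u * out["mimic_u"]
        + config.lambda_v * out["mimic_v"]
    )
    return out


# -- the model ---------------------------------------------------------------

class MMOEMatchModel:
    """Parameter container plus forward / backward passes.

    Embedding tables are shared between the main and match networks (one
    embedding layer feeds both).  Row 0 of every table is the frozen
    padding/unknown row (all zeros, excluded from field means).
    """

    def __init__(
        self,
        config: ModelConfig,
        vocab_sizes: dict[str, int],
        n_elements: int,
        rng: np.random.Generator | int | None = 0,
    ):
        self.config = config
        self.vocab_sizes = dict(vocab_sizes)
        self.n_elements = n_elements
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng)

    # widths -----------------------------------------------------------------

    @property
    def d(self) -> int:
        return self.config.embedding_dim

    @property
    def input_width(self) -> int:
        w = 5 * self.d + self.config.stat_dim
        if self.config.uses_match_feature:
            w += 1
        return w

    @property
    def augment_dim(self) -> int:
        return self.config.match_tower_sizes[-1]

    # initialization ----------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg, p = self.config, self.params
        std = cfg.init_std

        def tn(*shape):
            return _truncated_normal(rng, shape, std)

        for f in FIELDS:
            table = tn(self.vocab_sizes[f] + 1, self.d)
            table[0] = 0.0
            p[f"emb_{f}"] = table
        table = tn(self.n_elements + 1, self.d)
        table[0] = 0.0
        p["emb_element"] = table

        in_dim = self.input_width
        for i in range(cfg.n_experts):
            prev = in_dim
            for l, size in enumerate(cfg.expert_layer_sizes):
                p[f"expert{i}_W{l}"] = tn(prev, size)
                p[f"expert{i}_b{l}"] = np.zeros(size)
                prev = size
        for k in range(cfg.n_tasks):
            p[f"gate{k}_W"] = tn(in_dim, cfg.n_experts)
            prev = cfg.expert_layer_sizes[-1]
            for l, size in enumerate(cfg.tower_layer_sizes):
                p[f"tower{k}_W{l}"] = tn(prev, size)
                p[f"tower{k}_b{l}"] = np.zeros(size)
                prev = size
            p[f"tower{k}_out_W"] = tn(prev)
            p[f"tower{k}_out_b"] = np.zeros(())

        head = cfg.resolved_head
        if head == "concat":
            prev = 5 * self.d
            for l, size in enumerate(cfg.match_tower_sizes):
                p[f"match_W{l}"] = tn(prev, size)
                p[f"match_b{l}"] = np.zeros(size)
                prev = size
            p["match_p"] = tn(prev)
            p["match_pb"] = np.zeros(())
        elif head == "cosine":
            m = self.augment_dim
            for side, width in (("u", 4 * self.d + m), ("v", self.d + m)):
                prev = width
                for l, size in enumerate(cfg.match_tower_sizes):
                    p[f"match_{side}_W{l}"] = tn(prev, size)
                    p[f"match_{side}_b{l}"] = np.zeros(size)
                    prev = size
            p["match_w"] = np.asarray(1.0)  # cosine temperature (learned)
            p["match_wb"] = np.zeros(())
            p["a_u"] = tn(m)
            if cfg.per_element_augment:
                p["a_v"] = tn(self.n_elements + 1, m)
            else:
                p["a_v"] = tn(m)

    # forward ------------------------------------------------------------------

    def _pool_field(self, f: str, ids: np.ndarray) -> tuple[np.ndarray, dict]:
        table = self.params[f"emb_{f}"]
        emb = table[ids]                              # (N, L, d)
        mask = (ids > 0).astype(float)                # (N, L)
        cnt = np.maximum(mask.sum(axis=1), 1.0)       # (N,) zero-safe
        pooled = (emb * mask[:, :, None]).sum(axis=1) / cnt[:, None]
        return pooled, {"ids": ids, "mask": mask, "cnt": cnt}

    def embed_fields(self, batch: Batch) -> tuple[np.ndarray, dict]:
        """Field-averaged embeddings concatenated over the five fields.

        A field containing only padding ids contributes a zero vector.
        """
        caches: dict = {}
        pooled = []
        for f in FIELDS:
            v, c = self._pool_field(f, batch.field_ids[f])
            pooled.append(v)
            caches[f] = c
        elem_e = self.params["emb_element"][batch.element_ids]
        E_sym = np.concatenate(pooled, axis=1)
        E = np.concatenate([E_sym, elem_e], axis=1)
        caches["E_sym"] = E_sym
        caches["elem_e"] = elem_e
        return E, caches

    def _mlp_forward(self, x: np.ndarray, prefix: str, n_layers: int) -> list[np.ndarray]:
        """Stack of Dense+ReLU layers; returns [x, h1, ..., hL]."""
        hs = [x]
        for l in range(n_layers):
            z = hs[-1] @ self.params[f"{prefix}_W{l}"] + self.params[f"{prefix}_b{l}"]
            hs.append(np.maximum(z, 0.0))
        return hs

    def match_forward(
        self, E_sym: np.ndarray, elem_e: np.ndarray
    ) -> tuple[np.ndarray, dict]:
        """Match-network logits plus cached intermediates.

        Returns ``(z_match, cache)``; the matching probability is
        ``sigmoid(z_match)``.  The cache carries ``p_u`` / ``p_v`` in cosine
        mode.
        """
        cfg, p = self.config, self.params
        head = cfg.resolved_head
        L = len(cfg.match_tower_sizes)
        if head == "concat":
            hs = self._mlp_forward(np.concatenate([E_sym, elem_e], axis=1), "match", L)
            z = hs[-1] @ p["match_p"] + p["match_pb"]
            return z, {"head": "concat", "hs": hs}
        if head == "cosine":
            a_v = p["a_v"]
            if cfg.per_element_augment:
                raise RuntimeError("per-element a_v requires element ids; use _forward_all")
            c_u, c_v = mimic_augment(E_sym, elem_e, p["a_u"], a_v)
            hs_u = self._mlp_forward(c_u, "match_u", L)
            hs_v = self._mlp_forward(c_v, "match_v", L)
            p_u, nu = l2_normalize(hs_u[-1])
            p_v, nv = l2_normalize(hs_v[-1])
            dot = (p_u * p_v).sum(axis=1)
            z = p["match_w"] * dot + p["match_wb"]
            return z, {
                "head": "cosine", "hs_u": hs_u, "hs_v": hs_v,
                "p_u": p_u, "p_v": p_v, "nu": nu, "nv": nv, "dot": dot,
            }
        raise RuntimeError("match_forward called with fusion='none'")

    def mmoe_forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Per-task probabilities from the fused input vector.

        ``x`` has shape (N, input_width); returns logits (n_tasks, N) and a
        cache of expert outputs and gate weights.
        """
        cfg, p = self.config, self.params
        n_exp_layers = len(cfg.expert_layer_sizes)
        expert_hs = [self._mlp_forward(x, f"expert{i}", n_exp_layers) for i in range(cfg.n_experts)]
        O = np.stack([hs[-1] for hs in expert_hs], axis=1)   # (N, n_experts, d_out)
        logits = []
        gates, tower_hs = [], []
        for k in range(cfg.n_tasks):
            gl = x @ p[f"gate{k}_W"]
            gl -= gl.max(axis=1, keepdims=True)
            g = np.exp(gl)
            g /= g.sum(axis=1, keepdims=True)
            fk = np.einsum("ne,ned->nd", g, O)
            hs = [fk]
            for l in range(len(cfg.tower_layer_sizes)):
                z = hs[-1] @ p[f"tower{k}_W{l}"] + p[f"tower{k}_b{l}"]
                hs.append(np.maximum(z, 0.0))
            zk = hs[-1] @ p[f"tower{k}_out_W"] + p[f"tower{k}_out_b"]
            logits.append(zk)
            gates.append(g)
            tower_hs.append(hs)
        return np.stack(logits), {"x": x, "expert_hs": expert_hs, "O": O,
                                  "gates": gates, "tower_hs": tower_hs}

    def _forward_all(self, batch: Batch) -> dict:
        cfg = self.config
        E, emb_cache = self.embed_fields(batch)
        E_sym, elem_e = emb_cache["E_sym"], emb_cache["elem_e"]
        cache: dict = {"E": E, "emb": emb_cache, "batch": batch}
        z_m, y_m = None, None
        if cfg.resolved_head is not None:
            if cfg.resolved_head == "cosine" and cfg.per_element_augment:
                p = self.params
                a_v_rows = p["a_v"][batch.element_ids]
                c_u, c_v = mimic_augment(E_sym, elem_e, p["a_u"], a_v_rows)
                L = len(cfg.match_tower_sizes)
                hs_u = self._mlp_forward(c_u, "match_u", L)
                hs_v = self._mlp_forward(c_v, "match_v", L)
                p_u, nu = l2_normalize(hs_u[-1])
                p_v, nv = l2_normalize(hs_v[-1])
                dot = (p_u * p_v).sum(axis=1)
                z_m = p["match_w"] * dot + p["match_wb"]
                cache["match"] = {"head": "cosine", "hs_u": hs_u, "hs_v": hs_v,
                                  "p_u": p_u, "p_v": p_v, "nu": nu, "nv": nv, "dot": dot}
            else:
                z_m, mcache = self.match_forward(E_sym, elem_e)
                cache["match"] = mcache
            y_m = sigmoid(z_m)
        cache["z_match"] = z_m
        cache["y_match"] = y_m
        x = fuse_match_feature(E, y_m if cfg.uses_match_feature else None, batch.extra)
        z_main, mmoe_cache = self.mmoe_forward(x)
        cache["x"] = x
        cache["z_main"] = z_main
        cache["y_main"] = sigmoid(z_main)
        cache["mmoe"] = mmoe_cache
        return cache

    def predict(self, batch: Batch, chunk: int = 20000) -> np.ndarray:
        """Task-0 probabilities, computed in memory-bounded chunks."""
        n = len(batch)
        out = np.empty(n)
        for start in range(0, n, chunk):
            idx = np.arange(start, min(start + chunk, n))
            out[idx] = self._forward_all(batch.take(idx))["y_main"][0]
        return out

    # loss + gradients ---------------------------------------------------------

    def loss_and_grads(self, batch: Batch) -> tuple[dict[str, float], dict[str, np.ndarray]]:
        """Total loss components and gradients w.r.t. every parameter."""
        cfg, p = self.config, self.params
        n = len(batch)
        if n == 0:
            raise ValueError("empty batch")
        y = batch.labels
        cache = self._forward_all(batch)
        z_main, z_m = cache["z_main"], cache["z_match"]

        losses = {
            "main": float(np.mean([_bce_from_logits(zk, y) for zk in z_main])),
            "match": _bce_from_logits(z_m, y) if z_m is not None else 0.0,
            "mimic_u": 0.0,
            "mimic_v": 0.0,
        }
        grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in p.items()}

        # ---- mimic losses (gradients flow to a_u / a_v only) ----
        if cfg.uses_mimic:
            mc = cache["match"]
            p_u, p_v = mc["p_u"], mc["p_v"]
            diff_u = p["a_u"][None, :] - p_v
            losses["mimic_u"] = float((y @ (diff_u**2).sum(axis=1)) / n)
            grads["a_u"] += cfg.lambda_u * (2.0 / n) * (y[:, None] * diff_u).sum(axis=0)
            if cfg.per_element_augment:
                a_v_rows = p["a_v"][batch.element_ids]
                diff_v = a_v_rows - p_u
                losses["mimic_v"] = float((y @ (diff_v**2).sum(axis=1)) / n)
                np.add.at(
                    grads["a_v"], batch.element_ids,
                    cfg.lambda_v * (2.0 / n) * y[:, None] * diff_v,
                )
            else:
                diff_v = p["a_v"][None, :] - p_u
                losses["mimic_v"] = float((y @ (diff_v**2).sum(axis=1)) / n)
                grads["a_v"] += cfg.lambda_v * (2.0 / n) * (y[:, None] * diff_v).sum(axis=0)
        losses["total"] = (
            losses["main"]
            + cfg.lambda1 * losses["match"]
            + cfg.lambda_u * losses["mimic_u"]
            + cfg.lambda_v * losses["mimic_v"]
        )

        # ---- main network backward ----
        mmoe = cache["mmoe"]
        x = cache["x"]
        dx = np.zeros_like(x)
        d_out = cfg.expert_layer_sizes[-1]
        dO = np.zeros_like(mmoe["O"])
        for k in range(cfg.n_tasks):
            dz = (sigmoid(z_main[k]) - y) / (n * cfg.n_tasks)
            hs = mmoe["tower_hs"][k]
            dh = dz[:, None] * p[f"tower{k}_out_W"][None, :]
            grads[f"tower{k}_out_W"] += hs[-1].T @ dz
            grads[f"tower{k}_out_b"] += dz.sum()
            for l in reversed(range(len(cfg.tower_layer_sizes))):
                dzl = dh * (hs[l + 1] > 0)
                grads[f"tower{k}_W{l}"] += hs[l].T @ dzl
                grads[f"tower{k}_b{l}"] += dzl.sum(axis=0)
                dh = dzl @ p[f"tower{k}_W{l}"].T
            df = dh                                     # (N, d_out)
            g = mmoe["gates"][k]
            dO += g[:, :, None] * df[:, None, :]
            dg = np.einsum("nd,ned->ne", df, mmoe["O"])
            dgl = g * (dg - (g * dg).sum(axis=1, keepdims=True))
            grads[f"gate{k}_W"] += x.T @ dgl
            dx += dgl @ p[f"gate{k}_W"].T
        for i in range(cfg.n_experts):
            hs = mmoe["expert_hs"][i]
            dh = dO[:, i, :]
            for l in reversed(range(len(cfg.expert_layer_sizes))):
                dzl = dh * (hs[l + 1] > 0)
                grads[f"expert{i}_W{l}"] += hs[l].T @ dzl
                grads[f"expert{i}_b{l}"] += dzl.sum(axis=0)
                dh = dzl @ p[f"expert{i}_W{l}"].T
            dx += dh

        # ---- split fused input gradient ----
        width_E = 5 * self.d
        dE = dx[:, :width_E].copy()
        dz_m = np.zeros(n) if z_m is not None else None
        if cfg.uses_match_feature and not cfg.detach_match_feature:
            d_ym = dx[:, -1]
            s = sigmoid(z_m)
            dz_m += d_ym * s * (1 - s)

        # ---- match network backward ----
        dE_sym_extra = np.zeros((n, 4 * self.d))
        delem_extra = np.zeros((n, self.d))
        if z_m is not None:
            dz_m += cfg.lambda1 * (sigmoid(z_m) - y) / n
            mc = cache["match"]
            if mc["head"] == "concat":
                hs = mc["hs"]
                dh = dz_m[:, None] * p["match_p"][None, :]
                grads["match_p"] += hs[-1].T @ dz_m
                grads["match_pb"] += dz_m.sum()
                for l in reversed(range(len(cfg.match_tower_sizes))):
                    dzl = dh * (hs[l + 1] > 0)
                    grads[f"match_W{l}"] += hs[l].T @ dzl
                    grads[f"match_b{l}"] += dzl.sum(axis=0)
                    dh = dzl @ p[f"match_W{l}"].T
                dE_sym_extra += dh[:, : 4 * self.d]
                delem_extra += dh[:, 4 * self.d :]
            else:
                p_u, p_v = mc["p_u"], mc["p_v"]
                grads["match_w"] += dz_m @ mc["dot"]
                grads["match_wb"] += dz_m.sum()
                dp_u = p["match_w"] * dz_m[:, None] * p_v
                dp_v = p["match_w"] * dz_m[:, None] * p_u
                for side, dp, nr in (("u", dp_u, mc["nu"]), ("v", dp_v, mc["nv"])):
                    hs = mc[f"hs_{side}"]
                    pvec = mc[f"p_{side}"]
                    dh = (dp - pvec * (pvec * dp).sum(axis=1, keepdims=True)) / nr
                    for l in reversed(range(len(cfg.match_tower_sizes))):
                        dzl = dh * (hs[l + 1] > 0)
                        grads[f"match_{side}_W{l}"] += hs[l].T @ dzl
                        grads[f"match_{side}_b{l}"] += dzl.sum(axis=0)
                        dh = dzl @ p[f"match_{side}_W{l}"].T
                    if side == "u":
                        dE_sym_extra += dh[:, : 4 * self.d]
                        grads["a_u"] += dh[:, 4 * self.d :].sum(axis=0)
                    else:
                        delem_extra += dh[:, : self.d]
                        if cfg.per_element_augment:
                            np.add.at(grads["a_v"], batch.element_ids, dh[:, self.d :])
                        else:
                            grads["a_v"] += dh[:, self.d :].sum(axis=0)

        # ---- embeddings backward ----
        emb_cache = cache["emb"]
        offset = 0
        for f in FIELDS:
            c = emb_cache[f]
            dpool = dE[:, offset : offset + self.d] + dE_sym_extra[:, offset : offset + self.d]
            offset += self.d
            dtok = (dpool / c["cnt"][:, None])[:, None, :] * c["mask"][:, :, None]
            ids = c["ids"]
            flat = ids.ravel()
            np.add.at(grads[f"emb_{f}"], flat, dtok.reshape(-1, self.d))
            grads[f"emb_{f}"][0] = 0.0
        delem = dE[:, offset:] + delem_extra
        np.add.at(grads["emb_element"], batch.element_ids, delem)
        grads["emb_element"][0] = 0.0

        if not np.isfinite(losses["total"]):
            raise FloatingPointError("non-finite loss")
        return losses, grads

    # checkpointing -------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a flat parameter archive plus a YAML config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "config": asdict(self.config),
            "vocab_sizes": self.vocab_sizes,
            "n_elements": self.n_elements,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "MMOEMatchModel":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        cfg_dict = meta["config"]
        for key in ("expert_layer_sizes", "tower_layer_sizes", "match_tower_sizes"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        model = cls(config, meta["vocab_sizes"], meta["n_elements"], rng=0)
        with np.load(path.with_suffix(".npz")) as arch:
            for k in model.params:
                if k not in arch:
                    raise ValueError(f"checkpoint missing parameter {k!r}")
                if arch[k].shape != model.params[k].shape:
                    raise ValueError(
                        f"checkpoint parameter {k!r} has shape {arch[k].shape}, "
                        f"expected {model.params[k].shape}"
                    )
                model.params[k] = arch[k]
        return model


def make_model(
    config: ModelConfig, vocab: Vocabulary, rng: np.random.Generator | int | None = 0
) -> MMOEMatchModel:
    """Build a model sized to a vocabulary."""
    sizes = {f: vocab.field_size(f) for f in FIELDS}
    return MMOEMatchModel(config, sizes, vocab.n_elements, rng=rng)
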