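"""Topology and semantic perturbations of a knowledge graph.

Two topology perturbations change the degree structure before training:

* degree-weighted triple downsampling — triples are removed iteratively in
  batches with probability mass p*(e) ∝ (1+deg(e))^alpha, where
  deg(e) = deg(h) + deg(t); positive alpha preferentially removes high-degree
  triples (raising entity entropy), negative alpha removes low-degree triples;
* hub removal — entities with degree above the p-th percentile of the degree
  multiset are removed uniformly at random (with all incident triples).

Two semantic perturbations ablate relation meaning while leaving topology
intact: corruption resamples a triple's relation uniformly from the other
relations of the pre-perturbation vocabulary, and flattening maps relations to
a single generic label ("relates").  Both act only on non-whitelist triples;
the task-defining whitelist relations are never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up
from .kg_core import KnowledgeGraph, Triple, kg_stats

logger = logging.getLogger(__name__)

__all__ = [
    "DownsampleConfig",
    "HubRemovalConfig",
    "SemanticPerturbConfig",
    "downsample_triples",
    "remove_hubs",
    "corrupt_relations",
    "flatten_relations",
    "apply_semantic_perturbation",
]


@dataclass(frozen=True)
class DownsampleConfig:
    """Parameters of degree-weighted triple downsampling.

    d : fraction of the initial triples to retain, in (0, 1].
    alpha : degree-strength exponent; sign selects whether high-degree
        (positive) or low-degree (negative) triples carry more removal mass.
    batch_fraction : fraction of the current graph removed per iteration
        before degrees are recomputed (small batches approximate fully
        sequential weighted sampling).
    """

    d: float
    alpha: float = 0.0
    batch_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.d <= 1.0):
            raise ValueError(f"d must be in (0, 1], got {self.d}")
        if not (0.0 < self.batch_fraction <= 1.0):
            raise ValueError(
                f"batch_fraction must be in (0, 1], got {self.batch_fraction}"
            )


@dataclass(frozen=True)
class HubRemovalConfig:
    """Parameters of hub-entity removal.

    p : degree percentile in [0, 1] defining the hub threshold deg_p
        (p = 1 means no entity qualifies, i.e. identity).
    f_hubs : fraction of above-threshold entities removed uniformly at random.
    """

    p: float
    f_hubs: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (0.0 <= self.f_hubs <= 1.0):
            raise ValueError(f"f_hubs must be in [0, 1], got {self.f_hubs}")


@dataclass(frozen=True)
class SemanticPerturbConfig:
    """Parameters of relation corruption / flattening.

    mode : one of {"corrupt", "flatten", "none"}.
    fraction : fraction of non-whitelist triples perturbed (default 1.0:
        every non-whitelist triple).
    whitelist : protected relation identifiers (task-defining relations).
    flat_label : the single replacement relation used by flattening.
    """

    mode: str = "none"
    fraction: float = 1.0
    whitelist: frozenset[str] = field(default_factory=frozenset)
    flat_label: str = "relates"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("corrupt", "flatten", "none"):
            raise ValueError(f"unknown semantic perturbation mode {self.mode!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if not self.flat_label:
            raise ValueError("flat_label must be non-empty")
        object.__setattr__(self, "whitelist", frozenset(self.whitelist))


def _log_stats(op: str, before: KnowledgeGraph, after: KnowledgeGraph) -> None:
    if len(after) and logger.isEnabledFor(logging.DEBUG):
        logger.debug("%s: before=%s after=%s", op, kg_stats(before), kg_stats(after))


def downsample_triples(kg: KnowledgeGraph, cfg: DownsampleConfig) -> KnowledgeGraph:
    """Remove triples in degree-weighted batches until round(d·|T|) remain.

    Each iteration recomputes triple degrees on the current graph, forms
    p*(e) = (1+deg(e))^alpha / Σ (1+deg(e'))^alpha over the remaining triples,
    and draws a batch without replacement with that probability mass.
    Deterministic given (graph, config, seed).
    """
    if len(kg) == 0:
        raise ValueError("cannot downsample an empty graph")
    target = round_half_up(cfg.d * len(kg))
    if target < 1:
        raise ValueError(
            f"target count round(d*|T|) = {target} < 1 (d={cfg.d}, |T|={len(kg)})"
        )
    if target >= len(kg):
        return kg

    triples = kg.sorted_triples()
    # integer-encode endpoints once; degrees via bincount inside the loop
    ent_index = {e: i for i, e in enumerate(sorted(kg.entities))}
    h_idx = np.array([ent_index[t.head] for t in triples], dtype=np.intp)
    t_idx = np.array([ent_index[t.tail] for t in triples], dtype=np.intp)
    n_ent = len(ent_index)
    alive = np.ones(len(triples), dtype=bool)
    n_alive = len(triples)
    rng = np.random.default_rng(cfg.seed)

    while n_alive > target:
        batch = max(1, round_half_up(cfg.batch_fraction * n_alive))
        batch = min(batch, n_alive - target)
        hh, tt = h_idx[alive], t_idx[alive]
        deg = np.bincount(hh, minlength=n_ent)
        # self-loops count once in node degree
        deg += np.bincount(tt[tt != hh], minlength=n_ent)
        tdeg = deg[hh] + deg[tt]
        with np.errstate(over="raise"):
            u = (1.0 + tdeg) ** cfg.alpha
        p = u / u.sum()
        local = rng.choice(n_alive, size=batch, replace=False, p=p)
        global_idx = np.flatnonzero(alive)[local]
        alive[global_idx] = False
        n_alive -= batch

    out = KnowledgeGraph(triples[i] for i in np.flatnonzero(alive))
    _log_stats("downsample_triples", kg, out)
    return out


def remove_hubs(kg: KnowledgeGraph, cfg: HubRemovalConfig) -> KnowledgeGraph:
    """Remove a fraction of entities with degree strictly above deg_p.

    deg_p is the linear-interpolation p-th quantile of the node-degree
    multiset; round(f_hubs · |hub set|) hubs are drawn uniformly at random and
    deleted together with every incident triple.  Entities left with degree 0
    drop out of the entity vocabulary automatically (it is derived from the
    triples).  p = 1 or f_hubs = 0 are identities.
    """
    if len(kg) == 0:
        raise ValueError("cannot remove hubs from an empty graph")
    entities = sorted(kg.entities)
    degrees = np.array([kg.degree_index[e] for e in entities], dtype=float)
    deg_p = float(np.quantile(degrees, cfg.p))
    hubs = [e for e, d in zip(entities, degrees) if d > deg_p]
    n_remove = round_half_up(cfg.f_hubs * len(hubs))
    if n_remove == 0:
        return kg
    rng = np.random.default_rng(cfg.seed)
    removed = set(rng.choice(np.array(hubs, dtype=object), size=n_remove, replace=False))
    out = KnowledgeGraph(
        t for t in kg.triples if t.head not in removed and t.tail not in removed
    )
    logger.info(
        "remove_hubs: deg_p=%.2f, removed %d/%d hubs, %d -> %d triples",
        deg_p, n_remove, len(hubs), len(kg), len(out),
    )
    _log_stats("remove_hubs", kg, out)
    return out


def _pick_nonwhitelist(
    kg: KnowledgeGraph, cfg: SemanticPerturbConfig, rng: np.random.Generator
) -> tuple[list[Triple], set[Triple]]:
    """Deterministically choose round(fraction·n) non-whitelist triples."""
    non_wl = [t for t in kg.sorted_triples() if t.relation not in cfg.whitelist]
    n_pick = round_half_up(cfg.fraction * len(non_wl))
    if n_pick == 0:
        return non_wl, set()
    chosen_idx = rng.choice(len(non_wl), size=n_pick, replace=False)
    return non_wl, {non_wl[i] for i in chosen_idx}


def corrupt_relations(kg: KnowledgeGraph, cfg: SemanticPerturbConfig) -> KnowledgeGraph:
    """Resample the relation of a fraction of non-whitelist triples.

    The new relation is drawn uniformly from R \\ {current relation}, with R
    frozen as the pre-perturbation vocabulary.  Heads, tails and whitelist
    triples are untouched, so the entity set and topology are preserved up to
    deduplication of collisions (two triples becoming identical), whose count
    is logged.
    """
    rng = np.random.default_rng(cfg.seed)
    relations = sorted(kg.relations)
    non_wl, chosen = _pick_nonwhitelist(kg, cfg, rng)
    if chosen and len(relations) < 2:
        raise ValueError("relation corruption needs >=2 relations in the vocabulary")
    if not chosen:
        return kg
    rel_index = {r: i for i, r in enumerate(relations)}
    out: list[Triple] = []
    for t in kg.sorted_triples():
        if t in chosen:
            # uniform over the other |R|-1 relations: skip past the original
            j = int(rng.integers(0, len(relations) - 1))
            if j >= rel_index[t.relation]:
                j += 1
            out.append(Triple(t.head, relations[j], t.tail))
        else:
            out.append(t)
    new_kg = KnowledgeGraph(out)
    collisions = len(kg) - len(new_kg)
    if collisions:
        logger.info("corrupt_relations: %d collision(s) deduplicated", collisions)
    _log_stats("corrupt_relations", kg, new_kg)
    return new_kg


def flatten_relations(kg: KnowledgeGraph, cfg: SemanticPerturbConfig) -> KnowledgeGraph:
    """Map the relations of a fraction of non-whitelist triples to one label.

    The replacement label (default "relates") must not collide with a
    whitelist relation.  Duplicate triples created by the relabeling collapse;
    the collapse count is logged.
    """
    if cfg.flat_label in cfg.whitelist:
        raise ValueError(
            f"flat_label {cfg.flat_label!r} collides with a whitelist relation"
        )
    rng = np.random.default_rng(cfg.seed)
    _, chosen = _pick_nonwhitelist(kg, cfg, rng)
    if not chosen:
        return kg
    out = [
        Triple(t.head, cfg.flat_label, t.tail) if t in chosen else t
        for t in kg.sorted_triples()
    ]
    new_kg = KnowledgeGraph(out)
    collisions = len(kg) - len(new_kg)
    if collisions:
        logger.info("flatten_relations: %d collision(s) deduplicated", collisions)
    _log_stats("flatten_relations", kg, new_kg)
    return new_kg


def apply_semantic_perturbation(
    kg: KnowledgeGraph, cfg: SemanticPerturbConfig
) -> KnowledgeGraph:
    """Dispatch on ``cfg.mode`` ("none" is the identity / control condition)."""
    if cfg.mode == "none":
        return kg
    if cfg.mode == "corrupt":
        return corrupt_relations(kg, cfg)
    return flatten_relations(kg, cfg)
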