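"""Whitelist-based train/test splitting, entity ranking, AMRI, and
performance-drop computation.

Evaluation follows the knowledge-reconstruction protocol: the head and tail
of each held-out whitelist triple are concealed in turn, every candidate
entity is scored in the concealed slot, and the rank of the true entity is
recorded.  Ranks use the filtered protocol (candidates forming a known triple
other than the test triple itself are excluded) with realistic tie handling
(mean of the best and worst rank of the true entity).

The adjusted mean rank index (AMRI) rescales pooled ranks so that 1 means the
true entity always ranks first, 0 is the expectation under uniform-random
scoring, and -1 means it always ranks last:

    AMRI = 1 - 2 · Σ_i (rank_i - 1) / Σ_i (n_candidates_i - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .embeddings import EmbeddingSet, vec_scores
from .kg_core import KnowledgeGraph, Triple, node_degree

logger = logging.getLogger(__name__)

__all__ = [
    "SplitConfig",
    "RankRecord",
    "sample_test_set",
    "rank_entity",
    "evaluate",
    "amri",
    "performance_drop",
    "records_frame",
]


@dataclass(frozen=True)
class SplitConfig:
    """Test-split parameters.

    A triple is permissible for the test set iff its relation is in the task
    whitelist and min(deg(h), deg(t)) >= ``min_endpoint_degree``, with degrees
    computed on the post-perturbation graph.  ``test_fraction`` of the
    permissible triples (default 5%) are sampled uniformly.
    """

    whitelist: frozenset[str]
    min_endpoint_degree: int = 4
    test_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.min_endpoint_degree < 0:
            raise ValueError("min_endpoint_degree must be >= 0")
        object.__setattr__(self, "whitelist", frozenset(self.whitelist))


@dataclass(frozen=True)
class RankRecord:
    """Rank of the true entity for one concealed slot of one test triple."""

    test_triple: Triple
    side: str  # "head" | "tail"
    rank: float  # realistic rank; half-integers possible under ties
    n_candidates: int

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.n_candidates):
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates}]"
            )


def sample_test_set(
    kg: KnowledgeGraph, cfg: SplitConfig
) -> tuple[KnowledgeGraph, frozenset[Triple]]:
    """Split a (post-perturbation) graph into train graph and test triples.

    Returns ``(train, test)`` with ``train ∪ test`` equal to the input triples
    and ``train ∩ test`` empty; all other triples — including unsampled
    whitelist triples — remain in the training graph.
    """
    if len(kg) == 0:
        raise ValueError("cannot split an empty graph")
    whitelisted = [t for t in kg.sorted_triples() if t.relation in cfg.whitelist]
    permissible = [
        t
        for t in whitelisted
        if min(node_degree(kg, t.head), node_degree(kg, t.tail))
        >= cfg.min_endpoint_degree
    ]
    if not permissible:
        raise ValueError(
            f"no permissible test triples: {len(whitelisted)} whitelist triple(s), "
            f"{len(whitelisted) - len(permissible)} fail the degree criterion "
            f"min(deg(h), deg(t)) >= {cfg.min_endpoint_degree}"
        )
    n_test = round_half_up(cfg.test_fraction * len(permissible))
    rng = np.random.default_rng(cfg.seed)
    pick = rng.choice(len(permissible), size=n_test, replace=False)
    test = frozenset(permissible[i] for i in pick)
    train = KnowledgeGraph(kg.triples - test)
    return train, test


def _realistic_rank(scores: np.ndarray, true_pos: int) -> tuple[float, int]:
    """Mean of best and worst rank of the true candidate under ties."""
    true_score = scores[true_pos]
    best = 1 + int(np.sum(scores > true_score))
    worst = int(np.sum(scores >= true_score))
    return (best + worst) / 2.0, len(scores)


def rank_entity(
    embeddings: EmbeddingSet | None,
    test_triple: Triple,
    side: str,
    candidate_entities: Sequence[str],
    known_triples: Iterable[Triple] = (),
    filtered: bool = True,
    scorer: Callable[[list[Triple]], np.ndarray] | None = None,
) -> RankRecord:
    """Rank the concealed entity of one test triple among candidates.

    Every candidate is substituted into the concealed slot and scored with
    the embedding model (or an explicit ``scorer`` callable mapping a list of
    candidate triples to scores, useful for oracle/random baselines).  Under
    the filtered protocol, candidates that form a triple in ``known_triples``
    other than the test triple itself are excluded before ranking.
    """
    if side not in ("head", "tail"):
        raise ValueError(f"side must be 'head' or 'tail', got {side!r}")
    true_entity = test_triple.head if side == "head" else test_triple.tail
    candidates = list(candidate_entities)
    try:
        true_pos = candidates.index(true_entity)
    except ValueError:
        raise ValueError(
            f"true {side} entity {true_entity!r} missing from candidates"
        ) from None

    if filtered:
        known = set(known_triples)
        keep: list[int] = []
        for i, c in enumerate(candidates):
            cand_triple = (
                Triple(c, test_triple.relation, test_triple.tail)
                if side == "head"
                else Triple(test_triple.head, test_triple.relation, c)
            )
            if i != true_pos and cand_triple in known:
                continue
            keep.append(i)
        candidates = [candidates[i] for i in keep]
        true_pos = candidates.index(true_entity)

    cand_triples = [
        Triple(c, test_triple.relation, test_triple.tail)
        if side == "head"
        else Triple(test_triple.head, test_triple.relation, c)
        for c in candidates
    ]
    if scorer is not None:
        scores = np.asarray(scorer(cand_triples), dtype=float)
    else:
        if embeddings is None:
            raise ValueError("either embeddings or a scorer must be provided")
        r_vec = embeddings.relation_vector(test_triple.relation)
        cand_vecs = np.stack([embeddings.entity_vector(c) for c in candidates])
        if side == "head":
            fixed = embeddings.entity_vector(test_triple.tail)
            scores = vec_scores(embeddings.model, cand_vecs, r_vec, fixed)
        else:
            fixed = embeddings.entity_vector(test_triple.head)
            scores = vec_scores(embeddings.model, fixed, r_vec, cand_vecs)
    rank, n_cand = _realistic_rank(scores, true_pos)
    return RankRecord(test_triple, side, rank, n_cand)


def evaluate(
    embeddings: EmbeddingSet,
    train_kg: KnowledgeGraph,
    test_triples: Iterable[Triple],
    filtered: bool = True,
) -> list[RankRecord]:
    """Head and tail rank records for every evaluable test triple.

    Candidates are all entities of the training vocabulary.  Test triples
    whose head or tail is absent from that vocabulary (possible after
    perturbation) are skipped; the count is logged.
    """
    candidates = embeddings.entities
    vocab = set(candidates)
    test = sorted(set(test_triples))
    known = frozenset(train_kg.triples) | frozenset(test)
    records: list[RankRecord] = []
    skipped = 0
    for triple in test:
        if triple.head not in vocab or triple.tail not in vocab:
            skipped += 1
            continue
        for side in ("head", "tail"):
            records.append(
                rank_entity(embeddings, triple, side, candidates, known, filtered)
            )
    if skipped:
        logger.info("evaluate: skipped %d test triple(s) outside train vocabulary", skipped)
    return records


def amri(records: Sequence[RankRecord]) -> float:
    """Adjusted mean rank index of pooled rank records, in [-1, 1]."""
    if not records:
        raise ValueError("amri requires at least one rank record")
    for rec in records:
        if rec.n_candidates < 2:
            raise ValueError("amri requires n_candidates >= 2 for every record")
    num = sum(rec.rank - 1.0 for rec in records)
    den = sum(rec.n_candidates - 1.0 for rec in records)
    return 1.0 - 2.0 * num / den


def performance_drop(control_amri: float, perturbed_amri: float) -> float:
    """Relative AMRI drop in percent: 100·(control − perturbed)/control.

    Negative values indicate gains.  Undefined for non-positive control AMRI
    (a control no better than random cannot anchor a relative drop).
    """
    if control_amri <= 0:
        raise ValueError(
            f"performance drop undefined for control AMRI <= 0 (got {control_amri})"
        )
    return 100.0 * (control_amri - perturbed_amri) / control_amri


def records_frame(records: Sequence[RankRecord]) -> pd.DataFrame:
    """Rank records as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "head": [r.test_triple.head for r in records],
            "relation": [r.test_triple.relation for r in records],
            "tail": [r.test_triple.tail for r in records],
            "side": [r.side for r in records],
            "rank": [r.rank for r in records],
            "n_candidates": [r.n_candidates for r in records],
        }
    )
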