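"""Knowledge-graph data model, degree computations, topology metrics and I/O.

A knowledge graph is a set of directed labeled triples (head, relation, tail)
over typed entity identifiers such as ``Compound::DB00001``.  The topology
metrics implemented here quantify how "hubby" the graph is: the entity
selection probability P_ESP(n) is the probability that entity n appears in a
triple drawn uniformly from the graph, and entity entropy EE is the Shannon
entropy (in nats) of that distribution.  Hub-dominated graphs concentrate
P_ESP mass on a few entities and therefore score low EE; graphs with even
degrees score close to the maximum ln|E|.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "KGStats",
    "load_kg",
    "save_kg",
    "node_degree",
    "triple_degree",
    "entity_selection_probability",
    "entity_entropy",
    "normalized_entity_entropy",
    "kg_stats",
    "entity_type",
]


class Triple(NamedTuple):
    """A directed labeled edge (head entity, relation, tail entity)."""

    head: str
    relation: str
    tail: str


def entity_type(identifier: str) -> str:
    """Entity type parsed from the ``Type::ID`` identifier convention.

    Identifiers without the ``::`` separator get type ``"unknown"``.  Types
    are metadata (used by the synthetic generator and reporting); none of the
    topology math depends on them.
    """
    if "::" in identifier:
        return identifier.split("::", 1)[0]
    return "unknown"


class KnowledgeGraph:
    """Immutable set of triples with derived vocabularies and a degree index.

    Set semantics: duplicate triples collapse.  The degree of an entity is the
    number of triples in which it appears as head or tail; a self-loop triple
    counts once (the defining set comprehension is a disjunction).
    Operations that perturb a graph return new ``KnowledgeGraph`` objects.
    """

    __slots__ = ("_triples", "_degree", "_relations")

    def __init__(self, triples: Iterable[Triple] = ()):
        tset = frozenset(Triple(*t) for t in triples)
        for h, r, t in tset:
            if not (h and r and t):
                raise ValueError(f"triple with empty field: {(h, r, t)!r}")
        degree: Counter[str] = Counter()
        relations: set[str] = set()
        for h, r, t in tset:
            degree[h] += 1
            if t != h:
                degree[t] += 1
            relations.add(r)
        self._triples = tset
        self._degree = dict(degree)
        self._relations = frozenset(relations)

    @property
    def triples(self) -> frozenset[Triple]:
        return self._triples

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(self._degree)

    @property
    def relations(self) -> frozenset[str]:
        return self._relations

    @property
    def degree_index(self) -> Mapping[str, int]:
        return self._degree

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, triple: object) -> bool:
        return triple in self._triples

    def __eq__(self, other: object) -> bool:
        if isinstance(other, KnowledgeGraph):
            return self._triples == other._triples
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._triples)

    def __repr__(self) -> str:
        return (
            f"KnowledgeGraph(|T|={len(self._triples)}, |E|={len(self._degree)}, "
            f"|R|={len(self._relations)})"
        )

    def sorted_triples(self) -> list[Triple]:
        """Triples in deterministic lexicographic order."""
        return sorted(self._triples)


@dataclass(frozen=True)
class KGStats:
    """Summary statistics of a knowledge graph (one row of a stats report)."""

    n_triples: int
    n_entities: int
    n_relations: int
    median_node_degree: float
    max_node_degree: int
    entity_entropy: float
    normalized_entity_entropy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def load_kg(path: str | Path) -> KnowledgeGraph:
    """Load a tab-separated triple file (head, relation, tail; no header).

    Lines starting with ``#`` and blank lines are skipped; extra columns are
    ignored.  Duplicate triples collapse (the count dropped is logged).

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        For a non-empty line with fewer than 3 columns, naming the line number.
    """
    path = Path(path)
    triples: list[Triple] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(cols)}"
                )
            triples.append(Triple(cols[0], cols[1], cols[2]))
    kg = KnowledgeGraph(triples)
    dupes = len(triples) - len(kg)
    if dupes:
        logger.info("load_kg(%s): dropped %d duplicate triple(s)", path, dupes)
    return kg


def save_kg(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write a graph as a tab-separated triple file in lexicographic order.

    Deterministic: two saves of the same graph are byte-identical.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for h, r, t in kg.sorted_triples():
            fh.write(f"{h}\t{r}\t{t}\n")


def node_degree(kg: KnowledgeGraph, entity: str) -> int:
    """Number of triples in which ``entity`` appears as head or tail.

    Returns 0 for entities absent from the graph.  A self-loop contributes 1.
    """
    return kg.degree_index.get(entity, 0)


def triple_degree(kg: KnowledgeGraph, triple: Triple) -> int:
    """deg(h) + deg(t) for a triple of the graph."""
    if triple not in kg:
        raise KeyError(f"triple not in graph: {triple!r}")
    return node_degree(kg, triple.head) + node_degree(kg, triple.tail)


def _require_nonempty(kg: KnowledgeGraph) -> None:
    if len(kg) == 0:
        raise ValueError("operation undefined on an empty knowledge graph")


def entity_selection_probability(kg: KnowledgeGraph) -> dict[str, float]:
    """P_ESP(n) = deg(n) / (2|T|) for every entity n.

    For self-loop-free graphs the values sum to 1.  A self-loop contributes
    only once to its entity's degree, so graphs with self-loops sum to <1;
    this follows the defining formula and is deliberate.
    """
    _require_nonempty(kg)
    denom = 2.0 * len(kg)
    return {e: d / denom for e, d in kg.degree_index.items()}

def entity_entropy(kg: KnowledgeGraph) -> float:
    """Entity entropy EE = Σ_n −P_ESP(n)·ln P_ESP(n), in nats.

    Hubbier graphs score lower; the maximum ln|E| is attained when every
    entity has the same degree.
    """
    p = np.array(list(entity_selection_probability(kg).values()))
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_entity_entropy(kg: KnowledgeGraph) -> float:
    """EE / ln|E|, in [0, 1]; equals 1 iff P_ESP is uniform.

    Requires at least two entities (ln|E| would otherwise be <= 0).
    """
    n_ent = len(kg.entities)
    if n_ent < 2:
        raise ValueError(f"normalized entity entropy needs >=2 entities, got {n_ent}")
    return entity_entropy(kg) / math.log(n_ent)


def kg_stats(kg: KnowledgeGraph) -> KGStats:
    """All summary statistics of a non-empty graph.

    The median over an even-sized degree multiset is the mean of the two
    central values.
    """
    _require_nonempty(kg)
    degrees = np.fromiter(kg.degree_index.values(), dtype=np.int64)
    return KGStats(
        n_triples=len(kg),
        n_entities=len(kg.entities),
        n_relations=len(kg.relations),
        median_node_degree=float(np.median(degrees)),
        max_node_degree=int(degrees.max()),
        entity_entropy=entity_entropy(kg),
        normalized_entity_entropy=(
            normalized_entity_entropy(kg) if len(kg.entities) >= 2 else float("nan")
        ),
    )
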