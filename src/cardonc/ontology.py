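"""SNOMED-style concept hierarchy and value-set expansion.

Clinical cohort definitions in EHR registries are expressed as computable
value sets over a polyhierarchical terminology: "this concept, including
descendants, OR that concept ... AND NOT these exclusions".  This module
stores a concept hierarchy as a directed acyclic graph (child -> parent
edges), expands include/exclude rules into concrete code sets, and matches
Problem-List entries against them.

The hierarchy is a DAG, not a tree: a concept may have several parents,
as in SNOMED CT.  Codes are opaque strings compared by exact equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "Concept",
    "ConceptHierarchy",
    "ValueSetRule",
    "ValueSet",
    "ValueSetTerm",
    "UnknownCodeError",
    "CyclicHierarchyError",
    "descendants",
    "expand_value_set",
    "problem_list_matches",
]


class UnknownCodeError(KeyError):
    """A referenced concept code does not exist in the hierarchy."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return f"unknown concept code: {self.code!r}"


class CyclicHierarchyError(ValueError):
    """The child->parent relation contains a directed cycle."""


@dataclass(frozen=True)
class Concept:
    """A coded clinical concept with zero or more parent concepts."""

    code: str
    display: str = ""
    parent_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("concept code must be nonempty")
        object.__setattr__(self, "parent_codes", frozenset(self.parent_codes))


class ConceptHierarchy:
    """A DAG of coded concepts supporting descendant queries.

    Parameters
    ----------
    concepts
        The concepts to load.  Every parent code referenced by a concept
        must itself be present, codes must be unique, and the implied
        child-of relation must be acyclic; violations raise at load time.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: dict[str, Concept] = {}
        # edge direction: parent -> child, so nx.descendants walks downward
        g = nx.DiGraph()
        for c in concepts:
            if c.code in self._concepts:
                raise ValueError(f"duplicate concept code: {c.code!r}")
            self._concepts[c.code] = c
            g.add_node(c.code)
        for c in self._concepts.values():
            for p in c.parent_codes:
                if p not in self._concepts:
                    raise UnknownCodeError(p)
                g.add_edge(p, c.code)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicHierarchyError(
                f"concept hierarchy contains a cycle: {cycle}"
            )
        self._graph = g

    # -- basic container protocol -------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self):
        return iter(self._concepts.values())

    @property
    def codes(self) -> set[str]:
        return set(self._concepts)

    def get(self, code: str) -> Concept:
        try:
            return self._concepts[code]
        except KeyError:
            raise UnknownCodeError(code) from None

    def descendants(self, code: str) -> set[str]:
        """All codes subsumed under ``code``, excluding ``code`` itself."""
        if code not in self._concepts:
            raise UnknownCodeError(code)
        return set(nx.descendants(self._graph, code))

    # -- I/O ----------------------------------------------------------------------
    @classmethod
    def from_frames(
        cls, concepts: pd.DataFrame, edges: pd.DataFrame
    ) -> "ConceptHierarchy":
        """Build from a concept table (code, display) and an edge list
        (child_code, parent_code)."""
        for col in ("code", "display"):
            if col not in concepts.columns:
                raise ValueError(f"concepts table missing column {col!r}")
        for col in ("child_code", "parent_code"):
            if col not in edges.columns:
                raise ValueError(f"edges table missing column {col!r}")
        parents: dict[str, set[str]] = {c: set() for c in concepts["code"].astype(str)}
        for child, parent in zip(
            edges["child_code"].astype(str), edges["parent_code"].astype(str)
        ):
            if child not in parents:
                raise UnknownCodeError(child)
            parents[child].add(parent)
        return cls(
            Concept(code=str(row.code), display=str(row.display),
                    parent_codes=frozenset(parents[str(row.code)]))
            for row in concepts.itertuples()
        )

    @classmethod
    def read_csv(cls, concepts_path, edges_path) -> "ConceptHierarchy":
        return cls.from_frames(
            pd.read_csv(concepts_path, dtype=str),
            pd.read_csv(edges_path, dtype=str),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        concepts = pd.DataFrame(
            [(c.code, c.display) for c in self], columns=["code", "display"]
        ).sort_values("code", ignore_index=True)
        edges = pd.DataFrame(
            [(c.code, p) for c in self for p in sorted(c.parent_codes)],
            columns=["child_code", "parent_code"],
        ).sort_values(["child_code", "parent_code"], ignore_index=True)
        return concepts, edges


@dataclass(frozen=True)
class ValueSetTerm:
    """One include/exclude term: a concept, optionally with descendants."""

    code: str
    with_descendants: bool = True


@dataclass(frozen=True)
class ValueSetRule:
    """An include/exclude expression over a concept hierarchy.

    The expanded set is the union of the include-term expansions minus the
    union of the exclude-term expansions; exclusion always wins.
    """

    includes: tuple[ValueSetTerm, ...] = ()
    excludes: tuple[ValueSetTerm, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "includes", tuple(self.includes))
        object.__setattr__(self, "excludes", tuple(self.excludes))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ValueSetRule":
        def terms(key: str) -> tuple[ValueSetTerm, ...]:
            return tuple(
                ValueSetTerm(
                    code=str(t["code"]),
                    with_descendants=bool(t.get("with_descendants", True)),
                )
                for t in d.get(key, [])
            )

        return cls(includes=terms("includes"), excludes=terms("excludes"),
                   name=str(d.get("name", "")))

    @classmethod
    def read_yaml(cls, path) -> "ValueSetRule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "includes": [
                {"code": t.code, "with_descendants": t.with_descendants}
                for t in self.includes
            ],
            "excludes": [
                {"code": t.code, "with_descendants": t.with_descendants}
                for t in self.excludes
            ],
        }


@dataclass(frozen=True)
class ValueSet:
    """A concrete code set together with the rule it was expanded from."""

    codes: frozenset[str]
    rule: ValueSetRule

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)


def descendants(hierarchy: ConceptHierarchy, code: str) -> set[str]:
    """All codes reachable downward from ``code``, excluding ``code``."""
    return hierarchy.descendants(code)


def _expand_term(hierarchy: ConceptHierarchy, term: ValueSetTerm) -> set[str]:
    # self-inclusive: "X, including descendants" contains X itself
    if term.code not in hierarchy:
        raise UnknownCodeError(term.code)
    out = {term.code}
    if term.with_descendants:
        out |= hierarchy.descendants(term.code)
    return out


def expand_value_set(hierarchy: ConceptHierarchy, rule: ValueSetRule) -> ValueSet:
    """Expand an include/exclude rule into a concrete code set.

    Every referenced code must exist in the hierarchy; an empty include
    list yields an empty value set (not an error).
    """
    included: set[str] = set()
    for term in rule.includes:
        included |= _expand_term(hierarchy, term)
    excluded: set[str] = set()
    for term in rule.excludes:
        excluded |= _expand_term(hierarchy, term)
    return ValueSet(codes=frozenset(included - excluded), rule=rule)


def problem_list_matches(problems: Sequence[str] | pd.Series, vs: ValueSet) -> bool:
    """True iff at least one Problem-List code is in the value set."""
    if isinstance(problems, pd.Series):
        problems = problems.tolist()
    return any(code in vs.codes for code in problems)
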