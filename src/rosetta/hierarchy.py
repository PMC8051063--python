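"""Semantic hierarchy of clinical domains.

The harmonization framework organises every behavioral concept under a
three-domain tree (Cognitive, Motor, Somatic) whose terminal nodes — the
*leaf categories* — are the units to which both instrument items and
harmonized questions attach.  Node identifiers are full slash-delimited
paths (``Cognitive/Behavioral/Emotional/Adaptability``) so that repeated
labels (catch-all leaves named after their own subgroup, e.g. a leaf
``Social`` under the subgroup ``Social``) remain unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "DomainNode",
    "Hierarchy",
    "HierarchyParseError",
    "build_default_hierarchy",
    "validate_hierarchy",
    "leaf_path",
]


class HierarchyParseError(ValueError):
    """Raised when a hierarchy document cannot be parsed at all.

    Distinct from validation failures, which are reported as a list of
    violations on a structurally parseable hierarchy.
    """


@dataclass(frozen=True)
class DomainNode:
    """One node of the clinical-domain tree.

    ``id`` is the full path from a top-level domain down to this node;
    ``parent`` is ``None`` only for the three top-level domains, which hang
    off an implicit root.
    """

    id: str
    name: str
    parent: str | None = None
    children: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Hierarchy:
    """An ordered collection of :class:`DomainNode` forming a forest of
    (normally three) trees under an implicit root."""

    def __init__(self, nodes: Iterable[DomainNode]):
        nodes = list(nodes)
        self._order = [n.id for n in nodes]
        self._nodes: dict[str, DomainNode] = {}
        self._duplicates: list[str] = []
        for n in nodes:
            if n.id in self._nodes:
                self._duplicates.append(n.id)
            self._nodes[n.id] = n

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[DomainNode]:
        seen = set()
        for nid in self._order:
            if nid not in seen:
                seen.add(nid)
                yield self._nodes[nid]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> DomainNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown hierarchy node: {node_id!r}") from None

    # -- derived sets -------------------------------------------------------
    @property
    def roots(self) -> list[DomainNode]:
        return [n for n in self if n.parent is None]

    @property
    def leaves(self) -> list[DomainNode]:
        return [n for n in self if n.is_leaf]

    @property
    def internal(self) -> list[DomainNode]:
        return [n for n in self if not n.is_leaf]

    def is_leaf(self, node_id: str) -> bool:
        return self.node(node_id).is_leaf

    # -- validation ---------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of human-readable invariant violations (empty when
        the hierarchy is well formed)."""
        violations: list[str] = []
        for dup in self._duplicates:
            violations.append(f"duplicate id: {dup!r}")
        for n in self:
            if n.parent is not None and n.parent not in self._nodes:
                violations.append(
                    f"orphan node: {n.id!r} references absent parent {n.parent!r}"
                )
            for c in n.children:
                if c not in self._nodes:
                    violations.append(
                        f"dangling child: {n.id!r} lists absent child {c!r}"
                    )
                elif self._nodes[c].parent != n.id:
                    violations.append(
                        f"inconsistent link: {c!r} is a child of {n.id!r} "
                        f"but records parent {self._nodes[c].parent!r}"
                    )
        n_roots = len(self.roots)
        if n_roots != 3:
            violations.append(f"expected 3 top-level domains, found {n_roots}")
        # reachability / cycle detection from the implicit root
        reachable: set[str] = set()
        stack = [r.id for r in self.roots]
        while stack:
            nid = stack.pop()
            if nid in reachable:
                violations.append(f"cycle detected at {nid!r}")
                continue
            reachable.add(nid)
            node = self._nodes.get(nid)
            if node is not None:
                stack.extend(node.children)
        unreachable = [nid for nid in self._nodes if nid not in reachable]
        for nid in sorted(unreachable):
            violations.append(f"unreachable node: {nid!r}")
        return violations

    # -- queries ------------------------------------------------------------
    def leaf_path(self, leaf_id: str) -> list[str]:
        """Ordered list of node *names* from top-level domain to the leaf."""
        node = self.node(leaf_id)
        if not node.is_leaf:
            raise ValueError(f"{leaf_id!r} is an internal node, not a leaf")
        names = [node.name]
        while node.parent is not None:
            node = self.node(node.parent)
            names.append(node.name)
        return list(reversed(names))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "rosetta-hierarchy/1",
            "nodes": [
                {"id": n.id, "name": n.name, "parent": n.parent} for n in self
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Hierarchy":
        if not isinstance(doc, dict) or "nodes" not in doc:
            raise HierarchyParseError("document lacks a 'nodes' section")
        fmt = doc.get("format", "rosetta-hierarchy/1")
        if not str(fmt).startswith("rosetta-hierarchy"):
            raise HierarchyParseError(f"unrecognised format header: {fmt!r}")
        raw = doc["nodes"]
        if not isinstance(raw, list):
            raise HierarchyParseError("'nodes' must be a list")
        children: dict[str, list[str]] = {}
        parsed = []
        for entry in raw:
            try:
                nid, name = entry["id"], entry["name"]
            except (TypeError, KeyError) as exc:
                raise HierarchyParseError(f"malformed node entry: {entry!r}") from exc
            parent = entry.get("parent")
            parsed.append((nid, name, parent))
            if parent is not None:
                children.setdefault(parent, []).append(nid)
        return cls(
            DomainNode(
                id=nid,
                name=name,
                parent=parent,
                children=tuple(children.get(nid, ())),
            )
            for nid, name, parent in parsed
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Hierarchy":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise HierarchyParseError(f"not valid JSON: {exc}") from exc
        return cls.from_dict(doc)


def build_default_hierarchy() -> Hierarchy:
    """The packaged Generation-1 clinical-domain tree (57 leaf categories).

    Cognitive splits into Behavioral (Emotional: 7 leaves, Sensory: 2,
    Social: 19), Language & Communication (4) and Executive Functioning (14);
    Motor into Fine plus two gross-motor leaves; Somatic into 8 leaves.
    """
    from .fixtures import load_fixture

    return load_fixture("hierarchy")


def validate_hierarchy(h: Hierarchy) -> list[str]:
    """Functional alias for :meth:`Hierarchy.validate`."""
    return h.validate()


def leaf_path(h: Hierarchy, leaf_id: str) -> list[str]:
    """Functional alias for :meth:`Hierarchy.leaf_path`."""
    return h.leaf_path(leaf_id)
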