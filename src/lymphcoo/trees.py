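"""Declarative rule engine for the published IHC decision-tree algorithms.

The eight classifiers compared here (Hans, Colomo, Nyman, Choi, Choi*,
Hans*, VY3, VY4) are all fixed decision trees: an ordered sequence of
marker >= cut-off tests ending in GCB or non-GCB. Tree structures and
cut-offs are data, not code — they ship as JSON transcribed from the
original algorithm publications and can be overridden from user files.

The Hans rule, the de-facto clinical reference, calls a case GCB when
CD10 and/or BCL6 are positive with MUM1 negative, and non-GCB for the
reverse staining pattern.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from .cohort import GCB, NON_GCB
from .panel import (
    MARKERS,
    MarkerProfile,
    MarkerError,
    canonical_marker,
    is_missing,
    markers_to_tags,
)

Terminal = str  # GCB or NON_GCB

BUILTIN_NAMES = ("Hans", "Colomo", "Nyman", "Choi", "Choi*", "Hans*", "VY3", "VY4")

#: antibody-tag combinations per built-in algorithm (1=CD10 ... 5=MUM1)
BUILTIN_COMBINATIONS = {
    "Hans": (1, 2, 5),
    "Colomo": (1, 2, 5),
    "Nyman": (3, 5),
    "Choi": (1, 2, 3, 4, 5),
    "Choi*": (1, 3, 4, 5),
    "Hans*": (1, 5),
    "VY3": (1, 2, 3),
    "VY4": (1, 2, 3, 4),
}


class TreeError(ValueError):
    pass


class MissingMarkerError(KeyError):
    """A profile lacks a marker the classifier requires."""


@dataclass
class TreeNode:
    """One marker >= cut-off test; each branch is a node or a terminal class."""

    marker: str
    cutoff: float
    if_positive: Union["TreeNode", Terminal]
    if_negative: Union["TreeNode", Terminal]


@dataclass
class TreeSpec:
    """A named decision tree over a subset of the five-antibody panel."""

    name: str
    root: TreeNode
    combination: tuple[int, ...]  # sorted antibody tags

    @property
    def markers(self) -> tuple[str, ...]:
        from .panel import tags_to_markers

        return tags_to_markers(self.combination)


def _validate(root: TreeNode, name: str) -> tuple[int, ...]:
    """Check structural invariants; return the tag combination actually used."""
    seen_markers: set[str] = set()

    def walk(node, path: frozenset):
        if isinstance(node, str):
            if node not in (GCB, NON_GCB):
                raise TreeError(f"{name}: terminal {node!r} is not GCB/non-GCB")
            return
        if node.marker in path:
            raise TreeError(f"{name}: path revisits marker {node.marker}")
        if not (0.0 < node.cutoff <= 100.0):
            raise TreeError(f"{name}: cut-off {node.cutoff} outside (0, 100]")
        seen_markers.add(node.marker)
        walk(node.if_positive, path | {node.marker})
        walk(node.if_negative, path | {node.marker})

    walk(root, frozenset())
    return markers_to_tags(seen_markers)


def tree_from_dict(spec: dict) -> TreeSpec:
    """Build a :class:`TreeSpec` from the JSON schema.

    Schema: ``{"name": ..., "nodes": [{"id", "marker", "cutoff_percent",
    "if_positive", "if_negative"}, ...]}`` where branch values are node ids
    or the terminals ``"GCB"`` / ``"nonGCB"``. The first node is the root.
    """
    name = spec["name"]
    raw = {n["id"]: n for n in spec["nodes"]}
    built: dict[str, TreeNode] = {}

    def resolve(ref: str, stack: tuple = ()):
        if ref == "GCB":
            return GCB
        if ref in ("nonGCB", "non-GCB"):
            return NON_GCB
        if ref in stack:
            raise TreeError(f"{name}: node cycle at {ref!r}")
        if ref not in raw:
            raise TreeError(f"{name}: undefined node reference {ref!r}")
        if ref not in built:
            n = raw[ref]
            built[ref] = TreeNode(
                marker=canonical_marker(n["marker"]),
                cutoff=float(n["cutoff_percent"]),
                if_positive=resolve(n["if_positive"], stack + (ref,)),
                if_negative=resolve(n["if_negative"], stack + (ref,)),
            )
        return built[ref]

    root = resolve(spec["nodes"][0]["id"])
    combination = _validate(root, name)
    return TreeSpec(name=name, root=root, combination=combination)


def _load_builtins() -> dict[str, TreeSpec]:
    text = resources.files("lymphcoo.data").joinpath("trees.json").read_text()
    data = json.loads(text)
    specs = {}
    for name, spec in data.items():
        ts = tree_from_dict(spec)
        expected = BUILTIN_COMBINATIONS[name]
        if ts.combination != expected:
            raise TreeError(
                f"{name}: tree uses tags {ts.combination}, expected {expected}"
            )
        specs[name] = ts
    return specs


_BUILTINS: dict[str, TreeSpec] | None = None


def builtin_tree(name: str) -> TreeSpec:
    """Return one of the eight published decision trees by name."""
    global _BUILTINS
    if _BUILTINS is None:
        _BUILTINS = _load_builtins()
    if name not in _BUILTINS:
        raise TreeError(
            f"unknown algorithm {name!r}; valid names: {', '.join(BUILTIN_NAMES)}"
        )
    return _BUILTINS[name]


def load_tree(path) -> TreeSpec:
    """Load a (possibly custom) tree spec from a JSON file."""
    return tree_from_dict(json.loads(Path(path).read_text()))


def classify_tree(profile: MarkerProfile, spec: TreeSpec) -> str:
    """Traverse a decision tree on one staining profile.

    Every marker in the tree's combination must be present — the published
    protocols exclude cases with incomplete panels rather than guessing.
    """
    for m in spec.markers:
        if m not in profile or is_missing(profile[m]):
            raise MissingMarkerError(
                f"{spec.name}: profile lacks required marker {m}"
            )
    node = spec.root
    while not isinstance(node, str):
        value = float(profile[node.marker])
        if not (0.0 <= value <= 100.0):
            raise MarkerError(f"{node.marker} value {value} outside [0, 100]")
        node = node.if_positive if value >= node.cutoff else node.if_negative
    return node


def enumerate_patterns(spec: TreeSpec) -> pd.DataFrame:
    """Tabulate the class assigned to each of the 2^k binary marker patterns.

    Patterns are realised as extreme profiles (0 or 100 percent staining,
    always on the correct side of any cut-off) and pushed through
    :func:`classify_tree`, so the table is exactly the tree's truth table.
    """
    markers = spec.markers
    rows = []
    for bits in itertools.product((0, 1), repeat=len(markers)):
        profile = {m: 100.0 if b else 0.0 for m, b in zip(markers, bits)}
        rows.append(dict(zip(markers, bits), **{"class": classify_tree(profile, spec)}))
    return pd.DataFrame(rows)


def unique_combinations(specs) -> set[frozenset[int]]:
    """Distinct antibody-tag sets among a list of trees (Hans and Colomo
    share (1,2,5), so the eight built-ins yield seven combinations)."""
    return {frozenset(s.combination) for s in specs}
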