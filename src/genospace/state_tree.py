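"""State-Transition Tree: immutable exploration states with LRU caching.

Every transformation applied during exploration creates a new node whose
edge stores the (replayable) transition spec.  Nodes are immutable; going
back to any earlier state is therefore always possible.  To bound memory,
only the ``capacity`` most recently accessed non-root states keep their
matrix in memory; the root is cached permanently, and an evicted state is
reconstructed on demand by walking up to the nearest cached ancestor and
replaying the stored transitions downward.  Dendrograms attached to
clustering nodes are never evicted, since recomputing them is the
expensive part of a cluster transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SessionError, TransitionError
from .space import GenometricSpace
from .transitions import TransitionSpec, apply_spec


@dataclass
class STTNode:
    """One exploration state.  ``cached_space`` is None when evicted."""

    node_id: str
    parent: str | None
    transition: TransitionSpec | None
    cached_space: GenometricSpace | None
    dendrogram: object = None
    created_at: int = 0
    last_access: int = 0
    terminal: bool = False

    @property
    def is_root(self) -> bool:
        return self.parent is None


class STT:
    """The exploration tree.

    Parameters
    ----------
    root_space:
        The first exploration state; permanently cached.
    capacity:
        Number of non-root states kept in memory (user modifiable).
    """

    def __init__(self, root_space: GenometricSpace, capacity: int = 10):
        if capacity < 1:
            raise SessionError("capacity must be a positive integer")
        self._capacity = int(capacity)
        self._clock = 0
        self.root_id = "n0"
        self.nodes: dict[str, STTNode] = {
            self.root_id: STTNode(node_id=self.root_id, parent=None,
                                  transition=None, cached_space=root_space)
        }
        #: number of edge replays performed for reconstruction (observability)
        self.replay_count = 0

    # -- bookkeeping -------------------------------------------------------

    @property
    def capacity(self) -> int:
        return self._capacity

    @capacity.setter
    def capacity(self, value: int):
        if value < 1:
            raise SessionError("capacity must be a positive integer")
        self._capacity = int(value)
        self._evict()

    def _tick(self) -> int:
        self._clock += 1
        return self._clock

    def _touch(self, node: STTNode):
        node.last_access = self._tick()

    def cached_ids(self) -> list[str]:
        """Ids of non-root nodes currently holding their space."""
        return [n.node_id for n in self.nodes.values()
                if not n.is_root and n.cached_space is not None]

    def _evict(self):
        cached = [self.nodes[i] for i in self.cached_ids()]
        while len(cached) > self._capacity:
            victim = min(cached, key=lambda n: n.last_access)
            victim.cached_space = None  # dendrogram survives
            cached.remove(victim)

    def edges(self) -> list[tuple[str, str]]:
        return [(node.parent, node.node_id) for node in self.nodes.values()
                if node.parent is not None]

    # -- operations --------------------------------------------------------

    def apply(self, node_id: str, spec: TransitionSpec) -> str:
        """Apply a transition to a node, creating and caching a child.

        The parent is untouched.  Children of BICLUSTER nodes cannot be
        created: a bi-clustered state is a terminal artifact.
        """
        node = self._get_node(node_id)
        if node.terminal:
            raise TransitionError(
                f"node {node_id} is a bi-cluster leaf and takes no "
                "further transitions")
        spec = (spec if isinstance(spec, TransitionSpec)
                else TransitionSpec.from_dict(spec))
        parent_space = self.get_space(node_id)
        child_space, dendrogram = apply_spec(parent_space, spec)
        child_id = f"n{len(self.nodes)}"
        tick = self._tick()
        child = STTNode(node_id=child_id, parent=node_id, transition=spec,
                        cached_space=child_space, dendrogram=dendrogram,
                        created_at=tick, last_access=tick,
                        terminal=spec.op == "BICLUSTER")
        self.nodes[child_id] = child
        self._evict()
        return child_id

    def get_space(self, node_id: str) -> GenometricSpace:
        """Return a node's space, reconstructing it by replay if evicted."""
        node = self._get_node(node_id)
        if node.cached_space is not None:
            self._touch(node)
            return node.cached_space
        # walk up to the nearest cached ancestor (the root is always cached)
        path: list[STTNode] = []
        cursor = node
        while cursor.cached_space is None:
            path.append(cursor)
            cursor = self._get_node(cursor.parent)
        space = cursor.cached_space
        for ancestor in reversed(path):
            space, dendrogram = apply_spec(space, ancestor.transition)
            self.replay_count += 1
            if ancestor.dendrogram is None:
                ancestor.dendrogram = dendrogram
        node.cached_space = space
        self._touch(node)
        self._evict()
        return space

    def get_dendrogram(self, node_id: str):
        return self._get_node(node_id).dendrogram

    def _get_node(self, node_id: str) -> STTNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise SessionError(f"unknown node {node_id!r}")


# -- session persistence ---------------------------------------------------

def save_session(stt: STT, path) -> None:
    """Write a session manifest (JSON) plus a human-readable root table.

    The manifest carries the capacity, the tree of transition specs and a
    full-fidelity serialization of the root space; non-root spaces are
    dropped and reconstructed lazily after :func:`load_session`.  A
    sibling ``<name>.root.tsv`` holds the root matrix for inspection.
    """
    path = Path(path)
    root_table_name = path.stem + ".root.tsv"
    ordered = sorted(stt.nodes.values(), key=lambda n: int(n.node_id[1:]))
    manifest = {
        "format": "genospace-session/1",
        "capacity": stt.capacity,
        "root": root_table_name,
        "root_space": stt.nodes[stt.root_id].cached_space.to_dict(),
        "nodes": [
            {
                "id": node.node_id,
                "parent": node.parent,
                "spec": (node.transition.to_dict()
                         if node.transition is not None else None),
            }
            for node in ordered
        ],
    }
    with open(path, "wt") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    (path.parent / root_table_name).write_text(
        stt.nodes[stt.root_id].cached_space.to_table())


def load_session(path) -> STT:
    """Rebuild a tree from a session manifest; spaces other than the
    root's are reconstructed on demand."""
    try:
        with open(path) as handle:
            manifest = json.load(handle)
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionError(f"cannot read session {path}: {exc}")
    try:
        root_space = GenometricSpace.from_dict(manifest["root_space"])
        stt = STT(root_space, capacity=manifest["capacity"])
        entries = manifest["nodes"]
    except (KeyError, TypeError) as exc:
        raise SessionError(f"corrupt session {path}: missing {exc}")
    for entry in entries:
        if entry["parent"] is None:
            stt.root_id = entry["id"]
            stt.nodes[entry["id"]] = stt.nodes.pop("n0")
            stt.nodes[entry["id"]].node_id = entry["id"]
            continue
        spec = TransitionSpec.from_dict(entry["spec"])
        tick = stt._tick()
        stt.nodes[entry["id"]] = STTNode(
            node_id=entry["id"], parent=entry["parent"], transition=spec,
            cached_space=None, created_at=tick, last_access=tick,
            terminal=spec.op == "BICLUSTER")
    return stt
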