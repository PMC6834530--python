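"""SWC morphology container and plain-text round trip.

An SWC file is a list of points, one per row, seven whitespace-separated
columns: ``id type x y z radius parent`` with ``#`` comments.  Type codes
follow the convention 1 = soma, 2 = axon, 3 = basal dendrite, 4 = apical
dendrite.  Coordinates and radii are in micrometres; ``parent`` is -1 for
a root.  The parent graph must be a forest: ids unique, every parent
existing or -1, no cycles, radii positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SWCPoint", "SWCTree", "read_swc", "write_swc"]


@dataclass
class SWCPoint:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class SWCTree:
    """A forest of SWC points.

    Mutation helpers keep the forest invariants; :meth:`validate` checks
    them explicitly (unique ids, parents resolvable, acyclic, positive
    radii).
    """

    points: list[SWCPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def by_id(self) -> dict[int, SWCPoint]:
        return {p.id: p for p in self.points}

    def next_id(self) -> int:
        return max((p.id for p in self.points), default=0) + 1

    def add(self, type: int, x: float, y: float, z: float, radius: float, parent: int = -1) -> SWCPoint:
        p = SWCPoint(self.next_id(), type, float(x), float(y), float(z), float(radius), parent)
        self.points.append(p)
        return p

    def validate(self) -> None:
        ids = [p.id for p in self.points]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate SWC ids")
        idset = set(ids)
        for p in self.points:
            if p.parent != -1 and p.parent not in idset:
                raise ValueError(f"point {p.id} has dangling parent {p.parent}")
            if p.parent == p.id:
                raise ValueError(f"point {p.id} is its own parent")
            if not (p.radius > 0 and math.isfinite(p.radius)):
                raise ValueError(f"point {p.id} has non-positive radius {p.radius}")
        parent = {p.id: p.parent for p in self.points}
        state: dict[int, int] = {}  # 0 visiting, 1 done
        for start in ids:
            chain = []
            i = start
            while i != -1 and state.get(i) != 1:
                if state.get(i) == 0:
                    raise ValueError(f"cycle in parent graph through id {i}")
                state[i] = 0
                chain.append(i)
                i = parent[i]
            for c in chain:
                state[c] = 1

    # -- graph queries -------------------------------------------------

    def children(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {p.id: [] for p in self.points}
        for p in self.points:
            if p.parent != -1:
                kids[p.parent].append(p.id)
        return kids

    def degree(self) -> dict[int, int]:
        deg = {p.id: 0 for p in self.points}
        for p in self.points:
            if p.parent != -1:
                deg[p.id] += 1
                deg[p.parent] += 1
        return deg

    def components(self) -> list[list[int]]:
        """Connected components as lists of ids (edges ignore direction)."""
        adj: dict[int, list[int]] = {p.id: [] for p in self.points}
        for p in self.points:
            if p.parent != -1:
                adj[p.id].append(p.parent)
                adj[p.parent].append(p.id)
        seen: set[int] = set()
        comps = []
        for p in self.points:
            if p.id in seen:
                continue
            stack, comp = [p.id], []
            seen.add(p.id)
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in adj[i]:
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            comps.append(comp)
        return comps

    def endpoints(self) -> list[SWCPoint]:
        """Points of degree <= 1 (tips, roots of chains, isolated points)."""
        deg = self.degree()
        return [p for p in self.points if deg[p.id] <= 1]

    def cable_length(self, ids=None) -> float:
        """Total length of parent-child edges, in micrometres."""
        byid = self.by_id()
        sel = set(ids) if ids is not None else None
        total = 0.0
        for p in self.points:
            if p.parent == -1:
                continue
            if sel is not None and (p.id not in sel or p.parent not in sel):
                continue
            q = byid[p.parent]
            total += float(np.linalg.norm(p.xyz - q.xyz))
        return total

    def reroot(self, new_root_id: int) -> None:
        """Reverse parent links so ``new_root_id`` becomes a root of its component."""
        byid = self.by_id()
        chain = []
        i = new_root_id
        while i != -1:
            chain.append(i)
            i = byid[i].parent
        for child, par in zip(chain, chain[1:]):
            byid[par].parent = child
        byid[new_root_id].parent = -1

    def renumber(self) -> None:
        """Renumber ids 1..N preserving topology, roots first."""
        order = []
        kids = self.children()
        byid = self.by_id()
        for p in self.points:
            if p.parent == -1:
                stack = [p.id]
                while stack:
                    i = stack.pop()
                    order.append(i)
                    stack.extend(sorted(kids[i], reverse=True))
        remap = {old: new for new, old in enumerate(order, start=1)}
        for p in self.points:
            p.id = remap[p.id]
            if p.parent != -1:
                p.parent = remap[p.parent]
        self.points.sort(key=lambda p: p.id)
        # keep byid consistent for callers holding references
        del byid

    def copy(self) -> "SWCTree":
        return SWCTree([SWCPoint(p.id, p.type, p.x, p.y, p.z, p.radius, p.parent) for p in self.points])


def read_swc(text: str) -> SWCTree:
    """Parse SWC text into a validated :class:`SWCTree`.

    Raises ``ValueError`` with the offending row number on malformed
    rows, duplicate ids, dangling parents or cycles.
    """
    points = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        cols = body.split()
        if len(cols) != 7:
            raise ValueError(f"row {lineno}: expected 7 columns, got {len(cols)}")
        try:
            p = SWCPoint(
                int(cols[0]), int(cols[1]),
                float(cols[2]), float(cols[3]), float(cols[4]),
                float(cols[5]), int(cols[6]),
            )
        except ValueError as exc:
            raise ValueError(f"row {lineno}: {exc}") from exc
        points.append(p)
    tree = SWCTree(points)
    try:
        tree.validate()
    except ValueError as exc:
        raise ValueError(f"invalid SWC: {exc}") from exc
    return tree


def write_swc(tree: SWCTree, header: str | None = None) -> str:
    """Serialize a tree to SWC text (4-decimal floats).

    The header comment records the coordinate convention; pass extra
    lines via ``header``.
    """
    lines = ["# SWC morphology (id type x y z radius parent); coordinates in um, 0-based voxel origin"]
    if header:
        lines.extend("# " + h for h in header.splitlines())
    for p in tree.points:
        lines.append(
            f"{p.id} {p.type} {p.x:.4f} {p.y:.4f} {p.z:.4f} {p.radius:.4f} {p.parent}"
        )
    return "\n".join(lines) + "\n"
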