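"""Readers and writers for generated networks and experiment results.

Formats:

* edge list — CSV, header ``source,target``, two integer columns, 0-based ids
* node table — CSV, header ``agent_id,x,y,sr``
* GraphML — node attributes ``x`` (int), ``y`` (int), ``sr`` (double)
* results tables — CSV, one row per design
* run manifest — JSON (config echo, seeds, outputs, version, timestamp)
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import networkx as nx

from .generator import Placement, SocialCirclesNetwork

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_node_table",
    "read_node_table",
    "write_graphml",
    "read_graphml",
    "RunManifest",
]


def write_edge_list(network: SocialCirclesNetwork, path: str | Path) -> Path:
    path = Path(path)
    lines = ["source,target"]
    lines += [f"{i},{j}" for i, j in sorted(network.edges)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edge_list(path: str | Path) -> SocialCirclesNetwork:
    """Parse a two-column CSV edge list.

    Positions and reaches are not recorded in this format, so placements are
    reconstructed as id-only stubs (x=y=0, sr=0) for every id that appears on
    an edge; isolated nodes cannot be recovered.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or text[0].strip().lower() not in ("source,target", "source\ttarget"):
        raise ValueError(f"{path}: line 1: expected 'source,target' header")
    edges: set[tuple[int, int]] = set()
    ids: set[int] = set()
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.replace("\t", ",").split(",")
        try:
            i, j = int(parts[0]), int(parts[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {lineno}: malformed edge {line!r}") from exc
        if i == j:
            raise ValueError(f"{path}: line {lineno}: self-loop on {i}")
        ids.update((i, j))
        edges.add((min(i, j), max(i, j)))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    placements = [Placement(i, 0, 0, 0.0) for i in sorted(ids)]
    return SocialCirclesNetwork(placements, edges)


def write_node_table(network: SocialCirclesNetwork, path: str | Path) -> Path:
    path = Path(path)
    lines = ["agent_id,x,y,sr"]
    lines += [
        f"{p.agent_id},{p.x},{p.y},{p.sr!r}" for p in network.placements
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_node_table(path: str | Path) -> list[Placement]:
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "agent_id,x,y,sr":
        raise ValueError(f"{path}: line 1: expected 'agent_id,x,y,sr' header")
    placements = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        try:
            i, x, y, sr = line.split(",")
            placements.append(Placement(int(i), int(x), int(y), float(sr)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed row {line!r}") from exc
    return placements


def write_graphml(network: SocialCirclesNetwork, path: str | Path) -> Path:
    path = Path(path)
    g = network.to_networkx()
    nx.write_graphml(g, path)
    return path


def read_graphml(path: str | Path) -> SocialCirclesNetwork:
    """Parse GraphML written by :func:`write_graphml` (attributes x, y, sr)."""
    path = Path(path)
    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise ValueError(f"{path}: not readable as GraphML: {exc}") from exc
    placements = []
    for node, data in g.nodes(data=True):
        placements.append(
            Placement(
                int(node),
                int(data.get("x", 0)),
                int(data.get("y", 0)),
                float(data.get("sr", 0.0)),
            )
        )
    edges = {
        (min(int(u), int(v)), max(int(u), int(v))) for u, v in g.edges() if u != v
    }
    return SocialCirclesNetwork(sorted(placements, key=lambda p: p.agent_id), edges)


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run: enough to regenerate every output bit-identically."""

    command: str
    config: dict
    base_seed: int
    replicate_seeds: list[int]
    outputs: list[str]
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        missing = [o for o in self.outputs if not Path(o).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
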