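"""Regulatory network topologies and the `.topo` file dialect.

A topology is a set of named nodes plus signed directed edges
(activation or inhibition).  The on-disk format is the whitespace
delimited ``Source Target Type`` table used by the RACIPE family of
tools, with ``Type`` 1 for activation and 2 for inhibition and an
optional single header row.

Three networks are shipped as package data:

``core_emt_pdl1``
    The five-node EMT circuit (ZEB1, SLUG, miR200, CDH1) coupled to
    PD-L1: miR-200 directly represses PD-L1, and PD-L1 in turn
    represses CDH1.
``stemness_extended``
    The core plus the stemness regulators OCT4, miR145, LIN28 and let7
    (two mutual-inhibition toggles coupled to the EMT axis).
``er_extended``
    The core plus the estrogen receptor isoforms ERa66 and ERa36,
    with mutual antagonism between ERa66 and the pro-mesenchymal group
    and an inhibitory ERa66 -> PD-L1 link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "ACTIVATION",
    "INHIBITION",
    "TopologyError",
    "RegulatoryEdge",
    "NetworkTopology",
    "read_topo",
    "write_topo",
    "builtin_network",
    "BUILTIN_NETWORKS",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"

_TYPE_CODES = {1: ACTIVATION, 2: INHIBITION}
_CODE_OF_SIGN = {ACTIVATION: 1, INHIBITION: 2}


class TopologyError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed directed regulatory interaction."""

    source: str
    target: str
    sign: str  # "activation" or "inhibition"

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise TopologyError(f"unknown edge sign {self.sign!r}")


@dataclass(frozen=True)
class NetworkTopology:
    """Named nodes plus signed edges; node order fixes the state-vector layout."""

    name: str
    nodes: tuple[str, ...]
    edges: tuple[RegulatoryEdge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise TopologyError(f"duplicate node names in {self.name!r}")
        if not self.edges:
            raise TopologyError(f"topology {self.name!r} has no edges")
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in node_set:
                raise TopologyError(f"edge source {e.source!r} is not a declared node")
            if e.target not in node_set:
                raise TopologyError(f"edge target {e.target!r} is not a declared node")
            if (e.source, e.target) in seen:
                raise TopologyError(
                    f"duplicate edge {e.source} -> {e.target} in {self.name!r}"
                )
            seen.add((e.source, e.target))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise TopologyError(
                f"node {name!r} not in topology {self.name!r} (nodes: {', '.join(self.nodes)})"
            ) from None

    def edge_arrays(self):
        """Edge endpoints as index arrays plus +1/-1 signs (numpy)."""
        import numpy as np

        src = np.array([self.node_index(e.source) for e in self.edges], dtype=np.int64)
        tgt = np.array([self.node_index(e.target) for e in self.edges], dtype=np.int64)
        sign = np.array(
            [1 if e.sign == ACTIVATION else -1 for e in self.edges], dtype=np.int64
        )
        return src, tgt, sign


def _parse_rows(lines: Iterable[str], name: str) -> NetworkTopology:
    nodes: list[str] = []
    edges: list[RegulatoryEdge] = []
    seen_nodes: set[str] = set()

    def note(node: str) -> None:
        if node not in seen_nodes:
            seen_nodes.add(node)
            nodes.append(node)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise TopologyError(
                f"line {lineno}: expected 'Source Target Type', got {line!r}"
            )
        src, tgt, code = parts
        if lineno == 1 and not code.lstrip("+-").isdigit():
            continue  # header row
        try:
            code_i = int(code)
        except ValueError:
            raise TopologyError(f"line {lineno}: interaction type {code!r} is not an integer")
        if code_i not in _TYPE_CODES:
            raise TopologyError(
                f"line {lineno}: unknown interaction type {code_i} (expected 1=activation, 2=inhibition)"
            )
        note(src)
        note(tgt)
        edges.append(RegulatoryEdge(src, tgt, _TYPE_CODES[code_i]))
    if not edges:
        raise TopologyError(f"no edges found in topology {name!r}")
    return NetworkTopology(name=name, nodes=tuple(nodes), edges=tuple(edges))


def read_topo(path: str | Path, name: str | None = None) -> NetworkTopology:
    """Read a `.topo` file; node order is first-appearance order."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    return _parse_rows(lines, name or path.stem)


def write_topo(topology: NetworkTopology, path: str | Path) -> None:
    """Write a topology so that ``read_topo`` round-trips it exactly."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write("Source Target Type\n")
            for e in topology.edges:
                fh.write(f"{e.source} {e.target} {_CODE_OF_SIGN[e.sign]}\n")
    except OSError as err:
        raise OSError(f"cannot write topology to {path}: {err}") from err


BUILTIN_NETWORKS = ("core_emt_pdl1", "stemness_extended", "er_extended")


def builtin_network(name: str) -> NetworkTopology:
    """Load one of the shipped networks by name."""
    if name not in BUILTIN_NETWORKS:
        raise TopologyError(
            f"unknown builtin network {name!r}; available: {', '.join(BUILTIN_NETWORKS)}"
        )
    ref = resources.files("emtpdl1").joinpath("data", f"{name}.topo")
    lines = ref.read_text().splitlines()
    return _parse_rows(lines, name)
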