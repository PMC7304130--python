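"""Score-filtered undirected interaction network over catalog genes.

Edges are STRING-style functional associations with an integer combined
score in [0, 1000]; only high-confidence edges (score >= 900 by default)
enter the network.  Two construction modes mirror the two passes of the
prioritization workflow:

* CROSS_GROUP — keep only edges whose endpoints can be assigned to opposite
  catalog groups (predicted vs validated; BOTH satisfies either side);
* EXPANDED — additionally keep within-group edges, which can merge
  cross-group components into larger ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, PreconditionError, RowError
from .target_catalog import Group, TargetCatalog, normalize_gene

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 900
DEFAULT_MIN_COMPONENT_SIZE = 2


class NetworkMode(str, Enum):
    CROSS_GROUP = "CROSS_GROUP"
    EXPANDED = "EXPANDED"


class ExpansionKind(str, Enum):
    """Which within-group edges the EXPANDED network admits."""

    BOTH_WITHIN = "BOTH_WITHIN"
    PREDICTED_ONLY = "PREDICTED_ONLY"


@dataclass(frozen=True, order=True)
class ScoredEdge:
    """Canonical undirected edge: endpoints in lexicographic order, a != b."""

    a: str
    b: str
    combined_score: int


@dataclass
class InteractionNetwork:
    nodes: dict[str, Group]
    edges: list[ScoredEdge]
    mode: NetworkMode

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            (e.a, e.b, e.combined_score) for e in self.edges
        )
        return g

    def degree(self, gene: str) -> int:
        return sum(1 for e in self.edges if gene in (e.a, e.b))

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.a, e.b, e.combined_score, self.mode.value) for e in self.edges]
        return pd.DataFrame(rows, columns=["geneA", "geneB", "combined_score", "mode"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Component:
    id: int
    genes: tuple[str, ...]  # sorted

    def __len__(self) -> int:
        return len(self.genes)

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _canonical(a: str, b: str, score: int) -> ScoredEdge:
    return ScoredEdge(a, b, score) if a < b else ScoredEdge(b, a, score)


def parse_edge_table(
    source,
    alias_map: Mapping[str, str] | None = None,
    strict_aliases: bool = False,
    columns: Sequence[str] = ("geneA", "geneB", "score"),
) -> list[ScoredEdge]:
    """Parse a STRING-links-style edge table into canonical scored edges.

    Accepts tab- or whitespace-delimited text with or without a header;
    duplicate pairs keep the maximum score, self-loops are dropped with a
    warning.  With ``alias_map`` in strict mode an unmappable identifier is a
    row error; otherwise unmapped identifiers pass through as-is.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        if isinstance(source, str) and "\n" in source:
            source = StringIO(source)
        df = pd.read_csv(source, sep=r"\s+", engine="python", dtype=str)
        if list(df.columns[:3]) != list(columns[:3]):
            # header absent: first line was data — reread headerless
            if hasattr(source, "seek"):
                source.seek(0)
            df = pd.read_csv(source, sep=r"\s+", engine="python",
                             dtype=str, header=None)
            if df.shape[1] < 3:
                raise FormatError("edge table needs three columns: geneA geneB score")
            df.columns = list(columns) + [f"extra{i}" for i in range(df.shape[1] - 3)]
    ca, cb, cs = columns[:3]
    for col in (ca, cb, cs):
        if col not in df.columns:
            raise FormatError(f"edge table lacks required column {col!r}")

    best: dict[tuple[str, str], int] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        a = normalize_gene(getattr(row, ca))
        b = normalize_gene(getattr(row, cb))
        if alias_map is not None:
            mapped = []
            for g in (a, b):
                if g in alias_map:
                    mapped.append(alias_map[g])
                elif strict_aliases:
                    raise RowError(f"identifier {g!r} not in alias map", row=idx)
                else:
                    mapped.append(g)
            a, b = mapped
        try:
            score = int(float(getattr(row, cs)))
        except (TypeError, ValueError):
            raise RowError(f"non-numeric score {getattr(row, cs)!r}", row=idx) from None
        if not (0 <= score <= 1000):
            raise RowError(f"combined score {score} outside [0, 1000]", row=idx)
        if a == b:
            logger.warning("dropping self-loop on %s (row %d)", a, idx)
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best or score > best[key]:
            best[key] = score
    return [ScoredEdge(a, b, s) for (a, b), s in sorted(best.items())]


def filter_edges(edges: Iterable[ScoredEdge],
                 min_score: int = DEFAULT_MIN_SCORE) -> list[ScoredEdge]:
    """Keep edges with combined_score >= min_score (inclusive boundary)."""
    return [e for e in edges if e.combined_score >= min_score]


def _cross_group(ga: Group, gb: Group) -> bool:
    # BOTH can stand in for either side; only pure within-group pairs fail.
    if ga == Group.BOTH or gb == Group.BOTH:
        return True
    return ga != gb


def build_network(
    catalog: TargetCatalog,
    edges: Iterable[ScoredEdge],
    mode: NetworkMode | str,
    expansion: ExpansionKind | str = ExpansionKind.BOTH_WITHIN,
) -> InteractionNetwork:
    """Restrict edges to catalog genes and apply the mode's group rule."""
    mode = NetworkMode(mode)
    expansion = ExpansionKind(expansion)
    if not catalog.group:
        raise PreconditionError("catalog is empty")
    kept: list[ScoredEdge] = []
    for e in edges:
        ga = catalog.group.get(e.a)
        gb = catalog.group.get(e.b)
        if ga is None or gb is None:
            continue
        if _cross_group(ga, gb):
            kept.append(e)
        elif mode is NetworkMode.EXPANDED:
            within_predicted = ga == gb == Group.PREDICTED
            if expansion is ExpansionKind.BOTH_WITHIN or within_predicted:
                kept.append(e)
    return InteractionNetwork(dict(catalog.group), sorted(kept), mode)


def connected_components(
    network: InteractionNetwork,
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE,
) -> tuple[list[Component], set[str]]:
    """Decompose the network into connected components.

    Returns ``(components, isolated)`` where components smaller than
    ``min_component_size`` are reported in the isolated set instead.
    Ordering is deterministic: descending size, then lexicographic first gene.
    """
    comps = [tuple(sorted(c)) for c in nx.connected_components(network.graph())]
    comps.sort(key=lambda genes: (-len(genes), genes[0]))
    kept: list[Component] = []
    isolated: set[str] = set()
    for genes in comps:
        if len(genes) >= min_component_size:
            kept.append(Component(id=len(kept), genes=genes))
        else:
            isolated.update(genes)
    return kept, isolated


def components_to_frame(components: Sequence[Component]) -> pd.DataFrame:
    rows = [(c.id, g) for c in components for g in c.genes]
    return pd.DataFrame(rows, columns=["component_id", "gene"])
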