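"""Candidate prioritization: before/after comparison of neuroinflammation enrichment.

Pathways are classed as neuroinflammation-associated by case-insensitive
keyword substring match on their names (toll-like receptor, MyD88, IL-1,
NF-kB, ... by default).  For each component of the EXPANDED network we count
the distinct neuro-classified enriched pathways before expansion (over the
CROSS_GROUP components it absorbed) and after; the component with the
largest gain is the prioritization target, and its genes are ranked by how
many enriched neuro pathways contain them, then by network degree, then by
symbol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import MirprioError
from .interaction_network import Component, InteractionNetwork
from .pathway_enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

# Anchor vocabulary of the innate-immune / TLR signaling family; shipped as a
# config file (keywords.txt) so users can extend it without touching code.
DEFAULT_KEYWORDS = (
    "toll-like receptor", "tlr", "myd88", "interleukin", "il-1",
    "nf-kb", "nfkb", "inflammasome", "innate immune", "traf",
)


@dataclass(frozen=True)
class KeywordSet:
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self):
        if not self.keywords:
            raise MirprioError("keyword set must be non-empty")
        object.__setattr__(
            self, "keywords", tuple(k.strip().lower() for k in self.keywords if k.strip())
        )

    def matches(self, pathway_name: str) -> bool:
        name = pathway_name.lower()
        return any(kw in name for kw in self.keywords)


def load_keywords(path: str | Path) -> KeywordSet:
    """Read one keyword per line; '#' starts a comment."""
    lines = Path(path).read_text().splitlines()
    kws = [ln.split("#", 1)[0].strip() for ln in lines]
    return KeywordSet(tuple(k for k in kws if k))


def classify_pathway(pathway_name: str, keywords: KeywordSet) -> bool:
    """True iff any keyword is a case-insensitive substring of the name."""
    return keywords.matches(pathway_name)


@dataclass(frozen=True)
class ComponentComparison:
    expanded_component_id: int
    genes: tuple[str, ...]
    n_neuro_before: int
    n_neuro_after: int

    @property
    def delta(self) -> int:
        return self.n_neuro_after - self.n_neuro_before


@dataclass(frozen=True)
class Candidate:
    gene: str
    component_id: int
    n_enriched_neuro_pathways: int
    degree: int


@dataclass
class PrioritizationReport:
    comparisons: list[ComponentComparison]
    candidates: list[Candidate]

    def to_dict(self) -> dict:
        return {
            "comparisons": [
                {**asdict(c), "delta": c.delta} for c in self.comparisons
            ],
            "candidates": [asdict(c) for c in self.candidates],
            "prioritized_gene": self.candidates[0].gene if self.candidates else None,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def candidates_frame(self) -> pd.DataFrame:
        rows = [
            (i + 1, c.gene, c.component_id, c.n_enriched_neuro_pathways, c.degree)
            for i, c in enumerate(self.candidates)
        ]
        return pd.DataFrame(rows, columns=[
            "rank", "gene", "component_id", "n_enriched_neuro_pathways", "degree"])


def _neuro_enriched(results: Iterable[EnrichmentResult],
                    keywords: KeywordSet) -> dict[int, set[str]]:
    """component_id -> set of enriched neuro-classified pathway ids."""
    out: dict[int, set[str]] = {}
    for r in results:
        if r.enriched and classify_pathway(r.pathway_name, keywords):
            out.setdefault(r.component_id, set()).add(r.pathway_id)
    return out


def compare_modes(
    cross_components: Sequence[Component],
    cross_results: Sequence[EnrichmentResult],
    expanded_components: Sequence[Component],
    expanded_results: Sequence[EnrichmentResult],
    keywords: KeywordSet = KeywordSet(),
) -> list[ComponentComparison]:
    """Match cross-group components into expanded ones and count neuro pathways.

    Every cross component must be a gene-subset of exactly one expanded
    component (the coarsening guarantee); its enriched neuro pathways
    contribute to that expanded component's "before" count.
    """
    cross_neuro = _neuro_enriched(cross_results, keywords)
    expanded_neuro = _neuro_enriched(expanded_results, keywords)

    containers: dict[int, int] = {}
    for cc in cross_components:
        hits = [ec.id for ec in expanded_components
                if cc.gene_set() <= ec.gene_set()]
        if len(hits) != 1:
            raise MirprioError(
                f"cross component {cc.id} ({cc.genes[:3]}...) contained in "
                f"{len(hits)} expanded components; coarsening violated")
        containers[cc.id] = hits[0]

    comparisons = []
    for ec in expanded_components:
        before: set[str] = set()
        for cc in cross_components:
            if containers[cc.id] == ec.id:
                before |= cross_neuro.get(cc.id, set())
        after = expanded_neuro.get(ec.id, set())
        comparisons.append(ComponentComparison(
            expanded_component_id=ec.id, genes=ec.genes,
            n_neuro_before=len(before), n_neuro_after=len(after)))
    comparisons.sort(key=lambda c: (-c.delta, -c.n_neuro_after,
                                    c.expanded_component_id))
    return comparisons


def rank_candidates(
    comparisons: Sequence[ComponentComparison],
    network: InteractionNetwork,
    expanded_results: Sequence[EnrichmentResult],
    expanded_components: Sequence[Component],
    keywords: KeywordSet = KeywordSet(),
    pathway_genes: dict[str, frozenset[str]] | None = None,
) -> list[Candidate]:
    """Rank genes of the top-delta component.

    Ranking keys: (1) number of enriched neuro-classified pathways containing
    the gene, (2) degree in the expanded network, (3) gene symbol ascending.
    Returns an empty list (with a warning) when no component gained neuro
    pathways.
    """
    if not comparisons or comparisons[0].delta <= 0:
        logger.warning("no component gained neuroinflammation pathways; "
                       "no candidates to rank")
        return []
    top = comparisons[0]
    comp_results = [r for r in expanded_results
                    if r.component_id == top.expanded_component_id
                    and r.enriched and classify_pathway(r.pathway_name, keywords)]
    degrees = {g: network.degree(g) for g in top.genes}
    membership: dict[str, int] = {g: 0 for g in top.genes}
    if pathway_genes is not None:
        for r in comp_results:
            genes = pathway_genes.get(r.pathway_id, frozenset())
            for g in top.genes:
                if g in genes:
                    membership[g] += 1
    cands = [
        Candidate(g, top.expanded_component_id, membership[g], degrees[g])
        for g in top.genes
    ]
    cands.sort(key=lambda c: (-c.n_enriched_neuro_pathways, -c.degree, c.gene))
    return cands


def prioritize(
    cross_components: Sequence[Component],
    cross_results: Sequence[EnrichmentResult],
    expanded_components: Sequence[Component],
    expanded_results: Sequence[EnrichmentResult],
    network: InteractionNetwork,
    keywords: KeywordSet = KeywordSet(),
    pathway_genes: dict[str, frozenset[str]] | None = None,
) -> PrioritizationReport:
    comparisons = compare_modes(cross_components, cross_results,
                                expanded_components, expanded_results, keywords)
    candidates = rank_candidates(comparisons, network, expanded_results,
                                 expanded_components, keywords, pathway_genes)
    return PrioritizationReport(comparisons, candidates)
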