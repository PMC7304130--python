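"""Per-component pathway over-representation analysis.

Each connected component is tested against every pathway gene set with the
hypergeometric upper tail (one-sided over-representation), Bonferroni
corrected over the family of pathways actually tested for that component,
and thresholded at an adjusted p of 0.01.

The tail probability is computed in log space from log-gamma terms so that
large universes do not underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import FormatError, PreconditionError
from .interaction_network import Component
from .target_catalog import normalize_gene

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    entries: dict[str, Pathway]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.entries.values():
            out |= p.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EnrichmentResult:
    component_id: int
    pathway_id: str
    pathway_name: str
    k: int      # overlap
    n: int      # testable component size (within universe)
    K: int      # pathway size within universe
    N: int      # universe size
    p_raw: float
    p_adj: float
    enriched: bool


def parse_gmt(source) -> PathwayCollection:
    """Parse a standard GMT file: ``name <TAB> description <TAB> gene...``.

    Gene symbols are normalized and set-collapsed per line; duplicate pathway
    names get a deterministic numeric suffix.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        lines = source.splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    entries: dict[str, Pathway] = {}
    seen: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: expected name, description and "
                              f"at least one gene, got {len(fields)} field(s)")
        name, description = fields[0].strip(), fields[1].strip()
        genes = frozenset(normalize_gene(g) for g in fields[2:] if g.strip())
        if not genes:
            raise FormatError(f"GMT line {lineno}: pathway {name!r} has no genes")
        pid = name
        if pid in entries:
            seen[name] = seen.get(name, 1) + 1
            pid = f"{name}.{seen[name]}"
        entries[pid] = Pathway(pid, name, genes)
    return PathwayCollection(entries)


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space.

    N balls, K marked, n drawn without replacement; returns the probability
    of drawing at least k marked balls.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise PreconditionError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise PreconditionError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    lo = max(k, K + n - N)
    hi = min(K, n)
    denom = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    xs = np.arange(lo, hi + 1)
    log_terms = (
        gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
        + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
        - denom
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def enrich_component(
    component: Component,
    pathways: PathwayCollection,
    universe: frozenset[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
    min_pathway_size: int = 1,
    max_pathway_size: int | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of one component against every pathway.

    The tested family consists of pathways within the size bounds that
    overlap the component in at least one gene; Bonferroni adjustment is
    over that family.  All tested results are returned, sorted by adjusted p
    then pathway id; the ``enriched`` flag marks ``p_adj < alpha``.
    """
    universe = frozenset(universe)
    N = len(universe)
    comp_genes = component.gene_set() & universe
    n = len(comp_genes)
    if n == 0:
        logger.warning("component %d has no genes in the universe; skipping",
                       component.id)
        return []
    candidates = []
    for p in pathways.entries.values():
        pw_genes = p.genes & universe
        K = len(pw_genes)
        if K < min_pathway_size:
            continue
        if max_pathway_size is not None and K > max_pathway_size:
            continue
        k = len(comp_genes & pw_genes)
        if k < 1:
            continue
        candidates.append((p, k, K))
    m = len(candidates)
    results = []
    for p, k, K in candidates:
        p_raw = hypergeometric_upper_tail(k, K, n, N)
        p_adj = min(1.0, m * p_raw)
        results.append(EnrichmentResult(
            component_id=component.id, pathway_id=p.pathway_id,
            pathway_name=p.name, k=k, n=n, K=K, N=N,
            p_raw=p_raw, p_adj=p_adj, enriched=p_adj < alpha,
        ))
    results.sort(key=lambda r: (r.p_adj, r.pathway_id))
    return results


def enrich_all(
    components: Sequence[Component],
    pathways: PathwayCollection,
    universe: frozenset[str] | set[str],
    alpha: float = DEFAULT_ALPHA,
    min_pathway_size: int = 1,
    max_pathway_size: int | None = None,
    global_family: bool = False,
) -> list[EnrichmentResult]:
    """Run :func:`enrich_component` for every component.

    With ``global_family=True`` the Bonferroni family is the total number of
    tests across all components rather than per component.
    """
    per_comp = [
        enrich_component(c, pathways, universe, alpha,
                         min_pathway_size, max_pathway_size)
        for c in components
    ]
    if global_family:
        m = sum(len(rs) for rs in per_comp)
        rescaled: list[list[EnrichmentResult]] = []
        for rs in per_comp:
            new = []
            for r in rs:
                p_adj = min(1.0, m * r.p_raw)
                new.append(EnrichmentResult(
                    r.component_id, r.pathway_id, r.pathway_name,
                    r.k, r.n, r.K, r.N, r.p_raw, p_adj, p_adj < alpha))
            new.sort(key=lambda r: (r.p_adj, r.pathway_id))
            rescaled.append(new)
        per_comp = rescaled
    return [r for rs in per_comp for r in rs]


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    cols = ["component_id", "pathway_id", "pathway_name",
            "k", "n", "K", "N", "p_raw", "p_adj", "enriched"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results],
                        columns=cols)


def write_results_tsv(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
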