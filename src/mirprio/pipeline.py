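"""End-to-end orchestration: ingest -> filter -> two network builds ->
two enrichment passes -> before/after comparison -> candidate ranking.

`run_pipeline` is the library entry point; the `mirprio` command wraps it.
All defaults equal the study's printed parameters: top 15% of predicted
targets, combined score >= 900, Bonferroni-adjusted p < 0.01.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import interaction_network as net
from . import pathway_enrichment as enr
from . import prioritization as prio
from . import target_catalog as cat
from .errors import MirprioError

logger = logging.getLogger("mirprio")


@dataclass
class PipelineConfig:
    predicted: str | Path = "predicted.tsv"
    validated: str | Path = "validated.tsv"
    edges: str | Path = "edges.tsv"
    pathways: str | Path = "pathways.gmt"
    out: str | Path = "mirprio_out"
    keywords: str | Path | None = None
    top_fraction: float = 0.15
    min_score: int = 900
    alpha: float = 0.01
    min_component_size: int = 2
    expansion_mode: str = net.ExpansionKind.BOTH_WITHIN.value
    universe_mode: str = "PATHWAYS"  # or CATALOG
    gene_col: str = "gene"
    score_col: str = "context_score"
    alias_map: str | Path | None = None

    def __post_init__(self):
        if not (0 < self.top_fraction <= 1):
            raise MirprioError(f"top_fraction {self.top_fraction} outside (0, 1]")
        if not (0 <= self.min_score <= 1001):
            raise MirprioError(f"min_score {self.min_score} outside [0, 1001]")
        if not (0 < self.alpha <= 1):
            raise MirprioError(f"alpha {self.alpha} outside (0, 1]")
        if self.universe_mode not in ("PATHWAYS", "CATALOG"):
            raise MirprioError(f"unknown universe mode {self.universe_mode!r}")
        net.ExpansionKind(self.expansion_mode)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _setup_run_log(outdir: Path, verbose: bool = False) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mirprio")
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
    root.addHandler(handler)
    return handler


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> Path:
    """Run the full prioritization analysis and write the report directory.

    Writes catalog.tsv, network_{cross,expanded}.tsv,
    components_{cross,expanded}.tsv, enrichment_{cross,expanded}.tsv,
    report.json, candidates.tsv and run.log.  Deterministic: the report is a
    pure function of the inputs and the configuration.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir, verbose)
    try:
        logger.info("parameters: %s", json.dumps(
            {k: str(v) for k, v in asdict(config).items()}, sort_keys=True))
        for name in ("predicted", "validated", "edges", "pathways"):
            p = Path(getattr(config, name))
            if not p.exists():
                raise MirprioError(f"[ingest] input file missing: {p}")
            logger.info("input %s: %s sha256=%s", name, p, _sha256(p))

        alias = (cat.read_alias_map(config.alias_map)
                 if config.alias_map else None)

        # -- target catalog
        predicted = cat.parse_predicted_targets(
            str(config.predicted), gene_col=config.gene_col,
            score_col=config.score_col, alias_map=alias)
        validated = cat.parse_validated_targets(
            str(config.validated), gene_col=config.gene_col, alias_map=alias)
        selected = cat.select_top_fraction(predicted, config.top_fraction)
        catalog = cat.build_catalog(selected, {v.gene for v in validated})
        catalog.write_tsv(outdir / "catalog.tsv")
        logger.info("[catalog] %d predicted -> %d selected; %d validated; "
                    "%d catalog genes", len(predicted), len(selected),
                    len(validated), len(catalog.genes))

        # -- networks
        edges = net.parse_edge_table(str(config.edges), alias_map=alias)
        strong = net.filter_edges(edges, config.min_score)
        if not strong:
            raise MirprioError(
                f"[network] empty network: no edges with score >= {config.min_score}")
        logger.info("[network] %d edges, %d at score >= %d",
                    len(edges), len(strong), config.min_score)
        results = {}
        components = {}
        for mode in (net.NetworkMode.CROSS_GROUP, net.NetworkMode.EXPANDED):
            network = net.build_network(catalog, strong, mode,
                                        expansion=config.expansion_mode)
            tag = "cross" if mode is net.NetworkMode.CROSS_GROUP else "expanded"
            network.write_tsv(outdir / f"network_{tag}.tsv")
            comps, isolated = net.connected_components(
                network, config.min_component_size)
            net.components_to_frame(comps).to_csv(
                outdir / f"components_{tag}.tsv", sep="\t", index=False)
            logger.info("[network] %s: %d edges, %d components, %d isolated",
                        tag, len(network.edges), len(comps), len(isolated))
            components[tag] = comps
            if tag == "expanded":
                expanded_network = network

        # -- enrichment
        collection = enr.parse_gmt(str(config.pathways))
        universe = (collection.universe if config.universe_mode == "PATHWAYS"
                    else frozenset(catalog.genes))
        for tag in ("cross", "expanded"):
            res = enr.enrich_all(components[tag], collection, universe,
                                 alpha=config.alpha)
            enr.write_results_tsv(res, outdir / f"enrichment_{tag}.tsv")
            logger.info("[enrichment] %s: %d tests, %d enriched at alpha %g",
                        tag, len(res), sum(r.enriched for r in res), config.alpha)
            results[tag] = res

        # -- prioritization
        keywords = (prio.load_keywords(config.keywords)
                    if config.keywords else prio.KeywordSet())
        pathway_genes = {p.pathway_id: p.genes
                         for p in collection.entries.values()}
        report = prio.prioritize(
            components["cross"], results["cross"],
            components["expanded"], results["expanded"],
            expanded_network, keywords, pathway_genes)
        report.write_json(outdir / "report.json")
        report.candidates_frame().to_csv(
            outdir / "candidates.tsv", sep="\t", index=False)
        if report.candidates:
            logger.info("[prioritization] rank-1 candidate: %s",
                        report.candidates[0].gene)
        else:
            logger.warning("[prioritization] no prioritized gene")
        return outdir
    finally:
        logging.getLogger("mirprio").removeHandler(handler)
        handler.close()
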