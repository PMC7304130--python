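"""Target catalog: ingest predicted and validated miRNA-target tables.

Predicted targets carry a TargetScan-style context score where *more
negative means more confident*; validated targets carry optional free-text
evidence labels.  The catalog records, for every gene, whether it entered
through prediction, experimental validation, or both — the labels drive the
cross-group network construction downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import FormatError, PreconditionError, RowError

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.15


class Group(str, Enum):
    """Provenance of a catalog gene."""

    PREDICTED = "PREDICTED"
    VALIDATED = "VALIDATED"
    BOTH = "BOTH"


@dataclass(frozen=True)
class PredictedTarget:
    gene: str
    context_score: float


@dataclass(frozen=True)
class ValidatedTarget:
    gene: str
    evidence: tuple[str, ...] = ()


@dataclass
class TargetCatalog:
    """Labeled union of the selected-predicted and validated gene sets."""

    predicted_selected: frozenset[str]
    validated: frozenset[str]
    group: dict[str, Group] = field(init=False)

    def __post_init__(self):
        group: dict[str, Group] = {}
        for g in self.predicted_selected | self.validated:
            if g in self.predicted_selected and g in self.validated:
                group[g] = Group.BOTH
            elif g in self.predicted_selected:
                group[g] = Group.PREDICTED
            else:
                group[g] = Group.VALIDATED
        self.group = group

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.group)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((g, grp.value) for g, grp in self.group.items())
        return pd.DataFrame(rows, columns=["gene", "group"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_gene(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Uppercase and strip a gene symbol, optionally routing through an alias map."""
    g = str(symbol).strip().upper()
    if alias_map is not None:
        g = alias_map.get(g, g)
    return g


def _read_table(source) -> pd.DataFrame:
    """Read a delimited table from a path, file object, or literal text."""
    if isinstance(source, pd.DataFrame):
        return source
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = StringIO(source)
    return pd.read_csv(source, sep=None, engine="python", dtype=str)


def parse_predicted_targets(
    source,
    gene_col: str = "gene",
    score_col: str = "context_score",
    alias_map: Mapping[str, str] | None = None,
) -> list[PredictedTarget]:
    """Parse a predicted-target table into normalized, deduplicated records.

    Duplicate genes collapse to the most confident (minimum) context score.

    Raises
    ------
    FormatError
        If the gene or score column is missing.
    RowError
        If a score fails numeric coercion; the row index is reported.
    """
    df = _read_table(source)
    for col in (gene_col, score_col):
        if col not in df.columns:
            raise FormatError(f"predicted-target table lacks required column {col!r} "
                              f"(found: {list(df.columns)})")
    best: dict[str, float] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        gene = normalize_gene(getattr(row, gene_col), alias_map)
        if not gene:
            raise RowError("empty gene symbol", row=idx)
        raw = getattr(row, score_col)
        try:
            score = float(raw)
        except (TypeError, ValueError):
            raise RowError(f"non-numeric context score {raw!r}", row=idx) from None
        if not math.isfinite(score):
            raise RowError(f"non-finite context score {raw!r}", row=idx)
        if gene not in best or score < best[gene]:
            best[gene] = score
    return [PredictedTarget(g, s) for g, s in sorted(best.items())]


def parse_validated_targets(
    source,
    gene_col: str = "gene",
    evidence_col: str = "evidence",
    alias_map: Mapping[str, str] | None = None,
) -> list[ValidatedTarget]:
    """Parse a validated-target table; duplicate genes merge their evidence labels."""
    df = _read_table(source)
    if gene_col not in df.columns:
        raise FormatError(f"validated-target table lacks required column {gene_col!r} "
                          f"(found: {list(df.columns)})")
    merged: dict[str, list[str]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        gene = normalize_gene(getattr(row, gene_col), alias_map)
        if not gene:
            raise RowError("empty gene symbol", row=idx)
        labels = merged.setdefault(gene, [])
        if evidence_col in df.columns:
            ev = getattr(row, evidence_col)
            if isinstance(ev, str) and ev.strip():
                for label in ev.split(";"):
                    label = label.strip()
                    if label and label not in labels:
                        labels.append(label)
    return [ValidatedTarget(g, tuple(ev)) for g, ev in sorted(merged.items())]


def select_top_fraction(
    predicted: Sequence[PredictedTarget],
    fraction: float = DEFAULT_TOP_FRACTION,
    ascending: bool = True,
) -> set[str]:
    """Keep the most confident ``ceil(fraction * n)`` predicted genes.

    With ``ascending=True`` (the context-score convention) lower scores are
    more confident.  Ties at the cut boundary break by ascending gene symbol
    so builds are deterministic.
    """
    if not predicted:
        raise PreconditionError("select_top_fraction requires a non-empty list")
    if not (0 < fraction <= 1):
        raise PreconditionError(f"fraction must lie in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(predicted))
    sign = 1.0 if ascending else -1.0
    ranked = sorted(predicted, key=lambda t: (sign * t.context_score, t.gene))
    return {t.gene for t in ranked[:k]}


def build_catalog(selected: set[str], validated: set[str]) -> TargetCatalog:
    """Assemble the labeled catalog from the two gene sets."""
    if not selected and not validated:
        raise PreconditionError("both target sets are empty; nothing to analyze")
    if not selected:
        logger.warning("no predicted-selected genes; catalog is validated-only")
    if not validated:
        logger.warning("no validated genes; catalog is predicted-only")
    return TargetCatalog(frozenset(selected), frozenset(validated))


def read_alias_map(source) -> dict[str, str]:
    """Read a two-column TSV mapping foreign identifiers to gene symbols."""
    if isinstance(source, str) and "\n" in source:
        source = StringIO(source)
    df = pd.read_csv(source, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("alias map needs two columns: <identifier> <gene symbol>")
    return {
        normalize_gene(a): normalize_gene(b)
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
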