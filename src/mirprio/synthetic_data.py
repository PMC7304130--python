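"""Seeded synthetic fixtures with planted ground truth.

Every input the prioritization pipeline consumes can be generated here:
predicted/validated target tables, a scored edge table with a planted
dense component, a GMT pathway collection with a planted family of
neuro-named pathways concentrated on that component, colocalizing image
pairs with known overlap, and ameboid vs ramified cell masks.

The planted network structure mirrors the study design: a hub gene is
connected cross-group (to validated targets) at high confidence, and
within-group (to predicted targets) by edges that only enter the EXPANDED
network — so expansion merges extra genes into the hub's component.  The
pathway family splits into "core" sets (over-represented in the hub's
component both before and after expansion) and "expansion" sets that
concentrate on the within-group-attached genes and only become
over-represented after expansion.  The hub belongs to every planted
pathway and has the highest degree, so it is the unique expected rank-1
candidate.

All generators are pure functions of (spec, seed): one named NumPy
Generator per fixture, integer-grid geometry, no global RNG state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .quantification import IntensityImagePair

DEFAULT_HUB = "MYD88H"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted network/pathway fixture.

    Defaults describe a desk-scale analogue of the study inputs: a few dozen
    predicted targets of which the most confident 15% survive selection, a
    dozen validated targets, a five-gene planted component around the hub,
    four two-gene background components, and a pathway collection of eight
    neuro-named planted sets plus neutral decoys.
    """

    seed: int = 0
    n_predicted: int = 60
    n_validated: int = 12
    n_both: int = 2
    planted_hub: str = DEFAULT_HUB
    planted_component_size: int = 5
    n_background_components: int = 4
    within_group_edge_rate: float = 0.03
    cross_group_edge_rate: float = 0.03
    score_high_range: tuple[int, int] = (900, 1000)
    score_low_range: tuple[int, int] = (150, 899)
    n_planted_neuro_pathways: int = 8
    n_decoy_pathways: int = 12
    decoy_pathway_size: int = 8
    top_fraction: float = 0.15

    # -- derived roles ----------------------------------------------------
    @property
    def n_planted_validated(self) -> int:
        return (self.planted_component_size - 1) // 2

    @property
    def n_planted_predicted(self) -> int:
        return self.planted_component_size - 1 - self.n_planted_validated

    @property
    def n_selected(self) -> int:
        return math.ceil(self.top_fraction * self.n_predicted)

    @property
    def n_core_pathways(self) -> int:
        return max(1, self.n_planted_neuro_pathways * 3 // 8)

    def validate(self) -> None:
        if self.planted_component_size < 5:
            raise PreconditionError("planted component needs the hub plus at least "
                                    "two validated and two predicted genes")
        need_selected = 1 + self.n_planted_predicted + \
            self.n_background_components + self.n_both
        if self.n_selected < need_selected:
            raise PreconditionError(
                f"top fraction keeps {self.n_selected} predicted genes but the "
                f"planted roles need {need_selected}; increase n_predicted")
        need_validated = self.n_planted_validated + \
            self.n_background_components + self.n_both
        if self.n_validated < need_validated:
            raise PreconditionError(
                f"n_validated={self.n_validated} below the {need_validated} "
                "planted roles")
        if not (self.score_high_range[0] >= 900 and self.score_high_range[1] <= 1000):
            raise PreconditionError("score_high_range must lie within [900, 1000]")
        if not (0 <= self.score_low_range[0] and self.score_low_range[1] <= 899):
            raise PreconditionError("score_low_range must lie within [0, 899]")
        if self.n_predicted <= 0 or self.n_validated <= 0:
            raise PreconditionError("target counts must be positive")


@dataclass
class Roles:
    """Deterministic gene-role assignment implied by a FixtureSpec."""

    hub: str
    planted_predicted: list[str]
    planted_validated: list[str]
    background_predicted: list[str]
    background_validated: list[str]
    both_genes: list[str]
    extra_selected: list[str]
    filler_predicted: list[str]
    filler_validated: list[str]

    @property
    def selected(self) -> list[str]:
        return ([self.hub] + self.planted_predicted + self.background_predicted
                + self.both_genes + self.extra_selected)

    @property
    def predicted_all(self) -> list[str]:
        return self.selected + self.filler_predicted

    @property
    def validated_all(self) -> list[str]:
        return (self.planted_validated + self.background_validated
                + self.both_genes + self.filler_validated)

    @property
    def planted_cross_genes(self) -> set[str]:
        return {self.hub, *self.planted_validated}

    @property
    def planted_expanded_genes(self) -> set[str]:
        return {self.hub, *self.planted_validated, *self.planted_predicted}


def assign_roles(spec: FixtureSpec) -> Roles:
    spec.validate()
    pred_names = [f"G{i:04d}" for i in range(1, spec.n_predicted)]
    i = 0

    def take(n):
        nonlocal i
        chunk = pred_names[i:i + n]
        i += n
        return chunk

    planted_predicted = take(spec.n_planted_predicted)
    background_predicted = take(spec.n_background_components)
    both_genes = take(spec.n_both)
    n_sel_extra = spec.n_selected - 1 - len(planted_predicted) \
        - len(background_predicted) - len(both_genes)
    # any head-room in the selected set goes to extra isolated genes
    extra_selected = take(n_sel_extra)
    filler_predicted = pred_names[i:]
    val_names = [f"G{5000 + j:04d}" for j in range(1, spec.n_validated - spec.n_both + 1)]
    planted_validated = val_names[:spec.n_planted_validated]
    background_validated = val_names[
        spec.n_planted_validated:
        spec.n_planted_validated + spec.n_background_components]
    filler_validated = val_names[
        spec.n_planted_validated + spec.n_background_components:]
    return Roles(
        hub=spec.planted_hub,
        planted_predicted=planted_predicted,
        planted_validated=planted_validated,
        background_predicted=background_predicted,
        background_validated=background_validated,
        both_genes=both_genes,
        extra_selected=extra_selected,
        filler_predicted=filler_predicted,
        filler_validated=filler_validated,
    )


def make_target_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Predicted and validated target tables with the planted selection.

    Selected-role genes draw context scores from a confident band, fillers
    from a clearly worse band, so the top-15% cut recovers exactly the
    planted selection for any seed.
    """
    roles = assign_roles(spec)
    rng = np.random.default_rng(spec.seed)
    selected = roles.selected
    fillers = roles.filler_predicted
    good = np.sort(rng.uniform(-0.95, -0.55, size=len(selected)))
    bad = rng.uniform(-0.45, -0.05, size=len(fillers))
    pred_rows = list(zip(selected, good)) + list(zip(fillers, bad))
    order = rng.permutation(len(pred_rows))
    predicted = pd.DataFrame(
        [pred_rows[j] for j in order], columns=["gene", "context_score"])
    predicted["context_score"] = predicted["context_score"].round(6)

    evidences = ["reporter assay", "western blot", "microarray", "ngs"]
    validated = pd.DataFrame({
        "gene": roles.validated_all,
        "evidence": [evidences[j % len(evidences)]
                     for j in range(len(roles.validated_all))],
    })
    truth = {
        "hub": roles.hub,
        "selected_genes": sorted(selected),
        "planted_cross_genes": sorted(roles.planted_cross_genes),
        "planted_expanded_genes": sorted(roles.planted_expanded_genes),
    }
    return predicted, validated, truth


def make_interaction_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Scored edge table: planted high-confidence structure plus sub-threshold noise.

    The hub connects cross-group to the planted validated genes and
    within-group to the planted predicted genes, all at score >= 900;
    background components are single high-confidence cross-group edges; all
    noise edges score below 900 so the confidence filter removes exactly them.
    """
    roles = assign_roles(spec)
    rng = np.random.default_rng(spec.seed + 1)
    lo_hi = spec.score_high_range
    lo_lo = spec.score_low_range

    def hi():
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    def lo():
        return int(rng.integers(lo_lo[0], lo_lo[1] + 1))

    rows: list[tuple[str, str, int]] = []
    for v in roles.planted_validated:
        rows.append((roles.hub, v, hi()))
    for p in roles.planted_predicted:
        rows.append((roles.hub, p, hi()))
    for p, v in zip(roles.background_predicted, roles.background_validated):
        rows.append((p, v, hi()))

    # sub-threshold noise among all catalog genes
    catalog = sorted(set(roles.selected) | set(roles.validated_all))
    planted_pairs = {tuple(sorted((a, b))) for a, b, _ in rows}
    for ai in range(len(catalog)):
        for bi in range(ai + 1, len(catalog)):
            pair = (catalog[ai], catalog[bi])
            if pair in planted_pairs:
                continue
            if rng.random() < spec.within_group_edge_rate:
                rows.append((*pair, lo()))
    order = rng.permutation(len(rows))
    edges = pd.DataFrame([rows[j] for j in order],
                         columns=["geneA", "geneB", "score"])
    truth = {
        "n_components_cross": 1 + spec.n_background_components,
        "n_components_expanded": 1 + spec.n_background_components,
        "planted_cross_genes": sorted(roles.planted_cross_genes),
        "planted_expanded_genes": sorted(roles.planted_expanded_genes),
        "hub_degree": spec.planted_component_size - 1,
    }
    return edges, truth


def make_pathway_fixture(spec: FixtureSpec) -> tuple[str, dict]:
    """GMT text with planted neuro-named pathways and neutral decoys.

    Core pathways contain the hub and the planted validated genes (plus one
    planted predicted gene) — over-represented in the hub's component in both
    network modes.  Expansion pathways contain the hub and the planted
    predicted genes (plus one planted validated gene) — over-represented only
    after expansion.  Decoys partition a shuffled pool of all catalog genes,
    so the annotation universe is the full catalog regardless of seed.
    """
    roles = assign_roles(spec)
    rng = np.random.default_rng(spec.seed + 2)
    n_core = spec.n_core_pathways
    n_exp = spec.n_planted_neuro_pathways - n_core
    if n_exp < 1:
        raise PreconditionError("need at least one expansion pathway")
    pv, pp = roles.planted_validated, roles.planted_predicted
    lines = []
    planted_names = []
    for i in range(n_core):
        name = f"Toll-Like Receptor Cascade Variant {i + 1}"
        genes = [roles.hub, *pv, pp[i % len(pp)]]
        lines.append("\t".join([name, "planted core"] + genes))
        planted_names.append(name)
    for j in range(n_exp):
        name = f"MyD88-Dependent Signaling Branch {j + 1}"
        genes = [roles.hub, *pp, pv[j % len(pv)]]
        lines.append("\t".join([name, "planted expansion"] + genes))
        planted_names.append(name)

    pool = sorted(set(roles.selected) | set(roles.validated_all)
                  | set(roles.filler_predicted))
    shuffled = list(rng.permutation(pool))
    size = spec.decoy_pathway_size
    need = spec.n_decoy_pathways * size
    stream = (shuffled * (need // len(shuffled) + 1))[:need]
    decoy_themes = ["Metabolism Of Lipoproteins", "Axon Guidance Signaling",
                    "Cell Cycle Checkpoint", "Vesicle Transport Assembly"]
    for j in range(spec.n_decoy_pathways):
        name = f"{decoy_themes[j % len(decoy_themes)]} Set {j + 1}"
        genes = sorted(set(stream[j * size:(j + 1) * size]))
        lines.append("\t".join([name, "decoy"] + genes))
    gmt_text = "\n".join(lines) + "\n"
    truth = {
        "planted_pathway_names": planted_names,
        "n_core_pathways": n_core,
        "n_expansion_pathways": n_exp,
        "expected_neuro_before": n_core,
        "expected_neuro_after": spec.n_planted_neuro_pathways,
        "expected_delta_sign": 1,
    }
    return gmt_text, truth


# ---------------------------------------------------------------- images

def make_coloc_pair(
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    overlap_fraction: float = 0.5,
    arg1_level: float = 200.0,
    iba1_level: float = 150.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    support_side: int = 20,
) -> tuple[IntensityImagePair, dict]:
    """Two-channel image pair with a known colocalizing overlap fraction.

    The Arg1-positive support is a centered square block of uniform
    intensity; the Iba1-positive support covers the requested fraction of
    those pixels (raster order), so the noiseless thresholded M2 equals
    ``round(overlap_fraction * area) / area`` exactly.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise PreconditionError("overlap_fraction must lie in [0, 1]")
    h, w = shape
    if support_side > min(h, w):
        raise PreconditionError("support does not fit in the canvas")
    rng = np.random.default_rng(seed)
    arg1 = np.full(shape, background)
    iba1 = np.full(shape, background)
    r0 = (h - support_side) // 2
    c0 = (w - support_side) // 2
    arg1[r0:r0 + support_side, c0:c0 + support_side] = arg1_level
    area = support_side * support_side
    n_overlap = int(round(overlap_fraction * area))
    rr, cc = np.nonzero(arg1 > background)
    iba1[rr[:n_overlap], cc[:n_overlap]] = iba1_level
    expected_m2 = n_overlap / area
    if noise_sd > 0:
        arg1 = np.clip(arg1 + rng.normal(0, noise_sd, shape), 0, None)
        iba1 = np.clip(iba1 + rng.normal(0, noise_sd, shape), 0, None)
    pair = IntensityImagePair(arg1, iba1)
    truth = {"expected_m2": expected_m2, "n_overlap": n_overlap,
             "arg1_area": area, "noise_sd": noise_sd}
    return pair, truth


class Regime:
    AMEBOID = "AMEBOID"
    RAMIFIED = "RAMIFIED"


def _disk(radius: int) -> np.ndarray:
    d = 2 * radius + 1
    yy, xx = np.mgrid[:d, :d] - radius
    return (yy ** 2 + xx ** 2 <= radius ** 2)


def _ameboid_blob(radius: int) -> np.ndarray:
    # octagonal disk: flat and 45-degree edges keep the pixel union close to
    # its own convex hull, as an activated soma without processes should be
    d = 2 * radius + 1
    yy, xx = np.mgrid[:d, :d] - radius
    cut = int(round(1.4 * radius))
    return ((np.abs(yy) <= radius) & (np.abs(xx) <= radius)
            & (np.abs(yy) + np.abs(xx) <= cut))


def _ramified_cell(soma_radius: int, branch_len: int) -> np.ndarray:
    side = 2 * (soma_radius + branch_len) + 1
    c = side // 2
    cell = np.zeros((side, side), dtype=bool)
    soma = _disk(soma_radius)
    cell[c - soma_radius:c + soma_radius + 1,
         c - soma_radius:c + soma_radius + 1] = soma
    # four one-pixel-wide processes radiating from the soma
    cell[c, c + soma_radius:c + soma_radius + branch_len + 1] = True
    cell[c, c - soma_radius - branch_len:c - soma_radius + 1] = True
    cell[c + soma_radius:c + soma_radius + branch_len + 1, c] = True
    cell[c - soma_radius - branch_len:c - soma_radius + 1, c] = True
    return cell


def make_morphology_masks(
    seed: int = 0,
    regime: str = Regime.AMEBOID,
    n_cells: int = 9,
    canvas: tuple[int, int] = (192, 192),
) -> tuple[np.ndarray, dict]:
    """Labeled mask of synthetic cells: ameboid disks or ramified plus-shapes.

    Cells are placed on a non-touching grid; labels run 1..n_cells.
    """
    if n_cells < 1:
        raise PreconditionError("need at least one cell")
    rng = np.random.default_rng(seed)
    h, w = canvas
    per_row = math.ceil(math.sqrt(n_cells))
    cell_box = min(h, w) // per_row
    if cell_box < 34:
        raise PreconditionError("canvas too small to place the requested cells")
    mask = np.zeros(canvas, dtype=np.int32)
    for idx in range(n_cells):
        row, col = divmod(idx, per_row)
        if regime == Regime.AMEBOID:
            radius = int(rng.integers(7, 11))
            stamp = _ameboid_blob(radius)
        elif regime == Regime.RAMIFIED:
            soma = int(rng.integers(2, 4))
            branch = int(rng.integers(9, 13))
            stamp = _ramified_cell(soma, branch)
        else:
            raise PreconditionError(f"unknown regime {regime!r}")
        sh, sw = stamp.shape
        y0 = row * cell_box + (cell_box - sh) // 2
        x0 = col * cell_box + (cell_box - sw) // 2
        mask[y0:y0 + sh, x0:x0 + sw][stamp] = idx + 1
    truth = {"regime": regime, "n_cells": n_cells,
             "labels": list(range(1, n_cells + 1))}
    return mask, truth


# ---------------------------------------------------------------- directory

def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Write predicted.tsv, validated.tsv, edges.tsv, pathways.gmt and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    predicted, validated, t1 = make_target_fixture(spec)
    edges, t2 = make_interaction_fixture(spec)
    gmt_text, t3 = make_pathway_fixture(spec)
    predicted.to_csv(outdir / "predicted.tsv", sep="\t", index=False)
    validated.to_csv(outdir / "validated.tsv", sep="\t", index=False)
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    (outdir / "pathways.gmt").write_text(gmt_text)
    truth = {"spec": asdict(spec), **t1, **t2, **t3}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return outdir
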