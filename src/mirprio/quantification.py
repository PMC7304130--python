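"""Quantification formulas used around the network analysis.

Implements, exactly as stated, the study readout computations:

* edema-corrected lesion volume as a percentage of the contralateral
  hemisphere,
* relative mRNA expression by the 2^-ddCt method,
* absolute miRNA copy number from a log-linear standard curve,
* Pearson and thresholded Manders M2 colocalization coefficients for
  two-channel immunofluorescence images,
* per-cell morphometric descriptors of labeled Iba1+ regions.

Perimeter convention: the total exposed pixel-edge length of a region's
pixel union.  It is exact and deterministic on integer grids, but inflates
perimeters of smooth shapes relative to anti-aliased estimators — so
circularity values are comparable only within this convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

from .errors import PreconditionError

logger = logging.getLogger(__name__)

DEFAULT_T_ARG1 = 50.0
DEFAULT_T_IBA1 = 100.0


# ---------------------------------------------------------------- volumes

@dataclass(frozen=True)
class HemisphereVolumes:
    """Hemisphere and lesion volumes in one consistent unit (e.g. mm^3)."""

    v_contra: float
    v_ipsi: float
    v_lesion: float

    def __post_init__(self):
        if min(self.v_contra, self.v_ipsi, self.v_lesion) < 0:
            raise PreconditionError("volumes must be non-negative")
        if self.v_lesion > self.v_ipsi:
            raise PreconditionError("lesion volume cannot exceed the ipsilateral "
                                    "hemisphere volume")


def lesion_volume_percent(v: HemisphereVolumes) -> float:
    """Edema-corrected lesion volume as a percentage.

    100 * (contra - (ipsi - lesion)) / contra.  The correction subtracts the
    surviving ipsilateral tissue from the contralateral reference, so edema
    (ipsi > contra) deflates and shrinkage inflates the plain lesion/contra
    ratio.
    """
    if v.v_contra <= 0:
        raise PreconditionError("contralateral volume must be positive")
    return 100.0 * (v.v_contra - (v.v_ipsi - v.v_lesion)) / v.v_contra


# ---------------------------------------------------------------- qPCR

@dataclass(frozen=True)
class CtQuad:
    """Threshold cycles: target and reference gene, in sample and control."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_control: float
    ct_ref_control: float


def fold_change_ddct(q: CtQuad) -> float:
    """Relative expression 2^-ddCt, target normalized to reference and control."""
    cts = (q.ct_target_sample, q.ct_ref_sample,
           q.ct_target_control, q.ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise PreconditionError(f"non-finite Ct value in {cts}")
    ddct = ((q.ct_target_sample - q.ct_ref_sample)
            - (q.ct_target_control - q.ct_ref_control))
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Fit the absolute-quantification standard curve from dilution points.

    Requires at least two distinct positive copy numbers; slope should come
    out negative for a working amplification (one Ct lost per doubling gives
    slope = -1/log10(2) ~= -3.32).
    """
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape or copies.ndim != 1:
        raise PreconditionError("copies and ct must be equal-length 1-D sequences")
    if np.any(copies <= 0):
        raise PreconditionError("copy numbers must be positive")
    x = np.log10(copies)
    if np.unique(x).size < 2:
        raise PreconditionError("need at least two distinct copy numbers")
    slope, intercept = np.polyfit(x, ct, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((ct - fitted) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope >= 0:
        logger.warning("standard-curve slope %.3f is non-negative; check inputs",
                       slope)
    return StandardCurve(float(slope), float(intercept), r2)


def copies_from_ct(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept) / slope)."""
    if curve.slope == 0:
        raise PreconditionError("standard curve has zero slope")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


# ---------------------------------------------------------------- colocalization

@dataclass
class IntensityImagePair:
    """Two aligned single-channel intensity images (Arg1 and Iba1 roles)."""

    ch_arg1: np.ndarray
    ch_iba1: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.ch_arg1 = np.asarray(self.ch_arg1, dtype=float)
        self.ch_iba1 = np.asarray(self.ch_iba1, dtype=float)
        if self.ch_arg1.shape != self.ch_iba1.shape:
            raise PreconditionError("channel shapes differ: "
                                    f"{self.ch_arg1.shape} vs {self.ch_iba1.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.ch_arg1.shape:
                raise PreconditionError("mask shape differs from channels")

    def _flat(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is None:
            return self.ch_arg1.ravel(), self.ch_iba1.ravel()
        return self.ch_arg1[self.mask], self.ch_iba1[self.mask]


def pearson_colocalization(pair: IntensityImagePair) -> float:
    """Sample Pearson correlation of the two channels over the (masked) pixels."""
    a, b = pair._flat()
    if a.size < 2:
        raise PreconditionError("need at least 2 pixels for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise PreconditionError("correlation undefined for a constant channel")
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / math.sqrt(np.dot(a, a) * np.dot(b, b)))


def manders_m2(
    pair: IntensityImagePair,
    t_arg1: float = DEFAULT_T_ARG1,
    t_iba1: float = DEFAULT_T_IBA1,
    require_both: bool = True,
) -> float:
    """Thresholded Manders M2: Arg1-intensity fraction colocalizing with Iba1.

    Default (``require_both=True``): numerator sums Arg1 intensity over
    pixels above both thresholds, denominator over pixels above the Arg1
    threshold.  With ``require_both=False`` the numerator condition uses
    only the Iba1 threshold and the denominator is total Arg1 intensity
    (the unthresholded-partner variant).  Returns 0 with a warning when the
    denominator is empty.
    """
    a, b = pair._flat()
    iba1_pos = b > t_iba1
    if require_both:
        arg1_pos = a > t_arg1
        num = float(a[arg1_pos & iba1_pos].sum())
        den = float(a[arg1_pos].sum())
    else:
        num = float(a[iba1_pos].sum())
        den = float(a.sum())
    if den == 0:
        logger.warning("no Arg1-positive signal; M2 reported as 0")
        return 0.0
    return num / den


# ---------------------------------------------------------------- morphology

@dataclass(frozen=True)
class ShapeDescriptors:
    """Per-region morphometrics of a labeled cell mask (pixel units)."""

    label: int
    area: float
    perimeter: float
    area_perimeter_ratio: float
    compactness: float
    solidity: float
    eccentricity: float
    equiv_diameter: float
    circularity: float
    roundness: float


def _convex_hull_area(mask: np.ndarray) -> float:
    """Area of the convex hull polygon of the pixel-square union (exact)."""
    from scipy.spatial import ConvexHull

    ii, jj = np.nonzero(mask)
    corners = np.concatenate([
        np.stack([ii + di, jj + dj], axis=1)
        for di in (0, 1) for dj in (0, 1)
    ])
    corners = np.unique(corners, axis=0)
    if len(corners) < 3:
        return float(mask.sum())
    return float(ConvexHull(corners).volume)


def _exposed_edge_perimeter(mask: np.ndarray) -> int:
    """Boundary length of the pixel union: 4*area - 2*(4-adjacent pairs)."""
    m = mask.astype(np.int64)
    area = int(m.sum())
    pairs_h = int((m[:, :-1] & m[:, 1:]).sum())
    pairs_v = int((m[:-1, :] & m[1:, :]).sum())
    return 4 * area - 2 * (pairs_h + pairs_v)


def shape_descriptors(label_mask: np.ndarray) -> list[ShapeDescriptors]:
    """Compute the descriptor panel for every positive label in the mask.

    area = pixel count; perimeter = exposed pixel-edge length;
    circularity = 4*pi*area / perimeter^2; equiv_diameter = sqrt(4*area/pi);
    solidity = area / convex-hull area, with the hull taken as the exact
    convex polygon of the pixel-square union; eccentricity from the
    second-moment ellipse; roundness = 4*area / (pi * major^2);
    compactness = sqrt(4*area/pi) / major.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.ndim != 2 or not np.issubdtype(label_mask.dtype, np.integer):
        raise PreconditionError("label mask must be a 2-D integer array")
    if label_mask.min() < 0:
        raise PreconditionError("labels must be positive on zero background")
    out: list[ShapeDescriptors] = []
    for rp in regionprops(label_mask):
        area = float(rp.area)
        if area < 1:
            logger.warning("label %d has empty region; skipped", rp.label)
            continue
        mask = label_mask[rp.slice] == rp.label
        perimeter = float(_exposed_edge_perimeter(mask))
        major = float(rp.axis_major_length)
        equiv = math.sqrt(4.0 * area / math.pi)
        out.append(ShapeDescriptors(
            label=int(rp.label),
            area=area,
            perimeter=perimeter,
            area_perimeter_ratio=area / perimeter,
            compactness=(equiv / major) if major > 0 else 1.0,
            solidity=min(1.0, area / _convex_hull_area(mask)),
            eccentricity=float(rp.eccentricity),
            equiv_diameter=equiv,
            circularity=4.0 * math.pi * area / perimeter ** 2,
            roundness=(4.0 * area / (math.pi * major ** 2)) if major > 0 else 1.0,
        ))
    return out


def descriptors_to_rows(descs: list[ShapeDescriptors]) -> list[dict]:
    from dataclasses import asdict
    return [asdict(d) for d in descs]
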