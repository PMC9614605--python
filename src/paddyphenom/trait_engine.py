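"""Image-based traits (i-traits) from tip coordinates and masks.

Top-view traits: number of leaves (NL, = number of detected tips), convex
hull area of the tip coordinates (CHA), axis-aligned bounding box area
(BBA), plant aspect ratio (PAR = width / length), and leaves per convex
hull area (NLPCHA, a canopy-density trait). Side-view traits: plant
height and the plant elongation rate (PER, slope of height over time
snaps). All areas/lengths are converted from pixels with a scene-level
``cm_per_pixel`` calibration constant.

Degenerate geometry never raises: zero-area hulls give CHA = 0 and the
dependent ratios come back as NaN ("undefined-trait" flags).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plantseg_tips import PlantMask, TipSet


@dataclass
class TraitRecord:
    """Per-plant, per-time-snap i-trait vector."""

    genotype_id: str
    treatment: str
    time_snap: int
    NL: int
    CHA_cm2: float
    BBA_cm2: float
    PAR: float
    NLPCHA_per_cm2: float
    width_cm: float
    length_cm: float
    height_cm: float = float("nan")


def count_leaves(tips: TipSet) -> int:
    """NL: one visible tip per leaf, so the tip count is the leaf count."""
    return len(tips)


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> np.ndarray:
    """Convex hull of 2-D points, counter-clockwise, via monotone chain.

    Collinear boundary points are dropped. Degenerate inputs (a single
    point, two points, or all-collinear sets) return the extreme point
    pair (or the single point) rather than raising, since real tip sets
    can be degenerate for tiny plants.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("convex hull of an empty point set is undefined")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of points")
    uniq = sorted({(float(x), float(y)) for x, y in pts})
    if len(uniq) == 1:
        return np.array(uniq)
    lower: list[tuple[float, float]] = []
    for p in uniq:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(uniq):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # all points collinear -> extreme pair
        return np.array([uniq[0], uniq[-1]])
    return np.array(hull)


def hull_area(vertices, cm_per_pixel: float = 1.0) -> float:
    """Shoelace polygon area of hull vertices, converted to cm^2.

    Degenerate hulls (fewer than 3 vertices) have zero area.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    area_px = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_px * cm_per_pixel**2)


def bounding_box_area(points_or_mask, cm_per_pixel: float = 1.0) -> tuple[float, float, float]:
    """Axis-aligned extent: returns (BBA_cm2, width_cm, length_cm).

    Width is the x-extent and length the y-extent. Accepts either an
    (n, 2) point array or a boolean mask.
    """
    arr = np.asarray(points_or_mask)
    if arr.dtype == bool:
        if not arr.any():
            raise ValueError("empty mask has no bounding box")
        rows, cols = np.nonzero(arr)
        w_px = float(cols.max() - cols.min())
        l_px = float(rows.max() - rows.min())
    else:
        pts = arr.astype(float)
        if pts.size == 0:
            raise ValueError("empty point set has no bounding box")
        pts = pts.reshape(-1, 2)
        w_px = float(pts[:, 0].max() - pts[:, 0].min())
        l_px = float(pts[:, 1].max() - pts[:, 1].min())
    width_cm = w_px * cm_per_pixel
    length_cm = l_px * cm_per_pixel
    return width_cm * length_cm, width_cm, length_cm


def plant_aspect_ratio(width_cm: float, length_cm: float) -> float:
    """PAR = width / length; NaN (undefined flag) when length is zero."""
    if length_cm == 0:
        return float("nan")
    return width_cm / length_cm


def leaves_per_hull(NL: int, CHA_cm2: float) -> float:
    """NLPCHA = NL / CHA; NaN when the hull area is zero (and NL > 0)."""
    if NL < 0 or CHA_cm2 < 0:
        raise ValueError("NL and CHA must be non-negative")
    if NL == 0:
        return 0.0
    if CHA_cm2 == 0:
        return float("nan")
    return NL / CHA_cm2


def plant_height(side_mask: PlantMask, baseline_row: int, cm_per_pixel: float) -> float:
    """Side-view height: baseline row minus topmost foreground row, in cm."""
    mask = np.asarray(side_mask, dtype=bool)
    if not 0 <= baseline_row < mask.shape[0]:
        raise ValueError("baseline_row outside the image")
    rows = np.nonzero(mask.any(axis=1))[0]
    if rows.size == 0:
        return 0.0
    return float((baseline_row - rows.min()) * cm_per_pixel)


def elongation_rate(series) -> float:
    """PER: least-squares slope of height (cm) over time snap.

    ``series`` is an iterable of (time_snap, height_cm) pairs with
    strictly increasing snaps; at least two points are required.
    """
    pts = sorted((int(t), float(hgt)) for t, hgt in series)
    if len(pts) < 2:
        raise ValueError("elongation rate needs at least two time points")
    snaps = [t for t, _ in pts]
    if len(set(snaps)) != len(snaps):
        raise ValueError("time snaps must be strictly increasing")
    x = np.array(snaps, dtype=float)
    y = np.array([hgt for _, hgt in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def traits_from_tips(
    tips: TipSet,
    cm_per_pixel: float,
    genotype_id: str = "",
    treatment: str = "",
    time_snap: int = 0,
    height_cm: float = float("nan"),
) -> TraitRecord:
    """Assemble the full top-view TraitRecord from one image's tip set."""
    nl = count_leaves(tips)
    if nl == 0:
        return TraitRecord(genotype_id, treatment, time_snap, 0, 0.0, 0.0,
                           float("nan"), 0.0, 0.0, 0.0, height_cm)
    centers = tips.centers()
    hull = convex_hull(centers)
    cha = hull_area(hull, cm_per_pixel)
    bba, width_cm, length_cm = bounding_box_area(centers, cm_per_pixel)
    return TraitRecord(
        genotype_id=genotype_id,
        treatment=treatment,
        time_snap=time_snap,
        NL=nl,
        CHA_cm2=cha,
        BBA_cm2=bba,
        PAR=plant_aspect_ratio(width_cm, length_cm),
        NLPCHA_per_cm2=leaves_per_hull(nl, cha),
        width_cm=width_cm,
        length_cm=length_cm,
        height_cm=height_cm,
    )
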