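"""Classical leaf-tip detection and YOLO-format label I/O.

The leaf-counting hypothesis is that each rice leaf carries exactly one
visible tip, so counting tips counts leaves. The classical chain here is
excess-green segmentation -> morphological skeleton -> skeleton endpoints,
with spur pruning and endpoint merging as post-processing. YOLO-format
label files (``class cx cy w h``, normalised to [0,1], one line per tip)
are read and written bit-stably so externally produced detections can
enter the pipeline unchanged.

Coordinate convention: 0-based pixel indices, x rightward, y downward;
box centers are continuous pixel coordinates (pixel = normalised value x
image dimension).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

logger = logging.getLogger(__name__)

#: binary plant mask, same shape as the source image (foreground = plant)
PlantMask = np.ndarray


class SkeletonContractError(ValueError):
    """Raised when an input claimed to be a 1-px skeleton is not."""


@dataclass(frozen=True)
class Tip:
    """One tip detection/annotation: center + box, pixel units."""

    cx_px: float
    cy_px: float
    w_px: float
    h_px: float
    confidence: float = 1.0


@dataclass
class TipSet:
    """All tip boxes for one image."""

    image_id: str
    image_width_px: int
    image_height_px: int
    tips: list[Tip] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tips)

    def centers(self) -> np.ndarray:
        """(n, 2) array of (cx, cy) centers in pixels."""
        if not self.tips:
            return np.empty((0, 2))
        return np.array([[t.cx_px, t.cy_px] for t in self.tips])


def segment_plant(
    image: np.ndarray, exg_threshold: float = 0.0, min_area_px: int = 32
) -> PlantMask:
    """Segment plant pixels by the excess-green index ExG = 2G - R - B.

    Foreground is ExG > ``exg_threshold``; connected components smaller
    than ``min_area_px`` (noise specks) are removed.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    img = image.astype(np.int64)
    exg = 2 * img[..., 1] - img[..., 0] - img[..., 2]
    mask = exg > exg_threshold
    if min_area_px > 1 and mask.any():
        labels, n = ndimage.label(mask)
        if n:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_area_px) + 1
            mask = np.isin(labels, keep)
    return mask


def _ring(skel: np.ndarray, r: int, c: int) -> list[bool]:
    """8-neighborhood of (r, c) in clockwise ring order starting north."""
    h, w = skel.shape

    def at(rr: int, cc: int) -> bool:
        return bool(skel[rr, cc]) if 0 <= rr < h and 0 <= cc < w else False

    return [at(r - 1, c), at(r - 1, c + 1), at(r, c + 1), at(r + 1, c + 1),
            at(r + 1, c), at(r + 1, c - 1), at(r, c - 1), at(r - 1, c - 1)]


# ring order N, NE, E, SE, S, SW, W, NW; offsets for the 8 neighbors
_RING_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_RING_ADJ = [
    [j for j in range(8) if j != i
     and max(abs(_RING_OFFSETS[i][0] - _RING_OFFSETS[j][0]),
             abs(_RING_OFFSETS[i][1] - _RING_OFFSETS[j][1])) <= 1]
    for i in range(8)
]


def _deletable(skel: np.ndarray, r: int, c: int) -> bool:
    """Simple-point test: removal preserves topology and endpoints.

    Deletable iff the foreground 8-neighbors form a single 8-connected
    component, at least one 4-neighbor is background (no hole is
    created), and the pixel is not an endpoint.
    """
    ring = _ring(skel, r, c)
    fg = [i for i in range(8) if ring[i]]
    if len(fg) < 2:               # endpoint or isolated: keep
        return False
    if ring[0] and ring[2] and ring[4] and ring[6]:  # all 4-neighbors set
        return False
    seen = {fg[0]}
    stack = [fg[0]]
    while stack:
        i = stack.pop()
        for j in _RING_ADJ[i]:
            if ring[j] and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(fg)


def _thin_residual_blocks(skel: np.ndarray) -> np.ndarray:
    """Erase redundant pixels so no fully set 2x2 block survives.

    Thinning algorithms occasionally leave 2x2 blocks at staircase turns;
    one pixel per block is always topologically deletable.
    """
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        blocks = np.argwhere(
            skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        )
        for r, c in blocks:
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = int(r) + dr, int(c) + dc
                if skel[rr, cc] and _deletable(skel, rr, cc):
                    skel[rr, cc] = False
                    changed = True
                    break
    return skel


def skeletonize_mask(mask: PlantMask) -> PlantMask:
    """One-pixel-wide 8-connected medial skeleton (topology-preserving).

    A post-pass erases the residual 2x2 staircase blocks that thinning
    can leave, so the output honours the 1-px-wide contract exactly.
    """
    return _thin_residual_blocks(_sk_skeletonize(np.asarray(mask, dtype=bool)))


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def _endpoints(skel: np.ndarray) -> np.ndarray:
    """(n, 2) array of (row, col) endpoint pixels (exactly one 8-neighbor)."""
    nc = _neighbor_counts(skel)
    return np.argwhere(skel & (nc == 1))


def _check_one_px_wide(skel: np.ndarray) -> None:
    """Raise unless the skeleton is irreducibly thin.

    A fully set 2x2 block is a contract violation only when one of its
    pixels could be deleted without changing topology; blocks at the
    crossing of two diagonal strokes are irreducible and accepted.
    """
    if skel.shape[0] > 1 and skel.shape[1] > 1:
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                if _deletable(skel, int(r) + dr, int(c) + dc):
                    raise SkeletonContractError(
                        "skeleton is not one pixel wide (reducible 2x2 block)"
                    )


def _prune_spurs(skel: np.ndarray, prune_len_px: int) -> np.ndarray:
    """Remove terminal branches shorter than ``prune_len_px``.

    Walks inward from each endpoint; if a junction (>2 neighbors) is
    reached within the limit, the walked pixels are spur pixels and are
    erased. Branches that end at another endpoint (isolated arcs) are kept.
    """
    if prune_len_px <= 0:
        return skel
    skel = skel.copy()
    nc = _neighbor_counts(skel)
    h, w = skel.shape
    to_clear: list[tuple[int, int]] = []
    for r0, c0 in _endpoints(skel):
        path = [(int(r0), int(c0))]
        prev = None
        r, c = int(r0), int(c0)
        for _ in range(prune_len_px):
            nxt = None
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and skel[rr, cc] and (rr, cc) != prev:
                        nxt = (rr, cc)
                        break
                if nxt:
                    break
            if nxt is None:
                break
            if nc[nxt] > 2:          # reached a junction: everything walked is spur
                to_clear.extend(path)
                break
            prev, (r, c) = (r, c), nxt
            path.append(nxt)
    for r, c in to_clear:
        skel[r, c] = False
    return skel


def _geodesic_reach(skel: np.ndarray, start: tuple[int, int], budget: int) -> set[tuple[int, int]]:
    """Skeleton pixels reachable from ``start`` within ``budget`` 8-steps."""
    h, w = skel.shape
    seen = {start}
    frontier = [start]
    for _ in range(budget):
        nxt = []
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and skel[rr, cc]
                            and (rr, cc) not in seen):
                        seen.add((rr, cc))
                        nxt.append((rr, cc))
        frontier = nxt
        if not frontier:
            break
    return seen


def _merge_close(points: np.ndarray, radius: float, skel: np.ndarray | None = None) -> np.ndarray:
    """Merge duplicate endpoints closer than ``radius``; clusters -> centroids.

    With a skeleton given, two endpoints are duplicates only if they are
    also geodesically close on the skeleton (within 3x the radius in
    8-connected steps): forked-tip artifacts satisfy this, while distinct
    tips of different blades that merely land near each other are
    connected only through the culm and are kept separate.
    """
    n = len(points)
    if n <= 1 or radius <= 0:
        return points
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    reach: list[set[tuple[int, int]] | None] = [None] * n
    if skel is not None:
        budget = int(math.ceil(3 * radius))
        reach = [
            _geodesic_reach(skel, (int(round(y)), int(round(x))), budget)
            for x, y in points
        ]
    d = np.hypot(points[:, 0, None] - points[None, :, 0],
                 points[:, 1, None] - points[None, :, 1])
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] >= radius:
                continue
            if reach[i] is not None and not (reach[i] & reach[j]):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return np.array([points[idx].mean(axis=0) for _, idx in sorted(groups.items())])


def detect_tips(
    skeleton: PlantMask,
    prune_len_px: int = 3,
    merge_radius_px: float | None = None,
    culm_exclusion_px: float = 0.0,
    box_size_px: int = 16,
) -> TipSet:
    """Extract leaf tips as skeleton endpoints.

    An endpoint is a skeleton pixel with exactly one 8-neighbor. Spurs
    shorter than ``prune_len_px`` are pruned first; endpoints within
    ``merge_radius_px`` of each other are merged to their centroid
    (default: half the box size); endpoints within ``culm_exclusion_px``
    of the skeleton centroid are discarded (the culm area is crowded and
    its leaves uncountable; off by default). Each surviving endpoint is
    emitted as a ``box_size_px`` square with confidence 1.0.
    """
    skel = np.asarray(skeleton, dtype=bool)
    _check_one_px_wide(skel)
    if merge_radius_px is None:
        merge_radius_px = box_size_px / 2.0
    h, w = skel.shape
    skel = _prune_spurs(skel, prune_len_px)
    eps = _endpoints(skel)
    pts = eps[:, ::-1].astype(float)  # (row, col) -> (x, y)
    if len(pts) and culm_exclusion_px > 0:
        centroid = np.argwhere(skel).mean(axis=0)[::-1]
        keep = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1]) > culm_exclusion_px
        pts = pts[keep]
    pts = _merge_close(pts, merge_radius_px, skel=skel)
    tips = [
        Tip(cx_px=float(x), cy_px=float(y), w_px=float(box_size_px),
            h_px=float(box_size_px), confidence=1.0)
        for x, y in pts
    ]
    return TipSet(image_id="", image_width_px=w, image_height_px=h, tips=tips)


def detect_tips_in_image(
    image: np.ndarray,
    exg_threshold: float = 0.0,
    min_area_px: int = 32,
    prune_len_px: int = 3,
    merge_radius_px: float | None = None,
    culm_exclusion_px: float = 0.0,
    box_size_px: int = 16,
) -> TipSet:
    """Full classical chain: segment -> skeletonize -> endpoint tips."""
    mask = segment_plant(image, exg_threshold, min_area_px)
    skel = skeletonize_mask(mask)
    return detect_tips(skel, prune_len_px, merge_radius_px, culm_exclusion_px, box_size_px)


def read_yolo_labels(path: str | Path, image_width_px: int, image_height_px: int) -> TipSet:
    """Read a YOLO-format label file into pixel coordinates.

    Lines are ``class cx cy w h`` with values normalised to [0,1]. Only
    class 0 (leaf tip) is accepted; other classes are skipped with a
    logged warning. Out-of-range coordinates reject the line with an error.
    """
    path = Path(path)
    tips: list[Tip] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{ln}: expected 'class cx cy w h', got {line!r}")
        cls = int(float(parts[0]))
        vals = [float(v) for v in parts[1:5]]
        if cls != 0:
            logger.warning("%s:%d: skipping non-tip class %d", path, ln, cls)
            continue
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"{path}:{ln}: normalised coordinate out of [0, 1]: {line!r}")
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        tips.append(
            Tip(
                cx_px=vals[0] * image_width_px,
                cy_px=vals[1] * image_height_px,
                w_px=vals[2] * image_width_px,
                h_px=vals[3] * image_height_px,
                confidence=conf,
            )
        )
    return TipSet(
        image_id=path.stem,
        image_width_px=image_width_px,
        image_height_px=image_height_px,
        tips=tips,
    )


def write_yolo_labels(tips: TipSet, path: str | Path) -> Path:
    """Write a TipSet as a YOLO-format label file (6-decimal normalisation)."""
    path = Path(path)
    w, h = tips.image_width_px, tips.image_height_px
    lines = [
        f"0 {t.cx_px / w:.6f} {t.cy_px / h:.6f} {t.w_px / w:.6f} {t.h_px / h:.6f}"
        for t in tips.tips
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
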