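"""Synthetic top-view rice plants with exact ground truth.

Procedurally renders top-view RGB images of rice plants — tapered leaf
blades radiating from a central culm — together with the exact pixel
coordinates of every leaf tip, leaf-count trajectories over the five
imaging time snaps (TS1 = drought onset .. TS5 = post-rewatering), and
destructive biomass records. Every downstream stage of the pipeline
(segmentation, skeleton tip detection, trait geometry, the LER stress
index, clustering) can therefore be validated against programmed truth
without any external imagery.

Drought acts on two programmed axes: it suppresses leaf emergence by a
genotype-specific factor (``drought_emergence_factor``, the ground truth
that the LER index should recover) and rolls the leaf blades, shrinking
their rendered width (``rolling_factor``).

Colour contract: before additive noise, every plant pixel satisfies the
excess-green inequality 2G - R - B > 0 and every background pixel
satisfies 2G - R - B <= 0, so ExG segmentation has a correct answer.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import line as _line
from skimage.draw import polygon as _polygon

from .plantseg_tips import Tip, TipSet, write_yolo_labels

ARCHETYPES = ("erect", "semi_erect", "spread", "open")
TREATMENTS = ("control", "drought")
TIME_SNAPS = (1, 2, 3, 4, 5)

#: top-view erectness (radial foreshortening) typical of each archetype
_ARCHETYPE_ERECTNESS = {"erect": 0.80, "semi_erect": 0.55, "spread": 0.30, "open": 0.10}

# flat colours chosen so the ExG margin is comfortably signed on both sides:
# plant 2G-R-B = +190, background 2G-R-B = -30 (pre-noise)
_PLANT_RGB = (50, 150, 60)
_BACKGROUND_RGB = (130, 100, 100)


@dataclass(frozen=True)
class GenotypeSpec:
    """Parametric description of one synthetic rice genotype."""

    genotype_id: str
    archetype: str
    base_leaf_count: int              # leaves at TS1 (shared control/drought baseline)
    emergence_rate_control: float     # leaves emerging per time-snap interval, well-watered
    drought_emergence_factor: float   # in [0,1]; fraction of control emergence realised under drought
    erectness: float                  # in [0,1]; radial foreshortening of blades in top view
    rolling_factor: float             # in [0,1]; blade-width shrink under drought
    leaf_len_px: float
    leaf_width_px: float
    seed: int

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.base_leaf_count < 1:
            raise ValueError("base_leaf_count must be >= 1")
        for name in ("drought_emergence_factor", "erectness", "rolling_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.leaf_len_px <= 0 or self.leaf_width_px <= 0:
            raise ValueError("leaf dimensions must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Imaging-scene constants: canvas size, optics and annotation box size."""

    image_width_px: int = 608
    image_height_px: int = 608
    cm_per_pixel: float = 0.25
    box_size_px: int = 16             # ground-truth tip box edge
    background_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.box_size_px < 2:
            raise ValueError("box_size_px must be >= 2")
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")


@dataclass
class SyntheticPlant:
    """A rendered plant with its exact ground truth."""

    image: np.ndarray                 # uint8 RGB, (H, W, 3)
    tips: TipSet                      # ground-truth tip boxes
    leaf_count: int
    genotype_id: str
    treatment: str
    time_snap: int
    height_cm: float
    silhouette: np.ndarray = field(repr=False, default=None)  # pre-noise plant mask


@dataclass
class DestructiveRecord:
    """Destructive harvest record: weights (g) and areas (cm^2).

    BMW (above-ground biomass) is stem weight + leaf weight by definition.
    """

    genotype_id: str
    treatment: str
    stem_weight_g: float
    leaf_weight_g: float
    root_weight_g: float
    leaf_area_cm2: float
    stem_area_cm2: float

    @property
    def biomass_weight_g(self) -> float:
        return self.stem_weight_g + self.leaf_weight_g


def _round_half_up(x: float) -> int:
    # platform-stable alternative to banker's rounding; keeps trajectories monotone
    return int(math.floor(x + 0.5))


def make_genotype_panel(n: int, seed: int) -> list[GenotypeSpec]:
    """Generate a diverse panel of ``n`` genotype specifications.

    Archetypes are assigned round-robin so any n >= 4 spans all four;
    drought emergence factors are an evenly spaced sweep of [0.2, 1.0]
    (shuffled), so tolerance classes from sensitive to fully tolerant are
    all represented. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    rng = np.random.default_rng(seed)
    if n == 1:
        factors = np.array([0.6])
    else:
        factors = np.linspace(0.2, 1.0, n)
        rng.shuffle(factors)
    specs = []
    for i in range(n):
        arch = ARCHETYPES[i % 4]
        erect = float(np.clip(_ARCHETYPE_ERECTNESS[arch] + rng.normal(0, 0.05), 0, 1))
        specs.append(
            GenotypeSpec(
                genotype_id=f"G{i + 1:03d}",
                archetype=arch,
                base_leaf_count=int(rng.integers(8, 25)),
                emergence_rate_control=float(rng.integers(4, 9)),
                drought_emergence_factor=float(factors[i]),
                erectness=erect,
                rolling_factor=float(rng.uniform(0.2, 0.5)),
                leaf_len_px=float(np.clip(rng.normal(175, 25), 110, 235)),
                leaf_width_px=float(rng.uniform(5.0, 9.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def leaf_count_trajectory(
    g: GenotypeSpec, treatment: str, time_snaps: list[int] | tuple[int, ...]
) -> list[int]:
    """Leaf counts at the requested time snaps (1..5).

    TS1 equals ``base_leaf_count`` under both treatments (drought starts at
    TS1, so it is the shared baseline); each later interval adds
    round(emergence_rate) leaves, with the rate multiplied by the genotype's
    drought emergence factor under drought. Rounding is per interval, so
    trajectories are exactly arithmetic and monotone non-decreasing.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    snaps = list(time_snaps)
    if snaps != sorted(snaps) or len(set(snaps)) != len(snaps):
        raise ValueError("time_snaps must be sorted ascending without duplicates")
    if snaps and not (1 <= snaps[0] and snaps[-1] <= 5):
        raise ValueError("time snaps must lie in 1..5")
    rate = g.emergence_rate_control
    if treatment == "drought":
        inc = _round_half_up(rate * g.drought_emergence_factor)
    else:
        inc = _round_half_up(rate)
    return [g.base_leaf_count + (t - 1) * inc for t in snaps]


def _plant_height_cm(g: GenotypeSpec, treatment: str, time_snap: int) -> float:
    """Deterministic side-view height model (emitted numerically, not rendered)."""
    h0 = 18.0 + 0.5 * g.base_leaf_count
    rate = 2.5
    if treatment == "drought":
        rate *= 0.4 + 0.6 * g.drought_emergence_factor
    return h0 + rate * (time_snap - 1)


def _blade_polygon(
    x0: float, y0: float, x1: float, y1: float, half_w: float, bend: float, n_pts: int = 24
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tapered quadratic-Bezier blade from culm edge to tip.

    Returns polygon rows, cols and the centerline sample coordinates
    (bx, by); the centerline ends exactly at the tip (x1, y1).
    """
    mx, my = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy) or 1.0
    # perpendicular control-point offset gives the blade its curvature
    cx_, cy_ = mx - bend * dy / norm, my + bend * dx / norm
    t = np.linspace(0.0, 1.0, n_pts)
    bx = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * cx_ + t**2 * x1
    by = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * cy_ + t**2 * y1
    # tangents -> unit normals along the curve
    tx = 2 * (1 - t) * (cx_ - x0) + 2 * t * (x1 - cx_)
    ty = 2 * (1 - t) * (cy_ - y0) + 2 * t * (y1 - cy_)
    tn = np.hypot(tx, ty)
    tn[tn == 0] = 1.0
    nx, ny = -ty / tn, tx / tn
    # taper towards the tip but keep the distal end rasterisable (>= ~1.4 px wide)
    widths = np.maximum(half_w * (1.0 - 0.92 * t), 0.7)
    left_x, left_y = bx + nx * widths, by + ny * widths
    right_x, right_y = bx - nx * widths, by - ny * widths
    poly_x = np.concatenate([left_x, right_x[::-1]])
    poly_y = np.concatenate([left_y, right_y[::-1]])
    return poly_y, poly_x, bx, by


def render_plant(
    g: GenotypeSpec,
    treatment: str,
    time_snap: int,
    scene: SceneSpec,
    seed: int,
    leaf_count: int | None = None,
) -> SyntheticPlant:
    """Render one top-view plant; bit-identical for identical arguments.

    Blades radiate from a central culm disk at jittered azimuths; radial
    extent is scaled by ``1 - erectness * 0.5`` and blade width shrinks by
    the rolling factor under drought. Each blade's distal endpoint is
    recorded as a ground-truth tip with a ``box_size_px`` square box,
    clamped inside the image (never dropped). For erect/semi-erect plants
    with <= 15 leaves (the sparse regime) tips are re-jittered until
    pairwise separation >= box_size_px / 2.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if not 1 <= time_snap <= 5:
        raise ValueError("time_snap must lie in 1..5")
    if leaf_count is None:
        leaf_count = leaf_count_trajectory(g, treatment, [time_snap])[0]
    if leaf_count < 0:
        raise ValueError("leaf_count must be >= 0")

    tidx = TREATMENTS.index(treatment)
    w, h = scene.image_width_px, scene.image_height_px
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    culm_r = max(4.0, g.leaf_width_px * 0.9)
    radial_scale = 1.0 - 0.5 * g.erectness
    half_w = g.leaf_width_px / 2.0
    if treatment == "drought":
        half_w *= 1.0 - g.rolling_factor
    half_w = max(half_w, 1.0)

    min_sep = scene.box_size_px / 2.0
    sparse = g.archetype in ("erect", "semi_erect") and leaf_count <= 15

    n = leaf_count
    # per-leaf geometry is indexed by leaf number, not by time snap: leaves
    # persist as the plant grows, so tip sets at later snaps extend earlier
    # ones (NL and BBA trajectories are monotone by construction). Azimuths
    # follow golden-angle phyllotaxis plus jitter; radial extent grows 6%
    # per snap.
    rng_az = np.random.default_rng(np.random.SeedSequence([seed, g.seed, tidx, 1]))
    rng_rad = np.random.default_rng(np.random.SeedSequence([seed, g.seed, tidx, 2]))
    rng_bend = np.random.default_rng(np.random.SeedSequence([seed, g.seed, tidx, 3]))
    rng = np.random.default_rng(np.random.SeedSequence([seed, g.seed, tidx,
                                                        time_snap, 4]))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    growth = 1.0 + 0.06 * (time_snap - 1)
    # 0.03 rad azimuthal noise: phyllotaxis is regular; tiller placement
    # perturbs blade azimuths by only a few degrees
    azim = golden * np.arange(n) + rng_az.normal(0, 0.03, n)
    radii = g.leaf_len_px * radial_scale * growth * rng_rad.uniform(0.82, 1.18, n)
    bends = rng_bend.normal(0, 0.07, n) * radii

    def tip_xy(i: int) -> tuple[float, float]:
        x1 = cx0 + radii[i] * math.cos(azim[i])
        y1 = cy0 + radii[i] * math.sin(azim[i])
        return x1, y1

    if sparse and n > 1:
        # enforce the sparse-regime tip-separation guarantee by re-jittering
        # azimuths only (radii stay put so growth remains monotone)
        for _ in range(200):
            pts = np.array([tip_xy(i) for i in range(n)])
            d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
            np.fill_diagonal(d, np.inf)
            bad = np.unique(np.where(d < min_sep)[0])
            if bad.size == 0:
                break
            azim[bad] += rng.normal(0, 0.2, bad.size)

    silhouette = np.zeros((h, w), dtype=bool)
    rr, cc = _disk((cy0, cx0), culm_r, shape=(h, w))
    silhouette[rr, cc] = True

    tips: list[Tip] = []
    for i in range(n):
        x1, y1 = tip_xy(i)
        x0 = cx0 + culm_r * 0.6 * math.cos(azim[i])
        y0 = cy0 + culm_r * 0.6 * math.sin(azim[i])
        py, px, cbx, cby = _blade_polygon(x0, y0, x1, y1, half_w, bends[i])
        rr, cc = _polygon(py, px, shape=(h, w))  # rasteriser truncates at borders
        silhouette[rr, cc] = True
        # draw the centerline to the exact tip so the rendered blade always
        # reaches (and stays connected to) its recorded tip pixel
        for j in range(len(cbx) - 1):
            r0_, c0_ = int(round(cby[j])), int(round(cbx[j]))
            r1_, c1_ = int(round(cby[j + 1])), int(round(cbx[j + 1]))
            lr, lc = _line(r0_, c0_, r1_, c1_)
            inside = (lr >= 0) & (lr < h) & (lc >= 0) & (lc < w)
            silhouette[lr[inside], lc[inside]] = True
        # tip clamped inside the image, never dropped
        tx = float(np.clip(x1, 0.0, w - 1.0))
        ty = float(np.clip(y1, 0.0, h - 1.0))
        tips.append(Tip(cx_px=tx, cy_px=ty, w_px=float(scene.box_size_px),
                        h_px=float(scene.box_size_px), confidence=1.0))

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = _BACKGROUND_RGB
    image[silhouette] = _PLANT_RGB
    if scene.background_noise_sd > 0:
        image = image + rng.normal(0, scene.background_noise_sd, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    tipset = TipSet(
        image_id=f"{g.genotype_id}_{treatment}_TS{time_snap}",
        image_width_px=w,
        image_height_px=h,
        tips=tips,
    )
    return SyntheticPlant(
        image=image,
        tips=tipset,
        leaf_count=n,
        genotype_id=g.genotype_id,
        treatment=treatment,
        time_snap=time_snap,
        height_cm=_plant_height_cm(g, treatment, time_snap),
        silhouette=silhouette,
    )


# destructive-record allometry: grams of fresh leaf per counted leaf, and
# organ/area ratios relative to above-ground biomass (desk-scale stand-ins
# for harvest allometry; leaf share of biomass centred at ~0.45)
_LEAF_G_PER_LEAF = 0.35
_ROOT_PER_BMW = 1.14
_LEAF_AREA_PER_BMW = 20.0
_STEM_AREA_PER_BMW = 4.2


def simulate_destructive(
    g: GenotypeSpec,
    treatment: str,
    leaf_count: int,
    seed: int,
    noise_sd: float = 0.1,
) -> DestructiveRecord:
    """Synthetic destructive harvest for one plant.

    Leaf weight is proportional to the counted leaves with multiplicative
    noise; stem weight is drawn so the leaf share of above-ground biomass
    stays in the 30-70% range; root weight and leaf/stem areas scale
    positively with biomass.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if leaf_count < 0:
        raise ValueError("leaf_count must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, g.seed,
                                                        TREATMENTS.index(treatment), 77]))
    lw = _LEAF_G_PER_LEAF * leaf_count * (1.0 + rng.normal(0, noise_sd))
    lw = max(lw, 0.0)
    leaf_share = float(np.clip(rng.normal(0.45, 0.08), 0.30, 0.70))
    stw = lw * (1.0 - leaf_share) / leaf_share if lw > 0 else 0.0
    bmw = lw + stw
    jitter = lambda: 1.0 + rng.normal(0, noise_sd)  # noqa: E731
    return DestructiveRecord(
        genotype_id=g.genotype_id,
        treatment=treatment,
        stem_weight_g=stw,
        leaf_weight_g=lw,
        root_weight_g=max(_ROOT_PER_BMW * bmw * jitter(), 0.0),
        leaf_area_cm2=max(_LEAF_AREA_PER_BMW * bmw * jitter(), 0.0),
        stem_area_cm2=max(_STEM_AREA_PER_BMW * bmw * jitter(), 0.0),
    )


def write_plant(plant: SyntheticPlant, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a rendered plant as PNG plus its YOLO ground-truth label file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{plant.tips.image_id}.png"
    lbl_path = out_dir / f"{plant.tips.image_id}.txt"
    iio.imwrite(img_path, plant.image)
    write_yolo_labels(plant.tips, lbl_path)
    return img_path, lbl_path


def write_manifest(plants: list[SyntheticPlant], path: str | Path, seed: int) -> Path:
    """CSV manifest of a rendered panel (one row per plant image)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["genotype_id", "treatment", "time_snap", "leaf_count", "height_cm", "seed"])
        for p in plants:
            wr.writerow([p.genotype_id, p.treatment, p.time_snap, p.leaf_count,
                         f"{p.height_cm:.3f}", seed])
    return path
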