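"""Synthetic AgNOR cohorts and smear images with exact ground truth.

Two generators live here:

* a cohort simulator producing per-cell NOR (nucleolar organizer region)
  counts for the four study groups of an oral-cytology screening design —
  control (CG), carcinogen-exposed (EG), potentially malignant disorder
  (OPMDG) and squamous cell carcinoma (OSCCG) — with the published
  between-patient means/SDs and per-cell count-class percentages;
* a smear renderer that draws silver-stained nuclei (dark intranuclear
  dots on mid-gray elliptical nuclei over a light background) together
  with exact per-nucleus ground truth, so the image-quantification stage
  can be validated without any real slides.

Counts per nucleus live on 1..13.  The published per-cell distribution is
given over five classes (1, 2, 3, 4 and 5-or-more dots); the 5+ class is
expanded over {5..13} with geometric decay.  Per-patient heterogeneity is
coupled to the published summaries by exponential tilting: each patient
draws a latent mean m_p ~ Normal(mu_g, sigma_g) truncated to [1, 13], and
cell counts are sampled from the group's base distribution tilted so that
its expectation equals m_p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "GROUPS",
    "MAX_NORS",
    "GroupParams",
    "NucleusSpec",
    "SmearScene",
    "default_group_params",
    "draw_patient_means",
    "simulate_cohort",
    "make_scene",
    "render_smear",
    "write_cell_table",
    "read_cell_table",
    "stream_rng",
]

GROUPS = ("CG", "EG", "OPMDG", "OSCCG")
MAX_NORS = 13

#: geometric decay ratio for expanding the 5+ class over counts 5..13
FIVE_PLUS_DECAY = 0.5


@dataclass(frozen=True)
class GroupParams:
    """Published summary statistics for one patient group.

    ``mean_nors``/``sd_nors`` describe the between-patient distribution of
    mean AgNORs per nucleus; ``class_probs`` are the probabilities of a
    cell showing 1, 2, 3, 4 or 5+ dots (renormalized to sum to one).
    """

    group_id: str
    mean_nors: float
    sd_nors: float
    class_probs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.group_id not in GROUPS:
            raise ValueError(f"unknown group_id {self.group_id!r}")
        if self.sd_nors <= 0:
            raise ValueError("sd_nors must be positive")
        if self.mean_nors < 1:
            raise ValueError("mean_nors must be >= 1 (every counted cell has >= 1 dot)")
        p = np.asarray(self.class_probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or p.sum() <= 0:
            raise ValueError("class_probs must be 5 non-negative numbers with positive sum")
        object.__setattr__(self, "class_probs", tuple(p / p.sum()))


def default_group_params() -> list[GroupParams]:
    """The four study groups with their published means, SDs and class percentages."""
    raw = [
        ("CG", 2.89, 0.62, (13.3, 29.6, 26.1, 20.1, 11.1)),
        ("EG", 3.67, 1.03, (8.1, 17.0, 24.1, 21.1, 29.7)),
        ("OPMDG", 3.25, 0.63, (8.4, 20.0, 31.5, 23.6, 16.5)),
        ("OSCCG", 4.08, 0.46, (3.6, 12.6, 23.4, 29.0, 31.4)),
    ]
    return [
        GroupParams(g, m, s, tuple(p / 100.0 for p in pct)) for g, m, s, pct in raw
    ]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named, independent random stream derived from one global seed.

    Each (seed, stream-name) pair yields a reproducible generator that is
    statistically independent of the other streams, so e.g. re-rendering
    images does not perturb the cohort draw.
    """
    name_key = int.from_bytes(stream.encode(), "little") % (2**63)
    return np.random.default_rng(np.random.SeedSequence([int(seed), name_key]))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _support_probs(class_probs: np.ndarray) -> np.ndarray:
    """Expand the 5-class distribution onto the full count support 1..13."""
    w = FIVE_PLUS_DECAY ** np.arange(MAX_NORS - 4)  # weights for 5..13
    w = w / w.sum()
    full = np.empty(MAX_NORS)
    full[:4] = class_probs[:4]
    full[4:] = class_probs[4] * w
    return full / full.sum()


def _tilted_probs(base: np.ndarray, target_mean: float) -> np.ndarray:
    """Exponentially tilt ``base`` over support 1..13 to hit ``target_mean``.

    p_k(theta) ∝ base_k * exp(theta * k); the tilted mean is strictly
    increasing in theta, so a scalar root-find pins it to the target.
    """
    support = np.arange(1, MAX_NORS + 1, dtype=float)
    target = float(np.clip(target_mean, 1.0 + 1e-9, MAX_NORS - 1e-9))

    def tilted_mean(theta: float) -> float:
        # subtract max for overflow safety
        logw = np.log(base) + theta * support
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return float(w @ support)

    lo, hi = -1.0, 1.0
    while tilted_mean(lo) > target:
        lo *= 2
        if lo < -700:
            break
    while tilted_mean(hi) < target:
        hi *= 2
        if hi > 700:
            break
    theta = brentq(lambda t: tilted_mean(t) - target, lo, hi, xtol=1e-12)
    logw = np.log(base) + theta * support
    w = np.exp(logw - logw.max())
    return w / w.sum()


def draw_patient_means(
    params: GroupParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Latent per-patient mean counts: Normal(mu, sigma) truncated to [1, 13]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(params.mean_nors, params.sd_nors, size=n - filled)
        keep = draw[(draw >= 1.0) & (draw <= MAX_NORS)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_cohort(
    params: list[GroupParams],
    n_per_group: int,
    cells_per_patient: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a cohort of per-cell NOR counts.

    Returns a long-format table with columns
    ``patient_id, group_id, cell_index, nor_count`` (counts in 1..13).
    Identical seeds give identical tables.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if cells_per_patient < 1:
        raise ValueError("cells_per_patient must be >= 1")
    rng = stream_rng(seed, "cohort")
    rows: list[tuple[str, str, int, int]] = []
    for gp in params:
        base = _support_probs(np.asarray(gp.class_probs))
        means = draw_patient_means(gp, n_per_group, rng)
        for i, m_p in enumerate(means):
            pid = f"{gp.group_id}-{i + 1:03d}"
            probs = _tilted_probs(base, m_p)
            counts = rng.choice(np.arange(1, MAX_NORS + 1), size=cells_per_patient, p=probs)
            rows.extend(
                (pid, gp.group_id, j, int(c)) for j, c in enumerate(counts)
            )
    return pd.DataFrame(rows, columns=["patient_id", "group_id", "cell_index", "nor_count"])


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    expected = ["patient_id", "group_id", "cell_index", "nor_count"]
    if list(table.columns) != expected:
        raise ValueError(f"cell table must have columns {expected}, got {list(table.columns)}")
    return table


# ---------------------------------------------------------------------------
# smear rendering
# ---------------------------------------------------------------------------

@dataclass
class NucleusSpec:
    """Geometry of one synthetic nucleus and its intranuclear dots."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (semi-axis row, semi-axis col)
    rotation: float = 0.0  # radians
    dot_centers: list[tuple[float, float]] = field(default_factory=list)
    dot_radius: float = 3.0
    overlaps_other: bool = False
    is_background_artifact: bool = False


@dataclass
class SmearScene:
    """A full synthetic slide: nuclei plus stain/noise parameters."""

    image_size: tuple[int, int] = (512, 512)
    nuclei: list[NucleusSpec] = field(default_factory=list)
    nucleus_gray: int = 150
    dot_gray: int = 30
    background_gray: int = 230
    noise_sd: float = 8.0


def _inside_ellipse(point, nucleus: NucleusSpec) -> bool:
    dy = point[0] - nucleus.center[0]
    dx = point[1] - nucleus.center[1]
    c, s = np.cos(nucleus.rotation), np.sin(nucleus.rotation)
    u = c * dy + s * dx
    v = -s * dy + c * dx
    ay, ax = nucleus.axes
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def ground_truth_count(nucleus: NucleusSpec) -> int:
    """Fused-aware dot count: connected groups of intersecting dot disks.

    Overlapping or fused dots are a single structure, so the count is the
    number of connected components of the dot-intersection graph.
    """
    n = len(nucleus.dot_centers)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = np.asarray(nucleus.dot_centers, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            # disks touch or intersect -> fused, count once
            if np.hypot(*(centers[i] - centers[j])) <= 2 * nucleus.dot_radius:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def _nucleus_mask(nucleus: NucleusSpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        nucleus.center[0],
        nucleus.center[1],
        nucleus.axes[0],
        nucleus.axes[1],
        shape=shape,
        rotation=nucleus.rotation,
    )
    mask[rr, cc] = True
    return mask


def _check_in_canvas(nucleus: NucleusSpec, idx: int, shape: tuple[int, int]) -> None:
    r, c = nucleus.center
    margin = max(nucleus.axes)
    if r - margin < 0 or c - margin < 0 or r + margin >= shape[0] or c + margin >= shape[1]:
        raise ValueError(f"nucleus {idx} extends outside the canvas")


def render_smear(scene: SmearScene, seed: int):
    """Render a scene to an 8-bit grayscale image with ground truth.

    Returns ``(image, ground_truth, labelme)`` where ``ground_truth`` is a
    dict with one entry per nucleus (fused-aware NOR count, overlap /
    artifact flags, bounding box) and ``labelme`` is a LabelMe-style
    annotation dict whose ``shapes`` are rectangles around every nucleus
    that is not overlapping another and not an artifact — mirroring the
    manual bounding-box protocol, where overlapped nuclei are never boxed.
    Same seed, same scene → byte-identical image.
    """
    shape = tuple(scene.image_size)
    for k, nuc in enumerate(scene.nuclei):
        _check_in_canvas(nuc, k, shape)
        for d in nuc.dot_centers:
            if not _inside_ellipse(d, nuc):
                raise ValueError(f"dot {d} lies outside nucleus {k}")

    img = np.full(shape, float(scene.background_gray))
    masks = [_nucleus_mask(n, shape) for n in scene.nuclei]

    # pixel-level overlap detection augments any flags set at construction
    overlap = [bool(n.overlaps_other) for n in scene.nuclei]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                overlap[i] = overlap[j] = True

    for nuc, mask in zip(scene.nuclei, masks):
        img[mask] = scene.nucleus_gray
    for nuc in scene.nuclei:
        for dr, dc in nuc.dot_centers:
            rr, cc = draw_disk((dr, dc), nuc.dot_radius, shape=shape)
            img[rr, cc] = scene.dot_gray

    if scene.noise_sd > 0:
        rng = stream_rng(seed, "noise")
        img = img + rng.normal(0.0, scene.noise_sd, size=shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ground_truth = {"nuclei": []}
    shapes = []
    margin = 4  # box margin around the ellipse, px
    for k, (nuc, mask) in enumerate(zip(scene.nuclei, masks)):
        rows, cols = np.nonzero(mask)
        box = [int(cols.min()) - margin, int(rows.min()) - margin,
               int(cols.max()) + margin, int(rows.max()) + margin]
        box = [max(box[0], 0), max(box[1], 0),
               min(box[2], shape[1] - 1), min(box[3], shape[0] - 1)]
        entry = {
            "nucleus_id": f"n{k:03d}",
            "nor_count": ground_truth_count(nuc),
            "overlaps_other": overlap[k],
            "is_background_artifact": nuc.is_background_artifact,
            "box_xyxy": box,
        }
        ground_truth["nuclei"].append(entry)
        if not overlap[k] and not nuc.is_background_artifact:
            shapes.append(
                {
                    "label": f"n{k:03d}",
                    "points": [[box[0], box[1]], [box[2], box[3]]],
                    "shape_type": "rectangle",
                }
            )
    labelme = {
        "shapes": shapes,
        "imageHeight": shape[0],
        "imageWidth": shape[1],
    }
    return image, ground_truth, labelme


def make_scene(
    nor_counts: list[int],
    rng: np.random.Generator,
    image_size: tuple[int, int] = (512, 512),
    n_overlapping_pairs: int = 0,
    n_artifacts: int = 0,
    fused_fraction: float = 0.25,
    noise_sd: float = 8.0,
) -> SmearScene:
    """Randomly lay out a scene whose nuclei carry the requested NOR counts.

    Nuclei are placed without mutual overlap (rejection sampling); a dot
    group destined to be "fused" is realised as two touching disks, which
    the ground truth counts once.  ``n_overlapping_pairs`` adds pairs of
    deliberately overlapping nuclei and ``n_artifacts`` adds dark
    background blobs, both of which the annotation step skips.
    """
    scene = SmearScene(image_size=tuple(image_size), noise_sd=noise_sd)
    h, w = scene.image_size
    placed: list[tuple[float, float, float]] = []  # (r, c, radius)

    def place(
        radius: float,
        near: tuple[float, float] | None = None,
        skip_last: int = 0,
    ):
        """Find a spot with clearance from all placed nuclei.

        ``near`` confines the search close to a partner nucleus (used for
        overlap pairs); ``skip_last`` exempts the most recent placements
        (the partner itself) from the clearance check.
        """
        others = placed[: len(placed) - skip_last] if skip_last else placed
        for _ in range(4000):
            if near is None:
                r = rng.uniform(radius + 6, h - radius - 6)
                c = rng.uniform(radius + 6, w - radius - 6)
            else:
                ang = rng.uniform(0, 2 * np.pi)
                # just beyond touching: separate pixel masks, but boxes
                # collide — the protocol's "overlapping nuclei" situation
                dist = rng.uniform(2.12, 2.3) * radius
                r = near[0] + dist * np.sin(ang)
                c = near[1] + dist * np.cos(ang)
                if not (radius + 6 <= r < h - radius - 6 and radius + 6 <= c < w - radius - 6):
                    continue
            if all(np.hypot(r - pr, c - pc) > radius + prad + 8 for pr, pc, prad in others):
                return r, c
        raise RuntimeError("could not place nucleus; reduce count or enlarge canvas")

    def sample_dots(nuc: NucleusSpec, count: int) -> None:
        """Place `count` separated dot groups; some groups are fused twins."""
        groups: list[tuple[float, float]] = []
        rad = nuc.dot_radius
        # distinct structures must stay apart by more than the fuse
        # distance plus a raster-safety gap, or pixel connectivity and the
        # geometric ground truth could disagree
        sep = 2 * rad + 4
        for _ in range(count):
            for _ in range(4000):
                u = rng.uniform(-1, 1) * (nuc.axes[0] - 2.5 * rad)
                v = rng.uniform(-1, 1) * (nuc.axes[1] - 2.5 * rad)
                p = (nuc.center[0] + u, nuc.center[1] + v)
                if not _inside_ellipse(p, nuc):
                    continue
                if all(np.hypot(p[0] - g[0], p[1] - g[1]) > sep for g in groups):
                    groups.append(p)
                    break
            else:
                raise RuntimeError("could not place dot group")
        placed_dots: list[tuple[tuple[float, float], int]] = [
            (g, i) for i, g in enumerate(groups)
        ]
        for i, g in enumerate(groups):
            nuc.dot_centers.append(g)
            if rng.uniform() < fused_fraction:
                # fused twin: touching disk, same connected structure;
                # must keep its distance from every dot of OTHER groups
                for _ in range(20):
                    ang = rng.uniform(0, 2 * np.pi)
                    twin = (g[0] + 1.5 * rad * np.sin(ang), g[1] + 1.5 * rad * np.cos(ang))
                    if _inside_ellipse(twin, nuc) and all(
                        np.hypot(twin[0] - q[0], twin[1] - q[1]) > sep
                        for q, gi in placed_dots
                        if gi != i
                    ):
                        nuc.dot_centers.append(twin)
                        placed_dots.append((twin, i))
                        break

    for count in nor_counts:
        if not 1 <= count <= MAX_NORS:
            raise ValueError(f"nor count {count} outside [1, {MAX_NORS}]")
        # high-count nuclei are drawn larger so the dot groups fit with
        # enough separation to stay distinct structures
        bump = 2.5 * max(0, count - 5)
        axes = (rng.uniform(22, 30) + bump, rng.uniform(22, 30) + bump)
        radius = max(axes)
        r, c = place(radius)
        nuc = NucleusSpec(center=(r, c), axes=axes, rotation=rng.uniform(0, np.pi))
        placed.append((r, c, radius))
        sample_dots(nuc, count)
        scene.nuclei.append(nuc)

    for _ in range(n_overlapping_pairs):
        radius = rng.uniform(22, 28)
        axes = (radius, radius)
        r, c = place(radius)
        first = NucleusSpec(center=(r, c), axes=axes, overlaps_other=True)
        placed.append((r, c, radius))
        r2, c2 = place(radius, near=(r, c), skip_last=1)
        second = NucleusSpec(center=(r2, c2), axes=axes, overlaps_other=True)
        placed.append((r2, c2, radius))
        for nuc in (first, second):
            sample_dots(nuc, int(rng.integers(1, 5)))
        scene.nuclei.extend([first, second])

    for _ in range(n_artifacts):
        rad = rng.uniform(4, 9)
        r, c = place(rad)
        placed.append((r, c, rad))
        scene.nuclei.append(
            NucleusSpec(center=(r, c), axes=(rad, rad), is_background_artifact=True)
        )
    return scene


def save_labelme(labelme: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(labelme, indent=1))
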