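"""Classification-based trafficking index (TIC).

A k-means classifier with four classes — background, tumour, immune,
colour-saturated — is trained once per experiment on pixels pooled from one
randomly chosen image per (group, time point) cell, using only the raw
(red, green) intensity pair of each pixel.  The saturated class absorbs
pixels at the intensity ceiling whose red/green comparison is meaningless,
so they bias neither the tumour nor the immune class.

Once every pixel is labelled, trafficking is the fraction of
tumour-surrounded pixels that are immune: a pixel's surroundings are the
11 x 11 square centred on it (centre excluded), and it counts as
"surrounded by cancer" when tumour is the strict plurality class of those
120 neighbours.

    TIC = immune-surrounded-by-cancer / (immune-s-b-c + cancer-s-b-c)

which lies in [0, 1] and is 0 when the denominator is empty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    BorderPixelError,
    DegenerateInputError,
    ImageFormatError,
    LayoutError,
    RoleAssignmentError,
)
from .io import ChannelImage, ExperimentLayout, load_rgb_image, split_channels

__all__ = [
    "ROLES",
    "PixelClassifier",
    "ClassMap",
    "TICResult",
    "build_training_sample",
    "sample_pixels",
    "kmeans_train",
    "assign_roles",
    "classify_pixels",
    "neighborhood_majority",
    "compute_tic",
]

logger = logging.getLogger(__name__)

#: fixed role vocabulary; ClassMap codes index into this tuple
ROLES: tuple[str, ...] = ("background", "tumour", "immune", "saturated")

BACKGROUND, TUMOUR, IMMUNE, SATURATED = range(4)


@dataclass(frozen=True)
class PixelClassifier:
    """Trained 4-centroid k-means model in (red, green) intensity space.

    Centroids are stored sorted lexicographically by (red, green) so that
    nearest-centroid ties resolve to the lower index in a fixed ordering.
    ``roles`` maps centroid index -> role name and is ``None`` until
    :func:`assign_roles` has run.
    """

    centroids: np.ndarray                      # (k, 2) float64, (red, green)
    roles: tuple[str, ...] | None = None       # per-centroid role names
    tol: float = 1e-6
    seed: int = 0
    n_iterations_run: int = 0
    objective_history: tuple[float, ...] = ()  # within-class SSE per iteration

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"centroids must be (k, 2), got {c.shape}")
        object.__setattr__(self, "centroids", c)
        if self.roles is not None:
            roles = tuple(self.roles)
            if sorted(roles) != sorted(ROLES[: len(c)]):
                raise RoleAssignmentError(
                    f"roles must be a bijection onto {ROLES[:len(c)]}, got {roles}"
                )
            object.__setattr__(self, "roles", roles)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def role_centroid(self, role: str) -> np.ndarray:
        if self.roles is None:
            raise RoleAssignmentError("roles not assigned yet")
        return self.centroids[self.roles.index(role)]

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "centroids": self.centroids.tolist(),
            "roles": list(self.roles) if self.roles else None,
            "tol": self.tol,
            "seed": self.seed,
            "n_iterations_run": self.n_iterations_run,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelClassifier":
        payload = json.loads(Path(path).read_text())
        return cls(
            centroids=np.asarray(payload["centroids"], dtype=np.float64),
            roles=tuple(payload["roles"]) if payload.get("roles") else None,
            tol=float(payload.get("tol", 1e-6)),
            seed=int(payload.get("seed", 0)),
            n_iterations_run=int(payload.get("n_iterations_run", 0)),
        )


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel role codes (indices into :data:`ROLES`) for one image."""

    classes: np.ndarray  # 2-D uint8 of role codes

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes, dtype=np.uint8)
        if arr.ndim != 2:
            raise ImageFormatError(f"ClassMap needs a 2-D array, got {arr.shape}")
        object.__setattr__(self, "classes", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def counts(self) -> dict[str, int]:
        c = np.bincount(self.classes.ravel(), minlength=len(ROLES))
        return {role: int(c[i]) for i, role in enumerate(ROLES)}


@dataclass(frozen=True)
class TICResult:
    """TIC plus its numerator/denominator pieces.

    ``excluded_border`` counts pixels whose 11 x 11 window leaves the image;
    they enter neither count.  ``degenerate`` flags a zero denominator
    (no tumour-surrounded pixels at all), in which case ``tic`` is 0.
    """

    tic: float
    immune_in_tumour: int
    cancer_in_tumour: int
    excluded_border: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# training-sample construction
# ---------------------------------------------------------------------------

def sample_pixels(
    red: ChannelImage, green: ChannelImage, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of ``n`` (red, green) pixel pairs without replacement
    (all pixels if the image has fewer than ``n``)."""
    r = red.intensities.ravel()
    g = green.intensities.ravel()
    total = r.size
    if n >= total:
        idx = np.arange(total)
    else:
        idx = rng.choice(total, size=n, replace=False)
    return np.column_stack([r[idx], g[idx]]).astype(np.float64)


def build_training_sample(
    layout: ExperimentLayout,
    pixels_per_image: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Pool training pixels: one image per (group, time) cell, at random.

    For each cell of the experiment one replicate image is drawn uniformly
    at random, and ``pixels_per_image`` pixels are sampled uniformly without
    replacement from it.  A full 7-group x 4-time-point experiment therefore
    contributes 28 images.  Deterministic under a fixed seed.
    """
    if not layout.entries:
        raise LayoutError("cannot build a training sample from an empty layout")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    for group in layout.groups:
        for t in layout.times:
            cell = layout.cell(group, t)
            if not cell:
                continue
            entry = cell[int(rng.integers(len(cell)))]
            red, green = split_channels(load_rgb_image(entry.path))
            chunks.append(sample_pixels(red, green, pixels_per_image, rng))
    return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# k-means (Lloyd's algorithm, k-means++ seeding)
# ---------------------------------------------------------------------------

def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = np.empty((k, 2), dtype=np.float64)
    centroids[0] = points[rng.integers(n)]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0.0:
            centroids[j] = points[rng.integers(n)]
        else:
            centroids[j] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centroids[j]) ** 2, axis=1))
    return centroids


def _sqdist(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances; 2-D feature space so direct
    diff = points[:, None, :] - centroids[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def _lloyd(
    pts: np.ndarray, k: int, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, int, list[float]]:
    """One Lloyd run from a k-means++ start; returns (centroids, iters, SSE trace)."""
    centroids = _kmeanspp_init(pts, k, rng)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = _sqdist(pts, centroids)
        labels = np.argmin(d2, axis=1)
        new = centroids.copy()
        for j in range(k):
            members = pts[labels == j]
            if members.shape[0] == 0:
                far = int(np.argmax(np.min(d2, axis=1)))
                new[j] = pts[far]
                logger.warning(
                    "k-means: class %d emptied; re-seeded from farthest point %s",
                    j, pts[far],
                )
            else:
                new[j] = members.mean(axis=0)
        history.append(float(np.min(d2, axis=1).sum()))
        shift = float(np.max(np.abs(new - centroids)))
        centroids = new
        if shift < tol:
            break
    return centroids, n_iter, history


def kmeans_train(
    points: np.ndarray,
    k: int = 4,
    tol: float = 1e-6,
    seed: int = 0,
    max_iter: int = 500,
    n_init: int = 10,
) -> PixelClassifier:
    """Lloyd's k-means on (red, green) points; roles left unassigned.

    Each iteration assigns every point to its nearest centroid (squared
    Euclidean) and recomputes centroids as class means; iteration stops when
    the maximum centroid coordinate displacement between consecutive
    iterates falls below ``tol``.  The within-class sum of squares is
    recorded per iteration and is non-increasing within a run.  An emptied
    class is re-seeded from the point farthest from its nearest centroid
    (logged).

    Lloyd's algorithm only finds a local optimum, so ``n_init`` independent
    k-means++ starts (seeded deterministically from ``seed``) are run and
    the solution with the lowest within-class sum of squares is kept;
    ``n_iterations_run`` and ``objective_history`` describe the winning run.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (n, 2), got {pts.shape}")
    if np.unique(pts, axis=0).shape[0] < k:
        raise DegenerateInputError(
            f"need at least {k} distinct points to fit {k} centroids"
        )
    if n_init < 1:
        raise ValueError(f"n_init must be >= 1, got {n_init}")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int, list[float]] | None = None
    for _ in range(n_init):
        centroids, n_iter, history = _lloyd(pts, k, tol, max_iter, rng)
        if best is None or history[-1] < best[0]:
            best = (history[-1], centroids, n_iter, history)
    _, centroids, n_iter, history = best
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))  # by (red, green)
    return PixelClassifier(
        centroids=centroids[order],
        roles=None,
        tol=tol,
        seed=seed,
        n_iterations_run=n_iter,
        objective_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# role assignment and classification
# ---------------------------------------------------------------------------

def assign_roles(
    clf: PixelClassifier, saturation_level: float = 250.0
) -> PixelClassifier:
    """Deterministically name the four centroids.

    Rule (ties resolve to the lower centroid index, which is fixed by the
    (red, green) sort order):

    * background — minimises red + green (dimmest);
    * saturated  — of the rest, the centroid maximising min(red, green) if
      that minimum reaches ``saturation_level``, else the brightest
      (max red + green) centroid;
    * immune     — of the remaining two, the larger red - green;
    * tumour     — the last one.
    """
    if clf.k != 4:
        raise RoleAssignmentError(f"role assignment needs 4 centroids, got {clf.k}")
    c = clf.centroids
    remaining = list(range(4))

    def _pick(indices: list[int], key) -> int:
        scores = [key(c[i]) for i in indices]
        best = max(scores)
        return indices[scores.index(best)]  # first max -> lower index on ties

    bg = _pick(remaining, lambda p: -(p[0] + p[1]))
    remaining.remove(bg)
    sat_cand = _pick(remaining, lambda p: min(p[0], p[1]))
    if min(c[sat_cand]) >= saturation_level:
        sat = sat_cand
    else:
        sat = _pick(remaining, lambda p: p[0] + p[1])
    remaining.remove(sat)
    imm = _pick(remaining, lambda p: p[0] - p[1])
    remaining.remove(imm)
    tum = remaining[0]

    roles = [""] * 4
    roles[bg], roles[sat], roles[imm], roles[tum] = (
        "background", "saturated", "immune", "tumour",
    )
    if sorted(roles) != sorted(ROLES):
        raise RoleAssignmentError(f"role rule produced a non-bijection: {roles}")
    return PixelClassifier(
        centroids=clf.centroids,
        roles=tuple(roles),
        tol=clf.tol,
        seed=clf.seed,
        n_iterations_run=clf.n_iterations_run,
        objective_history=clf.objective_history,
    )


def classify_pixels(
    clf: PixelClassifier, red: ChannelImage, green: ChannelImage
) -> ClassMap:
    """Label every pixel with the role of its nearest centroid.

    Ties go to the lower-index centroid in the fixed (red, green)-sorted
    centroid order.
    """
    if clf.roles is None:
        raise RoleAssignmentError("classifier roles must be assigned before use")
    if red.shape != green.shape:
        raise ImageFormatError(f"red shape {red.shape} != green shape {green.shape}")
    feats = np.column_stack(
        [red.intensities.ravel(), green.intensities.ravel()]
    ).astype(np.float64)
    labels = np.argmin(_sqdist(feats, clf.centroids), axis=1)
    role_codes = np.array([ROLES.index(r) for r in clf.roles], dtype=np.uint8)
    return ClassMap(classes=role_codes[labels].reshape(red.shape))


# ---------------------------------------------------------------------------
# neighbourhood majority and TIC
# ---------------------------------------------------------------------------

def neighborhood_majority(
    cmap: ClassMap, pixel: tuple[int, int], window: int = 11
) -> str | None:
    """Strict-plurality class of the ``window x window`` square around a
    pixel, centre excluded.

    Returns ``None`` on a tied plurality ("none-majority").  A pixel whose
    window leaves the image raises :class:`BorderPixelError` — border pixels
    are excluded from the analysis, not padded.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    m = window // 2
    r, c = pixel
    h, w = cmap.shape
    if r < m or c < m or r >= h - m or c >= w - m:
        raise BorderPixelError(f"pixel {pixel} is within {m} of the image border")
    block = cmap.classes[r - m : r + m + 1, c - m : c + m + 1]
    counts = np.bincount(block.ravel(), minlength=len(ROLES)).astype(np.int64)
    counts[block[m, m]] -= 1  # exclude the centre pixel itself
    best = int(np.argmax(counts))
    if np.count_nonzero(counts == counts[best]) > 1:
        return None
    return ROLES[best]


def _window_sums(arr: np.ndarray, w: int) -> np.ndarray:
    """Exact w x w box sums via a 2-D integral image; shape (H-w+1, W-w+1)."""
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    return ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]


def compute_tic(cmap: ClassMap, window: int = 11) -> TICResult:
    """TIC over all interior pixels of a class map.

    Counts interior immune (resp. tumour) pixels whose neighbourhood strict
    plurality is tumour and forms the ratio immune / (immune + cancer).
    Background and saturated pixels never enter either count; tied
    pluralities count for nothing.  Implemented with integral-image window
    sums, so it is exact and linear in the number of pixels.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    h, w = cmap.shape
    m = window // 2
    total = h * w
    if h < window or w < window:
        return TICResult(0.0, 0, 0, total, degenerate=True)

    interior = cmap.classes[m : h - m, m : w - m]
    counts = np.empty((len(ROLES),) + interior.shape, dtype=np.int64)
    for code in range(len(ROLES)):
        onehot = (cmap.classes == code).astype(np.int64)
        counts[code] = _window_sums(onehot, window)
    # exclude each centre pixel from its own neighbourhood count
    for code in range(len(ROLES)):
        counts[code] -= (interior == code).astype(np.int64)

    tum = counts[TUMOUR]
    others = np.delete(counts, TUMOUR, axis=0)
    tumour_majority = np.all(tum > others, axis=0)  # strict plurality

    immune_in = int(np.count_nonzero(tumour_majority & (interior == IMMUNE)))
    cancer_in = int(np.count_nonzero(tumour_majority & (interior == TUMOUR)))
    excluded = total - interior.size
    denom = immune_in + cancer_in
    if denom == 0:
        return TICResult(0.0, immune_in, cancer_in, excluded, degenerate=True)
    return TICResult(immune_in / denom, immune_in, cancer_in, excluded)
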