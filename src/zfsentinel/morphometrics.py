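"""Landmark-based morphometrics: standard length, body-region areas,
generalized Procrustes alignment, consensus shapes, and shape PCA.

Shape is what remains of a landmark configuration after translation,
scale, and rotation are removed.  Generalized Procrustes analysis (GPA)
does this jointly for a sample: every configuration is centered, scaled
to unit centroid size, and iteratively rotated to the running mean shape
until the mean stabilizes.  Principal components of the aligned
coordinates (relative warps with uniform weighting) then give an
ordinated description of shape variation; the per-axis variance
fractions are directly comparable to those reported by tpsRelw in its
default use.

Region areas (posterior body: landmarks 2-3-4-5; anterior body:
landmarks 1-5-6-7) are computed on the original mm-scale landmarks,
because they are reported in mm^2 and size itself is informative here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .core_io import DataError, LandmarkSet

__all__ = [
    "ShapeAnalysis",
    "RegionAreas",
    "ANTERIOR_LANDMARKS",
    "POSTERIOR_LANDMARKS",
    "centroid_size",
    "standard_length",
    "region_areas",
    "gpa_align",
    "shape_pca",
    "consensus_by_group",
    "procrustes_distance",
]

#: 0-based landmark indices of the two body-region polygons, in vertex order.
ANTERIOR_LANDMARKS = (0, 4, 5, 6)   # mouth -> anal fin -> ventral surface -> ventral skull
POSTERIOR_LANDMARKS = (1, 2, 3, 4)  # dorsal skull -> dorsal fin -> caudal fin -> anal fin


@dataclass
class RegionAreas:
    """Absolute areas (mm^2) of the two body regions and their ratio."""

    anterior_mm2: float
    posterior_mm2: float

    @property
    def ratio(self) -> float:
        return self.posterior_mm2 / self.anterior_mm2


@dataclass
class ShapeAnalysis:
    """Result of GPA (and optionally PCA) over a landmark sample."""

    aligned: np.ndarray          # (n, 7, 2), dimensionless
    consensus: np.ndarray        # (7, 2), centered, unit centroid size
    centroid_sizes: np.ndarray   # (n,), mm
    fish_ids: list[str]
    sites: list[str]
    sexes: list[str]
    n_iterations: int = 0
    residual_history: list[float] = field(default_factory=list)
    pc_scores: np.ndarray | None = None        # (n, k)
    variance_explained: np.ndarray | None = None
    loadings: np.ndarray | None = None         # (k, 14)

    @property
    def n_specimens(self) -> int:
        return len(self.aligned)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances to the centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def standard_length(lm: LandmarkSet) -> float:
    """Distance (mm) from the mouth landmark to the caudal-fin landmark."""
    d = float(np.linalg.norm(lm.landmarks_mm[0] - lm.landmarks_mm[3]))
    if d == 0.0:
        warnings.warn(f"fish {lm.fish_id}: mouth and caudal landmarks coincide", stacklevel=2)
    return d


def _polygon_area(coords: np.ndarray, label: str, fish_id: str) -> float:
    poly = Polygon(coords)
    if not poly.is_valid:
        # signed triangle areas around the ring help diagnose the crossing
        x, y = coords[:, 0], coords[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        warnings.warn(
            f"fish {fish_id}: {label} polygon self-intersects "
            f"(signed shoelace area {signed:.6g}); reporting absolute area",
            stacklevel=3,
        )
        x, y = coords[:, 0], coords[:, 1]
        return float(abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    return float(poly.area)


def region_areas(lm: LandmarkSet) -> RegionAreas:
    """Shoelace areas of the anterior (LM 1,5,6,7) and posterior
    (LM 2,3,4,5) body-region quadrilaterals, on the mm-scale landmarks."""
    ant = _polygon_area(lm.landmarks_mm[list(ANTERIOR_LANDMARKS)], "anterior", lm.fish_id)
    post = _polygon_area(lm.landmarks_mm[list(POSTERIOR_LANDMARKS)], "posterior", lm.fish_id)
    if ant <= 0:
        raise DataError(f"fish {lm.fish_id}: zero anterior region area")
    return RegionAreas(anterior_mm2=ant, posterior_mm2=post)


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    c = coords - coords.mean(axis=0)
    size = np.sqrt(np.sum(c**2))
    return c / size, float(size)


def _rotate_to(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each centered shape (n, k, 2) onto ``target`` by the
    least-squares rotation (reflections disallowed).

    In 2-D the optimal angle has the closed form
    theta = atan2(sum(x_a y_t - y_a x_t), sum(x_a x_t + y_a y_t)),
    identical to the SVD orthogonal fit restricted to det +1.
    """
    a = np.sum(shapes[:, :, 0] * target[:, 1] - shapes[:, :, 1] * target[:, 0], axis=1)
    b = np.sum(shapes[:, :, 0] * target[:, 0] + shapes[:, :, 1] * target[:, 1], axis=1)
    theta = np.arctan2(a, b)
    cos, sin = np.cos(theta), np.sin(theta)
    x, y = shapes[:, :, 0], shapes[:, :, 1]
    out = np.empty_like(shapes)
    out[:, :, 0] = cos[:, None] * x - sin[:, None] * y
    out[:, :, 1] = sin[:, None] * x + cos[:, None] * y
    return out


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared difference between two pre-aligned shapes."""
    return float(np.sqrt(np.sum((np.asarray(a) - np.asarray(b)) ** 2)))


def gpa_align(
    sets: list[LandmarkSet] | np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
    project_tangent: bool = True,
) -> ShapeAnalysis:
    """Generalized Procrustes superimposition of a landmark sample.

    Each configuration is centered and scaled to unit centroid size,
    then iteratively rotated to the running consensus (which is itself
    re-centered and re-scaled each round) until the consensus moves by
    less than ``tol`` or ``max_iter`` rounds have run.  Reflections are
    never introduced: all photographs share one orientation.

    With ``project_tangent`` the aligned shapes are orthogonally
    projected onto the tangent plane at the consensus; at the small
    shape variation typical of within-species samples the effect is
    numerically negligible, but it makes the coordinates exactly linear
    for the downstream PCA.
    """
    if isinstance(sets, np.ndarray):
        arr = np.asarray(sets, dtype=float)
        ids = [f"specimen_{i}" for i in range(len(arr))]
        sites = [""] * len(arr)
        sexes = ["unknown"] * len(arr)
    else:
        arr = np.stack([lm.landmarks_mm for lm in sets])
        ids = [lm.fish_id for lm in sets]
        sites = [lm.site for lm in sets]
        sexes = [lm.sex for lm in sets]
    n = len(arr)
    if n < 2:
        raise DataError("GPA needs at least 2 landmark sets")

    shapes = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        c = arr[i] - arr[i].mean(axis=0)
        s = np.sqrt(np.sum(c**2))
        if s == 0:
            raise DataError(f"fish {ids[i]}: degenerate configuration (all landmarks coincident)")
        shapes[i] = c / s
        sizes[i] = s

    consensus = shapes[0].copy()
    residuals: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        shapes = _rotate_to(shapes, consensus)
        new_consensus, _ = _center_and_scale(shapes.mean(axis=0))
        residuals.append(float(np.sum((shapes - new_consensus) ** 2)))
        if np.sqrt(np.sum((new_consensus - consensus) ** 2)) < tol:
            consensus = new_consensus
            break
        consensus = new_consensus
    shapes = _rotate_to(shapes, consensus)

    # standardize orientation: rotate everything so the consensus'
    # major principal axis lies along x (sign fixed by making the
    # largest-magnitude consensus coordinate positive).  Makes the
    # output independent of the input configurations' orientations.
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    R = evecs[:, ::-1]  # major axis first
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1
    consensus = consensus @ R
    shapes = shapes @ R
    flat = consensus.ravel()
    if flat[np.argmax(np.abs(flat))] < 0:
        consensus = -consensus  # rotation by pi, not a reflection
        shapes = -shapes

    if project_tangent:
        # orthogonal projection onto the tangent plane at the consensus:
        # remove the component of each shape along the consensus direction
        # in excess of the consensus itself
        c_flat = consensus.ravel()
        x = shapes.reshape(n, -1)
        coef = x @ c_flat  # |c_flat| == 1
        x = x - (coef[:, None] - 1.0) * c_flat
        shapes = x.reshape(n, *consensus.shape)

    return ShapeAnalysis(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        fish_ids=ids,
        sites=sites,
        sexes=sexes,
        n_iterations=n_iter,
        residual_history=residuals,
    )


def shape_pca(analysis: ShapeAnalysis) -> ShapeAnalysis:
    """Principal components of the aligned coordinates (relative warps
    with uniform weighting).

    Shapes are flattened to 14-vectors and centered on the sample mean;
    scores, per-axis variance fractions (summing to 1 over all retained
    axes), and loadings are stored back on the analysis.  Component
    signs are fixed by making each loading's largest-magnitude entry
    positive.
    """
    if analysis.n_specimens < 3:
        raise DataError("shape PCA needs at least 3 specimens")
    x = analysis.aligned.reshape(analysis.n_specimens, -1)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-20:  # identical specimens up to floating-point jitter
        warnings.warn("all specimens identical: zero shape variance", stacklevel=2)
        analysis.pc_scores = np.zeros_like(u)
        analysis.variance_explained = np.zeros_like(var)
        analysis.loadings = vt
        return analysis
    # drop numerically null axes (rank of centered data is at most n-1
    # and at most 14 - 4 after removing the similarity transforms)
    keep = var > total * 1e-12
    u, s, vt, var = u[:, keep], s[keep], vt[keep], var[keep]
    flip = np.sign(vt[np.arange(len(vt)), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    scores = xc @ vt.T
    analysis.pc_scores = scores
    analysis.variance_explained = var / var.sum()
    analysis.loadings = vt
    return analysis


def consensus_by_group(
    analysis: ShapeAnalysis, labels: list[tuple[str, str]] | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """Mean aligned shape per (site, sex) group, for overlay plots.

    ``labels`` defaults to the site/sex labels carried through GPA.
    Empty groups are skipped with a warning.
    """
    if labels is None:
        labels = list(zip(analysis.sites, analysis.sexes))
    if len(labels) != analysis.n_specimens:
        raise DataError("labels length does not match specimen count")
    out: dict[tuple[str, str], np.ndarray] = {}
    for key in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == key]
        if not idx:
            warnings.warn(f"empty group {key}; skipped", stacklevel=2)
            continue
        out[key] = analysis.aligned[idx].mean(axis=0)
    return out
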