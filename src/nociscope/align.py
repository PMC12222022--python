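"""Guide-post-based registration of post hoc ISH images to in vivo recordings.

A set of landmark cells visible in both frames ("guide-posts") first drives
a closed-form least-squares scaled rotation (similarity transform), then a
smooth morph — an interpolating thin-plate spline by default, piecewise
affine as a faster alternative — that makes the mapping exact at every
guide-post.  Expression labels are transferred by mapping ISH centroids
through the model and greedily matching them one-to-one to in vivo ROI
centroids by ascending distance.  Multiple ISH rounds chain by function
composition through shared guide-posts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial.distance import cdist
from skimage.transform import (
    AffineTransform,
    PiecewiseAffineTransform,
    SimilarityTransform,
)


class _TPSWarp:
    """Interpolating thin-plate spline displacement (exact at landmarks)."""

    def __init__(self, src: np.ndarray, dst: np.ndarray, smoothing: float = 0.0):
        if len(np.unique(src, axis=0)) != len(src):
            raise AlignmentError("duplicate landmarks collide in the spline fit")
        self._rbf = RBFInterpolator(src, dst, kernel="thin_plate_spline",
                                    smoothing=smoothing)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(self._rbf(np.atleast_2d(pts)), dtype=float)


def _estimate(tf, src: np.ndarray, dst: np.ndarray) -> bool:
    # skimage <2.2 instance API, silenced against the from_estimate migration
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return bool(tf.estimate(src, dst))


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class GuidePostSet:
    """Matched landmark pairs: ``ish`` and ``invivo`` are (n, 2) pixel arrays."""

    ish: np.ndarray
    invivo: np.ndarray

    def __post_init__(self) -> None:
        ish = np.atleast_2d(np.asarray(self.ish, dtype=float))
        invivo = np.atleast_2d(np.asarray(self.invivo, dtype=float))
        if ish.shape != invivo.shape or ish.ndim != 2 or ish.shape[1] != 2:
            raise AlignmentError("guide-posts must be matched (n, 2) coordinate arrays")
        if len(np.unique(ish, axis=0)) != len(ish):
            raise AlignmentError("duplicate ISH guide-post coordinates")
        object.__setattr__(self, "ish", ish)
        object.__setattr__(self, "invivo", invivo)

    def __len__(self) -> int:
        return self.ish.shape[0]


@dataclass(frozen=True)
class SimilarityParams:
    """Scaled rotation + translation (pixel space, x right / y down)."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]

    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        s = self.scale
        return np.array(
            [
                [s * np.cos(th), -s * np.sin(th), self.translation[0]],
                [s * np.sin(th), s * np.cos(th), self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))])
        return (self.matrix() @ h.T).T[:, :2]


def _check_not_degenerate(pts: np.ndarray) -> None:
    if pts.shape[0] < 3:
        raise AlignmentError("similarity fit needs at least 3 guide-post pairs")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise AlignmentError("guide-posts are collinear; similarity fit is underdetermined")


def fit_similarity(guideposts: GuidePostSet) -> SimilarityParams:
    """Least-squares scaled rotation mapping ISH coordinates onto in vivo."""
    _check_not_degenerate(guideposts.ish)
    tf = SimilarityTransform()
    if not _estimate(tf, guideposts.ish, guideposts.invivo):
        raise AlignmentError("similarity estimation failed (degenerate configuration)")
    if tf.scale <= 0:
        raise AlignmentError("similarity fit produced non-positive scale")
    return SimilarityParams(
        scale=float(tf.scale),
        rotation_deg=float(np.rad2deg(tf.rotation)),
        translation=(float(tf.translation[0]), float(tf.translation[1])),
    )


@dataclass
class RegistrationModel:
    """Similarity pre-alignment plus an exact landmark-interpolating warp."""

    similarity: SimilarityParams
    warp: object | None = None  # skimage transform on pre-aligned coordinates
    method: str = "similarity"
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def transform(self, pts: np.ndarray) -> np.ndarray:
        out = self.similarity.apply(pts)
        if self.warp is not None:
            out = np.asarray(self.warp(out), dtype=float)
        return out

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self.transform(pts)


WARP_METHODS = ("thin_plate_spline", "piecewise_affine", "none")


def fit_warp(guideposts: GuidePostSet, method: str = "thin_plate_spline") -> RegistrationModel:
    """Similarity pre-fit followed by a guide-post-interpolating morph.

    ``thin_plate_spline`` (default) interpolates every guide-post exactly and
    extends smoothly; ``piecewise_affine`` triangulates the landmarks (with
    exactly 3 pairs it degenerates to the single exact affine map);
    ``none`` returns the similarity alone.
    """
    if method not in WARP_METHODS:
        raise AlignmentError(f"unknown warp method {method!r}; choose from {WARP_METHODS}")
    sim = fit_similarity(guideposts)
    pre = sim.apply(guideposts.ish)
    warp = None
    if method == "thin_plate_spline":
        if len(guideposts) < 4:
            raise AlignmentError("thin-plate spline needs at least 4 guide-post pairs")
        warp = _TPSWarp(pre, guideposts.invivo)
    elif method == "piecewise_affine":
        if len(guideposts) == 3:
            warp = AffineTransform()
            if not _estimate(warp, pre, guideposts.invivo):
                raise AlignmentError("affine estimation failed")
        else:
            warp = PiecewiseAffineTransform()
            if not _estimate(warp, pre, guideposts.invivo):
                raise AlignmentError("piecewise-affine estimation failed")
    model = RegistrationModel(similarity=sim, warp=warp, method=method)
    mapped = model.transform(guideposts.ish)
    model.residuals = np.linalg.norm(mapped - guideposts.invivo, axis=1)
    return model


@dataclass(frozen=True)
class MatchResult:
    """One-to-one label transfer: index pairs (ish -> roi) and drop counts."""

    pairs: tuple[tuple[int, int], ...]
    n_beyond_max_dist: int
    n_ambiguous: int

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def transfer_labels(
    ish_points: np.ndarray,
    roi_points: np.ndarray,
    model: RegistrationModel | None,
    max_dist: float,
) -> MatchResult:
    """Greedy one-to-one matching of mapped ISH cells to in vivo ROIs.

    ISH centroids are mapped through ``model`` (pass ``None`` for identity),
    then candidate pairs are taken in ascending distance; pairs beyond
    ``max_dist`` are dropped, as are exact-distance ties competing for the
    same endpoint (counted as ambiguous).
    """
    ish_points = np.atleast_2d(np.asarray(ish_points, dtype=float))
    roi_points = np.atleast_2d(np.asarray(roi_points, dtype=float))
    if roi_points.size == 0 or ish_points.size == 0:
        return MatchResult(pairs=(), n_beyond_max_dist=0, n_ambiguous=0)
    mapped = model.transform(ish_points) if model is not None else ish_points
    d = cdist(mapped, roi_points)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[int, int]] = []
    n_ambiguous = 0
    k = 0
    flat = [(d[i, j], int(i), int(j)) for i, j in order]
    while k < len(flat):
        dist, i, j = flat[k]
        if dist > max_dist:
            break
        if i in used_i or j in used_j:
            k += 1
            continue
        # exact-distance tie sharing an endpoint among still-unused pairs -> drop both
        tied = [
            (ii, jj)
            for dd, ii, jj in flat[k + 1 :]
            if dd == dist and (ii == i or jj == j) and ii not in used_i and jj not in used_j
        ]
        if tied:
            used_i.add(i)
            used_j.add(j)
            n_ambiguous += 1 + len(tied)
            k += 1
            continue
        pairs.append((i, j))
        used_i.add(i)
        used_j.add(j)
        k += 1
    n_beyond = ish_points.shape[0] - len(pairs) - n_ambiguous
    return MatchResult(
        pairs=tuple(pairs), n_beyond_max_dist=max(n_beyond, 0), n_ambiguous=n_ambiguous
    )


@dataclass
class ComposedModel:
    """Composition of per-round registration models (applied first to last)."""

    models: tuple

    def transform(self, pts: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(pts, dtype=float))
        for m in self.models:
            out = m.transform(out)
        return out

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self.transform(pts)


def chain_rounds(
    models: Sequence[RegistrationModel],
    shared_landmarks: Sequence[np.ndarray] | None = None,
) -> tuple[ComposedModel, list[np.ndarray]]:
    """Compose per-round models; report composite residuals at shared landmarks.

    ``shared_landmarks[k]`` are coordinate pairs (src, dst) shared between
    round k and the composite target, given as (n, 2, 2) arrays; residuals
    are returned per provided landmark set (empty list if none given).
    """
    if not models:
        raise AlignmentError("chain_rounds requires at least one model")
    composite = ComposedModel(models=tuple(models))
    residuals: list[np.ndarray] = []
    if shared_landmarks:
        for lm in shared_landmarks:
            lm = np.asarray(lm, dtype=float)
            if lm.ndim != 3 or lm.shape[0] < 3:
                raise AlignmentError("each shared landmark set needs >= 3 (src, dst) pairs")
            mapped = composite.transform(lm[:, 0, :])
            residuals.append(np.linalg.norm(mapped - lm[:, 1, :], axis=1))
    return composite, residuals
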