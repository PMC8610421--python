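"""Generalized Procrustes analysis of 3D landmark configurations.

The superimposition removes position (centering), size (scaling each
configuration to unit centroid size) and orientation (proper rotations
only) so that the residual coordinate differences are pure shape. The
scheme is the partial-Procrustes convention: configurations keep unit
centroid size during rotation, and the consensus is renormalized to
unit centroid size each iteration. Reflections are disallowed —
landmarks here are collected on one side of the vertebra, so an
improper "alignment" would be anatomically meaningless.

Use :class:`GeneralizedProcrustes` as a model object::

    fit = GeneralizedProcrustes(landmark_set, tol=1e-8).fit()
    fit.aligned          # (n, k, 3) shape coordinates
    fit.consensus        # (k, 3) mean shape
    fit.centroid_sizes   # per-specimen size in mm

The building blocks (:func:`centroid_size`, :func:`optimal_rotation`,
:func:`procrustes_distance`) are exposed for direct use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .datatypes import LandmarkSet

__all__ = [
    "centroid_size",
    "optimal_rotation",
    "procrustes_distance",
    "GeneralizedProcrustes",
    "ProcrustesAlignment",
]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: root summed squared landmark distances from the centroid.

    Zero when all landmarks coincide (degenerate for scaling).
    """
    x = np.asarray(config, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("centroid size needs a (k>=2, d) coordinate matrix")
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||a @ R - b||_F.

    Both matrices must be centered and of equal shape. The solution is
    the orthogonal Procrustes rotation with the standard singular-value
    sign correction: when the unconstrained optimum is a reflection, the
    singular vector of the smallest singular value is flipped, which is
    also the deterministic tie-break for rank-deficient cross-products.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:  # fully degenerate cross-product; pick the +1 branch
        d = 1.0
    sign = np.ones(a.shape[1])
    sign[-1] = d
    return (u * sign) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared coordinate difference between aligned shapes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _center_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    centered = x - x.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return centered / size, size


@dataclass
class ProcrustesAlignment:
    """Results of a generalized Procrustes superimposition."""

    aligned: np.ndarray  # (n, k, 3), unit centroid size each
    consensus: np.ndarray  # (k, 3), unit centroid size
    centroid_sizes: np.ndarray  # (n,), original sizes in mm
    iterations: int
    converged: bool
    tolerance: float
    specimen_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    landmark_labels: tuple[str, ...] = ()

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """Shape coordinates as an (n, 3k) matrix (x1 y1 z1 x2 ...)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Procrustes distances among aligned specimens."""
        flat = self.flattened()
        diff = flat[:, None, :] - flat[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))

    def distance(self, i: Union[int, str], j: Union[int, str]) -> float:
        i = self.specimen_ids.index(i) if isinstance(i, str) else i
        j = self.specimen_ids.index(j) if isinstance(j, str) else j
        return procrustes_distance(self.aligned[i], self.aligned[j])

    def rotate_to(self, reference: np.ndarray) -> "ProcrustesAlignment":
        """Rigidly rotate the whole alignment to best match a reference shape.

        GPA output is defined only up to a global rotation (the frame of
        the initial reference); this re-expresses every aligned shape
        and the consensus in the frame of ``reference`` (centered and
        unit-scaled first), leaving all Procrustes distances unchanged.
        """
        ref = np.asarray(reference, dtype=float)
        ref = ref - ref.mean(axis=0)
        norm = np.sqrt(np.sum(ref**2))
        if norm == 0:
            raise ValueError("degenerate reference shape")
        ref = ref / norm
        rot = optimal_rotation(self.consensus, ref)
        return ProcrustesAlignment(
            aligned=self.aligned @ rot,
            consensus=self.consensus @ rot,
            centroid_sizes=self.centroid_sizes.copy(),
            iterations=self.iterations,
            converged=self.converged,
            tolerance=self.tolerance,
            specimen_ids=list(self.specimen_ids),
            groups=list(self.groups),
            landmark_labels=self.landmark_labels,
        )

    def summary(self) -> str:
        lines = [
            "Generalized Procrustes Analysis",
            "===============================",
            f"specimens:        {self.n_specimens}",
            f"landmarks:        {self.n_landmarks}",
            f"iterations:       {self.iterations}"
            + ("" if self.converged else "  (NOT converged)"),
            f"tolerance:        {self.tolerance:g}",
            f"centroid size:    {self.centroid_sizes.min():.2f}"
            f" - {self.centroid_sizes.max():.2f} mm",
            f"mean rms shape distance to consensus: "
            f"{np.mean([procrustes_distance(s, self.consensus) for s in self.aligned]):.5f}",
        ]
        return "\n".join(lines)


class GeneralizedProcrustes:
    """Iterative generalized Procrustes superimposition model.

    Parameters
    ----------
    landmarks : LandmarkSet or (n, k, 3) array
        Configurations to superimpose; at least two, same cardinality.
    tol : float
        Convergence threshold on the root summed squared displacement of
        the consensus between iterations.
    max_iter : int
        Iteration cap; non-convergence returns a result flagged
        ``converged=False`` with a warning.
    """

    def __init__(
        self,
        landmarks: Union[LandmarkSet, np.ndarray, Sequence[np.ndarray]],
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        if isinstance(landmarks, LandmarkSet):
            self._arr = landmarks.as_array()
            self._ids = landmarks.specimen_ids
            self._groups = landmarks.groups
            self._labels = landmarks.landmark_labels
        else:
            self._arr = np.asarray(landmarks, dtype=float)
            if self._arr.ndim != 3:
                raise ValueError("expected an (n, k, 3) array of configurations")
            self._ids = [f"s{i}" for i in range(self._arr.shape[0])]
            self._groups = [""] * self._arr.shape[0]
            self._labels = tuple(
                f"lm{i + 1:02d}" for i in range(self._arr.shape[1])
            )
        if self._arr.shape[0] < 2:
            raise ValueError("GPA needs at least two configurations")
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self) -> ProcrustesAlignment:
        n = self._arr.shape[0]
        scaled = []
        sizes = np.empty(n)
        for i in range(n):
            s, sizes[i] = _center_scale(self._arr[i])
            scaled.append(s)
        shapes = np.stack(scaled)

        # Initialization: if the inputs already share an orientation their
        # raw mean is a non-degenerate shape and serves directly as the
        # starting consensus (so GPA on aligned data is a fixed point);
        # otherwise (random orientations shrink the mean toward zero)
        # rotate everything to the first configuration first.
        raw_mean = shapes.mean(axis=0)
        if np.sqrt(np.sum(raw_mean**2)) > 0.5:
            consensus = _renormalize(raw_mean)
        else:
            reference = shapes[0]
            for i in range(n):
                shapes[i] = shapes[i] @ optimal_rotation(shapes[i], reference)
            consensus = _renormalize(shapes.mean(axis=0))

        converged = False
        iterations = 0
        for iterations in range(1, self.max_iter + 1):
            for i in range(n):
                shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
            new_consensus = _renormalize(shapes.mean(axis=0))
            change = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
            consensus = new_consensus
            if change < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"GPA did not converge in {self.max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        return ProcrustesAlignment(
            aligned=shapes,
            consensus=consensus,
            centroid_sizes=sizes,
            iterations=iterations,
            converged=converged,
            tolerance=self.tol,
            specimen_ids=list(self._ids),
            groups=list(self._groups),
            landmark_labels=self._labels,
        )


def _renormalize(consensus: np.ndarray) -> np.ndarray:
    centered = consensus - consensus.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size == 0:
        raise ValueError("degenerate consensus shape")
    return centered / size
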