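"""Statistics on Procrustes shape coordinates.

Covers the standard geometric-morphometrics toolkit downstream of a
superimposition:

* :func:`subset_landmarks` — restrict a landmark set to a labelled
  subset (e.g. dropping process landmarks so incompletely preserved
  specimens can be included);
* :class:`ShapePCA` — principal components of the covariance matrix of
  flattened shape coordinates;
* :func:`pairwise_procrustes_distances` — within-/between-group and
  specimen-to-group Procrustes distance collections;
* :class:`ProcrustesAnova` — permutational linear-model variance
  partition of shape (shape ~ size * group) with sequential sums of
  squares and RRPP (randomization of residuals in a permutation
  procedure) inference;
* :class:`ShapeAllometry` — multivariate regression of shape on
  centroid size with standardized regression shape scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import LandmarkConfiguration, LandmarkSet, ValidationError
from .gpa import ProcrustesAlignment

__all__ = [
    "subset_landmarks",
    "ShapePCA",
    "PCAResults",
    "pairwise_procrustes_distances",
    "DistanceTables",
    "ProcrustesAnova",
    "ProcrustesAnovaResults",
    "ShapeAllometry",
    "AllometryResults",
    "pool_genus",
]


def subset_landmarks(lms: LandmarkSet, keep: Sequence[str]) -> LandmarkSet:
    """Restrict every configuration to the landmarks named in ``keep``.

    Landmark order of the original set is preserved regardless of the
    order of ``keep``; unknown labels are an error.
    """
    keep_set = set(keep)
    unknown = keep_set - set(lms.landmark_labels)
    if unknown:
        raise ValidationError(f"unknown landmark labels: {sorted(unknown)}")
    if not keep_set:
        raise ValidationError("cannot subset to an empty landmark set")
    idx = [i for i, lab in enumerate(lms.landmark_labels) if lab in keep_set]
    labels = tuple(lms.landmark_labels[i] for i in idx)
    configs = [
        LandmarkConfiguration(
            specimen=c.specimen,
            coordinates=c.coordinates[idx],
            landmark_labels=labels,
        )
        for c in lms
    ]
    return LandmarkSet(configurations=configs, landmark_labels=labels)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResults:
    """Principal components of shape coordinate covariance."""

    eigenvalues: np.ndarray  # descending, length r
    variance_proportions: np.ndarray
    scores: np.ndarray  # (n, r)
    eigenvectors: np.ndarray  # (r, 3k), rows are components
    mean: np.ndarray  # (3k,) centering vector
    specimen_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def project(self, flat: np.ndarray) -> np.ndarray:
        """Project new flattened shape coordinates onto the components."""
        return (np.atleast_2d(flat) - self.mean) @ self.eigenvectors.T

    def summary(self, n: int = 4) -> str:
        lines = ["Shape PCA (covariance matrix)", "============================="]
        for i in range(min(n, self.n_components)):
            lines.append(
                f"PC{i + 1}: eigenvalue {self.eigenvalues[i]:.6g}, "
                f"{100 * self.variance_proportions[i]:.1f}% of variance"
            )
        return "\n".join(lines)


class ShapePCA:
    """PCA of flattened Procrustes shape coordinates via the covariance matrix.

    Component signs are fixed by making the largest-magnitude loading of
    each eigenvector positive, so results are reproducible across runs
    and libraries. Optionally fit on a subset of specimens (e.g. extant
    only) and project the rest with :meth:`PCAResults.project`.
    """

    def __init__(self, alignment: Union[ProcrustesAlignment, np.ndarray]):
        if isinstance(alignment, ProcrustesAlignment):
            self._flat = alignment.flattened()
            self._ids = alignment.specimen_ids
            self._groups = alignment.groups
        else:
            self._flat = np.asarray(alignment, dtype=float)
            if self._flat.ndim == 3:
                self._flat = self._flat.reshape(self._flat.shape[0], -1)
            self._ids = [f"s{i}" for i in range(self._flat.shape[0])]
            self._groups = [""] * self._flat.shape[0]
        if self._flat.shape[0] < 3:
            raise ValueError("PCA needs at least three specimens")

    def fit(self) -> PCAResults:
        x = self._flat
        mean = x.mean(axis=0)
        centered = x - mean
        n = x.shape[0]
        # SVD of the centered data gives the covariance eigenstructure
        # without forming the (3k x 3k) matrix
        u, svals, vt = np.linalg.svd(centered, full_matrices=False)
        eigenvalues = svals**2 / (n - 1)
        # fix component signs: largest-magnitude loading positive
        for i in range(vt.shape[0]):
            j = np.argmax(np.abs(vt[i]))
            if vt[i, j] < 0:
                vt[i] = -vt[i]
        scores = centered @ vt.T
        total = eigenvalues.sum()
        proportions = (
            eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
        )
        return PCAResults(
            eigenvalues=eigenvalues,
            variance_proportions=proportions,
            scores=scores,
            eigenvectors=vt,
            mean=mean,
            specimen_ids=list(self._ids),
            groups=list(self._groups),
        )


def shape_pca(alignment: Union[ProcrustesAlignment, np.ndarray]) -> PCAResults:
    """Convenience wrapper: ``ShapePCA(alignment).fit()``."""
    return ShapePCA(alignment).fit()


# ---------------------------------------------------------------------------
# Pairwise distances


@dataclass
class DistanceTables:
    """Procrustes distance collections grouped by comparison type."""

    within: dict[str, np.ndarray]
    between: dict[tuple[str, str], np.ndarray]
    to_group: dict[tuple[str, str], np.ndarray]  # (specimen, group) -> dists
    flagged_groups: list[str]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for g, d in self.within.items():
            rows.append(("within", g, d))
        for (g1, g2), d in self.between.items():
            rows.append(("between", f"{g1} vs {g2}", d))
        for (sid, g), d in self.to_group.items():
            rows.append(("to_group", f"{sid} vs {g}", d))
        records = []
        for kind, label, d in rows:
            if len(d) == 0:
                continue
            records.append(
                {
                    "comparison": kind,
                    "label": label,
                    "n": len(d),
                    "median": float(np.median(d)),
                    "q25": float(np.quantile(d, 0.25)),
                    "q75": float(np.quantile(d, 0.75)),
                    "min": float(np.min(d)),
                    "max": float(np.max(d)),
                }
            )
        return pd.DataFrame.from_records(records)


def pairwise_procrustes_distances(
    alignment: ProcrustesAlignment,
    groups: Optional[Sequence[str]] = None,
    target_specimens: Sequence[str] = (),
) -> DistanceTables:
    """Within-group, between-group and specimen-to-group distances.

    ``target_specimens`` (e.g. individual fossils) are excluded from the
    group pools and compared against every group separately. Groups with
    fewer than two members are flagged (their within-group collection is
    empty), not fatal.
    """
    labels = list(groups) if groups is not None else list(alignment.groups)
    if len(labels) != alignment.n_specimens:
        raise ValueError("one group label per specimen is required")
    dmat = alignment.distance_matrix()
    ids = alignment.specimen_ids
    targets = set(target_specimens)
    pool_idx: dict[str, list[int]] = {}
    for i, (sid, g) in enumerate(zip(ids, labels)):
        if sid in targets:
            continue
        pool_idx.setdefault(g, []).append(i)

    within = {}
    flagged = []
    for g, idx in pool_idx.items():
        if len(idx) < 2:
            flagged.append(g)
            within[g] = np.array([])
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        within[g] = dmat[np.array(idx)[ii], np.array(idx)[jj]]

    between = {}
    group_names = sorted(pool_idx)
    for a_i in range(len(group_names)):
        for b_i in range(a_i + 1, len(group_names)):
            ga, gb = group_names[a_i], group_names[b_i]
            between[(ga, gb)] = dmat[np.ix_(pool_idx[ga], pool_idx[gb])].ravel()

    to_group = {}
    for sid in target_specimens:
        i = ids.index(sid)
        for g, idx in pool_idx.items():
            to_group[(sid, g)] = dmat[i, idx]

    return DistanceTables(
        within=within, between=between, to_group=to_group, flagged_groups=flagged
    )


# ---------------------------------------------------------------------------
# Procrustes ANOVA (shape ~ size * group) with RRPP


def pool_genus(taxon: str) -> str:
    """Pool species-level labels into the genera used in comparative tests.

    Chimpanzees and bonobos pool to Pan; western and eastern gorillas to
    Gorilla; humans to Homo; orangutan species to Pongo. Labels that
    match no rule are returned unchanged.
    """
    t = taxon.lower()
    if "pan" in t or "chimp" in t or "bonobo" in t or "paniscus" in t:
        return "Pan"
    if "gorilla" in t:
        return "Gorilla"
    if "pongo" in t or "orang" in t or "abelii" in t or "pygmaeus" in t:
        return "Pongo"
    if "homo" in t or "human" in t or "sapiens" in t:
        return "Homo"
    return taxon


def _design_matrices(
    size: np.ndarray, groups: Sequence[str]
) -> tuple[list[np.ndarray], list[str], list[int]]:
    """Sequential nested design matrices for shape ~ size * group.

    Returns ([X0, X1, ...], term names, term dfs) where X0 is the
    intercept-only design and each subsequent matrix adds one term.
    """
    n = len(size)
    levels = sorted(set(groups))
    intercept = np.ones((n, 1))
    designs = [intercept]
    names: list[str] = []
    dfs: list[int] = []

    terms: list[tuple[str, np.ndarray]] = []
    if np.ptp(size) > 0:
        terms.append(("size", size.reshape(-1, 1)))
    else:
        warnings.warn("constant centroid size: size term dropped", RuntimeWarning)
    if len(levels) > 1:
        dummies = np.column_stack(
            [(np.asarray(groups) == lv).astype(float) for lv in levels[1:]]
        )
        terms.append(("group", dummies))
        if np.ptp(size) > 0:
            terms.append(("size:group", size.reshape(-1, 1) * dummies))
    else:
        warnings.warn(
            "single group: group and interaction terms dropped", RuntimeWarning
        )

    current = intercept
    for name, cols in terms:
        current = np.hstack([current, cols])
        designs.append(current)
        names.append(name)
        dfs.append(cols.shape[1])
    return designs, names, dfs


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


@dataclass
class ProcrustesAnovaResults:
    """Variance partition of shape with permutation inference.

    ``table`` rows follow the sequential term order plus Residuals and
    Total; columns are Df, SS, MS, Rsq, F, Z, and the permutation p
    (``Pr(>F)``). Z is the observed F standardized within its
    permutation distribution (observed statistic included).
    """

    table: pd.DataFrame
    n_permutations: int
    seed: Optional[int]
    term_permutation_stats: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return [
            t for t in self.table.index if t not in ("Residuals", "Total")
        ]

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "Pr(>F)"])

    def summary(self) -> str:
        lines = [
            "Procrustes ANOVA (sequential SS, RRPP permutation)",
            "==================================================",
            f"permutations: {self.n_permutations} (+ observed), seed={self.seed}",
            "",
            self.table.to_string(
                float_format=lambda v: f"{v:.5f}", na_rep=""
            ),
        ]
        return "\n".join(lines)


class ProcrustesAnova:
    """Permutational ANOVA of shape coordinates: shape ~ size * group.

    Sums of squares are sequential (type I) in the order size, group,
    size:group, summed over all shape coordinates (equivalently,
    Procrustes distance-based). F for each term uses the residual mean
    square of the full model. Significance comes from RRPP: for each
    term, residuals of the reduced model (all preceding terms) are
    randomized across specimens, the term's statistic is recomputed, and
    the p-value is the proportion of the reference distribution
    (observed included) at or above the observed F.

    Parameters
    ----------
    shape : ProcrustesAlignment or (n, p) array
        Aligned shape coordinates (flattened or (n, k, 3)).
    size : array of float
        Centroid sizes, used untransformed by default.
    groups : sequence of str, optional
        Group labels; defaults to the alignment's groups.
    log_size : bool
        Use log centroid size instead (off by default).
    """

    def __init__(
        self,
        shape: Union[ProcrustesAlignment, np.ndarray],
        size: Optional[Sequence[float]] = None,
        groups: Optional[Sequence[str]] = None,
        log_size: bool = False,
    ):
        if isinstance(shape, ProcrustesAlignment):
            self._y = shape.flattened()
            if size is None:
                size = shape.centroid_sizes
            if groups is None:
                groups = shape.groups
        else:
            self._y = np.asarray(shape, dtype=float)
            if self._y.ndim == 3:
                self._y = self._y.reshape(self._y.shape[0], -1)
            if size is None:
                raise ValueError("size is required with a raw coordinate array")
            if groups is None:
                raise ValueError("groups are required with a raw coordinate array")
        self._size = np.asarray(size, dtype=float)
        if log_size:
            self._size = np.log(self._size)
        self._groups = list(groups)
        n = self._y.shape[0]
        if len(self._size) != n or len(self._groups) != n:
            raise ValueError("size and groups must match the number of specimens")
        counts = pd.Series(self._groups).value_counts()
        if (counts < 2).any() and counts.size > 1:
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 members: {small}")

    def fit(
        self, n_perm: int = 999, seed: Optional[int] = None
    ) -> ProcrustesAnovaResults:
        y = self._y
        n = y.shape[0]
        designs, names, dfs = _design_matrices(self._size, self._groups)
        hats = [_hat(x) for x in designs]
        h_full = hats[-1]
        df_model = sum(dfs)
        df_res = n - 1 - df_model
        if df_res <= 0:
            raise ValueError("no residual degrees of freedom")

        center = y.mean(axis=0)
        ss_total = float(np.sum((y - center) ** 2))
        rss_full = float(np.sum(((np.eye(n) - h_full) @ y) ** 2))
        ms_res = rss_full / df_res

        # projection onto each term's incremental subspace
        projectors = [hats[i + 1] - hats[i] for i in range(len(names))]
        ss_terms = [float(np.sum((p @ y) ** 2)) for p in projectors]
        f_terms = [
            (ss / df) / ms_res for ss, df in zip(ss_terms, dfs)
        ]

        rng = np.random.default_rng(seed)
        resid_proj = np.eye(n) - h_full
        perm_stats: dict[str, np.ndarray] = {}
        p_values = []
        z_values = []
        for t, (name, p_j, df_j, f_obs) in enumerate(
            zip(names, projectors, dfs, f_terms)
        ):
            h_red = hats[t]
            fitted = h_red @ y
            resid = y - fitted
            stats = np.empty(n_perm + 1)
            stats[0] = f_obs
            for b in range(n_perm):
                yb = fitted + resid[rng.permutation(n)]
                ss_b = float(np.sum((p_j @ yb) ** 2))
                rss_b = float(np.sum((resid_proj @ yb) ** 2))
                stats[b + 1] = (ss_b / df_j) / (rss_b / df_res)
            perm_stats[name] = stats
            p_values.append(float(np.mean(stats >= f_obs - 1e-12)))
            sd = stats.std(ddof=1)
            z_values.append(
                float((f_obs - stats.mean()) / sd) if sd > 0 else np.nan
            )

        rows = {}
        for name, df_j, ss, f, z, p in zip(
            names, dfs, ss_terms, f_terms, z_values, p_values
        ):
            rows[name] = {
                "Df": df_j,
                "SS": ss,
                "MS": ss / df_j,
                "Rsq": ss / ss_total,
                "F": f,
                "Z": z,
                "Pr(>F)": p,
            }
        rows["Residuals"] = {
            "Df": df_res,
            "SS": rss_full,
            "MS": ms_res,
            "Rsq": rss_full / ss_total,
            "F": np.nan,
            "Z": np.nan,
            "Pr(>F)": np.nan,
        }
        rows["Total"] = {
            "Df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "Rsq": np.nan,
            "F": np.nan,
            "Z": np.nan,
            "Pr(>F)": np.nan,
        }
        table = pd.DataFrame.from_dict(rows, orient="index")
        table["Df"] = table["Df"].astype(int)
        return ProcrustesAnovaResults(
            table=table,
            n_permutations=n_perm,
            seed=seed,
            term_permutation_stats=perm_stats,
        )


# ---------------------------------------------------------------------------
# Allometry


@dataclass
class AllometryResults:
    """Multivariate regression of shape on centroid size."""

    coefficients: np.ndarray  # (p,) slope vector over shape coordinates
    intercept: np.ndarray  # (p,) shape at size 0 (mean - b * mean size)
    scores: np.ndarray  # (n,) standardized regression shape scores
    sizes: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    @property
    def direction(self) -> np.ndarray:
        """Unit-normalized regression vector."""
        norm = np.linalg.norm(self.coefficients)
        if norm == 0:
            return np.zeros_like(self.coefficients)
        return self.coefficients / norm

    def predict(self, size: float) -> np.ndarray:
        """Predicted flattened shape at a given centroid size."""
        return self.intercept + self.coefficients * float(size)

    @property
    def predicted_extremes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.predict(self.sizes.min()),
            self.predict(self.sizes.max()),
        )

    def score_size_correlation(self) -> float:
        return float(np.corrcoef(self.scores, self.sizes)[0, 1])

    def summary(self) -> str:
        return "\n".join(
            [
                "Shape ~ centroid size (multivariate regression)",
                "===============================================",
                f"specimens:                 {len(self.scores)}",
                f"|slope vector|:            {np.linalg.norm(self.coefficients):.6g}",
                f"score-size correlation:    {self.score_size_correlation():.3f}",
                f"size range:                {self.sizes.min():.2f}"
                f" - {self.sizes.max():.2f} mm",
            ]
        )


class ShapeAllometry:
    """Fit the multivariate least-squares regression of shape on size.

    The standardized regression shape score of each specimen is the
    projection of its mean-centered shape coordinates onto the
    unit-normalized regression vector; plotted against size it
    visualizes the allometric trend.
    """

    def __init__(
        self,
        shape: Union[ProcrustesAlignment, np.ndarray],
        size: Optional[Sequence[float]] = None,
    ):
        if isinstance(shape, ProcrustesAlignment):
            self._y = shape.flattened()
            if size is None:
                size = shape.centroid_sizes
            self._ids = shape.specimen_ids
            self._groups = shape.groups
        else:
            self._y = np.asarray(shape, dtype=float)
            if self._y.ndim == 3:
                self._y = self._y.reshape(self._y.shape[0], -1)
            if size is None:
                raise ValueError("size is required with a raw coordinate array")
            self._ids = [f"s{i}" for i in range(self._y.shape[0])]
            self._groups = [""] * self._y.shape[0]
        self._size = np.asarray(size, dtype=float)
        if self._y.shape[0] != len(self._size):
            raise ValueError("size must match the number of specimens")
        if self._y.shape[0] < 2:
            raise ValueError("allometric regression needs at least 2 specimens")
        if np.ptp(self._size) == 0:
            raise ValueError("centroid size has zero variance")

    def fit(self) -> AllometryResults:
        y = self._y
        s = self._size
        s_c = s - s.mean()
        y_mean = y.mean(axis=0)
        y_c = y - y_mean
        b = (y_c.T @ s_c) / float(s_c @ s_c)
        direction = b / np.linalg.norm(b) if np.linalg.norm(b) > 0 else b
        scores = y_c @ direction
        intercept = y_mean - b * s.mean()
        return AllometryResults(
            coefficients=b,
            intercept=intercept,
            scores=scores,
            sizes=s.copy(),
            specimen_ids=list(self._ids),
            groups=list(self._groups),
        )
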