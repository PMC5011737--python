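"""Principal coordinates analysis and canonical analysis of principal
coordinates (CAP).

CAP asks whether an *a priori* grouping of samples explains the structure of
a dissimilarity matrix.  The dissimilarities are first embedded by PCoA
(eigendecomposition of the Gower-centered matrix); the first ``m``
*orthonormal* principal-coordinate axes are then related to the centered
group-indicator space by canonical correlation.  With ``Q_m`` the n x m
orthonormal axis matrix and ``H`` the hat (projection) matrix of the
centered group indicators, the squared canonical correlations ``delta^2``
are the eigenvalues of ``Q_m' H Q_m`` and the trace statistic is
``tr(Q_m' H Q_m)``.  Significance is assessed by permuting group labels;
classification quality by leave-one-out allocation of each sample to the
nearest group centroid in canonical space, with the left-out sample placed
by Gower's add-a-point projection.

The estimators follow scikit-learn conventions (``fit``, ``predict``,
``get_params``; fitted attributes carry a trailing underscore) and accept
either raw count tables or precomputed dissimilarity matrices.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .community import bray_curtis, sqrt_transform

__all__ = ["PCoA", "CAP", "cap", "loo_allocation", "pcoa"]

_EPS = 1e-12


def _as_square(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, DistanceMatrix):
        return np.asarray(X.data, dtype=float), list(X.ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.index))
    return np.asarray(X, dtype=float), None


class PCoA(TransformerMixin, BaseEstimator):
    """Principal coordinates analysis of a dissimilarity matrix.

    Eigendecomposition of the Gower-centered matrix ``G = J(-D^2/2)J`` with
    ``J = I - 11'/n``.  Axes with eigenvalues at or below numerical zero
    (including negative ones, which arise because Bray-Curtis is a
    semimetric) are excluded from the coordinate system; the relative
    magnitude of the negative part is reported as
    ``negative_eigenvalue_mass_``.  No Lingoes/Cailliez correction is
    applied.

    Attributes
    ----------
    eigenvalues_ : ndarray
        All n eigenvalues, descending.
    axes_ : ndarray of shape (n, r)
        Orthonormal eigenvectors of the retained (positive) axes.
    coordinates_ : ndarray of shape (n, r)
        Scaled sample coordinates ``axes_ * sqrt(eigenvalue)`` whose
        Euclidean distances reproduce the input for embeddable data.
    negative_eigenvalue_mass_ : float
        sum(|negative eigenvalues|) / sum(|eigenvalues|).
    """

    def fit(self, X, y=None):
        D, ids = _as_square(X)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        n = D.shape[0]
        A = -0.5 * D**2
        row = A.mean(axis=1, keepdims=True)
        grand = A.mean()
        G = A - row - row.T + grand
        lam, vec = np.linalg.eigh((G + G.T) / 2.0)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        tol = max(abs(lam[0]), 1.0) * n * np.finfo(float).eps
        pos = lam > tol
        self.n_samples_ = n
        self.ids_ = ids
        self.eigenvalues_ = lam
        self.axes_ = vec[:, pos]
        self.positive_eigenvalues_ = lam[pos]
        self.coordinates_ = self.axes_ * np.sqrt(lam[pos])
        total = np.abs(lam).sum()
        self.negative_eigenvalue_mass_ = (
            float(np.abs(lam[lam < -tol]).sum() / total) if total > 0 else 0.0
        )
        self._row_means = row.ravel()
        self._grand = grand
        return self

    def project(self, d_new) -> np.ndarray:
        """Gower add-a-point: orthonormal-axis coordinates of new samples.

        Parameters
        ----------
        d_new : array of shape (k, n) or (n,)
            Dissimilarities from each new sample to the *training* samples.
        """
        d = np.atleast_2d(np.asarray(d_new, dtype=float))
        if d.shape[1] != self.n_samples_:
            raise ValueError("need dissimilarities to every training sample")
        a = -0.5 * d**2
        g = a - self._row_means - a.mean(axis=1, keepdims=True) + self._grand
        return (g @ self.axes_) / self.positive_eigenvalues_

    def transform(self, X) -> np.ndarray:
        """Scaled PCo coordinates of new samples from their dissimilarities
        to the training samples (rows of ``X``, shape (k, n))."""
        return self.project(X) * np.sqrt(self.positive_eigenvalues_)


def pcoa(D) -> PCoA:
    """Functional wrapper: fitted :class:`PCoA` for a dissimilarity matrix."""
    return PCoA().fit(D)


def _group_basis(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Orthonormal basis (n x g-1) of the column-centered group indicators."""
    onehot = (y[:, None] == classes[None, :]).astype(float)
    centered = onehot - onehot.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, s > s[0] * 1e-9] if s.size and s[0] > 0 else u[:, :0]


def _distinct_label_orders(y: np.ndarray, limit: int = 200_000):
    """All distinct orderings of the label multiset ``y`` (exact permutation null)."""
    classes, counts = np.unique(y, return_counts=True)
    total = math.factorial(len(y))
    for c in counts:
        total //= math.factorial(int(c))
    if total > limit:
        raise ValueError(
            f"{total} distinct label orders exceed the exact-enumeration limit; "
            "use random permutations"
        )

    def rec(positions: tuple[int, ...], k: int, current):
        if k == len(classes):
            out = np.empty(len(y), dtype=classes.dtype)
            for cls, pos in zip(classes, current):
                out[list(pos)] = cls
            yield out
            return
        if k == len(classes) - 1:
            yield from rec((), k + 1, current + [positions])
            return
        for chosen in combinations(positions, int(counts[k])):
            rest = tuple(p for p in positions if p not in set(chosen))
            yield from rec(rest, k + 1, current + [chosen])

    yield from rec(tuple(range(len(y))), 0, [])


class CAP(ClassifierMixin, BaseEstimator):
    """Canonical analysis of principal coordinates with permutation tests.

    Parameters
    ----------
    m : int or None
        Number of orthonormal PCo axes entering the canonical analysis.
        ``None`` uses every positive axis.  Requests above the positive rank
        are reduced with a warning.
    n_permutations : int
        Random label permutations for the p-values (ignored when
        ``permutation="exact"``).  ``p = (#{perm stat >= observed} + 1)/(B + 1)``.
    permutation : {"random", "exact"}
        "exact" enumerates every distinct labeling (small n only) and uses
        the exact permutation p ``#{stat >= observed}/#labelings`` (the
        identity labeling is included, so p >= 1/#labelings).
    metric : {"braycurtis", "precomputed"}
        With "braycurtis", ``fit`` expects a sample x taxon abundance table
        (square-root transformed first when ``transform="sqrt"``); with
        "precomputed", a square dissimilarity matrix.
    transform : {"sqrt", None}
        Abundance pre-transform applied before the dissimilarity.
    random_state : int, Generator or None
        Seeds the permutation stream.

    Attributes
    ----------
    delta_sq_ : ndarray
        Squared canonical correlations, descending, in [0, 1].
    trace_ : float
        Sum of squared canonical correlations, tr(Q_m' H Q_m).
    p_delta_sq_, p_trace_ : float
        Permutation p-values for the first squared canonical correlation and
        for the trace.
    loo_allocation_ : computed lazily by :meth:`loo_allocation`.
    """

    def __init__(
        self,
        m: int | None = None,
        n_permutations: int = 9999,
        permutation: str = "random",
        metric: str = "braycurtis",
        transform: str | None = "sqrt",
        random_state=None,
    ):
        self.m = m
        self.n_permutations = n_permutations
        self.permutation = permutation
        self.metric = metric
        self.transform = transform
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _dissimilarity(self, X) -> tuple[np.ndarray, np.ndarray | None]:
        if self.metric == "precomputed":
            D, _ = _as_square(X)
            return D, None
        if self.metric != "braycurtis":
            raise ValueError("metric must be 'braycurtis' or 'precomputed'")
        Y, _, _ = _to_abundance(X, self.transform)
        return np.asarray(bray_curtis(Y).data), Y

    def _stats(self, U: np.ndarray, Qm: np.ndarray) -> tuple[float, float]:
        M = U.T @ Qm
        s = np.linalg.svd(M, compute_uv=False)
        s2 = np.clip(s**2, 0.0, 1.0)
        return float(s2[0]) if s2.size else 0.0, float(s2.sum())

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(list(y))
        D, Y = self._dissimilarity(X)
        if D.shape[0] != y.shape[0]:
            raise ValueError("one group label per sample is required")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("CAP needs at least 2 groups")
        self.classes_ = classes
        self.y_ = y
        self._Y = Y
        self.dissimilarity_ = D
        self.pcoa_ = PCoA().fit(D)

        rank = self.pcoa_.axes_.shape[1]
        m = rank if self.m is None else int(self.m)
        if m < 1:
            raise ValueError("m must be >= 1")
        if m > rank:
            warnings.warn(f"m={m} exceeds the positive PCoA rank {rank}; using m={rank}",
                          stacklevel=2)
            m = rank
        self.m_ = m
        Qm = self.pcoa_.axes_[:, :m]

        U = _group_basis(y, classes)
        M = U.T @ Qm
        _, s, Wt = np.linalg.svd(M, full_matrices=False)
        k = min(classes.size - 1, m)
        self.delta_sq_ = np.clip(s[:k] ** 2, 0.0, 1.0)
        self.trace_ = float(np.clip(s**2, 0.0, 1.0).sum())
        self.canonical_axes_ = Wt[:k].T  # m x k, in PCo-axis space
        self.scores_ = Qm @ self.canonical_axes_  # n x k canonical scores
        self.centroids_ = np.vstack(
            [self.scores_[y == c].mean(axis=0) for c in classes]
        )

        self._permutation_test(U, Qm, y)
        return self

    def _permutation_test(self, U: np.ndarray, Qm: np.ndarray, y: np.ndarray) -> None:
        obs_d1, obs_tr = self._stats(U, Qm)
        if self.permutation == "exact":
            d1s, trs = [], []
            for perm_y in _distinct_label_orders(y):
                Up = _group_basis(perm_y, self.classes_)
                d1, tr = self._stats(Up, Qm)
                d1s.append(d1)
                trs.append(tr)
            d1s, trs = np.asarray(d1s), np.asarray(trs)
            self.n_permutations_ = d1s.size
            self.p_delta_sq_ = float(np.mean(d1s >= obs_d1 - _EPS))
            self.p_trace_ = float(np.mean(trs >= obs_tr - _EPS))
            return
        if self.permutation != "random":
            raise ValueError("permutation must be 'random' or 'exact'")
        b = int(self.n_permutations)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        n = y.shape[0]
        ge_d1 = ge_tr = 0
        for _ in range(b):
            perm = rng.permutation(n)
            d1, tr = self._stats(U[perm], Qm)
            ge_d1 += d1 >= obs_d1 - _EPS
            ge_tr += tr >= obs_tr - _EPS
        self.n_permutations_ = b
        self.p_delta_sq_ = (ge_d1 + 1) / (b + 1)
        self.p_trace_ = (ge_tr + 1) / (b + 1)

    def predict(self, X) -> np.ndarray:
        """Allocate new samples to the nearest group centroid in canonical space.

        Requires ``metric="braycurtis"`` (new raw abundance rows are related
        to the training samples through the stored transformed table).
        """
        if self.metric == "precomputed":
            raise ValueError("predict is unavailable with a precomputed dissimilarity; "
                             "use project_dissimilarities")
        Ynew, _, _ = _to_abundance(X, self.transform)
        d = _cross_braycurtis(Ynew, self._Y)
        return self.project_dissimilarities(d)

    def project_dissimilarities(self, d_new) -> np.ndarray:
        """Allocate new samples given their dissimilarities to the training set."""
        q = self.pcoa_.project(d_new)[:, : self.m_]
        scores = q @ self.canonical_axes_
        dist = np.linalg.norm(scores[:, None, :] - self.centroids_[None], axis=2)
        return self.classes_[np.argmin(dist, axis=1)]

    def loo_allocation(self) -> pd.DataFrame:
        """Leave-one-out allocation success, per group and total.

        Each sample is held out; PCoA and the canonical axes are refit on the
        remaining n-1 samples; the held-out sample is placed by add-a-point
        projection and allocated to the nearest centroid.  A group of size 1
        can never be recovered (its centroid vanishes from the fold) and is
        counted as a structural miss with a warning.

        Returns
        -------
        DataFrame indexed by group (plus a ``"total"`` row) with columns
        ``correct``, ``n`` and ``success_pct``; also stored as
        ``loo_allocation_`` with predictions in ``loo_predictions_``.
        """
        D, y = self.dissimilarity_, self.y_
        n = y.shape[0]
        _, counts = np.unique(y, return_counts=True)
        if np.any(counts == 1):
            warnings.warn("group(s) of size 1: their samples are structural misses "
                          "under leave-one-out", stacklevel=2)
        preds = np.empty(n, dtype=self.classes_.dtype)
        for i in range(n):
            keep = np.arange(n) != i
            D_fold = D[np.ix_(keep, keep)]
            y_fold = y[keep]
            classes_fold = np.unique(y_fold)
            pc = PCoA().fit(D_fold)
            m_fold = min(self.m_, pc.axes_.shape[1])
            Qm = pc.axes_[:, :m_fold]
            U = _group_basis(y_fold, classes_fold)
            _, s, Wt = np.linalg.svd(U.T @ Qm, full_matrices=False)
            k = min(classes_fold.size - 1, m_fold)
            W = Wt[:k].T
            scores = Qm @ W
            centroids = np.vstack([scores[y_fold == c].mean(axis=0) for c in classes_fold])
            q_new = pc.project(D[i, keep])[:, :m_fold]
            c_new = q_new @ W
            dist = np.linalg.norm(centroids - c_new, axis=1)
            preds[i] = classes_fold[int(np.argmin(dist))]
        rows = {}
        for c in self.classes_:
            mask = y == c
            rows[str(c)] = {
                "correct": int((preds[mask] == c).sum()),
                "n": int(mask.sum()),
            }
        rows["total"] = {"correct": int((preds == y).sum()), "n": n}
        out = pd.DataFrame.from_dict(rows, orient="index")
        out["success_pct"] = out["correct"] / out["n"] * 100.0
        self.loo_predictions_ = preds
        self.loo_allocation_ = out
        return out

    def score(self, X, y) -> float:
        """Mean allocation accuracy of :meth:`predict` on new samples."""
        return float(np.mean(self.predict(X) == np.asarray(list(y))))


def _to_abundance(X, transform: str | None):
    if transform not in (None, "sqrt"):
        raise ValueError("transform must be 'sqrt' or None")
    if isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
        ids, taxa = list(map(str, X.index)), list(map(str, X.columns))
    else:
        arr = np.asarray(X, dtype=float)
        ids = taxa = None
    if transform == "sqrt":
        arr = sqrt_transform(arr)
    return arr, ids, taxa


def _cross_braycurtis(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Bray-Curtis between each row of A (new) and each row of B (training)."""
    num = np.abs(A[:, None, :] - B[None, :, :]).sum(axis=2)
    den = (A[:, None, :] + B[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return d


def cap(
    X,
    groups,
    m: int | None = None,
    n_permutations: int = 9999,
    seed=None,
    metric: str = "braycurtis",
    transform: str | None = "sqrt",
    permutation: str = "random",
) -> CAP:
    """Fit CAP on an abundance table (or precomputed dissimilarities) and groups."""
    return CAP(
        m=m,
        n_permutations=n_permutations,
        permutation=permutation,
        metric=metric,
        transform=transform,
        random_state=seed,
    ).fit(X, groups)


def loo_allocation(X, groups, m: int | None = None, metric: str = "braycurtis",
                   transform: str | None = "sqrt") -> pd.DataFrame:
    """Leave-one-out allocation table without a permutation test."""
    model = CAP(m=m, n_permutations=0, metric=metric, transform=transform).fit(X, groups)
    return model.loo_allocation()
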