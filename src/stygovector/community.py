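"""Community-level statistics for sample x taxon count tables.

Implements the dissimilarity / decomposition / diversity layer used to ask
whether stygofauna carry microbial communities distinct from the surrounding
groundwater: square-root transformation, Bray-Curtis dissimilarity, SIMPER
decomposition of between-group dissimilarity into per-taxon contributions,
and rarefaction curves (analytic expected richness plus Faith's phylogenetic
diversity under seeded subsampling).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

__all__ = [
    "sqrt_transform",
    "bray_curtis",
    "SimperResult",
    "simper",
    "rarefaction_expected_richness",
    "faith_pd",
    "RarefactionCurve",
    "rarefaction_curve",
    "as_tree",
]

#: Diss/SD ratio above which a taxon is called a consistent discriminator.
DISS_SD_THRESHOLD = 1.4


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.index)), list(map(str, X.columns))
    return np.asarray(X, dtype=float), None, None


def sqrt_transform(X):
    """Element-wise square root of a non-negative abundance matrix.

    Down-weights dominant taxa before Bray-Curtis so that the dissimilarity
    is not driven solely by the most abundant organisms.
    """
    arr, _, _ = _as_matrix(X)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(np.sqrt(arr), index=X.index, columns=X.columns)
    return np.sqrt(arr)


def bray_curtis(X, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between the rows of ``X``.

    d(a, b) = sum_i |y_ai - y_bi| / sum_i (y_ai + y_bi), in [0, 1].
    A pair of all-zero samples has an undefined (0/0) dissimilarity and is
    defined here as 0 with a warning.
    """
    arr, row_ids, _ = _as_matrix(X)
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(arr, metric="braycurtis")
    if np.any(~np.isfinite(condensed)):
        warnings.warn(
            "pair(s) of all-zero samples: Bray-Curtis undefined (0/0), defined as 0",
            stacklevel=2,
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    if ids is None:
        ids = row_ids
    return DistanceMatrix(squareform(condensed), ids=ids)


@dataclass(frozen=True)
class SimperResult:
    """Per-taxon decomposition of the between-group Bray-Curtis dissimilarity.

    ``table`` has one row per taxon (sorted by mean contribution, descending):
    ``mean_contribution_pct``, ``sd_contribution_pct``, ``diss_sd_ratio`` and
    ``discriminating`` (ratio strictly greater than 1.4).  Contributions sum
    to ``overall_mean_dissimilarity_pct``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    overall_mean_dissimilarity_pct: float
    n_pairs: int


def simper(X, groups, group_a: str, group_b: str) -> SimperResult:
    """SIMPER: which taxa drive the dissimilarity between two groups.

    For every cross-group sample pair (a, b), taxon i contributes
    |y_ai - y_bi| / sum_k (y_ak + y_bk) x 100 percentage points to the pair's
    Bray-Curtis dissimilarity.  The mean and SD of each taxon's contribution
    are taken over all pairs; taxa with mean/SD (Diss/SD) above 1.4
    discriminate the groups consistently rather than erratically.

    Parameters
    ----------
    X
        Transformed abundance matrix, samples x taxa (DataFrame or array).
    groups
        Group label per sample, aligned with the rows of ``X``.
    """
    arr, row_ids, col_ids = _as_matrix(X)
    groups = np.asarray(list(groups))
    if groups.shape[0] != arr.shape[0]:
        raise ValueError("one group label per sample is required")
    idx_a = np.flatnonzero(groups == group_a)
    idx_b = np.flatnonzero(groups == group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")

    # contributions[pair, taxon] in percentage points
    contribs = []
    for i in idx_a:
        for j in idx_b:
            denom = (arr[i] + arr[j]).sum()
            if denom == 0:
                contribs.append(np.zeros(arr.shape[1]))
            else:
                contribs.append(np.abs(arr[i] - arr[j]) / denom * 100.0)
    contribs = np.asarray(contribs)
    mean = contribs.mean(axis=0)
    sd = contribs.std(axis=0, ddof=1) if contribs.shape[0] > 1 else np.zeros(arr.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
    inf_mask = (sd == 0) & (mean > 0)
    ratio = np.where(inf_mask, np.inf, ratio)
    if np.any(inf_mask):
        warnings.warn("taxon with zero contribution SD but positive mean: ratio infinite",
                      stacklevel=2)
    taxa = col_ids if col_ids is not None else [f"taxon_{k}" for k in range(arr.shape[1])]
    table = pd.DataFrame(
        {
            "mean_contribution_pct": mean,
            "sd_contribution_pct": sd,
            "diss_sd_ratio": ratio,
            "discriminating": ratio > DISS_SD_THRESHOLD,
        },
        index=pd.Index(taxa, name="taxon_id"),
    ).sort_values("mean_contribution_pct", ascending=False, kind="stable")
    return SimperResult(
        table=table,
        group_a=str(group_a),
        group_b=str(group_b),
        overall_mean_dissimilarity_pct=float(mean.sum()),
        n_pairs=contribs.shape[0],
    )


def rarefaction_expected_richness(counts, depth: int) -> float:
    """Expected number of taxa observed in a subsample of ``depth`` sequences.

    Closed-form hypergeometric expectation over subsampling without
    replacement: E[S_d] = sum_i [1 - C(N - N_i, d) / C(N, d)].
    """
    n_i = np.asarray(counts, dtype=np.int64)
    if np.any(n_i < 0):
        raise ValueError("counts must be non-negative")
    n_total = int(n_i.sum())
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > n_total:
        raise ValueError(f"depth {depth} exceeds sample total {n_total}")
    n_i = n_i[n_i > 0]

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rem = n_total - n_i
    p_absent = np.zeros(n_i.size)
    ok = rem >= depth
    p_absent[ok] = np.exp(log_choose(rem[ok], depth) - log_choose(n_total, depth))
    return float(np.sum(1.0 - p_absent))


def as_tree(tree) -> TreeNode:
    """Coerce a newick string / file-like / TreeNode into a TreeNode."""
    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(_io.StringIO(str(tree)))


def faith_pd(tree, present_taxa) -> float:
    """Faith's phylogenetic diversity of a taxon set.

    Total branch length of the minimal rooted subtree spanning the root and
    every present taxon.
    """
    t = as_tree(tree)
    tips = {tip.name for tip in t.tips()}
    present = list(present_taxa)
    unknown = set(present) - tips
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if not present:
        return 0.0
    counts = np.ones(len(present), dtype=int)
    return float(_skbio_faith_pd(counts, present, t, validate=False))


def _edge_paths(tree: TreeNode) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-tip arrays of edge indices on the tip-to-root path, plus edge lengths."""
    nodes = list(tree.postorder(include_self=False))
    index = {id(n): k for k, n in enumerate(nodes)}
    lengths = np.array([n.length if n.length is not None else 0.0 for n in nodes])
    paths: dict[str, np.ndarray] = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node.parent is not None:
            path.append(index[id(node)])
            node = node.parent
        paths[tip.name] = np.asarray(path, dtype=np.intp)
    return paths, lengths


@dataclass(frozen=True)
class RarefactionCurve:
    """Per-sample diversity as a function of subsampling depth.

    ``richness`` (and ``phylogenetic_diversity`` when a tree was given) are
    DataFrames indexed by sample with one column per depth; entries are NaN
    where a sample is shallower than the requested depth.
    """

    depths: np.ndarray
    richness: pd.DataFrame
    phylogenetic_diversity: pd.DataFrame | None
    iterations: int
    seed: int | None


def rarefaction_curve(
    table: pd.DataFrame,
    depths=None,
    tree=None,
    iterations: int = 10,
    seed: int | None = None,
    max_depth: int = 10_000,
    step: int = 500,
) -> RarefactionCurve:
    """Rarefaction curves for every sample of a count table.

    Expected richness is analytic (hypergeometric); phylogenetic diversity is
    the mean of Faith's PD over ``iterations`` nested subsamples per sample
    (each iteration draws one random reading order of the sample's sequences
    and evaluates every depth on its prefixes, so each iteration's curve —
    and hence the mean — is monotone in depth).  Samples shallower than a
    depth are excluded at that depth with a warning, not extrapolated.

    Parameters
    ----------
    table
        Count DataFrame, samples x taxa.
    depths
        Ascending positive depths; default ``step, 2*step, ... , max_depth``.
    """
    counts = table.to_numpy(dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if depths is None:
        depths = np.arange(step, max_depth + 1, step, dtype=np.int64)
    depths = np.asarray(depths, dtype=np.int64)
    if depths.size == 0 or np.any(depths <= 0) or np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be positive and strictly ascending")

    t = as_tree(tree) if tree is not None else None
    if t is not None:
        paths, lengths = _edge_paths(t)
        taxon_paths = []
        for name in table.columns:
            if str(name) not in paths:
                raise ValueError(f"taxon {name!r} not in tree")
            taxon_paths.append(paths[str(name)])

    rng = np.random.default_rng(seed)
    rich = np.full((counts.shape[0], depths.size), np.nan)
    pd_vals = np.full((counts.shape[0], depths.size), np.nan) if t is not None else None

    for s in range(counts.shape[0]):
        total = int(counts[s].sum())
        usable = depths <= total
        if not usable.all():
            warnings.warn(
                f"sample {table.index[s]!r} has {total} sequences; "
                f"depths beyond that are excluded",
                stacklevel=2,
            )
        for k in np.flatnonzero(usable):
            rich[s, k] = rarefaction_expected_richness(counts[s], int(depths[k]))
        if t is None or not usable.any():
            continue
        seq = np.repeat(np.arange(counts.shape[1]), counts[s])
        cut_depths = depths[usable]
        acc = np.zeros(cut_depths.size)
        for _ in range(iterations):
            order = rng.permutation(seq)
            included = np.zeros(lengths.size, dtype=bool)
            seen = np.zeros(counts.shape[1], dtype=bool)
            running = 0.0
            ci = 0
            for pos, taxon in enumerate(order, start=1):
                if not seen[taxon]:
                    seen[taxon] = True
                    path = taxon_paths[taxon]
                    new = path[~included[path]]
                    running += lengths[new].sum()
                    included[new] = True
                while ci < cut_depths.size and pos == cut_depths[ci]:
                    acc[ci] += running
                    ci += 1
                if ci == cut_depths.size:
                    break
        pd_vals[s, np.flatnonzero(usable)] = acc / iterations

    cols = pd.Index(depths, name="depth")
    return RarefactionCurve(
        depths=depths,
        richness=pd.DataFrame(rich, index=table.index, columns=cols),
        phylogenetic_diversity=(
            pd.DataFrame(pd_vals, index=table.index, columns=cols) if t is not None else None
        ),
        iterations=iterations,
        seed=seed,
    )
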