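"""Community statistics: distances, ordination, environmental fitting,
group tests, hierarchical clustering, and co-expression networks.

Distance matrices use the scikit-bio ``DistanceMatrix`` container.  NMDS
minimizes Kruskal stress-1 by isotonic-regression-based majorization
(SMACOF), taking the best of several restarts (the first initialized from
classical scaling, the rest random) and returning a centered,
principal-axis-rotated configuration.  ``envfit``, ``bioenv``, and
``permanova`` use vectorized label permutations so that large calibration
studies are cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
import inspect

from sklearn.manifold import MDS as _SkMDS
from sklearn.decomposition import PCA as _SkPCA

# sklearn renamed the non-metric/precomputed switches; pick the right spelling
_mds_params = inspect.signature(_SkMDS.__init__).parameters
if "metric_mds" in _mds_params:
    _MDS_KWARGS = {"metric": "precomputed", "metric_mds": False}
else:  # pragma: no cover - older sklearn
    _MDS_KWARGS = {"dissimilarity": "precomputed", "metric": False}
if "init" in _mds_params:
    # an explicit configuration is always passed to fit(); this only
    # silences the changing-default warning
    _MDS_KWARGS["init"] = "random"

import networkx as nx

__all__ = [
    "Ordination",
    "EnvFitResult",
    "PermanovaResult",
    "BioenvResult",
    "ClusterResult",
    "CoexpressionNetwork",
    "bray_curtis",
    "nmds",
    "pca",
    "envfit",
    "bioenv",
    "permanova",
    "hcluster",
    "coexpression_network",
    "NETWORK_R_THRESHOLD",
]

#: Default absolute Pearson-correlation cutoff for co-expression edges.
NETWORK_R_THRESHOLD = 0.8
PERMUTATIONS_DEFAULT = 999


@dataclass
class Ordination:
    """Sample coordinates with fit diagnostics."""

    coords: pd.DataFrame  # samples x axes
    stress: float | None = None  # Kruskal stress-1 (NMDS)
    explained: np.ndarray | None = None  # variance fractions (PCA)
    seed: int | None = None
    restarts: int | None = None
    converged: bool = True


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the rows (samples) of a matrix.

    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j).  A pair of all-zero samples
    has an undefined ratio and is set to 0 by convention, with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative input")
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        den = (X[i] + X[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if np.any(den == 0):
            warnings.warn("all-zero sample pair: Bray-Curtis set to 0 by convention")
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else None
    return DistanceMatrix(d, ids=ids)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Principal-coordinates (Gower) embedding used as the first NMDS start."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Center and rotate a configuration onto its principal axes."""
    X = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    # fix signs so the largest-magnitude loading of each axis is positive
    R = vt.T
    X = X @ R
    for j in range(X.shape[1]):
        if X[np.argmax(np.abs(X[:, j])), j] < 0:
            X[:, j] = -X[:, j]
    return X


def nmds(
    d: DistanceMatrix,
    *,
    k: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> Ordination:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs SMACOF with isotonic regression from ``restarts`` starts: the
    first from classical scaling of the input distances, the rest from
    seeded random configurations.  The best (lowest-stress) configuration
    is centered and rotated onto its principal axes.  Deterministic for a
    given seed; adding restarts can only lower the final stress.
    """
    D = d.data
    n = D.shape[0]
    if n < k + 2:
        raise ValueError(f"NMDS in {k} dimensions needs at least {k + 2} samples")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best_coords = None
    best_stress = np.inf
    for r in range(restarts):
        if r == 0:
            init = _classical_scaling(D, k)
        else:
            rng = np.random.default_rng((seed, r))
            init = rng.normal(size=(n, k))
        model = _SkMDS(
            n_components=k,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            normalized_stress=True,
            random_state=0,
            **_MDS_KWARGS,
        )
        coords = model.fit_transform(D, init=init)
        if model.stress_ < best_stress:
            best_stress = float(model.stress_)
            best_coords = coords
    rotated = _principal_axes(best_coords)
    ids = list(d.ids)
    frame = pd.DataFrame(
        rotated, index=ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return Ordination(frame, stress=best_stress, seed=seed, restarts=restarts)


def pca(table: pd.DataFrame, *, scale: bool = True) -> Ordination:
    """PCA of a variables x samples table (used for lake categorization).

    Variables are centered and, with ``scale``, standardized; constant
    variables cannot be standardized and are dropped with a warning.
    """
    X = table.T.astype(float)  # samples x variables
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if scale:
        sd = X.std(axis=0, ddof=0)
        constant = sd[sd == 0].index.tolist()
        if constant:
            warnings.warn(f"dropping constant variable(s) under scaling: {constant}")
            X = X.drop(columns=constant)
            sd = sd.drop(constant)
        if X.shape[1] == 0:
            raise ValueError("no variables left after dropping constants")
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    k = min(X.shape[0] - 1, X.shape[1])
    model = _SkPCA(n_components=k)
    coords = model.fit_transform(X.to_numpy())
    frame = pd.DataFrame(
        coords, index=X.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return Ordination(frame, explained=model.explained_variance_ratio_)


@dataclass
class EnvFitResult:
    """Per-variable fit of environmental vectors onto an ordination."""

    table: pd.DataFrame  # index: variable; columns: axis cosines, r2, p, n
    permutations: int
    seed: int

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def envfit(
    ordination: Ordination | pd.DataFrame,
    env: pd.DataFrame,
    *,
    permutations: int = PERMUTATIONS_DEFAULT,
    seed: int = 0,
) -> EnvFitResult:
    """Fit environmental variables onto ordination axes with permutation tests.

    Each (centered) variable is regressed on the ordination coordinates;
    r^2 is the squared multiple correlation and the p-value is the
    fraction of row-shuffled permutations reaching at least the observed
    r^2, with the +1 numerator/denominator correction.  Direction cosines
    give the unit vector of steepest increase.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    coords = ordination.coords if isinstance(ordination, Ordination) else ordination
    if list(env.index) != list(coords.index):
        env = env.reindex(coords.index)
        if env.isna().any().any():
            raise ValueError("env rows do not align with ordination samples")
    X = coords.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    n, k = X.shape
    Q, _ = np.linalg.qr(X)
    rng = np.random.default_rng(seed)
    # one shared permutation block: rows of `perm` index into each variable
    perm = np.array([rng.permutation(n) for _ in range(permutations)])

    rows = []
    for var in env.columns:
        y = env[var].to_numpy(dtype=float)
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot == 0:
            rows.append([np.nan] * k + [np.nan, np.nan, n, "zero variance"])
            continue
        proj = Q.T @ yc
        r2 = float(proj @ proj) / ss_tot
        beta = np.linalg.lstsq(X, yc, rcond=None)[0]
        norm = np.linalg.norm(beta)
        cosines = beta / norm if norm > 0 else np.zeros(k)
        Yp = yc[perm]  # permutations x n
        proj_p = Yp @ Q  # permutations x k
        r2_p = (proj_p**2).sum(axis=1) / ss_tot
        p = (1 + int((r2_p >= r2 - 1e-12).sum())) / (permutations + 1)
        rows.append(list(cosines) + [r2, p, n, ""])
    table = pd.DataFrame(
        rows,
        index=pd.Index(env.columns, name="variable"),
        columns=[f"axis{i + 1}" for i in range(k)] + ["r2", "p", "n", "note"],
    )
    return EnvFitResult(table, permutations, seed)


@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    rho: float
    ranking: pd.DataFrame  # all subsets, sorted by rho descending


def bioenv(
    community_d: DistanceMatrix,
    env: pd.DataFrame,
    *,
    max_subset: int | None = None,
    max_evaluations: int = 100_000,
) -> BioenvResult:
    """Best subset of environmental variables explaining community distances.

    Exhaustively searches variable subsets up to ``max_subset``; each
    subset's environmental distance is Euclidean on z-scored variables and
    is scored by the Spearman rank correlation with the community
    distances over the vectorized upper triangles.
    """
    if env.shape[1] < 1:
        raise ValueError("bioenv needs at least one environmental variable")
    env = env.reindex(list(community_d.ids))
    if env.isna().any().any():
        raise ValueError("env rows do not align with distance-matrix samples")
    variables = list(env.columns)
    if max_subset is None:
        max_subset = len(variables)
    if max_subset > len(variables):
        raise ValueError("max_subset exceeds the number of variables")
    n_eval = sum(_ncomb(len(variables), s) for s in range(1, max_subset + 1))
    if n_eval > max_evaluations:
        raise ValueError(
            f"{n_eval} subsets exceed the exhaustive budget "
            f"({max_evaluations}); lower max_subset"
        )
    Z = (env - env.mean(axis=0)) / env.std(axis=0, ddof=0)
    comm = community_d.condensed_form()
    rows = []
    for size in range(1, max_subset + 1):
        for subset in combinations(variables, size):
            sub = Z[list(subset)].to_numpy(dtype=float)
            diffs = sub[:, None, :] - sub[None, :, :]
            d = np.sqrt((diffs**2).sum(axis=2))
            rho = stats.spearmanr(comm, squareform(d, checks=False)).statistic
            rows.append((subset, size, float(rho)))
    ranking = pd.DataFrame(rows, columns=["subset", "size", "rho"]).sort_values(
        "rho", ascending=False, kind="mergesort", ignore_index=True
    )
    best = ranking.iloc[0]
    return BioenvResult(tuple(best["subset"]), float(best["rho"]), ranking)


def _ncomb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p: float | None
    permutations: int
    n_groups: int


def permanova(
    d: DistanceMatrix,
    groups,
    *,
    permutations: int = PERMUTATIONS_DEFAULT,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances (equivalently, the trace
    of the Gower-centered inner-product matrix) into among- and
    within-group components; the p-value comes from free permutation of
    the group labels.  Groups of size 1 everywhere leave no within-group
    degrees of freedom, so F is reported with p = None and a warning.
    """
    labels = pd.Series(list(groups))
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    D2 = d.data.astype(float) ** 2
    n = D2.shape[0]
    if len(labels) != n:
        raise ValueError("group labels do not match the distance matrix size")
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n

    def _ssw(code_matrix: np.ndarray) -> np.ndarray:
        # code_matrix: (m, n) integer labels; returns within-group SS per row
        m = code_matrix.shape[0]
        ssw = np.zeros(m)
        for g in range(a):
            M = (code_matrix == g).astype(float)
            sizes = M.sum(axis=1)
            quad = np.einsum("pi,ij,pj->p", M, D2, M)
            with np.errstate(invalid="ignore", divide="ignore"):
                ssw += np.where(sizes > 0, quad / (2.0 * np.maximum(sizes, 1)), 0.0)
        return ssw

    ssw_obs = float(_ssw(codes[None, :])[0])
    ssa = ss_total - ssw_obs
    df_within = n - a
    if df_within == 0:
        warnings.warn("all groups of size 1: no within-group df, p undefined")
        return PermanovaResult(np.inf, ssa / ss_total, None, 0, a)
    F = (ssa / (a - 1)) / (ssw_obs / df_within)
    r2 = ssa / ss_total
    rng = np.random.default_rng(seed)
    perm_codes = np.array([rng.permutation(codes) for _ in range(permutations)])
    ssw_p = _ssw(perm_codes)
    F_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / df_within)
    p = (1 + int((F_p >= F - 1e-12).sum())) / (permutations + 1)
    return PermanovaResult(float(F), float(r2), float(p), permutations, a)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def cut(self, k: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")


def hcluster(
    profiles: pd.DataFrame,
    *,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of the rows of a profile matrix.

    Rows are sorted by id before linkage so exact-tie merges are broken
    deterministically.  NaNs are rejected with the offending row named.
    """
    if profiles.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    bad = profiles.index[profiles.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"NaN values in profile row(s): {bad[:5]}")
    ordered = profiles.sort_index(kind="mergesort")
    Z = hierarchy.linkage(ordered.to_numpy(dtype=float), method=method, metric=metric)
    leaves = hierarchy.leaves_list(Z)
    labels = list(ordered.index)
    return ClusterResult(Z, labels, [labels[i] for i in leaves])


@dataclass
class CoexpressionNetwork:
    edges: pd.DataFrame  # feature_a, feature_b, r, n
    nodes: list[str]  # all retained features, including isolated ones
    threshold: float
    excluded: list[str] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.feature_a, row.feature_b, r=row.r, n=row.n)
        return g


def coexpression_network(
    matrix: pd.DataFrame,
    *,
    threshold: float = NETWORK_R_THRESHOLD,
    min_n: int = 3,
    mode: str = "magnitude",
    alpha: float = 0.05,
) -> CoexpressionNetwork:
    """Thresholded Pearson co-expression network from a features x samples matrix.

    Correlations use pairwise-complete observations; an undirected edge is
    created for every feature pair with |r| >= ``threshold`` (the sign of r
    is retained on the edge).  ``mode="pvalue"`` instead keeps pairs with a
    two-sided p-value <= ``alpha``.  Features with fewer than ``min_n``
    complete observations in every pairing are excluded with a warning.
    """
    if matrix.shape[1] < min_n:
        raise ValueError(f"need at least {min_n} samples")
    X = matrix.to_numpy(dtype=float)
    features = list(matrix.index)
    valid = ~np.isnan(X)
    keep, excluded = [], []
    for i, f in enumerate(features):
        if valid[i].sum() >= min_n:
            keep.append(i)
        else:
            excluded.append(f)
    if excluded:
        warnings.warn(f"excluding feature(s) with < {min_n} observations: {excluded}")
    rows = []
    nodes = [features[i] for i in keep]
    for ai, bi in combinations(keep, 2):
        mask = valid[ai] & valid[bi]
        n = int(mask.sum())
        if n < min_n:
            continue
        x, y = X[ai, mask], X[bi, mask]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        hit = (p <= alpha) if mode == "pvalue" else (abs(r) >= threshold)
        if hit:
            a, b = sorted((features[ai], features[bi]))
            rows.append((a, b, float(r), n))
    edges = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "n"])
    edges = edges.astype({"r": float, "n": int})  # stable dtypes when empty
    edges = edges.sort_values(["feature_a", "feature_b"], ignore_index=True)
    return CoexpressionNetwork(edges, nodes, threshold, excluded)
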