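"""Unsupervised hierarchical clustering of samples on editing profiles.

Samples are clustered on the efficiency matrix of label-blind selected
sites (coverage >= 10 in every sample, not SNP-flagged, all-sample weighted
average efficiency within [0.02, 0.98]) using the Pearson correlation
distance ``1 - r`` and average (UPGMA) linkage. Branch confidence comes
from bootstrap resampling of sites: the bootstrap proportion (BP) of a
branch is the fraction of scale-1 replicates containing the same sample
bipartition; when several scale factors are resampled, an approximately
unbiased (AU) value is extrapolated from the scale-wise BPs by the standard
normal-quantile linear fit in sqrt(scale). The AU values are an
approximation of the published multiscale-bootstrap procedure and are
labelled as such in output.

For heatmaps, :func:`center_matrix` subtracts each site's all-sample mean
from its row, producing the signed residual matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, ContractViolationError, EmptyInputError
from .profile import EditingProfile
from .selection import snp_mask

DEFAULT_BAND = (0.02, 0.98)
DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


@dataclass
class ClusterInput:
    """Selected-site efficiency matrix (sites x samples) plus provenance."""

    matrix: pd.DataFrame
    report: dict[str, int]  # diagnostic counts from site selection


@dataclass
class ClusterTree:
    """Sample dendrogram with optional per-branch bootstrap supports."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    supports: dict[frozenset, dict[str, float]] = field(default_factory=dict)

    def leaf_sets(self) -> list[frozenset]:
        """Leaf-label set of every internal node, in merge order."""
        n = len(self.labels)
        sets: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        out = []
        for a, b, _, _ in self.linkage:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            out.append(merged)
        return out

    def bipartitions(self) -> list[frozenset]:
        """Canonical bipartition of every non-root internal node."""
        universe = frozenset(self.labels)
        return [_canonical(s, universe) for s in self.leaf_sets()[:-1]]

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self, support: str = "bp") -> str:
        """Newick string with branch supports as internal-node labels."""
        root = hierarchy.to_tree(self.linkage)
        universe = frozenset(self.labels)

        def leaves(node) -> frozenset:
            return frozenset(self.labels[i] for i in node.pre_order(lambda x: x.id) if i < len(self.labels))

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            label = ""
            key = _canonical(leaves(node), universe)
            if self.supports and key in self.supports and support in self.supports[key]:
                label = f"{self.supports[key][support]:.3f}"
            return f"({inner}){label}:{length:.6g}"

        inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def _canonical(leafset: frozenset, universe: frozenset) -> frozenset:
    """Represent the bipartition {A | U \\ A} by its smaller side
    (lexicographic tie-break), so complements compare equal."""
    comp = universe - leafset
    if len(leafset) < len(comp):
        return leafset
    if len(comp) < len(leafset):
        return comp
    return min(leafset, comp, key=lambda s: sorted(s))


def select_cluster_sites(
    profile: EditingProfile,
    min_cov: int = 10,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ClusterInput:
    """Label-blind site selection for clustering.

    Keeps sites with coverage >= min_cov in every sample, not SNP-flagged,
    and with all-sample pooled (weighted) average efficiency inside the
    closed band. Raises :class:`EmptyInputError` with diagnostic counts if
    nothing survives.
    """
    cov_ok = (profile.coverage >= min_cov).all(axis=1)
    not_snp = ~snp_mask(profile)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = profile.n_i.sum(axis=1) / np.maximum(profile.coverage.sum(axis=1), 1)
    in_band = (pooled >= band[0]) & (pooled <= band[1])
    keep = cov_ok & not_snp & in_band
    report = {
        "n_input": profile.n_sites,
        "n_low_coverage": int((~cov_ok).sum()),
        "n_snp": int((cov_ok & ~not_snp).sum()),
        "n_outside_band": int((cov_ok & not_snp & ~in_band).sum()),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise EmptyInputError(f"no sites survive clustering selection: {report}")
    sub = profile.subset_sites(keep)
    matrix = pd.DataFrame(sub.efficiency, index=sub.site_ids, columns=sub.samples)
    return ClusterInput(matrix=matrix, report=report)


def correlation_distance(x, y) -> float:
    """Pearson correlation distance 1 - r, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ContractViolationError("need >= 3 shared sites")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ContractViolationError("zero-variance efficiency vector")
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def sample_distance_matrix(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """1 - Pearson correlation between sample columns; NaN-free by contract."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    sd = values.std(axis=0)
    if (sd == 0).any():
        names = (
            [matrix.columns[i] for i in np.flatnonzero(sd == 0)]
            if isinstance(matrix, pd.DataFrame)
            else list(np.flatnonzero(sd == 0))
        )
        raise ContractViolationError(f"zero-variance sample vector(s): {names}")
    d = 1.0 - np.corrcoef(values.T)
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(distance: np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """UPGMA tree from a symmetric zero-diagonal dissimilarity matrix."""
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ContractViolationError("distance matrix must be square and symmetric")
    if labels is None:
        labels = [str(i) for i in range(d.shape[0])]
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return ClusterTree(linkage=Z, labels=list(labels))


def _replicate_bipartitions(values: np.ndarray, idx: np.ndarray, labels: list[str]) -> set[frozenset]:
    sub = values[idx, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.T)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    tree = ClusterTree(linkage=Z, labels=labels)
    return set(tree.bipartitions())


def bootstrap_support(
    cluster_input: ClusterInput,
    n_boot: int = 1000,
    scales: tuple[float, ...] = (1.0,),
    seed: int = 0,
) -> ClusterTree:
    """UPGMA tree with per-branch bootstrap supports.

    Sites are resampled with replacement ``n_boot`` times at each scale
    factor r (resample size round(r * n_sites)). BP is the branch's
    recovery fraction at scale 1 (which must be among ``scales``); when at
    least two scales are given, an approximate AU value is extrapolated
    from the scale-wise proportions.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    if not scales:
        raise ConfigurationError("scales must be non-empty")
    if 1.0 not in scales:
        raise ConfigurationError("scales must include 1.0 (plain bootstrap)")
    matrix = cluster_input.matrix
    labels = list(matrix.columns)
    values = matrix.to_numpy()
    S = values.shape[0]
    tree = average_linkage(sample_distance_matrix(matrix), labels)
    # the root's two children induce the same bipartition: count each key once
    observed = sorted(set(tree.bipartitions()), key=lambda s: (len(s), sorted(s)))

    rng = np.random.default_rng(seed)
    counts: dict[float, dict[frozenset, int]] = {
        r: {b: 0 for b in observed} for r in scales
    }
    for r in scales:
        size = max(3, int(round(r * S)))
        for _ in range(n_boot):
            idx = rng.integers(0, S, size=size)
            found = _replicate_bipartitions(values, idx, labels)
            for b in observed:
                if b in found:
                    counts[r][b] += 1

    tree.supports = {}
    for b in observed:
        bp_by_scale = {r: counts[r][b] / n_boot for r in scales}
        entry = {"bp": bp_by_scale[1.0]}
        if len(scales) >= 2:
            entry["au"] = _au_extrapolate(bp_by_scale, n_boot)
        tree.supports[b] = entry
    return tree


def _au_extrapolate(bp_by_scale: dict[float, float], n_boot: int) -> float:
    """Approximate AU support: fit z(r) = v*sqrt(r) + c/sqrt(r) to the
    normal quantiles of (1 - BP_r), then AU = 1 - Phi(v - c)."""
    eps = 1.0 / (n_boot + 1)
    rs, zs = [], []
    for r, bp in bp_by_scale.items():
        bp = min(max(bp, eps), 1 - eps)
        rs.append(r)
        zs.append(stats.norm.ppf(1.0 - bp))
    rs = np.asarray(rs)
    zs = np.asarray(zs)
    X = np.column_stack([np.sqrt(rs), 1.0 / np.sqrt(rs)])
    (v, c), *_ = np.linalg.lstsq(X, zs, rcond=None)
    return float(1.0 - stats.norm.cdf(v - c))


def center_matrix(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Subtract each site's all-sample mean efficiency from its row."""
    if isinstance(matrix, pd.DataFrame):
        return matrix.sub(matrix.mean(axis=1), axis=0)
    values = np.asarray(matrix, dtype=float)
    return values - values.mean(axis=1, keepdims=True)


def plot_dendrogram(tree: ClusterTree, path=None, ax=None):
    """Dendrogram with BP labels; returns the matplotlib axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(tree.labels) * 0.3), 4))
    hierarchy.dendrogram(tree.linkage, labels=tree.labels, ax=ax)
    ax.set_ylabel("correlation distance (average linkage)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
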