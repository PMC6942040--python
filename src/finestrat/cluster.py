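"""Iterative-PCA clustering of genotypes (fine-scale population structure).

The engine recursively splits the sample set in principal-component space.
At each node it:

1. standardizes the node's dosage submatrix (monomorphic SNPs dropped, each
   column centered and scaled by ``sqrt(2 p (1-p))``) and computes a PCA;
2. attempts rotation-based peeling (``rubikclust``): the 3-D cloud of the
   first three PC scores is rotated over a fixed angular grid and each axis
   projection is scanned for internal gaps wider than ``gap_factor`` times
   its interquartile range — outlying individuals and grossly separated
   groups split off here, independent of the stopping statistic;
3. applies the spectral stopping rule: the node is declared structureless
   (a terminal group) when the EigenFit statistic — the largest consecutive
   log10 gap among the leading eigenvalues — falls below ``threshold``.
   Only *group-supported* components enter the statistic: a component whose
   scores are effectively carried by fewer than ``outlier_report_size``
   samples is an outlier direction, not group structure, and is excluded;
4. otherwise proposes a two-way split with a Gaussian mixture model on the
   top PC scores (2 components vs. 1 by BIC);
5. gates every proposed split on the average Hudson FST between the two
   largest children (``min_fst``); children smaller than ``min_in_group``
   become terminal and are reported as outlier groups when smaller than
   ``outlier_report_size``.

Everything is deterministic for a fixed ``random_state``.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array

from . import popstat
from .io import MISSING, ClusterAssignmentTable, GenotypeDataset

__all__ = [
    "IPCAPSParams",
    "ClusterNode",
    "ClusterTree",
    "standardize",
    "node_pca",
    "eigenfit",
    "effective_support",
    "rubikclust",
    "mixture_split",
    "IterativePCAClustering",
    "ipcaps",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class IPCAPSParams:
    """Engine parameters.

    ``threshold`` is the EigenFit stop value (log10 eigenvalue-gap units;
    meaningful range 0.03-0.18, smaller splits more).  ``min_in_group`` bars
    nodes below that size from further splitting; terminal groups smaller
    than ``outlier_report_size`` are reported as outlier groups.
    ``min_fst`` is the minimum average Hudson FST between the two largest
    children for a split to be accepted.
    """

    threshold: float = 0.18
    min_in_group: int = 20
    min_fst: float = 0.0008
    method: str = "mix"
    outlier_report_size: int = 5
    n_pcs_cluster: int = 3
    n_eigs_fit: int = 10
    gap_factor: float = 3.0
    angle_step: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method != "mix":
            raise ValueError("only method='mix' is implemented")
        if self.min_fst < 0:
            raise ValueError("min_fst must be non-negative")
        if self.n_pcs_cluster < 3:
            raise ValueError("n_pcs_cluster must be at least 3")
        if not 0.03 <= self.threshold <= 0.18:
            warnings.warn(
                f"threshold {self.threshold} outside the calibrated range 0.03-0.18",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Tree containers


@dataclass
class ClusterNode:
    """One node of the nested splitting history."""

    members: np.ndarray
    depth: int
    path: str
    eigenvalues: np.ndarray | None = None
    eigenfit_value: float | None = None
    split_method: str = "none"  # rubik | mixture | none
    inter_child_fst: float | None = None
    status: str = "pending"  # split | leaf | outlier
    children: list["ClusterNode"] = field(default_factory=list)
    group_id: int | None = None

    @property
    def size(self) -> int:
        return int(len(self.members))

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out: list[ClusterNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "depth": self.depth,
            "size": self.size,
            "members": self.members.tolist(),
            "eigenvalues": None if self.eigenvalues is None else [float(x) for x in self.eigenvalues],
            "eigenfit": self.eigenfit_value,
            "split_method": self.split_method,
            "inter_child_fst": self.inter_child_fst,
            "status": self.status,
            "group_id": self.group_id,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class ClusterTree:
    """Full splitting history plus the ordered terminal groups."""

    root: ClusterNode
    groups: list[ClusterNode]
    outlier_groups: list[ClusterNode]
    params: IPCAPSParams

    @property
    def n_samples(self) -> int:
        return self.root.size

    def labels(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(group id, outlier flag, node path) per sample in input order."""
        n = self.n_samples
        group = np.zeros(n, dtype=int)
        outlier = np.zeros(n, dtype=bool)
        paths = [""] * n
        for node in self.groups + self.outlier_groups:
            group[node.members] = node.group_id
            outlier[node.members] = node.status == "outlier"
            for i in node.members:
                paths[i] = node.path
        return group, outlier, paths

    def to_json(self, path=None) -> str:
        payload = {
            "params": {k: getattr(self.params, k) for k in self.params.__dataclass_fields__},
            "n_samples": self.n_samples,
            "n_groups": len(self.groups),
            "n_outlier_groups": len(self.outlier_groups),
            "root": self.root.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# PCA primitives


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale a node's dosage matrix for PCA.

    Columns monomorphic within the node are dropped; each remaining column
    is mean-centered and divided by ``sqrt(2 p (1-p))`` with ``p`` the
    column mean divided by 2 (the variance of a binomial(2, p) draw).
    Returns the standardized matrix and the indices of the kept columns.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.any(X == MISSING) or np.isnan(X).any():
        raise ValueError("standardize requires imputed (complete) dosages")
    mean = X.mean(axis=0)
    p = mean / 2.0
    keep = np.flatnonzero((p > 0) & (p < 1))
    scale = np.sqrt(2.0 * p[keep] * (1.0 - p[keep]))
    Z = (X[:, keep] - mean[keep]) / scale
    return Z, keep


def node_pca(standardized: np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues and top-``k`` sample scores of a standardized matrix.

    Eigenvalues are those of the sample covariance along principal axes
    (``singular_value^2 / (n - 1)``), non-negative and descending; trailing
    zeros are returned for rank-deficient input.  Scores are returned for the
    top ``k`` components with the sign convention that each component's
    largest-magnitude SNP loading is positive.  The third return value is
    the matrix of unit-norm left singular vectors (per-component sample
    weights), used to assess how many samples support a component.
    """
    Z = np.asarray(standardized, dtype=float)
    n, m = Z.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    if n <= m:
        gram = Z @ Z.T
        w, V = np.linalg.eigh(gram)
        w = w[::-1]
        V = V[:, ::-1]
        w = np.clip(w, 0.0, None)
    else:
        U_full, s, _ = np.linalg.svd(Z, full_matrices=False)
        w = s**2
        V = U_full
    eigenvalues = w / (n - 1)
    k = min(k, V.shape[1])
    s = np.sqrt(w[:k])
    U = V[:, : max(k, min(n, 20))]
    # sign convention: largest-|.| loading of each reported component positive
    with np.errstate(invalid="ignore", divide="ignore"):
        for j in range(k):
            if s[j] <= 0:
                continue
            loading = Z.T @ V[:, j] / s[j]
            top = np.argmax(np.abs(loading))
            if loading[top] < 0:
                V[:, j] = -V[:, j]
    scores = V[:, :k] * s
    return eigenvalues, scores, U


def effective_support(weights: np.ndarray) -> np.ndarray:
    """Effective number of samples carrying each component.

    Inverse participation ratio of each unit-norm column: ``1 / sum(u^4)``.
    Equals ``c`` for a vector spread uniformly over ``c`` samples and ~``n/3``
    for a generic random direction.
    """
    U = np.asarray(weights, dtype=float)
    norms = (U**2).sum(axis=0)
    norms[norms == 0] = 1.0
    U = U / np.sqrt(norms)
    return 1.0 / (U**4).sum(axis=0)


def eigenfit(eigenvalues: np.ndarray, n_eigs_fit: int = 10) -> float:
    """Largest consecutive log10 gap among the leading eigenvalues.

    Non-positive eigenvalues are excluded before taking logs; if fewer than
    ``n_eigs_fit`` remain the sequence is padded with its smallest positive
    value (contributing zero gaps).  A flat spectrum scores 0; a spectrum
    like (100, 1, 1, ...) scores 2.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    ev = ev[ev > 0]
    if ev.size < 2:
        return 0.0
    ev = np.sort(ev)[::-1]
    if ev.size < n_eigs_fit:
        ev = np.concatenate([ev, np.full(n_eigs_fit - ev.size, ev[-1])])
    lead = np.log10(ev[:n_eigs_fit])
    return float(np.max(-np.diff(lead)))


# ---------------------------------------------------------------------------
# Split proposers


@lru_cache(maxsize=8)
def _rotation_bank(angle_step: float) -> np.ndarray:
    """All pairwise-axis rotations on a fixed angular grid, shape (R, 3, 3)."""
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step))

    def rot(axis: int, t: float) -> np.ndarray:
        c, s = np.cos(t), np.sin(t)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c
        m[i, j] = -s
        m[j, i] = s
        m[j, j] = c
        return m

    bank = []
    for a_axis, b_axis in ((0, 1), (0, 2), (1, 2)):
        for a in angles:
            for b in angles:
                bank.append(rot(a_axis, a) @ rot(b_axis, b))
    return np.array(bank)


def rubikclust(
    scores3: np.ndarray, gap_factor: float = 3.0, angle_step: float = 10.0
) -> np.ndarray | None:
    """Gap-based partition of the 3-D PC-score cloud under grid rotations.

    For every rotation in the bank the three axis projections are scanned
    for internal gaps exceeding ``gap_factor`` times the interquartile range
    of the *majority* side of the gap (so a balanced two-cloud separation
    qualifies just like a peeled outlier, and a handful of stragglers on the
    minority side cannot inflate the spread).  The projection holding the single
    widest qualifying gap wins, and the cloud is cut at *every* qualifying
    gap of that projection (so several outliers strung along one direction
    peel in one call).  Returns integer part labels ordered along the
    projection, or ``None`` when no rotation shows clear separation
    (including n < 4).
    """
    S = np.asarray(scores3, dtype=float)
    if S.ndim != 2 or S.shape[1] < 3:
        raise ValueError("rubikclust needs 3-D scores")
    n = S.shape[0]
    if n < 4:
        return None
    bank = _rotation_bank(float(angle_step))
    proj = S[:, :3] @ bank.reshape(-1, 3).T  # n x (3R)
    ordered = np.sort(proj, axis=0)
    gaps = np.diff(ordered, axis=0)

    # side-wise IQRs for every candidate gap, via index gathers on the
    # pre-sorted columns (nearest-rank quantiles)
    sizes_left = np.arange(1, n)  # gap i separates i+1 points from n-i-1
    sizes_right = n - sizes_left

    def side_iqr(offsets_lo, offsets_hi):
        return ordered[offsets_hi] - ordered[offsets_lo]

    l_lo = (0.25 * (sizes_left - 1)).astype(int)
    l_hi = np.ceil(0.75 * (sizes_left - 1)).astype(int)
    r_lo = sizes_left + (0.25 * (sizes_right - 1)).astype(int)
    r_hi = sizes_left + np.ceil(0.75 * (sizes_right - 1)).astype(int)
    iqr_left = side_iqr(l_lo, l_hi)
    iqr_right = side_iqr(r_lo, r_hi)
    spread = np.where(sizes_left[:, None] >= sizes_right[:, None], iqr_left, iqr_right)
    qualifies = (gaps > gap_factor * spread) & (spread > 0)
    if not qualifies.any():
        return None
    widest = np.where(qualifies, gaps, 0.0).max(axis=0)
    best = int(np.argmax(widest))
    v = proj[:, best]
    sv = ordered[:, best]
    cut_rows = np.flatnonzero(qualifies[:, best])
    cuts = (sv[cut_rows] + sv[cut_rows + 1]) / 2.0
    return np.digitize(v, np.sort(cuts))


def mixture_split(scores: np.ndarray, random_state: int = 0) -> np.ndarray | None:
    """Two-component Gaussian-mixture partition of top PC scores.

    Full-covariance EM with k-means initialization; returns the
    maximum-a-posteriori two-way labels, or ``None`` when BIC prefers a
    single component or the fit degenerates.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 4:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm1 = GaussianMixture(
                n_components=1, covariance_type="full", random_state=random_state
            ).fit(S)
            gm2 = GaussianMixture(
                n_components=2,
                covariance_type="full",
                random_state=random_state,
                n_init=2,
                reg_covar=1e-6,
            ).fit(S)
    except ValueError:
        return None
    if not gm2.converged_:
        return None
    if gm2.bic(S) >= gm1.bic(S):
        return None
    labels = gm2.predict(S)
    if len(np.unique(labels)) < 2:
        return None
    return labels


# ---------------------------------------------------------------------------
# Engine


class IterativePCAClustering(ClusterMixin, BaseEstimator):
    """Iterative-PCA population clustering as a scikit-learn estimator.

    Parameters mirror :class:`IPCAPSParams`.  ``fit`` expects an
    ``n_samples x n_snps`` matrix of imputed allele dosages in {0, 1, 2}
    (floats accepted).  Fitted attributes:

    ``labels_``
        terminal group id per sample (1-based; outlier groups numbered after
        accepted groups),
    ``outlier_``
        boolean mask of samples in outlier groups,
    ``tree_``
        the full :class:`ClusterTree`,
    ``n_groups_``
        number of accepted (non-outlier) groups.
    """

    def __init__(
        self,
        threshold: float = 0.18,
        min_in_group: int = 20,
        min_fst: float = 0.0008,
        method: str = "mix",
        outlier_report_size: int = 5,
        n_pcs_cluster: int = 3,
        n_eigs_fit: int = 10,
        gap_factor: float = 3.0,
        angle_step: float = 10.0,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.min_in_group = min_in_group
        self.min_fst = min_fst
        self.method = method
        self.outlier_report_size = outlier_report_size
        self.n_pcs_cluster = n_pcs_cluster
        self.n_eigs_fit = n_eigs_fit
        self.gap_factor = gap_factor
        self.angle_step = angle_step
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _params(self) -> IPCAPSParams:
        return IPCAPSParams(
            threshold=self.threshold,
            min_in_group=self.min_in_group,
            min_fst=self.min_fst,
            method=self.method,
            outlier_report_size=self.outlier_report_size,
            n_pcs_cluster=self.n_pcs_cluster,
            n_eigs_fit=self.n_eigs_fit,
            gap_factor=self.gap_factor,
            angle_step=self.angle_step,
            seed=self.random_state,
        )

    def _node_seed(self, node: ClusterNode) -> int:
        digest = zlib.crc32(f"{int(self.random_state)}:{node.path}".encode())
        return int(digest) & 0x7FFFFFFF

    def _structure_eigenfit(
        self, eigenvalues: np.ndarray, weights: np.ndarray
    ) -> float:
        """EigenFit over group-supported components only."""
        k = weights.shape[1]
        support = effective_support(weights)
        keep = np.ones(eigenvalues.size, dtype=bool)
        keep[:k] = support >= self.outlier_report_size
        ev = eigenvalues[keep & (eigenvalues > 0)]
        return eigenfit(ev, self.n_eigs_fit)

    def _sibling_fst(self, children: list[np.ndarray]) -> float | None:
        """Average Hudson FST between the two largest proposed children.

        Returns ``None`` when the second-largest child is a single sample
        (peeled outlier; no FST is computable or required).
        """
        by_size = sorted(children, key=len, reverse=True)
        a, b = by_size[0], by_size[1]
        if len(b) < 2:
            return None
        try:
            comp = popstat.snp_fst_components(self._X, a, b)
            return comp.ratio_of_averages()
        except ValueError:
            return float("-inf")  # no informative SNP: no evidence of divergence

    def _attach_children(self, node: ClusterNode, parts: list[np.ndarray], method: str):
        parts = sorted(parts, key=lambda p: int(p.min()))
        node.children = [
            ClusterNode(members=np.sort(p), depth=node.depth + 1, path=f"{node.path}.{i}")
            for i, p in enumerate(parts)
        ]
        node.split_method = method
        node.status = "split"

    def _process(self, node: ClusterNode) -> None:
        members = node.members
        n = members.size
        if n < self.min_in_group:
            node.status = "leaf"
            return

        Z, kept = standardize(self._X[members])
        if kept.size == 0 or n < 4:
            node.status = "leaf"
            return
        k_scores = min(max(self.n_pcs_cluster, 3), n - 1)
        eigenvalues, scores, weights = node_pca(Z, k=k_scores)
        node.eigenvalues = eigenvalues[: max(self.n_eigs_fit, 15)].copy()
        node.eigenfit_value = self._structure_eigenfit(eigenvalues, weights)

        # 1) rotation-based peeling, independent of the stopping statistic
        labels = rubikclust(scores[:, :3], self.gap_factor, self.angle_step)
        if labels is not None:
            parts = [members[labels == v] for v in np.unique(labels)]
            if self._accept(node, parts, "rubik"):
                return

        # 2) spectral stop
        if node.eigenfit_value < self.threshold:
            node.status = "leaf"
            return

        # 3) mixture-model split
        if n >= 2 * self.min_in_group:
            labels = mixture_split(scores[:, : self.n_pcs_cluster], self._node_seed(node))
            if labels is not None:
                parts = [members[labels == v] for v in np.unique(labels)]
                if self._accept(node, parts, "mixture"):
                    return
        node.status = "leaf"

    def _accept(self, node: ClusterNode, parts: list[np.ndarray], method: str) -> bool:
        """Gate a proposed split on inter-child FST; recurse if accepted."""
        if len(parts) < 2:
            return False
        fst = self._sibling_fst(parts)
        if fst is not None and fst < self.min_fst:
            return False
        node.inter_child_fst = fst
        self._attach_children(node, parts, method)
        for child in node.children:
            self._process(child)
        return True

    # -- public API --------------------------------------------------------

    def fit(self, X, y=None):
        params = self._params()  # validates + warns
        X = check_array(X, dtype=float)
        if np.nanmin(X) < 0 or np.nanmax(X) > 2 or np.isnan(X).any():
            raise ValueError("fit expects imputed allele dosages in [0, 2]")
        self._X = X
        n = X.shape[0]
        root = ClusterNode(members=np.arange(n), depth=0, path="r")
        if n < max(self.min_in_group, 3):
            root.status = "leaf"
        else:
            self._process(root)
            if root.status == "pending":
                root.status = "leaf"
        groups, outliers = self._number_groups(root)
        self.tree_ = ClusterTree(root=root, groups=groups, outlier_groups=outliers, params=params)
        labels, outlier_mask, _ = self.tree_.labels()
        self.labels_ = labels
        self.outlier_ = outlier_mask
        self.n_groups_ = len(groups)
        del self._X
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _number_groups(self, root: ClusterNode):
        leaves = root.leaves()
        accepted: list[ClusterNode] = []
        outliers: list[ClusterNode] = []
        for leaf in leaves:  # depth-first order; children ordered by min member
            if leaf is root:
                leaf.status = "leaf"
                accepted.append(leaf)
                continue
            if leaf.size < self.outlier_report_size:
                leaf.status = "outlier"
                outliers.append(leaf)
            else:
                leaf.status = "leaf"
                accepted.append(leaf)
        for gid, node in enumerate(accepted, start=1):
            node.group_id = gid
        for gid, node in enumerate(outliers, start=len(accepted) + 1):
            node.group_id = gid
        return accepted, outliers


# ---------------------------------------------------------------------------
# Dataset-level wrapper


def ipcaps(
    dataset: GenotypeDataset, params: IPCAPSParams = IPCAPSParams()
) -> tuple[ClusterTree, ClusterAssignmentTable]:
    """Cluster a QC'd, imputed dataset; returns the tree and assignment table."""
    if (dataset.dosages == MISSING).any():
        raise ValueError("dataset contains missing genotypes; impute first")
    est = IterativePCAClustering(
        threshold=params.threshold,
        min_in_group=params.min_in_group,
        min_fst=params.min_fst,
        method=params.method,
        outlier_report_size=params.outlier_report_size,
        n_pcs_cluster=params.n_pcs_cluster,
        n_eigs_fit=params.n_eigs_fit,
        gap_factor=params.gap_factor,
        angle_step=params.angle_step,
        random_state=params.seed,
    ).fit(dataset.dosages.astype(float))
    group, outlier, paths = est.tree_.labels()
    table = ClusterAssignmentTable(
        table=pd.DataFrame(
            {
                "family_id": [s.family_id for s in dataset.samples],
                "individual_id": [s.individual_id for s in dataset.samples],
                "group": group,
                "outlier": outlier,
                "node_path": paths,
            }
        )
    )
    return est.tree_, table
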