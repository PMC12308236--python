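"""Phylogenetic trees and the correlation structures derived from them.

Trees are read from Newick, validated (unique tips, non-negative branch
lengths, near-ultrametric), and converted into species-by-species
correlation matrices under an Ornstein--Uhlenbeck process, Pagel's
lambda branch scaling, plain Brownian motion, or no signal at all.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "CorrelationStructure",
    "read_newick",
    "tree_from_newick_string",
    "shared_path_times",
    "ou_correlation",
    "lambda_correlation",
    "bm_correlation",
    "identity_correlation",
    "correlation_for",
    "nearest_pd_jitter",
]

#: Relative tolerance on tip-depth spread for a tree to count as ultrametric.
DEFAULT_ULTRA_TOL = 1e-3

#: alpha below this is treated as the Brownian-motion limit.
_ALPHA_BM_LIMIT = 1e-8


def normalize_label(label: str) -> str:
    """Canonical tip label: trimmed, spaces mapped to underscores."""
    return label.strip().replace(" ", "_")


class TreeError(ValueError):
    """Raised for invalid or unusable phylogenies."""


@dataclass
class PhyloTree:
    """A rooted, tip-labelled tree with branch lengths, validated on build.

    ``tips`` holds canonical labels in a fixed order; all matrices built
    from the tree follow that order.  ``depth`` is the (maximum) root-to-tip
    distance after any normalization.
    """

    tree: dendropy.Tree
    tips: list[str]
    depth: float
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_dendropy(
        cls,
        dtree: dendropy.Tree,
        normalize_depth: bool = False,
        ultra_tol: float = DEFAULT_ULTRA_TOL,
    ) -> "PhyloTree":
        tips: list[str] = []
        seen: set[str] = set()
        for leaf in dtree.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise TreeError("tree contains a tip with an empty label")
            lab = normalize_label(str(leaf.taxon.label))
            if lab in seen:
                raise TreeError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
            tips.append(lab)
        if len(tips) < 2:
            raise TreeError("tree must have at least 2 tips")

        root = dtree.seed_node
        for node in dtree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeError("tree has edges with missing branch lengths")
            if node.edge.length < 0:
                raise TreeError(f"negative branch length: {node.edge.length}")

        depths = _tip_depths(dtree)
        depth = float(max(depths.values()))
        if depth <= 0:
            raise TreeError("tree depth must be positive")
        dmin_lab = min(depths, key=depths.get)
        dmax_lab = max(depths, key=depths.get)
        spread = (depths[dmax_lab] - depths[dmin_lab]) / depth
        if spread > ultra_tol:
            raise TreeError(
                "tree is not ultrametric within tolerance "
                f"{ultra_tol:g}: tip {dmax_lab!r} has depth "
                f"{depths[dmax_lab]:.6g} vs {dmin_lab!r} at {depths[dmin_lab]:.6g}"
            )

        meta: dict = {"ultra_tol": ultra_tol, "tip_depth_spread": spread}
        if normalize_depth:
            for node in dtree.preorder_node_iter():
                if node.edge.length is not None:
                    node.edge.length = node.edge.length / depth
            meta["depth_scale"] = depth
            depth = 1.0
        return cls(tree=dtree, tips=tips, depth=depth, meta=meta)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    @property
    def n_tips(self) -> int:
        return len(self.tips)


def _tip_depths(dtree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    node_depth: dict[int, float] = {}
    for node in dtree.preorder_node_iter():
        el = node.edge.length or 0.0
        parent = node.parent_node
        d = el + (node_depth[id(parent)] if parent is not None else 0.0)
        node_depth[id(node)] = d
        if node.is_leaf():
            depths[normalize_label(str(node.taxon.label))] = d
    return depths


def read_newick(
    path: str,
    normalize_depth: bool = False,
    ultra_tol: float = DEFAULT_ULTRA_TOL,
) -> PhyloTree:
    """Read and validate a Newick tree file.

    Raises :class:`TreeError` on parse failure, missing branch lengths,
    duplicate tips, or a tip-depth spread beyond ``ultra_tol``.
    """
    try:
        dtree = dendropy.Tree.get(
            path=path, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"could not parse Newick file {path!r}: {exc}") from exc
    return PhyloTree.from_dendropy(
        dtree, normalize_depth=normalize_depth, ultra_tol=ultra_tol
    )


def tree_from_newick_string(
    newick: str,
    normalize_depth: bool = False,
    ultra_tol: float = DEFAULT_ULTRA_TOL,
) -> PhyloTree:
    """As :func:`read_newick` but from an in-memory string."""
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(newick), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"could not parse Newick string: {exc}") from exc
    return PhyloTree.from_dendropy(
        dtree, normalize_depth=normalize_depth, ultra_tol=ultra_tol
    )


def shared_path_times(ptree: PhyloTree) -> np.ndarray:
    """S x S matrix of root-to-MRCA times; diagonal holds tip depths.

    On an ultrametric tree this equals ``depth - patristic/2`` elementwise.
    """
    S = ptree.n_tips
    idx = {lab: i for i, lab in enumerate(ptree.tips)}
    M = np.zeros((S, S))
    node_depth: dict[int, float] = {}
    clade_tips: dict[int, list[int]] = {}
    for node in ptree.tree.preorder_node_iter():
        el = node.edge.length or 0.0
        parent = node.parent_node
        node_depth[id(node)] = el + (
            node_depth[id(parent)] if parent is not None else 0.0
        )
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[normalize_label(str(node.taxon.label))]
            M[i, i] = node_depth[id(node)]
            clade_tips[id(node)] = [i]
        else:
            groups = [clade_tips.pop(id(c)) for c in node.child_nodes()]
            d = node_depth[id(node)]
            for a in range(len(groups)):
                ga = groups[a]
                for b in range(a + 1, len(groups)):
                    gb = groups[b]
                    for i in ga:
                        M[i, gb] = d
                        M[gb, i] = d
            clade_tips[id(node)] = [t for g in groups for t in g]
    return M


@dataclass
class CorrelationStructure:
    """A species-by-species correlation matrix and its generating parameter."""

    labels: list[str]
    matrix: np.ndarray
    family: str  # OU | LAMBDA | BM | IDENTITY
    parameter: Optional[float] = None

    def validate(self, psd_tol: float = 1e-8) -> None:
        R = self.matrix
        S = len(self.labels)
        if R.shape != (S, S):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal is not 1")
        if R.min() < -1e-12 or R.max() > 1 + 1e-12:
            raise ValueError("correlation entries outside [0, 1]")
        if np.linalg.eigvalsh(R).min() < -psd_tol:
            raise ValueError("correlation matrix is not positive semi-definite")

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path
        )


def ou_correlation(ptree: PhyloTree, alpha: float) -> CorrelationStructure:
    """Correlation matrix of a root-anchored OU process on an ultrametric tree.

    With shared path times t_ij and depth T, the covariance is
    ``exp(-2a(T - t_ij)) (1 - exp(-2a t_ij)) / (2a)``; dividing by the
    constant diagonal gives the correlation.  ``alpha -> 0`` recovers the
    Brownian-motion correlation ``t_ij / T``.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    T = ptree.depth
    t = shared_path_times(ptree)
    if alpha <= _ALPHA_BM_LIMIT:
        R = t / T
    else:
        a2 = 2.0 * alpha
        R = np.exp(-a2 * (T - t)) * (-np.expm1(-a2 * t)) / (-np.expm1(-a2 * T))
    np.fill_diagonal(R, 1.0)
    out = CorrelationStructure(
        labels=list(ptree.tips), matrix=R, family="OU", parameter=float(alpha)
    )
    out.validate()
    return out


def lambda_correlation(ptree: PhyloTree, lam: float) -> CorrelationStructure:
    """Pagel's-lambda correlation: off-diagonals are ``lam * t_ij / T``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    T = ptree.depth
    R = lam * shared_path_times(ptree) / T
    np.fill_diagonal(R, 1.0)
    out = CorrelationStructure(
        labels=list(ptree.tips), matrix=R, family="LAMBDA", parameter=float(lam)
    )
    out.validate()
    return out


def bm_correlation(ptree: PhyloTree) -> CorrelationStructure:
    R = shared_path_times(ptree) / ptree.depth
    np.fill_diagonal(R, 1.0)
    out = CorrelationStructure(labels=list(ptree.tips), matrix=R, family="BM")
    out.validate()
    return out


def identity_correlation(ptree: PhyloTree) -> CorrelationStructure:
    return CorrelationStructure(
        labels=list(ptree.tips),
        matrix=np.eye(ptree.n_tips),
        family="IDENTITY",
    )


def correlation_for(
    ptree: PhyloTree, family: str, parameter: Optional[float] = None
) -> CorrelationStructure:
    """Dispatch on structure family name (OU | LAMBDA | BM | IDENTITY)."""
    fam = family.upper()
    if fam == "OU":
        if parameter is None:
            raise ValueError("OU structure requires alpha")
        return ou_correlation(ptree, parameter)
    if fam == "LAMBDA":
        if parameter is None:
            raise ValueError("LAMBDA structure requires lambda")
        return lambda_correlation(ptree, parameter)
    if fam == "BM":
        return bm_correlation(ptree)
    if fam == "IDENTITY":
        return identity_correlation(ptree)
    raise ValueError(f"unknown structure family: {family!r}")


def nearest_pd_jitter(
    matrix: np.ndarray, max_jitter: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Smallest diagonal inflation making Cholesky succeed.

    Tries eps in {0, 1e-10, 1e-9, ..., max_jitter}; returns the inflated
    matrix and the eps used.  Raises ``np.linalg.LinAlgError`` if even
    ``max_jitter`` fails.
    """
    M = np.asarray(matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    candidates = [0.0]
    eps = 1e-10
    while eps < max_jitter:
        candidates.append(eps)
        eps *= 10.0
    candidates.append(max_jitter)
    I = np.eye(M.shape[0])
    for eps in candidates:
        try:
            np.linalg.cholesky(M + eps * I)
            return M + eps * I, eps
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"matrix not positive definite within jitter {max_jitter:g}"
    )


def cholesky_with_jitter(matrix: np.ndarray, max_jitter: float = 1e-6) -> np.ndarray:
    """Cholesky factor of ``nearest_pd_jitter(matrix)``."""
    M, _ = nearest_pd_jitter(matrix, max_jitter=max_jitter)
    return np.linalg.cholesky(M)
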