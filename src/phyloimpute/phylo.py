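"""Phylogenies: Newick ingestion, patristic distances, eigenvectors, signal.

Phylogenetic structure enters the imputation models as *phylogenetic
eigenvectors*: a principal coordinates decomposition (PCoA) of the patristic
distance matrix, keeping the smallest number of leading axes whose cumulative
share of the positive-eigenvalue variance reaches a threshold (0.65 by
default).  The eigenvector columns are appended to the trait table as fully
observed continuous predictors.

Two phylogenetic-signal estimators are provided so a dataset's suitability
for phylogenetic imputation can be gauged per trait:

* Pagel's lambda for continuous traits — the multiplier in [0, 1] applied to
  the off-diagonal of the Brownian-motion tip covariance that maximises the
  multivariate-normal likelihood.  lambda = 0 means a star phylogeny (no
  signal); lambda = 1 means plain Brownian motion.
* Fritz & Purvis' D for binary traits — the observed sum of character
  changes scaled between the expectations under random shuffling (D = 1)
  and under a threshold-Brownian model (D = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = [
    "PhyloTree",
    "PhyloError",
    "EigenvectorSet",
    "SignalEstimate",
    "read_newick",
    "parse_newick",
    "patristic_distances",
    "extract_eigenvectors",
    "pagels_lambda",
    "fritz_purvis_D",
]


class PhyloError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, wrapping a dendropy Tree."""

    tree: dendropy.Tree
    label: str = "tree"

    def __post_init__(self) -> None:
        leaves = self.leaf_labels
        if len(leaves) < 2:
            raise PhyloError("tree needs at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            dup = sorted({l for l in leaves if leaves.count(l) > 1})
            raise PhyloError(f"duplicate leaf labels: {dup}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise PhyloError("tree has an edge without a branch length")
            if not np.isfinite(edge.length) or edge.length < 0:
                raise PhyloError(f"invalid branch length {edge.length!r}")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def is_ultrametric(self, rel_tol: float = 1e-3) -> bool:
        depths = self._leaf_depths()
        dmax = max(depths.values())
        if dmax == 0:
            return True
        return (dmax - min(depths.values())) / dmax <= rel_tol

    def _leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for lf in self.tree.leaf_node_iter():
            d, node = 0.0, lf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[lf.taxon.label] = d
        return depths

    def vcv(self, species: list[str] | None = None) -> pd.DataFrame:
        """Brownian-motion tip covariance (shared root-to-MRCA path lengths).

        Uses the identity cov(i, j) = (depth_i + depth_j - d_ij) / 2, with
        d_ij the patristic distance — exact on any additive tree.
        """
        species = list(species) if species is not None else self.leaf_labels
        D = patristic_distances(self, species).values
        depths = self._leaf_depths()
        d = np.array([depths[s] for s in species])
        C = (d[:, None] + d[None, :] - D) / 2.0
        np.fill_diagonal(C, d)
        return pd.DataFrame(C, index=species, columns=species)


def parse_newick(newick: str, label: str = "tree") -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"cannot parse Newick: {exc}") from exc
    return PhyloTree(tree=tree, label=label)


def read_newick(path, label: str | None = None) -> PhyloTree:
    with open(path) as fh:
        text = fh.read()
    return parse_newick(text, label=label or str(path))


# ---------------------------------------------------------------------------
# Distances and eigenvectors


def patristic_distances(
    tree: PhyloTree, species: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of path-length distances between leaves."""
    species = list(species) if species is not None else tree.leaf_labels
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    unknown = [s for s in species if s not in taxa]
    if unknown:
        raise PhyloError(f"species not in tree: {unknown}")
    pdm = tree.tree.phylogenetic_distance_matrix()
    n = len(species)
    D = np.zeros((n, n))
    for i, a in enumerate(species):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[species[j]])
    return pd.DataFrame(D, index=species, columns=species)


@dataclass
class EigenvectorSet:
    """Retained PCoA axes of a patristic distance matrix.

    ``coordinates`` holds one column per retained axis (EV1..EVk), scaled so
    squared Euclidean distances over *all* positive axes reproduce the
    squared patristic distances.  ``variance_fractions`` are shares of the
    positive-eigenvalue total; the retained set is the smallest prefix whose
    cumulative share reaches ``threshold``.
    """

    species: list[str]
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    cumulative_fraction: float
    threshold: float
    source_label: str

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_csv(self, path) -> None:
        out = self.coordinates.copy()
        out.index.name = "species"
        out.to_csv(path)


def extract_eigenvectors(
    tree: PhyloTree,
    species: list[str] | None = None,
    threshold: float = 0.65,
    source_label: str | None = None,
) -> EigenvectorSet:
    """PCoA of the patristic distance matrix with a variance threshold.

    Gower double-centering of -0.5 * D**2 followed by an eigendecomposition;
    negative eigenvalues (possible on non-ultrametric inputs) are dropped
    from both the numerator and denominator of the variance fractions.
    """
    D = patristic_distances(tree, species)
    species = list(D.index)
    n = len(species)
    if n < 3:
        raise PhyloError("eigenvector extraction needs at least 3 species")
    if not (0 < threshold <= 1):
        raise PhyloError("threshold must be in (0, 1]")
    A = -0.5 * D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    if not pos.any():
        raise PhyloError("degenerate tree: no positive eigenvalues")
    lam = eigval[pos]
    vec = eigvec[:, pos]
    fractions = lam / lam.sum()
    cum = np.cumsum(fractions)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    coords = vec[:, :k] * np.sqrt(lam[:k])
    frame = pd.DataFrame(
        coords,
        index=pd.Index(species, name="species"),
        columns=[f"EV{i + 1}" for i in range(k)],
    )
    return EigenvectorSet(
        species=species,
        coordinates=frame,
        eigenvalues=lam[:k],
        variance_fractions=fractions[:k],
        cumulative_fraction=float(cum[k - 1]),
        threshold=threshold,
        source_label=source_label or tree.label,
    )


# ---------------------------------------------------------------------------
# Phylogenetic signal


@dataclass
class SignalEstimate:
    metric: str  # "lambda" or "D"
    value: float
    p_value_no_signal: float
    p_value_brownian: float | None = None
    n_random: int | None = None
    n_brownian: int | None = None
    unidentifiable: bool = False
    message: str = ""


def _lambda_loglik(lam: float, y: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of lambda (mean and rate maximised out)."""
    n = len(y)
    Cl = lam * C + (1 - lam) * np.diag(np.diag(C))
    sign, logdet = np.linalg.slogdet(Cl)
    if sign <= 0:
        return -np.inf
    Ci = np.linalg.inv(Cl)
    one = np.ones(n)
    mu = (one @ Ci @ y) / (one @ Ci @ one)
    r = y - mu
    s2 = (r @ Ci @ r) / n
    if s2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagels_lambda(tree: PhyloTree, trait: pd.Series) -> SignalEstimate:
    """Maximum-likelihood Pagel's lambda on [0, 1] for a continuous trait.

    The likelihood-ratio p-value against lambda = 0 uses the boundary
    mixture 0.5*chi2(0) + 0.5*chi2(1) since lambda = 0 sits on the edge of
    the parameter space.
    """
    trait = trait.dropna()
    if trait.nunique() <= 1:
        raise PhyloError("constant trait: lambda undefined")
    species = list(trait.index)
    C = tree.vcv(species).values
    y = trait.values.astype(float)
    off = C - np.diag(np.diag(C))
    if np.allclose(off, 0):
        return SignalEstimate(
            metric="lambda",
            value=np.nan,
            p_value_no_signal=np.nan,
            unidentifiable=True,
            message="star tree: covariance independent of lambda",
        )
    res = minimize_scalar(
        lambda l: -_lambda_loglik(l, y, C),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    ll_hat = _lambda_loglik(lam_hat, y, C)
    ll0 = _lambda_loglik(0.0, y, C)
    if ll0 >= ll_hat:  # optimum at the boundary
        lam_hat, ll_hat = 0.0, ll0
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = 1.0 if lr == 0 else 0.5 * chi2.sf(lr, df=1)
    return SignalEstimate(metric="lambda", value=lam_hat, p_value_no_signal=float(p))


def _sum_of_changes(tree_nodes, values: dict) -> float:
    """Sum over edges of |parent - child| after averaging tip states rootward.

    ``tree_nodes`` is a postorder node list; internal node values are the
    unweighted mean of their children's values.
    """
    node_val: dict = {}
    for node in tree_nodes:
        if node.is_leaf():
            node_val[node] = values[node.taxon.label]
        else:
            node_val[node] = float(
                np.mean([node_val[c] for c in node.child_nodes()])
            )
    total = 0.0
    for node in tree_nodes:
        parent = node.parent_node
        if parent is not None:
            total += abs(node_val[parent] - node_val[node])
    return total


def fritz_purvis_D(
    tree: PhyloTree,
    trait: pd.Series,
    n_random: int = 1000,
    n_brownian: int = 1000,
    seed: int | None = None,
) -> SignalEstimate:
    """Fritz & Purvis' D for a binary trait (0/1 or two labels).

    D = (d_obs - mean(d_B)) / (mean(d_R) - mean(d_B)) where d is the sum of
    character changes across the tree, d_R its expectation under tip-label
    shuffling and d_B under threshold-Brownian simulation at the observed
    prevalence.  Reports tail p-values of d_obs within each null: a small
    ``p_value_no_signal`` rejects random structure (signal present); a
    small ``p_value_brownian`` rejects Brownian clumping.
    """
    if n_random < 10 or n_brownian < 10:
        raise PhyloError("need at least 10 null replicates")
    trait = trait.dropna()
    levels = sorted(trait.unique(), key=str)
    if len(levels) != 2:
        raise PhyloError(f"binary trait must have both categories present, got {levels}")
    y = (trait == levels[1]).astype(float)
    species = list(y.index)
    n = len(species)
    n_ones = int(y.sum())

    sub = tree.tree.extract_tree_with_taxa_labels(species)
    postorder = list(sub.postorder_node_iter())
    rng = np.random.default_rng(seed)

    d_obs = _sum_of_changes(postorder, dict(zip(y.index, y.values)))

    vals = y.values.copy()
    d_rand = np.empty(n_random)
    for i in range(n_random):
        rng.shuffle(vals)
        d_rand[i] = _sum_of_changes(postorder, dict(zip(species, vals)))

    C = tree.vcv(species).values
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n) * np.trace(C) / n)
    d_brown = np.empty(n_brownian)
    for i in range(n_brownian):
        z = L @ rng.standard_normal(n)
        cut = np.sort(z)[::-1][n_ones - 1] if n_ones > 0 else np.inf
        b = (z >= cut).astype(float)
        d_brown[i] = _sum_of_changes(postorder, dict(zip(species, b)))

    denom = d_rand.mean() - d_brown.mean()
    if abs(denom) < 1e-12:
        raise PhyloError("degenerate nulls: random and Brownian expectations equal")
    D = (d_obs - d_brown.mean()) / denom
    p_rand = float(np.mean(d_rand <= d_obs))  # small when obs more clumped than random
    p_brown = float(np.mean(d_brown >= d_obs))
    return SignalEstimate(
        metric="D",
        value=float(D),
        p_value_no_signal=p_rand,
        p_value_brownian=p_brown,
        n_random=n_random,
        n_brownian=n_brownian,
    )
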