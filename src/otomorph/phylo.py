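"""Phylogenetic comparative machinery.

Occurrence-based time calibration of a fixed topology, Brownian-motion (BM)
covariance, multivariate phylogenetic signal (Blomberg's K and its
multivariate generalization), and BM ancestral-state estimates for
phylomorphospace projection.

Time calibration follows the paleontological logic of stochastic
time-scaling: node ages honor the oldest first appearance among descendants,
and zero-length branches are removed by stochastic root-ward extensions whose
expected size shrinks as the fossil sampling rate grows.  Sampling and
extinction rates are estimated from taxon stratigraphic durations under a
constant-rates exponential model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import stats

from otomorph.types import EstimationError, OccurrenceRecord, ValidationError


@dataclass
class TimeTree:
    """A rooted topology with branch durations in Myr and tip ages in Ma."""

    tree: dendropy.Tree
    tip_ages: Dict[str, float]

    @property
    def taxa(self) -> List[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def node_depths(self) -> Dict[dendropy.Node, float]:
        """Path length from the root to each node (root depth 0)."""
        depths = {}
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        return depths

    @property
    def root_age(self) -> float:
        depths = self.node_depths()
        leaf = next(self.tree.leaf_node_iter())
        return self.tip_ages[leaf.taxon.label] + depths[leaf]

    def node_ages(self) -> Dict[dendropy.Node, float]:
        root_age = self.root_age
        return {nd: root_age - d for nd, d in self.node_depths().items()}

    def validate(self, tol: float = 1e-6) -> None:
        ages = self.node_ages()
        for leaf in self.tree.leaf_node_iter():
            expect = self.tip_ages[leaf.taxon.label]
            if abs(ages[leaf] - expect) > tol:
                raise ValidationError(
                    f"tip {leaf.taxon.label!r}: path length inconsistent with tip age "
                    f"({ages[leaf]:.6f} vs {expect:.6f})"
                )
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < -tol:
                raise ValidationError("negative branch duration")

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return all(abs(a) <= tol for a in self.tip_ages.values())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class RateEstimates:
    """Per-lineage-Myr rates; speciation is assumed equal to extinction."""

    sampling_rate: float
    extinction_rate: float

    @property
    def speciation_rate(self) -> float:
        return self.extinction_rate


@dataclass(frozen=True)
class PhyloSignalResult:
    K: float
    p_value: float
    n_permutations: int


def estimate_rates(durations: Sequence[float], interval_length: float = 1.0) -> RateEstimates:
    """Estimate extinction and fossil-sampling rates from stratigraphic durations.

    The extinction rate is the maximum-likelihood rate of the exponential
    duration distribution under the constant-rates model (with a half-interval
    continuity correction for point occurrences).  The sampling rate comes
    from the frequency of single-interval taxa: sampling events along an
    exponential lifetime are Poisson, so the number of occupied intervals
    given at least one find is geometric with success probability
    q / (q + r), and the singleton fraction p1 estimates r = q (1 - p1) / p1.
    """
    d = np.asarray(list(durations), dtype=float)
    if len(d) < 3:
        raise EstimationError("need at least 3 taxon durations")
    if np.any(d < 0):
        raise EstimationError("durations must be nonnegative")
    if np.all(d == 0):
        raise EstimationError("all durations zero: uninformative for rate estimation")
    d_eff = np.maximum(d, interval_length / 2.0)
    q = 1.0 / d_eff.mean()
    p1 = float(np.mean(d < interval_length))
    n = len(d)
    if p1 <= 0.0:
        r = q * n  # no singletons observed: sampling is effectively dense
    else:
        r = max(q * (1.0 - p1) / p1, q / n)
    return RateEstimates(sampling_rate=r, extinction_rate=q)


def _min_ages(tree: dendropy.Tree, fad: Dict[str, float]) -> Dict[dendropy.Node, float]:
    """Oldest descendant first-appearance age per node (stratigraphic floor)."""
    out = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            out[nd] = fad[nd.taxon.label]
        else:
            out[nd] = max(out[ch] for ch in nd.child_nodes())
    return out


def time_calibrate(
    topology: dendropy.Tree,
    occurrences: Sequence[OccurrenceRecord],
    rates: RateEstimates,
    n_trees: int = 250,
    seed: int = 0,
) -> List[TimeTree]:
    """Stochastically time-scale a topology against fossil occurrences.

    Each replicate assigns tip ages at last appearance, floors every internal
    node at the oldest descendant first appearance, and then extends each
    internal node root-ward by an Exponential(sampling_rate) increment above
    the maximum of its stratigraphic floor and its children's ages.  Larger
    sampling rates imply less unsampled history and hence smaller extensions.
    """
    occ = {o.taxon: o for o in occurrences}
    tips = [l.taxon.label for l in topology.leaf_node_iter()]
    missing = [t for t in tips if t not in occ]
    if missing:
        raise ValidationError(f"no occurrence record for tip(s): {missing}")
    if rates.sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    fad = {t: occ[t].first_appearance for t in tips}
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        tree = topology.clone(depth=1)
        floors = _min_ages(tree, fad)
        ages: Dict[dendropy.Node, float] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                ages[nd] = occ[nd.taxon.label].last_appearance
            else:
                base = max([floors[nd]] + [ages[ch] for ch in nd.child_nodes()])
                ages[nd] = base + rng.exponential(1.0 / rates.sampling_rate)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = ages[nd.parent_node] - ages[nd]
        tt = TimeTree(tree=tree, tip_ages={t: occ[t].last_appearance for t in tips})
        out.append(tt)
    return out


def _clade_key(nd: dendropy.Node) -> frozenset:
    return frozenset(l.taxon.label for l in nd.leaf_iter())


def consensus_tree(trees: Sequence[TimeTree]) -> TimeTree:
    """Average node ages over a list of identically-shaped time trees."""
    if not trees:
        raise ValidationError("empty tree list")
    ref = trees[0]
    ref_keys = {_clade_key(nd) for nd in ref.tree.preorder_node_iter()}
    sums: Dict[frozenset, float] = {k: 0.0 for k in ref_keys}
    for tt in trees:
        ages = tt.node_ages()
        keys = set()
        for nd, age in ages.items():
            k = _clade_key(nd)
            keys.add(k)
            if k not in sums:
                raise ValidationError("trees have mixed topologies")
            sums[k] += age
        if keys != ref_keys:
            raise ValidationError("trees have mixed topologies")
    mean_age = {k: s / len(trees) for k, s in sums.items()}
    tree = ref.tree.clone(depth=1)
    ages = {nd: mean_age[_clade_key(nd)] for nd in tree.preorder_node_iter()}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = ages[nd.parent_node] - ages[nd]
    tip_ages = {l.taxon.label: ages[l] for l in tree.leaf_node_iter()}
    return TimeTree(tree=tree, tip_ages=tip_ages)


def bm_covariance(tt: TimeTree, taxa: Optional[Sequence[str]] = None) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length per tip pair.

    Rows/columns follow ``taxa`` (default: sorted tip labels).  ``taxa`` may
    be a subset of the tips; the restricted matrix is the BM covariance of
    that subset.
    """
    taxa = list(taxa) if taxa is not None else tt.taxa
    index = {t: i for i, t in enumerate(taxa)}
    unknown = [t for t in taxa if t not in {l.taxon.label for l in tt.tree.leaf_node_iter()}]
    if unknown:
        raise ValidationError(f"taxa not on the tree: {unknown}")
    n = len(taxa)
    depths = tt.node_depths()
    C = np.zeros((n, n))
    for nd in tt.tree.postorder_node_iter():
        if nd.is_leaf():
            if nd.taxon.label not in index:
                continue
            i = index[nd.taxon.label]
            C[i, i] = depths[nd]
            continue
        children = nd.child_nodes()
        leaf_sets = [
            [index[l.taxon.label] for l in ch.leaf_iter() if l.taxon.label in index]
            for ch in children
        ]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in leaf_sets[a]:
                    for j in leaf_sets[b]:
                        C[i, j] = C[j, i] = depths[nd]
    return C


def _k_statistic(X: np.ndarray, Cinv: np.ndarray, trC: float, denom_expect: float) -> float:
    n = X.shape[0]
    ones = np.ones(n)
    w = Cinv @ ones
    a = (w @ X) / (ones @ w)
    D = X - a
    mse0 = np.einsum("ij,ij->", D, D) / (n - 1)
    mse = np.einsum("ij,ij->", D, Cinv @ D) / (n - 1)
    if mse <= 0:
        raise EstimationError("zero phylogenetically-corrected variance")
    return (mse0 / mse) / denom_expect


def blomberg_k_mult(
    data: np.ndarray,
    tt: TimeTree,
    n_perm: int = 1000,
    seed: int = 0,
    taxa: Optional[Sequence[str]] = None,
) -> PhyloSignalResult:
    """Multivariate Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of ordinary to phylogenetically-corrected
    mean squared error (about the generalized-least-squares root state) to its
    Brownian-motion expectation; K = 1 under BM, K < 1 when relatives resemble
    each other less than BM predicts.  For multivariate data the mean squares
    are traces over all columns.  The p-value is the add-one-corrected
    fraction of tip-label permutations with K at least as large as observed.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.ndim != 2:
        raise ValidationError("data must be an n x d matrix")
    C = bm_covariance(tt, taxa=taxa)
    n = C.shape[0]
    if X.shape[0] != n:
        raise ValidationError(f"data rows ({X.shape[0]}) must match tips ({n})")
    if np.allclose(X, X[0]):
        raise EstimationError("zero total variance in data")
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    denom_expect = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    k_obs = _k_statistic(X, Cinv, np.trace(C), denom_expect)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _k_statistic(X[perm], Cinv, np.trace(C), denom_expect) >= k_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PhyloSignalResult(K=float(k_obs), p_value=float(p), n_permutations=n_perm)


def ancestral_states_bm(
    data: np.ndarray, tt: TimeTree, taxa: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[dendropy.Node]]:
    """Maximum-likelihood BM ancestral states for all internal nodes.

    The estimate at node v is the generalized-least-squares projection
    a + c_v' C^{-1} (X - 1 a), where C is the tip BM covariance, a the GLS
    root state and c_v the vector of shared path lengths between v and each
    tip.  Returns the internal-node x d matrix and the node list (preorder).
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    taxa = list(taxa) if taxa is not None else tt.taxa
    index = {t: i for i, t in enumerate(taxa)}
    C = bm_covariance(tt, taxa=taxa)
    n = C.shape[0]
    if X.shape[0] != n:
        raise ValidationError("data rows must match tips")
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    w = Cinv @ ones
    a = (w @ X) / (ones @ w)
    resid = X - a
    depths = tt.node_depths()
    # ancestors (root-ward path) per node, with descendant leaf index sets
    leafsets = {}
    for nd in tt.tree.postorder_node_iter():
        if nd.is_leaf():
            lbl = nd.taxon.label
            leafsets[nd] = {index[lbl]} if lbl in index else set()
        else:
            leafsets[nd] = set().union(*(leafsets[ch] for ch in nd.child_nodes()))
    internal = [nd for nd in tt.tree.preorder_node_iter() if not nd.is_leaf()]
    out = np.zeros((len(internal), X.shape[1]))
    for r, nd in enumerate(internal):
        c_v = np.zeros(n)
        for i in leafsets[nd]:
            c_v[i] = depths[nd]
        anc = nd.parent_node
        remaining = set(range(n)) - leafsets[nd]
        node = nd
        while anc is not None and remaining:
            newly = leafsets[anc] - leafsets[node]
            for i in newly & remaining:
                c_v[i] = depths[anc]
            remaining -= newly
            node, anc = anc, anc.parent_node
        out[r] = a + c_v @ Cinv @ resid
    return out, internal
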