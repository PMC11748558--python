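"""Tree building and comparison for amplicon concordance analysis.

The concordance stage compares a maximum-likelihood tree of long-read ASVs
with the tree of their pseudo-short-read counterparts.  This module supplies
the pieces: Jukes–Cantor distances from an alignment, neighbor joining as a
starting topology, a GTR+I likelihood (Felsenstein pruning with an
invariant-sites mixture), hill-climbing NNI search, the normalized
Robinson–Foulds distance between the resulting trees, and tip-pair export
for tanglegram plotting.

Trees are :class:`dendropy.Tree` objects throughout, so newick round-trips
and tip manipulation use a standard library; the likelihood machinery,
neighbor joining, and bipartition comparison are implemented here.

Branch lengths are in expected substitutions per site of the *variable*
fraction; the invariant-sites proportion ``p_inv`` enters only as a mixture
weight on column likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from . import seqcore
from .alignment import Alignment

__all__ = [
    "DistanceMatrix",
    "SubstModel",
    "TreeComparison",
    "distances",
    "nj_tree",
    "nj_joins",
    "loglik",
    "optimize_branch_lengths",
    "optimize_model",
    "nni_search",
    "rf_distance",
    "tanglegram_pairs",
    "read_newick",
    "write_newick",
]

_SATURATION_CAP = 5.0  # substitutions/site assigned to saturated (p >= 3/4) pairs


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        m = np.asarray(self.d, dtype=float)
        if m.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if m.min() < 0:
            raise ValueError("distances must be nonnegative")
        self.d = m


@dataclass
class SubstModel:
    """Reversible nucleotide substitution model (JC or GTR) + invariant sites.

    ``exchangeabilities`` are the six symmetric rates in the order
    (AC, AG, AT, CG, CT, GT); the GT rate is conventionally fixed at 1 when
    fitting.  The rate matrix is normalised to one expected substitution
    per unit branch length.
    """

    model: str = "JC"
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.model not in ("JC", "GTR"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities <= 0).any():
            raise ValueError("need six positive exchangeabilities")
        if self.base_freqs.shape != (4,) or not math.isclose(
            self.base_freqs.sum(), 1.0, abs_tol=1e-8
        ):
            raise ValueError("base frequencies must sum to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")

    @classmethod
    def jc(cls, p_inv: float = 0.0) -> "SubstModel":
        return cls("JC", np.ones(6), np.full(4, 0.25), p_inv)

    @classmethod
    def gtr(
        cls, exchangeabilities, base_freqs, p_inv: float = 0.0
    ) -> "SubstModel":
        return cls("GTR", np.asarray(exchangeabilities), np.asarray(base_freqs), p_inv)

    def rate_matrix(self) -> np.ndarray:
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.exchangeabilities, pairs):
            s[i, j] = s[j, i] = r
        q = s * self.base_freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(self.base_freqs * np.diag(q)).sum()
        return q / scale

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # reversible Q diagonalised through the pi^{1/2} similarity transform
        pi = self.base_freqs
        sq = np.sqrt(pi)
        sym = (sq[:, None] / sq[None, :]) * self.rate_matrix() * 1.0
        sym = (sym + sym.T) / 2.0
        lam, u = np.linalg.eigh(sym)
        left = u.T * sq[None, :]
        right = u / sq[:, None]
        return lam, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        lam, right, left = self._eigen()
        p = (right * np.exp(lam * t)[None, :]) @ left
        return np.clip(p, 0.0, 1.0)


@dataclass
class TreeComparison:
    rf: int
    n_shared_tips: int
    max_rf: int
    nrf: float


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def distances(msa: Alignment, model: str = "JC") -> DistanceMatrix:
    """Pairwise Jukes–Cantor distances, ``d = -(3/4) ln(1 - 4p/3)``.

    ``p`` is the proportion of differing sites over columns where both rows
    carry a concrete base.  Saturated pairs (``p >= 3/4``) are capped at
    5 substitutions/site and listed in ``saturated``.
    """
    if model != "JC":
        raise ValueError("only JC distances are implemented")
    if msa.n_rows < 3:
        raise ValueError("need at least three rows")
    rows = msa.rows
    n = msa.n_rows
    codes = []
    for r in rows:
        codes.append(
            np.array([{"A": 0, "C": 1, "G": 2, "T": 3}.get(c, -1) for c in r])
        )
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            shared = int(ok.sum())
            if shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            p = float((codes[i][ok] != codes[j][ok]).mean())
            if p >= 0.75:
                dist = _SATURATION_CAP
                saturated.append((msa.ids[i], msa.ids[j]))
            else:
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.ids), d, saturated)


def _nj_agglomerate(dm: DistanceMatrix):
    """Shared NJ core: yields (i_active, j_active, li, lj) joins.

    Cluster identity is tracked by the lexicographically smallest tip label
    it contains, so tie-breaking on the Q matrix — smallest Q, then the
    smallest (label_i, label_j) pair — is invariant to input order.
    """
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("need at least three taxa")
    d = dm.d.copy()
    active = list(range(n0))
    reps = {i: dm.taxa[i] for i in range(n0)}
    joins = []
    nxt = n0
    dist = {(i, j): d[i, j] for i in range(n0) for j in range(n0)}

    def get(i, j):
        return dist[(i, j)] if (i, j) in dist else dist[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                lab = tuple(sorted((reps[i], reps[j])))
                key = (q, lab)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        for k in active:
            if k in (i, j):
                continue
            dist[(nxt, k)] = (get(i, k) + get(j, k) - dij) / 2.0
        reps[nxt] = min(reps[i], reps[j])
        joins.append((i, j, li, lj, nxt))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return joins, active, get, reps, nxt


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcating seed node).

    Deterministic: Q-matrix ties break on the lexicographically smallest
    pair of cluster representative labels, so permuting the input taxa
    leaves the unrooted topology unchanged.  Negative NJ branch length
    estimates are clamped to zero.
    """
    joins, active, get, reps, _ = _nj_agglomerate(dm)
    frag = {i: f"{t}" for i, t in enumerate(dm.taxa)}
    for i, j, li, lj, new in joins:
        frag[new] = f"({frag[i]}:{li:.12g},{frag[j]}:{lj:.12g})"
    i, j, k = active
    li = max((get(i, j) + get(i, k) - get(j, k)) / 2.0, 0.0)
    lj = max((get(i, j) + get(j, k) - get(i, k)) / 2.0, 0.0)
    lk = max((get(i, k) + get(j, k) - get(i, j)) / 2.0, 0.0)
    newick = f"({frag[i]}:{li:.12g},{frag[j]}:{lj:.12g},{frag[k]}:{lk:.12g});"
    return dendropy.Tree.get(data=newick, schema="newick")


def nj_joins(dm: DistanceMatrix) -> list[tuple[int, int]]:
    """NJ agglomeration order as (cluster_a, cluster_b) index pairs.

    Leaves are clusters ``0..n-1``; each join creates cluster ``n + step``.
    The final three clusters are joined closest-pair-first, giving the
    rooted merge schedule used as a progressive-alignment guide.
    """
    joins, active, get, reps, nxt = _nj_agglomerate(dm)
    out = [(i, j) for i, j, *_ in joins]
    i, j, k = active
    pairs = sorted(
        [(get(i, j), tuple(sorted((reps[i], reps[j]))), i, j),
         (get(i, k), tuple(sorted((reps[i], reps[k]))), i, k),
         (get(j, k), tuple(sorted((reps[j], reps[k]))), j, k)]
    )
    _, _, a, b = pairs[0]
    out.append((a, b))
    c = next(x for x in (i, j, k) if x not in (a, b))
    out.append((nxt, c))
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_MASK_VEC = np.zeros((16, 4))
for _m in range(1, 16):
    for _b in range(4):
        if _m >> _b & 1:
            _MASK_VEC[_m, _b] = 1.0


def _tip_masks(msa: Alignment) -> dict[str, np.ndarray]:
    out = {}
    for tid, row in zip(msa.ids, msa.rows):
        masks = np.array(
            [15 if c == "-" else int(seqcore.encode_mask(c)[0]) for c in row],
            dtype=np.int64,
        )
        out[tid] = masks
    return out


def _compress(msa: Alignment) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Collapse identical site patterns; returns per-tip pattern masks + counts."""
    masks = _tip_masks(msa)
    stack = np.stack([masks[t] for t in msa.ids])  # (ntips, ncols)
    pats, counts = np.unique(stack, axis=1, return_counts=True)
    return {t: pats[i] for i, t in enumerate(msa.ids)}, counts.astype(float)


def loglik(tree: dendropy.Tree, msa: Alignment, model: SubstModel) -> float:
    """Log-likelihood by Felsenstein pruning with an invariant-sites mixture.

    Column likelihood is ``(1-p_inv) L_var + p_inv * sum(pi_b)`` over bases
    ``b`` compatible with every tip in the column (zero if none).
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(msa.ids):
        raise ValueError("tree tips do not match alignment rows")
    pat_masks, counts = _compress(msa)
    npat = len(counts)

    lam, right, left = model._eigen()

    def pmat(t: float) -> np.ndarray:
        if t is None:
            t = 0.0
        if t < 0:
            raise ValueError("negative branch length")
        return np.clip((right * np.exp(lam * t)[None, :]) @ left, 0.0, 1.0)

    partial: dict[int, np.ndarray] = {}
    scale_log = np.zeros(npat)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partial[id(node)] = _MASK_VEC[pat_masks[node.taxon.label]]
        else:
            acc = np.ones((npat, 4))
            for child in node.child_nodes():
                p = pmat(child.edge.length)
                acc = acc * (partial[id(child)] @ p.T)
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            scale_log += np.log(mx)
            partial[id(node)] = acc / mx[:, None]
    root_l = partial[id(tree.seed_node)] @ model.base_freqs
    log_lvar = np.log(np.maximum(root_l, 1e-300)) + scale_log

    if model.p_inv > 0:
        feas = np.full(npat, 15, dtype=np.int64)
        for m in pat_masks.values():
            feas &= m
        l_inv = _MASK_VEC[feas] @ model.base_freqs
        col = np.logaddexp(
            math.log1p(-model.p_inv) + log_lvar,
            np.where(l_inv > 0, math.log(model.p_inv) + np.log(np.maximum(l_inv, 1e-300)), -np.inf),
        )
    else:
        col = log_lvar
    return float((col * counts).sum())


def optimize_branch_lengths(
    tree: dendropy.Tree,
    msa: Alignment,
    model: SubstModel,
    rounds: int = 2,
    max_length: float = 10.0,
) -> float:
    """In-place per-edge line search; returns the final log-likelihood."""
    edges = [
        e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    ]
    for _ in range(rounds):
        for e in edges:
            def neg(t, _e=e):
                _e.length = float(t)
                return -loglik(tree, msa, model)

            res = minimize_scalar(
                neg, bounds=(1e-8, max_length), method="bounded",
                options={"xatol": 1e-6},
            )
            e.length = float(res.x)
    return loglik(tree, msa, model)


def optimize_model(
    tree: dendropy.Tree,
    msa: Alignment,
    model: SubstModel,
    rounds: int = 2,
    tol: float = 1e-6,
) -> SubstModel:
    """Coordinate-ascent fit of exchangeabilities (GT fixed at 1) and p_inv.

    Base frequencies are fixed at their empirical values from the
    alignment; each free parameter gets a bounded univariate line search
    per round.
    """
    counts = np.zeros(4)
    for r in msa.rows:
        for c in r:
            if c in "ACGT":
                counts["ACGT".index(c)] += 1
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    if model.model == "JC":
        freqs = np.full(4, 0.25)

    ex = model.exchangeabilities.copy()
    p_inv = model.p_inv
    prev = -np.inf
    for _ in range(rounds):
        if model.model == "GTR":
            for k in range(5):  # GT (index 5) stays fixed at 1
                def neg(v, _k=k):
                    e2 = ex.copy()
                    e2[_k] = v
                    return -loglik(tree, msa, SubstModel("GTR", e2, freqs, p_inv))

                res = minimize_scalar(
                    neg, bounds=(1e-3, 100.0), method="bounded",
                    options={"xatol": 1e-4},
                )
                ex[k] = float(res.x)

        def neg_pinv(v):
            return -loglik(
                tree, msa, SubstModel(model.model, ex, freqs, float(v))
            )

        res = minimize_scalar(
            neg_pinv, bounds=(0.0, 0.9), method="bounded", options={"xatol": 1e-4}
        )
        p_inv = float(res.x)
        cur = -neg_pinv(p_inv)
        if cur - prev < tol:
            break
        prev = cur
    return SubstModel(model.model, ex, freqs, p_inv)


def _internal_edges(tree: dendropy.Tree):
    out = []
    for e in tree.preorder_edge_iter():
        if (
            e.tail_node is not None
            and e.head_node.child_nodes()
            and e.head_node is not tree.seed_node
        ):
            out.append(e)
    return out


def _apply_nni(tree: dendropy.Tree, edge_index: int, which: int) -> dendropy.Tree:
    """Return a copy of ``tree`` with one NNI applied across an internal edge.

    ``which`` selects which child of the edge's head node is exchanged with
    the head node's sibling subtree.
    """
    t = tree.clone(depth=1)
    e = _internal_edges(t)[edge_index]
    v = e.head_node
    u = e.tail_node
    sibs = [c for c in u.child_nodes() if c is not v]
    c = sibs[0]
    a = v.child_nodes()[which]
    u.remove_child(c)
    v.remove_child(a)
    v.add_child(c)
    u.add_child(a)
    return t


def nni_search(
    start: dendropy.Tree,
    msa: Alignment,
    model: SubstModel,
    max_rounds: int = 20,
    tol: float = 1e-4,
    fit_model: bool = False,
    bl_rounds: int = 1,
) -> tuple[dendropy.Tree, float]:
    """Hill-climbing nearest-neighbor-interchange search.

    Each round scores both rearrangements of every internal edge at the
    current branch lengths, accepts the single best strictly improving
    move, then re-optimises branch lengths (and model parameters when
    ``fit_model``); stops when no move improves the log-likelihood by more
    than ``tol``.  The accepted log-likelihood sequence is non-decreasing
    by construction.  Returns ``(tree, loglik)``.
    """
    for node in start.preorder_node_iter():
        kids = node.child_nodes()
        if kids and node is not start.seed_node and len(kids) != 2:
            raise ValueError("nni_search requires a binary (unrooted) start tree")
    tree = start.clone(depth=1)
    cur = optimize_branch_lengths(tree, msa, model, rounds=bl_rounds)
    for _ in range(max_rounds):
        n_edges = len(_internal_edges(tree))
        best_ll, best_tree = cur, None
        for ei in range(n_edges):
            for which in (0, 1):
                cand = _apply_nni(tree, ei, which)
                ll = loglik(cand, msa, model)
                if ll > best_ll + tol:
                    best_ll, best_tree = ll, cand
        if best_tree is None:
            break
        tree = best_tree
        if fit_model:
            model = optimize_model(tree, msa, model, rounds=1)
        cur = optimize_branch_lengths(tree, msa, model, rounds=bl_rounds)
        assert cur >= best_ll - 1e-6
    return tree, cur


# ---------------------------------------------------------------------------
# Robinson–Foulds and tanglegrams
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree, shared: set[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions restricted to a shared tip set.

    Each internal edge contributes the shared tips on its far side,
    canonicalised to the side not containing the alphabetically first
    shared tip; splits that become trivial after restriction are dropped.
    """
    ref = min(shared)
    n = len(shared)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {
            leaf.taxon.label for leaf in node.leaf_iter()
        } & shared
        if ref in below:
            below = shared - below
        if 2 <= len(below) <= n - 2:
            out.add(frozenset(below))
    return out


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> TreeComparison:
    """Robinson–Foulds symmetric difference on the shared tip set.

    ``max_rf`` is the total number of non-trivial splits in the two
    restricted trees — ``2(n-3)`` when both are binary — and ``nrf`` is
    ``rf / max_rf`` (0 when neither tree has internal structure).
    """
    tips_a = {l.taxon.label for l in a.leaf_node_iter()}
    tips_b = {l.taxon.label for l in b.leaf_node_iter()}
    shared = tips_a & tips_b
    if len(shared) < 4:
        raise ValueError("need at least four shared tips")
    ba = _bipartitions(a, shared)
    bb = _bipartitions(b, shared)
    rf = len(ba ^ bb)
    max_rf = len(ba) + len(bb)
    nrf = rf / max_rf if max_rf else 0.0
    return TreeComparison(rf=rf, n_shared_tips=len(shared), max_rf=max_rf, nrf=nrf)


def _leaf_order(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def count_crossings(left_order: list[str], right_order: list[str],
                    mapping: dict[str, str]) -> int:
    """Number of crossing line pairs in a tanglegram layout."""
    pos = {t: i for i, t in enumerate(left_order)}
    seq = [pos[mapping[r]] for r in right_order if mapping.get(r) in pos]
    inv = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                inv += 1
    return inv


def tanglegram_pairs(
    a: dendropy.Tree,
    b: dendropy.Tree,
    mapping: dict[str, str],
    categories: dict[str, str] | None = None,
    barycenter_passes: int = 3,
) -> list[tuple[str, str, str]]:
    """Tip-pair lines for a tanglegram of tree ``a`` (left) vs ``b`` (right).

    ``mapping`` sends right tips to left tips (pseudo read -> parent ASV);
    right tips without a mapped left partner get category ``unassigned``.
    The right tree's children are reordered by repeated barycenter passes
    to reduce line crossings; the left leaf order is taken as drawn.
    """
    categories = categories or {}
    left = _leaf_order(a)
    pos = {t: i for i, t in enumerate(left)}
    b = b.clone(depth=1)

    def bary(node) -> float:
        vals = [
            pos[mapping[l.taxon.label]]
            for l in node.leaf_iter()
            if mapping.get(l.taxon.label) in pos
        ]
        return sum(vals) / len(vals) if vals else math.inf

    for _ in range(barycenter_passes):
        for node in b.postorder_node_iter():
            kids = node.child_nodes()
            if len(kids) > 1:
                node.set_child_nodes(sorted(kids, key=bary))
    out = []
    for rt in _leaf_order(b):
        lt = mapping.get(rt)
        if lt is None or lt not in pos:
            out.append(("", rt, "unassigned"))
        else:
            out.append((lt, rt, categories.get(rt, "one_to_one")))
    return out


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
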