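"""Synthetic gene families for exercising the whole pipeline offline.

The generator emulates the structure the real workflow consumes: a marker
gene family evolving on a known Yule tree, with (a) conserved primer
windows *planted* in every in-group taxon so the design stage has a
recoverable optimum, (b) a more distant out-group clade lacking those
windows so off-target screening has something to find, (c) a slowly
evolving 16S-like companion locus from which the identity map is built,
and (d) per-sample ASV count tables with overdispersed (lognormal +
Dirichlet-multinomial-style) abundances.

What it deliberately does not emulate: sequencing error, chimeras, indel
evolution (sequences stay aligned by construction, so the identity map can
be computed exactly), and gene-length variation.  Passing tests on this
generator therefore demonstrate algorithmic correctness, not robustness to
real-data noise.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .alignment import IdentityMap
from .classify_concord import RANKS
from .phylo import SubstModel

__all__ = [
    "SimulationParams",
    "SimulatedFamily",
    "simulate_gene_family",
    "simulate_asv_tables",
    "evolve_sequences",
    "make_sisters_identical",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated family.

    ``tree_depth`` is calibrated so the *average pairwise* tip divergence
    on the gene equals ``2 * tree_depth`` substitutions/site — in-group
    gyrB-like divergence of a bacterial family.  The out-group clade sits
    ``outgroup_depth_multiplier`` times deeper.  The 16S-like marker
    evolves at ``marker_rate_scale`` times the gene rate, so the default
    in-group spans roughly 96–100% marker identity while the out-group
    falls below a 91–95% ``idlow`` cut-off.
    """

    n_ingroup: int = 12
    n_outgroup: int = 5
    gene_length: int = 1800
    tree_depth: float = 0.15
    planted_windows: tuple[tuple[int, int], ...] = ((200, 21), (1500, 21))
    model: SubstModel = field(default_factory=SubstModel.jc)
    seed: int = 0
    outgroup_depth_multiplier: float = 4.0
    marker_length: int = 800
    marker_rate_scale: float = 0.1
    target_family: str = "Conservaceae"
    outgroup_family: str = "Divergentaceae"
    plant_in_outgroup: bool = False

    def __post_init__(self) -> None:
        if self.n_ingroup < 3:
            raise ValueError("need at least three in-group taxa")
        if self.tree_depth < 0 or self.gene_length < 1:
            raise ValueError("invalid depth or length")
        spans = sorted((p, p + l) for p, l in self.planted_windows)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("planted windows overlap")
        for p, l in self.planted_windows:
            if p < 0 or p + l > self.gene_length:
                raise ValueError("planted window outside gene bounds")


@dataclass
class SimulatedFamily:
    tree: dendropy.Tree
    gene_records: list[tuple[str, str]]
    marker_records: list[tuple[str, str]]
    taxonomy: pd.DataFrame
    identity_map: IdentityMap
    root_gene: str
    planted_sequences: list[str]
    params: SimulationParams


_BASES = np.array(list("ACGT"))


def _sample_states(p_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = p_rows.cumsum(axis=1)
    return (u[:, None] > cum).sum(axis=1)


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    model: SubstModel,
    rng: np.random.Generator,
    root_states: np.ndarray | None = None,
    rate_scale: float = 1.0,
) -> dict[str, str]:
    """Evolve one column-wise sequence per tip along a tree.

    The root is drawn from the model's base frequencies unless
    ``root_states`` is given; a ``p_inv`` fraction of sites is frozen.
    Branch lengths are multiplied by ``rate_scale``.
    """
    if root_states is None:
        root_states = _sample_states(
            np.tile(model.base_freqs, (length, 1)), rng.random(length)
        )
    inv_mask = rng.random(length) < model.p_inv
    states = {id(tree.seed_node): root_states}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            t = (node.edge.length or 0.0) * rate_scale
            parent = states[id(node.parent_node)]
            if t <= 0:
                child = parent.copy()
            else:
                p = model.transition_matrix(t)
                child = _sample_states(p[parent], rng.random(length))
                child[inv_mask] = parent[inv_mask]
            states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[states[id(node)]])
    return out


def _yule(n: int, rng: random.Random, prefix: str) -> dendropy.Tree:
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=rng
    )
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"{prefix}{i:02d}"
    return tree

def _subtree_newick(tree: dendropy.Tree) -> str:
    tree.seed_node.edge.length = None
    s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return s.rstrip(";")


def _mean_pairwise(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    tot = n = 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            tot += pdm.distance(taxa[i], taxa[j])
            n += 1
    return tot / n if n else 0.0


def _scale(tree: dendropy.Tree, factor: float) -> None:
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= factor


def _disrupt(window: str) -> str:
    """Deterministically break a planted window (cyclic substitution at
    every other position) so out-group templates cannot be primed."""
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return "".join(
        rot[c] if i % 2 == 0 else c for i, c in enumerate(window)
    )


def simulate_gene_family(params: SimulationParams) -> SimulatedFamily:
    """Generate the full fixture bundle for one family.

    Returns the combined in-/out-group tree, gene and 16S-like marker
    sequences, a ranked taxonomy table, and the marker identity map.  The
    planted windows are copied unchanged from the root haplotype into every
    in-group taxon, and (by default) disrupted in the out-group.
    """
    rng = np.random.default_rng(params.seed)
    trng = random.Random(params.seed + 1)

    in_tree = _yule(params.n_ingroup, trng, "IN")
    if _mean_pairwise(in_tree) > 0 and params.tree_depth > 0:
        _scale(in_tree, 2 * params.tree_depth / _mean_pairwise(in_tree))
    elif params.tree_depth == 0:
        _scale(in_tree, 0.0)

    if params.n_outgroup > 0:
        stem = params.tree_depth * max(params.outgroup_depth_multiplier - 1.0, 0.0)
        if params.n_outgroup >= 3:
            out_tree = _yule(params.n_outgroup, trng, "OUT")
            if _mean_pairwise(out_tree) > 0 and params.tree_depth > 0:
                _scale(out_tree, 2 * params.tree_depth / _mean_pairwise(out_tree))
            out_nwk = _subtree_newick(out_tree)
        elif params.n_outgroup == 2:
            d = params.tree_depth
            out_nwk = f"(OUT01:{d:.12g},OUT02:{d:.12g})"
        else:
            out_nwk = f"OUT01:{params.tree_depth:.12g}"
        combined = (
            f"({_subtree_newick(in_tree)}:{stem:.12g},{out_nwk}:{stem:.12g});"
        )
        tree = dendropy.Tree.get(data=combined, schema="newick")
    else:
        tree = in_tree

    root_gene = _sample_states(
        np.tile(params.model.base_freqs, (params.gene_length, 1)),
        rng.random(params.gene_length),
    )
    genes = evolve_sequences(
        tree, params.gene_length, params.model, rng, root_states=root_gene
    )
    planted = []
    root_str = "".join(_BASES[root_gene])
    for pos, ln in params.planted_windows:
        win = root_str[pos : pos + ln]
        planted.append(win)
        broken = _disrupt(win)
        for tid in list(genes):
            s = genes[tid]
            if tid.startswith("IN") or params.plant_in_outgroup:
                genes[tid] = s[:pos] + win + s[pos + ln :]
            else:
                genes[tid] = s[:pos] + broken + s[pos + ln :]

    markers = evolve_sequences(
        tree, params.marker_length, params.model, rng,
        rate_scale=params.marker_rate_scale,
    )

    ids = sorted(genes)
    gene_records = [(t, genes[t]) for t in ids]
    marker_records = [(t, markers[t]) for t in ids]

    # the generator emits gapless equal-length loci, so percent identity is
    # exact column agreement (equivalent to aligning first)
    n = len(ids)
    m = np.full((n, n), 100.0)
    arrs = [np.frombuffer(markers[t].encode(), dtype=np.uint8) for t in ids]
    for i in range(n):
        for j in range(i + 1, n):
            pid = 100.0 * float((arrs[i] == arrs[j]).mean())
            m[i, j] = m[j, i] = pid
    imap = IdentityMap(ids, m)

    rows = []
    for t in ids:
        ingroup = t.startswith("IN")
        rows.append(
            {
                "id": t,
                "kingdom": "Bacteria",
                "phylum": "Simulota",
                "class": "Simulia",
                "order": "Simulales",
                "family": params.target_family if ingroup else params.outgroup_family,
                "genus": "Ingenus" if ingroup else "Outgenus",
                "species": f"{'Ingenus' if ingroup else 'Outgenus'} sp{t[-2:]}",
            }
        )
    taxonomy = pd.DataFrame(rows, columns=("id",) + RANKS)

    return SimulatedFamily(
        tree=tree,
        gene_records=gene_records,
        marker_records=marker_records,
        taxonomy=taxonomy,
        identity_map=imap,
        root_gene=root_str,
        planted_sequences=planted,
        params=params,
    )


def simulate_asv_tables(
    amplicons: list[tuple[str, str]],
    n_samples: int = 4,
    depth: int = 10_000,
    dispersion: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample ASV count tables with overdispersed abundances.

    Each ASV gets a lognormal base abundance; per sample the abundances
    are jittered by a Gamma(dispersion, 1/dispersion) factor (variance
    1/dispersion, so dispersion -> infinity approaches plain multinomial
    sampling) and ``depth`` reads are drawn multinomially.  Long-format
    output: asv_id, sample, count; each sample sums exactly to ``depth``.
    """
    if not amplicons:
        raise ValueError("need at least one amplicon")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    ids = [a[0] for a in amplicons]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(ids))
    rows = []
    for s in range(1, n_samples + 1):
        w = base * rng.gamma(shape=dispersion, scale=1.0 / dispersion, size=len(ids))
        counts = rng.multinomial(depth, w / w.sum())
        for aid, c in zip(ids, counts):
            rows.append({"asv_id": aid, "sample": f"S{s}", "count": int(c)})
    return pd.DataFrame(rows)


def make_sisters_identical(
    records: list[tuple[str, str]], a: str, b: str, region: tuple[int, int]
) -> list[tuple[str, str]]:
    """Copy taxon ``a``'s sub-region onto taxon ``b``.

    Used to build the resolution fixture where two sister species are
    indistinguishable over a short amplicon but divergent elsewhere.
    """
    start, end = region
    seqs = dict(records)
    if a not in seqs or b not in seqs:
        raise KeyError("taxon not in records")
    donor = seqs[a][start:end]
    seqs[b] = seqs[b][:start] + donor + seqs[b][end:]
    return [(t, seqs[t]) for t, _ in records]
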