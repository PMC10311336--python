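"""Gene-tree simulation under the multispecies coalescent with substitution rates.

The model: each species-tree branch *i* carries a duration in generations
(``tau``), a haploid effective population size (``N``) and a per-generation
substitution rate (``nu``).  Derived per-branch quantities are the coalescent
unit (CU) length ``T = tau / N``, the CU substitution rate ``mu = nu * N`` and
the substitution-unit (SU) length ``t = tau * nu = T * mu``.  Gene trees are
drawn under the standard coalescent inside the species tree (exponential
waiting times at rate C(j,2) in CU time among j lineages), and every gene-tree
branch segment lying inside species branch *i* accrues SU length at rate
``mu_i``.  Unequal ``nu`` across branches yields non-ultrametric gene trees.

Optionally each gene is scaled by an i.i.d. rate multiplier with mean one
(lognormal), and per-gene-per-branch multipliers (heterotachy) can be enabled
as a robustness perturbation that lies outside the theoretical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trees_io import Node, PhyloTree

__all__ = [
    "BranchParams",
    "SimSpeciesTree",
    "SimConfig",
    "make_quartet_model",
    "random_model_tree",
    "simulate_gene_trees",
    "drop_leaves",
    "collapse_random_edges",
]

_TOL = 1e-12


@dataclass
class BranchParams:
    """Per-branch model parameters; ``tau=None`` marks the unbounded root stem."""

    tau: Optional[float]
    N: float
    nu: float

    @property
    def T(self) -> Optional[float]:
        return None if self.tau is None else self.tau / self.N

    @property
    def mu(self) -> float:
        return self.nu * self.N

    @property
    def t(self) -> Optional[float]:
        return None if self.tau is None else self.tau * self.nu

    def validate(self) -> None:
        if self.N <= 0 or self.nu <= 0:
            raise ValueError("N and nu must be positive")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be non-negative")


class SimSpeciesTree:
    """A species tree whose every node carries :class:`BranchParams`.

    The params attached to a non-root node describe the branch above it; the
    params attached to the root describe the (unbounded) stem above the root,
    whose ``mu`` governs coalescence and substitution accumulation there.
    """

    def __init__(self, tree: PhyloTree, params: Dict[Node, BranchParams]):
        self.tree = tree
        self.params = params
        for node in tree.preorder():
            if node not in params:
                raise ValueError(f"missing BranchParams for node {node!r}")
            params[node].validate()
        # consistency of derived identities (t = T * mu) is structural here,
        # but guard against inconsistent hand-built params dictionaries
        for p in params.values():
            if p.tau is not None and abs(p.t - p.T * p.mu) > _TOL * max(1.0, abs(p.t)):
                raise ValueError("derived identities t = T * mu violated")

    def su_annotated_tree(self) -> PhyloTree:
        """The species tree with true SU branch lengths (the simulation truth)."""
        out = self.tree.copy()
        for node, onode in zip(self.tree.preorder(), out.preorder()):
            onode.length = None if node is self.tree.root else self.params[node].t
        return out


@dataclass
class SimConfig:
    """Gene-count, seed and rate-variation switches for a simulation run."""

    k: int = 1000
    seed: int = 0
    rate_multiplier_sigma: Optional[float] = None  # per-gene lognormal sigma; None = off
    heterotachy_sigma: Optional[float] = None  # per-gene-per-branch sigma; None = off
    individuals: Dict[str, int] = field(default_factory=dict)  # species -> #individuals

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


def make_quartet_model(
    T1: float,
    T2: float,
    mu1: float,
    mu2: float,
    mu3: float,
    terminals: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    shape: str = "unbalanced",
    terminal_cu: float = 1.0,
) -> SimSpeciesTree:
    """Build a 4-taxon model tree matching the quartet parameterization.

    Unbalanced shape ``(((A,B),C),D)``: the internal branch above the (A,B)
    ancestor has CU length ``T1`` and rate ``mu1``; the branch between the
    (A,B,C) ancestor and the root has CU length ``T2`` and rate ``mu2``;
    ``mu3`` is the rate above the root.  Balanced shape ``((A,B),(C,D))``:
    ``T1, mu1`` describe the branch above the (A,B) ancestor and ``T2, mu2``
    the branch above the (C,D) ancestor.  ``terminals`` are SU lengths
    ``(tA, tB, tC, tD)``.  Population sizes are set to one, so ``tau = T``
    and ``nu = mu``.
    """
    if shape not in ("unbalanced", "balanced"):
        raise ValueError(f"unknown shape {shape!r}")
    if len(terminals) != 4:
        raise ValueError("terminals must be (tA, tB, tC, tD)")
    if T1 < 0 or T2 < 0 or min(mu1, mu2, mu3) <= 0:
        raise ValueError("CU lengths must be >= 0 and rates > 0")
    tA, tB, tC, tD = terminals

    def leaf(label: str, t_su: float) -> Tuple[Node, BranchParams]:
        node = Node(label)
        # with one sampled individual the terminal CU length is inert; pick
        # terminal_cu and set nu so the SU length comes out exactly t_su
        rate = t_su / terminal_cu if t_su > 0 else 1e-12
        return node, BranchParams(tau=terminal_cu, N=1.0, nu=rate)

    params: Dict[Node, BranchParams] = {}
    a, pa = leaf("A", tA)
    b, pb = leaf("B", tB)
    c, pc = leaf("C", tC)
    d, pd = leaf("D", tD)
    ab = Node()
    ab.add_child(a)
    ab.add_child(b)
    root = Node()
    if shape == "unbalanced":
        abc = Node()
        abc.add_child(ab)
        abc.add_child(c)
        root.add_child(abc)
        root.add_child(d)
        params[ab] = BranchParams(tau=T1, N=1.0, nu=mu1)
        params[abc] = BranchParams(tau=T2, N=1.0, nu=mu2)
        params[d] = pd
    else:
        cd = Node()
        cd.add_child(c)
        cd.add_child(d)
        root.add_child(ab)
        root.add_child(cd)
        params[ab] = BranchParams(tau=T1, N=1.0, nu=mu1)
        params[cd] = BranchParams(tau=T2, N=1.0, nu=mu2)
        params[d] = pd
    params[a], params[b], params[c] = pa, pb, pc
    params[root] = BranchParams(tau=None, N=1.0, nu=mu3)
    return SimSpeciesTree(PhyloTree(root, rooted=True), params)


def random_model_tree(
    n_species: int,
    seed: int = 0,
    T_range: Tuple[float, float] = (0.3, 1.5),
    mu_range: Tuple[float, float] = (1.0, 1.0),
    labels: Optional[Sequence[str]] = None,
) -> SimSpeciesTree:
    """Random rooted binary model tree (uniform random joins).

    Internal and terminal branches draw CU lengths uniformly from ``T_range``
    and CU rates from ``mu_range``; with the default ``mu_range`` the tree is
    clock-like in CU but the SU lengths still vary with the drawn durations.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"s{i+1}" for i in range(n_species)]
    nodes = [Node(lab) for lab in labels]
    params: Dict[Node, BranchParams] = {}

    def draw() -> BranchParams:
        T = float(rng.uniform(*T_range))
        mu = float(rng.uniform(*mu_range))
        return BranchParams(tau=T, N=1.0, nu=mu)

    for node in nodes:
        params[node] = draw()
    pool = list(nodes)
    while len(pool) > 2:
        i = int(rng.integers(len(pool)))
        a = pool.pop(i)
        j = int(rng.integers(len(pool)))
        b = pool.pop(j)
        join = Node()
        join.add_child(a)
        join.add_child(b)
        params[join] = draw()
        pool.append(join)
    root = Node()
    root.add_child(pool[0])
    root.add_child(pool[1])
    params[root] = BranchParams(tau=None, N=1.0, nu=float(rng.uniform(*mu_range)))
    return SimSpeciesTree(PhyloTree(root, rooted=True), params)


# ---------------------------------------------------------------------------
# gene-tree perturbations (fixture utilities)
# ---------------------------------------------------------------------------


def drop_leaves(gene: PhyloTree, labels) -> PhyloTree:
    """Copy of ``gene`` without the given leaves; degree-2 nodes are merged
    (their edge lengths summed) so the result is a valid unrooted gene tree."""
    drop = set(labels)
    tree = gene.copy()

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return None if node.label in drop else node
        kept = []
        for child in node.children:
            sub = prune(child)
            if sub is not None:
                kept.append(sub)
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            if node.length is not None and only.length is not None:
                only.length += node.length
            elif node.length is None:
                only.length = only.length  # root child keeps its own length
            only.parent = None
            return only
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = prune(tree.root)
    if new_root is None:
        raise ValueError("cannot drop all leaves")
    new_root.parent = None
    if new_root.is_leaf:
        raise ValueError("fewer than two leaves left")
    new_root.length = None
    return PhyloTree(new_root, rooted=len(new_root.children) == 2)


def collapse_random_edges(
    gene: PhyloTree, fraction: float, rng: np.random.Generator
) -> PhyloTree:
    """Copy of ``gene`` with a random ``fraction`` of internal edges collapsed
    into polytomies (their children reattached to the parent)."""
    tree = gene.copy()
    internal = [
        n
        for n in tree.preorder()
        if not n.is_leaf and n.parent is not None
    ]
    for node in internal:
        if rng.random() < fraction and node.parent is not None:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children.pop(idx)
            for c in node.children:
                c.parent = parent
            parent.children[idx:idx] = node.children
    return tree


# ---------------------------------------------------------------------------
# the coalescent sampler
# ---------------------------------------------------------------------------


def _coalesce_in_branch(
    lineages: List[Tuple[Node, float]],
    T_cu: Optional[float],
    mu: float,
    rng: np.random.Generator,
) -> List[Tuple[Node, float]]:
    """Run the coalescent among ``lineages`` for CU duration ``T_cu`` (None =
    unbounded) at substitution rate ``mu``; returns surviving lineages.

    Each lineage is (gene node, SU length accrued so far on its open edge).
    """
    elapsed = 0.0
    while len(lineages) > 1:
        j = len(lineages)
        wait = rng.exponential(2.0 / (j * (j - 1)))
        if T_cu is not None and elapsed + wait > T_cu:
            break
        elapsed += wait
        dsu = wait * mu
        i1 = int(rng.integers(j))
        i2 = int(rng.integers(j - 1))
        if i2 >= i1:
            i2 += 1
        parent = Node()
        for idx in (i1, i2):
            child, pending = lineages[idx]
            child.length = pending + dsu
            parent.add_child(child)
        lineages = [
            (n, pending + dsu) for t, (n, pending) in enumerate(lineages) if t not in (i1, i2)
        ]
        lineages.append((parent, 0.0))
    if T_cu is not None and lineages:
        remaining = (T_cu - elapsed) * mu
        lineages = [(n, pending + remaining) for n, pending in lineages]
    return lineages


def simulate_gene_trees(sp: SimSpeciesTree, cfg: SimConfig) -> List[PhyloTree]:
    """Draw ``cfg.k`` gene trees with SU branch lengths; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    order = list(sp.tree.postorder())
    genes: List[PhyloTree] = []
    for _ in range(cfg.k):
        if cfg.heterotachy_sigma:
            s = cfg.heterotachy_sigma
            branch_factor = {
                node: math.exp(rng.normal(-0.5 * s * s, s)) for node in order
            }
        else:
            branch_factor = None
        surviving: Dict[Node, List[Tuple[Node, float]]] = {}
        for node in order:
            p = sp.params[node]
            mu = p.mu if branch_factor is None else p.mu * branch_factor[node]
            if node.is_leaf:
                n_ind = cfg.individuals.get(node.label, 1)
                if n_ind == 1:
                    lineages = [(Node(node.label), 0.0)]
                else:
                    lineages = [
                        (Node(f"{node.label}_{i+1}"), 0.0) for i in range(n_ind)
                    ]
            else:
                lineages = []
                for child in node.children:
                    lineages.extend(surviving.pop(child))
            T_cu = None if node is sp.tree.root else p.T
            surviving[node] = _coalesce_in_branch(lineages, T_cu, mu, rng)
        (gene_root, _pending), = surviving[sp.tree.root]
        gene_root.length = None
        if cfg.rate_multiplier_sigma:
            s = cfg.rate_multiplier_sigma
            r = math.exp(rng.normal(-0.5 * s * s, s))
            stack = [gene_root]
            while stack:
                n = stack.pop()
                if n.length is not None:
                    n.length *= r
                stack.extend(n.children)
        genes.append(PhyloTree(gene_root, rooted=True))
    return genes
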