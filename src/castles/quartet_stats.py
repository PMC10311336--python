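"""Per-branch quartet branch-length aggregation.

Every internal branch of a rooted binary species tree splits the taxa into
four groups (the quadripartition): the two child subtrees below the branch
(A and B), the sibling subtree (C), and everything beyond the parent (D).
Each choice of one leaf per group induces a 4-leaf subtree in every gene
tree; its unrooted topology either matches the species tree (AB|CD) or not,
and its five branches (four pendants + internal) have SU lengths readable
from the gene tree.  This module computes, for every species-tree branch,
the mean of each of the five branch lengths over all (quartet x gene)
observations, split into matching and non-matching buckets - the raw
material for the branch-length estimators.

Two interchangeable engines are provided: an explicit brute force over all
quartets (the reference), and a junction-anchored dynamic program that runs
in O(m) per gene and branch - O(n^2 k) overall - by anchoring every resolved
quartet at the unique gene-tree node where the paths of its "near" pair
diverge, and aggregating pair counts and path-length sums over subtree and
rerooted "up" components.  Both weight every resolved (quartet x gene)
observation equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .trees_io import (
    PhyloTree,
    TaxonMap,
    ValidatedBundle,
    ValidationError,
    validate_inputs,
)

__all__ = [
    "ROLES",
    "Quadripartition",
    "RoleMeans",
    "quadripartitions",
    "induced_quartet_obs",
    "brute_force_role_means",
    "fast_role_means",
    "role_means_table",
]

ROLES = ("A", "B", "C", "D", "I")

# pairings of the four parts: (near1, near2, far1, far2); the first is the
# species-tree (matching) split, the others are the two discordant splits
_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
# role index (into ROLES) of near1/near2/far1/far2 for each pairing
_ROLE_OF = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass(frozen=True)
class Quadripartition:
    """The four leaf-label groups probing one species-tree branch.

    ``clade`` is the label set below the focal branch (its stable key across
    tree copies).  ``kind`` is ``"internal"`` for an ordinary internal branch
    and ``"balanced_root"`` for the root path when both root children are
    internal (parts C and D are then the two subtrees of the sibling root
    child).
    """

    clade: FrozenSet[str]
    parts: Tuple[FrozenSet[str], FrozenSet[str], FrozenSet[str], FrozenSet[str]]
    kind: str = "internal"


@dataclass
class RoleMeans:
    """Counts and length sums per bucket for one species-tree branch."""

    n_match: float = 0.0
    n_nonmatch: float = 0.0
    n_unresolved: float = 0.0
    n_missing: float = 0.0
    match_sums: List[float] = field(default_factory=lambda: [0.0] * 5)
    nonmatch_sums: List[float] = field(default_factory=lambda: [0.0] * 5)

    def mean_match(self, role: str) -> Optional[float]:
        if self.n_match <= 0:
            return None
        return self.match_sums[ROLES.index(role)] / self.n_match

    def mean_nonmatch(self, role: str) -> Optional[float]:
        if self.n_nonmatch <= 0:
            return None
        return self.nonmatch_sums[ROLES.index(role)] / self.n_nonmatch

    def diff(self, role: str) -> Optional[float]:
        m, n = self.mean_match(role), self.mean_nonmatch(role)
        return None if m is None or n is None else m - n

    @property
    def delta(self) -> Optional[float]:
        """Normalized internal difference driving the CU-length estimate."""
        n = self.mean_nonmatch("I")
        if n is None or n <= 0:
            return None
        return self.diff("I") / n


# ---------------------------------------------------------------------------
# quadripartitions
# ---------------------------------------------------------------------------


def quadripartitions(species: PhyloTree) -> List[Quadripartition]:
    """One quadripartition per estimable internal branch (preorder order).

    A root child with an internal sibling yields the single balanced-root
    quadripartition (emitted for the first root child only); a root child
    with a leaf sibling yields none (the root sum is then estimated from the
    D role of the branches just below it).
    """
    leafset: Dict[object, FrozenSet[str]] = {}
    for node in species.postorder():
        if node.is_leaf:
            leafset[node] = frozenset([node.label])
        else:
            s: FrozenSet[str] = frozenset()
            for c in node.children:
                s |= leafset[c]
            leafset[node] = s
    all_labels = leafset[species.root]
    quads: List[Quadripartition] = []
    for node in species.preorder():
        if node.is_leaf or node is species.root:
            continue
        parent = node.parent
        sibling = next(c for c in parent.children if c is not node)
        if parent is species.root:
            if sibling.is_leaf or node is not parent.children[0]:
                continue
            a, b = (leafset[c] for c in node.children)
            c_, d_ = (leafset[c] for c in sibling.children)
            quads.append(Quadripartition(leafset[node], (a, b, c_, d_), "balanced_root"))
        else:
            a, b = (leafset[c] for c in node.children)
            v = leafset[sibling]
            p = all_labels - a - b - v
            quads.append(Quadripartition(leafset[node], (a, b, v, p), "internal"))
    return quads


# ---------------------------------------------------------------------------
# per-gene index
# ---------------------------------------------------------------------------


class _GeneIndex:
    """Flat postorder arrays for one gene tree (root last)."""

    __slots__ = (
        "n",
        "parent",
        "edge_len",
        "children",
        "is_leaf",
        "species",
        "topo_depth",
        "su_depth",
        "leaf_by_species",
        "species_present",
    )

    def __init__(self, gene: PhyloTree, taxon_map: TaxonMap):
        nodes = list(gene.postorder())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        self.n = len(nodes)
        self.parent = [-1] * self.n
        self.edge_len = [0.0] * self.n
        self.children: List[List[int]] = [[] for _ in range(self.n)]
        self.is_leaf = [nd.is_leaf for nd in nodes]
        self.species: List[Optional[str]] = [None] * self.n
        self.leaf_by_species: Dict[str, List[int]] = {}
        for i, nd in enumerate(nodes):
            if nd.parent is not None:
                p = idx[id(nd.parent)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_len[i] = nd.length if nd.length is not None else 0.0
            if nd.is_leaf:
                sp = taxon_map.species_of(nd.label)
                self.species[i] = sp
                self.leaf_by_species.setdefault(sp, []).append(i)
        self.species_present = set(self.leaf_by_species)
        self.topo_depth = [0] * self.n
        self.su_depth = [0.0] * self.n
        for i in reversed(range(self.n)):  # preorder
            p = self.parent[i]
            if p >= 0:
                self.topo_depth[i] = self.topo_depth[p] + 1
                self.su_depth[i] = self.su_depth[p] + self.edge_len[i]

    def lca(self, i: int, j: int) -> int:
        while self.topo_depth[i] > self.topo_depth[j]:
            i = self.parent[i]
        while self.topo_depth[j] > self.topo_depth[i]:
            j = self.parent[j]
        while i != j:
            i, j = self.parent[i], self.parent[j]
        return i

    def dist(self, i: int, j: int) -> Tuple[float, int]:
        a = self.lca(i, j)
        return (
            self.su_depth[i] + self.su_depth[j] - 2.0 * self.su_depth[a],
            self.topo_depth[i] + self.topo_depth[j] - 2 * self.topo_depth[a],
        )


# ---------------------------------------------------------------------------
# single-quartet observation (reference path computation)
# ---------------------------------------------------------------------------


def _classify(gi: _GeneIndex, leaves: Sequence[int]):
    """Topology class (0=AB|CD, 1=AC|BD, 2=AD|BC, None=unresolved) and the
    five SU lengths (pendant A..D, internal) for one individual quartet."""
    su = {}
    td = {}
    for x in range(4):
        for y in range(x + 1, 4):
            su[(x, y)] = su[(y, x)] = 0.0
            td[(x, y)] = td[(y, x)] = 0
            s, t = gi.dist(leaves[x], leaves[y])
            su[(x, y)] = su[(y, x)] = s
            td[(x, y)] = td[(y, x)] = t
    sums = []
    for (p1, p2) in _PAIRINGS:
        sums.append(td[p1] + td[p2])
    best = min(sums)
    if sums.count(best) > 1:
        return None, None
    cls = sums.index(best)
    (x1, x2), (y1, y2) = _PAIRINGS[cls]
    p_x1 = (su[(x1, x2)] + su[(x1, y1)] - su[(x2, y1)]) / 2.0
    p_x2 = (su[(x1, x2)] + su[(x2, y1)] - su[(x1, y1)]) / 2.0
    p_y1 = (su[(y1, y2)] + su[(y1, x1)] - su[(y2, x1)]) / 2.0
    p_y2 = (su[(y1, y2)] + su[(y2, x1)] - su[(y1, x1)]) / 2.0
    internal = (su[(x1, y1)] + su[(x2, y2)] - su[(x1, x2)] - su[(y1, y2)]) / 2.0
    pendants = [0.0] * 4
    for part, val in zip((x1, x2, y1, y2), (p_x1, p_x2, p_y1, p_y2)):
        pendants[part] = val
    return cls, (pendants[0], pendants[1], pendants[2], pendants[3], internal)


def induced_quartet_obs(
    gene: PhyloTree,
    a: str,
    b: str,
    c: str,
    d: str,
    taxon_map: Optional[TaxonMap] = None,
):
    """Observation for one species quartet (one individual per species).

    Returns ``None`` if any of the four species is absent from the gene tree;
    otherwise ``(topology, lengths)`` where ``topology`` is ``"ab|cd"``,
    ``"ac|bd"``, ``"ad|bc"`` or ``"unresolved"`` and ``lengths`` is the tuple
    (pendant a, pendant b, pendant c, pendant d, internal), ``None`` when
    unresolved.  With several individuals per species the first is used.
    """
    gi = _GeneIndex(gene, taxon_map or TaxonMap())
    try:
        leaves = [gi.leaf_by_species[s][0] for s in (a, b, c, d)]
    except KeyError:
        return None
    cls, lengths = _classify(gi, leaves)
    if cls is None:
        return "unresolved", None
    return ("ab|cd", "ac|bd", "ad|bc")[cls], lengths


# ---------------------------------------------------------------------------
# brute-force engine
# ---------------------------------------------------------------------------


def _accumulate(rm: RoleMeans, pairing: int, lengths, weight: float = 1.0) -> None:
    (r_n1, r_n2), (r_f1, r_f2) = _ROLE_OF[pairing]
    sums = rm.match_sums if pairing == 0 else rm.nonmatch_sums
    if pairing == 0:
        rm.n_match += weight
    else:
        rm.n_nonmatch += weight
    pa, pb, pc, pd, internal = lengths
    sums[0] += pa
    sums[1] += pb
    sums[2] += pc
    sums[3] += pd
    sums[4] += internal


def _brute_one(gi: _GeneIndex, quad: Quadripartition, rm: RoleMeans) -> None:
    part_leaves = []
    present_sp = []
    for part in quad.parts:
        leaves: List[int] = []
        np_sp = 0
        for sp in part:
            li = gi.leaf_by_species.get(sp)
            if li:
                leaves.extend(li)
                np_sp += 1
        part_leaves.append(leaves)
        present_sp.append(np_sp)
    sizes = [len(p) for p in quad.parts]
    total_sp_quartets = sizes[0] * sizes[1] * sizes[2] * sizes[3]
    present_sp_quartets = present_sp[0] * present_sp[1] * present_sp[2] * present_sp[3]
    rm.n_missing += total_sp_quartets - present_sp_quartets
    if not all(part_leaves):
        return
    for combo in product(*part_leaves):
        cls, lengths = _classify(gi, combo)
        if cls is None:
            rm.n_unresolved += 1
        else:
            _accumulate(rm, cls, lengths)


# ---------------------------------------------------------------------------
# fast engine: junction-anchored aggregation
# ---------------------------------------------------------------------------


def _fast_one(gi: _GeneIndex, quad: Quadripartition, rm: RoleMeans) -> None:
    n = gi.n
    part_of = [-1] * n
    sp_to_part: Dict[str, int] = {}
    for pi, part in enumerate(quad.parts):
        for sp in part:
            sp_to_part[sp] = pi
    for i in range(n):
        sp = gi.species[i]
        if sp is not None:
            part_of[i] = sp_to_part[sp]

    # subtree counts and distance sums per part (shared across pairings)
    cnt = [[0] * 4 for _ in range(n)]
    sdist = [[0.0] * 4 for _ in range(n)]
    for i in range(n):
        if gi.is_leaf[i]:
            cnt[i][part_of[i]] = 1
        else:
            ci_ = cnt[i]
            si_ = sdist[i]
            for c in gi.children[i]:
                lc = gi.edge_len[c]
                cc, sc_ = cnt[c], sdist[c]
                for p in range(4):
                    ci_[p] += cc[p]
                    si_[p] += sc_[p] + cc[p] * lc
    root = n - 1
    # up (rerooted) counts / distance sums
    ucnt = [[0] * 4 for _ in range(n)]
    usdist = [[0.0] * 4 for _ in range(n)]
    for i in reversed(range(n - 1)):  # preorder, excluding root
        p = gi.parent[i]
        li = gi.edge_len[i]
        for q in range(4):
            ucnt[i][q] = ucnt[p][q] + cnt[p][q] - cnt[i][q]
            usdist[i][q] = (
                usdist[p][q]
                + (sdist[p][q] - (sdist[i][q] + cnt[i][q] * li))
                + ucnt[i][q] * li
            )

    sp_counts = [sum(1 for sp in part if sp in gi.species_present) for part in quad.parts]
    sizes = [len(p) for p in quad.parts]
    rm.n_missing += (
        sizes[0] * sizes[1] * sizes[2] * sizes[3]
        - sp_counts[0] * sp_counts[1] * sp_counts[2] * sp_counts[3]
    )
    present = cnt[root][0] * cnt[root][1] * cnt[root][2] * cnt[root][3]
    if present == 0:
        return
    resolved = 0.0

    for pairing, ((nr1, nr2), (f1, f2)) in enumerate(_PAIRINGS):
        # --- bottom-up far-pair aggregates -------------------------------
        pr = [0.0] * n  # pairs (c in f1, d in f2) within subtree
        sc = [0.0] * n  # sum over pairs of d(c, junction)
        sd = [0.0] * n  # sum over pairs of d(d, junction)
        sj = [0.0] * n  # sum over pairs of d(node, junction)
        for i in range(n):
            if gi.is_leaf[i]:
                continue
            ch = gi.children[i]
            t_pr = t_sc = t_sd = t_sj = 0.0
            C1 = C2 = 0.0
            S1 = S2 = 0.0
            diag_n = diag_s1 = diag_s2 = 0.0
            for c in ch:
                lc = gi.edge_len[c]
                n1 = cnt[c][f1]
                n2 = cnt[c][f2]
                sd1 = sdist[c][f1] + n1 * lc
                sd2 = sdist[c][f2] + n2 * lc
                t_pr += pr[c]
                t_sc += sc[c]
                t_sd += sd[c]
                t_sj += sj[c] + pr[c] * lc
                C1 += n1
                C2 += n2
                S1 += sd1
                S2 += sd2
                diag_n += n1 * n2
                diag_s1 += sd1 * n2
                diag_s2 += n1 * sd2
            pr[i] = t_pr + (C1 * C2 - diag_n)
            sc[i] = t_sc + (S1 * C2 - diag_s1)
            sd[i] = t_sd + (C1 * S2 - diag_s2)
            sj[i] = t_sj  # cross pairs have junction here: distance 0

        # --- top-down far-pair aggregates for the "up" component ---------
        upr = [0.0] * n
        usc = [0.0] * n
        usd = [0.0] * n
        usj = [0.0] * n
        # per-parent totals over children
        for i in reversed(range(n - 1)):
            p = gi.parent[i]
            li = gi.edge_len[i]
            # totals over p's children
            t_pr = t_sc = t_sd = t_sj = 0.0
            diag_n = diag_s1 = diag_s2 = 0.0
            n1_i = sd1_i = n2_i = sd2_i = 0.0
            for c in gi.children[p]:
                lc = gi.edge_len[c]
                n1 = cnt[c][f1]
                n2 = cnt[c][f2]
                sd1 = sdist[c][f1] + n1 * lc
                sd2 = sdist[c][f2] + n2 * lc
                t_pr += pr[c]
                t_sc += sc[c]
                t_sd += sd[c]
                t_sj += sj[c] + pr[c] * lc
                diag_n += n1 * n2
                diag_s1 += sd1 * n2
                diag_s2 += n1 * sd2
                if c == i:
                    n1_i, sd1_i, n2_i, sd2_i = n1, sd1, n2, sd2
            C1 = float(cnt[p][f1])
            C2 = float(cnt[p][f2])
            S1 = sdist[p][f1]
            S2 = sdist[p][f2]
            # (a) both within one sibling subtree
            pra = t_pr - pr[i]
            sca = t_sc - sc[i]
            sda = t_sd - sd[i]
            sja = t_sj - (sj[i] + pr[i] * li)
            # (b) crossing two different siblings (junction = p)
            X1 = C1 - n1_i
            X2 = C2 - n2_i
            SX1 = S1 - sd1_i
            SX2 = S2 - sd2_i
            cnt_b = X1 * X2 - (diag_n - n1_i * n2_i)
            sc_b = SX1 * X2 - (diag_s1 - sd1_i * n2_i)
            sd_b = X1 * SX2 - (diag_s2 - n1_i * sd2_i)
            # (c) one beyond p, one in a sibling (junction = p)
            cnt_c = ucnt[p][f1] * X2 + X1 * ucnt[p][f2]
            sc_c = usdist[p][f1] * X2 + SX1 * ucnt[p][f2]
            sd_c = ucnt[p][f1] * SX2 + X1 * usdist[p][f2]
            cnt_ii = pra + cnt_b + cnt_c
            upr[i] = upr[p] + cnt_ii
            usc[i] = usc[p] + sca + sc_b + sc_c
            usd[i] = usd[p] + sda + sd_b + sd_c
            usj[i] = usj[p] + upr[p] * li + sja + cnt_ii * li

        # --- anchor pass --------------------------------------------------
        N = PA = PB = PC = PD = INT = 0.0
        for v in range(n):
            if gi.is_leaf[v]:
                continue
            comp_n1: List[float] = []
            comp_n2: List[float] = []
            comp_s1: List[float] = []
            comp_s2: List[float] = []
            comp_np: List[float] = []
            comp_sc: List[float] = []
            comp_sd: List[float] = []
            comp_sj: List[float] = []
            for c in gi.children[v]:
                lc = gi.edge_len[c]
                comp_n1.append(cnt[c][nr1])
                comp_n2.append(cnt[c][nr2])
                comp_s1.append(sdist[c][nr1] + cnt[c][nr1] * lc)
                comp_s2.append(sdist[c][nr2] + cnt[c][nr2] * lc)
                comp_np.append(pr[c])
                comp_sc.append(sc[c])
                comp_sd.append(sd[c])
                comp_sj.append(sj[c] + pr[c] * lc)
            if v != root:
                comp_n1.append(ucnt[v][nr1])
                comp_n2.append(ucnt[v][nr2])
                comp_s1.append(usdist[v][nr1])
                comp_s2.append(usdist[v][nr2])
                comp_np.append(upr[v])
                comp_sc.append(usc[v])
                comp_sd.append(usd[v])
                comp_sj.append(usj[v])
            Tn1 = sum(comp_n1)
            Tn2 = sum(comp_n2)
            TS1 = sum(comp_s1)
            TS2 = sum(comp_s2)
            diag_nn = sum(a * b for a, b in zip(comp_n1, comp_n2))
            diag_sn = sum(a * b for a, b in zip(comp_s1, comp_n2))
            diag_ns = sum(a * b for a, b in zip(comp_n1, comp_s2))
            for l in range(len(comp_np)):
                if comp_np[l] == 0.0 and comp_sj[l] == 0.0:
                    continue
                n1l, n2l = comp_n1[l], comp_n2[l]
                s1l, s2l = comp_s1[l], comp_s2[l]
                cnt_near = (Tn1 - n1l) * (Tn2 - n2l) - (diag_nn - n1l * n2l)
                if cnt_near == 0.0:
                    continue
                sum1 = (TS1 - s1l) * (Tn2 - n2l) - (diag_sn - s1l * n2l)
                sum2 = (Tn1 - n1l) * (TS2 - s2l) - (diag_ns - n1l * s2l)
                N += cnt_near * comp_np[l]
                PA += sum1 * comp_np[l]
                PB += sum2 * comp_np[l]
                PC += cnt_near * comp_sc[l]
                PD += cnt_near * comp_sd[l]
                INT += cnt_near * comp_sj[l]

        resolved += N
        (r_n1, r_n2), (r_f1, r_f2) = _ROLE_OF[pairing]
        sums = rm.match_sums if pairing == 0 else rm.nonmatch_sums
        if pairing == 0:
            rm.n_match += N
        else:
            rm.n_nonmatch += N
        sums[r_n1] += PA
        sums[r_n2] += PB
        sums[r_f1] += PC
        sums[r_f2] += PD
        sums[4] += INT

    rm.n_unresolved += present - resolved


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------


def _role_means(
    species: PhyloTree,
    genes: Sequence[PhyloTree],
    taxon_map: Optional[TaxonMap],
    engine,
    bundle: Optional[ValidatedBundle] = None,
) -> Dict[FrozenSet[str], RoleMeans]:
    if bundle is None:
        bundle = validate_inputs(species, genes, taxon_map)
    quads = quadripartitions(bundle.species)
    out: Dict[FrozenSet[str], RoleMeans] = {q.clade: RoleMeans() for q in quads}
    for gene in bundle.usable_genes:
        gi = _GeneIndex(gene, bundle.taxon_map)
        for quad in quads:
            engine(gi, quad, out[quad.clade])
    return out


def brute_force_role_means(
    species: PhyloTree,
    genes: Sequence[PhyloTree],
    taxon_map: Optional[TaxonMap] = None,
    bundle: Optional[ValidatedBundle] = None,
) -> Dict[FrozenSet[str], RoleMeans]:
    """Reference engine: enumerate every quartet of every gene explicitly."""
    return _role_means(species, genes, taxon_map, _brute_one, bundle)


def fast_role_means(
    species: PhyloTree,
    genes: Sequence[PhyloTree],
    taxon_map: Optional[TaxonMap] = None,
    bundle: Optional[ValidatedBundle] = None,
) -> Dict[FrozenSet[str], RoleMeans]:
    """O(n^2 k) engine; output contract identical to the brute force."""
    return _role_means(species, genes, taxon_map, _fast_one, bundle)


def role_means_table(means: Dict[FrozenSet[str], RoleMeans]) -> str:
    """TSV debug dump: one row per (branch, role, bucket)."""
    lines = ["branch\trole\tbucket\tcount\tmean"]
    for clade in sorted(means, key=lambda s: (len(s), tuple(sorted(s)))):
        rm = means[clade]
        name = "|".join(sorted(clade))
        for role in ROLES:
            for bucket, mean, cnt_ in (
                ("match", rm.mean_match(role), rm.n_match),
                ("nonmatch", rm.mean_nonmatch(role), rm.n_nonmatch),
            ):
                val = "NA" if mean is None else f"{mean:.10g}"
                lines.append(f"{name}\t{role}\t{bucket}\t{cnt_:g}\t{val}")
    return "\n".join(lines) + "\n"
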