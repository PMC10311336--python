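"""Species-tree branch-length assignment from per-branch quartet role means.

The driver walks the internal branches of the rooted species tree and turns
each branch's matching / non-matching quartet length means into SU lengths:

* an ordinary internal branch gets the internal-branch estimator (local
  clock: the non-matching internal mean estimates the branch rate, the
  normalized matching/non-matching difference gives the CU length);
* a leaf sibling of the focal clade gets the middle-terminal estimator;
* leaf children of the focal clade get the cherry-terminal estimator;
* the two root-incident branches are identifiable only through their sum,
  estimated either from the root-adjacent (D) role of the branch(es) just
  below the root - when one root child is a leaf - or from the balanced-root
  quadripartition when both root children are internal; the sum is then
  split between the two root edges according to ``root_split``.

A branch with no resolved quartet observations at all is an error (no
signal).  A branch whose non-matching bucket is empty (no observed
discordance) falls back to the matching-bucket mean for the corresponding
role, which is exact in the degenerate case where all gene trees equal the
species tree; such branches are logged as low-confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

from . import estimators as est
from .quartet_stats import (
    Quadripartition,
    RoleMeans,
    brute_force_role_means,
    fast_role_means,
    quadripartitions,
)
from .trees_io import (
    Node,
    PhyloTree,
    TaxonMap,
    ValidatedBundle,
    ValidationError,
    validate_inputs,
)

logger = logging.getLogger("castles")

__all__ = ["AnnotatedSpeciesTree", "InsufficientSignalError", "run_castles"]


class InsufficientSignalError(ValidationError):
    """A species-tree branch had zero resolved quartet observations."""


@dataclass
class AnnotatedSpeciesTree:
    """Input species topology with estimated SU branch lengths.

    ``root_sum`` is the inferred combined SU length of the two root-incident
    branches (only their sum is identifiable); ``root_split`` records how it
    was divided between them in ``tree``.  ``diagnostics`` maps each branch
    (keyed by the label set below it) to the estimation path taken.
    """

    tree: PhyloTree
    root_sum: float
    root_split: str
    diagnostics: Dict[FrozenSet[str], Dict[str, object]] = field(default_factory=dict)

    def newick(self, precision: int = 10) -> str:
        from .trees_io import write_newick

        return write_newick(self.tree, precision=precision)


def _leafset(node: Node) -> FrozenSet[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return frozenset(out)


def run_castles(
    species: PhyloTree,
    genes: Sequence[PhyloTree],
    taxon_map: Optional[TaxonMap] = None,
    *,
    engine: str = "fast",
    min_len: float = est.DEFAULT_FLOOR,
    root_split: str = "even",
    solver: str = "exact",
    bundle: Optional[ValidatedBundle] = None,
) -> AnnotatedSpeciesTree:
    """Annotate every branch of ``species`` with an SU length.

    ``engine`` selects the quartet aggregation ("fast" or "brute");
    ``min_len`` is the floor applied to non-positive estimates;
    ``root_split`` divides the root sum ("even", "left" or "right");
    ``solver`` picks the CU-length inversion ("exact" or "taylor").
    """
    if root_split not in ("even", "left", "right"):
        raise ValueError(f"unknown root_split {root_split!r}")
    if bundle is None:
        bundle = validate_inputs(species, genes, taxon_map)
    tree = bundle.species
    quads = quadripartitions(tree)
    means_fn = fast_role_means if engine == "fast" else brute_force_role_means
    means = means_fn(None, None, None, bundle=bundle)

    clade_to_node: Dict[FrozenSet[str], Node] = {}
    for node in tree.postorder():
        clade_to_node[_leafset(node)] = node
    quad_by_clade: Dict[FrozenSet[str], Quadripartition] = {q.clade: q for q in quads}

    diagnostics: Dict[FrozenSet[str], Dict[str, object]] = {}
    assigned: Dict[int, float] = {}  # id(node) -> SU length

    no_signal = [
        q.clade
        for q in quads
        if means[q.clade].n_match + means[q.clade].n_nonmatch == 0
    ]
    if no_signal:
        names = ["{" + ",".join(sorted(c)) + "}" for c in no_signal]
        raise InsufficientSignalError(
            "no resolved quartet observations for branch(es) above " + ", ".join(names)
        )

    def set_len(node: Node, value: float, clade: FrozenSet[str], **diag) -> None:
        assigned[id(node)] = max(value, min_len)
        diagnostics.setdefault(clade, {}).update(diag)

    root_sum_candidates: List[float] = []
    # internal branch estimates per focal clade (T1_hat and mu1_hat for reuse
    # by the terminal and root estimators; None marks the zero-discordance
    # fallback path)
    internal_fit: Dict[FrozenSet[str], Dict[str, Optional[float]]] = {}

    for quad in quads:
        rm = means[quad.clade]
        u = clade_to_node[quad.clade]
        if rm.n_nonmatch == 0 or rm.mean_nonmatch("I") <= 0:
            internal_fit[quad.clade] = {"T1": None, "mu1": None}
            su = rm.mean_match("I")
            logger.info(
                "branch above {%s}: no discordant quartets; using matching means "
                "(low confidence)",
                ",".join(sorted(quad.clade)),
            )
            fallback = True
        else:
            li_nm = rm.mean_nonmatch("I")
            delta = rm.delta
            T1 = est.invert_delta(delta, solver) if delta is not None and delta > 0 else 0.0
            internal_fit[quad.clade] = {"T1": T1, "mu1": li_nm}
            su = est.estimate_internal_su(li_nm, rm.diff("I"), floor=min_len,
                                          solver=solver)
            fallback = False

        if quad.kind == "balanced_root":
            root_sum_candidates.append(su if su is not None else min_len)
            diagnostics.setdefault(quad.clade, {}).update(
                method="balanced_root", fallback=fallback, delta=rm.delta
            )
        else:
            set_len(u, su, quad.clade, method="internal", fallback=fallback,
                    delta=rm.delta)

    # second pass: terminals and root-sum candidates that need the internal
    # fits.  Processed children-before-parents so that a leaf reachable both
    # as a sibling (middle-terminal role, at the deeper branch) and as a
    # cherry child (at its parent) takes the deeper assignment; later
    # passes skip already-assigned leaves.
    for quad in reversed(quads):
        rm = means[quad.clade]
        u = clade_to_node[quad.clade]
        fit = internal_fit[quad.clade]
        T1, mu1 = fit["T1"], fit["mu1"]
        fallback = T1 is None

        def terminal(role: str, kind: str) -> float:
            if fallback:
                return rm.mean_match(role)
            if kind == "cherry":
                return est.estimate_terminal_cherry(
                    rm.mean_nonmatch(role), rm.diff(role), mu1, T1, floor=min_len
                )
            return est.estimate_terminal_sibling(
                rm.mean_nonmatch(role), rm.diff(role), T1, floor=min_len
            )

        if quad.kind == "balanced_root":
            # terminal children of both root children, via the balanced
            # machinery: the estimated root-path CU length T1 here is the
            # total S; each pendant's own difference locates its side's share
            v = next(c for c in tree.root.children if c is not u)
            for node, role in zip(list(u.children) + list(v.children), "ABCD"):
                if node.is_leaf and id(node) not in assigned:
                    val = (
                        rm.mean_match(role)
                        if fallback
                        else est.estimate_terminal_balanced(
                            rm.mean_nonmatch(role), rm.diff(role), mu1, T1,
                            floor=min_len,
                        )
                    )
                    set_len(node, val, frozenset([node.label]),
                            method="balanced_root_cherry", fallback=fallback)
            continue

        parent = u.parent
        sibling = next(c for c in parent.children if c is not u)
        if sibling.is_leaf and id(sibling) not in assigned:
            set_len(sibling, terminal("C", "sibling"), frozenset([sibling.label]),
                    method="sibling", fallback=fallback)
        for child, role in zip(u.children, ("A", "B")):
            if child.is_leaf and id(child) not in assigned:
                set_len(child, terminal(role, "cherry"), frozenset([child.label]),
                        method="cherry", fallback=fallback)

        # if the grandparent is the root and the root's other child is a leaf,
        # this branch's D role sees exactly the two root-incident branches
        gp = parent.parent
        if gp is tree.root:
            aunt = next(c for c in gp.children if c is not parent)
            if aunt.is_leaf:
                if fallback:
                    root_sum_candidates.append(rm.mean_match("D"))
                else:
                    root_sum_candidates.append(
                        est.estimate_root_unbalanced(
                            rm.mean_nonmatch("D"), rm.diff("D"), T1, floor=min_len
                        )
                    )

    if not root_sum_candidates:
        raise InsufficientSignalError("could not form a root-sum estimate")
    root_sum = max(sum(root_sum_candidates) / len(root_sum_candidates), min_len)
    left, right = tree.root.children
    if root_split == "even":
        half = max(root_sum / 2.0, min_len)
        assigned[id(left)] = half
        assigned[id(right)] = half
    elif root_split == "left":
        assigned[id(left)] = max(root_sum - min_len, min_len)
        assigned[id(right)] = min_len
    else:
        assigned[id(left)] = min_len
        assigned[id(right)] = max(root_sum - min_len, min_len)
    diagnostics[frozenset(tree.leaf_labels())] = {
        "method": "root_sum",
        "root_sum": root_sum,
        "candidates": len(root_sum_candidates),
    }

    out = tree.copy()
    for node, onode in zip(tree.preorder(), out.preorder()):
        if node is tree.root:
            onode.length = None
            continue
        try:
            onode.length = assigned[id(node)]
        except KeyError:  # pragma: no cover - coverage guarantee
            raise AssertionError(
                f"branch above {sorted(_leafset(node))} was never assigned"
            )
    return AnnotatedSpeciesTree(
        PhyloTree(out.root, rooted=True), root_sum, root_split, diagnostics
    )
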