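"""Evaluation statistics: branch-length error summaries and ILS quantification.

Branch-length comparison assumes the two trees share one topology; branches
correspond by the leaf-label set below them, and the two root-incident
branches are compared as their sum, since only the sum is identifiable from
gene trees.  Non-positive lengths are replaced by a small floor before the
log error, mirroring common practice for downstream usability.

The discordance level of a gene-tree set (the "average distance", AD) is the
mean normalized Robinson-Foulds distance between the species tree and each
gene tree, computed on their shared taxa and normalized by the total number
of internal edges of the two (unrooted) trees, so a hard polytomy can never
be penalized as a full conflict.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt
from typing import Dict, FrozenSet, Optional, Sequence

import dendropy
from dendropy.calculate import treecompare

from .trees_io import PhyloTree, TreeError, write_newick

__all__ = ["ErrorSummary", "branch_length_errors", "average_discordance", "summary_table"]

_FLOOR = 1e-6


@dataclass(frozen=True)
class ErrorSummary:
    """Error metrics between two length-annotated copies of one topology."""

    mae: float
    bias: float
    rmse: float
    male: float
    n_branches: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "mae": self.mae,
            "bias": self.bias,
            "rmse": self.rmse,
            "male": self.male,
            "n_branches": self.n_branches,
        }


def _branch_lengths(tree: PhyloTree) -> Dict[FrozenSet[str], float]:
    """Map each comparable branch to its SU length.

    Keys are the label sets below each non-root edge; the two root-incident
    edges collapse into a single record keyed by the full leaf set, holding
    their summed length.
    """
    out: Dict[FrozenSet[str], float] = {}
    leafset: Dict[int, FrozenSet[str]] = {}
    root_sum = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            leafset[id(node)] = frozenset([node.label])
        else:
            s: FrozenSet[str] = frozenset()
            for c in node.children:
                s |= leafset[id(c)]
            leafset[id(node)] = s
        if node is tree.root:
            continue
        if node.length is None:
            raise TreeError(
                f"unannotated branch above {sorted(leafset[id(node)])[:3]}"
            )
        if node.parent is tree.root:
            root_sum += node.length
        else:
            out[leafset[id(node)]] = node.length
    out[leafset[id(tree.root)]] = root_sum
    return out


def branch_length_errors(
    truth: PhyloTree, estimate: PhyloTree, floor: float = _FLOOR
) -> ErrorSummary:
    """MAE, signed bias, RMSE and mean absolute log error between two
    annotations of the same rooted topology."""
    bt = _branch_lengths(truth)
    be = _branch_lengths(estimate)
    if set(bt) != set(be):
        only_t = [sorted(c)[:3] for c in list(set(bt) - set(be))[:3]]
        only_e = [sorted(c)[:3] for c in list(set(be) - set(bt))[:3]]
        raise TreeError(
            f"topologies differ: clades only in truth {only_t}, only in estimate {only_e}"
        )
    errs = []
    logs = []
    for clade in bt:
        t, e = bt[clade], be[clade]
        errs.append(e - t)
        logs.append(abs(log(max(e, floor) / max(t, floor))))
    n = len(errs)
    mae = sum(abs(x) for x in errs) / n
    bias = sum(errs) / n
    rmse = sqrt(sum(x * x for x in errs) / n)
    male = sum(logs) / n
    return ErrorSummary(mae, bias, rmse, male, n)


# ---------------------------------------------------------------------------
# discordance
# ---------------------------------------------------------------------------


def _normalized_rf(species_newick: str, gene: PhyloTree) -> Optional[float]:
    gene_labels = set(l.label for l in gene.leaves())
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=species_newick, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    t2 = dendropy.Tree.get(
        data=write_newick(gene, require_lengths=False), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    sp_labels = {x.taxon.label for x in t1.leaf_node_iter()}
    shared = sp_labels & gene_labels
    if len(shared) < 4:
        return None
    t1.retain_taxa_with_labels(shared)
    t2.retain_taxa_with_labels(shared)
    for t in (t1, t2):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    fp, fn = treecompare.false_positives_and_negatives(t1, t2)
    denom = 0
    for t in (t1, t2):
        denom += sum(
            1 for nd in t.preorder_internal_node_iter() if nd is not t.seed_node
        )
    if denom == 0:
        return 0.0
    return (fp + fn) / denom


def average_discordance(species: PhyloTree, genes: Sequence[PhyloTree]) -> float:
    """Mean normalized RF distance between the species tree and the gene trees."""
    sp_newick = write_newick(species, require_lengths=False)
    vals = []
    for gene in genes:
        v = _normalized_rf(sp_newick, gene)
        if v is not None:
            vals.append(v)
    if not vals:
        raise TreeError("no gene tree shares >= 4 taxa with the species tree")
    return sum(vals) / len(vals)


def summary_table(rows: Sequence[Dict[str, float]]) -> str:
    """TSV report, one row per replicate (MAE, bias, RMSE, MALE, AD...)."""
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(f"{row[c]:.10g}" if isinstance(row[c], float) else str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"
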