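import math

import numpy as np
import pytest

import dendropy

from castles.msc_sim import SimConfig, make_quartet_model, simulate_gene_trees
from castles.quartet_stats import (
    ROLES,
    brute_force_role_means,
    fast_role_means,
    induced_quartet_obs,
    quadripartitions,
    role_means_table,
)
from castles.trees_io import parse_newick


def _parts(quad):
    return tuple(set(p) for p in quad.parts)


class TestQuadripartitions:
    def test_caterpillar_quartet(self):
        quads = quadripartitions(parse_newick("(((a,b),c),d);"))
        assert len(quads) == 1
        assert quads[0].kind == "internal"
        assert _parts(quads[0]) == ({"a"}, {"b"}, {"c"}, {"d"})

    def test_balanced_quartet_merges_far_side_via_root(self):
        quads = quadripartitions(parse_newick("((a,b),(c,d));"))
        assert len(quads) == 1
        assert quads[0].kind == "balanced_root"
        assert _parts(quads[0]) == ({"a"}, {"b"}, {"c"}, {"d"})

    def test_six_leaf_caterpillar_by_hand(self):
        sp = parse_newick("(((((a,b),c),d),e),f);")
        quads = {frozenset(q.clade): _parts(q) for q in quadripartitions(sp)}
        assert quads[frozenset("ab")] == ({"a"}, {"b"}, {"c"}, {"d", "e", "f"})
        assert quads[frozenset("abc")] == ({"a", "b"}, {"c"}, {"d"}, {"e", "f"})
        assert quads[frozenset("abcd")] == ({"a", "b", "c"}, {"d"}, {"e"}, {"f"})
        # the root child {abcde} has a leaf sibling: no quadripartition
        assert frozenset("abcde") not in quads
        assert len(quads) == 3

    def test_balanced_root_emitted_once(self):
        sp = parse_newick("(((a,b),c),((d,e),f));")
        quads = quadripartitions(sp)
        bal = [q for q in quads if q.kind == "balanced_root"]
        assert len(bal) == 1
        assert _parts(bal[0]) == ({"a", "b"}, {"c"}, {"d", "e"}, {"f"})

    def test_parts_partition_all_leaves(self):
        from castles.msc_sim import random_model_tree

        sp = random_model_tree(9, seed=2).tree
        for q in quadripartitions(sp):
            union = set().union(*q.parts)
            assert union == set(sp.leaf_labels())
            assert sum(len(p) for p in q.parts) == len(union)


class TestInducedQuartetObs:
    def test_gene_is_its_own_quartet(self):
        g = parse_newick("((a:1,b:2):3,(c:4,d:5):0);")
        topo, lengths = induced_quartet_obs(g, "a", "b", "c", "d")
        assert topo == "ab|cd"
        assert lengths == pytest.approx((1, 2, 4, 5, 3))

    def test_discordant_gene(self):
        g = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        topo, lengths = induced_quartet_obs(g, "a", "b", "c", "d")
        assert topo == "ac|bd"
        assert lengths[4] == pytest.approx(2.0)  # both root-incident edges

    def test_missing_species_gives_absent(self):
        g = parse_newick("((a:1,b:2):3,c:4);")
        assert induced_quartet_obs(g, "a", "b", "c", "d") is None

    def test_polytomy_is_unresolved(self):
        g = parse_newick("(a:1,b:1,c:1,d:1);")
        topo, lengths = induced_quartet_obs(g, "a", "b", "c", "d")
        assert topo == "unresolved"
        assert lengths is None

    def test_zero_length_internal_edge_still_resolves(self):
        g = parse_newick("((a:1,b:1):0,(c:1,d:1):0);")
        topo, lengths = induced_quartet_obs(g, "a", "b", "c", "d")
        assert topo == "ab|cd"
        assert lengths[4] == 0.0

    def test_against_patristic_four_point_oracle(self):
        # independent oracle: dendropy patristic distance matrix + four-point
        # decomposition on a 6-leaf gene tree
        newick = "(((a:0.4,b:0.9):0.2,(c:0.5,e:0.1):0.7):0.3,(d:1.1,f:0.6):0.2);"
        gene = parse_newick(newick)
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}

        def d(x, y):
            return pdm.patristic_distance(taxa[x], taxa[y])

        for quartet in (("a", "b", "c", "d"), ("a", "c", "e", "f"),
                        ("b", "e", "d", "f")):
            topo, lengths = induced_quartet_obs(gene, *quartet)
            a, b, c, dd_ = quartet
            pairs = {"ab|cd": (a, b, c, dd_), "ac|bd": (a, c, b, dd_),
                     "ad|bc": (a, dd_, b, c)}
            x1, x2, y1, y2 = pairs[topo]
            internal = (d(x1, y1) + d(x2, y2) - d(x1, x2) - d(y1, y2)) / 2
            p_x1 = (d(x1, x2) + d(x1, y1) - d(x2, y1)) / 2
            assert lengths[4] == pytest.approx(internal, abs=1e-9)
            exp_pendants = {
                x1: p_x1,
                x2: d(x1, x2) - p_x1,
                y1: (d(y1, y2) + d(y1, x1) - d(y2, x1)) / 2,
            }
            for leaf, val in exp_pendants.items():
                idx = quartet.index(leaf)
                assert lengths[idx] == pytest.approx(val, abs=1e-9)


class TestBruteForce:
    def test_single_gene_identical_to_species(self):
        sp = parse_newick("(((a,b),c),d);")
        gene = parse_newick("(((a:0.1,b:0.2):0.5,c:0.3):0.8,d:0.4);")
        rm = brute_force_role_means(sp, [gene])[frozenset("ab")]
        assert rm.n_match == 1
        assert rm.n_nonmatch == 0
        assert rm.mean_match("A") == pytest.approx(0.1)
        assert rm.mean_match("B") == pytest.approx(0.2)
        assert rm.mean_match("C") == pytest.approx(0.3)
        assert rm.mean_match("D") == pytest.approx(0.4 + 0.8)
        assert rm.mean_match("I") == pytest.approx(0.5)
        assert rm.mean_nonmatch("I") is None

    def test_three_topologies_unit_lengths(self):
        sp = parse_newick("(((a,b),c),d);")
        genes = [
            parse_newick("((a:1,b:1):1,(c:1,d:1):1);"),
            parse_newick("((a:1,c:1):1,(b:1,d:1):1);"),
            parse_newick("((a:1,d:1):1,(b:1,c:1):1);"),
        ]
        rm = brute_force_role_means(sp, genes)[frozenset("ab")]
        assert rm.n_match == 1
        assert rm.n_nonmatch == 2
        for role in "ABCD":
            assert rm.mean_match(role) == pytest.approx(1.0)
        assert rm.mean_match("I") == pytest.approx(2.0)  # path through the root
        for role in ROLES:
            assert rm.diff(role) == pytest.approx(0.0)
        assert rm.delta == pytest.approx(0.0)

    def test_counts_invariant_single_individual(self, messy_instances):
        for species, genes, tmap in messy_instances[:6]:
            if not tmap.is_identity:
                continue
            k = len(genes)
            means = brute_force_role_means(species, genes, tmap)
            for quad in quadripartitions(species):
                rm = means[quad.clade]
                total = np.prod([len(p) for p in quad.parts]) * k
                assert (
                    rm.n_match + rm.n_nonmatch + rm.n_unresolved + rm.n_missing
                    == pytest.approx(total)
                )


class TestFastEqualsBrute:
    def test_quartet_is_exact(self):
        sp = make_quartet_model(0.5, 1.0, 1.0, 1.3, 0.9, (0.2, 0.3, 0.1, 0.6))
        genes = simulate_gene_trees(sp, SimConfig(k=100, seed=21))
        species = sp.tree.copy()
        bf = brute_force_role_means(species, genes)
        ff = fast_role_means(species, genes)
        rb, rf = bf[frozenset("AB")], ff[frozenset("AB")]
        assert rb.n_match == rf.n_match
        assert rb.match_sums == pytest.approx(rf.match_sums, abs=1e-12)
        assert rb.nonmatch_sums == pytest.approx(rf.nonmatch_sums, abs=1e-12)

    def test_messy_instances_agree(self, messy_instances):
        for species, genes, tmap in messy_instances:
            bf = brute_force_role_means(species, genes, tmap)
            ff = fast_role_means(species, genes, tmap)
            assert set(bf) == set(ff)
            for clade in bf:
                a, b = bf[clade], ff[clade]
                for attr in ("n_match", "n_nonmatch", "n_unresolved", "n_missing"):
                    assert getattr(a, attr) == pytest.approx(
                        getattr(b, attr), abs=1e-9
                    ), (clade, attr)
                for sa, sb in ((a.match_sums, b.match_sums),
                               (a.nonmatch_sums, b.nonmatch_sums)):
                    for x, y in zip(sa, sb):
                        assert x == pytest.approx(y, rel=1e-9, abs=1e-9)

    def test_empirical_quadratic_scaling(self):
        # doubling n at fixed k should roughly quadruple the fast engine's
        # work; allow generous slack (soft check)
        import time

        from castles.msc_sim import random_model_tree

        times = {}
        for n in (16, 32):
            sp = random_model_tree(n, seed=n)
            genes = simulate_gene_trees(sp, SimConfig(k=30, seed=1))
            species = sp.tree.copy()
            t0 = time.perf_counter()
            fast_role_means(species, genes)
            times[n] = time.perf_counter() - t0
        ratio = times[32] / times[16]
        assert ratio < 8.0  # quadratic-ish, definitely not cubic


def test_matching_fraction_property():
    # empirical matching fraction approaches 1 - (2/3) e^-T1 (standard MSC
    # quartet probability)
    T1 = 0.7
    sp = make_quartet_model(T1, 1.0, 1.0, 1.0, 1.0, (0.1,) * 4)
    genes = simulate_gene_trees(sp, SimConfig(k=20000, seed=31))
    rm = fast_role_means(sp.tree.copy(), genes)[frozenset("AB")]
    p = 1 - (2 / 3) * math.exp(-T1)
    n = rm.n_match + rm.n_nonmatch
    se = math.sqrt(p * (1 - p) / n)
    assert abs(rm.n_match / n - p) < 3 * se


def test_role_means_table_format():
    sp = parse_newick("(((a,b),c),d);")
    gene = parse_newick("(((a:0.1,b:0.2):0.5,c:0.3):0.8,d:0.4);")
    tsv = role_means_table(brute_force_role_means(sp, [gene]))
    lines = tsv.strip().splitlines()
    assert lines[0] == "branch\trole\tbucket\tcount\tmean"
    assert len(lines) == 1 + 10  # 5 roles x 2 buckets for the single branch
    assert any("NA" in l for l in lines[1:])  # empty non-matching bucket
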