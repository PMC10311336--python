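import numpy as np
import pytest

from castles.msc_sim import (
    SimConfig,
    collapse_random_edges,
    drop_leaves,
    random_model_tree,
    simulate_gene_trees,
)


@pytest.fixture(scope="session")
def messy_instances():
    """Random (species, genes, map) bundles with missing leaves, polytomies
    and multi-individual genes, shared by the aggregation-equivalence tests."""
    from castles.trees_io import TaxonMap

    rng = np.random.default_rng(20240917)
    instances = []
    for rep in range(12):
        n = int(rng.integers(5, 11))
        k = int(rng.integers(5, 15))
        sp = random_model_tree(n, seed=int(rng.integers(2**31)))
        individuals = {}
        tmap = TaxonMap()
        if rep % 3 == 0:
            labels = sp.tree.leaf_labels()
            individuals = {labels[0]: 2, labels[1]: 3}
            tmap = TaxonMap(
                {
                    f"{lab}_{i + 1}": lab
                    for lab, c in individuals.items()
                    for i in range(c)
                }
            )
        genes = simulate_gene_trees(
            sp, SimConfig(k=k, seed=rep, individuals=individuals)
        )
        perturbed = []
        for g in genes:
            labs = [l.label for l in g.leaves()]
            ndrop = int(rng.binomial(len(labs), 0.1))
            if ndrop and len(labs) - ndrop >= 2:
                g = drop_leaves(g, list(rng.choice(labs, ndrop, replace=False)))
            g = collapse_random_edges(g, 0.2, rng)
            perturbed.append(g)
        instances.append((sp.tree.copy(), perturbed, tmap))
    return instances
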