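import numpy as np
import pytest

import oceanmg as om

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def greedy_cluster_oracle(records, id_thresh, cov_thresh):
    """Independent brute-force greedy clustering over the full pairwise
    identity/coverage matrix (same ordering contract as the implementation,
    computed without it)."""
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.gene_id))
    pair = {}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            pair[(a.gene_id, b.gene_id)] = om.align_identity(a.sequence, b.sequence)
            pair[(b.gene_id, a.gene_id)] = pair[(a.gene_id, b.gene_id)]
    reps, clusters = [], {}
    for rec in ordered:
        for rep in reps:
            ident, cov = pair[(rec.gene_id, rep)]
            if ident >= id_thresh and cov >= cov_thresh:
                clusters[rep].append(rec.gene_id)
                break
        else:
            reps.append(rec.gene_id)
            clusters[rec.gene_id] = [rec.gene_id]
    return clusters


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree with positive branch lengths plus its exact
    tip-to-tip (additive) distance matrix."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    tree = TreeNode(children=nodes)
    dm = tree.tip_tip_distances()
    return tree, dm


@pytest.fixture(scope="session")
def routedb():
    return om.load_routedb()


@pytest.fixture(scope="session")
def three_strain_community():
    """3 strains sharing 10 core genes, 4 private accessory genes each,
    abundances 0.5/0.3/0.2."""
    pangenomes, records = om.generate_pangenomes(
        3, core_size=10, accessory_size=4, gene_len_range=(200, 1200), seed=7
    )
    spec = om.community_spec(pangenomes, records, [0.5, 0.3, 0.2])
    return pangenomes, records, spec
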