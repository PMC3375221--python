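import numpy as np
import pytest

from regdiverge import phylo_core as pc


@pytest.fixture(scope="session")
def hky_params():
    return pc.HKY85Params(2.0, np.array([0.3, 0.2, 0.2, 0.3]))


@pytest.fixture(scope="session")
def scaled_tree():
    """The fixed 4-species topology with genome-scale fourfold rates."""
    return pc.yeast_tree([0.05, 0.10, 0.08, 0.15, 0.20])


def enumeration_log_likelihood(aln, tree, params, ratios=None):
    """Brute-force phylogenetic likelihood by summing over every internal-node
    state assignment, column by column.  Independent oracle for pruning."""
    if ratios is None:
        ratios = np.ones(tree.n_branches)
    eig = pc.HKY85EigenSystem(params)
    P = eig.transition_probs(tree.branch_lengths * np.asarray(ratios, dtype=float))
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}

    internals = []

    def collect(node):
        if node.children:
            internals.append(node)
            for c in node.children:
                collect(c)

    collect(tree.root)

    total = 0.0
    for col in aln.matrix.T:
        site = 0.0
        for states in np.ndindex(*(4,) * len(internals)):
            assign = dict(zip((id(n) for n in internals), states))

            def prob(node, state):
                p = 1.0
                for child in node.children:
                    if child.children:
                        cs = assign[id(child)]
                        p *= P[child.edge_index][state, cs] * prob(child, cs)
                    else:
                        obs = col[taxon_row[child.label]]
                        if obs < 0:  # missing data: sum over states = 1
                            continue
                        p *= P[child.edge_index][state, obs]
                return p

            root_state = assign[id(tree.root)]
            site += params.pi[root_state] * prob(tree.root, root_state)
        total += np.log(site)
    return total
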