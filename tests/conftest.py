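import itertools

import numpy as np
import pandas as pd
import pytest

from acsiva import fixtures, isotope_tables


@pytest.fixture
def rng():
    return np.random.default_rng(20120726)


def make_samples(rows):
    """Build a sample frame from (id, species, genus, site, d13C, d15N) tuples."""
    return pd.DataFrame(
        rows, columns=["specimen_id", "species", "genus", "site", "d13C", "d15N"]
    )


@pytest.fixture
def tiny_samples():
    return make_samples(
        [
            ("s1", "A a", "A", "x", -30.0, 8.0),
            ("s2", "A a", "A", "x", -28.0, 10.0),
            ("s3", "B b", "B", "x", -26.0, 6.0),
            ("s4", "B b", "B", "y", -31.0, 9.0),
            ("s5", "C c", "C", "y", -29.0, 7.0),
        ]
    )


def write_csv(df, path):
    df.to_csv(path, index=False)
    return str(path)


def random_tree(rng, n_tips, scale_lengths=True):
    """Random Yule topology with independently rescaled branch lengths."""
    cfg = fixtures.SimulationConfig(
        seed=int(rng.integers(2**31)),
        genera=fixtures.default_genera(n_tips),
    )
    tree = fixtures.simulate_tree(cfg)
    if scale_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None:
                edge.length = float(rng.uniform(0.1, 3.0))
    return tree


def bruteforce_pls(tree, tip_values, unit_lengths=False):
    """Independent oracle: solve the weighted least-squares objective as an
    incidence-matrix regression (rows = branches scaled by 1/sqrt(length))."""
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(internal)}
    rows, rhs = [], []
    for node in tree.preorder_node_iter():
        if node.edge.tail_node is None:
            continue
        w = 1.0 if unit_lengths else 1.0 / np.sqrt(node.edge.length)
        row = np.zeros(len(internal))
        row[idx[id(node.edge.tail_node)]] = w
        if node.is_leaf():
            rhs.append(w * tip_values[node.taxon.label])
        else:
            row[idx[id(node)]] -= w
            rhs.append(0.0)
        rows.append(row)
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return {nd: v for nd, v in zip(internal, sol)}


def circular_diff(a, b):
    """Signed angular difference a - b in (-180, 180]."""
    return (a - b + 180.0) % 360.0 - 180.0


def vectors_from_samples(samples):
    means = isotope_tables.species_means(samples)
    centroids = isotope_tables.assemblage_centroids(means)
    return isotope_tables.individual_vectors(samples, centroids), centroids
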