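"""Synthetic data generators mirroring the structure the analysis assumes.

Generates (a) Yule trees over genus labels, (b) Brownian evolution of the
shifted Cartesian vector components along the tree, and (c) assemblage
sample tables in which each genus has a von Mises directional preference
about its site centroid.  Everything is driven by a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import DomainError
from .phylo import tree_from_string

__all__ = [
    "GenusSpec",
    "SimulationConfig",
    "simulate_tree",
    "simulate_vector_evolution",
    "simulate_assemblages",
    "make_bundle",
]


@dataclass(frozen=True)
class GenusSpec:
    """True directional preference of one genus."""

    label: str
    mu_deg: float
    kappa: float
    occupancy: float = 0.7  # probability of being present at a site

    def __post_init__(self):
        if self.kappa < 0:
            raise DomainError("kappa must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise DomainError("occupancy must be in [0, 1]")


def default_genera(
    n: int = 30, kappa: float = 4.0, occupancy: float = 0.7
) -> List[GenusSpec]:
    """Evenly spaced true directions for ``n`` genera."""
    return [
        GenusSpec(f"Genus{i:02d}", (360.0 * i / n) % 360.0, kappa, occupancy)
        for i in range(n)
    ]


@dataclass
class SimulationConfig:
    """Everything needed to generate a reproducible fixture bundle."""

    seed: int = 0
    n_sites: int = 19
    genera: List[GenusSpec] = field(default_factory=default_genera)
    species_per_genus: int = 2
    individuals_per_species: Tuple[int, int] = (2, 8)  # inclusive range
    isotope_scale: float = 1.5  # ‰ scale of vector magnitudes
    centroid_jitter: float = 3.0  # ‰ SD of site centroid positions
    measurement_noise: float = 0.0  # ‰ SD added to each sample
    base_centroid: Tuple[float, float] = (-28.0, 8.0)
    tree_newick: Optional[str] = None  # fixed topology overrides the Yule draw
    brownian_rate: float = 0.05  # variance per unit branch length

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Seeded Yule (pure-birth) tree over the configured genus labels.

    Exponential waiting times between splits; branch lengths are strictly
    positive.  With exactly two genera this is a cherry.
    """
    labels = [g.label for g in config.genera]
    if len(labels) < 2:
        raise DomainError("need at least 2 genera")
    if config.tree_newick is not None:
        return tree_from_string(config.tree_newick)
    rng = np.random.default_rng((config.seed, 0x7EE))
    newick = _yule_newick(labels, rng)
    return tree_from_string(newick)


class _YuleNode:
    __slots__ = ("children", "length", "label")

    def __init__(self) -> None:
        self.children: List["_YuleNode"] = []
        self.length = 0.0
        self.label = ""


def _yule_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Forward pure-birth simulation: split a random lineage until n tips."""
    n_target = len(labels)
    root = _YuleNode()
    active = [_YuleNode(), _YuleNode()]
    root.children = list(active)
    while len(active) < n_target:
        wait = rng.exponential(1.0 / len(active))
        for lin in active:
            lin.length += wait
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.children = [_YuleNode(), _YuleNode()]
        active.extend(node.children)
    wait = rng.exponential(1.0 / len(active))
    for lin in active:
        lin.length += wait + 0.1  # pendant lengths strictly positive
    for leaf, k in zip(active, rng.permutation(n_target)):
        leaf.label = labels[int(k)]

    def render(node: _YuleNode) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.6f}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.6f}"

    inner = ",".join(render(c) for c in root.children)
    return f"({inner});"


def simulate_vector_evolution(
    tree: dendropy.Tree,
    brownian_rate: float,
    root_xy: Tuple[float, float] = (1.0, 1.0),
    *,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, Tuple[float, float]]:
    """Brownian motion of the shifted (X, Y) components along the tree.

    Returns per-tip true mean vectors as ``label -> (mu_deg, r)`` derived
    from the unshifted components, with r clipped to at most 1.
    """
    if brownian_rate < 0:
        raise DomainError("brownian_rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    xy: Dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            xy[id(node)] = np.asarray(root_xy, dtype=float)
            continue
        length = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(brownian_rate * length), size=2)
        xy[id(node)] = xy[id(node.parent_node)] + step
    out = {}
    for leaf in tree.leaf_node_iter():
        x, y = xy[id(leaf)] - 1.0
        r = min(float(np.hypot(x, y)), 1.0)
        mu = float(np.degrees(np.arctan2(y, x)) % 360.0) if r > 0 else 0.0
        out[leaf.taxon.label] = (mu, r)
    return out


def simulate_assemblages(
    config: SimulationConfig,
    directions: Optional[Dict[str, Tuple[float, float]]] = None,
    *,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Sample table with per-genus von Mises directions about site centroids.

    ``directions`` optionally overrides each genus's true mean direction
    (``label -> (mu_deg, r)``; the r part is ignored, concentration comes
    from the genus spec).  Individual magnitudes are gamma(shape 2) scaled
    by ``isotope_scale``; centroids are jittered per site in absolute
    isotope space.  Empty sites are redrawn.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 0xA55))
    lo, hi = config.individuals_per_species
    if lo < 1 or hi < lo:
        raise DomainError("individuals_per_species must be a valid range >= 1")
    rows = []
    specimen = 0
    for s in range(config.n_sites):
        site = f"site{s:02d}"
        cx, cy = (
            np.asarray(config.base_centroid)
            + rng.normal(0.0, config.centroid_jitter, size=2)
        )
        present: List[GenusSpec] = []
        for _ in range(1000):
            present = [g for g in config.genera if rng.random() < g.occupancy]
            if present:
                break
        for g in present:
            mu = directions[g.label][0] if directions and g.label in directions else g.mu_deg
            for sp in range(config.species_per_genus):
                species = f"{g.label} sp{sp + 1}"
                n_ind = int(rng.integers(lo, hi + 1))
                for _ in range(n_ind):
                    theta = (
                        np.radians(mu)
                        if np.isinf(g.kappa)
                        else rng.vonmises(np.radians(mu), g.kappa)
                    )
                    mag = rng.gamma(2.0, config.isotope_scale / 2.0)
                    noise = rng.normal(0.0, config.measurement_noise, size=2) if config.measurement_noise > 0 else (0.0, 0.0)
                    rows.append(
                        {
                            "specimen_id": f"spec{specimen:05d}",
                            "species": species,
                            "genus": g.label,
                            "site": site,
                            "d13C": cx + mag * np.cos(theta) + noise[0],
                            "d15N": cy + mag * np.sin(theta) + noise[1],
                        }
                    )
                    specimen += 1
    return pd.DataFrame.from_records(
        rows, columns=["specimen_id", "species", "genus", "site", "d13C", "d15N"]
    )


def make_bundle(config: SimulationConfig, outdir) -> Dict[str, str]:
    """Write a ready-to-run fixture bundle (samples.csv, tree.nwk, truth.json).

    Returns the mapping of artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    rng = config.rng()
    truth_tips = simulate_vector_evolution(
        tree, config.brownian_rate, rng=np.random.default_rng((config.seed, 0xB0))
    )
    # genus true directions: keep the configured von Mises means; the tree
    # truth is recorded alongside for reconstruction studies
    samples = simulate_assemblages(config, rng=rng)
    paths = {
        "samples": str(outdir / "samples.csv"),
        "tree": str(outdir / "tree.nwk"),
        "truth": str(outdir / "truth.json"),
    }
    samples.to_csv(paths["samples"], index=False)
    tree.write(path=paths["tree"], schema="newick", suppress_rooting=True)
    truth = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("genera",)
            },
            "genera": [dataclasses.asdict(g) for g in config.genera],
        },
        "tip_vectors_from_tree": {k: list(v) for k, v in truth_tips.items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
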