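"""Ancestral reconstruction of niche-vector components on a phylogeny.

Tip mean vectors are projected to Cartesian components (X = r cos μ + 1,
Y = r sin μ + 1, the +1 shift keeping all values positive), internal-node
states are estimated by branch-length-weighted least squares — the values
minimizing Σ over branches of (parent − child)² / branch_length, i.e.
weighted squared-change parsimony, which is also the Brownian-motion
least-squares solution — and node states are converted back to angles
with quadrant correction and binned into eight 45° sectors.

Trees are :class:`dendropy.Tree` objects; tips are genus labels.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError, DomainError, ParseError, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "tree_from_string",
    "prune_to_taxa",
    "dedupe_congeneric_tips",
    "tips_to_cartesian",
    "pls_ancestral_states",
    "reconstruct_vector_states",
    "states_to_angles",
    "count_axis_transitions",
]

SECTOR_DEG = 45.0
#: default palette for the eight 45° sectors, counterclockwise from 0°
SECTOR_COLORS = (
    "#e41a1c", "#ff7f00", "#ffd92f", "#4daf4a",
    "#1b9e77", "#377eb8", "#984ea3", "#f781bf",
)


def _fix_branch_lengths(tree: dendropy.Tree) -> int:
    """Replace missing/zero/negative branch lengths with 1.0; returns count."""
    fixed = 0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # the seed edge is not a branch
            continue
        if edge.length is None or edge.length <= 0.0:
            edge.length = 1.0
            fixed += 1
    return fixed


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; absent or zero branch lengths become 1.0."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from exc
    fixed = _fix_branch_lengths(tree)
    if fixed:
        logger.warning("replaced %d missing/zero branch length(s) with 1.0", fixed)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string with the same conventions as :func:`read_newick`."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"cannot parse Newick string: {exc}") from exc
    _fix_branch_lengths(tree)
    return tree


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_taxa(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Tree:
    """Minimal induced subtree on ``labels``; collapsed edges sum lengths.

    Unmatched labels are reported in the raised error.  Requires at least
    two retained tips.
    """
    keep = list(dict.fromkeys(labels))
    present = set(tip_labels(tree))
    unmatched = [x for x in keep if x not in present]
    if unmatched:
        raise DataError(f"label(s) not in tree: {unmatched}")
    if len(keep) < 2:
        raise DomainError("pruning needs at least 2 labels")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    # drop any leading root knuckle left by pruning
    pruned.suppress_unifurcations()
    return pruned


def dedupe_congeneric_tips(
    tree: dendropy.Tree,
    type_species: Optional[Mapping[str, str]] = None,
    *,
    relabel_to_genus: bool = True,
) -> dendropy.Tree:
    """Keep one tip per genus (label's first token).

    Keeps the configured type species for a genus when present, else the
    first tip encountered.  Retained tips are relabelled to the bare genus
    name by default.
    """
    type_species = dict(type_species or {})
    chosen: Dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        genus = label.replace("_", " ").split()[0]
        want = type_species.get(genus)
        if genus not in chosen:
            chosen[genus] = label
        if want is not None and label == want:
            chosen[genus] = label
    out = prune_to_taxa(tree, list(chosen.values())) if len(chosen) >= 2 else tree
    if relabel_to_genus:
        back = {v: k for k, v in chosen.items()}
        for leaf in out.leaf_node_iter():
            if leaf.taxon.label in back:
                leaf.taxon.label = back[leaf.taxon.label]
    return out


def tips_to_cartesian(
    mean_vectors: Mapping[str, Tuple[float, float]]
) -> Dict[str, Tuple[float, float]]:
    """Shifted Cartesian components per tip: (r cos μ + 1, r sin μ + 1)."""
    out = {}
    for label, (mu_deg, r) in mean_vectors.items():
        rad = math.radians(mu_deg)
        out[label] = (r * math.cos(rad) + 1.0, r * math.sin(rad) + 1.0)
    return out


def assign_node_ids(tree: dendropy.Tree) -> None:
    """Give every node a stable id: tip label for leaves, N<k> preorder else."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.acsiva_id = node.taxon.label
        else:
            node.acsiva_id = f"N{k}"
            k += 1


def pls_ancestral_states(
    tree: dendropy.Tree,
    tip_values: Mapping[str, float],
    *,
    unit_lengths: bool = False,
) -> Dict[str, float]:
    """Exact branch-length-weighted least-squares ancestral states.

    Internal-node values minimize Σ_branches (v_parent − v_child)² / length.
    Solved by the (dense) linear system from the normal equations.  Returns
    a dict node id -> value covering every node; run
    :func:`assign_node_ids` is implied.

    With ``unit_lengths=True`` every branch counts 1 (unweighted
    squared-change parsimony).
    """
    assign_node_ids(tree)
    leaves = list(tree.leaf_node_iter())
    missing = [lf.taxon.label for lf in leaves if lf.taxon.label not in tip_values]
    if missing:
        raise DataError(f"tip(s) without data: {missing}")
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    if not internal:
        raise StructureError("tree has no internal nodes")
    index = {id(nd): i for i, nd in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in tree.preorder_node_iter():
        edge = node.edge
        if edge.tail_node is None:
            continue
        w = 1.0 if unit_lengths else 1.0 / edge.length
        parent, child = edge.tail_node, node
        pi = index[id(parent)]
        A[pi, pi] += w
        if child.is_leaf():
            b[pi] += w * tip_values[child.taxon.label]
        else:
            ci = index[id(child)]
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise StructureError(f"degenerate tree: {exc}") from exc
    out = {nd.acsiva_id: float(x[index[id(nd)]]) for nd in internal}
    for lf in leaves:
        out[lf.acsiva_id] = float(tip_values[lf.taxon.label])
    return out


def _angle_sector(x: float, y: float) -> Tuple[Optional[float], Optional[int]]:
    if x == 0.0 and y == 0.0:
        return None, None
    angle = math.degrees(math.atan2(y, x)) % 360.0
    if angle >= 360.0:
        angle = 0.0
    return angle, int(angle // SECTOR_DEG) % 8


def states_to_angles(states: Mapping[str, Tuple[float, float]]) -> pd.DataFrame:
    """Convert shifted (X, Y) node states to angles, sectors and axis labels.

    Columns: node, X, Y, angle_deg, sector, N_label, C_label.  The angle is
    ``atan2(Y−1, X−1)`` in [0, 360) (NaN, with NaN sector, at the centroid
    point (1, 1)); sector is ``floor(angle/45)``; axis labels carry the sign
    of the unshifted components ("enriched" / "depleted" / "at-centroid").
    """
    rows = []
    for node, (X, Y) in states.items():
        x, y = X - 1.0, Y - 1.0
        angle, sector = _angle_sector(x, y)
        rows.append(
            {
                "node": node,
                "X": X,
                "Y": Y,
                "angle_deg": np.nan if angle is None else angle,
                "sector": np.nan if sector is None else sector,
                "N_label": "at-centroid" if y == 0 else ("enriched" if y > 0 else "depleted"),
                "C_label": "at-centroid" if x == 0 else ("enriched" if x > 0 else "depleted"),
            }
        )
    return pd.DataFrame.from_records(rows)


def reconstruct_vector_states(
    tree: dendropy.Tree,
    mean_vectors: Mapping[str, Tuple[float, float]],
    *,
    unit_lengths: bool = False,
    prune: bool = False,
) -> pd.DataFrame:
    """Full reconstruction: tips -> Cartesian -> PLS per axis -> angles.

    X and Y are reconstructed independently (the quadratic objective is
    separable).  Returns the :func:`states_to_angles` frame augmented with
    a ``parent`` column (empty string at the root) and ``is_tip``.
    """
    tips = set(tip_labels(tree))
    have = set(mean_vectors)
    orphan_tips = tips - have
    if orphan_tips:
        if not prune:
            raise DataError(f"tip(s) without mean vectors: {sorted(orphan_tips)}")
        tree = prune_to_taxa(tree, sorted(tips & have))
        logger.warning("pruned %d tip(s) without data", len(orphan_tips))
    cart = tips_to_cartesian({k: v for k, v in mean_vectors.items() if k in tips})
    xs = pls_ancestral_states(tree, {k: v[0] for k, v in cart.items()}, unit_lengths=unit_lengths)
    ys = pls_ancestral_states(tree, {k: v[1] for k, v in cart.items()}, unit_lengths=unit_lengths)
    states = {node: (xs[node], ys[node]) for node in xs}
    df = states_to_angles(states)
    parent = {}
    is_tip = {}
    for node in tree.preorder_node_iter():
        parent[node.acsiva_id] = (
            "" if node.parent_node is None else node.parent_node.acsiva_id
        )
        is_tip[node.acsiva_id] = node.is_leaf()
    df["parent"] = df["node"].map(parent)
    df["is_tip"] = df["node"].map(is_tip)
    return df[["node", "parent", "is_tip", "X", "Y", "angle_deg", "sector", "N_label", "C_label"]]


def count_axis_transitions(
    tree: dendropy.Tree, labels: Mapping[str, str]
) -> Tuple[int, int]:
    """Count branches whose endpoint labels differ.

    ``labels`` maps node id -> axis label ("enriched"/"depleted"/...);
    branches touching an undefined or "at-centroid" node are skipped.
    Returns (transitions, skipped_branches).
    """
    transitions = skipped = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a = labels.get(node.acsiva_id)
        b = labels.get(node.parent_node.acsiva_id)
        if a in (None, "at-centroid") or b in (None, "at-centroid"):
            skipped += 1
            continue
        if a != b:
            transitions += 1
    if skipped:
        logger.warning("%d branch(es) skipped for undefined axis labels", skipped)
    return transitions, skipped
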