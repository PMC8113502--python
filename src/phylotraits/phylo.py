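"""Newick trees and the Brownian-motion phylogenetic correlation matrix.

Under Brownian motion on a rooted tree the covariance between the trait
values of two species is the length of their shared root-to-tip path, i.e.
the depth of their most recent common ancestor.  The correlation matrix
``rho`` rescales that covariance to a unit diagonal and is what the
phylogenetic random effect of the multilevel model consumes.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .exceptions import DegenerateTreeError, PhyloTraitsError
from .io import normalize_species_label

__all__ = ["read_newick", "phylo_correlation", "PhyloCorrelation"]


def read_newick(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Parse a rooted Newick tree from a path, a Newick string, or pass through.

    Branch lengths are required on all non-root edges; polytomies are allowed.
    """
    if isinstance(source, dendropy.Tree):
        tree = source
    else:
        text: str | None = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types with positions
            raise PhyloTraitsError(f"failed to parse Newick source: {exc}") from exc
    tree.is_rooted = True
    tips = tree.leaf_nodes()
    if len(tips) < 2:
        raise PhyloTraitsError("tree must have at least 2 tips")
    labels = [t.taxon.label for t in tips if t.taxon is not None]
    if len(labels) != len(tips):
        raise PhyloTraitsError("every tip must carry a label")
    if len(set(labels)) != len(labels):
        raise PhyloTraitsError("tip labels must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise PhyloTraitsError(
                f"missing branch length on edge above {edge.head_node!r}"
            )
        if edge.length < 0:
            raise PhyloTraitsError("negative branch length")
    return tree


@dataclasses.dataclass
class PhyloCorrelation:
    """Species-ordered phylogenetic correlation matrix.

    ``rho`` is symmetric with unit diagonal and, for trees with nonnegative
    branch lengths, entries in [0, 1].  ``cov`` is the underlying
    Brownian-motion covariance (shared root-to-tip path lengths).
    """

    species: list[str]
    rho: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (len(self.species), len(self.species)):
            raise ValueError("rho shape does not match species list")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def reorder(self, species: Sequence[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(
            species=list(species),
            rho=self.rho[np.ix_(idx, idx)],
            cov=self.cov[np.ix_(idx, idx)],
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.rho)[0])


def _tip_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {
        normalize_species_label(leaf.taxon.label): leaf
        for leaf in tree.leaf_node_iter()
    }


def phylo_correlation(
    tree: dendropy.Tree | str | Path, species: Sequence[str]
) -> PhyloCorrelation:
    """Brownian-motion correlation matrix among ``species`` (tip subset).

    cov[m, n] is the depth of the MRCA of m and n, computed as
    ``(depth(m) + depth(n) - patristic(m, n)) / 2``; rho divides each entry by
    the geometric mean of the two diagonal entries (cov2cor), so the tree need
    not be ultrametric.  Matrix order follows the requested species order.
    """
    tree = read_newick(tree)
    species = list(species)
    tips = _tip_map(tree)
    nodes = []
    for sp in species:
        key = normalize_species_label(sp)
        if key not in tips:
            raise KeyError(f"species {sp!r} not found among tree tips")
        nodes.append(tips[key])

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = np.array([n.root_distance for n in nodes], dtype=float)
    if np.any(depth <= 0):
        bad = [species[i] for i in np.flatnonzero(depth <= 0)]
        raise DegenerateTreeError(
            f"zero root-to-tip distance for {bad}; correlation undefined"
        )

    pdm = tree.phylogenetic_distance_matrix()
    k = len(species)
    cov = np.zeros((k, k))
    for i in range(k):
        cov[i, i] = depth[i]
        for j in range(i + 1, k):
            d = pdm.patristic_distance(nodes[i].taxon, nodes[j].taxon)
            cov[i, j] = cov[j, i] = 0.5 * (depth[i] + depth[j] - d)
    cov = np.maximum(cov, 0.0)  # guard tiny negative round-off on deep splits

    denom = np.sqrt(np.outer(depth, depth))
    rho = cov / denom
    np.fill_diagonal(rho, 1.0)
    rho = 0.5 * (rho + rho.T)

    off = rho[~np.eye(k, dtype=bool)]
    if off.size and np.any(off > 1 - 1e-12):
        warnings.warn(
            "tree contains effectively identical tips (off-diagonal correlation "
            "of 1); downstream factorizations add a diagonal ridge",
            stacklevel=2,
        )
    return PhyloCorrelation(species=species, rho=rho, cov=cov)
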