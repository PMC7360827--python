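"""Standardization, Euclidean distances, UPGMA dendrogram, group profiles.

The trait matrix mixes real-valued quantitative traits with
integer-coded qualitative states; following common germplasm practice
all columns are treated numerically and z-scored before the distance
computation, so every trait contributes on a comparable scale. UPGMA
(unweighted pair-group method with arithmetic mean) then merges, at
each step, the pair of clusters with the smallest average inter-cluster
Euclidean distance; the merge height is that average distance itself.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .collection import GermplasmCollection


@dataclass
class StandardizedMatrix:
    accession_ids: list[str]
    trait_codes: list[str]
    values: np.ndarray  # accessions x traits, column z-scores
    dropped_ids: list[str] = field(default_factory=list)  # rows excluded for missingness
    constant_traits: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` follows the scipy linkage convention: row i merges
    clusters ``a`` and ``b`` (ids < n are leaves, id n+i is the cluster
    created by row i) at ``height`` into a cluster of ``size`` leaves.
    """

    merges: np.ndarray  # (n-1) x 4: a, b, height, size
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(cophenet(self.merges))

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        if n == 1:
            return f"{self.leaf_ids[0]}:0;"
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        for i, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + i] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["cluster_a", "cluster_b", "height", "size"])
            for a, b, h, s in self.merges:
                w.writerow([int(a), int(b), repr(float(h)), int(s)])
        return path


@dataclass
class GroupProfile:
    group_label: str
    size: int
    quantitative_summary: dict[str, tuple[float, float]]  # trait -> (mean, sd)
    qualitative_summary: dict[str, tuple[int, float]]  # trait -> (modal level, freq)


def standardize(collection: GermplasmCollection,
                traits: list[str] | None = None) -> StandardizedMatrix:
    """Column-wise z-scoring of the trait matrix (sample sd).

    Rows with any missing included-trait value are excluded and listed
    in ``dropped_ids``; constant columns become all-zero with a warning.
    """
    catalog = collection.catalog
    codes = traits if traits is not None else catalog.codes
    for c in codes:
        if c not in catalog:
            raise KeyError(f"trait {c} not in catalog")

    kept_ids, rows, dropped = [], [], []
    for acc in collection:
        vals = [acc.value(c) for c in codes]
        if any(v is None for v in vals):
            dropped.append(acc.id)
            continue
        kept_ids.append(acc.id)
        rows.append([float(v) for v in vals])
    if len(rows) < 2:
        raise ValueError("standardize requires at least 2 complete accessions")

    x = np.asarray(rows, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = [codes[j] for j in np.nonzero(sd == 0)[0]]
    if constant:
        warnings.warn(f"constant trait column(s) set to zero: {constant}",
                      stacklevel=2)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return StandardizedMatrix(kept_ids, list(codes), z, dropped, constant)


def euclidean_distances(matrix: StandardizedMatrix) -> np.ndarray:
    """Symmetric accession-by-accession Euclidean distance matrix."""
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    return squareform(pdist(matrix.values, metric="euclidean"))


def upgma(dist: np.ndarray, leaf_ids: list[str]) -> Dendrogram:
    """UPGMA tree from a square distance matrix.

    Heights are the average inter-cluster distances at each merge;
    after a merge the distance to any other cluster is the size-weighted
    average of the merged members' distances (the unweighted pair-group
    definition).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if dist.shape[0] != len(leaf_ids):
        raise ValueError("leaf_ids length must match matrix size")
    merges = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(merges=merges, leaf_ids=list(leaf_ids))


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> dict[str, str]:
    """Partition leaves into k groups by removing the k-1 highest merges.

    Group labels are ``"G1"``, ``"G2"``, ... ordered by group size
    descending (ties broken by first-occurring leaf).
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = fcluster(dendrogram.merges, t=k, criterion="maxclust")
    # order group labels by size (desc), then by first appearance
    order = sorted(
        set(raw),
        key=lambda g: (-(raw == g).sum(), int(np.argmax(raw == g))),
    )
    relabel = {g: f"G{i + 1}" for i, g in enumerate(order)}
    return {leaf: relabel[g] for leaf, g in zip(dendrogram.leaf_ids, raw)}


def summarize_groups(collection: GermplasmCollection,
                     labels: dict[str, str]) -> list[GroupProfile]:
    """Per-group trait profiles: mean/sd for quantitative traits, modal
    level with its within-group frequency for qualitative traits."""
    known = set(collection.ids)
    unknown = sorted(set(labels) - known)
    if unknown:
        raise KeyError(f"labels reference unknown accession(s): {unknown}")

    groups: dict[str, list] = {}
    for acc in collection:
        if acc.id in labels:
            groups.setdefault(labels[acc.id], []).append(acc)

    profiles = []
    for label in sorted(groups):
        members = groups[label]
        quant: dict[str, tuple[float, float]] = {}
        qual: dict[str, tuple[int, float]] = {}
        for desc in collection.catalog:
            vals = [a.value(desc.code) for a in members]
            vals = [v for v in vals if v is not None]
            if not vals:
                continue
            if desc.is_qualitative:
                counts: dict[int, int] = {}
                for v in vals:
                    counts[v] = counts.get(v, 0) + 1
                mode = max(sorted(counts), key=lambda lv: counts[lv])
                qual[desc.code] = (mode, counts[mode] / len(vals))
            else:
                arr = np.asarray(vals, dtype=float)
                sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
                quant[desc.code] = (float(arr.mean()), sd)
        profiles.append(GroupProfile(label, len(members), quant, qual))
    return profiles
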