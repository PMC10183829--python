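"""Presence/absence matrix assembly, phi-coefficient co-evolution and
Ward-D2 clustering of the correlation profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

STAGE_ORDER = ("round1", "profile", "genome-rescue")


def assemble_matrix(hits: Sequence, taxa: Sequence[str], families: Sequence[str],
                    screens: Optional[Mapping[str, Set[str]]] = None,
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Binary taxa x families matrix from search hits of all stages.

    An entry is 1 iff some hit for that (taxon, family) passed its stage
    threshold and, when a paralog screen is available for the family,
    its target survived the screen (genome-rescue predictions are exempt:
    they are new gene models, not annotated candidates). Returns the matrix
    and a same-shaped provenance frame holding the earliest supporting stage.
    """
    matrix = pd.DataFrame(0, index=pd.Index(sorted(taxa), name="taxon"),
                          columns=sorted(families), dtype=int)
    provenance = pd.DataFrame("", index=matrix.index, columns=matrix.columns)
    seen: Dict[Tuple[str, str, str, str], float] = {}
    for hit in hits:
        key = (hit.family, hit.taxon, hit.target_id, hit.stage)
        if key in seen and seen[key] != hit.raw_score:
            raise ValueError(f"conflicting duplicate hit records for {key}")
        seen[key] = hit.raw_score
        if hit.family not in matrix.columns or hit.taxon not in matrix.index:
            continue
        if screens is not None and hit.family in screens and hit.stage != "genome-rescue":
            if hit.target_id not in screens[hit.family]:
                continue
        matrix.loc[hit.taxon, hit.family] = 1
        prev = provenance.loc[hit.taxon, hit.family]
        if prev == "" or STAGE_ORDER.index(hit.stage) < STAGE_ORDER.index(prev):
            provenance.loc[hit.taxon, hit.family] = hit.stage
    return matrix, provenance


def phi(x: Sequence[int], y: Sequence[int]) -> float:
    """Phi coefficient of two binary vectors; NaN when a marginal is zero."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = r1 * r0 * c1 * c0
    if denom == 0:
        return math.nan
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def phi_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise phi over matrix columns; constant columns give NaN flags."""
    fams = list(presence.columns)
    out = pd.DataFrame(np.nan, index=fams, columns=fams)
    for i, a in enumerate(fams):
        for j, b in enumerate(fams):
            if j < i:
                continue
            v = phi(presence[a].to_numpy(), presence[b].to_numpy())
            out.loc[a, b] = v
            out.loc[b, a] = v
    return out


@dataclass
class Dendrogram:
    ids: List[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def n_merges(self) -> int:
        return int(self.linkage.shape[0])

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6f}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return render(root, root.dist) + ";"


def ward_cluster(phi_df: pd.DataFrame, impute: bool = True) -> Dendrogram:
    """Ward-D2 / Euclidean clustering of the phi matrix's row vectors.

    Families whose phi is undefined against every partner (constant
    presence columns) are excluded from the clustering input. Remaining
    scattered NaN entries are mean-imputed when ``impute`` is set;
    otherwise they raise.
    """
    defined = phi_df.index[~phi_df.isna().all(axis=1)]
    if len(defined) == 0:
        return Dendrogram(ids=list(phi_df.index), linkage=np.empty((0, 4)))
    phi_df = phi_df.loc[defined, defined]
    m = phi_df.to_numpy(dtype=float).copy()
    if np.isnan(m).any():
        if not impute:
            raise ValueError("phi matrix contains undefined entries")
        fill = np.nanmean(m) if np.isfinite(np.nanmean(m)) else 0.0
        m[np.isnan(m)] = fill
    ids = list(phi_df.index)
    if len(ids) == 1:
        return Dendrogram(ids=ids, linkage=np.empty((0, 4)))
    link = hierarchy.linkage(m, method="ward", metric="euclidean")
    return Dendrogram(ids=ids, linkage=link)
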