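"""Congener-profile matrices, hierarchical clustering and heat maps.

The contamination profile is viewed as a matrix with one row per congener
and one column per sample (or per group mean). Because the congeners span
two orders of magnitude (PCB180 near 10 ng/g fat, PCB28 near 0.1), raw
Euclidean distances are dominated by the heavy congeners; rows are
therefore scaled to unit variance by default (the convention of the
ClustVis-style heat-map tools), and for fully z-scored rows the squared
Euclidean distance is an affine function of the Pearson correlation,
d^2 = 2 (n-1) (1 - r), licensing a correlation reading of the dendrogram.

Agglomeration is implemented directly (Lance-Williams updates) so that tie
handling is deterministic: among equally distant pairs the one whose
clusters contain the lexicographically smallest leaf labels merges first.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .congeners import CONGENERS
from .errors import DataError, SchemaError

__all__ = [
    "ProfileMatrix",
    "ClusterTree",
    "build_profile_matrix",
    "hierarchical_cluster",
    "export_tree",
    "render_heatmap",
]

_SCALINGS = ("none", "row_unit_variance", "row_z_score")
_LINKAGES = ("average", "complete", "single", "ward")


@dataclasses.dataclass(frozen=True)
class ProfileMatrix:
    """Congener-by-column concentration matrix with a scaling annotation."""

    data: pd.DataFrame  # rows: congeners; columns: samples or groups
    scaling: str
    unscaled_rows: tuple[str, ...] = ()  # constant rows left raw under scaling

    @property
    def row_labels(self) -> list[str]:
        return [str(r) for r in self.data.index]


def build_profile_matrix(
    records: pd.DataFrame,
    group_by: str = "sample",
    scaling: str = "row_unit_variance",
) -> ProfileMatrix:
    """Profile matrix from a sample table.

    ``group_by="sample"`` uses one column per sample (labeled by sample_id);
    ``"product"``/``"brand"`` use group means. Scaling options: ``none``,
    ``row_unit_variance`` (divide by row SD), ``row_z_score`` (center and
    divide by row SD). Constant rows cannot be scaled; they are kept raw and
    reported in ``unscaled_rows``.
    """
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be one of {_SCALINGS}, got {scaling!r}")
    names = [c.value for c in CONGENERS]
    missing = [n for n in names if n not in records.columns]
    if missing:
        raise SchemaError(f"records missing congener columns {missing}")
    if group_by == "sample":
        cols = records["sample_id"] if "sample_id" in records.columns else records.index
        mat = records[names].astype(float).T
        mat.columns = [str(c) for c in cols]
    elif group_by in ("product", "brand"):
        if group_by not in records.columns:
            raise SchemaError(f"records missing grouping column {group_by!r}")
        # preserve first-appearance column order rather than sorting labels
        order = list(dict.fromkeys(records[group_by]))
        mat = records.groupby(group_by, sort=False)[names].mean().loc[order].T
    else:
        raise ValueError(f"group_by must be sample/product/brand, got {group_by!r}")
    if mat.shape[1] < 2:
        raise DataError(f"profile matrix needs >= 2 columns, got {mat.shape[1]}")

    unscaled: list[str] = []
    if scaling != "none":
        scaled = mat.copy()
        for row in mat.index:
            sd = mat.loc[row].std(ddof=1)
            # a spread at rounding level of the row magnitude is constant
            if sd <= 1e-12 * float(mat.loc[row].abs().max()):
                unscaled.append(str(row))
                continue
            if scaling == "row_z_score":
                scaled.loc[row] = (mat.loc[row] - mat.loc[row].mean()) / sd
            else:
                scaled.loc[row] = mat.loc[row] / sd
        mat = scaled
    return ProfileMatrix(data=mat, scaling=scaling, unscaled_rows=tuple(unscaled))


@dataclasses.dataclass(frozen=True)
class ClusterTree:
    """Agglomeration history over the matrix rows.

    ``merges`` lists (left, right, height, size) with node ids < n denoting
    leaves (in ``labels`` order) and id n + k the cluster formed by merge k.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    leaf_order: tuple[str, ...]
    metric: str
    linkage: str


def _pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def hierarchical_cluster(
    matrix: ProfileMatrix | pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of the matrix rows.

    Supports the Euclidean metric with average (default), complete, single
    or Ward linkage, via Lance-Williams distance updates. Ties are broken by
    the lexicographically smallest pair of cluster representatives (each
    cluster represented by its smallest leaf label), so the tree is fully
    deterministic.
    """
    data = matrix.data if isinstance(matrix, ProfileMatrix) else matrix
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    x = data.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DataError("profile matrix contains non-finite values")
    n = x.shape[0]
    if n < 2:
        raise DataError(f"need >= 2 rows to cluster, got {n}")
    labels = tuple(str(r) for r in data.index)

    dist = _pairwise_euclidean(x)
    active: dict[int, dict] = {
        i: {"size": 1, "repr": labels[i]} for i in range(n)
    }
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n

    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    while len(active) > 1:
        # pick the closest pair; ties resolved by representative labels
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                *sorted((active[kv[0][0]]["repr"], active[kv[0][1]]["repr"])),
            ),
        )
        (i, j), h = best
        ni, nj = active[i]["size"], active[j]["size"]
        new = next_id
        next_id += 1
        merges.append((i, j, h, ni + nj))
        children[new] = (i, j)
        rep = min(active[i]["repr"], active[j]["repr"])
        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k]["size"]
            dik, djk = d[key(i, k)], d[key(j, k)]
            if linkage == "single":
                dn = min(dik, djk)
            elif linkage == "complete":
                dn = max(dik, djk)
            elif linkage == "average":
                dn = (ni * dik + nj * djk) / (ni + nj)
            else:  # ward (Lance-Williams on Euclidean distances)
                dij = h
                dn = np.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                    / (ni + nj + nk)
                )
            d[key(new, k)] = float(dn)
        for k in list(d):
            if i in k or j in k:
                del d[k]
        del active[i], active[j]
        active[new] = {"size": ni + nj, "repr": rep}

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        l, r = children[node]
        return leaves(l) + leaves(r)

    order = tuple(labels[i] for i in leaves(next_id - 1))
    return ClusterTree(
        labels=labels,
        merges=tuple(merges),
        leaf_order=order,
        metric=metric,
        linkage=linkage,
    )


def export_tree(tree: ClusterTree) -> str:
    """Newick serialization with merge heights as ultrametric branch lengths.

    A node created at merge height h sits at ultrametric height h/2
    (midpoint allocation: the two leaves of a height-h merge are h apart
    along the tree). Branch lengths are parent height minus child height.
    """
    n = len(tree.labels)
    height = {i: 0.0 for i in range(n)}
    node_str = {i: tree.labels[i] for i in range(n)}
    for k, (l, r, h, _) in enumerate(tree.merges):
        node = n + k
        height[node] = h / 2.0
        bl_l = height[node] - height[l]
        bl_r = height[node] - height[r]
        node_str[node] = f"({node_str[l]}:{bl_l:.10g},{node_str[r]}:{bl_r:.10g})"
    return node_str[n + len(tree.merges) - 1] + ";"


def render_heatmap(
    matrix: ProfileMatrix | pd.DataFrame,
    path: str,
    row_tree: ClusterTree | None = None,
    col_tree: ClusterTree | None = None,
    cmap: str = "viridis",
) -> str:
    """Write a dendrogram-ordered heat map of the profile matrix to ``path``.

    Row (and optionally column) order follows the leaf order of the supplied
    cluster trees; output format is inferred from the file extension
    (PNG/SVG/PDF). Deterministic for fixed inputs.
    """
    from matplotlib.figure import Figure

    data = matrix.data if isinstance(matrix, ProfileMatrix) else matrix
    if not np.isfinite(data.to_numpy(dtype=float)).all():
        raise DataError("matrix contains non-finite values")
    if row_tree is not None:
        data = data.loc[list(row_tree.leaf_order)]
    if col_tree is not None:
        data = data[list(col_tree.leaf_order)]

    fig = Figure(figsize=(max(4.0, 0.6 * data.shape[1] + 2.5), 0.45 * data.shape[0] + 2.0))
    ax = fig.subplots()
    im = ax.imshow(data.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_yticks(range(data.shape[0]), [str(i) for i in data.index])
    ax.set_xticks(range(data.shape[1]), [str(c) for c in data.columns],
                  rotation=45, ha="right")
    label = "scaled concentration" if isinstance(matrix, ProfileMatrix) and matrix.scaling != "none" else "ng/g fat"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    return str(path)
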