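"""Habitat-use and habitat-availability operations.

Use proportions are computed per individual from pre-classified GPS fixes
(the land-cover class column is the interface; raster extraction happens
upstream).  Availability is the per-management-unit class distribution of
randomly sampled points; units are compared by a Pearson chi-square test on
the point counts and by an L1 (sum of absolute differences) distance matrix
that feeds a neighbor-joining tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    HABITAT_CLASSES,
    AvailabilityTable,
    HabitatUseTable,
    TranslocationTable,
    ValidationError,
)
from .genetics import PCAResult, _covariance_pca
from .io import TreeNode


def use_proportions(fixes: pd.DataFrame) -> HabitatUseTable:
    """Per-individual proportion of GPS fixes in each land-cover class."""
    bad = set(fixes["landcover"]) - set(HABITAT_CLASSES)
    if bad:
        raise ValidationError(f"unknown land-cover classes: {sorted(bad)}")
    counts = (
        fixes.groupby(["id", "landcover"], sort=True).size()
        .unstack(fill_value=0)
        .reindex(columns=list(HABITAT_CLASSES), fill_value=0)
    )
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise ValidationError(f"individuals with zero fixes: {empty}")
    props = counts.div(totals, axis=0)
    return HabitatUseTable(
        [str(i) for i in counts.index],
        props.to_numpy(float),
        fix_counts=totals.to_numpy(),
    )


def arcsine_sqrt(use: HabitatUseTable | np.ndarray) -> np.ndarray:
    """Element-wise arcsine-square-root transform of proportions.

    Maps [0, 1] onto [0, pi/2]; the variance-stabilising transform for
    proportions, applied before clustering and PCA.
    """
    p = use.proportions if isinstance(use, HabitatUseTable) else np.asarray(use, float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def habitat_pca(transformed: np.ndarray, n_axes: int = 3) -> PCAResult:
    """Covariance PCA of the transformed 7-column habitat-use matrix."""
    X = np.asarray(transformed, dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 individuals")
    return _covariance_pca(X, n_axes)


# ---------------------------------------------------------------------------
# availability


def availability_from_points(points: pd.DataFrame) -> AvailabilityTable:
    """Per-unit class proportions of randomly sampled, pre-classified points.

    ``points`` needs 'unit' and 'landcover' columns; every unit must be
    sampled at least once.
    """
    bad = set(points["landcover"]) - set(HABITAT_CLASSES)
    if bad:
        raise ValidationError(f"unknown land-cover classes: {sorted(bad)}")
    counts = (
        points.groupby(["unit", "landcover"], sort=True).size()
        .unstack(fill_value=0)
        .reindex(columns=list(HABITAT_CLASSES), fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError(
            f"units with zero sampled points: {totals[totals == 0].index.tolist()}"
        )
    props = counts.div(totals, axis=0)
    return AvailabilityTable(
        [str(u) for u in counts.index], props.to_numpy(float), totals.to_numpy()
    )


def availability_chi2(a: AvailabilityTable) -> tuple[float, int, float]:
    """Pearson chi-square heterogeneity test on the units x classes counts.

    Returns (chi2, df, p) with df = (U-1)(C-1).  The test runs on point
    counts (proportions alone carry no sample-size information); a zero
    expected count is an error advising class pooling.
    """
    counts = a.counts()
    col = counts.sum(axis=0)
    if (col == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError(
            "zero expected count; pool rare land-cover classes before testing"
        )
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def availability_distance(a: AvailabilityTable, mode: str = "sum") -> np.ndarray:
    """Unit x unit distance: sum (default) or mean of |availability diffs|."""
    if len(a.units) < 2:
        raise ValidationError("need at least 2 units")
    if mode not in ("sum", "mean"):
        raise ValidationError("mode must be 'sum' or 'mean'")
    P = a.proportions
    d = np.abs(P[:, None, :] - P[None, :, :]).sum(axis=2)
    if mode == "mean":
        d /= P.shape[1]
    return d


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(d: np.ndarray, taxa: list[str],
                     clamp_negative: bool = False) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric zero-diagonal matrix.

    Agglomerates by the Q-criterion, with ties broken by lowest (row,
    column) index for determinism.  Negative limb lengths are retained by
    default (``clamp_negative=True`` floors them at 0).  The result is an
    unrooted tree represented by a root of degree 3.
    """
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(taxa) != n:
        raise ValidationError("distance matrix / taxa size mismatch")
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValidationError("distance matrix must have a zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    D = D.copy()
    active = list(range(n))

    def limb(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) tie-break: argmin on the flattened matrix scans
        # row-major, returning the first minimum
        flat = np.argmin(Q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        a, b = active[i], active[j]
        nodes[a].length = limb(li)
        nodes[b].length = limb(lj)
        parent = TreeNode(children=[nodes[a], nodes[b]])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[a, :] + D[b, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]

    a, b, c = active
    # final star: limb lengths from the three-point formulas
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = limb(ln)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_path_lengths(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]

    # accumulate distances from each node down to its leaves
    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        combined: dict[str, float] = {}
        groups = []
        for c in node.children:
            sub = collect(c)
            sub = {k: v + (c.length or 0.0) for k, v in sub.items()}
            groups.append(sub)
            combined.update(sub)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for na, da in groups[gi].items():
                    for nb, db in groups[gj].items():
                        dist[(na, nb)] = dist[(nb, na)] = da + db
        return combined

    dist: dict[tuple[str, str], float] = {}
    collect(tree)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = dist[(names[i], names[j])]
    return names, out


# ---------------------------------------------------------------------------
# translocations


@dataclass
class TranslocationSummary:
    """Counts, percentages and the unit-to-unit flow matrix."""

    n_total: int
    n_cross_unit: int
    n_northward: int           # among cross-unit events
    pct_cross_unit: float | None       # percentage, unrounded
    pct_northward: float | None        # percentage of cross-unit, unrounded
    pct_cross_unit_rounded: int | None   # nearest integer
    pct_northward_rounded_ten: int | None  # nearest ten
    flow: pd.DataFrame         # source x destination counts


def translocation_summary(t: TranslocationTable,
                          unit_order: list[str]) -> TranslocationSummary:
    """Summarise translocation events against a south-to-north unit order."""
    ev = t.events
    present = set(ev["source_unit"]) | set(ev["dest_unit"])
    missing = present - set(unit_order)
    if missing:
        raise ValidationError(f"units absent from ordering: {sorted(missing)}")
    rank = {u: k for k, u in enumerate(unit_order)}
    total = len(ev)
    flow = (
        ev.groupby(["source_unit", "dest_unit"]).size().unstack(fill_value=0)
        .reindex(index=unit_order, columns=unit_order, fill_value=0)
    )
    if total == 0:
        return TranslocationSummary(0, 0, 0, None, None, None, None, flow)
    src = ev["source_unit"].map(rank)
    dst = ev["dest_unit"].map(rank)
    cross = dst != src
    north = cross & (dst > src)
    n_cross, n_north = int(cross.sum()), int(north.sum())
    pct_cross = 100.0 * n_cross / total
    pct_north = 100.0 * n_north / n_cross if n_cross else None
    return TranslocationSummary(
        n_total=total,
        n_cross_unit=n_cross,
        n_northward=n_north,
        pct_cross_unit=pct_cross,
        pct_northward=pct_north,
        pct_cross_unit_rounded=int(round(pct_cross)),
        pct_northward_rounded_ten=(int(round(pct_north / 10.0) * 10)
                                   if pct_north is not None else None),
        flow=flow,
    )
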