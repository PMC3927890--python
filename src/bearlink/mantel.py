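"""Individual-based isolation-by-ecology matrices and Mantel machinery.

Builds the four matrix families used in the individual-based test battery
-- genetic similarity G (relatedness or coancestry), geographic distance D,
sex similarity S (0 F/F, 0.5 F/M, 1 M/M), and ecological divergence E^PCa
(absolute difference of habitat-use PC scores on axis a) -- and runs simple
and partial Mantel permutation tests over them.

Orientation note: G is a similarity while D and E are distances, so a
*negative* G~E correlation means related pairs use similar habitat.  The
matrices are used exactly as supplied; no sign flipping happens anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import PairwiseMatrix, ValidationError


# ---------------------------------------------------------------------------
# matrix builders


def geographic_distance(coords: np.ndarray, ids: list[str]) -> PairwiseMatrix:
    """Euclidean distance between planar capture coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(ids), 2):
        raise ValidationError("coords must be (n, 2) planar x,y")
    if np.isnan(coords).any():
        bad = [ids[i] for i in np.nonzero(np.isnan(coords).any(axis=1))[0]]
        raise ValidationError(f"missing coordinates for: {bad}")
    d = squareform(pdist(coords, metric="euclidean"))
    return PairwiseMatrix(list(ids), d, kind="geographic")


def sex_matrix(sexes: list[str], ids: list[str]) -> PairwiseMatrix:
    """Pairwise sex coding: F/F = 0, F/M = 0.5, M/M = 1."""
    codes = []
    for s in sexes:
        if s not in ("F", "M"):
            raise ValidationError(f"unknown sex code {s!r} (expected 'F' or 'M')")
        codes.append(0.0 if s == "F" else 1.0)
    v = np.asarray(codes)
    mat = 0.5 * (v[:, None] + v[None, :])
    return PairwiseMatrix(list(ids), mat, kind="sex")


def ecological_distance(pc_scores: np.ndarray, axis: int,
                        ids: list[str], max_axis: int = 3) -> PairwiseMatrix:
    """Absolute difference of habitat-use PC scores on one axis (1-based)."""
    scores = np.asarray(pc_scores, dtype=float)
    if not (1 <= axis <= min(max_axis, scores.shape[1])):
        raise ValidationError(f"axis {axis} out of range 1..{min(max_axis, scores.shape[1])}")
    s = scores[:, axis - 1]
    mat = np.abs(s[:, None] - s[None, :])
    return PairwiseMatrix(list(ids), mat, kind=f"ecological-PC{axis}")


# ---------------------------------------------------------------------------
# Mantel tests


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    ci_low: float
    ci_high: float
    controls: tuple[str, ...] = ()
    alternative: str = "auto"

    def summary(self) -> str:
        ctrl = f" | {'+'.join(self.controls)}" if self.controls else ""
        return (f"Mantel{ctrl}: r = {self.r:+.3f}, one-sided p = {self.p:.4f} "
                f"({self.n_perm} permutations), 95% CI [{self.ci_low:+.3f}, "
                f"{self.ci_high:+.3f}]")


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n, k=-1)


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    du, dv = np.sqrt((u * u).sum()), np.sqrt((v * v).sum())
    if du == 0 or dv == 0:
        raise ValidationError("zero variance in a triangle vector: test undefined")
    return float((u * v).sum() / (du * dv))


def _check_pair(a: PairwiseMatrix, b: PairwiseMatrix) -> None:
    if a.ids != b.ids:
        raise ValidationError("matrices must share the same individuals in order")


def _perm_null(values: np.ndarray, vb: np.ndarray, n_perm: int,
               rng: np.random.Generator) -> np.ndarray:
    """Correlations of vb with row/column-permuted `values` triangles."""
    n = values.shape[0]
    ti, tj = _tri_indices(n)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    pa = values[perms[:, ti], perms[:, tj]]  # (n_perm, n_pairs)
    pa = pa - pa.mean(axis=1, keepdims=True)
    vbc = vb - vb.mean()
    denom = np.sqrt((pa * pa).sum(axis=1)) * np.sqrt((vbc * vbc).sum())
    return (pa @ vbc) / denom


def _pvalue(obs: float, null: np.ndarray, alternative: str) -> float:
    n_perm = len(null)
    if alternative == "auto":
        alternative = "greater" if obs >= 0 else "less"
    if alternative == "greater":
        extreme = int((null >= obs).sum())
    elif alternative == "less":
        extreme = int((null <= obs).sum())
    elif alternative == "two-sided":
        extreme = int((np.abs(null) >= abs(obs)).sum())
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return (extreme + 1) / (n_perm + 1)


def _bootstrap_ci(a: np.ndarray, b: np.ndarray, n_boot: int,
                  rng: np.random.Generator,
                  resid_bases: tuple[np.ndarray, ...] = ()) -> tuple[float, float]:
    """Percentile CI by resampling individuals.

    Pairs in which the same original individual appears twice are dropped
    from each bootstrap replicate (their distance is a structural zero, not
    data).  When `resid_bases` is given (partial test), the control
    residualisation is redone inside each replicate.
    """
    n = a.shape[0]
    ti, tj = _tri_indices(n)
    rs = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        keep = idx[ti] != idx[tj]
        if keep.sum() < 3:
            continue
        va = a[idx[ti], idx[tj]][keep]
        vb = b[idx[ti], idx[tj]][keep]
        try:
            if resid_bases:
                C = np.column_stack(
                    [np.ones(keep.sum())]
                    + [c[idx[ti], idx[tj]][keep] for c in resid_bases]
                )
                va = va - C @ np.linalg.lstsq(C, va, rcond=None)[0]
                vb = vb - C @ np.linalg.lstsq(C, vb, rcond=None)[0]
            rs.append(_corr(va, vb))
        except ValidationError:
            continue
    if not rs:
        return (np.nan, np.nan)
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def mantel(a: PairwiseMatrix, b: PairwiseMatrix, n_perm: int = 10_000,
           seed: int = 0, alternative: str = "auto",
           n_boot: int = 1_000, ci_method: str = "bootstrap") -> MantelResult:
    """Simple Mantel test between two pairwise matrices.

    r is the Pearson correlation of the strictly-lower-triangle vectors;
    the null permutes rows and columns of `a` simultaneously.  The
    one-sided p follows the sign of the observed r by default
    (``alternative='auto'``); fixed directions and a two-sided test are
    available.  The 95% CI resamples individuals (percentile bootstrap);
    ``ci_method='permutation'`` instead reports the null-quantile band
    centred conventions of permutation software.
    """
    _check_pair(a, b)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = a.n
    ti, tj = _tri_indices(n)
    va, vb = a.values[ti, tj], b.values[ti, tj]
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValidationError("NaN entries in matrix triangle")
    r = _corr(va, vb)
    rng = np.random.default_rng(seed)
    null = _perm_null(a.values, vb, n_perm, rng)
    p = _pvalue(r, null, alternative)
    if ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(a.values, b.values, n_boot, rng)
    elif ci_method == "permutation":
        qlo, qhi = np.percentile(null, [2.5, 97.5])
        lo, hi = r - (qhi - 0.0), r - (qlo - 0.0)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    lo, hi = min(lo, r), max(hi, r)
    return MantelResult(r, p, n_perm, lo, hi, (), alternative)


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    C = np.column_stack([np.ones(len(v)), controls])
    cond = np.linalg.cond(C)
    if cond > 1e8:
        raise ValidationError(f"collinear control matrices (condition {cond:.2g})")
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def partial_mantel(a: PairwiseMatrix, b: PairwiseMatrix,
                   controls: list[PairwiseMatrix], n_perm: int = 10_000,
                   seed: int = 0, alternative: str = "auto",
                   n_boot: int = 1_000) -> MantelResult:
    """Partial Mantel test controlling for one or two matrices.

    Both triangle vectors are residualised by OLS (with intercept) on the
    control triangles; r is the correlation of the residuals.  The
    permutation null follows Legendre's residual method: the residuals of
    `a` are reconstituted into a symmetric matrix whose rows/columns are
    permuted jointly.
    """
    _check_pair(a, b)
    if not 1 <= len(controls) <= 2:
        raise ValidationError("need 1 or 2 control matrices")
    for c in controls:
        _check_pair(a, c)
    n = a.n
    ti, tj = _tri_indices(n)
    va, vb = a.values[ti, tj], b.values[ti, tj]
    ctrl = np.column_stack([c.values[ti, tj] for c in controls])
    ra = _residualize(va, ctrl)
    rb = _residualize(vb, ctrl)
    for name, res, orig in (("a", ra, va), ("b", rb, vb)):
        scale = float(((orig - orig.mean()) ** 2).sum())
        if float((res**2).sum()) <= 1e-16 * max(scale, 1e-300):
            raise ValidationError(
                f"matrix {name} is fully explained by the controls: "
                "partial test undefined")
    r = _corr(ra, rb)

    res_mat = np.zeros((n, n))
    res_mat[ti, tj] = ra
    res_mat = res_mat + res_mat.T
    rng = np.random.default_rng(seed)
    null = _perm_null(res_mat, rb, n_perm, rng)
    p = _pvalue(r, null, alternative)
    lo, hi = _bootstrap_ci(a.values, b.values, n_boot, rng,
                           resid_bases=tuple(c.values for c in controls))
    lo, hi = min(lo, r), max(hi, r)
    return MantelResult(r, p, n_perm, lo, hi,
                        tuple(c.kind for c in controls), alternative)


# ---------------------------------------------------------------------------
# the full test battery


def ibe_suite(G: dict[str, PairwiseMatrix], D: PairwiseMatrix,
              S: PairwiseMatrix, E: list[PairwiseMatrix],
              n_perm: int = 10_000, seed: int = 0,
              n_boot: int = 500) -> pd.DataFrame:
    """Run the individual-based isolation-by-ecology battery.

    For each genetic metric in ``G`` (e.g. relatedness and coancestry) the
    suite runs, per ecological axis a: S~E^a and E^a~D (null models) and
    G~E^a (ecological divergence); plus G~D, G~S, and the two partial
    models G~D|E*+S and G~E*|D+S, where E* is the axis with the strongest
    simple |G~E| correlation for that metric.  Returns a tidy table with
    one row per test.
    """
    rows = []
    run_seed = iter(range(seed, seed + 10_000))
    for metric, g in G.items():
        per_axis_r = {}
        for e in E:
            res = mantel(S, e, n_perm, next(run_seed), n_boot=n_boot)
            rows.append(("S ~ " + e.kind, metric, res))
            res = mantel(e, D, n_perm, next(run_seed), n_boot=n_boot)
            rows.append((e.kind + " ~ D", metric, res))
            res = mantel(g, e, n_perm, next(run_seed), n_boot=n_boot)
            per_axis_r[e.kind] = abs(res.r)
            rows.append(("G ~ " + e.kind, metric, res))
        rows.append(("G ~ D", metric, mantel(g, D, n_perm, next(run_seed), n_boot=n_boot)))
        rows.append(("G ~ S", metric, mantel(g, S, n_perm, next(run_seed), n_boot=n_boot)))
        star = max(per_axis_r, key=per_axis_r.get)
        e_star = next(e for e in E if e.kind == star)
        rows.append((f"G ~ D | {star}+S", metric,
                     partial_mantel(g, D, [e_star, S], n_perm, next(run_seed),
                                    n_boot=n_boot)))
        rows.append((f"G ~ {star} | D+S", metric,
                     partial_mantel(g, e_star, [D, S], n_perm, next(run_seed),
                                    n_boot=n_boot)))
    return pd.DataFrame(
        [
            {
                "test": name,
                "genetic_metric": metric,
                "r": res.r,
                "p": res.p,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "controls": "+".join(res.controls),
                "n_perm": res.n_perm,
                "significant_0.05": res.p <= 0.05,
            }
            for name, metric, res in rows
        ]
    )
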