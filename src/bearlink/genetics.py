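"""Individual and pairwise genetic statistics for microsatellite panels.

Covers allele frequencies, observed/expected heterozygosity, a Monte-Carlo
Hardy-Weinberg exact test, homozygosity by loci (HL), Queller-Goodnight
pairwise relatedness, allele-sharing molecular coancestry, and a
covariance-matrix PCA of the genotypes.

HL weights each locus by its expected heterozygosity, so homozygosity at
an informative locus counts for more than at a near-monomorphic one:

    HL_i = sum_{l in hom(i)} E_l / (sum_{l in hom(i)} E_l + sum_{l in het(i)} E_l)

with E_l = 1 - sum_a p_a^2 computed from the full sample and missing loci
excluded from both sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeTable, PairwiseMatrix, ValidationError


@dataclass
class AlleleFrequencies:
    """Per-locus relative allele frequencies over non-missing gene copies."""

    loci: list[str]
    freqs: list[dict[int, float]]  # one {allele_code: frequency} per locus

    def expected_heterozygosity(self, unbiased: bool = False,
                                n_copies: list[int] | None = None) -> np.ndarray:
        """He = 1 - sum p^2 per locus; optional small-sample correction.

        The unbiased variant multiplies by 2n/(2n-1) with 2n the number of
        gene copies actually observed at the locus.
        """
        he = np.array([1.0 - sum(p * p for p in f.values()) for f in self.freqs])
        if unbiased:
            if n_copies is None:
                raise ValidationError("unbiased He needs per-locus copy counts")
            nc = np.asarray(n_copies, dtype=float)
            he = he * nc / (nc - 1.0)
        return he


def allele_frequencies(g: GenotypeTable) -> AlleleFrequencies:
    """Tally relative allele frequencies per locus over non-missing calls."""
    freqs = []
    for j, locus in enumerate(g.loci):
        calls = g.alleles[:, j, :].ravel()
        calls = calls[calls > 0]
        if calls.size == 0:
            raise ValidationError(f"locus {locus!r} has no non-missing calls")
        codes, counts = np.unique(calls, return_counts=True)
        total = counts.sum()
        freqs.append({int(c): n / total for c, n in zip(codes, counts)})
    return AlleleFrequencies(list(g.loci), freqs)


def _copies_per_locus(g: GenotypeTable) -> list[int]:
    present = ~g.missing_mask()
    return [int(2 * present[:, j].sum()) for j in range(g.n_loci)]


@dataclass
class HeterozygosityReport:
    loci: list[str]
    ho: np.ndarray         # per-locus observed heterozygosity
    he: np.ndarray         # per-locus expected heterozygosity (sample)
    he_unbiased: np.ndarray
    mean_ho: float
    mean_he: float


def heterozygosities(g: GenotypeTable) -> HeterozygosityReport:
    """Observed and expected heterozygosity per locus and averaged."""
    af = allele_frequencies(g)
    present = ~g.missing_mask()
    het = (g.alleles[:, :, 0] != g.alleles[:, :, 1]) & present
    with np.errstate(invalid="ignore"):
        ho = het.sum(axis=0) / present.sum(axis=0)
    he = af.expected_heterozygosity()
    he_u = af.expected_heterozygosity(unbiased=True, n_copies=_copies_per_locus(g))
    return HeterozygosityReport(list(g.loci), ho, he, he_u,
                                float(np.mean(ho)), float(np.mean(he)))


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(g: GenotypeTable, locus: str, n_perm: int = 10_000,
             seed: int = 0) -> tuple[int, float]:
    """Monte-Carlo exact test of Hardy-Weinberg proportions at one locus.

    The observed heterozygote count is compared with counts from genotype
    tables obtained by randomly re-pairing the pooled gene copies.  The
    two-sided p-value is (# permuted tables with |het - mean| >= |obs -
    mean| + 1) / (n_perm + 1), where the mean is over the permutation null.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    j = g.loci.index(locus)
    calls = g.alleles[:, j, :]
    calls = calls[calls[:, 0] > 0]
    if np.unique(calls).size < 2:
        raise ValidationError(f"HWE test undefined for monomorphic locus {locus!r}")
    obs = int((calls[:, 0] != calls[:, 1]).sum())

    rng = np.random.default_rng(seed)
    pool = calls.ravel().copy()
    m = len(calls)
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        rng.shuffle(pool)
        pairs = pool.reshape(m, 2)
        null[b] = (pairs[:, 0] != pairs[:, 1]).sum()
    centre = null.mean()
    p = (np.count_nonzero(np.abs(null - centre) >= abs(obs - centre)) + 1) / (n_perm + 1)
    return obs, float(p)


# ---------------------------------------------------------------------------
# homozygosity by loci


def homozygosity_by_loci(g: GenotypeTable, unbiased_he: bool = False) -> np.ndarray:
    """Per-individual HL in [0, 1]; 0 = fully heterozygous, 1 = fully homozygous."""
    af = allele_frequencies(g)
    he = af.expected_heterozygosity(
        unbiased=unbiased_he,
        n_copies=_copies_per_locus(g) if unbiased_he else None,
    )
    present = ~g.missing_mask()
    if (~present).all(axis=1).any():
        bad = [g.ids[i] for i in np.nonzero((~present).all(axis=1))[0]]
        raise ValidationError(f"individuals with all loci missing: {bad}")
    hom = (g.alleles[:, :, 0] == g.alleles[:, :, 1]) & present
    num = (hom * he).sum(axis=1)
    den = (present * he).sum(axis=1)
    return num / den


def single_locus_homozygosities(g: GenotypeTable) -> np.ndarray:
    """(n, L) float array: 1 homozygous, 0 heterozygous, NaN missing."""
    out = (g.alleles[:, :, 0] == g.alleles[:, :, 1]).astype(float)
    out[g.missing_mask()] = np.nan
    return out


# ---------------------------------------------------------------------------
# pairwise relatedness / coancestry


def _freq_arrays(g: GenotypeTable) -> np.ndarray:
    """(n, L, 2) array of the sample frequency of each carried allele."""
    af = allele_frequencies(g)
    pf = np.zeros(g.alleles.shape, dtype=float)
    for j in range(g.n_loci):
        lookup = af.freqs[j]
        for c in (0, 1):
            col = g.alleles[:, j, c]
            pf[:, j, c] = [lookup.get(int(a), 0.0) for a in col]
    return pf


def qg_relatedness(g: GenotypeTable) -> PairwiseMatrix:
    """Queller-Goodnight pairwise relatedness, symmetrised.

    For focal x with alleles (a, b) and partner y with (c, d), each locus
    contributes numerator 0.5*(d_ac + d_ad + d_bc + d_bd) - p_a - p_b and
    denominator 1 + d_ab - p_a - p_b (d_* are identity indicators, p the
    sample frequencies).  The estimate is the ratio of locus-summed sums;
    the reported value is the mean of the two ordered estimates.  Loci
    missing in either member are excluded pairwise; a pair sharing no typed
    locus is flagged NaN.
    """
    if g.n_individuals < 2:
        raise ValidationError("relatedness needs at least 2 individuals")
    n, L = g.n_individuals, g.n_loci
    A = g.alleles
    pf = _freq_arrays(g)
    present = ~g.missing_mask()

    vals = np.zeros((n, n))
    np.fill_diagonal(vals, np.nan)
    for x in range(n):
        ax, bx = A[x, :, 0], A[x, :, 1]
        px = pf[x, :, 0] + pf[x, :, 1]
        for y in range(x + 1, n):
            shared = present[x] & present[y]
            if not shared.any():
                vals[x, y] = vals[y, x] = np.nan
                continue
            ay, by = A[y, :, 0], A[y, :, 1]
            sim = ((ax == ay).astype(float) + (ax == by) + (bx == ay) + (bx == by))
            # ordered estimate with x focal
            num_x = 0.5 * sim - px
            den_x = 1.0 + (ax == bx) - px
            py = pf[y, :, 0] + pf[y, :, 1]
            num_y = 0.5 * sim - py
            den_y = 1.0 + (ay == by) - py
            rx = num_x[shared].sum() / den_x[shared].sum()
            ry = num_y[shared].sum() / den_y[shared].sum()
            vals[x, y] = vals[y, x] = 0.5 * (rx + ry)
    # self-relatedness of a fully typed individual, via the same formula
    for x in range(n):
        sh = present[x]
        px = pf[x, :, 0] + pf[x, :, 1]
        hom = (A[x, :, 0] == A[x, :, 1]).astype(float)
        num = 0.5 * (2.0 + 2.0 * hom) - px
        den = 1.0 + hom - px
        vals[x, x] = num[sh].sum() / den[sh].sum()
    return PairwiseMatrix(list(g.ids), vals, kind="relatedness")


def molecular_coancestry(g: GenotypeTable) -> PairwiseMatrix:
    """Allele-sharing (Malecot-style) coancestry.

    f_xy is the mean over shared typed loci of (d_ac+d_ad+d_bc+d_bd)/4 —
    the probability that one allele drawn from each individual at a locus
    is identical in state.
    """
    if g.n_individuals < 2:
        raise ValidationError("coancestry needs at least 2 individuals")
    n = g.n_individuals
    A = g.alleles
    present = ~g.missing_mask()
    vals = np.zeros((n, n))
    for x in range(n):
        ax, bx = A[x, :, 0], A[x, :, 1]
        for y in range(x, n):
            shared = present[x] & present[y]
            if not shared.any():
                vals[x, y] = vals[y, x] = np.nan
                continue
            ay, by = A[y, :, 0], A[y, :, 1]
            sim = ((ax == ay).astype(float) + (ax == by) + (bx == ay) + (bx == by)) / 4.0
            vals[x, y] = vals[y, x] = sim[shared].mean()
    return PairwiseMatrix(list(g.ids), vals, kind="coancestry")


# ---------------------------------------------------------------------------
# genotype PCA


@dataclass
class PCAResult:
    scores: np.ndarray          # (n, n_axes)
    percent_variance: np.ndarray  # (n_axes,)
    loadings: np.ndarray        # (p, n_axes)


def _covariance_pca(X: np.ndarray, n_axes: int) -> PCAResult:
    """Covariance-matrix PCA with the sign convention that each axis's
    largest-|loading| element is positive."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    rank = int((evals > max(evals.max(), 1e-300) * 1e-12).sum())
    if n_axes > rank:
        raise ValidationError(f"n_axes={n_axes} exceeds data rank {rank}")
    evecs = evecs[:, :n_axes]
    for a in range(n_axes):
        pivot = np.argmax(np.abs(evecs[:, a]))
        if evecs[pivot, a] < 0:
            evecs[:, a] = -evecs[:, a]
    scores = Xc @ evecs
    total = evals.sum()
    pct = 100.0 * evals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return PCAResult(scores, pct, evecs)


def genotype_indicator_matrix(g: GenotypeTable) -> np.ndarray:
    """Individuals x allele-indicator matrix of per-allele counts (0/1/2).

    Missing genotypes are column-mean imputed before centering.
    """
    af = allele_frequencies(g)
    cols = []
    present = ~g.missing_mask()
    for j in range(g.n_loci):
        codes = sorted(af.freqs[j])
        for code in codes:
            cnt = (g.alleles[:, j, :] == code).sum(axis=1).astype(float)
            obs = present[:, j]
            if (~obs).any():
                cnt[~obs] = cnt[obs].mean()
            cols.append(cnt)
    return np.column_stack(cols)


def genotype_pca(g: GenotypeTable, n_axes: int = 3) -> PCAResult:
    """Covariance PCA of the allele-count indicator matrix."""
    if g.n_individuals < 3:
        raise ValidationError("PCA needs at least 3 individuals")
    return _covariance_pca(genotype_indicator_matrix(g), n_axes)
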