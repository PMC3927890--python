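"""Ecotype and genotype clustering.

Two complementary clustering routes:

* habitat-use ecotypes: hard K-means solved by simulated annealing on the
  arcsine-square-root-transformed proportions, with the number of clusters
  selected by spherical-Gaussian BIC and the Calinski-Harabasz pseudo-F.
  Squaring the absolute difference in proportions is exactly the squared
  Euclidean distance, so centroid-based within-group SSE is the objective.

* genetic clusters: an admixture-model Gibbs sampler (uncorrelated
  Dirichlet(1) cluster allele frequencies, Dirichlet(alpha) individual
  membership), with the number of clusters chosen by the Evanno
  second-difference statistic on replicate mean log-likelihoods and hard
  assignments by highest Q.

The two assignment vectors are compared by a plain Pearson correlation of
the integer labels, together with a relabeling-sensitivity report (the
correlation depends on the arbitrary ordering of categorical labels).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import GenotypeTable, ValidationError


# ---------------------------------------------------------------------------
# K-means by simulated annealing


@dataclass
class ClusterSolution:
    k: int
    assignment: np.ndarray     # (n,) labels in 1..k
    sse: float
    restarts: int
    bic: float | None = None
    pseudo_f: float | None = None


def _sse(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    total = 0.0
    for g in range(1, k + 1):
        pts = X[labels == g]
        if len(pts):
            c = pts.mean(axis=0)
            total += ((pts - c) ** 2).sum()
    return total


def sa_kmeans(X: np.ndarray, k: int, steps: int = 20_000, restarts: int = 5,
              seed: int = 0, t0_fraction: float = 0.01,
              t_end_fraction: float = 1e-6) -> ClusterSolution:
    """Minimise within-group SSE by simulated annealing.

    Proposal: move one random individual to a random other group; accept
    improvements always and deteriorations with probability
    exp(-dSSE / T) under geometric cooling from T0 (a fraction of the
    initial SSE) to t_end_fraction * T0.  The best state over all restarts
    and steps is returned.  With k = 1 the answer is closed-form: all
    points in one group, SSE = total centred sum of squares.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    if k == 1:
        labels = np.ones(n, dtype=np.int64)
        return ClusterSolution(1, labels, _sse(X, labels, 1), restarts)

    rng = np.random.default_rng(seed)
    best_labels, best_sse = None, np.inf
    for _ in range(restarts):
        labels = rng.integers(1, k + 1, size=n)
        # group sufficient statistics for O(d) move evaluation
        sums = np.zeros((k + 1, d))
        cnts = np.zeros(k + 1, dtype=np.int64)
        for g in range(1, k + 1):
            sums[g] = X[labels == g].sum(axis=0)
            cnts[g] = (labels == g).sum()
        sse = _sse(X, labels, k)
        t0 = max(t0_fraction * sse, 1e-12)
        t_end = t_end_fraction * t0
        cool = (t_end / t0) ** (1.0 / max(steps - 1, 1))
        T = t0
        cur_best_sse, cur_best_labels = sse, labels.copy()
        for _step in range(steps):
            i = rng.integers(n)
            a = labels[i]
            b = rng.integers(1, k + 1)
            if b == a:
                T *= cool
                continue
            xa = X[i]
            na, nb = cnts[a], cnts[b]
            ca = sums[a] / na
            gain = 0.0 if na == 1 else (na / (na - 1.0)) * float(((xa - ca) ** 2).sum())
            if nb == 0:
                cost = 0.0
            else:
                cb = sums[b] / nb
                cost = (nb / (nb + 1.0)) * float(((xa - cb) ** 2).sum())
            delta = cost - gain
            if delta <= 0 or rng.random() < math.exp(-delta / T):
                labels[i] = b
                sums[a] -= xa
                sums[b] += xa
                cnts[a] -= 1
                cnts[b] += 1
                sse += delta
                if sse < cur_best_sse - 1e-12:
                    cur_best_sse, cur_best_labels = sse, labels.copy()
            T *= cool
        if cur_best_sse < best_sse:
            best_sse, best_labels = cur_best_sse, cur_best_labels
    best_sse = _sse(X, best_labels, k)  # recompute to kill float drift
    return ClusterSolution(k, best_labels, best_sse, restarts)


def pseudo_f(solution: ClusterSolution, X: np.ndarray) -> float:
    """Calinski-Harabasz index (SSB/(k-1)) / (SSW/(n-k)).

    Returns +inf when SSW is 0 (perfect separation) and is undefined
    (error) at k = 1 or k = n.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = solution.k
    if k <= 1 or k >= n:
        raise ValidationError("pseudo-F undefined for k=1 or k=n")
    grand = X.mean(axis=0)
    ssb = 0.0
    for g in range(1, k + 1):
        pts = X[solution.assignment == g]
        if len(pts):
            ssb += len(pts) * float(((pts.mean(axis=0) - grand) ** 2).sum())
    ssw = _sse(X, solution.assignment, k)
    if ssw == 0.0:
        return math.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def kmeans_bic(solution: ClusterSolution, X: np.ndarray) -> float:
    """Spherical-Gaussian BIC: n*d*ln(SSE/(n*d)) + k*d*ln(n); argmin selects k."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if solution.sse == 0.0:
        return -math.inf
    return n * d * math.log(solution.sse / (n * d)) + solution.k * d * math.log(n)


def kmeans_scan(X: np.ndarray, k_values: range | list[int],
                steps: int = 20_000, restarts: int = 5,
                seed: int = 0) -> list[ClusterSolution]:
    """Run sa_kmeans over a range of k and attach BIC / pseudo-F."""
    out = []
    for idx, k in enumerate(k_values):
        sol = sa_kmeans(X, k, steps=steps, restarts=restarts, seed=seed + idx)
        sol.bic = kmeans_bic(sol, X)
        if 1 < k < X.shape[0]:
            sol.pseudo_f = pseudo_f(sol, X)
        out.append(sol)
    return out


# ---------------------------------------------------------------------------
# admixture-model Gibbs sampler


@dataclass
class AdmixtureResult:
    k: int
    Q: np.ndarray                 # (n, k) posterior-mean memberships
    allele_freqs: list            # per locus (k, A) posterior-mean frequencies
    mean_loglik: float            # mean over retained sweeps
    loglik_trace: np.ndarray      # per retained sweep
    assignment: np.ndarray = field(init=False)  # argmax Q, labels 1..k

    def __post_init__(self) -> None:
        self.assignment = np.argmax(self.Q, axis=1) + 1


def _genotype_copies(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Flatten genotypes into per-copy (allele-index, locus-index) arrays.

    Returns (codes (n, 2L) zero-based allele indices with -1 missing,
    locus index per copy (2L,), per-locus allele counts, max alleles).
    """
    n, L, _ = g.alleles.shape
    counts = []
    codes = np.empty((n, 2 * L), dtype=np.int64)
    maps = []
    for j in range(g.n_loci):
        observed = np.unique(g.alleles[:, j, :][g.alleles[:, j, :] > 0])
        lookup = {int(c): idx for idx, c in enumerate(observed)}
        maps.append(lookup)
        counts.append(len(observed))
        for c in (0, 1):
            col = g.alleles[:, j, c]
            codes[:, 2 * j + c] = [lookup.get(int(a), -1) for a in col]
    loc_idx = np.repeat(np.arange(L), 2)
    # interleave copy columns as (locus0 copy0, locus0 copy1, ...)
    order = np.arange(2 * L)
    return codes[:, order], loc_idx, np.array(counts), int(max(counts))


def admixture_loglik(codes: np.ndarray, loc_idx: np.ndarray,
                     p: np.ndarray, q: np.ndarray) -> float:
    """log P(genotypes | p, q) with per-copy mixture over cluster origins."""
    valid = codes >= 0
    safe = np.where(valid, codes, 0)
    like = p[:, loc_idx[None, :], safe]       # (k, n, 2L)
    mix = np.einsum("ik,kic->ic", q, like)    # (n, 2L)
    return float(np.log(mix[valid]).sum())


def admixture_gibbs(g: GenotypeTable, k: int, iterations: int = 20_000,
                    burn_in_fraction: float = 0.2, replicates: int = 1,
                    seed: int = 0, alpha: float = 1.0,
                    thin: int = 10) -> list[AdmixtureResult]:
    """Admixture-model Gibbs sampling of cluster memberships.

    Model: each allele copy of individual i originates from cluster z with
    P(z=c) proportional to q_i[c] * p_c(locus, allele); cluster allele
    frequencies get a Dirichlet(1) prior (conjugate, uncorrelated across
    clusters) and individual membership vectors q_i a Dirichlet(alpha)
    prior.  Q is the posterior mean of q over retained sweeps; the
    per-sweep data log-likelihood trace supports the Evanno criterion.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    burn = int(iterations * burn_in_fraction)
    if iterations - burn < 100:
        raise ValidationError("need >= 100 post-burn-in iterations")

    n, L, _ = g.alleles.shape
    codes, loc_idx, n_alleles, A = _genotype_copies(g)
    valid = codes >= 0
    safe = np.where(valid, codes, 0)
    flat_locus = loc_idx[None, :].repeat(n, axis=0)  # (n, 2L)

    results = []
    for rep in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        q = rng.dirichlet(np.full(k, alpha), size=n)
        p = np.empty((k, L, A))
        for c in range(k):
            for j in range(L):
                p[c, j, : n_alleles[j]] = rng.dirichlet(np.ones(n_alleles[j]))
                p[c, j, n_alleles[j]:] = 0.0

        q_sum = np.zeros((n, k))
        p_sum = np.zeros_like(p)
        trace = []
        kept = 0
        for sweep in range(iterations):
            like = p[:, flat_locus, safe]                   # (k, n, 2L)
            w = q.T[:, :, None] * like                       # (k, n, 2L)
            w_sum = w.sum(axis=0)
            w_sum[w_sum == 0] = 1.0
            # sample origins via inverse-CDF on the k axis
            u = rng.random((n, codes.shape[1])) * w_sum
            cdf = np.cumsum(w, axis=0)
            z = (u[None, :, :] > cdf).sum(axis=0)            # (n, 2L) in 0..k-1
            z = np.minimum(z, k - 1)

            # membership update: counts of origins per individual
            zc = np.zeros((n, k))
            for c in range(k):
                zc[:, c] = ((z == c) & valid).sum(axis=1)
            q = np.empty((n, k))
            gam = rng.standard_gamma(alpha + zc)
            q = gam / gam.sum(axis=1, keepdims=True)

            # frequency update: per (cluster, locus, allele) counts
            flat = (z * (L * A) + flat_locus * A + safe)[valid]
            cnt = np.bincount(flat.ravel(), minlength=k * L * A).reshape(k, L, A)
            gamp = rng.standard_gamma(1.0 + cnt)
            for j in range(L):
                gamp[:, j, n_alleles[j]:] = 0.0
            p = gamp / gamp.sum(axis=2, keepdims=True)

            if sweep >= burn and (sweep - burn) % thin == 0:
                q_sum += q
                p_sum += p
                kept += 1
                trace.append(admixture_loglik(codes, loc_idx, p, q))

        Q = q_sum / kept
        p_mean = p_sum / kept
        freqs = [p_mean[:, j, : n_alleles[j]] for j in range(L)]
        trace = np.asarray(trace)
        results.append(AdmixtureResult(k, Q, freqs, float(trace.mean()), trace))
    return results


def evanno_delta_k(loglik_by_k: dict[int, list[float]]) -> tuple[dict[int, float], int]:
    """Evanno second-difference criterion on replicate mean log-likelihoods.

    delta_K(k) = |mean L(k+1) - 2 mean L(k) + mean L(k-1)| / sd_rep(L(k));
    endpoints are undefined and excluded; selected k = argmax delta_K.
    A zero replicate sd flags delta_K as +inf with a warning semantics left
    to the caller.
    """
    ks = sorted(loglik_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValidationError("need >= 3 consecutive k values")
    for k in ks:
        if len(loglik_by_k[k]) < 2:
            raise ValidationError(f"need >= 2 replicates at k={k}")
    means = {k: float(np.mean(loglik_by_k[k])) for k in ks}
    sds = {k: float(np.std(loglik_by_k[k], ddof=1)) for k in ks}
    delta = {}
    for k in ks[1:-1]:
        second = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
        delta[k] = math.inf if sds[k] == 0 else second / sds[k]
    selected = max(delta, key=lambda k: (delta[k], -k))
    return delta, selected


# ---------------------------------------------------------------------------
# ecotype / genotype assignment correlation


@dataclass
class AssignmentCorrelation:
    r: float
    p: float
    max_abs_r_over_relabelings: float


def assignment_correlation(eco: np.ndarray, gen: np.ndarray) -> AssignmentCorrelation:
    """Pearson correlation of two integer cluster-label vectors.

    The correlation of categorical labels depends on the arbitrary value
    assigned to each cluster; alongside the plain r (labels as given), the
    maximum |r| over all relabelings of both label sets is reported as a
    sensitivity measure.  (Relabeling a binary vector is an affine map and
    never moves |r|; with three or more clusters relabelings can change it
    substantially, so both sides are scanned.)
    """
    eco = np.asarray(eco, dtype=float)
    gen = np.asarray(gen, dtype=float)
    if eco.shape != gen.shape:
        raise ValidationError("label vectors must have equal length")
    if len(eco) < 3:
        raise ValidationError("need at least 3 individuals")
    if np.std(eco) == 0 or np.std(gen) == 0:
        raise ValidationError("constant label vector: correlation undefined")
    r, p = stats.pearsonr(eco, gen)

    ev, gv = sorted(set(eco)), sorted(set(gen))
    best = 0.0
    for eperm in itertools.permutations(ev):
        emap = dict(zip(ev, eperm))
        e_re = np.array([emap[v] for v in eco], dtype=float)
        for gperm in itertools.permutations(gv):
            gmap = dict(zip(gv, gperm))
            g_re = np.array([gmap[v] for v in gen], dtype=float)
            rr, _ = stats.pearsonr(e_re, g_re)
            best = max(best, abs(rr))
    return AssignmentCorrelation(float(r), float(p), float(best))
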