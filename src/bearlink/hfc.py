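"""Heterozygosity-fitness correlation models.

The centre of the package: Bayesian hierarchical linear models relating
fitness proxies (log body mass, log straight-line length, body condition
index) to sex, age, capture northing, season, individual homozygosity (HL)
and cluster/PC covariates, with intercepts -- and optionally HL slopes --
varying by management unit:

    y_i      = x_i' beta + alpha_{u(i)} (+ gamma_{u(i)} * hl_i) + eps_i
    alpha_u  ~ N(mu_alpha, sigma_alpha^2)
    gamma_u  ~ N(mu_gamma, sigma_gamma^2)        (unit-varying HL slopes)
    eps_i    ~ N(0, sigma^2)

with vague conjugate priors: beta, mu_alpha, mu_gamma ~ N(0, 100^2) and
inverse-gamma(0.001, 0.001) on all variances.  The posterior is sampled by
a blocked Gibbs sampler; fits are compared by DIC (conditional-likelihood
convention), convergence by the Gelman-Rubin statistic (R-hat < 1.1), and
effects summarised by 95% credible intervals.

The public surface follows the Model/Results idiom: build a
:class:`HierarchicalHFCModel` (directly or via ``from_dataframe``), call
``fit()`` and read the returned :class:`HFCResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

_PRIOR_SD = 100.0      # N(0, 100^2) on fixed effects and hypermeans
_IG_A = 0.001          # inverse-gamma shape on variances
_IG_B = 0.001          # inverse-gamma scale


# ---------------------------------------------------------------------------
# body condition index


def compute_bci(mass: np.ndarray, sll: np.ndarray) -> np.ndarray:
    """Body condition index: standardised residual of ln(mass) on ln(SLL).

    Positive values mean heavier than expected for the animal's length.
    """
    mass = np.asarray(mass, dtype=float)
    sll = np.asarray(sll, dtype=float)
    if mass.shape != sll.shape or mass.ndim != 1:
        raise ValidationError("mass and sll must be equal-length vectors")
    if len(mass) < 3:
        raise ValidationError("BCI needs at least 3 individuals")
    if (mass <= 0).any() or (sll <= 0).any():
        raise ValidationError("mass and SLL must be strictly positive")
    x, y = np.log(sll), np.log(mass)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=1)
    if sd == 0:
        return np.zeros_like(resid)
    return resid / sd


# ---------------------------------------------------------------------------
# model specification and design construction


@dataclass(frozen=True)
class ModelSpec:
    """One model in the suite.

    ``model_id`` mirrors the suite convention: M1 base covariates only;
    M2 = M1 + HL; M3 = M2 + hard cluster assignments; M4 = M2 + PC scores;
    the ``hl_by_sex`` ('x') and ``unit_varying_hl`` ('y') switches extend a
    base model.
    """

    model_id: str = "M2"
    response: str = "log_mass"   # log_mass | log_sll | bci
    include_hl: bool = True
    hl_by_sex: bool = False
    include_genetic_k: bool = False
    include_genetic_pc: bool = False
    include_habitat_k: bool = False
    include_habitat_pc: bool = False
    unit_varying_hl: bool = False
    standardize: bool = True
    chains: int = 2
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0

    def label(self) -> str:
        tag = self.model_id
        if self.hl_by_sex:
            tag += "x"
        if self.unit_varying_hl:
            tag += "y"
        return tag


M1 = ModelSpec(model_id="M1", include_hl=False)
M2 = ModelSpec(model_id="M2")
M3 = ModelSpec(model_id="M3", include_genetic_k=True, include_habitat_k=True)
M4 = ModelSpec(model_id="M4", include_genetic_pc=True, include_habitat_pc=True)
DEFAULT_SUITE = (M1, M2, M3, M4)


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    names: list[str]
    groups: np.ndarray          # integer unit index per row
    unit_names: list[str]
    hl: np.ndarray | None       # per-row HL on the modelling scale
    n_dropped: int
    ids: list[str]


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=1)
    if sd == 0:
        return col - col.mean()
    return (col - col.mean()) / sd


def build_design(records: pd.DataFrame, spec: ModelSpec,
                 genetic_k: np.ndarray | None = None,
                 genetic_pc: np.ndarray | None = None,
                 habitat_k: np.ndarray | None = None,
                 habitat_pc: np.ndarray | None = None) -> DesignMatrices:
    """Assemble response, fixed-effect design and unit grouping.

    ``records`` needs columns id, sex (F/M), age, y (northing), season
    (spring/summer/fall; fall is the reference), unit, mass, sll and hl.
    Cluster assignments arrive as integer label vectors aligned with
    ``records`` rows; PC scores as (n, >=2) arrays.  Rows with any missing
    required value are dropped (complete-case analysis) and the dropped
    count is reported.  Continuous covariates are standardised to mean 0,
    sd 1 unless ``spec.standardize`` is off; dummies are left as 0/1.
    """
    df = records.reset_index(drop=True).copy()
    n0 = len(df)
    aligned = {
        "genetic_k": genetic_k, "genetic_pc": genetic_pc,
        "habitat_k": habitat_k, "habitat_pc": habitat_pc,
    }
    for name, arr in aligned.items():
        if arr is not None and len(arr) != n0:
            raise ValidationError(f"{name} not aligned with records ({len(arr)} vs {n0})")

    needed = ["sex", "age", "y", "season", "unit", "mass", "sll"]
    if spec.include_hl or spec.unit_varying_hl or spec.hl_by_sex:
        needed.append("hl")
    keep = ~df[needed].isna().any(axis=1)
    if spec.response in ("log_mass",):
        keep &= df["mass"] > 0
    if spec.response in ("log_sll", "bci"):
        keep &= df["sll"] > 0
    df = df[keep]
    idx = np.nonzero(keep.to_numpy())[0]
    n = len(df)
    if n < 3:
        raise ValidationError("fewer than 3 complete cases")

    if spec.response == "log_mass":
        yv = np.log(df["mass"].to_numpy(float))
    elif spec.response == "log_sll":
        yv = np.log(df["sll"].to_numpy(float))
    elif spec.response == "bci":
        yv = compute_bci(df["mass"].to_numpy(float), df["sll"].to_numpy(float))
    else:
        raise ValidationError(f"unknown response {spec.response!r}")

    sex = (df["sex"] == "M").to_numpy(float)
    if set(df["sex"]) - {"F", "M"}:
        raise ValidationError("sex must be 'F' or 'M'")
    season = df["season"].to_numpy()
    if set(season) - {"spring", "summer", "fall"}:
        raise ValidationError("season must be spring/summer/fall")
    spring = (season == "spring").astype(float)
    summer = (season == "summer").astype(float)
    age = df["age"].to_numpy(float)
    northing = df["y"].to_numpy(float)

    std = _standardize if spec.standardize else (lambda c: c)
    cols = [sex, std(age), std(northing), spring, summer]
    names = ["sex", "age", "northing", "spring", "summer"]

    hl_col = None
    if spec.include_hl or spec.unit_varying_hl or spec.hl_by_sex:
        hl_raw = df["hl"].to_numpy(float)
        hl_col = std(hl_raw)
    if spec.include_hl and not spec.unit_varying_hl:
        cols.append(hl_col)
        names.append("hl")
    if spec.hl_by_sex:
        cols.append(hl_col * sex)
        names.append("hl_x_sex")

    def add_dummies(labels: np.ndarray, prefix: str) -> None:
        lv = np.asarray(labels)[idx]
        levels = sorted(set(int(x) for x in lv))
        if len(levels) < 2:
            raise ValidationError(f"{prefix} has fewer than 2 levels")
        for lev in levels[:-1]:  # last level is the reference
            cols.append((lv == lev).astype(float))
            names.append(f"{prefix}{lev}")

    if spec.include_genetic_k:
        if genetic_k is None:
            raise ValidationError("model requires genetic cluster assignments")
        add_dummies(genetic_k, "gen_k")
    if spec.include_habitat_k:
        if habitat_k is None:
            raise ValidationError("model requires habitat cluster assignments")
        add_dummies(habitat_k, "hab_k")
    if spec.include_genetic_pc:
        if genetic_pc is None:
            raise ValidationError("model requires genetic PC scores")
        for a in range(2):
            cols.append(std(np.asarray(genetic_pc)[idx, a].astype(float)))
            names.append(f"gen_pc{a + 1}")
    if spec.include_habitat_pc:
        if habitat_pc is None:
            raise ValidationError("model requires habitat PC scores")
        for a in range(2):
            cols.append(std(np.asarray(habitat_pc)[idx, a].astype(float)))
            names.append(f"hab_pc{a + 1}")

    units = sorted(set(df["unit"]))
    gmap = {u: i for i, u in enumerate(units)}
    groups = df["unit"].map(gmap).to_numpy()
    return DesignMatrices(
        y=yv, X=np.column_stack(cols), names=names, groups=groups,
        unit_names=units, hl=hl_col, n_dropped=n0 - n,
        ids=df["id"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# Gibbs sampler


@dataclass
class HFCResults:
    """Posterior sample and diagnostics for one fitted model."""

    spec: ModelSpec
    param_names: list[str]
    chains: np.ndarray          # (n_chains, n_draws, n_params)
    unit_names: list[str]
    dic: float
    dbar: float
    pd_eff: float
    rhat: dict[str, float]
    n_obs: int

    def __post_init__(self) -> None:
        flat = self.chains.reshape(-1, self.chains.shape[2])
        self._flat = flat
        self.means = {n: float(flat[:, i].mean())
                      for i, n in enumerate(self.param_names)}
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        self.ci = {n: (float(lo[i]), float(hi[i]))
                   for i, n in enumerate(self.param_names)}
        self.converged = all(r < 1.1 for r in self.rhat.values()
                             if np.isfinite(r))

    def chain(self, name: str) -> np.ndarray:
        return self.chains[:, :, self.param_names.index(name)]

    def significant(self, name: str) -> bool:
        lo, hi = self.ci[name]
        return lo > 0 or hi < 0

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for n in self.param_names:
            lo, hi = self.ci[n]
            rows.append({"parameter": n, "mean": self.means[n],
                         "ci_low": lo, "ci_high": hi,
                         "rhat": self.rhat.get(n, np.nan),
                         "ci_excludes_zero": self.significant(n)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Hierarchical HFC model {self.spec.label()} "
            f"(response: {self.spec.response}, n = {self.n_obs})",
            f"DIC = {self.dic:.2f} (Dbar = {self.dbar:.2f}, pD = {self.pd_eff:.2f})"
            f"   converged: {self.converged}",
            f"{'parameter':<14}{'mean':>9}{'2.5%':>9}{'97.5%':>9}{'Rhat':>7}",
        ]
        for n in self.param_names:
            lo, hi = self.ci[n]
            star = "*" if self.significant(n) else " "
            lines.append(
                f"{n:<14}{self.means[n]:>9.3f}{lo:>9.3f}{hi:>9.3f}"
                f"{self.rhat.get(n, float('nan')):>7.3f} {star}"
            )
        lines.append("* 95% credible interval excludes 0")
        return "\n".join(lines)


class HierarchicalHFCModel:
    """Bayesian hierarchical linear model with unit-varying intercepts.

    Parameters
    ----------
    y : ndarray
        Response vector (already log-transformed for mass / SLL).
    X : ndarray
        Fixed-effect design (no intercept column: the overall intercept is
        the hypermean of the unit intercepts).
    groups : ndarray
        Integer management-unit index per observation.
    hl : ndarray, optional
        Per-observation homozygosity on the modelling scale; required when
        ``spec.unit_varying_hl`` is on.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                 spec: ModelSpec, names: list[str] | None = None,
                 hl: np.ndarray | None = None,
                 unit_names: list[str] | None = None) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.groups = np.asarray(groups, dtype=np.int64)
        self.spec = spec
        self.hl = None if hl is None else np.asarray(hl, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,) or self.groups.shape != (n,):
            raise ValidationError("y / X / groups size mismatch")
        self.n_units = int(self.groups.max()) + 1
        if self.n_units < 2:
            raise ValidationError("need at least 2 management units")
        if spec.unit_varying_hl and self.hl is None:
            raise ValidationError("unit-varying HL slopes need an hl vector")
        self.names = names or [f"x{i}" for i in range(p)]
        self.unit_names = unit_names or [f"unit{i}" for i in range(self.n_units)]

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, spec: ModelSpec,
                       **covariates) -> "HierarchicalHFCModel":
        d = build_design(records, spec, **covariates)
        return cls(d.y, d.X, d.groups, spec, names=d.names, hl=d.hl,
                   unit_names=d.unit_names)

    # -- sampling ---------------------------------------------------------

    def fit(self, chains: int | None = None, iterations: int | None = None,
            burn_in: int | None = None, seed: int | None = None,
            thin: int | None = None) -> HFCResults:
        spec = self.spec
        chains = chains or spec.chains
        iterations = iterations or spec.iterations
        burn_in = spec.burn_in if burn_in is None else burn_in
        thin = thin or spec.thin
        seed = spec.seed if seed is None else seed
        if chains < 2:
            raise ValidationError("need at least 2 chains for diagnostics")
        if iterations - burn_in < 100 * thin:
            raise ValidationError("fewer than 100 retained draws per chain")

        all_draws = []
        for c in range(chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(c,)))
            all_draws.append(self._run_chain(rng, iterations, burn_in, thin))
        draws = np.stack(all_draws)  # (chains, n_draws, n_params)

        names = self._param_names()
        rhat = {n: gelman_rubin(draws[:, :, i])
                for i, n in enumerate(names)}
        dic, dbar, pd_eff = self._dic(draws)
        return HFCResults(spec, names, draws, self.unit_names,
                          dic, dbar, pd_eff, rhat, len(self.y))

    def _param_names(self) -> list[str]:
        names = list(self.names)
        names += [f"alpha[{u}]" for u in self.unit_names]
        names += ["mu_alpha", "sigma_alpha"]
        if self.spec.unit_varying_hl:
            names += [f"gamma[{u}]" for u in self.unit_names]
            names += ["mu_gamma", "sigma_gamma"]
        names.append("sigma_resid")
        return names

    def _run_chain(self, rng: np.random.Generator, iterations: int,
                   burn_in: int, thin: int) -> np.ndarray:
        y, X, g = self.y, self.X, self.groups
        n, p = X.shape
        U = self.n_units
        slopes = self.spec.unit_varying_hl
        h = self.hl if slopes else None
        XtX = X.T @ X
        counts = np.bincount(g, minlength=U).astype(float)
        if slopes:
            h2_by_u = np.bincount(g, weights=h * h, minlength=U)

        beta = np.zeros(p)
        alpha = np.zeros(U)
        mu_a, var_a = 0.0, 1.0
        gamma = np.zeros(U)
        mu_g, var_g = 0.0, 1.0
        var_e = float(y.var()) or 1.0

        keep = []
        prior_prec = np.eye(p) / _PRIOR_SD**2
        for it in range(iterations):
            offset = alpha[g] + (gamma[g] * h if slopes else 0.0)
            # fixed effects
            prec = XtX / var_e + prior_prec
            L = np.linalg.cholesky(prec)
            rhs = X.T @ (y - offset) / var_e
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)

            xb = X @ beta
            # unit intercepts
            resid = y - xb - (gamma[g] * h if slopes else 0.0)
            s_u = np.bincount(g, weights=resid, minlength=U)
            prec_a = counts / var_e + 1.0 / var_a
            mean_a = (s_u / var_e + mu_a / var_a) / prec_a
            alpha = mean_a + rng.standard_normal(U) / np.sqrt(prec_a)
            # hypermean / hypervariance of intercepts
            prec_mu = U / var_a + 1.0 / _PRIOR_SD**2
            mu_a = (alpha.sum() / var_a) / prec_mu \
                + rng.standard_normal() / math.sqrt(prec_mu)
            ssa = float(((alpha - mu_a) ** 2).sum())
            var_a = _sample_inv_gamma(rng, _IG_A + U / 2.0, _IG_B + ssa / 2.0)

            if slopes:
                resid = y - xb - alpha[g]
                sh_u = np.bincount(g, weights=h * resid, minlength=U)
                prec_g = h2_by_u / var_e + 1.0 / var_g
                mean_g = (sh_u / var_e + mu_g / var_g) / prec_g
                gamma = mean_g + rng.standard_normal(U) / np.sqrt(prec_g)
                prec_mu = U / var_g + 1.0 / _PRIOR_SD**2
                mu_g = (gamma.sum() / var_g) / prec_mu \
                    + rng.standard_normal() / math.sqrt(prec_mu)
                ssg = float(((gamma - mu_g) ** 2).sum())
                var_g = _sample_inv_gamma(rng, _IG_A + U / 2.0, _IG_B + ssg / 2.0)

            # residual variance
            eps = y - xb - alpha[g] - (gamma[g] * h if slopes else 0.0)
            rss = float((eps * eps).sum())
            var_e = _sample_inv_gamma(rng, _IG_A + n / 2.0, _IG_B + rss / 2.0)

            if it >= burn_in and (it - burn_in) % thin == 0:
                row = [*beta, *alpha, mu_a, math.sqrt(var_a)]
                if slopes:
                    row += [*gamma, mu_g, math.sqrt(var_g)]
                row.append(math.sqrt(var_e))
                keep.append(row)
        return np.asarray(keep)

    # -- DIC --------------------------------------------------------------

    def _fitted(self, beta: np.ndarray, alpha: np.ndarray,
                gamma: np.ndarray | None) -> np.ndarray:
        mu = self.X @ beta + alpha[self.groups]
        if gamma is not None:
            mu = mu + gamma[self.groups] * self.hl
        return mu

    def _deviance(self, mu: np.ndarray, var_e: float) -> float:
        n = len(self.y)
        rss = float(((self.y - mu) ** 2).sum())
        return n * math.log(2.0 * math.pi * var_e) + rss / var_e

    def _dic(self, draws: np.ndarray) -> tuple[float, float, float]:
        """DIC with the conditional (given unit effects) Gaussian likelihood."""
        flat = draws.reshape(-1, draws.shape[2])
        if flat.shape[0] < 100:
            raise ValidationError("DIC needs at least 100 retained draws")
        p = self.X.shape[1]
        U = self.n_units
        slopes = self.spec.unit_varying_hl
        dev = np.empty(flat.shape[0])
        for d in range(flat.shape[0]):
            row = flat[d]
            beta = row[:p]
            alpha = row[p:p + U]
            pos = p + U + 2
            gamma = row[pos:pos + U] if slopes else None
            var_e = float(row[-1]) ** 2
            dev[d] = self._deviance(self._fitted(beta, alpha, gamma), var_e)
        dbar = float(dev.mean())
        mean_row = flat.mean(axis=0)
        beta = mean_row[:p]
        alpha = mean_row[p:p + U]
        pos = p + U + 2
        gamma = mean_row[pos:pos + U] if slopes else None
        var_hat = float((flat[:, -1] ** 2).mean())
        dhat = self._deviance(self._fitted(beta, alpha, gamma), var_hat)
        pd_eff = dbar - dhat
        return dbar + pd_eff, dbar, pd_eff


def _sample_inv_gamma(rng: np.random.Generator, a: float, b: float) -> float:
    if b <= 0:
        raise ValidationError("degenerate variance update (non-positive scale)")
    return b / rng.standard_gamma(a)


def dic(result: HFCResults) -> tuple[float, float, float]:
    """(DIC, Dbar, pD) of a fitted model."""
    return result.dic, result.dbar, result.pd_eff


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction R-hat for one parameter.

    ``chains`` is (n_chains, n_draws); R-hat = sqrt(((n-1)/n W + B/n) / W)
    with B = n var(chain means), W = mean within-chain variance.  Values
    below 1.1 are conventionally taken as converged.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValidationError("need >= 2 chains of length >= 2")
    m, n = c.shape
    W = float(c.var(axis=1, ddof=1).mean())
    B = n * float(c.mean(axis=1).var(ddof=1))
    if W == 0:
        return math.inf
    return math.sqrt(((n - 1) / n * W + B / n) / W)


# ---------------------------------------------------------------------------
# single-locus F-test


def single_locus_ftest(y: np.ndarray, base_X: np.ndarray,
                       locus_hom: np.ndarray) -> tuple[float, int, int, float]:
    """Test whether the homozygosity effect is driven by a single locus.

    Compares two OLS fits on top of the base covariates: the restricted
    model adds one combined homozygosity predictor (the unweighted mean of
    the per-locus 0/1 indicators, so the models are exactly nested), the
    full model adds all L per-locus indicators.  Returns (F, df1, df2, p)
    with df1 = L - 1.  Collinear locus columns are dropped (df adjusted).
    """
    y = np.asarray(y, dtype=float)
    base_X = np.asarray(base_X, dtype=float)
    H = np.asarray(locus_hom, dtype=float)
    n, L = H.shape
    if np.isnan(H).any():
        keep = ~np.isnan(H).any(axis=1)
        y, base_X, H = y[keep], base_X[keep], H[keep]
        n = len(y)
    combined = H.mean(axis=1)

    ones = np.ones((n, 1))
    Xr = np.column_stack([ones, base_X, combined])
    Xf = np.column_stack([ones, base_X, H])
    rank_f = np.linalg.matrix_rank(Xf)
    dropped = Xf.shape[1] - rank_f
    df1 = L - 1 - dropped
    p_f = rank_f
    df2 = n - p_f
    if df2 <= 0 or df1 <= 0:
        raise ValidationError("not enough observations for the locus F-test")

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_r, rss_f = rss(Xr), rss(Xf)
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


# ---------------------------------------------------------------------------
# model suite


def run_model_suite(records: pd.DataFrame, responses: tuple[str, ...] = (
        "log_mass", "log_sll", "bci"),
        specs: tuple[ModelSpec, ...] = DEFAULT_SUITE,
        seed: int = 0, extend_best: bool = True,
        **covariates) -> pd.DataFrame:
    """Fit the model suite per response and rank by DIC.

    Fits every spec in ``specs`` for each response, then (by default) adds
    the HL-by-sex ('x') and unit-varying-HL ('y') variants of the
    DIC-best HL-carrying model.  Returns a tidy table with one row per
    (response, model): DIC, convergence, and the coefficient estimates
    with a flag for 95% credible intervals excluding zero.
    """
    rows = []
    for r_i, response in enumerate(responses):
        fits: dict[str, HFCResults] = {}
        for s_i, spec in enumerate(specs):
            sp = replace(spec, response=response, seed=seed + 31 * r_i + s_i)
            model = HierarchicalHFCModel.from_dataframe(records, sp, **covariates)
            fits[sp.label()] = model.fit()
        if extend_best:
            hl_fits = {k: v for k, v in fits.items() if v.spec.include_hl}
            if hl_fits:
                best = min(hl_fits, key=lambda k: hl_fits[k].dic)
                base = fits[best].spec
                for variant in ({"hl_by_sex": True}, {"unit_varying_hl": True}):
                    sp = replace(base, seed=base.seed + 101, **variant)
                    model = HierarchicalHFCModel.from_dataframe(
                        records, sp, **covariates)
                    fits[sp.label()] = model.fit()
        for label, res in fits.items():
            coef = res.coefficient_table()
            rows.append({
                "response": response,
                "model": label,
                "dic": res.dic,
                "pd": res.pd_eff,
                "converged": res.converged,
                "coefficients": coef,
                "hl_mean": res.means.get("hl", np.nan),
                "hl_significant": (res.significant("hl")
                                   if "hl" in res.means else False),
            })
    out = pd.DataFrame(rows)
    out["dic_rank"] = out.groupby("response")["dic"].rank(method="first")
    return out.sort_values(["response", "dic"]).reset_index(drop=True)
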