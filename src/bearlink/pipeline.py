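"""End-to-end orchestration of the genotype-ecotype-phenotype analysis.

``simulate_all`` writes a full synthetic input set (Genepop genotypes,
habitat-use, phenotype and translocation CSVs plus a ground-truth file);
``run_all`` executes the analysis stages in order -- genetic statistics,
clustering, the isolation-by-ecology Mantel battery, the hierarchical HFC
model suite, and the habitat-availability / translocation summaries --
writing one result table per stage plus a JSON run manifest.

Every stochastic stage derives its own substream from the global seed, and
the manifest records each seed actually used.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ValidationError
from . import cluster as cl
from . import genetics as gen
from . import habitat as hab
from . import hfc
from . import io
from . import mantel as mt
from . import simulate as sim


@dataclass
class PipelineConfig:
    """Desk-scale defaults; the full-scale study settings (10 000
    permutations, k 1-20, 100 restarts, 3 admixture replicates, 10^6
    sweeps) remain expressible through the same fields."""

    seed: int = 0
    out_dir: str = "results"
    # simulation
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    n_translocations: int = 362
    p_cross: float = 229 / 362
    p_north: float = 204 / 229
    availability_points_per_unit: int = 2000
    # clustering
    k_range_eco: tuple[int, int] = (1, 6)
    sa_steps: int = 20_000
    sa_restarts: int = 5
    k_range_gen: tuple[int, int] = (1, 5)
    admixture_sweeps: int = 2_000
    admixture_replicates: int = 3
    # mantel
    n_perm: int = 1_000
    n_boot: int = 200
    # hfc
    mcmc_chains: int = 2
    mcmc_iterations: int = 2_000
    mcmc_burn_in: int = 500
    # stage toggles
    skip_cluster: bool = False
    skip_ibe: bool = False
    skip_hfc: bool = False
    skip_habitat: bool = False
    skip_translocations: bool = False


def _sub_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(stage,))
               .generate_state(1)[0] % (2**31))


def simulate_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Generate and write all synthetic inputs; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = cfg.sim
    g, truth = sim.generate_genotypes(sc)
    use = sim.generate_habitat_use(sc, truth)
    hl = gen.homozygosity_by_loci(g)
    pheno = sim.generate_phenotypes(sc, truth, hl)
    trans = sim.generate_translocations(cfg.n_translocations, sc.n_units,
                                        cfg.p_cross, cfg.p_north, seed=sc.seed)
    io.write_genepop(g, out / "genotypes.gen")
    io.write_habitat_use(use, out / "habitat_use.csv")
    io.write_csv(pheno, out / "phenotypes.csv")
    io.write_translocations(trans, out / "translocations.csv")
    truth_df = pd.DataFrame({
        "id": g.ids,
        "genetic_cluster": truth.genetic_cluster,
        "ecotype": truth.ecotype,
        "unit": [sc.unit_names()[u] for u in truth.unit],
        "hl": hl,
    })
    io.write_csv(truth_df, out / "truth.csv")
    meta = {
        "seed": sc.seed,
        "hl_effect": truth.hl_effect,
        "unit_intercepts": list(map(float, truth.unit_intercepts)),
        "config": asdict(sc),
    }
    (out / "truth_meta.json").write_text(json.dumps(meta, indent=2))
    return {p.name: str(p) for p in sorted(out.iterdir())}


def run_all(cfg: PipelineConfig, in_dir: str | Path,
            out_dir: str | Path) -> dict:
    """Run the analysis stages on the files in ``in_dir``."""
    inp, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stages": {}, "stage_seeds": {}}
    t_start = time.time()

    g = io.read_genepop(inp / "genotypes.gen")
    use = io.read_habitat_use(inp / "habitat_use.csv")
    pheno = io.read_csv(inp / "phenotypes.csv")
    trans = io.read_translocations(inp / "translocations.csv")
    if g.ids != use.ids:
        raise ValidationError("genotype and habitat tables disagree on ids")

    # --- genetics stage (always runs: downstream stages need it)
    het = gen.heterozygosities(g)
    hl = gen.homozygosity_by_loci(g)
    io.write_csv(pd.DataFrame({
        "locus": het.loci, "ho": het.ho, "he": het.he,
        "he_unbiased": het.he_unbiased,
    }), out / "diversity.csv")
    io.write_csv(pd.DataFrame({"id": g.ids, "hl": hl}), out / "hl.csv")
    G_rel = gen.qg_relatedness(g)
    G_coa = gen.molecular_coancestry(g)
    io.write_pairwise(G_rel.ids, G_rel.values, out / "relatedness.csv")
    io.write_pairwise(G_coa.ids, G_coa.values, out / "coancestry.csv")
    gen_pca = gen.genotype_pca(g, n_axes=3)
    manifest["stages"]["genetics"] = {"n": g.n_individuals,
                                      "mean_ho": het.mean_ho,
                                      "mean_he": het.mean_he}

    trans_x = hab.arcsine_sqrt(use)
    hab_pca = hab.habitat_pca(trans_x, n_axes=3)

    eco_assign = gen_assign = None
    if not cfg.skip_cluster:
        s = _sub_seed(cfg.seed, 1)
        manifest["stage_seeds"]["cluster"] = s
        sols = cl.kmeans_scan(trans_x, range(cfg.k_range_eco[0],
                                             cfg.k_range_eco[1] + 1),
                              steps=cfg.sa_steps, restarts=cfg.sa_restarts,
                              seed=s)
        stats_df = pd.DataFrame([{
            "k": so.k, "sse": so.sse, "bic": so.bic, "pseudo_f": so.pseudo_f,
        } for so in sols])
        io.write_csv(stats_df, out / "ecotype_selection.csv")
        with_f = [so for so in sols if so.pseudo_f is not None]
        best_eco = max(with_f, key=lambda so: so.pseudo_f) if with_f else sols[0]
        eco_assign = best_eco.assignment

        logliks: dict[int, list[float]] = {}
        admix: dict[int, list[cl.AdmixtureResult]] = {}
        for k in range(cfg.k_range_gen[0], cfg.k_range_gen[1] + 1):
            reps = cl.admixture_gibbs(
                g, k, iterations=cfg.admixture_sweeps,
                replicates=cfg.admixture_replicates, seed=s + k)
            admix[k] = reps
            logliks[k] = [r.mean_loglik for r in reps]
        delta, k_sel = cl.evanno_delta_k(logliks)
        gen_assign = admix[k_sel][0].assignment
        io.write_csv(pd.DataFrame([
            {"k": k, "delta_k": delta.get(k, np.nan),
             "mean_loglik": float(np.mean(logliks[k]))}
            for k in sorted(logliks)
        ]), out / "genotype_selection.csv")
        corr = cl.assignment_correlation(eco_assign, gen_assign)
        io.write_csv(pd.DataFrame({
            "id": g.ids, "ecotype": eco_assign, "genetic_cluster": gen_assign,
        }), out / "assignments.csv")
        manifest["stages"]["cluster"] = {
            "k_eco": int(best_eco.k), "k_gen": int(k_sel),
            "assignment_r": corr.r, "assignment_p": corr.p,
            "max_abs_r_over_relabelings": corr.max_abs_r_over_relabelings,
        }

    if not cfg.skip_ibe:
        s = _sub_seed(cfg.seed, 2)
        manifest["stage_seeds"]["ibe"] = s
        pheno_idx = pheno.set_index("id").loc[g.ids]
        coords = pheno_idx[["x", "y"]].to_numpy(float)
        D = mt.geographic_distance(coords, g.ids)
        S = mt.sex_matrix(pheno_idx["sex"].tolist(), g.ids)
        E = [mt.ecological_distance(hab_pca.scores, a, g.ids) for a in (1, 2, 3)]
        suite = mt.ibe_suite({"relatedness": G_rel, "coancestry": G_coa},
                             D, S, E, n_perm=cfg.n_perm, seed=s,
                             n_boot=cfg.n_boot)
        io.write_csv(suite, out / "ibe_suite.csv")
        manifest["stages"]["ibe"] = {"rows": len(suite)}

    if not cfg.skip_hfc:
        s = _sub_seed(cfg.seed, 3)
        manifest["stage_seeds"]["hfc"] = s
        pheno_idx = pheno.set_index("id").loc[g.ids].reset_index()
        if "hl" not in pheno_idx.columns:
            pheno_idx["hl"] = hl
        suite = hfc.run_model_suite(
            pheno_idx, seed=s,
            genetic_k=gen_assign if gen_assign is not None else None,
            genetic_pc=gen_pca.scores[:, :2],
            habitat_k=eco_assign if eco_assign is not None else None,
            habitat_pc=hab_pca.scores[:, :2],
            specs=tuple(
                hfc.ModelSpec(
                    model_id=m.model_id, include_hl=m.include_hl,
                    include_genetic_k=m.include_genetic_k and gen_assign is not None,
                    include_genetic_pc=m.include_genetic_pc,
                    include_habitat_k=m.include_habitat_k and eco_assign is not None,
                    include_habitat_pc=m.include_habitat_pc,
                    chains=cfg.mcmc_chains, iterations=cfg.mcmc_iterations,
                    burn_in=cfg.mcmc_burn_in,
                ) for m in hfc.DEFAULT_SUITE),
        )
        flat = suite.drop(columns=["coefficients"])
        io.write_csv(flat, out / "hfc_models.csv")
        coef_rows = []
        for _, row in suite.iterrows():
            c = row["coefficients"].copy()
            c.insert(0, "model", row["model"])
            c.insert(0, "response", row["response"])
            coef_rows.append(c)
        io.write_csv(pd.concat(coef_rows), out / "hfc_coefficients.csv")
        manifest["stages"]["hfc"] = {
            "models": len(suite),
            "all_converged": bool(suite["converged"].all()),
        }

    units = cfg.sim.unit_names()
    if not cfg.skip_habitat:
        s = _sub_seed(cfg.seed, 4)
        manifest["stage_seeds"]["habitat"] = s
        rng = np.random.default_rng(s)
        # availability: per-unit Dirichlet profiles sampled into points
        pts = []
        for u, unit in enumerate(units):
            profile = rng.dirichlet(np.array(
                cfg.sim.eco_concentrations[u % cfg.sim.k_eco]))
            draws = rng.choice(len(profile),
                               size=cfg.availability_points_per_unit, p=profile)
            pts.extend((unit, hab.HABITAT_CLASSES[c]) for c in draws)
        points = pd.DataFrame(pts, columns=["unit", "landcover"])
        av = hab.availability_from_points(points)
        io.write_availability(av, out / "availability.csv")
        chi2, df, p = hab.availability_chi2(av)
        dmat = hab.availability_distance(av)
        io.write_pairwise(av.units, dmat, out / "availability_distance.csv")
        tree = hab.neighbor_joining(dmat, av.units)
        (out / "availability_nj.nwk").write_text(io.write_newick(tree) + "\n")
        manifest["stages"]["habitat"] = {"chi2": chi2, "df": df, "p": p}

    if not cfg.skip_translocations:
        summ = hab.translocation_summary(trans, units)
        io.write_csv(summ.flow.reset_index(), out / "translocation_flow.csv")
        manifest["stages"]["translocations"] = {
            "total": summ.n_total,
            "cross_unit": summ.n_cross_unit,
            "northward": summ.n_northward,
            "pct_cross_unit": summ.pct_cross_unit,
            "pct_northward": summ.pct_northward,
        }

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
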