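"""Pipeline driver: validated config -> staged analysis -> report bundle.

Stages (any subset, dependencies validated up front):

* ``simulate``        — study-like structured-coalescent data set
* ``popgen``          — diversity table, pairwise F_ST with bootstrap CIs, AMOVA
* ``neutrality``      — DHEW compound test and multilocus HKA per locus
* ``dispersal``       — synthetic flow scenario, particle ensembles, kernels,
                        single-generation transition matrix
* ``stepping_stone``  — joint (multi-generation) connectivity + normalization
* ``compare``         — genetic vs dispersal concordance report

Every stage writes CSV (tabular) or NetCDF (gridded) outputs under the
run directory, plus a JSON manifest with seeds, configuration and
package version. All randomness derives from the single config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coalsim import make_study_like
from .concordance import GeneFlowMatrix, compare
from .dispersal import (
    VentRegistry,
    advect,
    build_synthetic_field,
    kernel,
    settle,
    transition_matrix,
)
from .diversity import amova, diversity_table, fst_bootstrap
from .genetic_io import four_gamete_scan
from .neutrality import LocusSummary, dhew_test, hka_ml, polarized_sfs
from .stepping_stone import eligibility_filter, joint_transition, normalize_to_source

log = logging.getLogger("ventconn")

STAGES = ("simulate", "popgen", "neutrality", "dispersal", "stepping_stone", "compare")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    text = Path(path_or_dict).read_text()
    if str(path_or_dict).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def validate_config(config: dict) -> None:
    """Schema and stage-dependency checks; raises before any stage runs."""
    if "stages" not in config or not config["stages"]:
        raise ValueError("config must list stages")
    unknown = [s for s in config["stages"] if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    stages = list(config["stages"])
    if "seed" not in config:
        raise ValueError("config must set a seed")
    if "out_dir" not in config:
        raise ValueError("config must set out_dir")
    needs = {
        "popgen": ["simulate"],
        "neutrality": ["simulate"],
        "stepping_stone": ["dispersal"],
    }
    for stage, deps in needs.items():
        if stage in stages:
            for dep in deps:
                if dep not in stages:
                    raise ValueError(f"stage {stage!r} requires stage {dep!r}")
    if "compare" in stages:
        cmp_cfg = config.get("compare", {})
        has_dispersal = "stepping_stone" in stages
        has_genetic = "simulate" in stages or "gene_flow_csv" in cmp_cfg
        if not (has_dispersal and has_genetic):
            raise ValueError(
                "stage 'compare' requires both a dispersal source "
                "(stepping_stone stage) and a genetic source "
                "(simulate stage or compare.gene_flow_csv)"
            )
    if "dispersal" in stages:
        dcfg = config.get("dispersal", {})
        if "sites" not in dcfg or not dcfg["sites"]:
            raise ValueError("dispersal stage requires dispersal.sites")


def _truth_gene_flow(dataset) -> GeneFlowMatrix:
    """Ground-truth forward gene flow from the simulated (backward) migration
    matrix: forward migration i->j is the backward rate j->i."""
    M_bwd = np.asarray(dataset.provenance["migration"], dtype=float)
    pops = [d[0] for d in dataset.provenance["demes"]]
    m_fwd = M_bwd.T.copy()
    return GeneFlowMatrix(pops, m_fwd, m_fwd > 0, {"source": "simulation-truth"})


def run_pipeline(config) -> dict:
    """Execute the configured stages; returns in-memory results and writes
    the report bundle (CSVs, NetCDF grids, JSON manifest) to out_dir."""
    config = load_config(config)
    validate_config(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = list(config["stages"])
    results: dict = {}
    manifest: dict = {"version": __version__, "seed": seed, "config": config, "stages": {}}

    dataset = None
    if "simulate" in stages:
        scfg = config.get("simulate", {})
        log.info("stage simulate: preset=%s", scfg.get("preset", "boucheti-like"))
        dataset = make_study_like(
            scfg.get("preset", "boucheti-like"),
            seed=seed,
            theta=float(scfg.get("theta", 5.0)),
            m_within=float(scfg.get("m_within", 10.0)),
            m_between=float(scfg.get("m_between", 0.5)),
            asymmetry=float(scfg.get("asymmetry", 0.0)),
        )
        dataset.write(out / "simulated")
        results["dataset"] = dataset
        manifest["stages"]["simulate"] = {"provenance": dataset.provenance}

    if "popgen" in stages:
        pcfg = config.get("popgen", {})
        log.info("stage popgen")
        div = diversity_table(dataset.alignments, dataset.hierarchy)
        div.to_csv(out / "diversity.csv", index=False)
        n_boot = int(pcfg.get("n_boot", 200))
        pops = [
            p
            for p in dataset.hierarchy.populations
            if all(
                sum(
                    1
                    for r in a.records
                    if dataset.hierarchy.population_of(r.individual_id) == p
                )
                >= 2
                for a in dataset.alignments
            )
        ]
        mito = [a for a in dataset.alignments if a.ploidy == 1]
        nuclear = [a for a in dataset.alignments if a.ploidy == 2]
        fst_rows = []
        for name, loci in (("mito", mito), ("nuclear", nuclear)):
            for i, pa in enumerate(pops):
                for pb in pops[i + 1 :]:
                    res = fst_bootstrap(
                        loci, dataset.hierarchy, pa, pb, n_boot=n_boot, seed=seed
                    )
                    fst_rows.append(
                        {
                            "marker": name,
                            "pop_a": pa,
                            "pop_b": pb,
                            "theta": res.theta,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "significant": res.significant,
                        }
                    )
        fst_df = pd.DataFrame(fst_rows)
        fst_df.to_csv(out / "pairwise_fst.csv", index=False)
        amova_frames = []
        for a in dataset.alignments:
            levels = (
                ("region", "population")
                if a.ploidy == 1
                else ("region", "population", "individual")
            )
            try:
                am = amova(a, dataset.hierarchy, levels)
            except ValueError:
                continue
            f = am.to_frame()
            f.insert(0, "locus", a.locus_name)
            amova_frames.append(f)
        amova_df = pd.concat(amova_frames, ignore_index=True)
        amova_df.to_csv(out / "amova.csv", index=False)
        results["diversity"] = div
        results["fst"] = fst_df
        results["amova"] = amova_df
        manifest["stages"]["popgen"] = {"n_boot": n_boot, "populations": pops}

    if "neutrality" in stages:
        ncfg = config.get("neutrality", {})
        log.info("stage neutrality")
        rows = []
        summaries = []
        rng = np.random.default_rng(seed + 7)
        for a in dataset.alignments:
            truth = dataset.truth[a.locus_name]
            outgroup = truth["ancestral"]
            violations, _ = four_gamete_scan(a)
            rep = dhew_test(
                a,
                outgroup,
                alpha=float(ncfg.get("alpha", 0.05)),
                n_sims=int(ncfg.get("n_sims", 2000)),
                seed=int(rng.integers(2**31 - 1)),
            )
            sfs = polarized_sfs(a, outgroup)
            # divergence: fixed differences between ingroup consensus and outgroup
            D = _consensus_divergence(a, outgroup)
            summaries.append(
                LocusSummary(a.locus_name, rep.S, D, a.n_sequences, a.length)
            )
            rows.append(
                {
                    "locus": a.locus_name,
                    "n": rep.n,
                    "S": rep.S,
                    "tajima_d": rep.tajima_d,
                    "faywu_h_norm": rep.faywu_h_norm,
                    "ew_homozygosity": rep.ew_homozygosity,
                    "dhew_reject": rep.dhew_reject,
                    "four_gamete_violations": len(violations),
                }
            )
        neut_df = pd.DataFrame(rows)
        free = list(ncfg.get("free_k_loci", [summaries[0].name]))
        hka = hka_ml(summaries, free, seed=seed)
        neut_df["hka_k"] = [hka.k[s.name] for s in summaries]
        neut_df["hka_log_k"] = np.log(neut_df["hka_k"])
        neut_df["hka_lrt_p"] = hka.p_value
        neut_df.to_csv(out / "neutrality.csv", index=False)
        results["neutrality"] = neut_df
        results["hka"] = hka
        manifest["stages"]["neutrality"] = {
            "free_k_loci": free,
            "lrt": hka.lrt,
            "p": hka.p_value,
        }

    registry = None
    trans = None
    if "dispersal" in stages:
        dcfg = config.get("dispersal", {})
        log.info("stage dispersal")
        registry = VentRegistry(pd.DataFrame(dcfg["sites"]))
        depth = float(dcfg.get("dispersal_depth_m", 1000.0))
        scenario = build_synthetic_field(
            dcfg.get("domain", {"x_km": 800.0, "y_km": 400.0, "dx_km": 10.0}),
            dcfg.get("components", [{"type": "uniform_jet", "u": -0.1, "v": 0.0}]),
            seed=seed,
            dispersal_depth_m=depth,
        )
        scenario.to_dataset().to_netcdf(out / "flow_scenario.nc", engine="scipy")
        ensembles = {}
        for k, site_id in enumerate(registry.ids):
            site = registry.site(site_id)
            ens = advect(
                scenario,
                float(site["x_km"]),
                float(site["y_km"]),
                n_particles=int(dcfg.get("n_particles", 2000)),
                dt_seconds=float(dcfg.get("dt_seconds", 3600.0)),
                seed=seed + 1000 + k,
                jitter_km=float(dcfg.get("jitter_km", 2.0)),
                store_every=int(dcfg.get("store_every", 4)),
                release_site=site_id,
            )
            ens = settle(
                ens,
                registry,
                scenario,
                radius_km=float(dcfg.get("radius_km", 5.0)),
                min_competency=float(dcfg.get("min_competency", 0.0)),
            )
            ensembles[site_id] = ens
            kern = kernel(ens, cell_km=float(dcfg.get("cell_km", 10.0)))
            kern.to_dataset().to_netcdf(out / f"kernel_{site_id}.nc", engine="scipy")
        trans = transition_matrix(ensembles, registry)
        trans.to_csv(out / "transition_matrix.csv")
        results["transition_matrix"] = trans
        results["registry"] = registry
        manifest["stages"]["dispersal"] = {
            "dispersal_depth_m": depth,
            "n_particles": int(dcfg.get("n_particles", 2000)),
        }

    N = None
    if "stepping_stone" in stages:
        sscfg = config.get("stepping_stone", {})
        log.info("stage stepping_stone")
        depth = float(config.get("dispersal", {}).get("dispersal_depth_m", 1000.0))
        kept = eligibility_filter(registry, depth)
        keep_ids = [s for s in trans.sites if s in kept.ids]
        idx = [trans.sites.index(s) for s in keep_ids]
        sub = type(trans)(keep_ids, trans.P[np.ix_(idx, idx)])
        joint = joint_transition(
            sub,
            max_steps=int(sscfg.get("max_steps", 100)),
            tol=float(sscfg.get("tol", 1e-12)),
        )
        joint.to_csv(out / "joint_transition.csv")
        N = normalize_to_source(joint)
        N.to_csv(out / "joint_normalized.csv")
        results["joint"] = joint
        results["normalized"] = N
        manifest["stages"]["stepping_stone"] = {
            "steps_used": joint.steps_used,
            "converged": joint.converged,
        }

    if "compare" in stages:
        ccfg = config.get("compare", {})
        log.info("stage compare")
        if "gene_flow_csv" in ccfg:
            gf = GeneFlowMatrix.from_csv(ccfg["gene_flow_csv"])
        else:
            gf = _truth_gene_flow(dataset)
        mapping = ccfg.get("mapping")
        report = compare(
            gf, N, mapping, threshold_d=float(ccfg.get("threshold_d", 1e-3))
        )
        report.pairs.to_csv(out / "concordance.csv", index=False)
        results["comparison"] = report
        manifest["stages"]["compare"] = {
            "rank_concordance": report.rank_concordance,
            "classes": report.class_counts(),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results


def _consensus_divergence(aln, outgroup_seq: str) -> int:
    """Fixed differences between the ingroup majority consensus and the
    outgroup on retained (complete) columns."""
    import numpy as np

    m = aln.matrix()
    keep = aln.complete_columns()
    og = np.array(list(outgroup_seq.upper()))
    D = 0
    for j in np.flatnonzero(keep):
        col = m[:, j]
        vals, counts = np.unique(col, return_counts=True)
        consensus = vals[np.argmax(counts)]
        if len(vals) == 1 and og[j] not in "N-" and consensus != og[j]:
            D += 1
    return D
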