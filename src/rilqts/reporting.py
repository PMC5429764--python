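"""Publication-style tables, unconditional-vs-conditional comparison, network
export, and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import mapping, screening, simulate, trait_stats
from .datamodel import DatasetBundle, validate_dataset
from .mapping import QTSModel

logger = logging.getLogger(__name__)

__all__ = [
    "classify_terms",
    "compare_conditional",
    "render_qts_table",
    "parse_qts_table",
    "export_network",
    "model_to_dict",
    "run_pipeline",
]

STATUSES = (
    "retained",
    "retained_component_changed",
    "absent_under_conditioning",
    "novel_conditional",
)


def classify_terms(unconditional: dict, conditional: dict) -> dict:
    """Status of every term given two {term: component-set} mappings.

    A pure function of the two significance sets: terms in both with an
    unchanged component set are retained; in both with a changed set,
    retained_component_changed; unconditional-only, absent_under_conditioning;
    conditional-only, novel_conditional.
    """
    out = {}
    for term, comps in unconditional.items():
        if term in conditional:
            out[term] = (
                "retained"
                if frozenset(comps) == frozenset(conditional[term])
                else "retained_component_changed"
            )
        else:
            out[term] = "absent_under_conditioning"
    for term in conditional:
        if term not in unconditional:
            out[term] = "novel_conditional"
    return out


def _model_components(model: QTSModel) -> dict:
    return {t.term: frozenset(t.components) for t in model.terms}


def compare_conditional(unconditional: QTSModel, conditionals: dict) -> pd.DataFrame:
    """Per-QTS status for each conditioning trait."""
    rows = []
    base = _model_components(unconditional)
    for given, model in conditionals.items():
        statuses = classify_terms(base, _model_components(model))
        for term, status in statuses.items():
            rows.append(
                {
                    "term": " & ".join(term) if isinstance(term, tuple) else term,
                    "conditioning": given,
                    "status": status,
                }
            )
    return pd.DataFrame(rows, columns=["term", "conditioning", "status"])


def _fmt_term(term) -> str:
    return " & ".join(term) if isinstance(term, tuple) else str(term)


def _fmt_chrom(chrom) -> str:
    return " & ".join(chrom) if isinstance(chrom, tuple) else str(chrom)


def render_qts_table(model: QTSModel, path=None) -> pd.DataFrame:
    """Table of detected QTSs: one row per component per term, effects and h2
    rounded to 2 decimals, total heritability on the first row."""
    rows = []
    first = True
    for t in model.terms:
        main = t.kind
        rows.append(
            {
                "trait": model.trait,
                "qts": _fmt_term(t.term),
                "chromosome": _fmt_chrom(t.chromosome),
                "effect_type": main,
                "effect_size": round(t.effect, 2),
                "neg_log10_p": round(t.neg_log10_p, 2),
                "h2_pct": round(t.h2.get(main, 0.0), 2),
                "h2_total_pct": round(model.h2_total, 2) if first else np.nan,
            }
        )
        first = False
        inter = "ae" if main == "a" else "aae"
        if inter in t.components:
            for h, env in enumerate(model.environments, start=1):
                rows.append(
                    {
                        "trait": model.trait,
                        "qts": _fmt_term(t.term),
                        "chromosome": _fmt_chrom(t.chromosome),
                        "effect_type": f"{inter}{h}",
                        "effect_size": round(t.env_dev[env], 2),
                        "neg_log10_p": round(-np.log10(max(t.p_env, 1e-300)), 2),
                        "h2_pct": round(t.h2[inter], 2) if h == 1 else np.nan,
                        "h2_total_pct": np.nan,
                    }
                )
    cols = [
        "trait",
        "qts",
        "chromosome",
        "effect_type",
        "effect_size",
        "neg_log10_p",
        "h2_pct",
        "h2_total_pct",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def parse_qts_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def export_network(models, path_prefix=None):
    """Node/edge lists of the QTS architecture across traits.

    Nodes are individual QTSs (trait, detected components, whether any
    environment-specific component is present); edges are epistatic pairs.
    """
    nodes = {}
    edges = []
    for model in models:
        for t in model.terms:
            members = t.term if isinstance(t.term, tuple) else (t.term,)
            env_specific = any(c in ("ae", "aae") for c in t.components)
            for m in members:
                key = (m, model.trait)
                if key not in nodes:
                    nodes[key] = {
                        "qts": m,
                        "trait": model.trait,
                        "components": set(),
                        "environment_specific": False,
                    }
                nodes[key]["components"].update(t.components)
                nodes[key]["environment_specific"] |= env_specific
            if isinstance(t.term, tuple):
                edges.append(
                    {
                        "source": t.term[0],
                        "target": t.term[1],
                        "trait": model.trait,
                        "aa_effect": t.effect,
                    }
                )
    node_df = pd.DataFrame(
        [
            {
                "qts": v["qts"],
                "trait": v["trait"],
                "components": ",".join(sorted(v["components"])),
                "environment_specific": v["environment_specific"],
            }
            for v in nodes.values()
        ],
        columns=["qts", "trait", "components", "environment_specific"],
    )
    edge_df = pd.DataFrame(edges, columns=["source", "target", "trait", "aa_effect"])
    if path_prefix is not None:
        node_df.to_csv(f"{path_prefix}_nodes.tsv", sep="\t", index=False)
        edge_df.to_csv(f"{path_prefix}_edges.tsv", sep="\t", index=False)
    return node_df, edge_df


def model_to_dict(model: QTSModel) -> dict:
    return {
        "trait": model.trait,
        "environments": list(model.environments),
        "mu_hat": model.mu_hat,
        "residual_variance": model.residual_variance,
        "env_variance": model.env_variance,
        "V_P": model.V_P,
        "h2_total": model.h2_total,
        "converged": bool(model.converged),
        "terms": [
            {
                "term": list(t.term) if isinstance(t.term, tuple) else t.term,
                "kind": t.kind,
                "chromosome": list(t.chromosome)
                if isinstance(t.chromosome, tuple)
                else t.chromosome,
                "effect": t.effect,
                "se": t.se,
                "env_dev": dict(t.env_dev),
                "env_dev_se": dict(t.env_dev_se),
                "neg_log10_p": t.neg_log10_p,
                "p_main": t.p_main,
                "p_env": t.p_env,
                "components": list(t.components),
                "var_x": t.var_x,
                "h2": dict(t.h2),
            }
            for t in model.terms
        ],
    }


def _derived_seed(seed: int, *key) -> int:
    # stable across processes (unlike hash())
    digest = [zlib.crc32(str(k).encode()) % (2**31) for k in key]
    ss = np.random.SeedSequence([int(seed), *digest])
    return int(ss.generate_state(1)[0] % (2**31))


def _map_trait(bundle: DatasetBundle, trait: str, cfg: dict, seed: int):
    """Screen -> permutation threshold -> scans -> stepwise -> Gibbs for one trait."""
    scr = cfg.get("screening", {})
    mp = cfg.get("mapping", {})
    k_folds = int(scr.get("k_folds", 5))
    per_chrom_k = int(scr.get("per_chromosome_k", 400))
    pair_top_k = int(scr.get("pair_top_k", 10))
    g, p = bundle.genotypes, bundle.phenotypes

    scores_1d = screening.gmdr_screen_1d(g, p, trait, k_folds, seed=_derived_seed(seed, trait, "screen"))
    candidates = screening.select_top_candidates(scores_1d, per_chrom_k)
    pair_scores = screening.gmdr_screen_2d(
        g, p, trait, candidates, k_folds, seed=_derived_seed(seed, trait, "screen2")
    )
    pair_ranked = sorted(pair_scores, key=lambda s: (-s.testing_accuracy, s.position_bp, s.term))
    pairs = [s.term for s in pair_ranked[:pair_top_k]]

    thr = mapping.permutation_threshold(
        bundle,
        trait,
        candidates,
        alpha=float(mp.get("alpha", 0.05)),
        n_permutations=int(mp.get("n_permutations", 2000)),
        seed=_derived_seed(seed, trait, "perm"),
        pairs=pairs,
    )
    scan1 = mapping.mark_significant(mapping.scan_single_locus(bundle, trait, candidates), thr)
    scan2 = mapping.mark_significant(mapping.scan_epistasis(bundle, trait, pairs), thr)
    selected = mapping.stepwise_select(bundle, trait, scan1, scan2, thr)
    model = mapping.estimate_effects_mcmc(
        bundle,
        trait,
        selected,
        n_iter=int(mp.get("mcmc_iterations", 20_000)),
        burn_in=int(mp.get("burn_in", 2_000)),
        thin=int(mp.get("thin", 10)),
        seed=_derived_seed(seed, trait, "mcmc"),
    )
    return model, thr, candidates


def _simulate_stage(cfg: dict, seed: int):
    sim = cfg.get("simulate", {})
    environments = [str(e) for e in cfg.get("environments", ["E1", "E2"])]
    traits = list(sim.get("traits", ["GYD", "NP", "NFGP", "GW"]))
    presets = {t: simulate.make_truth_preset(t) for t in traits if t in simulate.PRESET_TRAITS}
    loci = [loc for pr in presets.values() for loc in pr.qts_loci()]
    gmap = simulate.build_marker_map(
        int(sim.get("n_chromosomes", 12)),
        int(sim.get("markers_per_chromosome", 20)),
        float(sim.get("chromosome_length_cM", 150.0)),
        loci,
    )
    smc = simulate.SimMapConfig(
        n_chromosomes=int(sim.get("n_chromosomes", 12)),
        markers_per_chromosome=int(sim.get("markers_per_chromosome", 20)),
        chromosome_length_cM=float(sim.get("chromosome_length_cM", 150.0)),
        n_lines=int(sim.get("n_lines", 138)),
        n_selfing_generations=int(sim.get("n_selfing_generations", 12)),
        seed=_derived_seed(seed, "genotypes"),
    )
    g = simulate.simulate_ril_genotypes(smc, gmap, method=sim.get("method", "meiosis"))
    pheno = None
    truths = {}
    for t in traits:
        if t in presets:
            truth = presets[t].truth(environments)
        else:  # unnamed traits are pure-noise controls
            truth = simulate.make_null_truth(residual_sd=float(sim.get("null_sd", 1.0)))
        truths[t] = truth
        table = simulate.simulate_phenotypes(
            g, truth, environments, seed=_derived_seed(seed, "pheno", t), trait_name=t
        )
        pheno = table if pheno is None else pheno.add_trait(table)
    return g, pheno, truths


def _load_stage(cfg: dict):
    inputs = cfg["inputs"]
    g = rio.read_genotypes(
        inputs["genotypes"],
        format=inputs.get("format", "tsv"),
        map_path=inputs.get("map"),
        paternal_sample=inputs.get("paternal_sample"),
        maternal_sample=inputs.get("maternal_sample"),
    )
    p = rio.read_phenotypes(inputs["phenotypes"])
    return g, p


def run_pipeline(config, outdir) -> dict:
    """Execute simulate/load -> summarize -> screen -> map -> condition ->
    report; write all tables plus a machine-readable manifest.

    ``config`` is a YAML path or an equivalent dict; the run is a
    deterministic function of (config, seed).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"config": config, "stages": [], "models": {}, "outputs": []}
    log_lines = []

    def stage(name):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
            log_lines.append(f"{name}: {dt:.3f}s")

        return done

    try:
        done = stage("load")
        if "inputs" in config:
            g, pheno = _load_stage(config)
        else:
            g, pheno, _ = _simulate_stage(config, seed)
            rio.write_genotypes(g, outdir / "genotypes.tsv", map_path=outdir / "marker_map.tsv")
            rio.write_phenotypes(pheno, outdir / "phenotypes.csv")
        bundle = validate_dataset(g, pheno)
        done()

        done = stage("summarize")
        base_traits = [t for t in bundle.trait_names]
        summary = trait_stats.summarize_traits(bundle.phenotypes)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        corr = trait_stats.phenotypic_correlations(bundle.phenotypes)
        for env, (r, _) in corr.phenotypic.items():
            r.to_csv(outdir / f"phenotypic_correlations_{env}.tsv", sep="\t")
        if len(bundle.phenotypes.environments) >= 2 and len(base_traits) >= 2:
            gv = trait_stats.predict_genotypic_values(bundle.phenotypes)
            gr, _ = trait_stats.genotypic_correlations(gv)
            gr.to_csv(outdir / "genotypic_correlations.tsv", sep="\t")
        done()

        done = stage("condition")
        conditionings = [tuple(c) for c in config.get("conditionings", [])]
        pheno_all = bundle.phenotypes
        for target, given in conditionings:
            cond = trait_stats.conditional_phenotypes(pheno_all, target, given)
            pheno_all = pheno_all.add_trait(cond)
        bundle = DatasetBundle(
            genotypes=bundle.genotypes,
            phenotypes=pheno_all,
            trait_names=pheno_all.traits,
            dropped_genotype_lines=bundle.dropped_genotype_lines,
            dropped_phenotype_lines=bundle.dropped_phenotype_lines,
        )
        rio.write_phenotypes(pheno_all, outdir / "phenotypes_with_conditional.csv")
        done()

        done = stage("map")
        models = {}
        for trait in base_traits:
            models[trait], thr, cand = _map_trait(bundle, trait, config, seed)
            log_lines.append(
                f"map {trait}: {len(cand)} candidates, threshold F={thr.threshold:.3f}, "
                f"{len(models[trait].terms)} terms"
            )
        for target, given in conditionings:
            name = f"{target}|{given}"
            models[name], thr, cand = _map_trait(bundle, name, config, seed)
            log_lines.append(
                f"map {name}: {len(cand)} candidates, threshold F={thr.threshold:.3f}, "
                f"{len(models[name].terms)} terms"
            )
        done()

        done = stage("report")
        for name, model in models.items():
            safe = name.replace("|", "_given_")
            render_qts_table(model, outdir / f"qts_{safe}.tsv")
            with open(outdir / f"model_{safe}.yaml", "w") as fh:
                yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
            manifest["models"][name] = f"model_{safe}.yaml"
        by_target: dict = {}
        for target, given in conditionings:
            by_target.setdefault(target, {})[given] = models[f"{target}|{given}"]
        for target, conds in by_target.items():
            cmp_df = compare_conditional(models[target], conds)
            cmp_df.to_csv(outdir / f"comparison_{target}.tsv", sep="\t", index=False)
        export_network(list(models.values()), path_prefix=str(outdir / "network"))
        done()
    except Exception as exc:  # annotate failures with the stage name
        failed = len(manifest["stages"])
        names = ["load", "summarize", "condition", "map", "report"]
        stage_name = names[failed] if failed < len(names) else "unknown"
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir() if p.is_file())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
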