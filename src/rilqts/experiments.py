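"""Calibration and recovery experiments run on the synthetic population.

These drive the full pipeline at the study's scale (138 RILs, two
environments) and measure its operating characteristics: the experiment-wise
type-I error of the permutation-calibrated scan under a pure-noise null, and
the selection/recovery rate of the planted yield-trait effects.
"""

from __future__ import annotations

import numpy as np

from . import mapping, screening, simulate
from .datamodel import validate_dataset

__all__ = ["null_scan_type1_error", "preset_recovery"]


def _child_seed(seed: int, *key) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def null_scan_type1_error(
    n_datasets: int = 200,
    n_lines: int = 138,
    n_markers: int = 100,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Experiment-wise false-positive rate of the permutation max-F scan.

    Simulates ``n_datasets`` null datasets (unlinked markers — one per
    chromosome — and pure-noise phenotypes in two environments), computes
    each dataset's permutation threshold, and reports the fraction of
    datasets declaring at least one significant marker.
    """
    declared = 0
    truth = simulate.make_null_truth(residual_sd=1.0)
    for d in range(n_datasets):
        cfg = simulate.SimMapConfig(
            n_chromosomes=n_markers,
            markers_per_chromosome=1,
            n_lines=n_lines,
            seed=_child_seed(seed, 0, d),
        )
        g = simulate.simulate_ril_genotypes(cfg, method="mosaic")
        p = simulate.simulate_phenotypes(
            g, truth, ["E1", "E2"], seed=_child_seed(seed, 1, d), trait_name="null"
        )
        bundle = validate_dataset(g, p)
        thr = mapping.permutation_threshold(
            bundle,
            "null",
            g.map.marker_ids,
            alpha=alpha,
            n_permutations=n_permutations,
            seed=_child_seed(seed, 2, d),
        )
        scan = mapping.scan_single_locus(bundle, "null", g.map.marker_ids)
        if any(r.F_statistic > thr.threshold for r in scan):
            declared += 1
    return {"rate": declared / n_datasets, "n_datasets": n_datasets}


def preset_recovery(
    trait: str = "GYD",
    n_replicates: int = 50,
    n_lines: int = 138,
    markers_per_chromosome: int = 10,
    per_chromosome_k: int = 3,
    n_permutations: int = 200,
    mcmc_iterations: int = 20_000,
    h2_floor: float = 5.0,
    seed: int = 0,
) -> dict:
    """Selection-and-recovery rate of a trait preset's planted effects.

    Each replicate simulates the preset population, screens candidates,
    calibrates the experiment-wise threshold, selects terms stepwise and
    estimates effects by the Gibbs sampler.  A planted locus with published
    heritability >= ``h2_floor`` percent counts as recovered when it is
    selected and its posterior mean lies within 2 posterior SDs of the
    planted effect.
    """
    preset = simulate.make_truth_preset(trait)
    gmap = preset.build_map(markers_per_chromosome)
    targets = {l.qts: l.a for l in preset.loci if l.h2 >= h2_floor}
    selected_counts = {q: 0 for q in targets}
    recovered_counts = {q: 0 for q in targets}
    truth = preset.truth(["E1", "E2"])
    for rep in range(n_replicates):
        cfg = simulate.SimMapConfig(
            markers_per_chromosome=markers_per_chromosome,
            n_lines=n_lines,
            seed=_child_seed(seed, 10, rep),
        )
        g = simulate.simulate_ril_genotypes(cfg, gmap)
        p = simulate.simulate_phenotypes(
            g, truth, ["E1", "E2"], seed=_child_seed(seed, 11, rep), trait_name=trait
        )
        bundle = validate_dataset(g, p)
        scores = screening.gmdr_screen_1d(
            g, p, trait, k_folds=5, seed=_child_seed(seed, 12, rep)
        )
        candidates = screening.select_top_candidates(scores, per_chromosome_k)
        thr = mapping.permutation_threshold(
            bundle,
            trait,
            candidates,
            n_permutations=n_permutations,
            seed=_child_seed(seed, 13, rep),
        )
        scan = mapping.scan_single_locus(bundle, trait, candidates)
        terms = mapping.stepwise_select(bundle, trait, scan, None, thr)
        if not terms:
            continue
        model = mapping.estimate_effects_mcmc(
            bundle,
            trait,
            terms,
            n_iter=mcmc_iterations,
            seed=_child_seed(seed, 14, rep),
        )
        estimates = {t.term: t for t in model.terms}
        for q, a in targets.items():
            if q in estimates:
                selected_counts[q] += 1
                est = estimates[q]
                if abs(est.effect - a) <= 2.0 * est.se:
                    recovered_counts[q] += 1
    return {
        "targets": targets,
        "selected_rate": {q: selected_counts[q] / n_replicates for q in targets},
        "recovered_rate": {q: recovered_counts[q] / n_replicates for q in targets},
        "recovered_given_selected": {
            q: (recovered_counts[q] / selected_counts[q]) if selected_counts[q] else 0.0
            for q in targets
        },
        "n_replicates": n_replicates,
    }
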