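"""Preliminary candidate-SNP screening by cross-validated classification.

A desk-scale reduction of generalized multifactor dimensionality reduction
(GMDR): trait values are reduced to residuals around their environment
means; each genotype class of a marker (or each of the four cells of a
marker pair) is labeled high/low by the sign of its mean training residual;
the score is the cross-validated proportion of held-out observations whose
residual sign matches their class label (ambiguous cells and zero residuals
earn half credit).  The top-scoring loci per chromosome are kept as
candidates for the mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GenotypeMatrix, PhenotypeTable

__all__ = ["ScreenScore", "gmdr_screen_1d", "gmdr_screen_2d", "select_top_candidates"]


@dataclass
class ScreenScore:
    term: object  # marker_id or (marker_i, marker_j)
    testing_accuracy: float
    chromosome: object  # label or (label_i, label_j)
    position_bp: object  # int or (int_i, int_j)
    rank_within_chromosome: int | None = None


def _screen_arrays(g: GenotypeMatrix, p: PhenotypeTable, trait: str):
    """Aligned arrays for screening: codes, per-line residual sums, obs residuals."""
    if np.isnan(g.codes).any():
        raise ValueError("screening requires a fully imputed genotype matrix")
    sub = p.records[p.records["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present")
    sub = sub[sub["line_id"].isin(set(g.line_ids))]
    env_means = sub.groupby("environment")["value"].transform("mean")
    resid = (sub["value"] - env_means).to_numpy()
    line_pos = {l: i for i, l in enumerate(g.line_ids)}
    line_idx = sub["line_id"].map(line_pos).to_numpy()
    n = g.n_lines
    s_line = np.bincount(line_idx, weights=resid, minlength=n)
    c_line = np.bincount(line_idx, minlength=n).astype(float)
    return line_idx, resid, s_line, c_line


def _line_folds(n_lines: int, k_folds: int, seed: int):
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_lines)
    return [np.sort(chunk) for chunk in np.array_split(perm, k_folds)]


def _credit(labels: np.ndarray, sgn_r: np.ndarray) -> np.ndarray:
    """Per-observation credit matrix given class labels (obs x markers)."""
    s = sgn_r[:, None]
    tie = (labels == 0) | (s == 0)
    match = (labels == s) & ~tie
    return match * 1.0 + tie * 0.5


def gmdr_screen_1d(
    g: GenotypeMatrix, p: PhenotypeTable, trait: str, k_folds: int = 5, seed: int = 0
) -> list[ScreenScore]:
    """Cross-validated single-locus testing accuracy for every marker."""
    line_idx, resid, s_line, c_line = _screen_arrays(g, p, trait)
    X = g.codes
    n, m = X.shape
    plus = (X > 0).astype(float)
    minus = 1.0 - plus
    folds = _line_folds(n, k_folds, seed)
    sgn_r = np.sign(resid)
    acc = np.zeros(m)
    for test_lines in folds:
        train = np.ones(n, dtype=bool)
        train[test_lines] = False
        w = s_line * train
        cnt_p = plus.T @ (c_line * train)
        cnt_m = minus.T @ (c_line * train)
        num_p = plus.T @ w
        num_m = minus.T @ w
        lab_p = np.where(cnt_p > 0, np.sign(num_p), 0.0)
        lab_m = np.where(cnt_m > 0, np.sign(num_m), 0.0)
        obs_test = ~train[line_idx]
        Xl = X[line_idx[obs_test]]
        labels = np.where(Xl > 0, lab_p[None, :], lab_m[None, :])
        acc += _credit(labels, sgn_r[obs_test]).mean(axis=0)
    acc /= len(folds)
    tab = g.map.table
    return [
        ScreenScore(
            term=tab["marker_id"].iloc[j],
            testing_accuracy=float(acc[j]),
            chromosome=tab["chromosome"].iloc[j],
            position_bp=int(tab["position_bp"].iloc[j]),
        )
        for j in range(m)
    ]


def gmdr_screen_2d(
    g: GenotypeMatrix,
    p: PhenotypeTable,
    trait: str,
    candidates,
    k_folds: int = 5,
    seed: int = 0,
    max_pairs: int = 20_000,
) -> list[ScreenScore]:
    """Cross-validated 4-cell testing accuracy for all candidate marker pairs."""
    candidates = list(candidates)
    n_pairs = len(candidates) * (len(candidates) - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(
            f"{n_pairs} pairs exceed the {max_pairs} limit; tighten the single-locus screen"
        )
    line_idx, resid, s_line, c_line = _screen_arrays(g, p, trait)
    n = g.n_lines
    folds = _line_folds(n, k_folds, seed)
    sgn_r = np.sign(resid)
    cols = {m: g.column(m) for m in candidates}
    scores = []
    order = {m: g.map.index_of(m) for m in candidates}
    candidates = sorted(candidates, key=lambda m: order[m])
    for ii in range(len(candidates)):
        for jj in range(ii + 1, len(candidates)):
            mi, mj = candidates[ii], candidates[jj]
            cid = ((cols[mi] > 0).astype(int) << 1) | (cols[mj] > 0).astype(int)
            acc = 0.0
            for test_lines in folds:
                train = np.ones(n, dtype=bool)
                train[test_lines] = False
                num = np.bincount(cid, weights=s_line * train, minlength=4)
                cnt = np.bincount(cid, weights=c_line * train, minlength=4)
                lab = np.where(cnt > 0, np.sign(num), 0.0)
                obs_test = ~train[line_idx]
                labels = lab[cid[line_idx[obs_test]]][:, None]
                acc += float(_credit(labels, sgn_r[obs_test]).mean())
            scores.append(
                ScreenScore(
                    term=(mi, mj),
                    testing_accuracy=acc / len(folds),
                    chromosome=(g.map.chromosome_of(mi), g.map.chromosome_of(mj)),
                    position_bp=(g.map.position_of(mi), g.map.position_of(mj)),
                )
            )
    return scores


def _single_key(s: ScreenScore):
    return (-s.testing_accuracy, s.position_bp, s.term)


def select_top_candidates(
    scores: list[ScreenScore],
    per_chromosome_k: int = 400,
    pair_scores: list[ScreenScore] | None = None,
) -> list:
    """Union of the top-k single-locus terms per chromosome, plus every marker
    appearing in a top-k pair (pairs ranked globally).

    Ties break toward the smaller bp position, then the marker id.  Assigns
    ``rank_within_chromosome`` on the single-locus scores as a side effect.
    """
    by_chrom: dict = {}
    for s in scores:
        by_chrom.setdefault(s.chromosome, []).append(s)
    keep: list = []
    for chrom_scores in by_chrom.values():
        chrom_scores.sort(key=_single_key)
        for rank, s in enumerate(chrom_scores, start=1):
            s.rank_within_chromosome = rank
        keep.extend(s.term for s in chrom_scores[:per_chromosome_k])
    if pair_scores:
        ranked = sorted(
            pair_scores, key=lambda s: (-s.testing_accuracy, s.position_bp, s.term)
        )
        for pair in ranked[:per_chromosome_k]:
            keep.extend(pair.term)
    seen = set()
    out = []
    for m in keep:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out
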