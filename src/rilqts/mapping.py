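"""Genome scan, permutation calibration, stepwise selection, Gibbs estimation
and heritability partitioning for the saturated QTS model.

All tests operate on the two-environment stacked data.  The single-locus
test is an F-test with 2 numerator degrees of freedom (additive effect plus
its environment interaction) against the environment-only null; the pair
test adds the product term and its environment interaction to a model that
already carries both marginal terms.  Experiment-wise significance comes
from the permutation distribution of the maximum F over all candidate
terms, with line identities shuffled jointly across environments so the
environment structure is preserved while genotype-phenotype links break.

Effects of the selected model are estimated by a Gibbs sampler: the
population mean, additive and epistatic effects are fixed (flat priors);
the environment main effect and all environment interactions are random
with scaled-inverse-chi-square variance priors.  Heritability of each
component is its variance contribution relative to the pooled
within-environment phenotypic variance V_P:

    h2(a_i)  = 100 a_i^2 Var(x_i) / V_P
    h2(aa)   = 100 aa^2 Var(x_i x_j) / V_P
    h2(ae_i) = 100 mean_h(ae_hi^2) Var(x_i) / V_P   (mean, not sum, over environments)

and the total heritability is the sum over all detected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import DatasetBundle, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "PermutationThreshold",
    "TermEstimate",
    "QTSModel",
    "scan_single_locus",
    "scan_epistasis",
    "permutation_threshold",
    "mark_significant",
    "stepwise_select",
    "estimate_effects_mcmc",
    "compute_heritability",
    "additive_h2",
    "interaction_h2",
    "pooled_within_env_variance",
]

MAX_NEG_LOG10_P = 300.0
_F_CAP = np.inf  # F is reported as inf on a perfect fit; p is capped instead


@dataclass
class ScanResult:
    term: object  # marker_id or (marker_i, marker_j)
    F_statistic: float
    neg_log10_p: float
    effect: float  # a_hat (single) or aa_hat (pair)
    env_dev: dict  # environment -> interaction deviation
    significant: bool | None = None


@dataclass
class PermutationThreshold:
    alpha: float
    n_permutations: int
    threshold: float
    seed: int
    max_stats: np.ndarray = field(repr=False, default=None)


def _neglog10_sf_f(F, df1, df2) -> float:
    if not np.isfinite(F):
        return MAX_NEG_LOG10_P
    with np.errstate(divide="ignore"):
        val = -stats.f.logsf(F, df1, df2) / np.log(10.0)
    return float(min(val, MAX_NEG_LOG10_P))


def _scan_data(bundle: DatasetBundle, trait: str):
    """Aligned (codes, Y) with lines complete in both environments."""
    p = bundle.phenotypes
    if len(p.environments) != 2:
        raise ValueError("genome scans require exactly 2 environments")
    wide = p.wide(trait).reindex(bundle.genotypes.line_ids)
    keep = wide.notna().all(axis=1).to_numpy()
    lines = [l for l, k in zip(bundle.genotypes.line_ids, keep) if k]
    g = bundle.genotypes.subset_lines(lines)
    if np.isnan(g.codes).any():
        raise ValueError("scan requires a fully imputed genotype matrix")
    Y = wide.loc[keep].to_numpy()
    return g, Y


def _env_residuals(Y: np.ndarray):
    Yr = Y - Y.mean(axis=0, keepdims=True)
    ys = Yr[:, 0] + Yr[:, 1]
    yd = Yr[:, 0] - Yr[:, 1]
    rss0 = float((Yr**2).sum())
    return ys, yd, rss0


def _marker_F(Xc, xss, ys, yd, rss0, n_obs):
    """Vectorised single-locus F over centered marker columns.

    With balanced two-environment stacking the additive column [x; x] and the
    interaction column [x; -x] are exactly orthogonal to each other and to
    the environment design once x is centered, so the fit is closed-form.
    """
    s_a = Xc.T @ ys
    s_e = Xc.T @ yd
    with np.errstate(invalid="ignore", divide="ignore"):
        ssr = (s_a**2 + s_e**2) / (2.0 * xss)
    ssr = np.where(xss > 0, ssr, 0.0)
    df2 = n_obs - 4
    rss1 = np.maximum(rss0 - ssr, 0.0)
    tiny = 1e-10 * max(rss0, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(rss1 > tiny, (ssr / 2.0) / (rss1 / df2), np.inf)
    F = np.where(xss > 0, F, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_hat = np.where(xss > 0, s_a / (2.0 * xss), 0.0)
        ae1_hat = np.where(xss > 0, s_e / (2.0 * xss), 0.0)
    return F, a_hat, ae1_hat


def scan_single_locus(bundle: DatasetBundle, trait: str, candidates) -> list[ScanResult]:
    """F-test of additive + additive-by-environment terms per candidate marker."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate markers supplied")
    g, Y = _scan_data(bundle, trait)
    X = np.column_stack([g.column(m) for m in candidates])
    Xc = X - X.mean(axis=0, keepdims=True)
    xss = (Xc**2).sum(axis=0)
    ys, yd, rss0 = _env_residuals(Y)
    n_obs = 2 * len(Y)
    F, a_hat, ae1 = _marker_F(Xc, xss, ys, yd, rss0, n_obs)
    envs = bundle.phenotypes.environments
    out = []
    for j, m in enumerate(candidates):
        if xss[j] == 0:
            logger.warning("marker %s monomorphic in the sample; skipped", m)
            continue
        out.append(
            ScanResult(
                term=m,
                F_statistic=float(F[j]),
                neg_log10_p=_neglog10_sf_f(F[j], 2, n_obs - 4),
                effect=float(a_hat[j]),
                env_dev={envs[0]: float(ae1[j]), envs[1]: float(-ae1[j])},
            )
        )
    return out


def _stack(col: np.ndarray, kind: str) -> np.ndarray:
    """Stacked design column over (env1 block, env2 block)."""
    if kind == "main":
        return np.concatenate([col, col])
    return np.concatenate([col, -col])  # environment-interaction contrast


def _conditional_block_F(D_null, C_add, y, n_params_implicit=2):
    """F-test of an added column block given a null design.

    ``y`` and all columns are assumed already orthogonal to the intercept
    and environment design (``n_params_implicit`` counts those projected-out
    parameters in the residual degrees of freedom).
    """
    n = len(y)
    if D_null is not None and D_null.shape[1] > 0:
        beta, _, rank0, _ = np.linalg.lstsq(D_null, np.column_stack([y, C_add]), rcond=None)
        fitted = D_null @ beta
        y_r = y - fitted[:, 0]
        C_r = C_add - fitted[:, 1:]
    else:
        rank0 = 0
        y_r = y
        C_r = C_add
    rss0 = float(y_r @ y_r)
    coef, _, q, _ = np.linalg.lstsq(C_r, y_r, rcond=None)
    if q == 0:
        return 0.0, 1.0, np.zeros(C_add.shape[1]), 0
    ssr = float(y_r @ (C_r @ coef))
    ssr = max(0.0, min(ssr, rss0))
    df2 = n - n_params_implicit - int(rank0) - int(q)
    rss1 = rss0 - ssr
    tiny = 1e-10 * max(rss0, 1e-300)
    if rss1 <= tiny or df2 <= 0:
        return np.inf, 0.0, coef, int(q)
    F = (ssr / q) / (rss1 / df2)
    p = float(stats.f.sf(F, q, df2))
    return float(F), p, coef, int(q)


def scan_epistasis(bundle: DatasetBundle, trait: str, pairs, max_pairs: int = 20_000) -> list[ScanResult]:
    """F-test of the product term (and its environment interaction) per pair,
    conditional on both marginal terms."""
    pairs = [tuple(p) for p in pairs]
    if len(pairs) > max_pairs:
        raise ValueError(f"{len(pairs)} pairs exceed the {max_pairs} limit")
    g, Y = _scan_data(bundle, trait)
    Yr = Y - Y.mean(axis=0, keepdims=True)
    y = np.concatenate([Yr[:, 0], Yr[:, 1]])
    n_obs = len(y)
    envs = bundle.phenotypes.environments
    out = []
    for mi, mj in pairs:
        xi = g.column(mi)
        xj = g.column(mj)
        xic, xjc = xi - xi.mean(), xj - xj.mean()
        if xic @ xic == 0 or xjc @ xjc == 0:
            logger.warning("pair (%s, %s) has a monomorphic member; skipped", mi, mj)
            continue
        r = float(np.corrcoef(xi, xj)[0, 1])
        if abs(r) >= 1.0 - 1e-12:
            logger.warning("pair (%s, %s) collinear (|r|=1); skipped", mi, mj)
            continue
        prod = xi * xj
        pc = prod - prod.mean()
        D_null = np.column_stack(
            [_stack(xic, "main"), _stack(xic, "env"), _stack(xjc, "main"), _stack(xjc, "env")]
        )
        C_add = np.column_stack([_stack(pc, "main"), _stack(pc, "env")])
        F, pval, coef, q = _conditional_block_F(D_null, C_add, y)
        if q == 0:
            logger.warning("pair (%s, %s) adds no rank; skipped", mi, mj)
            continue
        nlp = MAX_NEG_LOG10_P if pval == 0 else float(min(-np.log10(pval), MAX_NEG_LOG10_P))
        out.append(
            ScanResult(
                term=(mi, mj),
                F_statistic=F,
                neg_log10_p=nlp,
                effect=float(coef[0]),
                env_dev={envs[0]: float(coef[1]), envs[1]: float(-coef[1])},
            )
        )
    return out


def permutation_threshold(
    bundle: DatasetBundle,
    trait: str,
    candidates,
    alpha: float = 0.05,
    n_permutations: int = 2000,
    seed: int = 0,
    pairs=None,
) -> PermutationThreshold:
    """Experiment-wise max-F threshold from line-identity permutations.

    Each permutation shuffles whole lines (both environment records move
    together), rescans all candidate markers (and, when given, candidate
    pairs) and records the maximum F; the threshold is the empirical
    (1 - alpha) quantile of that null distribution.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    candidates = list(candidates)
    g, Y = _scan_data(bundle, trait)
    X = np.column_stack([g.column(m) for m in candidates])
    Xc = X - X.mean(axis=0, keepdims=True)
    xss = (Xc**2).sum(axis=0)
    ys, yd, rss0 = _env_residuals(Y)
    n = len(Y)
    n_obs = 2 * n
    Yr = Y - Y.mean(axis=0, keepdims=True)
    y_stacked = np.concatenate([Yr[:, 0], Yr[:, 1]])
    pair_cols = []
    if pairs:
        for mi, mj in pairs:
            xi, xj = g.column(mi), g.column(mj)
            pair_cols.append((xi, xj))
    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        F, _, _ = _marker_F(Xc[perm], xss, ys, yd, rss0, n_obs)
        fmax = float(np.max(F)) if len(F) else 0.0
        for xi, xj in pair_cols:
            xip, xjp = xi[perm], xj[perm]
            xic, xjc = xip - xip.mean(), xjp - xjp.mean()
            if xic @ xic == 0 or xjc @ xjc == 0:
                continue
            prod = xip * xjp
            pc = prod - prod.mean()
            D_null = np.column_stack(
                [_stack(xic, "main"), _stack(xic, "env"), _stack(xjc, "main"), _stack(xjc, "env")]
            )
            C_add = np.column_stack([_stack(pc, "main"), _stack(pc, "env")])
            Fp, _, _, q = _conditional_block_F(D_null, C_add, y_stacked)
            if q > 0:
                fmax = max(fmax, Fp)
        max_stats[b] = fmax
    threshold = float(np.quantile(max_stats, 1.0 - alpha, method="higher"))
    return PermutationThreshold(
        alpha=alpha,
        n_permutations=n_permutations,
        threshold=threshold,
        seed=seed,
        max_stats=max_stats,
    )


def mark_significant(results: list[ScanResult], threshold: PermutationThreshold) -> list[ScanResult]:
    for r in results:
        r.significant = bool(r.F_statistic > threshold.threshold)
    return results


def _term_position(term, gmap):
    if isinstance(term, tuple):
        return tuple(sorted(gmap.position_of(m) for m in term))
    return (gmap.position_of(term),)


def _term_block(term, g) -> np.ndarray:
    """Stacked (main, env-interaction) column pair for a marker or pair term."""
    if isinstance(term, tuple):
        col = g.column(term[0]) * g.column(term[1])
    else:
        col = g.column(term)
    cc = col - col.mean()
    return np.column_stack([_stack(cc, "main"), _stack(cc, "env")])


def stepwise_select(
    bundle: DatasetBundle,
    trait: str,
    scan_1d: list[ScanResult],
    scan_2d: list[ScanResult] | None,
    threshold: PermutationThreshold,
    max_rounds: int = 50,
) -> list:
    """Forward/backward selection by conditional F against the experiment-wise
    threshold; iterates to a fixed point (ties break toward smaller positions)."""
    g, Y = _scan_data(bundle, trait)
    Yr = Y - Y.mean(axis=0, keepdims=True)
    y = np.concatenate([Yr[:, 0], Yr[:, 1]])
    terms = [r.term for r in scan_1d]
    if scan_2d:
        terms += [r.term for r in scan_2d]
    blocks = {t: _term_block(t, g) for t in terms}
    gmap = bundle.genotypes.map
    selected: list = []
    thr = threshold.threshold
    for _ in range(max_rounds):
        changed = False
        # forward: best conditional F among non-selected terms
        best = None
        D = np.column_stack([blocks[t] for t in selected]) if selected else None
        for t in terms:
            if t in selected:
                continue
            F, _, _, q = _conditional_block_F(D, blocks[t], y)
            if q == 0 or F <= thr:
                continue
            key = (-F, _term_position(t, gmap), str(t))
            if best is None or key < best[0]:
                best = (key, t)
        if best is not None:
            selected.append(best[1])
            changed = True
        # backward: drop weakest conditional F below threshold, repeat
        while len(selected) > 0:
            worst = None
            for t in selected:
                rest = [u for u in selected if u != t]
                D = np.column_stack([blocks[u] for u in rest]) if rest else None
                F, _, _, _ = _conditional_block_F(D, blocks[t], y)
                key = (F, _term_position(t, gmap), str(t))
                if worst is None or key < worst[0]:
                    worst = (key, t)
            if worst is not None and worst[0][0] <= thr:
                selected.remove(worst[1])
                changed = True
            else:
                break
        if not changed:
            return selected
    raise RuntimeError(f"stepwise selection did not stabilise in {max_rounds} rounds")


# --- Gibbs sampler ----------------------------------------------------------


@dataclass
class TermEstimate:
    term: object
    kind: str  # "a" (single marker) or "aa" (pair)
    chromosome: object
    effect: float
    se: float
    env_dev: dict  # environment -> posterior-mean interaction deviation
    env_dev_se: dict
    neg_log10_p: float
    p_main: float
    p_env: float
    components: list  # subset of ["a", "ae"] or ["aa", "aae"]
    var_x: float
    h2: dict = field(default_factory=dict)  # component -> percent


@dataclass
class QTSModel:
    trait: str
    environments: list
    mu_hat: float
    terms: list
    residual_variance: float
    env_variance: float
    V_P: float
    h2_total: float | None = None
    rhat: dict = field(default_factory=dict)
    converged: bool = True


def pooled_within_env_variance(p: PhenotypeTable, trait: str) -> float:
    """Phenotypic variance after removing environment means (pooled, n-H ddof)."""
    sub = p.records[p.records["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present")
    resid = sub["value"] - sub.groupby("environment")["value"].transform("mean")
    n_env = sub["environment"].nunique()
    vp = float((resid**2).sum() / (len(sub) - n_env))
    if vp <= 0:
        raise ValueError("phenotypic variance must be positive")
    return vp


def _sample_invgamma(rng, shape, rate) -> float:
    return float(rate / rng.gamma(shape))


def estimate_effects_mcmc(
    bundle: DatasetBundle,
    trait: str,
    terms,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 10,
    seed: int = 0,
) -> QTSModel:
    """Gibbs-sampler posterior means and SDs for the selected model.

    Fixed effects (mu, a, aa) carry flat priors; the environment main effect
    and every interaction deviation are random effects with
    inverse-gamma(1e-6, 1e-6) variance priors (a near-improper scaled
    inverse-chi-square).  Flags non-convergence when the split-chain Rhat of
    any fixed effect exceeds 1.1.
    """
    if burn_in >= n_iter:
        raise ValueError(f"burn_in ({burn_in}) must be smaller than n_iter ({n_iter})")
    terms = list(terms)
    g, Y = _scan_data(bundle, trait)
    envs = bundle.phenotypes.environments
    n = len(Y)
    N = 2 * n
    y = np.concatenate([Y[:, 0], Y[:, 1]])

    single = [t for t in terms if not isinstance(t, tuple)]
    pairs = [t for t in terms if isinstance(t, tuple)]
    cols = {}
    for t in single:
        cols[t] = g.column(t)
    for t in pairs:
        cols[t] = g.column(t[0]) * g.column(t[1])

    Xf = np.column_stack([np.ones(N)] + [_stack(cols[t], "main") for t in terms]) if terms else np.ones((N, 1))
    p_f = Xf.shape[1]

    # random-effect blocks: env main (2), ae (2 per single term), aae (2 per pair)
    env_block = np.zeros((N, 2))
    env_block[:n, 0] = 1.0
    env_block[n:, 1] = 1.0
    blocks = [("env", env_block)]
    if single:
        Z = np.zeros((N, 2 * len(single)))
        for i, t in enumerate(single):
            Z[:n, 2 * i] = cols[t]
            Z[n:, 2 * i + 1] = cols[t]
        blocks.append(("ae", Z))
    if pairs:
        Z = np.zeros((N, 2 * len(pairs)))
        for i, t in enumerate(pairs):
            Z[:n, 2 * i] = cols[t]
            Z[n:, 2 * i + 1] = cols[t]
        blocks.append(("aae", Z))

    # precomputed small grams so each sweep is O(p^2), independent of N
    A_f = Xf.T @ Xf
    L_f = np.linalg.cholesky(A_f + 1e-12 * np.eye(p_f))
    Xf_y = Xf.T @ y
    Xf_Z = {name: Xf.T @ Z for name, Z in blocks}
    Z_y = {name: Z.T @ y for name, Z in blocks}
    Z_Z = {}
    for ni, (name_i, Zi) in enumerate(blocks):
        for name_j, Zj in blocks[ni:]:
            Z_Z[(name_i, name_j)] = Zi.T @ Zj
    yty = float(y @ y)

    a0 = b0 = 1e-6
    rng = np.random.default_rng(seed)
    beta = np.linalg.solve(A_f + 1e-12 * np.eye(p_f), Xf_y)
    u = {name: np.zeros(Z.shape[1]) for name, Z in blocks}
    sigma2 = {name: 1.0 for name, _ in blocks}
    sigma2_eps = max(1e-8, float(np.var(y)))

    def rss_current():
        val = yty - 2.0 * beta @ Xf_y + beta @ (A_f @ beta)
        for name, _ in blocks:
            val -= 2.0 * u[name] @ Z_y[name]
            val += 2.0 * beta @ (Xf_Z[name] @ u[name])
        for ni, (name_i, _) in enumerate(blocks):
            for name_j, _ in blocks[ni:]:
                G = Z_Z[(name_i, name_j)]
                w = u[name_i] @ (G @ u[name_j])
                val += w if name_i == name_j else 2.0 * w
        return max(val, 0.0)

    kept_beta = []
    kept_u = []
    kept_sigma = []
    for it in range(n_iter):
        # fixed effects
        rhs = Xf_y.copy()
        for name, _ in blocks:
            rhs -= Xf_Z[name] @ u[name]
        mean = np.linalg.solve(A_f + 1e-12 * np.eye(p_f), rhs)
        z = rng.standard_normal(p_f)
        beta = mean + np.sqrt(sigma2_eps) * np.linalg.solve(L_f.T, z)
        # random-effect blocks
        for name, Z in blocks:
            k = Z.shape[1]
            rhs = Z_y[name] - Xf_Z[name].T @ beta
            for other, _ in blocks:
                if other == name:
                    continue
                G = Z_Z.get((name, other))
                if G is None:
                    G = Z_Z[(other, name)].T
                rhs = rhs - G @ u[other]
            P = Z_Z[(name, name)] / sigma2_eps + np.eye(k) / sigma2[name]
            Lp = np.linalg.cholesky(P)
            mu_u = np.linalg.solve(P, rhs / sigma2_eps)
            u[name] = mu_u + np.linalg.solve(Lp.T, rng.standard_normal(k))
            sigma2[name] = _sample_invgamma(
                rng, a0 + k / 2.0, b0 + float(u[name] @ u[name]) / 2.0
            )
        sigma2_eps = _sample_invgamma(rng, a0 + N / 2.0, b0 + rss_current() / 2.0)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_beta.append(beta.copy())
            kept_u.append({name: u[name].copy() for name, _ in blocks})
            kept_sigma.append({**{k_: v for k_, v in sigma2.items()}, "eps": sigma2_eps})

    B = np.asarray(kept_beta)
    env_u = np.asarray([ku["env"] for ku in kept_u])
    mu_draws = B[:, 0] + env_u.mean(axis=1)
    mu_hat = float(mu_draws.mean())
    env_variance = float(np.mean([ks["env"] for ks in kept_sigma]))
    residual_variance = float(np.mean([ks["eps"] for ks in kept_sigma]))

    # per-component significance from the final least-squares model
    y_env_r = np.concatenate(
        [Y[:, 0] - Y[:, 0].mean(), Y[:, 1] - Y[:, 1].mean()]
    )
    term_blocks = {t: _term_block(t, g) for t in terms}

    def _component_tests(t):
        others = [u_ for u_ in terms if u_ != t]
        D_rest = (
            np.column_stack([term_blocks[u_] for u_ in others]) if others else None
        )
        blk = term_blocks[t]
        F_joint, p_joint, _, _ = _conditional_block_F(D_rest, blk, y_env_r)
        D_main = (
            np.column_stack([D_rest, blk[:, 1:2]]) if D_rest is not None else blk[:, 1:2]
        )
        _, p_main, _, _ = _conditional_block_F(D_main, blk[:, 0:1], y_env_r)
        D_env = (
            np.column_stack([D_rest, blk[:, 0:1]]) if D_rest is not None else blk[:, 0:1]
        )
        _, p_env, _, _ = _conditional_block_F(D_env, blk[:, 1:2], y_env_r)
        nlp = MAX_NEG_LOG10_P if p_joint == 0 else float(min(-np.log10(p_joint), MAX_NEG_LOG10_P))
        return nlp, p_main, p_env

    gmap = bundle.genotypes.map
    estimates = []
    effect_draws = {"mu": mu_draws}
    for j, t in enumerate(terms):
        draws = B[:, j + 1]
        kind = "aa" if isinstance(t, tuple) else "a"
        block_name = "aae" if kind == "aa" else "ae"
        idx = pairs.index(t) if kind == "aa" else single.index(t)
        ublock = np.asarray([ku[block_name][2 * idx : 2 * idx + 2] for ku in kept_u])
        dev = ublock - ublock.mean(axis=1, keepdims=True)  # per-draw deviations
        # the fixed coefficient and the environment-mean of its random
        # interaction are only jointly identified; report their sum as the
        # cross-environment main effect
        draws = draws + ublock.mean(axis=1)
        effect_draws[str(t)] = draws
        nlp, p_main, p_env = _component_tests(t)
        components = [kind]
        if p_env < 0.05:
            components.append("ae" if kind == "a" else "aae")
        chrom = (
            tuple(gmap.chromosome_of(m) for m in t)
            if isinstance(t, tuple)
            else gmap.chromosome_of(t)
        )
        estimates.append(
            TermEstimate(
                term=t,
                kind=kind,
                chromosome=chrom,
                effect=float(draws.mean()),
                se=float(draws.std(ddof=1)),
                env_dev={e: float(dev[:, h].mean()) for h, e in enumerate(envs)},
                env_dev_se={e: float(dev[:, h].std(ddof=1)) for h, e in enumerate(envs)},
                neg_log10_p=nlp,
                p_main=p_main,
                p_env=p_env,
                components=components,
                var_x=float(np.var(cols[t], ddof=1)),
            )
        )

    # split-chain Rhat on the identified effect draws
    rhat = {}
    half = len(B) // 2
    for lab, draws in effect_draws.items():
        c1, c2 = draws[:half], draws[half : 2 * half]
        W = 0.5 * (c1.var(ddof=1) + c2.var(ddof=1))
        Bvar = half * np.var([c1.mean(), c2.mean()], ddof=1)
        rhat[lab] = float(np.sqrt(((half - 1) / half * W + Bvar / half) / W)) if W > 0 else 1.0
    converged = all(v <= 1.1 for v in rhat.values())
    if not converged:
        logger.warning("MCMC split-chain diagnostic exceeds 1.1: %s", rhat)

    model = QTSModel(
        trait=trait,
        environments=list(envs),
        mu_hat=mu_hat,
        terms=estimates,
        residual_variance=residual_variance,
        env_variance=env_variance,
        V_P=pooled_within_env_variance(bundle.phenotypes, trait),
        rhat=rhat,
        converged=converged,
    )
    return compute_heritability(model)


def additive_h2(effect: float, var_x: float, V_P: float) -> float:
    """Heritability percentage of a main (additive or epistatic) effect."""
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    return 100.0 * effect**2 * var_x / V_P


def interaction_h2(env_devs, var_x: float, V_P: float) -> float:
    """Heritability percentage of an environment-interaction term (mean of
    squared per-environment deviations)."""
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    devs = np.asarray(list(env_devs), dtype=float)
    return 100.0 * float(np.mean(devs**2)) * var_x / V_P


def compute_heritability(model: QTSModel) -> QTSModel:
    """Fill per-component h2 and the total h2 (sum over detected components)."""
    total = 0.0
    for t in model.terms:
        t.h2 = {}
        main = t.kind  # "a" or "aa"
        t.h2[main] = additive_h2(t.effect, t.var_x, model.V_P)
        total += t.h2[main]
        inter = "ae" if t.kind == "a" else "aae"
        if inter in t.components:
            t.h2[inter] = interaction_h2(t.env_dev.values(), t.var_x, model.V_P)
            total += t.h2[inter]
    model.h2_total = float(total)
    return model
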