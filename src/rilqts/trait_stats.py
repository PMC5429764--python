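"""Phenotypic summaries, correlations, genotypic values, and conditional traits.

The conditional trait T1|T2 removes from the target trait T1 the variation
linearly predictable from the given component trait T2, separately within
each environment, so that mapping on the conditional values reveals loci
masked or mediated by the component.  The defining contract is that the
conditional values have zero within-environment covariance with T2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PhenotypeTable

__all__ = [
    "summarize_traits",
    "phenotypic_correlations",
    "predict_genotypic_values",
    "genotypic_correlations",
    "conditional_phenotypes",
    "CorrelationReport",
]


def _stars(p: float, levels=(0.05, 0.01), symbols=("*", "**")) -> str:
    out = ""
    for lev, sym in zip(levels, symbols):
        if p <= lev:
            out = sym
    return out


def summarize_traits(p: PhenotypeTable) -> pd.DataFrame:
    """Per-trait, per-environment summary: mean, SD (n-1), min, max, CV% and
    the between-environment mean difference D = mean(E1) - mean(E2).

    D's significance uses Welch's two-sample comparison of environment means
    (coded * at 0.05, ** at 0.01); with two locations this is equivalent to a
    studentized-range test up to scaling.
    """
    rows = []
    for trait in p.traits:
        wide = p.wide(trait)
        env_values = {}
        for env in p.environments:
            v = wide[env].dropna().to_numpy()
            if len(v) < 2:
                raise ValueError(f"trait {trait!r}: fewer than 2 observations in {env}")
            env_values[env] = v
        if len(p.environments) >= 2:
            e1, e2 = p.environments[0], p.environments[1]
            d = float(env_values[e1].mean() - env_values[e2].mean())
            if np.allclose(env_values[e1], env_values[e1][0]) and np.allclose(
                env_values[e2], env_values[e2][0]
            ):
                pval = 1.0 if d == 0 else 0.0
            else:
                pval = float(stats.ttest_ind(env_values[e1], env_values[e2], equal_var=False).pvalue)
        else:
            d, pval = np.nan, np.nan
        for k, env in enumerate(p.environments):
            v = env_values[env]
            mean, sd = float(v.mean()), float(v.std(ddof=1))
            rows.append(
                {
                    "trait": trait,
                    "environment": env,
                    "n": len(v),
                    "mean": mean,
                    "sd": sd,
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
                    # D reported once per trait, on the first environment row
                    "D": d if k == 0 else np.nan,
                    "significance": _stars(pval) if k == 0 and np.isfinite(pval) else "",
                }
            )
    return pd.DataFrame(rows)


def _corr_matrix(frame: pd.DataFrame):
    """Pairwise Pearson r and two-sided p over the columns of ``frame``."""
    cols = list(frame.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pv = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = frame[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                pv.loc[a, b] = pv.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            pv.loc[a, b] = pv.loc[b, a] = float(res.pvalue)
    return r, pv


@dataclass
class CorrelationReport:
    phenotypic: dict = field(default_factory=dict)  # env -> (r_df, p_df)
    genotypic: tuple | None = None  # (r_df, p_df)

    @staticmethod
    def stars(p: float) -> str:
        return _stars(p, levels=(0.05, 0.01, 0.005), symbols=("*", "**", "***"))


def phenotypic_correlations(p: PhenotypeTable, traits=None) -> CorrelationReport:
    """Per-environment Pearson correlations between traits, with p-values."""
    traits = list(traits) if traits is not None else p.traits
    report = CorrelationReport()
    for env in p.environments:
        sub = p.records[p.records["environment"] == env]
        frame = sub.pivot(index="line_id", columns="trait", values="value").reindex(
            columns=traits
        )
        report.phenotypic[env] = _corr_matrix(frame)
    return report


def predict_genotypic_values(p: PhenotypeTable, traits=None) -> pd.DataFrame:
    """Predicted (shrunken) genotypic value per line and trait.

    Fits the two-way model y_hk = m + env_h + g_k + eps with random line
    effects; variance components come from the balanced moment estimators
    (residual = line x environment interaction mean square), and line means
    are shrunk by lambda_k = s2_g / (s2_g + s2_eps / H_k) toward the grand
    mean.  Returns a lines x traits frame.
    """
    traits = list(traits) if traits is not None else p.traits
    out = {}
    for trait in traits:
        wide = p.wide(trait)
        H = wide.shape[1]
        if H < 2:
            raise ValueError(
                f"trait {trait!r}: single environment without replication; residual "
                "variance is inestimable — use raw line means instead"
            )
        complete = wide.dropna()
        if len(complete) < 3:
            raise ValueError(f"trait {trait!r}: fewer than 3 complete lines")
        y = complete.to_numpy()
        grand = y.mean()
        line_means = y.mean(axis=1)
        env_means = y.mean(axis=0)
        resid = y - line_means[:, None] - env_means[None, :] + grand
        n = y.shape[0]
        s2_eps = float((resid**2).sum() / ((n - 1) * (H - 1)))
        ms_lines = H * float(np.var(line_means, ddof=1))
        s2_g = max(0.0, (ms_lines - s2_eps) / H)
        h_k = wide.notna().sum(axis=1).to_numpy()
        obs_means = wide.mean(axis=1).to_numpy()
        with np.errstate(invalid="ignore"):
            lam = np.where(
                (s2_g + s2_eps / np.maximum(h_k, 1)) > 0,
                s2_g / (s2_g + s2_eps / np.maximum(h_k, 1)),
                0.0,
            )
        gv = grand + lam * (obs_means - grand)
        out[trait] = pd.Series(gv, index=wide.index)
    return pd.DataFrame(out)


def genotypic_correlations(gv: pd.DataFrame):
    """Pearson correlations between predicted genotypic values; (r_df, p_df)."""
    return _corr_matrix(gv)


def conditional_phenotypes(
    p: PhenotypeTable,
    target: str,
    given: str,
    mode: str = "phenotype",
    gv: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """Conditional trait values target|given by within-environment regression.

    For each environment h, b_h = Cov_h(target, given) / Var_h(given) and
    y(T1|T2)_hk = y1_hk - b_h (y2_hk - mean_h(y2)).  ``mode="genotypic"``
    regresses instead on the given trait's predicted genotypic values (one
    per line), with ``gv`` from :func:`predict_genotypic_values`.
    """
    if mode not in ("phenotype", "genotypic"):
        raise ValueError(f"unknown conditioning mode {mode!r}")
    name = f"{target}|{given}"
    rows = []
    for env in p.environments:
        sub = p.records[p.records["environment"] == env]
        frame = sub.pivot(index="line_id", columns="trait", values="value")
        if target not in frame or given not in frame:
            raise KeyError(f"traits {target!r}/{given!r} not observed in {env}")
        if mode == "genotypic":
            if gv is None:
                gv = predict_genotypic_values(p, traits=[given])
            frame = frame[[target]].join(gv[[given]].rename(columns={given: "_given"}))
            frame = frame.rename(columns={"_given": given})
        if target == given:
            pair = frame[[target]].dropna()
            t = x = pair[target].to_numpy()
        else:
            pair = frame[[target, given]].dropna()
            t = pair[target].to_numpy()
            x = pair[given].to_numpy()
        var_g = float(np.var(x))
        if var_g == 0:
            raise ValueError(f"given trait {given!r} has zero variance in {env}")
        b = float(np.cov(t, x, bias=True)[0, 1] / var_g)
        cond = t - b * (x - x.mean())
        rows.append(
            pd.DataFrame(
                {
                    "line_id": pair.index,
                    "environment": env,
                    "trait": name,
                    "value": cond,
                }
            )
        )
    return PhenotypeTable(pd.concat(rows, ignore_index=True), p.environments)
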