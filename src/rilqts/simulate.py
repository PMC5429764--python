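"""Synthetic RIL population generator.

Emulates a biparental recombinant inbred population (default: 138 F13 lines
bred by single seed descent) genotyped at mapped SNPs and phenotyped in
multiple environments under the saturated genetic model

    y_hk = mu + sum_i a_i x_ik + sum_{i<j} aa_ij x_ik x_jk
           + e_h + sum_i ae_hi x_ik + sum_{i<j} aae_hij x_ik x_jk + eps_hk

with codes x in {+1 (paternal homozygote QQ), -1 (maternal homozygote qq)}.

Two genotype engines are available: a generation-by-generation meiosis
simulation under Haldane's map function (the default, and the reference for
correctness), and a fast "mosaic" sampler that draws chromosome mosaics
directly with the RIL-adjusted recombination fraction R = 2r/(1+2r).

Trait presets reproduce the published effect architecture of four rice yield
traits (GYD, NP, NFGP, GW) from the Xieyou9308-derived RIL study: additive
effects, one additive-by-environment interaction (GYD), two epistatic pairs
(NP, NFGP), and a residual SD calibrated so that the summed heritabilities
match the reported totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, MarkerMap, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimMapConfig",
    "QTSTruth",
    "TruthPreset",
    "build_marker_map",
    "simulate_ril_haplotypes",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "make_truth_preset",
    "make_null_truth",
    "PRESET_TRAITS",
]

CM_TO_BP = 250_000  # nominal physical/genetic ratio used for synthetic maps


@dataclass
class SimMapConfig:
    n_chromosomes: int = 12
    markers_per_chromosome: int = 20
    chromosome_length_cM: float = 150.0
    n_lines: int = 138
    n_selfing_generations: int = 12  # F13 = F1 + 12 selfing rounds
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "markers_per_chromosome", "n_lines", "n_selfing_generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chromosome_length_cM <= 0:
            raise ValueError("chromosome_length_cM must be positive")


def build_marker_map(
    n_chromosomes: int = 12,
    markers_per_chromosome: int = 20,
    chromosome_length_cM: float = 150.0,
    qts_loci=None,
) -> MarkerMap:
    """Evenly spaced markers per chromosome; named loci replace the grid
    markers nearest to evenly spread positions on their chromosome.

    ``qts_loci`` is a sequence of (marker_id, chromosome_label) pairs.
    """
    rows = []
    for c in range(1, n_chromosomes + 1):
        if markers_per_chromosome == 1:
            cm = np.array([chromosome_length_cM / 2.0])
        else:
            cm = np.linspace(0.0, chromosome_length_cM, markers_per_chromosome)
        for i, x in enumerate(cm):
            rows.append(
                {
                    "marker_id": f"c{c:02d}_m{i + 1:03d}",
                    "chromosome": str(c),
                    "position_bp": int(round(x * CM_TO_BP)) + 1,
                    "position_cM": float(x),
                }
            )
    table = pd.DataFrame(rows)
    if qts_loci:
        by_chrom: dict[str, list[str]] = {}
        for mid, chrom in qts_loci:
            by_chrom.setdefault(str(chrom), []).append(mid)
        for chrom, ids in by_chrom.items():
            idx = table.index[table["chromosome"] == chrom].to_numpy()
            if len(idx) < len(ids):
                raise ValueError(
                    f"chromosome {chrom} has {len(idx)} markers but {len(ids)} named loci"
                )
            cm = table.loc[idx, "position_cM"].to_numpy()
            targets = chromosome_length_cM * (np.arange(1, len(ids) + 1) / (len(ids) + 1))
            taken: set[int] = set()
            for mid, t in zip(ids, targets):
                order = np.argsort(np.abs(cm - t), kind="stable")
                j = next(int(k) for k in order if int(k) not in taken)
                taken.add(j)
                table.loc[idx[j], "marker_id"] = mid
    return MarkerMap(table)


def _haldane_r(delta_cM: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * delta_cM / 100.0))


def _gamete(hapA, hapB, r, rng):
    """One meiotic gamete per line under Haldane (independent interval exchanges)."""
    n, m = hapA.shape
    start = rng.integers(0, 2, size=n)
    if m > 1:
        switch = rng.random((n, m - 1)) < r
        state = np.empty((n, m), dtype=np.int64)
        state[:, 0] = start
        state[:, 1:] = (start[:, None] + np.cumsum(switch, axis=1)) % 2
    else:
        state = start[:, None]
    return np.where(state == 0, hapA, hapB)


def _chromosome_blocks(gmap: MarkerMap):
    if "position_cM" not in gmap.table.columns or gmap.table["position_cM"].isna().any():
        raise ValueError("simulator requires position_cM in the marker map")
    chroms = gmap.table["chromosome"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        cm = gmap.table.loc[cols, "position_cM"].to_numpy()
        yield cols, _haldane_r(np.diff(cm))


def simulate_ril_haplotypes(cfg: SimMapConfig, gmap: MarkerMap | None = None):
    """Run SSD from the F1 and return the terminal haplotype pair.

    Returns ``(hapA, hapB, gmap)`` where the haplotypes are lines x markers
    arrays in {+1, -1}; entries where they differ are residual heterozygotes.
    """
    if gmap is None:
        gmap = build_marker_map(
            cfg.n_chromosomes, cfg.markers_per_chromosome, cfg.chromosome_length_cM
        )
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_lines, gmap.n_markers
    hapA = np.ones((n, m), dtype=np.int64)
    hapB = -np.ones((n, m), dtype=np.int64)
    for _ in range(cfg.n_selfing_generations):
        newA = np.empty_like(hapA)
        newB = np.empty_like(hapB)
        for cols, r in _chromosome_blocks(gmap):
            a, b = hapA[:, cols], hapB[:, cols]
            newA[:, cols] = _gamete(a, b, r, rng)
            newB[:, cols] = _gamete(a, b, r, rng)
        hapA, hapB = newA, newB
    return hapA, hapB, gmap


def _mosaic_codes(cfg: SimMapConfig, gmap: MarkerMap, rng) -> np.ndarray:
    """Direct chromosome-mosaic draw with RIL recombination R = 2r/(1+2r)."""
    n, m = cfg.n_lines, gmap.n_markers
    codes = np.empty((n, m), dtype=np.int64)
    for cols, r in _chromosome_blocks(gmap):
        R = 2.0 * r / (1.0 + 2.0 * r)
        k = len(cols)
        start = rng.integers(0, 2, size=n)
        if k > 1:
            switch = rng.random((n, k - 1)) < R
            state = np.empty((n, k), dtype=np.int64)
            state[:, 0] = start
            state[:, 1:] = (start[:, None] + np.cumsum(switch, axis=1)) % 2
        else:
            state = start[:, None]
        codes[:, cols] = 1 - 2 * state
    return codes


def simulate_ril_genotypes(
    cfg: SimMapConfig, gmap: MarkerMap | None = None, method: str = "meiosis"
) -> GenotypeMatrix:
    """Simulate RIL genotype codes (+1/-1, fully observed).

    ``method="meiosis"`` runs the generation-by-generation SSD engine and
    resolves residual heterozygotes with a fair coin (count logged);
    ``method="mosaic"`` samples terminal mosaics directly.
    """
    line_ids = [f"RIL{i + 1:04d}" for i in range(cfg.n_lines)]
    if method == "meiosis":
        hapA, hapB, gmap = simulate_ril_haplotypes(cfg, gmap)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        het = hapA != hapB
        codes = hapA.astype(float)
        if het.any():
            logger.info(
                "resolved %d residual heterozygous calls (%.3e per entry)",
                int(het.sum()),
                het.mean(),
            )
            codes[het] = rng.choice([-1.0, 1.0], size=int(het.sum()))
        return GenotypeMatrix(line_ids, gmap, codes)
    if method == "mosaic":
        if gmap is None:
            gmap = build_marker_map(
                cfg.n_chromosomes, cfg.markers_per_chromosome, cfg.chromosome_length_cM
            )
        rng = np.random.default_rng(cfg.seed)
        return GenotypeMatrix(line_ids, gmap, _mosaic_codes(cfg, gmap, rng).astype(float))
    raise ValueError(f"unknown simulation method {method!r}")


@dataclass
class QTSTruth:
    """Generative effect configuration for phenotype simulation.

    ``ae_terms`` maps (marker_id, environment) to the interaction deviation
    in that environment; deviations must sum to ~0 over environments per
    marker (and likewise ``aae_terms`` per pair).
    """

    mu: float = 0.0
    additive_terms: list = field(default_factory=list)  # (marker_id, a)
    epistatic_terms: list = field(default_factory=list)  # (marker_i, marker_j, aa)
    env_effects: dict = field(default_factory=dict)  # environment -> e_h
    ae_terms: dict = field(default_factory=dict)  # (marker_id, env) -> ae
    aae_terms: dict = field(default_factory=dict)  # ((marker_i, marker_j), env) -> aae
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def markers(self) -> set:
        out = {m for m, _ in self.additive_terms}
        out |= {m for mi, mj, _ in self.epistatic_terms for m in (mi, mj)}
        out |= {m for m, _ in self.ae_terms}
        out |= {m for (pair, _e) in self.aae_terms for m in pair}
        return out

    def validate(self, gmap: MarkerMap, environments) -> None:
        known = set(gmap.marker_ids)
        unknown = self.markers() - known
        if unknown:
            raise ValueError(f"truth references unknown markers: {sorted(unknown)}")
        for table, label in ((self.ae_terms, "ae"), (self.aae_terms, "aae")):
            sums: dict = {}
            for (key, _env), val in table.items():
                sums[key] = sums.get(key, 0.0) + val
            for key, s in sums.items():
                # printed/rounded deviations are tolerated to 0.05
                if abs(s) > 0.05:
                    raise ValueError(f"{label} deviations for {key} sum to {s}, expected ~0")


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: QTSTruth,
    environments,
    seed: int,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Draw phenotypes from the saturated genetic model given planted effects."""
    environments = [str(e) for e in environments]
    truth.validate(g.map, environments)
    rng = np.random.default_rng(seed)
    n = g.n_lines
    genetic = np.full(n, truth.mu)
    for m, a in truth.additive_terms:
        genetic = genetic + a * g.column(m)
    for mi, mj, aa in truth.epistatic_terms:
        genetic = genetic + aa * g.column(mi) * g.column(mj)
    rows = []
    for env in environments:
        y = genetic + truth.env_effects.get(env, 0.0)
        for (m, e), ae in truth.ae_terms.items():
            if e == env:
                y = y + ae * g.column(m)
        for ((mi, mj), e), aae in truth.aae_terms.items():
            if e == env:
                y = y + aae * g.column(mi) * g.column(mj)
        if truth.residual_sd > 0:
            y = y + rng.normal(0.0, truth.residual_sd, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "line_id": g.line_ids,
                    "environment": env,
                    "trait": trait_name,
                    "value": y,
                }
            )
        )
    return PhenotypeTable(pd.concat(rows, ignore_index=True), environments)


# --- published trait presets -------------------------------------------------
#
# Effect architecture of the four yield traits: per-locus additive effects a,
# -log10(P), per-component heritability h2 (%), per-trait totals, one ae pair
# (GYD) and one epistatic pair each for NP and NFGP.  Environment main
# effects and the population mean come from the two-location trait summary
# (E1 = Hangzhou, E2 = Lingshui).

_PRESETS_RAW = {
    "GYD": {
        "mu": 20.275,
        "env_effects": [2.585, -2.585],
        "h2_total": 43.06,
        "loci": [
            ("rs8203251", "4", "C/T", -1.54, 12.43, 10.91, (-0.65, 0.64), (1.62, 1.61), 1.91),
            ("rs26662491", "5", "A/C", -1.04, 6.09, 5.02, None, None, None),
            ("rs5137246", "6", "T/G", 1.19, 7.76, 6.56, None, None, None),
            ("rs26302731", "6", "G/A", -1.42, 10.75, 9.34, None, None, None),
            ("rs12354751", "9", "A/G", -0.93, 4.98, 4.01, None, None, None),
            ("rs17926420", "12", "C/A", -1.07, 6.40, 5.31, None, None, None),
        ],
        "pairs": [],
    },
    "NP": {
        "mu": 9.405,
        "env_effects": [1.195, -1.195],
        "h2_total": 43.35,
        "loci": [
            ("rs28989077", "3", "C/T", -0.83, 20.65, 18.54, None, None, None),
            ("rs20829501", "7", "C/T", -0.65, 13.01, 11.39, None, None, None),
            ("rs20270326", "9", "T/C", -0.44, 6.23, 5.12, None, None, None),
            ("rs9429313", "10", "A/C", -0.47, 7.16, 5.98, None, None, None),
        ],
        "pairs": [("rs20829501", "rs9429313", 0.29, 3.12, 2.32)],
    },
    "NFGP": {
        "mu": 91.955,
        "env_effects": [-3.735, 3.735],
        "h2_total": 44.40,
        "loci": [
            ("rs41315645", "1", "G/A", 6.31, 9.70, 8.16, None, None, None),
            ("rs27878540", "3", "C/T", 4.31, 4.87, 3.82, None, None, None),
            ("rs29922937", "3", "A/T", 6.45, 10.10, 8.53, None, None, None),
            ("rs31992782", "4", "A/T", -4.60, 5.45, 4.33, None, None, None),
            ("rs645267", "5", "A/G", -5.57, 7.70, 6.35, None, None, None),
            ("rs24646393", "6", "G/A", 4.23, 4.70, 3.67, None, None, None),
            ("rs23681930", "11", "C/T", 5.83, 8.38, 6.96, None, None, None),
        ],
        "pairs": [("rs645267", "rs23681930", 3.55, 3.47, 2.58)],
    },
    "GW": {
        "mu": 25.41,
        "env_effects": [0.27, -0.27],
        "h2_total": 48.36,
        "loci": [
            ("rs7115540", "1", "C/T", -0.49, 7.09, 5.43, None, None, None),
            ("rs12778614", "2", "A/T", -0.44, 5.93, 4.45, None, None, None),
            ("rs18572583", "3", "T/C", -0.82, 18.52, 15.19, None, None, None),
            ("rs13250114", "5", "A/C", -0.50, 7.40, 5.69, None, None, None),
            ("rs23416877", "6", "G/A", -0.54, 8.64, 6.74, None, None, None),
            ("rs2377773", "11", "C/T", -0.46, 6.43, 4.87, None, None, None),
            ("rs25458920", "12", "T/C", 0.51, 7.76, 5.99, None, None, None),
        ],
        "pairs": [],
    },
}

PRESET_TRAITS = tuple(_PRESETS_RAW)


@dataclass
class PresetLocus:
    qts: str
    chromosome: str
    allele: str  # paternal/maternal
    a: float
    log10p: float
    h2: float
    ae: tuple | None = None  # per-environment deviations (ae1, ae2)
    ae_log10p: tuple | None = None
    ae_h2: float | None = None


@dataclass
class PresetPair:
    qts_i: str
    qts_j: str
    aa: float
    log10p: float
    h2: float


@dataclass
class TruthPreset:
    """A trait's published effect architecture plus the calibrated variance.

    ``V_P`` (within-environment phenotypic variance) is solved once from the
    requirement that the planted genetic variance — sum(a^2) + sum(aa^2) +
    mean over environments of sum(ae_h^2), with Var(x) = 1 — accounts for the
    published total heritability; ``residual_sd`` follows as the square root
    of the remainder.
    """

    trait: str
    mu: float
    env_effects: list
    loci: list
    pairs: list
    h2_total: float
    V_P: float
    residual_sd: float

    def qts_loci(self) -> list:
        return [(l.qts, l.chromosome) for l in self.loci]

    def h2_components(self) -> list:
        out = [l.h2 for l in self.loci]
        out += [l.ae_h2 for l in self.loci if l.ae_h2 is not None]
        out += [p.h2 for p in self.pairs]
        return out

    def additive_h2_subtotal(self) -> float:
        return float(sum(l.h2 for l in self.loci))

    def build_map(
        self,
        markers_per_chromosome: int = 20,
        chromosome_length_cM: float = 150.0,
        n_chromosomes: int = 12,
    ) -> MarkerMap:
        return build_marker_map(
            n_chromosomes, markers_per_chromosome, chromosome_length_cM, self.qts_loci()
        )

    def truth(self, environments=("E1", "E2")) -> QTSTruth:
        environments = [str(e) for e in environments]
        if len(environments) != len(self.env_effects):
            raise ValueError("preset defines effects for exactly 2 environments")
        ae_terms = {}
        for l in self.loci:
            if l.ae is not None:
                for env, val in zip(environments, l.ae):
                    ae_terms[(l.qts, env)] = val
        return QTSTruth(
            mu=self.mu,
            additive_terms=[(l.qts, l.a) for l in self.loci],
            epistatic_terms=[(p.qts_i, p.qts_j, p.aa) for p in self.pairs],
            env_effects=dict(zip(environments, self.env_effects)),
            ae_terms=ae_terms,
            aae_terms={},
            residual_sd=self.residual_sd,
        )


def make_truth_preset(trait: str) -> TruthPreset:
    """Published effect preset for one of the four yield traits."""
    if trait not in _PRESETS_RAW:
        raise KeyError(f"unknown trait {trait!r}; expected one of {PRESET_TRAITS}")
    raw = _PRESETS_RAW[trait]
    loci = [PresetLocus(*row) for row in raw["loci"]]
    pairs = [PresetPair(*row) for row in raw["pairs"]]
    genetic_var = sum(l.a**2 for l in loci) + sum(p.aa**2 for p in pairs)
    for l in loci:
        if l.ae is not None:
            genetic_var += float(np.mean([v**2 for v in l.ae]))
    V_P = genetic_var / (raw["h2_total"] / 100.0)
    residual_sd = float(np.sqrt(V_P - genetic_var))
    return TruthPreset(
        trait=trait,
        mu=raw["mu"],
        env_effects=list(raw["env_effects"]),
        loci=loci,
        pairs=pairs,
        h2_total=raw["h2_total"],
        V_P=V_P,
        residual_sd=residual_sd,
    )


def make_null_truth(residual_sd: float = 1.0, mu: float = 0.0) -> QTSTruth:
    """Pure-noise phenotype configuration (no genetic effects)."""
    return QTSTruth(mu=mu, residual_sd=residual_sd)
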