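"""Core data containers for RIL genotype/phenotype datasets.

Genotypes are coded by parental origin: +1 for the paternal homozygote (QQ)
and -1 for the maternal homozygote (qq).  Residual heterozygotes in an
advanced RIL are rare (expected frequency (1/2)^(g-1) after g generations of
selfing) and the genetic model carries no dominance term, so heterozygous or
inconsistent calls are treated as missing and later imputed from flanking
markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "DatasetBundle",
    "impute_missing",
    "validate_dataset",
]


def _chrom_sort_key(label: str):
    s = str(label)
    return (0, int(s)) if s.isdigit() else (1, s)


class MarkerMap:
    """Ordered marker map: marker_id, chromosome, position_bp, optional position_cM.

    Markers are stored sorted by (chromosome, position_bp); chromosome labels
    sort numerically when they are integer strings.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker_id", "chromosome", "position_bp"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        t = table.copy()
        t["marker_id"] = t["marker_id"].astype(str)
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_bp"] = t["position_bp"].astype(int)
        if (t["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1 (1-based coordinates)")
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        t = t.sort_values(
            by=["chromosome", "position_bp"],
            key=lambda col: col.map(_chrom_sort_key) if col.name == "chromosome" else col,
            kind="stable",
        ).reset_index(drop=True)
        if "position_cM" in t.columns and t["position_cM"].notna().all():
            t["position_cM"] = t["position_cM"].astype(float)
            if (t["position_cM"] < 0).any():
                raise ValueError("position_cM must be non-negative")
            for _, grp in t.groupby("chromosome", sort=False):
                if (np.diff(grp["position_cM"].to_numpy()) < 0).any():
                    raise ValueError("position_cM must be non-decreasing within chromosome")
        self.table = t

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosome_of(self, marker_id: str) -> str:
        return self._lookup(marker_id, "chromosome")

    def position_of(self, marker_id: str) -> int:
        return int(self._lookup(marker_id, "position_bp"))

    def _lookup(self, marker_id, col):
        hit = self.table.loc[self.table["marker_id"] == marker_id, col]
        if hit.empty:
            raise KeyError(f"unknown marker {marker_id!r}")
        return hit.iloc[0]

    def index_of(self, marker_id: str) -> int:
        idx = self.table.index[self.table["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def __len__(self) -> int:
        return self.n_markers

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)


class GenotypeMatrix:
    """Lines x markers code matrix with entries in {+1, -1, NaN}."""

    def __init__(self, line_ids, map: MarkerMap, codes):
        codes = np.asarray(codes, dtype=float)
        line_ids = [str(x) for x in line_ids]
        if codes.shape != (len(line_ids), map.n_markers):
            raise ValueError(
                f"codes shape {codes.shape} inconsistent with "
                f"{len(line_ids)} lines x {map.n_markers} markers"
            )
        valid = np.isnan(codes) | (codes == 1.0) | (codes == -1.0)
        if not valid.all():
            raise ValueError("genotype codes must be +1, -1 or missing")
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line ids")
        self.line_ids = line_ids
        self.map = map
        self.codes = codes

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return self.map.n_markers

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.codes).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.line_ids, columns=self.map.marker_ids)

    def column(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self.map.index_of(marker_id)]

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        rows = [pos[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.map, self.codes[rows])


class PhenotypeTable:
    """Long-format phenotype records: (line_id, environment, trait, value).

    ``environments`` is an ordered list; the first listed environment is E1,
    which fixes the sign convention of between-environment differences and of
    reported per-environment interaction deviations.
    """

    def __init__(self, records: pd.DataFrame, environments=None):
        required = {"line_id", "environment", "trait", "value"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"phenotype records missing columns: {sorted(missing)}")
        df = records.loc[:, ["line_id", "environment", "trait", "value"]].copy()
        df["line_id"] = df["line_id"].astype(str)
        df["environment"] = df["environment"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["line_id", "environment", "trait"])
        if dup.any():
            keys = df.loc[dup, ["line_id", "environment", "trait"]]
            raise ValueError(f"duplicate phenotype records:\n{keys.to_string(index=False)}")
        if environments is None:
            environments = list(dict.fromkeys(df["environment"]))
        else:
            environments = [str(e) for e in environments]
            unknown = set(df["environment"]) - set(environments)
            if unknown:
                raise ValueError(f"records reference unlisted environments: {sorted(unknown)}")
        self.records = df.reset_index(drop=True)
        self.environments = environments

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.records["trait"]))

    @property
    def line_ids(self) -> list[str]:
        return sorted(set(self.records["line_id"]))

    def wide(self, trait: str) -> pd.DataFrame:
        """Lines x environments value matrix for one trait (NaN where unobserved)."""
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        w = sub.pivot(index="line_id", columns="environment", values="value")
        return w.reindex(columns=self.environments)

    def subset_lines(self, line_ids) -> "PhenotypeTable":
        keep = self.records["line_id"].isin(set(line_ids))
        return PhenotypeTable(self.records[keep], self.environments)

    def add_trait(self, other: "PhenotypeTable") -> "PhenotypeTable":
        merged = pd.concat([self.records, other.records], ignore_index=True)
        return PhenotypeTable(merged, self.environments)


@dataclass
class DatasetBundle:
    """Genotypes and phenotypes aligned on a common, lexicographically ordered line set."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    trait_names: list = field(default_factory=list)
    dropped_genotype_lines: list = field(default_factory=list)
    dropped_phenotype_lines: list = field(default_factory=list)


def impute_missing(g: GenotypeMatrix, missing_ceiling: float = 0.2) -> GenotypeMatrix:
    """Fill missing codes from the nearest non-missing flanking marker.

    Distance is measured in bp on the same chromosome; exact ties go to the
    left (lower-position) flank.  Markers whose missing fraction exceeds
    ``missing_ceiling`` are rejected.
    """
    frac = g.missing_fraction()
    bad = np.asarray(g.map.marker_ids)[frac > missing_ceiling]
    if bad.size:
        raise ValueError(f"markers exceed missing-data ceiling {missing_ceiling}: {bad.tolist()}")
    codes = g.codes.copy()
    if not np.isnan(codes).any():
        return GenotypeMatrix(g.line_ids, g.map, codes)
    chroms = g.map.table["chromosome"].to_numpy()
    pos = g.map.table["position_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        block = codes[:, cols]
        p = pos[cols]
        miss = np.isnan(block)
        if not miss.any():
            continue
        if miss.all(axis=1).any():
            lines = np.asarray(g.line_ids)[miss.all(axis=1)]
            raise ValueError(
                f"lines with all markers missing on chromosome {chrom}: {lines.tolist()}"
            )
        for i in np.flatnonzero(miss.any(axis=1)):
            row = block[i]
            obs = np.flatnonzero(~np.isnan(row))
            for j in np.flatnonzero(np.isnan(row)):
                d = np.abs(p[obs] - p[j])
                # argmin returns the first (leftmost) index on ties; markers
                # are position-sorted, so ties resolve to the left flank
                row[j] = row[obs[np.argmin(d)]]
            block[i] = row
        codes[:, cols] = block
    return GenotypeMatrix(g.line_ids, g.map, codes)


def validate_dataset(g: GenotypeMatrix, p: PhenotypeTable) -> DatasetBundle:
    """Intersect and align the line sets of a genotype matrix and phenotype table.

    Lines are ordered lexicographically; lines present on only one side are
    dropped and reported in the bundle.
    """
    geno_lines = set(g.line_ids)
    pheno_lines = set(p.records["line_id"])
    common = sorted(geno_lines & pheno_lines)
    if not common:
        raise ValueError("no lines shared between genotypes and phenotypes")
    return DatasetBundle(
        genotypes=g.subset_lines(common),
        phenotypes=p.subset_lines(common),
        trait_names=p.traits,
        dropped_genotype_lines=sorted(geno_lines - pheno_lines),
        dropped_phenotype_lines=sorted(pheno_lines - geno_lines),
    )
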