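"""Readers and writers for genotype matrices, marker maps and phenotype tables.

Supported formats: plain TSV genotype matrix (rows = lines, columns =
marker ids, cells 1/-1/NA), VCF v4.x with the two parent lines as samples,
TSV marker maps, and wide CSV phenotype tables (line_id, environment, one
column per trait).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .datamodel import GenotypeMatrix, MarkerMap, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_marker_map",
    "write_marker_map",
    "read_phenotypes",
    "write_phenotypes",
]


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_marker_map(m: MarkerMap, path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def _default_map(marker_ids) -> MarkerMap:
    # TSV matrices without a companion map get a nominal single-chromosome map
    # preserving column order
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chromosome": "1",
                "position_bp": np.arange(1, len(marker_ids) + 1),
            }
        )
    )


def read_genotypes(
    path,
    format: str = "tsv",
    *,
    map_path=None,
    paternal_sample: str | None = None,
    maternal_sample: str | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix coded by parental origin.

    TSV: cells must be 1, -1 or NA.  VCF: each line's genotype is coded +1
    when it matches the designated paternal parent's homozygous call and -1
    for the maternal parent's; heterozygous, missing or inconsistent calls
    become missing.
    """
    if format == "tsv":
        return _read_tsv(path, map_path)
    if format == "vcf":
        if paternal_sample is None or maternal_sample is None:
            raise ValueError("VCF input requires paternal_sample and maternal_sample names")
        return _read_vcf(path, paternal_sample, maternal_sample)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv(path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    codes = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if pd.isna(cell) or str(cell).strip().upper() in {"NA", ""}:
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: line {i + 2}: cell {cell!r} in column {col!r} "
                    "is not 1, -1 or NA"
                ) from None
            if v not in (1.0, -1.0):
                raise ValueError(f"{path}: line {i + 2}: invalid code {v} in column {col!r}")
            codes[i, j] = v
    marker_ids = [str(c) for c in df.columns]
    gmap = read_marker_map(map_path) if map_path is not None else _default_map(marker_ids)
    if set(gmap.marker_ids) != set(marker_ids):
        raise ValueError("marker map does not match matrix columns")
    order = [marker_ids.index(m) for m in gmap.marker_ids]
    return GenotypeMatrix(df.index.tolist(), gmap, codes[:, order])


def _read_vcf(path, paternal_sample, maternal_sample) -> GenotypeMatrix:
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    for parent in (paternal_sample, maternal_sample):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} absent from VCF samples {samples}")
    lines = [s for s in samples if s not in {paternal_sample, maternal_sample}]
    rows = []
    codes = []
    for n_rec, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf, start=1):
        if rec.id is None:
            raise ValueError(f"{path}: record {n_rec}: missing SNP id")
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"{path}: record {n_rec} ({rec.id}): not a biallelic record")
        pat = rec.samples[paternal_sample].allele_indices
        mat = rec.samples[maternal_sample].allele_indices
        if None in (pat or (None,)) or None in (mat or (None,)):
            raise ValueError(f"{path}: record {n_rec} ({rec.id}): parent genotype missing")
        if len(set(pat)) != 1 or len(set(mat)) != 1 or pat[0] == mat[0]:
            raise ValueError(
                f"{path}: record {n_rec} ({rec.id}): parents must be homozygous and differ"
            )
        row = []
        for s in lines:
            al = rec.samples[s].allele_indices
            if al is None or None in al or len(set(al)) != 1:
                row.append(np.nan)  # het or missing call
            elif al[0] == pat[0]:
                row.append(1.0)
            elif al[0] == mat[0]:
                row.append(-1.0)
            else:
                row.append(np.nan)
        rows.append(
            {
                "marker_id": rec.id,
                "chromosome": str(rec.chrom),
                "position_bp": rec.pos,
            }
        )
        codes.append(row)
    if not rows:
        raise ValueError(f"{path}: no variant records")
    gmap = MarkerMap(pd.DataFrame(rows))
    codes = np.asarray(codes).T  # records x lines -> lines x markers
    order = [pd.DataFrame(rows)["marker_id"].tolist().index(m) for m in gmap.marker_ids]
    return GenotypeMatrix(lines, gmap, codes[:, order])


def write_genotypes(
    g: GenotypeMatrix,
    path,
    format: str = "tsv",
    *,
    map_path=None,
    paternal_sample: str = "ZH9308",
    maternal_sample: str = "XQZB",
) -> None:
    if format == "tsv":
        frame = g.to_frame()
        out = frame.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.index.name = "line_id"
        out.to_csv(path, sep="\t")
        if map_path is not None:
            write_marker_map(g.map, map_path)
        return
    if format == "vcf":
        _write_vcf(g, path, paternal_sample, maternal_sample)
        return
    raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(g, path, paternal_sample, maternal_sample) -> None:
    # REF carries the paternal allele, ALT the maternal allele, so parent
    # samples are 0/0 and 1/1 and +1/-1 codes round-trip exactly
    chroms = list(dict.fromkeys(g.map.table["chromosome"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + [paternal_sample, maternal_sample] + g.line_ids) + "\n")
        for j, row in g.map.table.iterrows():
            calls = []
            for v in g.codes[:, j]:
                if np.isnan(v):
                    calls.append("./.")
                elif v > 0:
                    calls.append("0/0")
                else:
                    calls.append("1/1")
            fields = [
                row["chromosome"],
                str(row["position_bp"]),
                row["marker_id"],
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT",
                "0/0",
                "1/1",
            ]
            fh.write("\t".join(fields + calls) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a wide phenotype CSV (line_id, environment, one column per trait).

    Non-numeric cells become missing records; the count is logged.
    """
    df = pd.read_csv(
        path, dtype={"line_id": str, "environment": str}, float_precision="round_trip"
    )
    for col in ("line_id", "environment"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["line_id", "environment"])
    if dup.any():
        keys = df.loc[dup, ["line_id", "environment"]]
        raise ValueError(f"{path}: duplicate (line, environment) rows:\n{keys.to_string(index=False)}")
    traits = [c for c in df.columns if c not in ("line_id", "environment")]
    if not traits:
        raise ValueError(f"{path}: no trait columns")
    environments = list(dict.fromkeys(df["environment"]))
    long = df.melt(
        id_vars=["line_id", "environment"], value_vars=traits, var_name="trait", value_name="value"
    )
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    n_missing = int(long["value"].isna().sum())
    if n_missing:
        logger.info("read_phenotypes: dropped %d non-numeric/blank cells from %s", n_missing, path)
    long = long.dropna(subset=["value"])
    return PhenotypeTable(long, environments)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    wide = p.records.pivot(index=["line_id", "environment"], columns="trait", values="value")
    wide = wide.loc[:, p.traits].reset_index()
    wide.columns.name = None
    # repr round-trips doubles exactly through the CSV
    wide.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
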