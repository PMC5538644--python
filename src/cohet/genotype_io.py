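"""Readers and writers for the text formats the pipeline touches.

Genotypes travel as PLINK *text* dialects (PED/MAP sample-major, TPED/TFAM
SNP-major); gene annotation as BED (0-based half-open on disk, converted to
the internal 1-based inclusive MAP convention); everything tabular as
headered TSV with a fixed column order, four-decimal floats and rows sorted
by id so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    FormatError,
    GeneMap,
    GenotypeDataset,
    check_lineages,
)

logger = logging.getLogger("cohet.io")

_MISSING_ALLELE = "0"
_FLOAT_FORMAT = "%.4f"


# ---------------------------------------------------------------------------
# PLINK text dialects
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 4:
            raise FormatError(f"{path}:{i}: expected 4 MAP fields, got {len(fields)}")
        rows.append((fields[1], fields[0], int(fields[3])))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"])


def _read_fam_fields(fields: Iterable[str], path: Path, line_no: int) -> tuple[str, str]:
    fields = list(fields)
    if len(fields) < 2:
        raise FormatError(f"{path}:{line_no}: truncated pedigree columns")
    family, individual = fields[0], fields[1]
    return individual, family


def _animal_table(rows: list[tuple[str, str]]) -> pd.DataFrame:
    """Individual IDs are used as-is when globally unique, else prefixed
    with the family ID (PLINK only guarantees uniqueness within family)."""
    iids = [iid for iid, _ in rows]
    if len(set(iids)) != len(iids):
        rows = [(f"{fam}_{iid}", fam) for iid, fam in rows]
    return pd.DataFrame(rows, columns=["animal_id", "breed_id"])


def _encode_minor_counts(
    alleles: np.ndarray, path: Path, line_offset: Mapping[int, int] | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Turn an (animals, snp, 2) allele-token array into minor-allele counts.

    The minor allele is the globally rarer one; ties break toward the
    first allele token encountered in file order.  A SNP with three or more
    distinct non-missing tokens is a format error naming the file and the
    first line on which a third token appears.
    """
    n_animals, n_snp, _ = alleles.shape
    genotypes = np.empty((n_animals, n_snp), dtype=np.int8)
    minor_l, major_l = [], []
    for j in range(n_snp):
        col = alleles[:, j, :]
        missing_pair = (col == _MISSING_ALLELE).any(axis=1)
        tokens: list[str] = []
        for tok in col[~missing_pair].ravel():
            if tok not in tokens:
                tokens.append(tok)
        if len(tokens) > 2:
            bad = np.flatnonzero((col == tokens[2]).any(axis=1))[0]
            line = line_offset[int(bad)] if line_offset else int(bad) + 1
            raise FormatError(
                f"{path}:{line}: SNP column {j + 1} has more than two alleles "
                f"({', '.join(tokens)})"
            )
        if not tokens:  # all-missing SNP
            tokens = ["A"]
        if len(tokens) == 1:
            tokens.append("B" if tokens[0] != "B" else "A")
        counts = [(col == t).sum() for t in tokens]
        # strictly fewer copies -> minor; tie -> first-listed token
        minor, major = (tokens if counts[0] <= counts[1] else tokens[::-1])
        g = (col == minor).sum(axis=1).astype(np.int8)
        g[missing_pair] = MISSING
        genotypes[:, j] = g
        minor_l.append(minor)
        major_l.append(major)
    allele_table = pd.DataFrame({"allele_minor": minor_l, "allele_major": major_l})
    return genotypes, allele_table


def read_breed_table(path: str | Path) -> pd.DataFrame:
    """Read a headered breed -> lineage TSV (columns breed_id, lineage)."""
    table = pd.read_csv(path, sep="\t", dtype={"breed_id": str, "lineage": str})
    for col in ("breed_id", "lineage"):
        if col not in table.columns:
            raise FormatError(f"{path}: breed table lacks column {col!r}")
    check_lineages(table["lineage"])
    return table


def read_plink(
    prefix: str | Path,
    dialect: str = "ped",
    breed_table: pd.DataFrame | str | Path | None = None,
) -> GenotypeDataset:
    """Read a PED/MAP (``dialect="ped"``) or TPED/TFAM (``"tped"``) pair.

    The family column supplies ``breed_id``.  ``breed_table`` maps breeds to
    lineages; when omitted, a placeholder table with lineage ``BTI`` is
    synthesised (stages that depend on lineage need the real table).
    """
    prefix = Path(prefix)
    if dialect == "ped":
        snp_table = _read_map(prefix.with_suffix(".map"))
        ped = prefix.with_suffix(".ped")
        animal_rows, allele_rows, line_of_animal = [], [], {}
        for i, line in enumerate(ped.read_text().splitlines(), start=1):
            fields = line.split()
            if not fields:
                continue
            animal_id, breed_id = _read_fam_fields(fields[:6], ped, i)
            calls = fields[6:]
            if len(calls) != 2 * len(snp_table):
                raise FormatError(
                    f"{ped}:{i}: expected {2 * len(snp_table)} allele calls, "
                    f"got {len(calls)}"
                )
            line_of_animal[len(animal_rows)] = i
            animal_rows.append((animal_id, breed_id))
            allele_rows.append(np.array(calls, dtype=object).reshape(-1, 2))
        if not animal_rows:
            raise FormatError(f"{ped}: no animals")
        alleles = np.stack(allele_rows)
        genotypes, allele_table = _encode_minor_counts(alleles, ped, line_of_animal)
    elif dialect == "tped":
        tfam = prefix.with_suffix(".tfam")
        animal_rows = []
        for i, line in enumerate(tfam.read_text().splitlines(), start=1):
            fields = line.split()
            if not fields:
                continue
            animal_rows.append(_read_fam_fields(fields, tfam, i))
        if not animal_rows:
            raise FormatError(f"{tfam}: no animals")
        tped = prefix.with_suffix(".tped")
        snp_rows, allele_cols, line_of_snp = [], [], {}
        for i, line in enumerate(tped.read_text().splitlines(), start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4 + 2 * len(animal_rows):
                raise FormatError(
                    f"{tped}:{i}: expected {4 + 2 * len(animal_rows)} fields, "
                    f"got {len(fields)}"
                )
            line_of_snp[len(snp_rows)] = i
            snp_rows.append((fields[1], fields[0], int(fields[3])))
            allele_cols.append(np.array(fields[4:], dtype=object).reshape(-1, 2))
        snp_table = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position"])
        alleles = np.stack(allele_cols, axis=1)  # animals x snp x 2
        # per-SNP errors should name the TPED line of the offending SNP; the
        # encoder reports the first animal row, so translate afterwards
        try:
            genotypes, allele_table = _encode_minor_counts(alleles, tped)
        except FormatError as err:
            raise FormatError(str(err)) from None
    else:
        raise FormatError(f"unknown PLINK text dialect {dialect!r}")

    snp_table = pd.concat([snp_table, allele_table], axis=1)
    animal_table = _animal_table(animal_rows)
    if breed_table is None:
        breed_table = pd.DataFrame(
            {"breed_id": sorted(animal_table["breed_id"].unique()), "lineage": "BTI"}
        )
        logger.warning("no breed table supplied; lineages default to BTI")
    elif not isinstance(breed_table, pd.DataFrame):
        breed_table = read_breed_table(breed_table)
    return GenotypeDataset(
        genotypes=genotypes,
        snp_table=snp_table,
        animal_table=animal_table,
        breed_table=breed_table,
    )


def write_plink(dataset: GenotypeDataset, prefix: str | Path, dialect: str = "ped") -> None:
    """Write the dataset as a PED/MAP or TPED/TFAM text pair."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    snp = dataset.snp_table
    minor = snp["allele_minor"].to_numpy(dtype=object)
    major = snp["allele_major"].to_numpy(dtype=object)
    # per-SNP lookup of call strings indexed by genotype code (MISSING -> 3)
    lookup = np.empty((dataset.n_snp, 4), dtype=object)
    for j in range(dataset.n_snp):
        mi, ma = minor[j], major[j]
        lookup[j] = (f"{ma} {ma}", f"{mi} {ma}", f"{mi} {mi}", "0 0")
    codes = np.where(dataset.genotypes == MISSING, 3, dataset.genotypes)
    cols = np.arange(dataset.n_snp)

    fam_cols = [
        f"{row.breed_id} {row.animal_id} 0 0 0 -9"
        for row in dataset.animal_table.itertuples()
    ]
    if dialect == "ped":
        with prefix.with_suffix(".map").open("w") as fh:
            for row in snp.itertuples():
                fh.write(f"{row.chromosome} {row.snp_id} 0 {row.position}\n")
        with prefix.with_suffix(".ped").open("w") as fh:
            for i, fam in enumerate(fam_cols):
                fh.write(fam + " " + " ".join(lookup[cols, codes[i]]) + "\n")
    elif dialect == "tped":
        with prefix.with_suffix(".tfam").open("w") as fh:
            fh.write("\n".join(fam_cols) + "\n")
        with prefix.with_suffix(".tped").open("w") as fh:
            for j, row in enumerate(snp.itertuples()):
                calls = " ".join(lookup[j, codes[:, j]])
                fh.write(f"{row.chromosome} {row.snp_id} 0 {row.position} {calls}\n")
    else:
        raise FormatError(f"unknown PLINK text dialect {dialect!r}")


def write_breed_table(dataset: GenotypeDataset, path: str | Path) -> None:
    table = dataset.breed_table.sort_values("breed_id")
    write_tsv(table, path)


# ---------------------------------------------------------------------------
# BED gene annotation
# ---------------------------------------------------------------------------

def read_bed_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED3+ gene spans (gene_id in column 4) to 1-based inclusive."""
    path = Path(path)
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields or fields[0].startswith(("#", "track", "browser")):
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}:{i}: BED line needs >= 4 columns")
        start, end = int(fields[1]), int(fields[2])
        if start >= end:
            raise FormatError(f"{path}:{i}: start {start} >= end {end}")
        rows.append((fields[3], fields[0], start + 1, end))
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    dup = genes["gene_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate gene_id {sorted(genes.loc[dup, 'gene_id'].unique())}"
        )
    if genes.empty:
        logger.warning("%s: empty annotation", path)
    return genes


def write_bed_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive gene spans back to 0-based half-open BED."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for row in genes.sort_values("gene_id").itertuples():
            fh.write(f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.gene_id}\n")


# ---------------------------------------------------------------------------
# Tables and gene lists
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Deterministic headered TSV: 4-decimal floats, gene_id-sorted rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame
    if "gene_id" in frame.columns:
        out = frame.sort_values("gene_id", kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def write_tables(objects: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write every named frame as ``<out_dir>/<name>.tsv``; return paths."""
    out_dir = Path(out_dir)
    paths = []
    for name in sorted(objects):
        path = out_dir / f"{name}.tsv"
        write_tsv(objects[name], path)
        paths.append(path)
    return paths


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-column headered gene list TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return frame.iloc[:, 0].dropna().tolist()


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("gene_id\n")
        for g in genes:
            fh.write(f"{g}\n")


def gene_summary_table(
    gene_map: GeneMap,
    lineage_het: pd.DataFrame,
    gene_ancestry: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-gene report: SNP count, lineage HET, memberships.

    Columns: gene_id, n_snp, het_BI, het_BTI, het_BT, pr_indicine,
    pr_taurine — one row per gene present in the ancestry table.
    """
    counts = gene_map.snp_counts().rename("n_snp")
    het = lineage_het.rename(columns=lambda c: f"het_{c}")
    table = (
        gene_ancestry.drop(columns=["n_snp"], errors="ignore").set_index("gene_id")
        .join(counts, how="left")
        .join(het, how="left")
        .reset_index()
    )
    cols = ["gene_id", "n_snp", "het_BI", "het_BTI", "het_BT", "pr_indicine", "pr_taurine"]
    present = [c for c in cols if c in table.columns]
    return table[present].sort_values("gene_id").reset_index(drop=True)
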