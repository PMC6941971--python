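"""Readers and writers for every external format the pipeline touches.

Formats: plain TSV matrices (genes x samples), GCT 1.2/1.3 dense matrices,
chemical->protein link tables in the ``protein_chemical.links`` dialect
(columns chemical / protein / combined_score), protein-protein link TSVs,
survival TSVs (id, time, event[, covariates]), and the typed result tables.

All writers are deterministic: fixed column order, floats at 6 significant
digits, UTF-8, LF line endings — a rewritten file is byte-identical.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CohortData,
    EnrichmentTable,
    MatchScoreTable,
    SurvivalTable,
    TargetLinkTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# expression matrices: TSV and GCT
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples matrix from TSV or GCT (sniffed by header)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#1.2") or first.startswith("#1.3"):
        return read_gct(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a dense GCT 1.2 or 1.3 file into a genes-x-samples frame.

    Row/column metadata fields of GCT 1.3 are parsed and discarded; only the
    data block is returned.  GCTX (HDF5) is not supported.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        dims = fh.readline().split()
        if version == "#1.2":
            n_rows, n_cols = int(dims[0]), int(dims[1])
            n_rmeta, n_cmeta = 1, 0
        elif version == "#1.3":
            n_rows, n_cols, n_rmeta, n_cmeta = (int(x) for x in dims[:4])
            n_rmeta += 1  # id column counts toward the row-annotation block
        else:
            raise ValidationError(f"{path}: unsupported GCT version {version!r}")
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[n_rmeta:]
        for _ in range(n_cmeta):
            fh.readline()
        body = pd.read_csv(
            StringIO(fh.read()), sep="\t", header=None, nrows=n_rows
        )
    index = body.iloc[:, 0].astype(str)
    data = body.iloc[:, n_rmeta:n_rmeta + n_cols]
    data.columns = sample_ids[:n_cols]
    data.index = pd.Index(index.to_numpy(), name=None)
    if data.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{path}: GCT data block {data.shape} != declared ({n_rows}, {n_cols})"
        )
    return data.astype(float)


def write_gct(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a genes-x-samples frame as a dense GCT 1.2 file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
        fh.write("NAME\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for gene, row in frame.iterrows():
            vals = "\t".join(FLOAT_FORMAT % v for v in row.to_numpy())
            fh.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _orient_factor_table(factors: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Return factors-x-samples, auto-transposing by sample-id overlap."""
    cols = {str(c).strip() for c in factors.columns}
    rows = {str(r).strip() for r in factors.index}
    samples = set(sample_ids)
    if cols & samples:
        return factors
    if rows & samples:
        return factors.T
    raise ValidationError(
        "no overlap between factor-table and expression sample ids"
    )


def read_cohort(
    factor_table_path: str | Path,
    expression_path: str | Path,
    landmark_list: list[str],
    cohort_id: str | None = None,
    allow_missing_genes: bool = False,
) -> CohortData:
    """Load one cohort and restrict it to shared samples and landmark genes.

    The expression file is a TSV matrix (genes x samples) or GCT; the factor
    table is a TSV oriented either way (auto-detected by matching sample ids).
    Expression rows are centred; dropped genes/samples are logged.  Missing
    expression values are rejected; missing factor values are kept as NaN.
    """
    expr = read_matrix(expression_path)
    expr.index = expr.index.astype(str).str.strip()
    expr.columns = expr.columns.astype(str).str.strip()
    if expr.isna().any().any():
        raise ValidationError(f"{expression_path}: missing expression values")

    factors = pd.read_csv(factor_table_path, sep="\t", index_col=0)
    factors = _orient_factor_table(factors, list(expr.columns))
    factors.index = factors.index.astype(str).str.strip()
    factors.columns = factors.columns.astype(str).str.strip()

    shared = [s for s in expr.columns if s in set(factors.columns)]
    if not shared:
        raise ValidationError("no overlap between expression and factor sample ids")
    dropped = expr.shape[1] - len(shared)
    if dropped:
        logger.info("read_cohort: dropped %d unmatched samples", dropped)

    landmark = [str(g).strip() for g in landmark_list]
    missing = [g for g in landmark if g not in expr.index]
    if missing and not allow_missing_genes:
        raise ValidationError(
            f"landmark genes absent from expression: {missing}"
        )
    kept_genes = [g for g in landmark if g in expr.index]
    if missing:
        logger.info("read_cohort: %d landmark genes missing, dropped", len(missing))

    Z = expr.loc[kept_genes, shared].to_numpy(dtype=float)
    Z = Z - Z.mean(axis=1, keepdims=True)
    Y = factors.loc[:, shared].to_numpy(dtype=float)

    cohort = CohortData(
        cohort_id=cohort_id or Path(expression_path).stem,
        patients=shared,
        factors=[str(f) for f in factors.index],
        Y=Y,
        gene_ids=kept_genes,
        Z=Z,
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# link tables
# ---------------------------------------------------------------------------

def read_target_links(path: str | Path, min_score: int = 0) -> TargetLinkTable:
    """Read a chemical->protein link TSV with 0-1000 combined scores.

    All records with score >= ``min_score`` are kept (the R+/R- split happens
    later, at enrichment time); scores are range-validated with the offending
    line reported; duplicated (chemical, protein) pairs keep the max score.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"chemical", "protein", "combined_score"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(needed)}")
    df = df[["chemical", "protein", "combined_score"]].copy()
    df["chemical"] = df["chemical"].astype(str).str.strip()
    df["protein"] = df["protein"].astype(str).str.strip()
    df["combined_score"] = df["combined_score"].astype(int)
    bad = (df["combined_score"] < 0) | (df["combined_score"] > 1000)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValidationError(
            f"{path}: combined_score outside [0, 1000] at line {line}"
        )
    dups = df.duplicated(["chemical", "protein"], keep=False)
    if dups.any():
        logger.warning(
            "read_target_links: %d duplicate (chemical, protein) pairs, keeping max",
            int(dups.sum()),
        )
        df = (
            df.groupby(["chemical", "protein"], as_index=False, sort=False)
            ["combined_score"].max()
        )
    df = df[df["combined_score"] >= min_score].reset_index(drop=True)
    table = TargetLinkTable(records=df)
    table.validate()
    return table


def read_protein_links(path: str | Path) -> pd.DataFrame:
    """Read a protein-protein link TSV (protein1, protein2, combined_score)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"protein1", "protein2", "combined_score"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(needed)}")
    return df[["protein1", "protein2", "combined_score"]]


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival TSV (id, time, event[, covariates])."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    table = SurvivalTable(table=df)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# typed table writers / readers (round-trip safe)
# ---------------------------------------------------------------------------

_MATCH_COLUMNS = ["drug", "feature", "direction", "score", "sigma_bar",
                  "n_cell_lines"]


def _write_frame(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n", encoding="utf-8")


def write_tables(objects: dict[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write typed tables as deterministic TSVs; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in objects.items():
        path = out_dir / f"{name}.tsv"
        if isinstance(obj, MatchScoreTable):
            cols = _MATCH_COLUMNS + [
                c for c in obj.table.columns if c not in _MATCH_COLUMNS
            ]
            _write_frame(obj.table[cols], path)
        elif isinstance(obj, EnrichmentTable):
            _write_frame(obj.table[list(EnrichmentTable.COLUMNS)], path)
        elif isinstance(obj, TargetLinkTable):
            _write_frame(obj.records, path)
        elif isinstance(obj, SurvivalTable):
            _write_frame(obj.table, path, index=True)
        elif isinstance(obj, pd.DataFrame):
            _write_frame(obj, path, index=bool(obj.index.name))
        else:
            raise TypeError(f"write_tables: unsupported object {type(obj)!r}")
        written[name] = path
    return written


def read_match_scores(path: str | Path) -> MatchScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"direction": str})
    table = MatchScoreTable(table=df)
    table.validate()
    return table


def read_enrichment(path: str | Path) -> EnrichmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"direction": str})
    table = EnrichmentTable(table=df)
    table.validate()
    return table


def write_signatures(sets: list, path: str | Path) -> None:
    """Signature TSV: gene_id + one column per (cohort, feature)."""
    frames = {}
    for s in sets:
        for j, feat in enumerate(s.feature_names):
            frames[f"{s.cohort_id}:{feat}"] = pd.Series(
                s.B[:, j], index=s.gene_ids
            )
    df = pd.DataFrame(frames)
    df.index.name = "gene_id"
    _write_frame(df, Path(path), index=True)
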