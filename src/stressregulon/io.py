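"""File formats: expression TSV + design table, gene-revision filter,
GEO series-matrix blocks, and the run's output manifest.

The expression matrix is a genes x samples table of strictly positive
normalized signal intensities.  The analysis background — the gene universe
for both the D1 denominator and enrichment — is whatever survives the
gene-revision filter, which drops loci that were split, merged or deleted
in later genome revisions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LoadError

logger = logging.getLogger(__name__)

COLLAPSE_RULES = ("median", "mean", "max")
#: Significant digits used for numeric TSV output.
TSV_PRECISION = 12


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "condition"}
    missing = required - set(design.columns)
    if missing:
        raise LoadError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise LoadError(f"duplicate sample_id in design table: {dup!r}")
    return design


def read_expression(path, design_path=None, collapse: str = "median"
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load a TSV expression matrix (first column gene IDs, header sample IDs).

    Duplicate probe rows for one gene are collapsed per ``collapse``
    (median by default).  Returns (matrix, design); design is None when no
    design path is given.  Raises :class:`LoadError` naming the offending
    gene/sample on nonnumeric or nonpositive cells and on design mismatches.
    """
    if collapse not in COLLAPSE_RULES:
        raise ValueError(f"collapse must be one of {COLLAPSE_RULES}, got {collapse!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str).str.strip()
    raw.index.name = "gene_id"
    matrix = _validate_and_collapse(raw, collapse)

    design = None
    if design_path is not None:
        design = read_design(design_path)
        unmatched = [c for c in matrix.columns if c not in set(design["sample_id"])]
        if unmatched:
            raise LoadError(f"matrix columns without a design row: {unmatched}")
    return matrix, design


def _validate_and_collapse(raw: pd.DataFrame, collapse: str) -> pd.DataFrame:
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.any().any():
        gene = values.index[bad.any(axis=1)][0]
        sample = values.columns[bad.loc[gene]][0]
        raise LoadError(f"nonnumeric signal intensity for gene {gene!r}, sample {sample!r}")
    nonpos = values <= 0
    if nonpos.any().any():
        gene = values.index[nonpos.any(axis=1)][0]
        sample = values.columns[nonpos.loc[gene]][0]
        raise LoadError(f"nonpositive signal intensity for gene {gene!r}, sample {sample!r}")
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        logger.info("collapsing %d duplicate probe rows by %s", n_dup, collapse)
        agg = {"median": "median", "mean": "mean", "max": "max"}[collapse]
        values = values.groupby(level=0, sort=False).agg(agg)
    return values


def read_revision_list(path) -> set[str]:
    """One gene ID per line (blank lines and '#' comments ignored)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def apply_revision_filter(matrix: pd.DataFrame, revision: set[str]) -> pd.DataFrame:
    """Drop revised (split/merged/deleted) loci; the result defines the
    analysis background."""
    keep = ~matrix.index.isin(revision)
    if not keep.any():
        logger.warning("revision filter removed every gene")
    return matrix.loc[keep]


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Extract the data block of a GEO series-matrix file.

    Only the ``!series_matrix_table_begin`` … ``!series_matrix_table_end``
    block is parsed; sample metadata lines are ignored — strain/condition
    assignment must come from a user-supplied design table.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise LoadError("no !series_matrix_table_begin/end block found") from None
    block = "\n".join(lines[start + 1:end])
    from io import StringIO
    table = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip().str.strip('"')
    table.columns = [str(c).strip().strip('"') for c in table.columns]
    table.index.name = "gene_id"
    return table.apply(pd.to_numeric, errors="coerce")


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write a matrix losslessly up to 12 significant digits."""
    matrix.to_csv(path, sep="\t", float_format=f"%.{TSV_PRECISION}g")


def write_results(objects: dict[str, pd.DataFrame], out_dir, summary: dict | None = None,
                  precision: int = 6) -> dict[str, str]:
    """Write every pipeline product as TSV plus one JSON run summary.

    ``objects`` maps a short product name to a DataFrame; each is written as
    ``<name>.tsv`` with ``precision`` significant digits.  The JSON summary
    records the caller-supplied metadata (config, seed, …), per-product row
    counts and file checksums.  Returns the file manifest (name → sha256).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise LoadError(f"cannot create output directory {out}: {exc}") from exc

    manifest: dict[str, str] = {}
    counts: dict[str, int] = {}
    for name, df in objects.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        counts[name] = len(df)

    payload = {"summary": summary or {}, "row_counts": counts, "files": manifest}
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    manifest[summary_path.name] = hashlib.sha256(summary_path.read_bytes()).hexdigest()
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
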