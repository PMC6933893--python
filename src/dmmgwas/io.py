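"""Genotype/phenotype readers and writers, and mode imputation.

Two genotype dialects are supported:

* CSV — header row of SNP ids, first column the sample id, cells in
  {0, 1, 2} or NA.
* PLINK ``.raw`` — whitespace-delimited with the six leading non-genotype
  columns FID IID PAT MAT SEX PHENOTYPE, then one column per SNP; NA marks
  a missing genotype.

Readers never coerce: any genotype token outside {0, 1, 2, NA} is a parse
error naming the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "read_genotypes", "write_genotypes",
           "impute_mode", "read_phenotype", "write_phenotype", "write_scores"]

PLINK_LEAD_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_VALID = {"0", "1", "2"}
_MISSING = {"NA", "nan", ""}


@dataclass
class GenotypeTable:
    """n x p genotype matrix with ids; missing cells are NaN."""

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray  # float array, entries in {0,1,2} or NaN
    source_format: str = "csv"

    def __post_init__(self):
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lengths do not match the value matrix")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != p:
            raise ValueError("duplicate SNP ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-{0,1,2} genotype values")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


class GenotypeParseError(ValueError):
    pass


def _parse_cell(tok: str, line_no: int, path) -> float:
    if tok in _VALID:
        return float(tok)
    if tok in _MISSING:
        return np.nan
    raise GenotypeParseError(
        f"{path}: line {line_no}: invalid genotype token {tok!r} "
        "(expected 0, 1, 2 or NA)")


def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeTable:
    path = Path(path)
    if format == "csv":
        return _read_delimited(path, sep=",", lead_cols=1, fmt="csv")
    if format == "plink_raw":
        return _read_delimited(path, sep=None, lead_cols=len(PLINK_LEAD_COLS),
                               fmt="plink_raw")
    raise ValueError(f"unknown genotype format {format!r}")


def _read_delimited(path: Path, sep, lead_cols: int, fmt: str) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    header = lines[0].split(sep) if sep else lines[0].split()
    if len(header) <= lead_cols:
        raise GenotypeParseError(f"{path}: line 1: malformed header")
    snp_ids = [h.strip() for h in header[lead_cols:]]
    sample_ids, rows = [], []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split(sep) if sep else line.split()
        if len(toks) != len(header):
            raise GenotypeParseError(
                f"{path}: line {i}: expected {len(header)} fields, "
                f"got {len(toks)}")
        sid = toks[1] if fmt == "plink_raw" else toks[0]
        sample_ids.append(sid.strip())
        rows.append([_parse_cell(t.strip(), i, path) for t in toks[lead_cols:]])
    return GenotypeTable(sample_ids=sample_ids, snp_ids=snp_ids,
                         values=np.asarray(rows, dtype=float),
                         source_format=fmt)


def write_genotypes(table: GenotypeTable, path: str | Path,
                    format: str = "csv") -> None:
    path = Path(path)
    vals = table.values

    def cell(v: float) -> str:
        return "NA" if np.isnan(v) else str(int(v))

    if format == "csv":
        lines = ["sample_id," + ",".join(table.snp_ids)]
        for sid, row in zip(table.sample_ids, vals):
            lines.append(sid + "," + ",".join(cell(v) for v in row))
    elif format == "plink_raw":
        lines = [" ".join(PLINK_LEAD_COLS + table.snp_ids)]
        for sid, row in zip(table.sample_ids, vals):
            lead = [sid, sid, "0", "0", "0", "-9"]
            lines.append(" ".join(lead + [cell(v) for v in row]))
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def impute_mode(table: GenotypeTable) -> GenotypeTable:
    """Replace each missing cell by its SNP's most frequent observed
    genotype; ties break toward the smaller genotype value."""
    vals = table.values.copy()
    missing_cols = np.where(np.isnan(vals).any(axis=0))[0]
    for j in missing_cols:
        col = vals[:, j]
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise ValueError(
                f"SNP {table.snp_ids[j]!r} has no observed genotypes; "
                "cannot impute its mode")
        counts = np.array([(observed == g).sum() for g in (0.0, 1.0, 2.0)])
        mode = float(np.argmax(counts))  # argmax takes the smallest on ties
        col[np.isnan(col)] = mode
    return GenotypeTable(sample_ids=list(table.sample_ids),
                         snp_ids=list(table.snp_ids), values=vals,
                         source_format=table.source_format)


# ---------------------------------------------------------------------------
# phenotypes and scores

def write_phenotype(sample_ids, y, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "value": np.asarray(y)}).to_csv(
        path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["sample_id", "value"]:
        raise ValueError(f"{path}: expected columns sample_id, value")
    y = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{path}: non-finite phenotype values")
    return df["sample_id"].astype(str).tolist(), y


def write_scores(snp_ids, omega, path: str | Path) -> None:
    """Selector score table: snp_id, omega, abs_omega, rank (1 = strongest)."""
    omega = np.asarray(omega, dtype=float)
    abs_omega = np.abs(omega)
    rank = np.empty(len(omega), dtype=int)
    rank[np.argsort(-abs_omega, kind="stable")] = np.arange(1, len(omega) + 1)
    pd.DataFrame({"snp_id": snp_ids, "omega": omega, "abs_omega": abs_omega,
                  "rank": rank}).to_csv(path, sep="\t", index=False)
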