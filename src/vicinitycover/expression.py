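"""Expression profiles: reading, filtering, normalization, PCC and estimation error.

A profile is a gene's TPM vector across tissues.  When a gene's profile is
estimated "for free" by copying its assigned reference gene's profile, the
quality of the estimate is 1 - PCC between the two profiles, which ranges
from 0 (perfectly correlated) to 2 (perfectly anti-correlated).  Averaging
that error over genes scores a whole cover solution.

Profiles that are incomplete (missing values) or flat (zero variance across
tissues) carry no correlation information and are dropped before any PCC is
computed.  The normalization used for display — log2(TPM+1), per-gene z-score,
then min-max to [0,1] — leaves PCC of the log profiles untouched because the
last two steps are affine per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionError",
    "read_expression",
    "filter_profiles",
    "normalize_profiles",
    "pcc",
    "estimation_error",
    "ErrorSummary",
]

ErrorMode = Literal["estimated_only", "all_genes"]


class ExpressionError(ValueError):
    """Raised for malformed expression input or degenerate profiles."""


@dataclass
class ExpressionMatrix:
    """Genes x tissues matrix (TPM unless flagged otherwise)."""

    values: pd.DataFrame  # index: gene ids, columns: tissue labels
    log_transformed: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ExpressionError(f"duplicate gene ids: {dup[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def write_gct(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{self.n_genes}\t{self.n_tissues}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, self.tissues)) + "\n")
            for gid, row in self.values.iterrows():
                vals = "\t".join(f"{v:.6g}" for v in row.to_numpy())
                fh.write(f"{gid}\t{gid}\t{vals}\n")

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def _coerce_numeric(df: pd.DataFrame, source: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna() & (df.astype(str) != "NA") & (df.astype(str) != "nan")
    if bad.to_numpy().any():
        warnings.warn(
            f"{source}: {int(bad.to_numpy().sum())} non-numeric cell(s) treated as missing",
            stacklevel=3,
        )
    return out


def read_expression(path: str | Path, format: Optional[str] = None) -> ExpressionMatrix:
    """Read a GCT (v1.2) or plain TSV expression matrix.

    TSV layout: first column gene ids, remaining columns one per tissue.
    GCT: ``#1.2`` version line, ``nrows ncols`` dims line, then a header with
    Name/Description.  ``NA`` and non-numeric cells become missing (warned).
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionError(f"expression file not found: {path}")
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ExpressionError(f"{path.name}: missing GCT version line, got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ExpressionError(f"{path.name}: malformed GCT dimensions line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        if df.shape != (n_rows, n_cols):
            raise ExpressionError(
                f"{path.name}: GCT header declares {n_rows}x{n_cols} "
                f"but data is {df.shape[0]}x{df.shape[1]}"
            )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ExpressionError(f"unknown expression format {fmt!r}")
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=_coerce_numeric(df, path.name))


def filter_profiles(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Drop profiles with any missing value or zero variance across tissues.

    Returns the filtered matrix and the dropped gene ids.  Raises if nothing
    survives.
    """
    vals = m.values
    has_missing = vals.isna().any(axis=1)
    variance = vals.var(axis=1, ddof=0)
    zero_var = variance.fillna(0.0) == 0.0
    drop = has_missing | zero_var
    dropped = list(vals.index[drop])
    kept = vals.loc[~drop]
    if kept.empty:
        raise ExpressionError("all profiles were dropped (missing or zero-variance)")
    return replace(m, values=kept), dropped


def normalize_profiles(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM+1), per-gene z-score (population sd), then min-max to [0,1].

    Input must already be filtered; applying the log step twice is refused.
    Every non-constant output row spans exactly [0, 1].
    """
    if m.normalized:
        return m
    if m.values.isna().any().any():
        raise ExpressionError("normalize_profiles requires a filtered matrix (missing values)")
    vals = m.values.to_numpy(dtype=float)
    if not m.log_transformed:
        if (vals < 0).any():
            raise ExpressionError("negative TPM values")
        vals = np.log2(vals + 1.0)
    sd = vals.std(axis=1, ddof=0)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} profile(s) constant after log transform; dropped",
            stacklevel=2,
        )
        vals = vals[~flat]
        idx = m.values.index[~flat]
        sd = sd[~flat]
    else:
        idx = m.values.index
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    lo = z.min(axis=1, keepdims=True)
    hi = z.max(axis=1, keepdims=True)
    out = (z - lo) / (hi - lo)
    df = pd.DataFrame(out, index=idx, columns=m.values.columns)
    return ExpressionMatrix(values=df, log_transformed=True, normalized=True)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two profiles.

    Computed directly as sum((x-ux)(y-uy)) / sqrt(sum((x-ux)^2) sum((y-uy)^2))
    over the tissues.  Inputs must have equal length >= 2 and nonzero
    variance (filter first).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ExpressionError(f"profiles must be equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ExpressionError("profiles need at least two tissues")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        raise ExpressionError("constant profile: PCC undefined (filter zero-variance rows first)")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


@dataclass
class ErrorSummary:
    """Average estimation error of a cover and its per-gene breakdown."""

    mode: ErrorMode
    mean: float
    sd: float
    n_genes: int
    n_references: int
    n_skipped: int
    per_gene: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "mean_error": self.mean,
            "sd_error": self.sd,
            "n_genes": self.n_genes,
            "n_references": self.n_references,
            "n_skipped": self.n_skipped,
        }


def estimation_error(
    m: ExpressionMatrix,
    assignment: Mapping[str, str],
    mode: ErrorMode = "estimated_only",
    use_log: bool = True,
) -> ErrorSummary:
    """Score a gene -> reference assignment by average estimation error.

    Per gene the error is ``1 - PCC(profile, reference profile)``; reference
    genes (assigned to themselves) contribute 0.  ``mode="estimated_only"``
    averages over non-reference genes only; ``mode="all_genes"`` over every
    scored gene.  PCC is computed on log2(TPM+1) profiles by default
    (``use_log=False`` correlates raw values).  Genes or references absent
    from the matrix are skipped and counted.
    """
    if not assignment:
        raise ExpressionError("empty assignment")
    if mode not in ("estimated_only", "all_genes"):
        raise ExpressionError(f"unknown error mode {mode!r}")
    vals = m.values
    if use_log and not m.log_transformed:
        arr = np.log2(vals.to_numpy(dtype=float) + 1.0)
    else:
        arr = vals.to_numpy(dtype=float)
    row = {gid: k for k, gid in enumerate(vals.index)}

    records = []
    skipped = 0
    for gid, ref in assignment.items():
        if gid not in row or ref not in row:
            skipped += 1
            continue
        if gid == ref:
            err = 0.0
        else:
            err = 1.0 - pcc(arr[row[gid]], arr[row[ref]])
        records.append({"gene_id": gid, "reference_id": ref, "error": err,
                        "is_reference": gid == ref})
    if not records:
        raise ExpressionError("no assigned gene found in the expression matrix")
    table = pd.DataFrame(records)
    if mode == "estimated_only":
        scored = table.loc[~table["is_reference"], "error"]
    else:
        scored = table["error"]
    mean = float(scored.mean()) if len(scored) else 0.0
    sd = float(scored.std(ddof=0)) if len(scored) else 0.0
    return ErrorSummary(
        mode=mode,
        mean=mean,
        sd=sd,
        n_genes=int(len(table)),
        n_references=int(table["is_reference"].sum()),
        n_skipped=skipped,
        per_gene=table,
    )
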