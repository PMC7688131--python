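"""Expression-matrix handling: filtering, probe collapse, correlation.

Operates on log2-normalized intensity matrices (probesets or genes in rows,
samples in columns), e.g. an RMA-normalized microarray series matrix.
Normalization itself is consumed, not performed.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionError",
    "ExpressionMatrix",
    "read_expression_matrix",
    "read_gene_map",
    "variance_filter",
    "filter_probes",
    "collapse_probesets",
    "correlate_with_response",
    "write_rnk",
    "write_gct",
]


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) with an optional probe->gene map."""

    values: pd.DataFrame
    gene_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(f"duplicate probe ids: {list(dupes)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ExpressionError("expression values must all be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_matrix(path, gene_map: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a tab-delimited matrix (first column probe id, header sample ids).

    GEO series-matrix files are accepted: ``!``-prefixed metadata lines are
    skipped and surrounding quotes stripped.
    """
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return ExpressionMatrix(df.astype(float), gene_map=gene_map)


def read_gene_map(path) -> dict[str, str]:
    """Two-column probe->gene TSV (header optional, detected)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ExpressionError("gene map needs two tab-separated columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("probe", "probe_id", "probeset"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def variance_filter(
    matrix: ExpressionMatrix,
    var_min: float = 0.8,
    mean_min: float = 5.5,
    range_min: float = 3.0,
    samples: list[str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-probe variance / mean / min-max report with a ``passed`` flag.

    A probe passes when variance >= ``var_min`` AND mean >= ``mean_min``
    AND (max - min) > ``range_min`` (note the strict inequality on the
    range, matching the fold-difference rule).  ``samples`` restricts the
    cohort over which the statistics are computed; ``ddof=1`` gives sample
    variance (``ddof=0`` for the population denominator).
    """
    values = matrix.values if samples is None else matrix.values[samples]
    if values.shape[1] < 2:
        raise ExpressionError("variance undefined with fewer than 2 samples")
    arr = values.to_numpy(dtype=float)
    report = pd.DataFrame(
        {
            "variance": arr.var(axis=1, ddof=ddof),
            "mean": arr.mean(axis=1),
            "min_max_range": arr.max(axis=1) - arr.min(axis=1),
        },
        index=values.index,
    )
    report["passed"] = (
        (report["variance"] >= var_min)
        & (report["mean"] >= mean_min)
        & (report["min_max_range"] > range_min)
    )
    return report


def filter_probes(matrix: ExpressionMatrix, report: pd.DataFrame) -> ExpressionMatrix:
    """Keep only probes flagged ``passed`` in a variance-filter report."""
    keep = report.index[report["passed"]]
    return ExpressionMatrix(matrix.values.loc[keep], gene_map=matrix.gene_map)


def collapse_probesets(matrix: ExpressionMatrix, method: str = "mean") -> ExpressionMatrix:
    """Collapse probesets to one row per gene symbol.

    For multi-probe genes the probe with the highest mean expression across
    samples is kept (``method="mean"``, the usual collapse convention);
    ``method="max"`` keeps the probe with the highest single-sample value.
    Ties break toward the lexicographically smallest probe id.  Probes
    without a mapping are dropped with a warning.
    """
    if not matrix.gene_map:
        raise ExpressionError("collapse requires a non-empty probe->gene map")
    if method not in ("mean", "max"):
        raise ExpressionError(f"unknown collapse method {method!r}")
    unmapped = [p for p in matrix.probe_ids if p not in matrix.gene_map]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} probes without gene mapping", stacklevel=2
        )
    score = (
        matrix.values.mean(axis=1) if method == "mean" else matrix.values.max(axis=1)
    )
    chosen: dict[str, str] = {}
    for probe in sorted(set(matrix.probe_ids) - set(unmapped)):
        gene = matrix.gene_map[probe]
        if gene not in chosen or score[probe] > score[chosen[gene]]:
            chosen[gene] = probe
    genes = sorted(chosen)
    collapsed = matrix.values.loc[[chosen[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(collapsed, gene_map=None)


def correlate_with_response(
    matrix: ExpressionMatrix, responses: pd.Series
) -> pd.DataFrame:
    """Pearson r and two-sided p of each probe against a per-sample response.

    p-values come from the t-distribution with n - 2 degrees of freedom.
    Samples are matched by id; at least 3 shared samples are required.  A
    constant response raises; a constant probe yields NaN with
    ``undefined=True`` in its row.
    """
    shared = [s for s in matrix.sample_ids if s in responses.index]
    if len(shared) < 3:
        raise ExpressionError("need at least 3 paired samples for correlation")
    y = responses.loc[shared].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ExpressionError("responses must be finite")
    if np.ptp(y) == 0:
        raise ExpressionError("response has zero variance; correlation undefined")
    X = matrix.values[shared].to_numpy(dtype=float)
    n = len(shared)

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    undefined = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    r[undefined] = np.nan
    p[undefined] = np.nan
    return pd.DataFrame(
        {"r": r, "p": p, "n": n, "undefined": undefined}, index=matrix.values.index
    )


def write_rnk(correlations: pd.DataFrame, path) -> None:
    """Write a GSEA .rnk file (probe/gene, Pearson r) sorted descending."""
    ranked = correlations["r"].dropna().sort_values(ascending=False)
    ranked.to_csv(path, sep="\t", header=False, float_format="%.6g")


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write a GSEA .gct expression file."""
    values = matrix.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(values.columns) + "\n")
        for probe, row in values.iterrows():
            gene = (matrix.gene_map or {}).get(probe, "na")
            fh.write(probe + "\t" + gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
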