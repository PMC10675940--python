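"""Marker-set scoring of cell-population abundance from bulk expression.

Abundance of a cell population in a sample is the arithmetic mean of
log2(x + 1)-transformed expression over the population's marker genes
(the MCP-counter estimator).  Genes that are zero or missing in at least
80% of samples are removed first.
"""

from __future__ import annotations

import pandas as pd


def filter_genes(expr: pd.DataFrame, max_bad_frac: float = 0.8) -> pd.DataFrame:
    """Drop genes that are zero or missing in >= ``max_bad_frac`` of samples.

    Parameters
    ----------
    expr
        Genes x samples linear-scale expression; NaN marks missing values.
    max_bad_frac
        A gene is removed when its fraction of bad (zero or missing)
        samples is at least this value.
    """
    if not 0 < max_bad_frac <= 1:
        raise ValueError("max_bad_frac must be in (0, 1]")
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("duplicate gene or sample ids")
    bad = expr.isna() | (expr == 0)
    keep = bad.mean(axis=1) < max_bad_frac
    out = expr.loc[keep]
    if out.empty:
        raise ValueError("no genes survive the zero/missing filter")
    return out


def estimate_abundance(
    expr: pd.DataFrame, markers: dict[str, list[str]]
) -> pd.DataFrame:
    """Score each sample for each cell population.

    Returns a samples x cell-types table of mean log2(expression + 1) over
    the marker genes present in the matrix.  Missing values are excluded
    from the mean.  A cell type with no marker present in the matrix is an
    error rather than a silent NaN.
    """
    import numpy as np

    if (expr.to_numpy(dtype=float, na_value=0.0) < 0).any():
        raise ValueError("expression values must be non-negative")
    scores = {}
    for cell_type, genes in markers.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            raise ValueError(
                f"no marker genes of {cell_type!r} are present in the expression matrix"
            )
        log2 = np.log2(expr.loc[present].astype(float) + 1.0)
        scores[cell_type] = log2.mean(axis=0, skipna=True)
    out = pd.DataFrame(scores, index=expr.columns)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite abundance scores (all-missing markers?)")
    return out
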