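"""Bait-vs-control enrichment scoring and top-hit ranking for pull-downs.

Proteins enriched in a bait pull-down (e.g. NIX-GST) relative to the tag-only
control (GST) are candidate interactors.  Scoring is a per-protein two-sample
t-test on complete (imputed) log2 intensities — pooled-variance Student t by
default (exactly calibrated at the small replicate numbers typical of
pull-downs; both groups share the same measurement noise), Welch
unequal-variance as an option — with Benjamini-Hochberg FDR correction
across all tested proteins, and a primary ranking by log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant_io import Log2Matrix, SampleDesign

ENRICHMENT_COLUMNS = [
    "gene", "log2fc", "t_stat", "df", "p_value", "q_value", "rank", "fully_imputed",
]


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sample t over rows; returns (t, df, p).

    ``equal_var=True`` is the pooled-variance Student t (df = n1 + n2 - 2);
    ``equal_var=False`` is Welch with the Welch-Satterthwaite df.  Degenerate
    rows (zero variance in both groups) get t = 0, p = 1 when the means
    agree, and t = +/-inf, p = 0 otherwise, with df = n1 + n2 - 2.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = np.full(a.shape[0], float(n1 + n2 - 2))
        else:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = diff / np.sqrt(se2)
    degenerate = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(degenerate, float(n1 + n2 - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, df, p


def compare_groups(
    matrix: Log2Matrix,
    design: SampleDesign,
    bait: str,
    control: str,
    observed_mask: pd.DataFrame | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein enrichment of ``bait`` over ``control``.

    Parameters
    ----------
    matrix : complete (imputed) log2 matrix.
    observed_mask : optional boolean proteins x samples frame, True where the
        value was observed before imputation; proteins with no observation in
        any sample of either group are flagged ``fully_imputed``.
    equal_var : pooled-variance Student t when True (default; calibrated at
        2-3 replicates per group), Welch unequal-variance t when False.

    Returns
    -------
    DataFrame indexed by protein_id with columns log2fc, t_stat, df, p_value,
    q_value (BH), rank (1..n by descending log2fc, ties by smaller p then
    protein_id) and fully_imputed.
    """
    if matrix.provenance != "imputed":
        raise ValueError(
            f"expected an imputed (complete) matrix, got provenance {matrix.provenance!r}"
        )
    if matrix.values.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; impute first")
    design.require_replicates(bait)
    design.require_replicates(control)
    bait_cols = design.samples(bait)
    ctrl_cols = design.samples(control)
    missing_cols = (set(bait_cols) | set(ctrl_cols)) - set(matrix.sample_ids)
    if missing_cols:
        raise ValueError(f"design samples not in matrix: {sorted(missing_cols)}")

    a = matrix.values[bait_cols].to_numpy(dtype=float)
    b = matrix.values[ctrl_cols].to_numpy(dtype=float)
    t, df, p = _two_sample_t(a, b, equal_var=equal_var)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    if observed_mask is not None:
        group_cols = bait_cols + ctrl_cols
        fully_imputed = ~observed_mask[group_cols].to_numpy(dtype=bool).any(axis=1)
    else:
        fully_imputed = np.zeros(len(matrix.values), dtype=bool)

    table = pd.DataFrame(
        {
            "gene": "",
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "fully_imputed": fully_imputed,
        },
        index=matrix.values.index,
    )
    # rank by log2fc descending; ties by smaller p, then lexicographic protein_id
    order = (
        table.assign(_pid=table.index.astype(str))
        .sort_values(["log2fc", "p_value", "_pid"],
                     ascending=[False, True, True], kind="mergesort")
        .index
    )
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    table["rank"] = table["rank"].astype(int)
    return table[ENRICHMENT_COLUMNS]


def top_hits(
    table: pd.DataFrame,
    n: int,
    min_log2fc: float = 1.0,
    max_q: float = 0.05,
    exclude_fully_imputed: bool = True,
) -> pd.DataFrame:
    """Proteins passing both thresholds, sorted by log2fc descending, truncated to n.

    Ties are broken by smaller p-value, then lexicographic protein_id.  An
    empty result is legal.  Proteins never observed in either group before
    imputation are excluded by default: their fold change is pure noise.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    mask = (table["log2fc"] >= min_log2fc) & (table["q_value"] <= max_q)
    if exclude_fully_imputed and "fully_imputed" in table.columns:
        mask &= ~table["fully_imputed"].astype(bool)
    hits = table.loc[mask].copy()
    hits["_pid"] = hits.index.astype(str)
    hits = hits.sort_values(
        ["log2fc", "p_value", "_pid"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="_pid")
    return hits.head(n)
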