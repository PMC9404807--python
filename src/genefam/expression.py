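"""Expression-matrix normalization, row ordering and qPCR fold changes.

Heatmap preparation follows the common two-step scheme: log2(x + 1)
then genewise z-scoring; row order comes from average-linkage
hierarchical clustering. Relative qPCR expression is the standard
2^(-ddCt) with a reference gene and a control condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionMatrix",
    "QpcrMeasurement",
    "QpcrResult",
    "normalize_for_heatmap",
    "order_rows",
    "delta_delta_ct",
    "stress_response_calls",
]


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x conditions
    state: str = "raw"  # raw | log2 | zscore
    flagged_constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state == "raw" and (self.values.values < 0).any():
            raise ValueError("raw expression values must be non-negative")


@dataclass
class QpcrMeasurement:
    gene: str
    # condition -> replicate Ct values of the target and the reference gene
    ct_target: dict[str, list[float]]
    ct_reference: dict[str, list[float]]


@dataclass
class QpcrResult:
    gene: str
    control: str
    delta_ct: dict[str, list[float]]  # per condition, per replicate
    delta_delta_ct: dict[str, float]
    fold_change: dict[str, float]  # 2^-ddCt
    fold_sd: dict[str, float]


def normalize_for_heatmap(m: ExpressionMatrix, log2p1: bool = True,
                          zscore: bool = True) -> ExpressionMatrix:
    """log2(x+1) then genewise z-score (each step switchable).

    Zero-variance rows become all-zero and are flagged. z-scores use the
    sample (n-1) standard deviation.
    """
    if m.state != "raw":
        vals = m.values.copy()
    else:
        vals = m.values.astype(float).copy()
    if log2p1:
        vals = np.log2(vals + 1.0)
    flagged: list[str] = []
    if zscore:
        means = vals.mean(axis=1)
        sds = vals.std(axis=1, ddof=1)
        constant = sds == 0
        flagged = list(vals.index[constant])
        sds[constant] = 1.0
        vals = vals.sub(means, axis=0).div(sds, axis=0)
        vals.loc[constant, :] = 0.0
    return ExpressionMatrix(vals, state="zscore" if zscore else "log2",
                            flagged_constant=flagged)


def order_rows(m: ExpressionMatrix, linkage: str = "average",
               metric: str = "euclidean") -> list[int]:
    """Dendrogram leaf order from agglomerative clustering of rows."""
    n = len(m.values)
    if n <= 1:
        return list(range(n))
    dists = pdist(m.values.values, metric=metric)
    Z = hierarchy.linkage(dists, method=linkage)
    return list(hierarchy.leaves_list(Z))


def delta_delta_ct(measurement: QpcrMeasurement, control_condition: str) -> QpcrResult:
    """Relative expression by 2^(-ddCt).

    dCt = Ct_target - Ct_reference per replicate; ddCt = mean dCt(condition)
    - mean dCt(control); fold = 2^-ddCt. The per-condition sd of the fold
    change is propagated from the replicate dCt spread
    (sd_fold = fold * ln2 * sd_dCt).
    """
    if control_condition not in measurement.ct_target:
        raise ValueError(f"control condition {control_condition!r} missing")
    dct: dict[str, list[float]] = {}
    for cond, targets in measurement.ct_target.items():
        refs = measurement.ct_reference.get(cond)
        if refs is None or len(refs) != len(targets):
            raise ValueError(f"{measurement.gene}/{cond}: missing reference Ct")
        dct[cond] = [t - r for t, r in zip(targets, refs)]
    control_mean = float(np.mean(dct[control_condition]))
    ddct, fold, fold_sd = {}, {}, {}
    for cond, values in dct.items():
        dd = float(np.mean(values)) - control_mean
        ddct[cond] = dd
        fold[cond] = 2.0 ** (-dd)
        sd_dct = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        fold_sd[cond] = fold[cond] * np.log(2.0) * sd_dct
    return QpcrResult(gene=measurement.gene, control=control_condition,
                      delta_ct=dct, delta_delta_ct=ddct, fold_change=fold,
                      fold_sd=fold_sd)


def stress_response_calls(m: ExpressionMatrix, stress: str, control: str,
                          log2fc_threshold: float = 1.0) -> dict[str, str]:
    """Up/down/unchanged calls by |log2 fold change| against a control column."""
    calls = {}
    for gene in m.values.index:
        a = float(m.values.loc[gene, stress])
        b = float(m.values.loc[gene, control])
        lfc = np.log2((a + 1.0) / (b + 1.0)) if m.state == "raw" else a - b
        if lfc >= log2fc_threshold:
            calls[gene] = "up"
        elif lfc <= -log2fc_threshold:
            calls[gene] = "down"
        else:
            calls[gene] = "unchanged"
    return calls
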