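"""Element-target co-expression: correlations on co-expressed subsets.

Correlations between the element and candidate target genes are
computed across samples, optionally restricted to the subset of samples
where both features are expressed (so that absence/presence patterns do
not drive the coefficient).  The default estimator is Pearson on
log2(TPM+1) ("pearson-log"); Spearman is available as a rank-based
alternative.  Tables of correlations carry Benjamini-Hochberg adjusted
q-values alongside the raw p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

METHODS = ("pearson-log", "spearman")
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    n: int
    r: float  # NaN when undefined (zero variance)
    p: float
    subset_rule: str  # all | co-expressed
    q: float | None = None
    undefined_reason: str | None = None


def coexpressed_subset(
    matrix: ExpressionMatrix, a: str, b: str, threshold: float = 1.0
) -> list[str]:
    """Sample ids where both features are expressed (TPM >= threshold)."""
    va, vb = matrix.feature(a), matrix.feature(b)
    return [s for s in matrix.sample_ids if va[s] >= threshold and vb[s] >= threshold]


def correlate(
    matrix: ExpressionMatrix,
    a: str,
    b: str,
    samples: Sequence[str] | None = None,
    method: str = "pearson-log",
    subset_rule: str = "all",
) -> CorrelationResult:
    """Correlation between two features over the given samples.

    pearson-log computes Pearson on log2(TPM+1); spearman is rank-based
    on raw TPM.  Fewer than 3 samples is an error; zero variance in
    either feature yields r = NaN with an explanatory flag.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if samples is None:
        samples = matrix.sample_ids
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples, got {len(samples)}")
    xa = matrix.feature(a)[list(samples)].to_numpy()
    xb = matrix.feature(b)[list(samples)].to_numpy()
    if method == "pearson-log":
        xa, xb = np.log2(xa + 1.0), np.log2(xb + 1.0)
        if np.std(xa) == 0 or np.std(xb) == 0:
            return CorrelationResult(
                a, b, len(samples), float("nan"), float("nan"), subset_rule,
                undefined_reason="zero variance",
            )
        r, p = stats.pearsonr(xa, xb)
    else:
        if np.std(xa) == 0 or np.std(xb) == 0:
            return CorrelationResult(
                a, b, len(samples), float("nan"), float("nan"), subset_rule,
                undefined_reason="zero variance",
            )
        r, p = stats.spearmanr(xa, xb)
    return CorrelationResult(a, b, len(samples), float(r), float(p), subset_rule)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted q-values (NaN p stays NaN)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        pm = p[mask]
        m = len(pm)
        order = np.argsort(pm)
        ranked = pm[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qm = np.empty(m)
        qm[order] = np.minimum(ranked, 1.0)
        q[mask] = qm
    return list(q)


def cis_trans_table(
    matrix: ExpressionMatrix,
    element_id: str,
    gene_ids: Sequence[str],
    threshold: float = 1.0,
    method: str = "pearson-log",
) -> pd.DataFrame:
    """Per-gene correlation with the element on co-expressed subsets.

    One row per gene, computed on samples where both the element and the
    gene pass the TPM threshold; BH adjustment across the table; rows
    sorted by r descending (NaN last).
    """
    if not gene_ids:
        raise ValueError("empty gene list")
    rows = []
    for gene in gene_ids:
        samples = coexpressed_subset(matrix, element_id, gene, threshold)
        if len(samples) < 3:
            rows.append(
                CorrelationResult(
                    element_id, gene, len(samples), float("nan"), float("nan"),
                    "co-expressed", undefined_reason="fewer than 3 co-expressed samples",
                )
            )
        else:
            rows.append(
                correlate(matrix, element_id, gene, samples, method, "co-expressed")
            )
    qs = bh_adjust([r.p for r in rows])
    table = pd.DataFrame(
        {
            "element": [r.feature_a for r in rows],
            "gene": [r.feature_b for r in rows],
            "n": [r.n for r in rows],
            "r": [r.r for r in rows],
            "p": [r.p for r in rows],
            "q": qs,
            "subset_rule": [r.subset_rule for r in rows],
        }
    )
    return table.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)


def promoter_ratio(
    matrix: ExpressionMatrix,
    noncoding_id: str,
    coding_id: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-sample log2 usage ratio of a noncoding vs coding promoter.

    ratio = log2((TPM_nc + pseudocount) / (TPM_coding + pseudocount)).
    The summary holds the median ratio and a two-sided sign-test p-value
    for the null of equal usage (zero ratios are discarded, as in the
    exact sign test).
    """
    nc = matrix.feature(noncoding_id)
    coding = matrix.feature(coding_id)
    ratios = np.log2((nc + pseudocount) / (coding + pseudocount))
    nonzero = ratios[ratios != 0]
    if len(nonzero) == 0:
        p = 1.0
    else:
        k = int((nonzero > 0).sum())
        p = float(stats.binomtest(k, len(nonzero), 0.5).pvalue)
    summary = {"median_log2_ratio": float(np.median(ratios)), "sign_test_p": p}
    return ratios, summary
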