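"""FPKM, log2 heat-map values, tissue-preferred calling, duplicate divergence.

A gene is tissue-preferred when its mean is at least two-fold higher in one
tissue than in EVERY other tissue, each comparison supported by a t-test at
p < alpha. Fold gates are applied on the linear scale (a log2 difference of
1); the t-tests are applied to log2(x+1)-transformed values, matching the
survey convention of testing log2-transformed abundances (and stabilizing
count variance at n = 3). Welch's unequal-variance t-test stands in for
"Student's t-test" because it is the conservative choice at n = 3. No
multiple-testing correction is applied by default, matching the survey
procedure; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class TissueCall:
    gene: str
    tissue: str | None
    min_fold_margin: float
    max_p: float
    verdict: bool


@dataclass(frozen=True)
class DivergenceCall:
    gene_a: str
    gene_b: str
    diverged: bool
    evidence: dict = field(default_factory=dict)


def fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, totals: pd.Series | None = None,
) -> pd.DataFrame:
    """fpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * mapped_total[s]).

    ``totals`` defaults to the per-sample count sums, under which
    sum_g fpkm[g, s] * length[g] == 1e9 for every sample.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive for all genes")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ExpressionError("per-sample totals must be positive")
    return counts * 1e9 / np.outer(lengths, totals)


def log2_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 of positive entries; zeros are masked as "no expression".

    Returns (log2 values with NaN at masked cells, boolean mask where True
    marks a silent cell). Masked cells are excluded from fold computations.
    """
    if (values < 0).any().any():
        raise ExpressionError("negative expression values")
    mask = values == 0
    out = values.where(~mask)
    return np.log2(out), mask


def _tissue_groups(values: pd.DataFrame, design: pd.DataFrame) -> dict[str, pd.DataFrame]:
    missing = set(values.columns) - set(design.index)
    if missing:
        raise ExpressionError(f"samples missing from design: {sorted(missing)}")
    return {
        t: values[design.index[design["tissue"] == t].intersection(values.columns)]
        for t in design["tissue"].unique()
    }


def _welch_p(a: np.ndarray, b: np.ndarray, log_scale: bool = True) -> float:
    if log_scale:
        a, b = np.log2(a + 1.0), np.log2(b + 1.0)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 0.0 if a.mean() != b.mean() else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def call_tissue_preferred(
    values: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.05, fold: float = 2.0,
    log_scale: bool = True,
) -> list[TissueCall]:
    """Tissue-preferred verdict per gene.

    The candidate tissue is the one with the highest mean; the verdict
    requires mean >= fold * mean_other AND Welch p < alpha against every
    other tissue. Genes silent everywhere are excluded (verdict False,
    tissue None). Tissues with fewer than 2 replicates are skipped from
    testing with a warning-level flag (their comparison cannot support a
    call, so the gene is not called).
    """
    groups = _tissue_groups(values, design)
    if len(groups) < 2:
        raise ExpressionError("need at least two tissues")
    calls: list[TissueCall] = []
    eps = 1e-12
    for gene in values.index:
        means = {t: g.loc[gene].mean() for t, g in groups.items()}
        if all(m == 0 for m in means.values()):
            calls.append(TissueCall(gene, None, 0.0, 1.0, False))
            continue
        best = max(sorted(means), key=lambda t: means[t])
        others = [t for t in means if t != best]
        folds, ps, testable = [], [], True
        for t in others:
            folds.append(means[best] / (means[t] + eps))
            a = groups[best].loc[gene].to_numpy(dtype=float)
            b = groups[t].loc[gene].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                testable = False
                continue
            ps.append(_welch_p(a, b, log_scale))
        min_fold = min(folds)
        max_p = max(ps) if ps else 1.0
        verdict = testable and bool(min_fold >= fold) and bool(max_p < alpha) and len(ps) == len(others)
        calls.append(TissueCall(gene, best if verdict else None, min_fold, max_p, verdict))
    return calls


def pair_divergence(
    gene_a: str, gene_b: str, values: pd.DataFrame, design: pd.DataFrame,
    alpha: float = 0.05, fold: float = 2.0, log_scale: bool = True,
) -> DivergenceCall:
    """Expression divergence between a duplicate pair.

    Diverged when some tissue shows a >= fold difference between the genes
    with Welch p < alpha, or when one gene is expressed in a tissue where
    the other is silent (specificity change).
    """
    for g in (gene_a, gene_b):
        if g not in values.index:
            raise ExpressionError(f"gene {g!r} not in the expression table")
    groups = _tissue_groups(values, design)
    evidence: dict[str, dict] = {}
    diverged = False
    eps = 1e-12
    for t, sub in groups.items():
        a = sub.loc[gene_a].to_numpy(dtype=float)
        b = sub.loc[gene_b].to_numpy(dtype=float)
        ma, mb = a.mean(), b.mean()
        spec_change = (ma == 0) != (mb == 0)
        f = max(ma, mb) / (min(ma, mb) + eps) if max(ma, mb) > 0 else 1.0
        p = _welch_p(a, b, log_scale) if len(a) > 1 and len(b) > 1 else float("nan")
        hit = bool(spec_change or (f >= fold and p == p and p < alpha))
        evidence[t] = {"mean_a": ma, "mean_b": mb, "fold": f, "p": p,
                       "specificity_change": spec_change, "diverged": hit}
        diverged = diverged or hit
    return DivergenceCall(gene_a, gene_b, diverged, evidence)


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (off by default in the calling rules)."""
    return list(stats.false_discovery_control(pvalues, method="bh"))
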