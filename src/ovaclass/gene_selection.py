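"""Per-gene ANOVA / volcano statistics and prominent-gene selection.

Each gene is tested with a one-way ANOVA between the normal and cancer
groups (for two groups, F equals the square of the pooled two-sample t
statistic).  The test runs on log2-transformed intensities by default, the
standard scale for microarray differential expression; fold change is
reported on the intensity scale as log2(mean_cancer / mean_normal).

Selection mirrors the study design that reduced ~33,000 genes to ~16,000
prominent genes: the default mode keeps the fraction 16000/33000 of genes
with the smallest p-values.  A volcano-style threshold mode (p < p_max and
|log2FC| > fc_min) and an absolute top-k mode are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

from .datasets import LabeledExpressionMatrix, subset_genes
from .errors import ConfigurationError, DataError

__all__ = [
    "GeneSelectionResult",
    "anova_volcano",
    "select_prominent",
    "apply_selection",
    "DEFAULT_FRACTION",
]

#: Default selected fraction, reproducing the 33,000 -> 16,000 gene reduction.
DEFAULT_FRACTION = 16000 / 33000

_EPS = 1e-9

SelectionMode = Literal["top_k_by_p", "fraction_by_p", "thresholds"]


@dataclass
class GeneSelectionResult:
    """Volcano statistics for every gene plus (optionally) a selected subset.

    ``selected_idx`` is ``None`` until :func:`select_prominent` is applied;
    afterwards it is a sorted, unique index array into the gene axis.
    ``criterion`` records the selection mode and parameters used.
    """

    f_stat: np.ndarray
    p_value: np.ndarray
    log2_fold_change: np.ndarray
    selected_idx: np.ndarray | None = None
    criterion: dict | None = None

    @property
    def n_genes(self) -> int:
        return self.f_stat.shape[0]


def anova_volcano(
    m: LabeledExpressionMatrix, *, log_transform: bool = True
) -> GeneSelectionResult:
    """Per-gene one-way ANOVA between classes plus intensity fold change.

    Genes whose two groups are constant and equal get F = 0, p = 1 by
    convention (flagged with a warning).  Requires >= 2 samples per class.
    """
    labels = m.labels
    for cls in (0, 1):
        if int(np.sum(labels == cls)) < 2:
            raise DataError(
                f"class {cls} has fewer than 2 samples; ANOVA needs >= 2 per class"
            )

    x = np.log2(m.values + _EPS) if log_transform else m.values
    a = x[:, labels == 0]
    b = x[:, labels == 1]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(a, b, axis=1)
    f = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = ~np.isfinite(f) & np.isclose(a.mean(axis=1), b.mean(axis=1))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) constant and equal across classes; "
            "setting F=0, p=1",
            stacklevel=2,
        )
        f[degenerate] = 0.0
        p[degenerate] = 1.0
    # constant but unequal groups: infinitely significant
    inf_sep = ~np.isfinite(f) & ~degenerate
    f[inf_sep] = np.inf
    p[inf_sep] = 0.0

    mean_normal = np.maximum(m.values[:, labels == 0].mean(axis=1), _EPS)
    mean_cancer = np.maximum(m.values[:, labels == 1].mean(axis=1), _EPS)
    log2_fc = np.log2(mean_cancer / mean_normal)

    return GeneSelectionResult(f_stat=f, p_value=p, log2_fold_change=log2_fc)


def _ranking(r: GeneSelectionResult) -> np.ndarray:
    """Gene order by ascending p, ties by larger |log2FC|, then lower index."""
    n = r.n_genes
    return np.lexsort((np.arange(n), -np.abs(r.log2_fold_change), r.p_value))


def select_prominent(
    r: GeneSelectionResult,
    mode: SelectionMode = "fraction_by_p",
    *,
    k: int | None = None,
    fraction: float = DEFAULT_FRACTION,
    p_max: float = 0.05,
    fc_min: float = 1.0,
) -> GeneSelectionResult:
    """Fill ``selected_idx`` according to ``mode``.

    ``top_k_by_p`` keeps the k smallest p-values; ``fraction_by_p`` keeps
    ``round(fraction * n_genes)``; ``thresholds`` keeps genes with
    p < p_max and |log2FC| > fc_min.  The returned index array is sorted by
    ascending original gene index (stable downstream gene ordering).
    Re-selecting an already-selected result with the same parameters is a
    no-op because selection is always recomputed from the full statistics.
    """
    n = r.n_genes
    if mode == "top_k_by_p":
        if k is None:
            raise ConfigurationError("top_k_by_p requires k")
        if not 1 <= k <= n:
            raise ConfigurationError(f"k={k} out of range [1, {n}]")
        selected = np.sort(_ranking(r)[:k])
        criterion = {"mode": mode, "k": int(k)}
    elif mode == "fraction_by_p":
        if not 0 < fraction <= 1:
            raise ConfigurationError(f"fraction={fraction} must lie in (0, 1]")
        kk = max(1, int(round(fraction * n)))
        selected = np.sort(_ranking(r)[:kk])
        criterion = {"mode": mode, "fraction": float(fraction), "k": kk}
    elif mode == "thresholds":
        mask = (r.p_value < p_max) & (np.abs(r.log2_fold_change) > fc_min)
        selected = np.flatnonzero(mask)
        criterion = {"mode": mode, "p_max": float(p_max), "fc_min": float(fc_min)}
    else:
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    return replace(r, selected_idx=selected, criterion=criterion)


def apply_selection(
    m: LabeledExpressionMatrix, r: GeneSelectionResult
) -> LabeledExpressionMatrix:
    """Restrict ``m`` to the genes in ``r.selected_idx`` (ascending index)."""
    if r.selected_idx is None:
        raise ConfigurationError("selection has not been applied; call select_prominent")
    return subset_genes(m, r.selected_idx)
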