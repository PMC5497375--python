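"""Differential expression, multi-condition set overlap and qPCR fold change.

Differential expression between two stages/conditions uses a per-gene
two-sample t-test (Welch by default, Student's available) with
Benjamini-Hochberg adjustment across all tested genes; a gene is called
significant when its adjusted p is strictly below the cutoff AND its linear
fold change (ratio of group means, larger over smaller) is strictly above
the cutoff — the MAQC-style test-plus-threshold rule (defaults q < 0.05,
FC > 1.4).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .network import bh_adjust

__all__ = [
    "two_sample_ttest",
    "stage_de",
    "VennSummary",
    "venn_overlap",
    "cross_dataset_overlap",
    "ddct_relative_expression",
]


def two_sample_ttest(values_a, values_b, variant: str = "welch") -> tuple[float, float]:
    """Two-sample t statistic and two-sided p.

    ``variant`` selects the variance assumption: ``"welch"`` (unequal) or
    ``"student"`` (pooled).  Degenerate zero-variance input is mapped to
    (0, 1) when the means are equal and (±inf, 0) with a warning otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: p = 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def stage_de(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    q_cutoff: float = 0.05,
    fc_cutoff: float = 1.4,
    variant: str = "welch",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two stage/condition labels.

    Returns a DataFrame indexed by gene with columns ``mean_a``, ``mean_b``,
    ``fold_change`` (linear, >= 1), ``direction`` (``"up"`` = higher in
    ``group_b``), ``t``, ``p``, ``q`` and ``significant``.  Genes with a
    zero mean in exactly one group get infinite fold change unless a
    ``pseudocount`` is supplied.
    """
    cols_a = expr.stage_columns(group_a)
    cols_b = expr.stage_columns(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least 2 replicates")
    A = expr.values[cols_a].to_numpy(dtype=float)
    B = expr.values[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)

    if pseudocount is not None:
        fa, fb = mean_a + pseudocount, mean_b + pseudocount
    else:
        fa, fb = mean_a, mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.maximum(fa, fb)
        lo = np.minimum(fa, fb)
        fc = np.where(hi == lo, 1.0, np.where(lo > 0, hi / lo, np.inf))

    t_arr = np.empty(len(mean_a))
    p_arr = np.empty(len(mean_a))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(mean_a)):
            t_arr[i], p_arr[i] = two_sample_ttest(A[i], B[i], variant=variant)
    q_arr = bh_adjust(p_arr)

    direction = np.where(mean_b > mean_a, "up", np.where(mean_b < mean_a, "down", "none"))
    significant = (q_arr < q_cutoff) & (fc > fc_cutoff)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "direction": direction,
            "t": t_arr,
            "p": p_arr,
            "q": q_arr,
            "significant": significant,
        },
        index=expr.values.index.rename("gene"),
    )


@dataclass
class VennSummary:
    """Exact set-algebra summary of two or more labelled gene sets.

    ``intersections`` maps each label combination (tuple, size >= 2,
    inclusive of higher-order overlaps) to its cardinality; ``exclusive``
    maps each nonempty membership pattern to the size of that exclusive
    region.
    """

    labels: list[str]
    sizes: dict[str, int]
    intersections: dict[tuple, int]
    exclusive: dict[tuple, int]
    union: int

    @property
    def triple(self) -> int | None:
        if len(self.labels) < 3:
            return None
        return self.intersections[tuple(self.labels[:3])] if len(self.labels) == 3 \
            else self.intersections.get(tuple(self.labels))

    def pairwise(self, a: str, b: str) -> int:
        key = tuple(l for l in self.labels if l in (a, b))
        return self.intersections[key]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "sizes": self.sizes,
            "intersections": {"&".join(k): v for k, v in self.intersections.items()},
            "exclusive": {"&".join(k): v for k, v in self.exclusive.items()},
            "union": self.union,
        }


def venn_overlap(sets, labels) -> VennSummary:
    """Region cardinalities for two or more gene sets.

    The union size is recomputed via inclusion-exclusion and asserted to
    match direct set algebra.
    """
    sets = [set(s) for s in sets]
    labels = list(labels)
    if len(sets) != len(labels):
        raise ValueError("sets and labels must have equal length")
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")

    by_label = dict(zip(labels, sets))
    sizes = {l: len(s) for l, s in by_label.items()}
    intersections: dict[tuple, int] = {}
    ie_union = 0
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inter = set.intersection(*(by_label[l] for l in combo))
            if r >= 2:
                intersections[combo] = len(inter)
            ie_union += (-1) ** (r + 1) * len(inter)
    union = len(set.union(*sets))
    assert union == ie_union, "inclusion-exclusion identity violated"

    exclusive: dict[tuple, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            region = set.intersection(*(by_label[l] for l in combo))
            for other in labels:
                if other not in combo:
                    region -= by_label[other]
            exclusive[combo] = len(region)
    return VennSummary(labels, sizes, intersections, exclusive, union)


def cross_dataset_overlap(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    rank_by: str = "min_q",
) -> list[str]:
    """Genes significant in both DE tables, ranked.

    ``rank_by="min_q"`` orders by the worse (maximum) of the two adjusted
    p-values, ascending; ``rank_by="max_fc"`` orders by the smaller of the
    two fold changes, descending.  Both are conservative both-dataset
    rankings.
    """
    shared = de_a.index.intersection(de_b.index)
    if len(shared) == 0:
        raise ValueError("DE tables share no gene ids")
    sig = [g for g in shared
           if bool(de_a.loc[g, "significant"]) and bool(de_b.loc[g, "significant"])]
    if rank_by == "min_q":
        key = {g: (max(de_a.loc[g, "q"], de_b.loc[g, "q"]), g) for g in sig}
        return sorted(sig, key=key.__getitem__)
    if rank_by == "max_fc":
        key = {g: (-min(de_a.loc[g, "fold_change"], de_b.loc[g, "fold_change"]), g)
               for g in sig}
        return sorted(sig, key=key.__getitem__)
    raise ValueError(f"unknown rank_by {rank_by!r}")


def ddct_relative_expression(
    ct_target,
    ct_housekeeping,
    ct_target_calibrator,
    ct_housekeeping_calibrator,
):
    """Relative expression by the ddCt method: ``2 ** -(ddCt)``.

    ``dCt = Ct_target - Ct_housekeeping`` per condition;
    ``ddCt = dCt_sample - dCt_calibrator``.  Accepts scalars or arrays.
    """
    ct = [np.asarray(x, dtype=float) for x in
          (ct_target, ct_housekeeping, ct_target_calibrator, ct_housekeeping_calibrator)]
    if any(not np.all(np.isfinite(x)) for x in ct):
        raise ValueError("Ct values must be finite")
    ddct = (ct[0] - ct[1]) - (ct[2] - ct[3])
    out = np.exp2(-ddct)
    return float(out) if out.ndim == 0 else out
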