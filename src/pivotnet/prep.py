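"""Expression preprocessing: TPM, expressed-gene filtering, probe handling.

Covers the preprocessing conventions of both input kinds the pipeline
accepts: RNA-seq-style count matrices (TPM normalization, expressed-gene
filter) and microarray-style probe matrices (detection filter, probe
collapse, quantile normalization, log2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix

__all__ = [
    "compute_tpm",
    "filter_expressed",
    "collapse_probes",
    "detection_filter",
    "quantile_normalize",
    "log2_transform",
]


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    Per sample: ``TPM_i = (count_i / length_i) / sum_j (count_j / length_j)
    * 1e6``, so every nonzero sample column sums to one million.  All-zero
    columns yield all-zero TPM with a warning.
    """
    if counts.lengths is None:
        raise ValueError("TPM requires per-gene transcript lengths")
    if (counts.values.values < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = counts.values.div(counts.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(f"all-zero sample columns: {list(colsum.index[zero])}")
        colsum = colsum.mask(zero, 1.0)
    tpm = rate.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, counts.samples, units="TPM", lengths=counts.lengths)


def filter_expressed(
    tpm: ExpressionMatrix,
    threshold: float = 1.0,
    replicate_fraction: float = 0.5,
) -> set[str]:
    """Genes expressed in at least one stage.

    A gene is retained iff there exists a stage where the fraction of
    replicates with TPM strictly above ``threshold`` strictly exceeds
    ``replicate_fraction`` (both comparisons strict).
    """
    if tpm.units != "TPM":
        raise ValueError(f"expected TPM units, got {tpm.units!r}")
    keep = pd.Series(False, index=tpm.values.index)
    for stage in tpm.stages:
        cols = tpm.stage_columns(stage)
        frac = (tpm.values[cols] > threshold).mean(axis=1)
        keep |= frac > replicate_fraction
    return set(keep.index[keep])


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map) -> ExpressionMatrix:
    """Collapse multi-probe genes to their highest-average-expression probe.

    ``probe_map`` maps probe id -> gene id (dict or Series).  For each gene
    the probe row with the maximal mean across all samples is kept; ties are
    broken by lexicographically smallest probe id.
    """
    pm = pd.Series(dict(probe_map) if not isinstance(probe_map, pd.Series) else probe_map)
    unmapped = [p for p in probe_matrix.values.index if p not in pm.index]
    if unmapped:
        raise ValueError(f"unmapped probes: {unmapped}")
    means = probe_matrix.values.mean(axis=1)
    choice = (
        pd.DataFrame({
            "probe": probe_matrix.values.index,
            "gene": pm.loc[probe_matrix.values.index].values,
            "mean": means.values,
        })
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True],
                     kind="mergesort")
        .drop_duplicates("gene")
    )
    out = probe_matrix.values.loc[choice["probe"]].copy()
    out.index = choice["gene"].values
    return ExpressionMatrix(out, probe_matrix.samples, units=probe_matrix.units)


def detection_filter(
    probe_matrix: ExpressionMatrix,
    detection_p: pd.DataFrame,
    alpha: float = 0.05,
    min_samples: int = 1,
    polarity: str = "conventional",
) -> ExpressionMatrix:
    """Filter probes by Illumina-style detection p-values.

    With the default ``"conventional"`` polarity a probe is retained iff it
    is detected (detection p < ``alpha``) in at least ``min_samples``
    samples.  The ``"literal"`` polarity inverts the rule (retains probes
    detected in fewer than ``min_samples`` samples) for reproducing
    pipelines stated with the opposite wording.
    """
    if detection_p.shape != probe_matrix.values.shape:
        raise ValueError(
            f"detection_p shape {detection_p.shape} does not match matrix "
            f"{probe_matrix.values.shape}"
        )
    detection_p = detection_p.set_axis(probe_matrix.values.index, axis=0).set_axis(
        probe_matrix.values.columns, axis=1
    )
    detected_in = (detection_p < alpha).sum(axis=1)
    if polarity == "conventional":
        keep = detected_in >= min_samples
    elif polarity == "literal":
        keep = detected_in < min_samples
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return ExpressionMatrix(
        probe_matrix.values.loc[keep], probe_matrix.samples, units=probe_matrix.units
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples.

    Every column is mapped onto the common reference distribution formed by
    the row-wise mean of the column-sorted input.  Ties within a column
    receive the mean of the reference values at the tied ranks (average-rank
    convention), so column means are equalized to machine precision.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        ranks = rankdata(X[:, j], method="average")  # 1-based, fractional on ties
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples, units=matrix.units,
                            lengths=matrix.lengths)


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset); the offset guards against log of zero on count data."""
    values = np.log2(matrix.values + offset)
    return ExpressionMatrix(values, matrix.samples, units=f"log2({matrix.units}+{offset:g})")
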