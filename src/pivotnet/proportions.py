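"""Proportion tests for centrosome-abnormality counts.

Each treated condition is compared with the control by a Pearson chi-square
test on the 2x2 table (cells with more than two centrosomes vs normal cells,
condition vs control), df = 1, continuity correction off by default so the
nominal chi-square reference applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["ProportionTestResult", "centrosome_chisq", "dose_response_table",
           "DoseResponseSummary", "significance_stars"]


@dataclass
class ProportionTestResult:
    chi_square: float
    degrees_of_freedom: int
    p: float
    proportions: dict[str, float]
    significant: bool


def significance_stars(p: float) -> str:
    """Asterisk convention: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def centrosome_chisq(
    control: tuple[int, int],
    treated: tuple[int, int],
    correction: bool = False,
    alpha: float = 0.05,
) -> ProportionTestResult:
    """Pearson chi-square on a 2x2 abnormal/normal x control/treated table.

    ``control`` and ``treated`` are ``(n_counted, n_abnormal)`` pairs.  A
    zero margin (no abnormal cells anywhere, or none normal) yields the
    defined result chi-square = 0, p = 1 with a warning.
    """
    (n_c, k_c), (n_t, k_t) = control, treated
    for n, k in ((n_c, k_c), (n_t, k_t)):
        if n <= 0:
            raise ValueError("cell counts must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"abnormal count {k} outside [0, {n}]")
    table = np.array([[k_c, n_c - k_c], [k_t, n_t - k_t]], dtype=float)
    props = {"control": k_c / n_c, "treated": k_t / n_t}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table: chi-square defined as 0, p = 1")
        return ProportionTestResult(0.0, 1, 1.0, props, False)
    chi2, p, dof, _ = chi2_contingency(table, correction=correction)
    return ProportionTestResult(float(chi2), int(dof), float(p), props, p <= alpha)


@dataclass
class DoseResponseSummary:
    table: pd.DataFrame
    proportions_nondecreasing: bool


def dose_response_table(
    counts: pd.DataFrame,
    control_label: str,
    correction: bool = False,
    alpha: float = 0.05,
) -> DoseResponseSummary:
    """Test every non-control condition against the control.

    ``counts`` has columns ``condition``, ``n_counted``, ``n_abnormal`` (one
    row per condition).  The summary also reports descriptively whether the
    abnormal proportion is non-decreasing down the table's row order
    (dose-response monotonicity).
    """
    conditions = list(counts["condition"])
    if control_label not in conditions:
        raise ValueError(f"control label {control_label!r} not present")
    by = counts.set_index("condition")
    ctrl = (int(by.loc[control_label, "n_counted"]),
            int(by.loc[control_label, "n_abnormal"]))
    rows = []
    props = [ctrl[1] / ctrl[0]]
    for cond in conditions:
        if cond == control_label:
            continue
        n, k = int(by.loc[cond, "n_counted"]), int(by.loc[cond, "n_abnormal"])
        res = centrosome_chisq(ctrl, (n, k), correction=correction, alpha=alpha)
        props.append(k / n)
        rows.append((cond, n, k, k / n, res.chi_square, res.p, res.significant,
                     significance_stars(res.p) if res.significant else ""))
    table = pd.DataFrame(rows, columns=["condition", "n_counted", "n_abnormal",
                                        "proportion", "chi_square", "p",
                                        "significant", "stars"])
    nondecreasing = all(b >= a - 1e-12 for a, b in zip(props, props[1:]))
    return DoseResponseSummary(table, nondecreasing)
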