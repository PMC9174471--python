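"""Relative gene expression by the 2^-ΔΔCt method.

Technical replicates are averaged on the Ct scale, each gene is normalised to
a reference gene (ΔCt), the control condition's mean ΔCt serves as baseline
(equivalent to the geometric mean of the control's linear ratios), and fold
changes are 2^-ΔΔCt. Primer efficiency is estimated from a cDNA dilution
series. Condition contrasts use two-tailed t-tests on the log2 fold scale.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_fold_change", "primer_efficiency"]

REQUIRED_COLUMNS = ("gene", "sample_id", "condition", "ct")


def _average_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of Ct over technical replicates per gene and sample."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return (
        table.groupby(["gene", "sample_id", "condition"], as_index=False)["ct"].mean()
    )


def ddct_fold_change(
    table: pd.DataFrame,
    ref_gene: str,
    control_condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample 2^-ΔΔCt fold changes with per-condition summary and t-tests.

    Returns (per-sample table, per-condition mean ± SE of fold, pairwise
    two-tailed t-tests on the log2 fold / -ΔΔCt scale). The control
    condition's geometric-mean fold is 1 by construction. Samples lacking the
    reference gene are dropped with a warning.
    """
    ct = _average_technical(table)
    ref = ct[ct["gene"] == ref_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene!r} not present")
    genes = ct[ct["gene"] != ref_gene].copy()
    missing_ref = sorted(set(genes["sample_id"]) - set(ref.index))
    if missing_ref:
        warnings.warn(
            f"samples without reference gene dropped: {missing_ref}", stacklevel=2
        )
        genes = genes[~genes["sample_id"].isin(missing_ref)]
    genes["dct"] = genes["ct"] - genes["sample_id"].map(ref)

    # baseline: arithmetic mean of the control condition's ΔCt per gene,
    # i.e. the log2 of the geometric mean of the control 2^-ΔCt values
    baseline = (
        genes[genes["condition"] == control_condition]
        .groupby("gene")["dct"].mean()
    )
    absent = sorted(set(genes["gene"]) - set(baseline.index))
    if absent:
        raise ValueError(f"genes without control-condition measurements: {absent}")
    genes["ddct"] = genes["dct"] - genes["gene"].map(baseline)
    genes["fold"] = 2.0 ** (-genes["ddct"])

    summary_rows = []
    test_rows = []
    for gene, sub in genes.groupby("gene"):
        conditions = list(dict.fromkeys(sub["condition"]))
        for cond in conditions:
            folds = sub.loc[sub["condition"] == cond, "fold"].to_numpy()
            summary_rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "mean_fold": float(folds.mean()),
                    "se_fold": float(folds.std(ddof=1) / np.sqrt(len(folds)))
                    if len(folds) > 1 else np.nan,
                    "n": len(folds),
                }
            )
        for i, ca in enumerate(conditions):
            for cb in conditions[i + 1 :]:
                la = -sub.loc[sub["condition"] == ca, "ddct"].to_numpy()
                lb = -sub.loc[sub["condition"] == cb, "ddct"].to_numpy()
                if len(la) < 2 or len(lb) < 2:
                    continue
                with warnings.catch_warnings():
                    # noise-free synthetic groups trip scipy's precision warning
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t, p = stats.ttest_ind(la, lb, equal_var=True)
                if np.isnan(p):
                    p = 1.0
                test_rows.append(
                    {"gene": gene, "condition_a": ca, "condition_b": cb,
                     "t": float(t) if np.isfinite(t) else 0.0, "p": float(p)}
                )
    per_sample = genes[["gene", "sample_id", "condition", "ct", "dct", "ddct", "fold"]]
    return per_sample, pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def primer_efficiency(dilution_series: Sequence[tuple[float, float]]) -> float:
    """Amplification efficiency from a dilution series.

    Least-squares slope of Ct against log10(template amount);
    efficiency = 10^(-1/slope) - 1 (1.0 means perfect doubling per cycle,
    slope -3.3219).
    """
    if len(dilution_series) < 3:
        raise ValueError("at least 3 dilution points required")
    x = np.array([p[0] for p in dilution_series], dtype=float)
    y = np.array([p[1] for p in dilution_series], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("dilution amounts are identical; fit is singular")
    slope = stats.linregress(x, y).slope
    if slope >= 0:
        raise ValueError("non-negative slope; Ct must decrease with template amount")
    return float(10 ** (-1.0 / slope) - 1.0)
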