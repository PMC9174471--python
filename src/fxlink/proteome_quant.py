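"""Label-free quantitative proteome statistics.

Relative iBAQ (intensity / theoretical tryptic peptide count, normalised to
a per-sample molar-fraction-like scale), subcellular-localisation abundance
sums with Bonferroni-corrected two-tailed t-tests, equalise-medians
normalisation, differential abundance with Benjamini–Hochberg volcano calls
(|log2FC| > 0.8, adjusted p < 0.05), presence/absence calls, and a generic
Fisher over-representation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .masscalc import digest

__all__ = [
    "AbundanceTable",
    "theoretical_peptide_count",
    "compute_ibaq",
    "relative_ibaq",
    "localisation_abundance",
    "equalise_medians",
    "differential_abundance",
    "presence_absence",
    "ora_fisher",
]

COMPARTMENTS = (
    "cytosol", "nucleus", "ER", "dense cytosol", "mitochondrium",
    "plasma membrane", "lysosome", "peroxisome", "golgi",
)

# MaxQuant-style iBAQ digestion convention
IBAQ_LENGTH_RANGE = (7, 30)
IBAQ_MISSED = 0

LFC_THRESHOLD = 0.8
ALPHA = 0.05


@dataclass
class AbundanceTable:
    """Protein x sample intensities with design annotations and iBAQ companion.

    ``intensity`` and ``ibaq`` are DataFrames indexed by protein accession
    with one column per sample; ``design`` maps sample -> (condition,
    replicate).
    """

    intensity: pd.DataFrame
    design: pd.DataFrame  # index: sample_id; columns: condition, replicate
    ibaq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.intensity.columns) != list(self.design.index):
            raise ValueError("intensity columns and design rows must align")

    def samples_of(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design["condition"]))


def theoretical_peptide_count(
    sequence: str,
    length_range: tuple[int, int] = IBAQ_LENGTH_RANGE,
    max_missed: int = IBAQ_MISSED,
) -> int:
    """Number of theoretically observable tryptic peptides (iBAQ denominator)."""
    return len(digest(sequence, max_missed=max_missed, length_range=length_range))


def compute_ibaq(
    intensity: pd.DataFrame, peptide_counts: Mapping[str, int]
) -> pd.DataFrame:
    """iBAQ = raw intensity / theoretical peptide count, per protein.

    Proteins with a zero peptide count are excluded with a warning.
    """
    counts = pd.Series(peptide_counts).reindex(intensity.index)
    bad = counts.index[(counts.isna()) | (counts <= 0)]
    if len(bad):
        warnings.warn(
            f"{len(bad)} protein(s) without a positive theoretical peptide "
            f"count excluded from iBAQ: {list(bad[:5])}...",
            stacklevel=2,
        )
    keep = counts.index.difference(bad)
    return intensity.loc[keep].div(counts.loc[keep], axis=0)


def relative_ibaq(ibaq: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalisation: each column sums to 1 over non-missing iBAQs."""
    return ibaq.div(ibaq.sum(axis=0, skipna=True), axis=1)


def localisation_abundance(
    rel_ibaq: pd.DataFrame,
    localisation: Mapping[str, str],
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summed relative iBAQ per subcellular compartment, with condition tests.

    Returns (per-sample compartment sums, per-condition mean ± SE table,
    pairwise two-tailed t-tests with Bonferroni-adjusted p). The Bonferroni
    family is the number of tests actually performed (compartments with no
    mapped proteins are skipped).
    """
    loc = pd.Series(localisation)
    mapped = rel_ibaq.index.intersection(loc.index)
    sums = rel_ibaq.loc[mapped].groupby(loc.loc[mapped]).sum(min_count=1)
    sums = sums.reindex(sorted(set(loc.values)), fill_value=0.0)

    conditions = list(dict.fromkeys(design["condition"]))
    stat_rows = []
    for comp in sums.index:
        for cond in conditions:
            vals = sums.loc[comp, design.index[design["condition"] == cond]].astype(float)
            stat_rows.append(
                {
                    "compartment": comp,
                    "condition": cond,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                    "n": int(len(vals)),
                }
            )
    summary = pd.DataFrame(stat_rows)

    test_rows = []
    for comp in sums.index:
        if (sums.loc[comp] == 0).all():
            continue  # no mapped protein: test skipped
        for i, ca in enumerate(conditions):
            for cb in conditions[i + 1 :]:
                va = sums.loc[comp, design.index[design["condition"] == ca]].astype(float)
                vb = sums.loc[comp, design.index[design["condition"] == cb]].astype(float)
                if len(va) < 2 or len(vb) < 2:
                    continue
                with warnings.catch_warnings():
                    # identical replicate values trip scipy's precision warning
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t, p = stats.ttest_ind(va, vb, equal_var=True)
                if np.isnan(p):  # identical constant values: no evidence
                    p = 1.0
                test_rows.append(
                    {"compartment": comp, "condition_a": ca, "condition_b": cb,
                     "t": float(t) if np.isfinite(t) else 0.0, "p": float(p)}
                )
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests["adj_p"] = np.minimum(tests["p"] * len(tests), 1.0)
    return sums, summary, tests


def equalise_medians(intensity: pd.DataFrame) -> pd.DataFrame:
    """Median-equalised log2 intensities.

    Each sample's log2 values are shifted so that its median equals the grand
    median of the sample medians; idempotent by construction.
    """
    if (intensity <= 0).any().any():
        raise ValueError("intensities must be positive (missing values allowed as NaN)")
    log2 = np.log2(intensity)
    medians = log2.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"sample(s) with no observed values: {bad}")
    grand = medians.median()
    return log2 + (grand - medians)


def differential_abundance(
    log2_table: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    min_obs: int = 2,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sample t-test on normalised log2 values with BH control.

    log2FC = mean(cond_a) - mean(cond_b). Proteins with fewer than ``min_obs``
    observations in either condition are not tested (see presence_absence).
    Calls: up if log2FC > threshold and adj_p < alpha; down if < -threshold
    and adj_p < alpha; else unchanged.
    """
    sa = design.index[design["condition"] == cond_a]
    sb = design.index[design["condition"] == cond_b]
    a = log2_table[sa]
    b = log2_table[sb]
    testable = (a.notna().sum(axis=1) >= min_obs) & (b.notna().sum(axis=1) >= min_obs)
    a = a.loc[testable].to_numpy()
    b = b.loc[testable].to_numpy()
    if a.shape[0] == 0:
        return pd.DataFrame(columns=["protein", "log2fc", "t", "p", "adj_p", "call"])
    lfc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isnan(p), 1.0, p)
    result = pd.DataFrame(
        {"protein": log2_table.index[testable], "log2fc": lfc, "t": t, "p": p}
    )
    result["adj_p"] = multipletests(result["p"], method="fdr_bh")[1]
    result["call"] = "unchanged"
    result.loc[(result["log2fc"] > lfc_threshold) & (result["adj_p"] < alpha), "call"] = "up"
    result.loc[(result["log2fc"] < -lfc_threshold) & (result["adj_p"] < alpha), "call"] = "down"
    return result.set_index("protein")


def presence_absence(
    table: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    min_obs: int = 2,
) -> dict[str, list[str]]:
    """Condition-specific proteins: >= min_obs in one condition, 0 in the other."""
    sa = design.index[design["condition"] == cond_a]
    sb = design.index[design["condition"] == cond_b]
    na = table[sa].notna().sum(axis=1)
    nb = table[sb].notna().sum(axis=1)
    return {
        cond_a: sorted(table.index[(na >= min_obs) & (nb == 0)]),
        cond_b: sorted(table.index[(nb >= min_obs) & (na == 0)]),
    }


def ora_fisher(
    gene_list: Sequence[str],
    background: Sequence[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation across gene sets, BH-adjusted."""
    genes = set(gene_list)
    bg = set(background)
    if not genes <= bg:
        raise ValueError("gene_list must be a subset of background")
    rows = []
    for name, members in gene_sets.items():
        in_bg = members & bg
        if not in_bg:
            continue  # no overlap with measurable genes
        k = len(genes & in_bg)
        table = [
            [k, len(genes) - k],
            [len(in_bg) - k, len(bg) - len(genes) - (len(in_bg) - k)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"gene_set": name, "overlap": k, "set_size": len(in_bg),
                     "p": float(p)})
    result = pd.DataFrame(rows)
    if len(result):
        result["adj_p"] = multipletests(result["p"], method="fdr_bh")[1]
    return result
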