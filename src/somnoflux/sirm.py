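"""Isotopologue accounting and pathway binning for 13C-glucose tracing.

After a U-13C-glucose bolus, each metabolite's mass-isotopologue
distribution (M+0 ... M+n, n = carbon count) records how much of its pool
was synthesized from the labeled glucose. "Labeled" here counts every M+i
with i >= 1; the fully labeled species M+n is also reported separately.
Metabolites are grouped into pathway bins (glycolysis, TCA cycle,
neurotransmitter synthesis, amino acid synthesis) and group differences
are assessed by two-way ANOVA over group x labeling status.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["CARBON_COUNTS", "DEFAULT_BINS", "validate_table",
           "fractional_enrichment", "bin_pathways", "compare_groups",
           "heatmap_matrix"]

#: Carbon counts of the metabolites covered by the default pathway bins.
CARBON_COUNTS = {
    "pyruvate": 3, "lactate": 3, "glucose-1-phosphate": 6,
    "citrate": 6, "malate": 4, "fumarate": 4,
    "glutamate": 5, "glutamine": 5, "GABA": 4, "pyroglutamic acid": 5,
    "NAA": 6, "myo-inositol": 6, "aspartate": 4,
    "alanine": 3, "creatinine": 4, "taurine": 2, "glycine": 2,
}

#: Default pathway bins; no metabolite appears in two bins.
DEFAULT_BINS = {
    "glycolysis": ["pyruvate", "lactate", "glucose-1-phosphate"],
    "TCA": ["citrate", "malate", "fumarate"],
    "neurotransmitter synthesis": ["glutamate", "glutamine", "GABA",
                                   "pyroglutamic acid", "NAA",
                                   "myo-inositol", "aspartate"],
    "amino acid synthesis": ["alanine", "creatinine", "taurine", "glycine"],
}

_COLUMNS = ["metabolite", "isotopologue", "sample", "group", "abundance"]


def validate_table(table: pd.DataFrame,
                   carbon_counts: dict | None = None) -> pd.DataFrame:
    """Check schema, non-negative abundances, isotopologue <= carbon count,
    and that every (metabolite, sample) carries an M+0 row."""
    counts = CARBON_COUNTS if carbon_counts is None else carbon_counts
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"isotopologue table missing columns: {sorted(missing)}")
    if (table["abundance"] < 0).any():
        raise InputError("abundances must be >= 0")
    for met, sub in table.groupby("metabolite"):
        n_c = counts.get(met)
        if n_c is not None and (sub["isotopologue"] > n_c).any():
            raise InputError(f"{met}: isotopologue index exceeds carbon count {n_c}")
    has_m0 = table[table["isotopologue"] == 0].groupby(
        ["metabolite", "sample"]).size()
    all_pairs = table.groupby(["metabolite", "sample"]).size()
    if not all_pairs.index.isin(has_m0.index).all():
        raise InputError("every (metabolite, sample) needs an M+0 row")
    return table


def fractional_enrichment(table: pd.DataFrame,
                          carbon_counts: dict | None = None) -> pd.DataFrame:
    """Labeled/unlabeled pools and fractions per (metabolite, sample).

    labeled = sum of M+i for i >= 1; unlabeled = M+0; fraction =
    labeled / total (NaN when the total pool is zero). The fully labeled
    fraction (M+n, n = carbon count) is reported alongside.
    """
    counts = CARBON_COUNTS if carbon_counts is None else carbon_counts
    validate_table(table, counts)
    rows = []
    for (met, sample), sub in table.groupby(["metabolite", "sample"], sort=True):
        group = sub["group"].iloc[0]
        unlabeled = float(sub.loc[sub["isotopologue"] == 0, "abundance"].sum())
        labeled = float(sub.loc[sub["isotopologue"] >= 1, "abundance"].sum())
        total = unlabeled + labeled
        n_c = counts.get(met)
        fully = float(sub.loc[sub["isotopologue"] == n_c, "abundance"].sum()) \
            if n_c is not None else np.nan
        rows.append({
            "metabolite": met, "sample": sample, "group": group,
            "unlabeled": unlabeled, "labeled": labeled, "total": total,
            "fraction": labeled / total if total > 0 else np.nan,
            "fully_labeled_fraction": fully / total if total > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def bin_pathways(enrichment: pd.DataFrame,
                 bin_map: dict | None = None) -> pd.DataFrame:
    """Pathway-level labeled abundance (sum) and mean labeled fraction.

    Metabolites absent from a sample contribute 0 to the sum (with a
    warning); a bin with no member metabolite anywhere in the table raises.
    """
    bins = DEFAULT_BINS if bin_map is None else bin_map
    assigned = [m for members in bins.values() for m in members]
    if len(assigned) != len(set(assigned)):
        raise InputError("a metabolite appears in two pathway bins")
    present = set(enrichment["metabolite"])
    rows = []
    for bin_name, members in bins.items():
        found = [m for m in members if m in present]
        if not found:
            raise InputError(f"pathway bin {bin_name!r} matches no metabolite")
        if len(found) < len(members):
            logger.warning("bin %s: %d member(s) absent from the table",
                           bin_name, len(members) - len(found))
        sub = enrichment[enrichment["metabolite"].isin(found)]
        for sample, ss in sub.groupby("sample"):
            rows.append({
                "bin": bin_name, "sample": sample,
                "group": ss["group"].iloc[0],
                "labeled_sum": float(ss["labeled"].sum()),
                "unlabeled_sum": float(ss["unlabeled"].sum()),
                "mean_fraction": float(ss["fraction"].mean()),
            })
    return pd.DataFrame(rows)


def compare_groups(binned: pd.DataFrame, unit: str = "bin") -> pd.DataFrame:
    """Two-way ANOVA (group x labeling status) per bin or metabolite.

    The response is pool abundance with labeling status (labeled vs
    unlabeled) as the second factor, so the group x status interaction
    captures a shift of label into or out of the pathway. Reports F and p
    for both main effects and the interaction, plus the direction
    (difference of group means of the labeled pool). Requires >= 2 samples
    per cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    key = "bin" if unit == "bin" else "metabolite"
    lab_col = "labeled_sum" if "labeled_sum" in binned.columns else "labeled"
    unlab_col = "unlabeled_sum" if "unlabeled_sum" in binned.columns else "unlabeled"
    rows = []
    for name, sub in binned.groupby(key):
        long = pd.concat([
            pd.DataFrame({"value": sub[lab_col], "status": "labeled",
                          "group": sub["group"]}),
            pd.DataFrame({"value": sub[unlab_col], "status": "unlabeled",
                          "group": sub["group"]}),
        ], ignore_index=True)
        cells = long.groupby(["group", "status"]).size()
        groups = long["group"].unique()
        if (cells < 2).any() or len(groups) < 2:
            raise InputError(f"{name}: need >= 2 samples per (group, status) cell")
        model = ols("value ~ C(group) * C(status)", data=long).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        lab = long[long["status"] == "labeled"]
        g_sorted = sorted(groups)
        direction = (lab.loc[lab["group"] == g_sorted[-1], "value"].mean()
                     - lab.loc[lab["group"] == g_sorted[0], "value"].mean())
        rows.append({
            key: name,
            "F_group": anova.loc["C(group)", "F"],
            "p_group": anova.loc["C(group)", "PR(>F)"],
            "F_status": anova.loc["C(status)", "F"],
            "p_status": anova.loc["C(status)", "PR(>F)"],
            "F_interaction": anova.loc["C(group):C(status)", "F"],
            "p_interaction": anova.loc["C(group):C(status)", "PR(>F)"],
            "labeled_diff": direction,
            "contrast": f"{g_sorted[-1]} - {g_sorted[0]}",
        })
    return pd.DataFrame(rows)


def heatmap_matrix(enrichment: pd.DataFrame, value: str = "labeled"
                   ) -> pd.DataFrame:
    """Metabolite x sample matrix of per-metabolite z-scores, for heatmaps."""
    piv = enrichment.pivot(index="metabolite", columns="sample", values=value)
    mu = piv.mean(axis=1)
    sd = piv.std(axis=1, ddof=1).replace(0, np.nan)
    return piv.sub(mu, axis=0).div(sd, axis=0)
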