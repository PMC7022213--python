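"""Tabular computations for the behavioral, qPCR, and expression stages.

Covers social-interaction (SI) ratio phenotyping of chronically defeated
mice, relative qPCR quantification by the ddCt method normalized on a
housekeeping gene, the 2-SD outlier screen, differential-expression
filtering at |fold change| >= 2 and P < 0.05 with Venn-region counts,
ChIP-qPCR percent-input enrichment, and the group-comparison contracts
(one/two-way ANOVA with Bonferroni posttests, Pearson correlation).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

PHENOTYPES = ("CTRL", "SS", "RES", "unclassified")


def compute_si(time_present: float, time_absent: float) -> float:
    """SI ratio: interaction-zone time with the aggressor present divided by
    the time with it absent."""
    if time_present < 0 or time_absent < 0:
        raise ValueError("interaction times must be nonnegative")
    if time_absent == 0:
        raise ValueError("time_absent is zero; SI ratio is undefined")
    return time_present / time_absent


def classify_phenotype(si_ratio: float, stressed: bool) -> str:
    """Stressed mice: ratio < 1 -> SS (susceptible), ratio > 1 -> RES
    (resilient), exactly 1 -> unclassified.  Unstressed mice are CTRL."""
    if not math.isfinite(si_ratio):
        raise ValueError("si_ratio must be finite")
    if not stressed:
        return "CTRL"
    if si_ratio < 1.0:
        return "SS"
    if si_ratio > 1.0:
        return "RES"
    return "unclassified"


def classify_behavior_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add si_ratio and phenotype columns to a behavior table with
    time_present, time_absent, stressed columns."""
    out = df.copy()
    out["si_ratio"] = [compute_si(tp, ta) for tp, ta
                       in zip(out["time_present"], out["time_absent"])]
    out["phenotype"] = [classify_phenotype(r, bool(s)) for r, s
                        in zip(out["si_ratio"], out["stressed"])]
    return out


@dataclass(frozen=True)
class QPCRRecord:
    sample_id: str
    group: str
    gene: str
    ct_gene: float
    ct_housekeeping: float


def ddct_fold_change(samples: pd.DataFrame,
                     control_group: str) -> pd.DataFrame:
    """ddCt relative quantification.

    Per sample, dCt = ct_gene - ct_housekeeping; per gene, ddCt = dCt minus
    the arithmetic mean dCt of the control group; fold change = 2**(-ddCt).
    The control group's fold changes then have geometric mean 1.
    """
    df = samples.copy()
    missing = df[df["ct_gene"].isna() | df["ct_housekeeping"].isna()]
    if len(missing):
        raise ValueError(
            "missing Ct values for samples: "
            + ", ".join(map(str, missing["sample_id"].tolist())))
    df["delta_ct"] = df["ct_gene"] - df["ct_housekeeping"]
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            raise ValueError(
                f"no {control_group!r} samples for gene {gene!r}")
        ref = float(ctrl.mean())
        sub = sub.copy()
        sub["ddct"] = sub["delta_ct"] - ref
        sub["fold_change"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def exclude_outliers(values) -> tuple[np.ndarray, list[int]]:
    """Single-pass 2-SD screen: remove values strictly more than 2
    population SDs from the mean of the full input.  Fewer than 3 values is
    a no-op with a warning."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1D sequence")
    if len(arr) < 3:
        warnings.warn("fewer than 3 values; outlier screen skipped",
                      stacklevel=2)
        return arr, []
    mean = arr.mean()
    sd = arr.std()
    removed = [int(i) for i in np.nonzero(np.abs(arr - mean) > 2.0 * sd)[0]]
    kept = np.delete(arr, removed)
    return kept, removed


def de_filter(table: pd.DataFrame, fc_cut: float = 2.0,
              p_cut: float = 0.05) -> tuple[list, list]:
    """Differential-expression filter on a signed linear fold-change table.

    up: fold_change >= +fc_cut and p < p_cut; down: fold_change <= -fc_cut
    and p < p_cut.  Boundaries: |FC| exactly at the cut is kept, p exactly
    at the cut is dropped.  Signed convention: -2 means halved expression.
    """
    fc = table["fold_change"].to_numpy(dtype=float)
    p = table["p_value"].to_numpy(dtype=float)
    if np.any(fc == 0):
        raise ValueError("fold_change must be nonzero (signed convention)")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p_value must lie in (0, 1]")
    sig = p < p_cut
    up = table.loc[(fc >= fc_cut) & sig, "gene_id"].tolist()
    down = table.loc[(fc <= -fc_cut) & sig, "gene_id"].tolist()
    return up, down


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Disjoint Venn-region counts for 2 or 3 named sets.

    Keys are sorted tuples of the member-set names; values sum to the size
    of the union.
    """
    names = sorted(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts supports exactly 2 or 3 sets")
    universe = set().union(*sets.values())
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            counts[combo] = 0
    for item in universe:
        members = tuple(n for n in names if item in sets[n])
        counts[members] += 1
    return counts


def chip_percent_input(ct_ip: float, ct_input: float,
                       input_fraction: float) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    The input Ct is first adjusted to represent 100% of the chromatin
    (subtract log2 of the dilution factor 1/input_fraction), then
    percent input = 100 * 2**(ct_input_adjusted - ct_ip).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (ct_input_adjusted - ct_ip)


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p_raw)."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def group_compare(values_by_group: dict[str, np.ndarray],
                  posthoc: bool = True, alpha: float = 0.05) -> dict:
    """One-way ANOVA across groups with pairwise Bonferroni posttests.

    Returns a report dict: test name, F, degrees of freedom, p, and for
    each group pair the raw and Bonferroni-adjusted two-sided t-test p.
    """
    groups = {g: np.asarray(v, dtype=float)
              for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; ANOVA is degenerate")
    names = list(groups)
    f_stat, p_val = sps.f_oneway(*groups.values())
    n_total = sum(len(v) for v in groups.values())
    report = {
        "test": "one-way ANOVA",
        "F": float(f_stat),
        "df": (len(groups) - 1, n_total - len(groups)),
        "p": float(p_val),
        "alpha": alpha,
        "significant": bool(p_val < alpha),
        "group_means": {g: float(v.mean()) for g, v in groups.items()},
        "group_n": {g: int(len(v)) for g, v in groups.items()},
        "posttests": [],
    }
    if posthoc:
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        for ga, gb in pairs:
            t, p = sps.ttest_ind(groups[ga], groups[gb])
            p_adj = bonferroni(float(p), m)
            report["posttests"].append({
                "pair": (ga, gb), "t": float(t), "p_raw": float(p),
                "p_adj": p_adj, "significant": bool(p_adj < alpha),
            })
    return report


def group_compare_twoway(df: pd.DataFrame, value_col: str, factor_a: str,
                         factor_b: str, alpha: float = 0.05) -> dict:
    """Two-way ANOVA (type II, with interaction) via ordinary least squares."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = df.rename(columns={value_col: "value", factor_a: "fa",
                              factor_b: "fb"})
    model = ols("value ~ C(fa) * C(fb)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {}
    mapping = {"C(fa)": factor_a, "C(fb)": factor_b,
               "C(fa):C(fb)": f"{factor_a} x {factor_b}"}
    for row, name in mapping.items():
        effects[name] = {
            "F": float(table.loc[row, "F"]),
            "p": float(table.loc[row, "PR(>F)"]),
            "df": float(table.loc[row, "df"]),
            "significant": bool(table.loc[row, "PR(>F)"] < alpha),
        }
    return {"test": "two-way ANOVA", "alpha": alpha, "effects": effects}


def pearson_correlation(x, y) -> dict:
    """Pearson r with two-sided p for paired numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    r, p = sps.pearsonr(x, y)
    return {"test": "Pearson correlation", "r": float(r), "p": float(p),
            "n": int(len(x))}
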