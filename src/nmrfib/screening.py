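"""Multi-criterion differential-metabolite screening.

A metabolite is called differential only when three lines of evidence agree:
model importance (VIP at or above the cut), S-plot reliability (|p(corr)| at
or above the cut) and univariate significance (Welch t-test p below alpha
for the obstructed-vs-sham-left comparison). Directions of change report the
A (UUO obstructed) vs C (sham left) contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import LatentModel, coefficients, vip
from .io import MetaboliteAssignment

_FLAT_EPS = 1e-9


@dataclass
class ScreeningCuts:
    vip: float = 1.0
    pcorr: float = 0.5
    alpha: float = 0.05


@dataclass
class ScreeningRecord:
    """Per-metabolite evidence and the conjunction verdict."""

    metabolite: str
    mean_by_group: dict[str, float]
    vip: float
    pcorr: float
    coefficient: float
    p_value_AC: float
    p_value_BC: float
    direction: str  # "up" | "down" | "flat" (A vs C)
    selected: bool


def group_compare(contents: pd.DataFrame, groups) -> pd.DataFrame:
    """Group means plus Welch t-test p-values for A vs C and B vs C.

    ``contents`` is samples x metabolites; ``groups`` aligns with its rows.
    Each compared group must have at least 3 samples. Two-group comparison
    by unequal-variance (Welch) t-test; with two groups the 95%-confidence
    ANOVA F-test is its equal-variance special case (F = t^2).
    """
    groups = np.asarray([str(g) for g in groups])
    if groups.size != len(contents):
        raise ValueError("groups length does not match contents rows")
    present = sorted(set(groups))
    counts = {g: int((groups == g).sum()) for g in present}
    for g in ("A", "B", "C"):
        if counts.get(g, 0) < 3:
            raise ValueError(f"group {g} needs at least 3 samples, "
                             f"got {counts.get(g, 0)}")
    out = {}
    for g in present:
        out[f"mean_{g}"] = contents[groups == g].mean(axis=0)
    for pair in ("AC", "BC"):
        a, b = contents[groups == pair[0]], contents[groups == pair[1]]
        pvals = {}
        for m in contents.columns:
            if np.allclose(a[m].var(ddof=1), 0) and np.allclose(b[m].var(ddof=1), 0) \
                    and np.isclose(a[m].mean(), b[m].mean()):
                pvals[m] = 1.0  # identical degenerate groups: no evidence
            else:
                pvals[m] = float(stats.ttest_ind(a[m], b[m], equal_var=False).pvalue)
        out[f"p_value_{pair}"] = pd.Series(pvals)
    df = pd.DataFrame(out)
    diff = df["mean_A"] - df["mean_C"]
    flat = diff.abs() <= _FLAT_EPS * df[["mean_A", "mean_C"]].abs().max(axis=1).clip(lower=1.0)
    df["direction"] = np.where(flat, "flat", np.where(diff > 0, "up", "down"))
    return df


def metabolite_criteria(model: LatentModel, splot_df: pd.DataFrame,
                        bucket_left_edges: np.ndarray, bucket_width: float,
                        assignments: list[MetaboliteAssignment]) -> pd.DataFrame:
    """Map bucket-level model evidence onto metabolites.

    For each metabolite, the representative bucket is the highest-VIP bucket
    whose interval lies inside the metabolite's quantification window; its
    VIP, p(corr) and regression coefficient become the metabolite's
    screening criteria (the spectral model sees buckets, the biology is per
    metabolite).
    """
    v = vip(model)
    coef = coefficients(model)
    edges = np.asarray(bucket_left_edges)
    rows = {}
    for a in assignments:
        lo, hi = a.quant_window
        inside = np.flatnonzero((edges >= lo - 1e-9) &
                                (edges + bucket_width <= hi + 1e-9))
        if inside.size == 0:
            raise ValueError(f"no surviving bucket inside quant window of {a.name}")
        j = inside[int(np.argmax(v[inside]))]
        rows[a.name] = {"vip": float(v[j]),
                        "pcorr": float(splot_df["pcorr"].iloc[j]),
                        "coefficient": float(coef[j]),
                        "bucket": float(edges[j])}
    return pd.DataFrame.from_dict(rows, orient="index")


def screen(criteria: pd.DataFrame, comparison: pd.DataFrame,
           cuts: ScreeningCuts | None = None) -> list[ScreeningRecord]:
    """Apply the conjunction rule and return records sorted by VIP.

    ``criteria`` is metabolite-indexed with columns vip/pcorr/coefficient;
    ``comparison`` comes from :func:`group_compare`. A metabolite missing
    any criterion is a hard error naming it.
    """
    cuts = cuts or ScreeningCuts()
    records = []
    needed_c = ["vip", "pcorr", "coefficient"]
    needed_g = ["p_value_AC", "p_value_BC", "mean_A", "mean_C", "direction"]
    for m in comparison.index:
        if m not in criteria.index:
            raise ValueError(f"missing model criteria for metabolite {m!r}")
        row_c, row_g = criteria.loc[m], comparison.loc[m]
        for col, row in [(c, row_c) for c in needed_c] + [(c, row_g) for c in needed_g]:
            if pd.isna(row[col]):
                raise ValueError(f"missing criterion {col!r} for metabolite {m!r}")
        selected = bool(row_c["vip"] >= cuts.vip
                        and abs(row_c["pcorr"]) >= cuts.pcorr
                        and row_g["p_value_AC"] < cuts.alpha)
        means = {g: float(row_g[f"mean_{g}"]) for g in "ABCD"
                 if f"mean_{g}" in comparison.columns}
        records.append(ScreeningRecord(
            metabolite=str(m), mean_by_group=means,
            vip=float(row_c["vip"]), pcorr=float(row_c["pcorr"]),
            coefficient=float(row_c["coefficient"]),
            p_value_AC=float(row_g["p_value_AC"]),
            p_value_BC=float(row_g["p_value_BC"]),
            direction=str(row_g["direction"]), selected=selected))
    records.sort(key=lambda r: -r.vip)
    return records


def direction_table(means: pd.DataFrame | list[ScreeningRecord]) -> pd.DataFrame:
    """Per-metabolite direction of change for the A vs C contrast.

    Accepts either a metabolite-indexed means table with columns ``A`` and
    ``C`` (group mean relative contents) or a list of screening records.
    Metabolites with no A-vs-C change are flagged "flat".
    """
    if isinstance(means, list):
        means = pd.DataFrame(
            {"A": {r.metabolite: r.mean_by_group["A"] for r in means},
             "C": {r.metabolite: r.mean_by_group["C"] for r in means}})
    diff = means["A"] - means["C"]
    flat = diff.abs() <= _FLAT_EPS * means[["A", "C"]].abs().max(axis=1).clip(lower=1.0)
    direction = np.where(flat, "flat", np.where(diff > 0, "up", "down"))
    return pd.DataFrame({"A": means["A"], "C": means["C"],
                         "direction": direction}, index=means.index)
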