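"""Contralateral fibrosis index.

For each differential metabolite the change rate

    alpha = (XB - XC) / (XA - XC)

expresses the contralateral (right, B) kidney's shift as a fraction of the
obstructed (left, A) kidney's shift, both relative to the sham-left (C)
baseline: alpha = 0 means the contralateral kidney is unchanged, alpha = 1
means it changed as much as the obstructed one. The percent average degree
of fibrosis (ADF) summarises the panel as 100 x mean |alpha| over the
included metabolites. alpha is unit-free: any common rescaling of XA, XB,
XC cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FibrosisIndexResult:
    """Per-metabolite alphas plus the percent-ADF summary.

    ``per_metabolite`` has columns XA, XB, XC, alpha; ``excluded`` lists
    (metabolite, reason) pairs dropped by the denominator guard.
    """

    per_metabolite: pd.DataFrame
    adf_percent: float
    n_used: int
    excluded: list[tuple[str, str]]


def _den_eps(xa: float, xc: float) -> float:
    return 1e-9 * max(abs(xa), abs(xc), 1.0)


def alpha(XA: float, XB: float, XC: float) -> float:
    """Change rate of one metabolite; raises on a vanishing denominator."""
    if abs(XA - XC) <= _den_eps(XA, XC):
        raise ValueError("no A-vs-C change: denominator below epsilon")
    return (XB - XC) / (XA - XC)


def average_degree_of_fibrosis(means: pd.DataFrame) -> FibrosisIndexResult:
    """ADF from a metabolite-indexed group-mean table with columns C, A, B.

    Metabolites whose A-vs-C denominator vanishes are excluded (with a
    reason) rather than poisoning the mean; zero included metabolites is a
    hard error.
    """
    for col in ("C", "A", "B"):
        if col not in means.columns:
            raise ValueError(f"means table lacks group column {col!r}")
    rows, excluded = {}, []
    for m, row in means.iterrows():
        xa, xb, xc = float(row["A"]), float(row["B"]), float(row["C"])
        if abs(xa - xc) <= _den_eps(xa, xc):
            excluded.append((str(m), "no A-vs-C change"))
            continue
        rows[m] = {"XA": xa, "XB": xb, "XC": xc, "alpha": (xb - xc) / (xa - xc)}
    if not rows:
        raise ValueError("no metabolite with a usable A-vs-C denominator")
    per = pd.DataFrame.from_dict(rows, orient="index")
    adf = 100.0 * float(per["alpha"].abs().mean())
    return FibrosisIndexResult(per_metabolite=per, adf_percent=adf,
                               n_used=len(per), excluded=excluded)


def fibrosis_index_from_samples(contents: pd.DataFrame,
                                groups) -> FibrosisIndexResult:
    """ADF from sample-level relative contents.

    XA/XB/XC are the group means of ``contents`` (samples x metabolites)
    over groups A, B and C; groups must each have at least 3 samples.
    """
    groups = np.asarray([str(g) for g in groups])
    if groups.size != len(contents):
        raise ValueError("groups length does not match contents rows")
    means = {}
    for g in ("A", "B", "C"):
        mask = groups == g
        if mask.sum() < 3:
            raise ValueError(f"group {g} needs at least 3 samples, got {mask.sum()}")
        means[g] = contents[mask].mean(axis=0)
    return average_degree_of_fibrosis(pd.DataFrame(means))
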