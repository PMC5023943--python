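"""Metabolite-vs-endpoint correlation reporting.

Pearson correlations between metabolite relative contents and the clinical /
histology endpoints (Scr, BUN, ALB, TIS, ICD), with the conventional
significance stars (* p<0.05, ** p<0.01, *** p<0.001; boundary p-values
fall in the weaker category), a sign-concordance check against a reference
pattern, and two-component PLS biplot coordinates linking samples,
metabolites and endpoints on a common basis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import fit_pls2
from .io import ENDPOINTS


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _join(contents: pd.DataFrame, endpoints: pd.DataFrame,
          sample_meta: pd.DataFrame, join: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align kidney samples with their animal's endpoint row.

    ``join="left"`` keeps left kidneys only (groups A and C: obstructed vs
    sham-left); ``join="both"`` joins both kidneys of an animal to the same
    endpoint values.
    """
    if join not in ("left", "both"):
        raise ValueError(f"unknown join mode {join!r}")
    meta = sample_meta.loc[contents.index]
    if join == "left":
        keep = meta["group"].isin(["A", "C"])
        contents, meta = contents[keep], meta[keep]
    ep = endpoints.set_index("animal_id")
    mapped = meta["animal_id"].map(lambda a: a in ep.index)
    if not mapped.all():
        missing = sorted(set(meta.loc[~mapped, "animal_id"]))
        raise ValueError(f"no endpoint row for animal(s): {missing}")
    ep_rows = ep.loc[meta["animal_id"], list(ENDPOINTS)].set_axis(contents.index)
    return contents, ep_rows


def correlate(contents: pd.DataFrame, endpoints: pd.DataFrame,
              sample_meta: pd.DataFrame, join: str = "left") -> pd.DataFrame:
    """Pearson r, two-sided p and stars for every (metabolite, endpoint).

    Returns a long-format frame with columns ``metabolite, endpoint, r, p,
    stars, undefined``. The p-value is the exact t-transform of r with
    n - 2 degrees of freedom. Zero-variance endpoints (or metabolites) are
    flagged undefined instead of erroring.
    """
    X, E = _join(contents, endpoints, sample_meta, join)
    n = len(X)
    if n < 4:
        raise ValueError(f"need at least 4 joined observations, got {n}")
    rows = []
    for m in X.columns:
        for e in E.columns:
            x, y = X[m].to_numpy(float), E[e].to_numpy(float)
            if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                rows.append({"metabolite": m, "endpoint": e, "r": np.nan,
                             "p": np.nan, "stars": "", "undefined": True})
                continue
            res = stats.pearsonr(x, y)
            rows.append({"metabolite": m, "endpoint": e, "r": float(res.statistic),
                         "p": float(res.pvalue), "stars": stars(float(res.pvalue)),
                         "undefined": False})
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format correlate() output to metabolites x endpoints r."""
    return table.pivot(index="metabolite", columns="endpoint", values="r")[
        list(ENDPOINTS)]


def sign_concordance(computed: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Fraction of cells whose r sign matches the reference sign.

    Both frames are metabolites x endpoints; the grids must coincide.
    Zero-valued reference cells are skipped; undefined computed cells count
    as discordant.
    """
    if set(computed.index) != set(reference.index) or \
            list(computed.columns) != list(reference.columns):
        raise ValueError("computed and reference tables cover different grids")
    computed = computed.loc[reference.index]
    ref = reference.to_numpy(float)
    got = computed.to_numpy(float)
    mask = np.sign(ref) != 0
    agree = np.sign(got[mask]) == np.sign(ref[mask])
    agree &= ~np.isnan(got[mask])
    return float(agree.sum() / mask.sum())


def biplot_coordinates(contents: pd.DataFrame, endpoints: pd.DataFrame,
                       sample_meta: pd.DataFrame, join: str = "left",
                       scaling: str = "uv") -> dict[str, pd.DataFrame]:
    """Two-component PLS biplot: samples, metabolites, endpoints on one basis.

    X = metabolite contents, Y = endpoint matrix. Returns sample scores
    (T), metabolite loadings (X weights) and endpoint loadings (Y loadings),
    each as a DataFrame with columns ``comp1, comp2``.
    """
    X, E = _join(contents, endpoints, sample_meta, join)
    if len(X) < 3:
        raise ValueError("need at least 3 samples for a biplot")
    fit = fit_pls2(X.to_numpy(float), E.to_numpy(float), n_components=2,
                   scaling=scaling)
    cols = ["comp1", "comp2"]
    return {
        "samples": pd.DataFrame(fit["T"], index=X.index, columns=cols),
        "metabolites": pd.DataFrame(fit["W"], index=X.columns, columns=cols),
        "endpoints": pd.DataFrame(fit["Q"], index=E.columns, columns=cols),
    }
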