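"""Packaged reference tables for the UUO kidney study.

Two fixtures are shipped as inline TSV text:

* the 14-metabolite group-mean table of relative contents for groups
  C (sham left), A (UUO obstructed/left) and B (UUO contralateral/right),
  together with the published per-metabolite change rate ``alpha``;
* the 14 x 5 Pearson correlation table between metabolite relative contents
  and the clinical / histology endpoints (Scr, BUN, ALB, TIS, ICD).

Both are verified against a frozen SHA-256 checksum on load, so silent edits
of the packaged values fail hard rather than drifting the analysis.
"""

from __future__ import annotations

import hashlib
import io

import pandas as pd

#: Canonical metabolite order of the group-mean table.
METABOLITES = (
    "Lactate",
    "Methionine",
    "Aspartate",
    "Allantoin",
    "Uracil",
    "3-HB",
    "Phenylalanine",
    "TMAO",
    "Leucine",
    "Valine",
    "Lysine",
    "Tyrosine",
    "Hypoxanthine",
    "Adenosine",
)

# Group-mean relative contents (arbitrary units, tissue-weight normalised)
# and published change rate alpha = (B - C) / (A - C).
_TABLE1_TSV = """\
metabolite\tC\tA\tB\talpha
Lactate\t1.540\t3.063\t1.842\t0.198
Methionine\t0.099\t0.561\t0.092\t-0.015
Aspartate\t0.134\t0.354\t0.119\t-0.069
Allantoin\t0.015\t0.187\t0.029\t0.082
Uracil\t0.062\t0.125\t0.071\t0.133
3-HB\t0.115\t0.177\t0.109\t-0.104
Phenylalanine\t0.176\t0.113\t0.166\t0.155
TMAO\t1.914\t1.104\t1.618\t0.365
Leucine\t1.126\t0.697\t0.972\t0.360
Valine\t0.661\t0.358\t0.572\t0.294
Lysine\t0.530\t0.332\t0.443\t0.437
Tyrosine\t0.169\t0.109\t0.144\t0.415
Hypoxanthine\t0.208\t0.138\t0.184\t0.352
Adenosine\t0.169\t0.051\t0.249\t-0.680
"""

# Pearson correlations between metabolite relative contents and endpoints.
_TABLE2_TSV = """\
metabolite\tScr\tBUN\tALB\tTIS\tICD
Lactate\t0.667\t0.657\t-0.325\t0.855\t0.851
Methionine\t0.842\t0.513\t-0.359\t0.670\t0.873
Aspartate\t0.855\t0.602\t-0.403\t0.750\t0.696
Allantoin\t0.784\t0.460\t-0.388\t0.774\t0.892
Uracil\t0.811\t0.546\t-0.221\t0.826\t0.809
3-HB\t0.824\t0.620\t-0.341\t0.779\t0.832
TMAO\t-0.775\t-0.672\t0.358\t-0.709\t-0.859
Leucine\t-0.760\t-0.815\t0.553\t-0.749\t-0.884
Valine\t-0.800\t-0.765\t0.564\t-0.750\t-0.928
Lysine\t-0.649\t-0.644\t0.463\t-0.785\t-0.869
Adenosine\t-0.769\t-0.682\t0.420\t-0.651\t-0.903
Tyrosine\t-0.744\t-0.771\t0.533\t-0.739\t-0.864
Phenylalanine\t0.703\t0.480\t-0.338\t0.798\t0.886
Hypoxanthine\t-0.794\t-0.610\t0.378\t-0.632\t-0.799
"""

_TABLE1_SHA256 = "29ad8518e2d4c03c96372b91f8ff88d7dfa68e5ef91c2f7e680c47a4ff027d8f"
_TABLE2_SHA256 = "07dda934cab725ac587e03103803640a2eee10c2eedb78090f253648c389df56"


def _checked(text: str, digest: str, name: str) -> str:
    got = hashlib.sha256(text.encode()).hexdigest()
    if got != digest:
        raise RuntimeError(f"packaged reference fixture {name!r} is corrupted "
                           f"(sha256 {got} != {digest})")
    return text


def load_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the packaged (group-mean table, endpoint-correlation table).

    The first frame is indexed by metabolite with columns ``C, A, B, alpha``
    (``alpha`` is the published change rate, kept for auditing; the analysis
    recomputes it). The second is indexed by metabolite with columns
    ``Scr, BUN, ALB, TIS, ICD`` holding Pearson r; its signs define the
    reference pattern for :func:`nmrfib.correlation.sign_concordance`.
    """
    t1 = pd.read_csv(io.StringIO(_checked(_TABLE1_TSV, _TABLE1_SHA256, "group-means")),
                     sep="\t", index_col="metabolite")
    t2 = pd.read_csv(io.StringIO(_checked(_TABLE2_TSV, _TABLE2_SHA256, "correlations")),
                     sep="\t", index_col="metabolite")
    # Present the correlation table in the canonical metabolite order.
    t2 = t2.loc[list(METABOLITES)]
    return t1, t2
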