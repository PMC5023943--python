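"""Metabolite peak assignments for kidney-extract 1H NMR spectra.

A compact, synthetic assignment library for the 14 differential metabolites,
built from canonical literature chemical shifts (lactate CH3 doublet at
1.33 ppm, TMAO N-CH3 singlet at 3.27 ppm, ...). Each metabolite carries the
peaks used to render synthetic spectra plus a ``quant_window`` around its
least-overlapping signal, from which relative contents are integrated.
Windows are pairwise disjoint and avoid the residual-water region
(4.68-5.23 ppm), so relative quantification is clean by construction; the
analysis contracts depend on relative contents, not on assignment truth
against any particular spectrometer.
"""

from __future__ import annotations

from .io import MetaboliteAssignment

# (name, peaks[(center ppm, relative area, multiplicity)], quant_window)
_LIBRARY = [
    ("Lactate", [(1.33, 1.0, "d"), (4.11, 0.33, "q")], (1.31, 1.35)),
    ("Methionine", [(2.14, 1.0, "s"), (2.64, 0.5, "t")], (2.12, 2.16)),
    ("Aspartate", [(2.80, 1.0, "dd"), (2.68, 0.8, "dd")], (2.78, 2.82)),
    ("Allantoin", [(5.39, 1.0, "s")], (5.37, 5.41)),
    ("Uracil", [(5.80, 1.0, "d"), (7.54, 1.0, "d")], (5.78, 5.82)),
    ("3-HB", [(1.20, 1.0, "d"), (2.31, 0.4, "dd")], (1.18, 1.22)),
    ("Phenylalanine", [(7.42, 1.0, "m"), (7.32, 0.6, "m")], (7.40, 7.45)),
    ("TMAO", [(3.27, 1.0, "s")], (3.25, 3.29)),
    ("Leucine", [(0.96, 1.0, "t")], (0.94, 0.98)),
    ("Valine", [(1.04, 1.0, "d"), (0.99, 1.0, "d")], (1.02, 1.06)),
    ("Lysine", [(3.02, 1.0, "t"), (1.72, 0.8, "m")], (3.00, 3.04)),
    ("Tyrosine", [(6.90, 1.0, "d"), (7.19, 1.0, "d")], (6.88, 6.92)),
    ("Hypoxanthine", [(8.19, 1.0, "s"), (8.21, 1.0, "s")], (8.17, 8.23)),
    ("Adenosine", [(6.08, 1.0, "d"), (8.35, 0.5, "s")], (6.06, 6.10)),
]


def default_assignments() -> list[MetaboliteAssignment]:
    """The packaged 14-metabolite assignment library (fresh copies)."""
    return [
        MetaboliteAssignment(name=n, peaks=list(p), quant_window=w)
        for n, p, w in _LIBRARY
    ]
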