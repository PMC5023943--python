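"""Synthetic four-group kidney-extract spectra and correlated endpoints.

The generator emulates the statistical structure the analysis assumes:

* per-animal latent *fibrosis severity* ``s`` (UUO animals ~1 with spread,
  sham animals 0) drives both kidneys' metabolite levels and the clinical /
  histology endpoints, so metabolite-endpoint correlations arise naturally;
* group mean relative contents default to the packaged reference group
  means (groups C, A, B; D defaults to C, since the sham left/right
  difference is negligible), with log-normal within-group dispersion of a
  configurable coefficient of variation;
* spectra are sums of unit-area Lorentzian peaks on a 0.78-9.66 ppm axis at
  0.001 ppm steps (10 points per 0.01 ppm bucket), scaled by tissue weight
  (an extract contains weight x per-gram content of each metabolite), plus
  Gaussian noise and a residual-water hump confined to 4.68-5.23 ppm;
* Scr, BUN, TIS, ICD increase with severity, ALB decreases, reproducing the
  reference correlation-sign pattern for Table-1-faithful metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignments import default_assignments
from .io import MetaboliteAssignment, SpectrumRecord, validate_endpoints
from .reference import load_reference_tables

#: per-group tissue-weight (mean, sd) in grams; B and D are published values,
#: A (hydronephrotic, enlarged) and C are package assumptions.
DEFAULT_WEIGHT_PARAMS = {
    "A": (2.20, 0.30),
    "B": (1.67, 0.23),
    "C": (1.18, 0.09),
    "D": (1.18, 0.09),
}

#: endpoint = intercept + slope * severity + noise; units: Scr umol/L,
#: BUN mmol/L, ALB g/L, TIS ordinal 0-3, ICD percent area.
DEFAULT_ENDPOINT_PARAMS = {
    "Scr": (35.0, 45.0),
    "BUN": (5.5, 9.0),
    "ALB": (38.0, -7.0),
    "TIS": (0.1, 2.6),
    "ICD": (3.0, 45.0),
}


def _default_means() -> pd.DataFrame:
    t1, _ = load_reference_tables()
    means = t1[["C", "A", "B"]].copy()
    means["D"] = means["C"]
    return means


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults reproduce the study design: 11 UUO and 9 sham animals, two
    kidneys each, group means from the packaged reference table, 15%
    within-group coefficient of variation.
    """

    n_uuo: int = 11
    n_so: int = 9
    seed: int = 17
    metabolite_means: pd.DataFrame | None = None  # index metabolite, cols C,A,B,D
    cv: float = 0.15
    severity_sd: float = 0.12  # spread of the latent UUO severity around 1
    linewidth: float = 0.003  # Lorentzian FWHM, ppm
    noise_sd: float = 0.01  # fraction of the median peak height
    axis_step: float = 0.001  # ppm sampling step
    weight_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_PARAMS))
    endpoint_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENDPOINT_PARAMS))
    endpoint_noise: float = 0.08  # endpoint noise sd as a fraction of |slope|

    def __post_init__(self) -> None:
        if self.n_uuo < 3 or self.n_so < 3:
            raise ValueError("need at least 3 animals per arm")
        if not self.cv > 0:
            raise ValueError("cv must be > 0")
        if self.metabolite_means is None:
            self.metabolite_means = _default_means()
        missing = {"C", "A", "B", "D"} - set(self.metabolite_means.columns)
        if missing:
            raise ValueError(f"metabolite_means missing group columns: {sorted(missing)}")
        if (self.metabolite_means[["C", "A", "B", "D"]] <= 0).any().any():
            raise ValueError("all metabolite means must be > 0")


def _severities(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Latent per-animal severity: UUO ~ N(1, sd) clipped to +-3 sd, sham 0."""
    lo, hi = 1 - 3 * config.severity_sd, 1 + 3 * config.severity_sd
    s_uuo = np.clip(rng.normal(1.0, config.severity_sd, config.n_uuo), lo, hi)
    ids = [f"u{i + 1:02d}" for i in range(config.n_uuo)] + \
          [f"s{i + 1:02d}" for i in range(config.n_so)]
    return pd.Series(np.concatenate([s_uuo, np.zeros(config.n_so)]), index=ids)


def simulate_concentrations(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample metabolite relative contents.

    Returns ``(meta, concentrations)``: ``meta`` has one row per kidney
    sample (sample_id index; animal_id, group, tissue_weight_g, severity),
    ``concentrations`` is the samples x metabolites table. A UUO animal with
    severity ``s`` has target mean ``C + s * (G - C)`` in kidney group G, so
    severity 1 reproduces the configured group means and both kidneys of an
    animal share one severity; log-normal noise with the configured cv is
    applied around the target (mean-preserving parametrisation).
    """
    rng = np.random.default_rng(config.seed)
    sev = _severities(config, rng)
    means = config.metabolite_means
    sigma2 = np.log1p(config.cv ** 2)
    meta_rows, conc_rows, index = [], [], []
    for animal_id, s in sev.items():
        arm = "UUO" if animal_id.startswith("u") else "SO"
        kidneys = ("A", "B") if arm == "UUO" else ("C", "D")
        for group in kidneys:
            target = means["C"] + s * (means[group] - means["C"])
            target = np.maximum(target, 1e-4)
            mu = np.log(target) - sigma2 / 2
            conc = np.exp(rng.normal(mu, np.sqrt(sigma2)))
            wm, ws = config.weight_params[group]
            weight = max(0.2, rng.normal(wm, ws))
            sid = f"{animal_id}{group}"
            index.append(sid)
            meta_rows.append({"animal_id": animal_id, "group": group,
                              "tissue_weight_g": weight, "severity": s})
            conc_rows.append(conc)
    meta = pd.DataFrame(meta_rows, index=pd.Index(index, name="sample_id"))
    conc = pd.DataFrame(conc_rows, index=meta.index, columns=means.index)
    return meta, conc


def render_spectrum(
    concentrations: pd.Series,
    assignments: list[MetaboliteAssignment],
    config: SimulationConfig,
    *,
    sample_id: str = "sample",
    animal_id: str = "animal",
    group: str = "C",
    tissue_weight: float = 1.0,
    rng: np.random.Generator | None = None,
) -> SpectrumRecord:
    """Render one sample's spectrum from its per-gram metabolite contents.

    Intensities are ``tissue_weight x sum over peaks of content x relative
    area x Lorentzian(center, linewidth)``, plus Gaussian noise scaled to the
    median peak height and a residual-water hump confined to 4.68-5.23 ppm.
    """
    rng = rng or np.random.default_rng(config.seed)
    by_name = {a.name: a for a in assignments}
    missing = [m for m in concentrations.index if m not in by_name]
    if missing:
        raise ValueError(f"assignment missing for metabolite(s): {missing}")
    n_pts = int(round((9.66 - 0.78) / config.axis_step)) + 1
    ppm = np.round(0.78 + config.axis_step * np.arange(n_pts), 9)
    intensity = np.zeros(n_pts)
    gamma = config.linewidth / 2.0
    heights = []
    for name, conc in concentrations.items():
        if conc == 0:
            continue
        for center, area, _mult in by_name[name].peaks:
            amp = tissue_weight * conc * area
            intensity += amp * (gamma / np.pi) / ((ppm - center) ** 2 + gamma ** 2)
            heights.append(amp / (np.pi * gamma))
    med = float(np.median(heights)) if heights else 0.0
    if med > 0:
        water = (ppm >= 4.68) & (ppm <= 5.23)
        gw = 0.12
        intensity[water] += 20 * med * (gw / np.pi) / (
            (ppm[water] - 4.955) ** 2 + gw ** 2)
    if config.noise_sd > 0 and med > 0:
        intensity += rng.normal(0.0, config.noise_sd * med, n_pts)
    return SpectrumRecord(sample_id=sample_id, animal_id=animal_id, group=group,
                          tissue_weight=tissue_weight, ppm=ppm, intensity=intensity)


def simulate_endpoints(meta: pd.DataFrame,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Animal-level clinical/histology endpoints from the latent severity.

    ``meta`` is the sample metadata from :func:`simulate_concentrations`
    (severity column required). Scr, BUN, TIS and ICD increase with
    severity, ALB decreases; Gaussian noise of sd ``endpoint_noise x |slope|``
    is added, TIS is clipped to [0, 3] and ICD to [0, 100].
    """
    if "severity" not in meta.columns:
        raise ValueError("meta lacks the 'severity' column")
    rng = rng or np.random.default_rng(config.seed + 1)
    animals = meta.drop_duplicates("animal_id").set_index("animal_id")
    rows = []
    for animal_id, row in animals.iterrows():
        s = row["severity"]
        arm = "UUO" if str(animal_id).startswith("u") else "SO"
        rec = {"animal_id": animal_id, "group_arm": arm}
        for name, (b0, slope) in config.endpoint_params.items():
            val = b0 + slope * s + rng.normal(0.0, config.endpoint_noise * abs(slope))
            if name == "TIS":
                val = float(np.clip(val, 0.0, 3.0))
            elif name == "ICD":
                val = float(np.clip(val, 0.0, 100.0))
            else:
                val = max(0.0, val)
            rec[name] = val
        rows.append(rec)
    return validate_endpoints(pd.DataFrame(rows))


def simulate_dataset(
    config: SimulationConfig | None = None,
    assignments: list[MetaboliteAssignment] | None = None,
) -> tuple[list[SpectrumRecord], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic dataset: ``(spectra, meta, concentrations, endpoints)``."""
    config = config or SimulationConfig()
    assignments = assignments or default_assignments()
    meta, conc = simulate_concentrations(config)
    rng = np.random.default_rng(config.seed + 2)
    spectra = [
        render_spectrum(conc.loc[sid], assignments, config,
                        sample_id=sid, animal_id=row["animal_id"],
                        group=row["group"], tissue_weight=row["tissue_weight_g"],
                        rng=rng)
        for sid, row in meta.iterrows()
    ]
    endpoints = simulate_endpoints(meta, config)
    return spectra, meta, conc, endpoints
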