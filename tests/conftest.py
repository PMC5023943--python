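import numpy as np
import pytest

import nmrfib as nf


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study at the default design (11 UUO / 9 sham, cv=0.15)."""
    cfg = nf.SimulationConfig(seed=17)
    spectra, meta, conc, endpoints = nf.simulate_dataset(cfg)
    return {"config": cfg, "spectra": spectra, "meta": meta,
            "concentrations": conc, "endpoints": endpoints}


@pytest.fixture(scope="session")
def bucket_table(default_dataset):
    return nf.build_matrix(default_dataset["spectra"])


@pytest.fixture(scope="session")
def contents(default_dataset):
    return nf.quantify_metabolites(default_dataset["spectra"],
                                   nf.default_assignments())


@pytest.fixture(scope="session")
def reference_tables():
    return nf.load_reference_tables()


@pytest.fixture(scope="session")
def ac_model(bucket_table):
    """UV-scaled OPLS-DA of obstructed (A) vs sham-left (C) buckets."""
    mask = np.isin(bucket_table.groups, ["A", "C"])
    X = bucket_table.values[mask]
    groups = [g for g, m in zip(bucket_table.groups, mask) if m]
    model = nf.fit_oplsda(X, groups, n_ortho=1, scaling="uv", seed=17)
    return {"model": model, "X": X, "groups": groups}


def make_flat_spectrum(value=1.0, sample_id="flat", group="C", weight=1.0,
                       step=0.001, lo=0.70, hi=9.70):
    n = int(round((hi - lo) / step)) + 1
    ppm = lo + step * np.arange(n)
    return nf.SpectrumRecord(sample_id=sample_id, animal_id=sample_id, group=group,
                             tissue_weight=weight, ppm=ppm,
                             intensity=np.full(n, float(value)))
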