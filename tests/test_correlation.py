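"""Correlation reporting: Pearson oracle, stars, concordance, biplot."""

import numpy as np
import pandas as pd
import pytest

import nmrfib as nf
from nmrfib.correlation import (
    biplot_coordinates,
    correlate,
    correlation_matrix,
    sign_concordance,
    stars,
)
from nmrfib.io import ENDPOINTS


def _toy(join_n=12, seed=0, coupled=True):
    """Small A/C dataset with an endpoint equal (or not) to a metabolite."""
    rng = np.random.default_rng(seed)
    animals = [f"u{i}" for i in range(join_n // 2)] + \
              [f"s{i}" for i in range(join_n // 2)]
    groups = ["A"] * (join_n // 2) + ["C"] * (join_n // 2)
    sample_ids = [a + g for a, g in zip(animals, groups)]
    m1 = np.r_[rng.normal(2, 0.2, join_n // 2), rng.normal(1, 0.2, join_n // 2)]
    contents = pd.DataFrame({"m1": m1, "m2": rng.normal(size=join_n)},
                            index=sample_ids)
    meta = pd.DataFrame({"animal_id": animals, "group": groups},
                        index=contents.index)
    ep = pd.DataFrame({"animal_id": animals,
                       "group_arm": ["UUO"] * (join_n // 2) + ["SO"] * (join_n // 2),
                       "Scr": m1 if coupled else rng.normal(50, 1, join_n),
                       "BUN": rng.normal(8, 1, join_n),
                       "ALB": rng.normal(35, 1, join_n),
                       "TIS": np.clip(rng.normal(1, 0.3, join_n), 0, 3),
                       "ICD": np.clip(rng.normal(20, 5, join_n), 0, 100)})
    return contents, ep, meta


def test_endpoint_equal_to_metabolite_is_perfect():
    contents, ep, meta = _toy()
    table = correlate(contents, ep, meta, join="left")
    cell = table[(table.metabolite == "m1") & (table.endpoint == "Scr")].iloc[0]
    assert cell["r"] == pytest.approx(1.0, abs=1e-12)
    assert cell["stars"] == "***"


def test_independent_endpoint_uncorrelated():
    rng = np.random.default_rng(1)
    n = 200
    animals = [f"u{i}" for i in range(n)]
    contents = pd.DataFrame({"m": rng.normal(size=n)},
                            index=[a + "A" for a in animals])
    meta = pd.DataFrame({"animal_id": animals, "group": ["A"] * n},
                        index=contents.index)
    ep = pd.DataFrame({"animal_id": animals, "group_arm": ["UUO"] * n,
                       "Scr": rng.normal(size=n), "BUN": rng.normal(size=n),
                       "ALB": rng.normal(size=n),
                       "TIS": np.clip(rng.normal(1.5, 0.4, n), 0, 3),
                       "ICD": np.clip(rng.normal(20, 5, n), 0, 100)})
    table = correlate(contents, ep, meta, join="left")
    assert (table["r"].abs() < 0.2).all()
    assert (table["stars"] != "***").all()


def test_pearson_matches_closed_form():
    """Oracle: r and the t-transform p computed from first principles."""
    from scipy import stats as ss

    contents, ep, meta = _toy(seed=3, coupled=False)
    table = correlate(contents, ep, meta, join="left")
    joined = meta["animal_id"]
    for _, cell in table.iterrows():
        x = contents.loc[:, cell.metabolite].to_numpy()
        y = ep.set_index("animal_id").loc[joined, cell.endpoint].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        n = len(x)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * ss.t.sf(abs(t), n - 2)
        assert cell["r"] == pytest.approx(r, abs=1e-12)
        assert cell["p"] == pytest.approx(p, abs=1e-12)


def test_affine_endpoint_rescaling_invariance():
    contents, ep, meta = _toy(seed=4)
    base = correlate(contents, ep, meta, join="left")
    ep2 = ep.assign(BUN=3.5 * ep["BUN"] + 10)
    rescaled = correlate(contents, ep2, meta, join="left")
    pd.testing.assert_series_equal(base["r"], rescaled["r"], atol=1e-12)


def test_zero_variance_endpoint_flagged():
    contents, ep, meta = _toy(seed=5)
    ep = ep.assign(BUN=7.0)
    table = correlate(contents, ep, meta, join="left")
    bun = table[table.endpoint == "BUN"]
    assert bun["undefined"].all()
    assert (bun["stars"] == "").all()


def test_too_few_joined_observations():
    contents, ep, meta = _toy(join_n=4)
    with pytest.raises(ValueError, match="at least 4"):
        correlate(contents.iloc[:3], ep, meta, join="left")


@pytest.mark.parametrize("p,expected", [
    (0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"),
    (0.03, "*"), (0.05, ""), (0.5, ""),
])
def test_star_boundaries_fall_to_weaker_category(p, expected):
    assert stars(p) == expected


def test_sign_concordance_self_and_negation(reference_tables):
    _, t2 = reference_tables
    assert sign_concordance(t2, t2) == 1.0
    assert sign_concordance(-t2, t2) == 0.0
    with pytest.raises(ValueError, match="grid"):
        sign_concordance(t2.iloc[:5], t2)


def test_default_synthetic_concordance(default_dataset, contents,
                                       reference_tables):
    """The severity-coupled generator reproduces at least 90% of the
    reference correlation signs (phenylalanine's row is the known outlier)."""
    _, t2 = reference_tables
    table = correlate(contents, default_dataset["endpoints"],
                      default_dataset["meta"], join="left")
    concord = sign_concordance(correlation_matrix(table), t2)
    assert concord >= 0.9


def test_both_kidney_join_mode(default_dataset, contents):
    table = correlate(contents, default_dataset["endpoints"],
                      default_dataset["meta"], join="both")
    # both kidneys of every animal join: 40 samples x 14 x 5 cells
    assert len(table) == 14 * 5
    assert not table["undefined"].any()


def test_biplot_endpoint_duplicated_as_x_column():
    """An endpoint smuggled into X must load collinearly with its Y twin."""
    contents, ep, meta = _toy(join_n=16, seed=6)
    contents = contents.assign(scr_copy=ep.set_index("animal_id")
                               .loc[meta["animal_id"], "Scr"].to_numpy())
    coords = biplot_coordinates(contents, ep, meta, join="left")
    x = coords["metabolites"].loc["scr_copy"].to_numpy()
    y = coords["endpoints"].loc["Scr"].to_numpy()
    cos = abs(x @ y) / (np.linalg.norm(x) * np.linalg.norm(y))
    assert cos > 0.99


def test_biplot_deterministic(default_dataset, contents):
    a = biplot_coordinates(contents, default_dataset["endpoints"],
                           default_dataset["meta"])
    b = biplot_coordinates(contents, default_dataset["endpoints"],
                           default_dataset["meta"])
    for key in ("samples", "metabolites", "endpoints"):
        pd.testing.assert_frame_equal(a[key], b[key])
    assert list(a["endpoints"].index) == list(ENDPOINTS)


def test_biplot_orthogonal_blocks_give_small_y_loadings():
    rng = np.random.default_rng(7)
    n = 400
    animals = [f"u{i}" for i in range(n)]
    contents = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"),
                            index=[a + "A" for a in animals])
    meta = pd.DataFrame({"animal_id": animals, "group": ["A"] * n},
                        index=contents.index)
    ep = pd.DataFrame({"animal_id": animals, "group_arm": ["UUO"] * n,
                       "Scr": rng.normal(size=n), "BUN": rng.normal(size=n),
                       "ALB": rng.normal(size=n),
                       "TIS": np.clip(rng.normal(1.5, 0.4, n), 0, 3),
                       "ICD": np.clip(rng.normal(20, 5, n), 0, 100)})
    coords = biplot_coordinates(contents, ep, meta, join="left")
    x_norm = np.linalg.norm(coords["metabolites"].to_numpy())
    y_norm = np.linalg.norm(coords["endpoints"].to_numpy())
    assert y_norm < 0.35 * x_norm
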