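"""Lipid composition, unsaturation indices, outlier screen, group tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chillrhythm import lipidomics
from chillrhythm.errors import (DegenerateSampleError, FormatError,
                                ValidationError)

FA_POOL = ["16:0", "16:1", "16:2", "16:3", "18:0", "18:1", "18:2", "18:3"]


def lipid_rows(sample, entries):
    return [{"sample_id": sample, "species": "sorghum", "condition": "control",
             "time_h": 0.0, "replicate": 1, "lipid_class": cls,
             "fatty_acid": fa, "amount": amt}
            for cls, fa, amt in entries]


@pytest.mark.parametrize("pool,expected", [
    ({"18:3": 100.0}, 3.0),
    ({"16:0": 100.0}, 0.0),
    ({"18:1": 50.0, "18:2": 50.0}, 1.5),
])
def test_dbi_closed_forms(pool, expected):
    assert lipidomics.compute_dbi(pool) == pytest.approx(expected, abs=1e-12)


def test_dbi_validates_inputs():
    with pytest.raises(ValidationError):
        lipidomics.compute_dbi({"18:3": 50.0})          # does not sum to 100
    with pytest.raises(ValidationError):
        lipidomics.compute_dbi({"20:1": 100.0})         # not a 16/18 carbon
    with pytest.raises(FormatError):
        lipidomics.compute_dbi({"banana": 100.0})


def test_unsaturation_index_examples():
    assert lipidomics.unsaturation_index({"18:0": 1, "18:2": 1}) == 1.0
    assert lipidomics.unsaturation_index({"18:1": 7.3}) == 1.0
    with pytest.raises(DegenerateSampleError):
        lipidomics.unsaturation_index({})


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=1,
                max_size=8))
def test_unsaturation_equals_dbi_on_restricted_pool(amounts):
    """On 16:n/18:n pools with n <= 3 the two indices are the same number."""
    labels = FA_POOL[:len(amounts)]
    total = sum(amounts)
    pcts = {la: 100.0 * a / total for la, a in zip(labels, amounts)}
    dbi = lipidomics.compute_dbi(pcts)
    ui = lipidomics.unsaturation_index(dict(zip(labels, amounts)))
    assert dbi == pytest.approx(ui, abs=1e-12)


def test_mole_percent_single_class_is_100():
    df = pd.DataFrame(lipid_rows("s1", [("MGDG", "18:3", 5.0)]))
    comp = lipidomics.mole_percent(df)
    assert comp.class_mole_percent.iloc[0]["MGDG"] == pytest.approx(100.0)


def test_mole_percent_three_to_one_split():
    df = pd.DataFrame(lipid_rows("s1", [("MGDG", "18:3", 3.0),
                                        ("DGDG", "18:3", 1.0)]))
    comp = lipidomics.mole_percent(df)
    row = comp.class_mole_percent.iloc[0]
    assert row["MGDG"] == pytest.approx(75.0)
    assert row["DGDG"] == pytest.approx(25.0)


def test_mole_percent_scale_invariance(rng):
    entries = [(cls, fa, rng.uniform(0.1, 5))
               for cls in ("MGDG", "PC", "TAG") for fa in ("16:0", "18:2")]
    base = pd.DataFrame(lipid_rows("s1", entries))
    scaled = base.assign(amount=base["amount"] * 37.5)
    a = lipidomics.mole_percent(base)
    b = lipidomics.mole_percent(scaled)
    pd.testing.assert_frame_equal(a.class_mole_percent, b.class_mole_percent)
    pd.testing.assert_frame_equal(a.fa_mole_percent, b.fa_mole_percent)


def test_mole_percent_rejects_all_zero_sample():
    df = pd.DataFrame(lipid_rows("dead", [("MGDG", "18:3", 0.0)]))
    with pytest.raises(DegenerateSampleError, match="dead"):
        lipidomics.mole_percent(df)


# --- outlier screen ---------------------------------------------------------

def test_iqr_window_hand_example():
    """{1,2,3,4,100}: median 3, IQR 2, window [1,5] drops only the 100."""
    v = np.array([1.0, 2, 3, 4, 100])
    keep = lipidomics.iqr_mask(v, 1.0)
    assert list(v[keep]) == [1, 2, 3, 4]


def test_screen_keeps_equal_values_and_symmetric_data():
    assert lipidomics.screen_outliers(np.full(6, 2.5)).all()
    assert lipidomics.screen_outliers(np.array([1.0, 2, 3, 4, 5])).all()


def test_screen_small_stratum_passthrough(caplog):
    keep = lipidomics.screen_outliers(np.array([1.0, 99.0]))
    assert keep.all()


def test_screen_idempotent_after_first_pass():
    v = np.array([1.0, 2, 3, 4, 100])
    keep = lipidomics.screen_outliers(v)
    again = lipidomics.screen_outliers(v[keep])
    assert again.all()


# --- group comparisons ------------------------------------------------------

def _two_group_frame(mean_a, mean_b, sd, n, rng):
    rows = []
    for g, mu in (("a", mean_a), ("b", mean_b)):
        for i in range(n):
            rows.append({"group": g, "replicate": i + 1,
                         "value": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("method", ["lsd", "tukey", "mixed_tukey"])
def test_strong_separation_all_methods(method, rng):
    df = _two_group_frame(0.0, 10.0, 0.01, 4, rng)
    res = lipidomics.compare_groups(df, method=method)
    assert (res["p"] < 1e-6).all()
    assert res["significant"].all()


def test_identical_groups_zero_noise_not_flagged():
    df = pd.DataFrame({"group": list("aabb"), "replicate": [1, 2, 1, 2],
                       "value": [3.0, 3.0, 3.0, 3.0]})
    res = lipidomics.compare_groups(df, method="lsd")
    assert (res["p"] == 1.0).all()
    assert not res["significant"].any()


def test_tukey_never_more_liberal_than_lsd(rng):
    """Studentized-range adjustment dominates the unadjusted pairwise t."""
    for _ in range(25):
        rows = []
        for g in "abc":
            for i in range(4):
                rows.append({"group": g, "replicate": i + 1,
                             "value": rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        lsd = lipidomics.compare_groups(df, method="lsd")
        tukey = lipidomics.compare_groups(df, method="tukey")
        assert np.all(tukey["p"].to_numpy() >= lsd["p"].to_numpy() - 1e-12)


def test_planted_species_effect_detected_with_power(rng):
    """At effect 3 sd 1 n 4 the planted contrast is flagged >= 80% of runs."""
    hits = 0
    for _ in range(100):
        df = _two_group_frame(0.0, 3.0, 1.0, 4, rng)
        res = lipidomics.compare_groups(df, method="lsd")
        hits += int(res["significant"].iloc[0])
    assert hits >= 80
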