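"""Library-composition metrics: rRNA percent, RPM, detection, correlation."""

import numpy as np
import pandas as pd
import pytest

from ribopanel.metrics import (
    GeneCountTable,
    detection_curve,
    expression_filter,
    library_correlation,
    organism_partition,
    rpm,
    rrna_percent,
)


def _table(counts: dict[str, list[int]], rrna=None, organism=None) -> GeneCountTable:
    genes = [f"g{i}" for i in range(len(next(iter(counts.values()))))]
    df = pd.DataFrame(counts, index=genes)
    df["organism"] = organism if organism is not None else "bact"
    df["is_rrna"] = rrna if rrna is not None else False
    return GeneCountTable(df)


# ---------------------------------------------------------------- rRNA percent

def test_rrna_percent_basic_and_zero():
    t = _table({"s": [800, 150, 50]}, rrna=[True, False, False])
    assert rrna_percent(t, "s") == pytest.approx(80.0)
    t0 = _table({"s": [0, 150, 50]}, rrna=[True, False, False])
    assert rrna_percent(t0, "s") == 0.0


def test_rrna_percent_mixed_table_matches_hand_sum():
    t = _table(
        {"s": [120, 30, 200, 50, 600]},
        rrna=[True, False, True, False, False],
        organism=["bact"] * 5,
    )
    assert rrna_percent(t, "s") == pytest.approx(100 * 320 / 1000)


def test_rrna_percent_restricted_to_one_organism():
    t = _table(
        {"s": [90, 10, 400]},
        rrna=[True, False, False],
        organism=["bact", "bact", "fungus"],
    )
    assert rrna_percent(t, "s", organism="bact") == pytest.approx(90.0)


def test_rrna_percent_rejects_empty_library():
    with pytest.raises(ValueError):
        rrna_percent(_table({"s": [0, 0]}), "s")


# ---------------------------------------------------------------- organism split

def test_organism_partition_sums_to_100():
    t = _table({"s": [60, 40]}, organism=["bact", "fungus"])
    parts = organism_partition(t, "s")
    assert parts == {"bact": 60.0, "fungus": 40.0}
    t3 = _table({"s": [10, 30, 60]}, organism=["a", "b", "c"])
    parts = organism_partition(t3, "s")
    assert parts == {"a": 1.0, "b": 3.0, "c": 6.0} or sum(parts.values()) == pytest.approx(100.0)
    assert parts["a"] == pytest.approx(10.0)


def test_single_organism_is_100_percent():
    parts = organism_partition(_table({"s": [5, 5]}), "s")
    assert parts == {"bact": 100.0}


def test_untagged_gene_rejected():
    t = _table({"s": [5, 5]}, organism=["bact", None])
    with pytest.raises(ValueError, match="organism"):
        organism_partition(t, "s")


# ---------------------------------------------------------------- RPM

def test_rpm_excludes_rrna_from_numerator_and_denominator():
    t = _table(
        {"s": [1_000_000, 10, 1_999_990]}, rrna=[True, False, False]
    )
    values = rpm(t)
    assert "g0" not in values.index
    assert values.loc["g1", "s"] == pytest.approx(5.0)


def test_rpm_zero_gene_and_conservation():
    t = _table({"s": [0, 250, 750]}, rrna=[False, False, False])
    values = rpm(t)
    assert values.loc["g0", "s"] == 0.0
    assert values["s"].sum() == pytest.approx(1e6)


def test_rpm_rejects_all_rrna_sample():
    t = _table({"s": [100, 0]}, rrna=[True, False])
    with pytest.raises(ValueError):
        rpm(t)


# ---------------------------------------------------------------- detection curves

def test_detection_curve_hand_counted():
    t = _table({"s": [5, 0, 100]})
    assert detection_curve(t, "s", [1, 10]) == [2, 1]
    assert detection_curve(t, "s", [1000]) == [0]


def test_detection_curve_downsample_noop_when_large():
    t = _table({"s": [5, 0, 100]})
    assert detection_curve(t, "s", [1, 10], downsample_to=10_000) == [2, 1]


def test_detection_curve_monotone_under_downsampling():
    rng = np.random.default_rng(0)
    t = _table({"s": list(rng.integers(0, 500, 50))})
    thresholds = [1, 5, 10, 50, 100]
    counts = detection_curve(t, "s", thresholds, downsample_to=2000, seed=3)
    assert counts == sorted(counts, reverse=True)
    # determinism under the same seed
    assert counts == detection_curve(t, "s", thresholds, downsample_to=2000, seed=3)


def test_detection_curve_validates_thresholds():
    t = _table({"s": [5]})
    with pytest.raises(ValueError):
        detection_curve(t, "s", [])
    with pytest.raises(ValueError):
        detection_curve(t, "s", [10, 1])


# ---------------------------------------------------------------- expression filter

def test_expression_filter_boundary_is_inclusive():
    # one gene at exactly 2 RPM in both samples
    t = _table({"a": [2, 999_998], "b": [2, 999_998]})
    kept = expression_filter(t, min_rpm=2.0)
    assert "g0" in kept
    assert expression_filter(t, min_rpm=2.0, strict=True) == ["g1"]


def test_expression_filter_requires_all_samples():
    t = _table({"a": [50, 100], "b": [0, 100]})
    assert expression_filter(t, min_rpm=2.0) == ["g1"]


def test_expression_filter_matches_manual_five_gene_table():
    t = _table({"a": [10, 0, 5, 500, 485], "b": [10, 2, 0, 500, 488]})
    rpm_a = rpm(t)["a"]
    expected = [
        g for g in rpm_a.index
        if rpm(t).loc[g, "a"] >= 2.0 and rpm(t).loc[g, "b"] >= 2.0
    ]
    assert expression_filter(t, min_rpm=2.0) == expected


# ---------------------------------------------------------------- correlation

def test_correlation_of_sample_with_itself_is_one():
    rng = np.random.default_rng(1)
    counts = list(rng.integers(0, 1000, 20))
    t = _table({"a": counts, "b": counts})
    assert library_correlation(t, "a", "b") == pytest.approx(1.0)


def test_correlation_scale_invariance_in_linear_rpm():
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 1000, 20)
    t = _table({"a": list(counts), "b": list(2 * counts)})
    assert library_correlation(t, "a", "b", log_transform=False) == pytest.approx(1.0)


def test_correlation_matches_closed_form_pearson():
    t = _table({"a": [10, 20, 5, 80, 40, 1, 7, 300, 65, 12],
                "b": [12, 18, 9, 70, 50, 2, 5, 280, 80, 14]})
    values = rpm(t)
    x = np.log10(values["a"].to_numpy() + 1)
    y = np.log10(values["b"].to_numpy() + 1)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
        n * (y**2).sum() - y.sum() ** 2
    )
    assert library_correlation(t, "a", "b") == pytest.approx(num / den, rel=1e-12)


def test_correlation_rejects_degenerate_input():
    t = _table({"a": [10, 10, 10], "b": [1, 2, 3]})
    with pytest.raises(ValueError):
        library_correlation(t, "a", "b", log_transform=False)


def test_table_validation():
    df = pd.DataFrame({"s": [1, 2]}, index=["g", "g"])
    df["organism"] = "b"
    df["is_rrna"] = False
    with pytest.raises(ValueError, match="unique"):
        GeneCountTable(df)
    df2 = pd.DataFrame({"s": [-1]}, index=["g"])
    df2["organism"] = "b"
    df2["is_rrna"] = False
    with pytest.raises(ValueError, match="non-negative"):
        GeneCountTable(df2)
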