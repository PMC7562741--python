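"""Connectivity filtering, direction consistency, target summaries."""

import numpy as np
import pandas as pd
import pytest

from synopipe.connectivity import (
    check_direction_consistency,
    filter_connectivity,
    format_target_table,
    rank_regulators,
    round_half_even,
    summarize_targets,
)


def rows(*specs):
    return pd.DataFrame(
        [dict(zip(("perturbagen", "type", "score", "target", "moa_direction"), s))
         for s in specs]
    )


def test_range_boundaries_inclusive():
    table = rows(
        ("a", "compound", -75.0, "T", "antagonist"),
        ("b", "compound", -74.9, "T", "antagonist"),
        ("c", "compound", -100.0, "T", "antagonist"),
    )
    kept = filter_connectivity(table)
    assert set(kept["perturbagen"]) == {"a", "c"}


def test_mixed_types_follow_their_own_ranges():
    table = rows(
        ("oe", "OE", 50.0, "T1", None),
        ("kd", "KD", -80.0, "T2", None),
        ("cp", "compound", -90.0, "T3", "agonist"),
        ("oe-low", "OE", 49.9, "T1", None),
        ("kd-out", "KD", -60.0, "T2", None),
    )
    kept = filter_connectivity(table)
    assert set(kept["perturbagen"]) == {"oe", "kd", "cp"}
    # brute-force range check agrees
    ranges = {"compound": (-100, -75), "KD": (-100, -75), "OE": (50, 100)}
    for _, r in table.iterrows():
        lo, hi = ranges[r["type"]]
        assert (r["perturbagen"] in set(kept["perturbagen"])) == (lo <= r["score"] <= hi)


def test_unknown_type_rejected():
    with pytest.raises(ValueError, match="unknown perturbation"):
        filter_connectivity(rows(("x", "shRNA", -80.0, "T", None)))


def test_score_out_of_range_rejected():
    with pytest.raises(ValueError, match="\\[-100, 100\\]"):
        filter_connectivity(rows(("x", "compound", -101.0, "T", None)))


def test_direction_consistency_rules():
    table = rows(
        ("ag", "compound", -90.0, "SameSide", "agonist"),
        ("an", "compound", -85.0, "SameSide", "antagonist"),
        ("ag2", "compound", -90.0, "Opposite", "agonist"),
        ("an2", "OE", 60.0, "Opposite", "antagonist"),
        ("only", "compound", -80.0, "OneDirection", "antagonist"),
    )
    res = check_direction_consistency(table).set_index("target")
    assert res.loc["SameSide", "passed"] == False  # noqa: E712
    assert res.loc["Opposite", "passed"] == True   # noqa: E712
    assert res.loc["OneDirection", "passed"] == True  # noqa: E712
    assert "vacuous" in res.loc["OneDirection", "note"]


@pytest.mark.parametrize(
    "scores,mean,sem",
    [
        ((-88.16, -93.36), -90.76, 2.60),   # cholinesterase group
        ((-88.13, -91.07), -89.60, 1.47),   # mTOR complex group
        ((-83.38, -97.26), -90.32, 6.94),   # VEGFR group
        ((-84.70, -88.90), -86.80, 2.10),   # pan-PI3K group
    ],
)
def test_two_compound_summary_reproduces_printed_mean_sem(scores, mean, sem):
    table = rows(
        ("c1", "compound", scores[0], "T", "antagonist"),
        ("c2", "compound", scores[1], "T", "antagonist"),
    )
    s = summarize_targets(filter_connectivity(table))[0]
    assert round_half_even(s.mean) == mean
    assert round_half_even(s.sem) == sem
    assert (s.score_min, s.score_max) == (min(scores), max(scores))
    assert s.top_compound == ("c1" if scores[0] < scores[1] else "c2")


def test_sem_identity_for_two_compounds(rng):
    for _ in range(25):
        x1, x2 = rng.uniform(-100, -75, 2)
        table = rows(("a", "compound", x1, "T", None), ("b", "compound", x2, "T", None))
        s = summarize_targets(filter_connectivity(table),
                              require_direction_consistency=False)[0]
        assert s.sem == pytest.approx(abs(x1 - x2) / 2.0, rel=1e-12)
        assert s.score_min <= s.mean <= s.score_max


def test_single_compound_target_excluded_and_row_order_invariance(rng):
    base = rows(
        ("a", "compound", -90.0, "T1", "antagonist"),
        ("b", "compound", -80.0, "T1", "antagonist"),
        ("c", "compound", -85.0, "T2", "antagonist"),
    )
    shuffled = base.sample(frac=1.0, random_state=1).reset_index(drop=True)
    s1 = summarize_targets(filter_connectivity(base))
    s2 = summarize_targets(filter_connectivity(shuffled))
    assert [x.target for x in s1] == ["T1"]
    assert [(x.target, x.mean, x.sem) for x in s1] == [
        (x.target, x.mean, x.sem) for x in s2
    ]


def test_summaries_sorted_by_ascending_mean():
    table = rows(
        ("a", "compound", -95.0, "Strong", None),
        ("b", "compound", -90.0, "Strong", None),
        ("c", "compound", -80.0, "Weak", None),
        ("d", "compound", -78.0, "Weak", None),
    )
    s = summarize_targets(filter_connectivity(table),
                          require_direction_consistency=False)
    assert [x.target for x in s] == ["Strong", "Weak"]
    assert s[0].mean <= s[1].mean


def test_empty_input_gives_empty_summary():
    assert summarize_targets(pd.DataFrame(
        columns=["perturbagen", "type", "score", "target", "moa_direction"])) == []


def test_format_table_rounding_half_even():
    assert round_half_even(2.675) == 2.68 or round_half_even(2.675) == 2.67
    assert round_half_even(-90.755) == -90.76
    assert round_half_even(1.285) == 1.28  # ties to even
    table = rows(
        ("c1", "compound", -88.16, "T", None),
        ("c2", "compound", -93.36, "T", None),
    )
    out = format_target_table(
        summarize_targets(filter_connectivity(table),
                          require_direction_consistency=False)
    )
    assert out.loc[0, "mean"] == -90.76
    assert out.loc[0, "sem"] == 2.60
    assert out.loc[0, "range"] == "(-88.16)–(-93.36)"


def test_rank_regulators_matches_sort_oracle(rng):
    recs = []
    for i in range(60):
        if i % 2:
            recs.append((f"kd{i}", "KD", float(np.round(rng.uniform(-100, -75), 2)),
                         f"R{i}", None))
        else:
            recs.append((f"oe{i}", "OE", float(np.round(rng.uniform(50, 100), 2)),
                         f"R{i}", None))
    table = rows(*recs)
    ranked = rank_regulators(filter_connectivity(table), top_n=50)
    assert len(ranked) == 50
    oracle = sorted(recs, key=lambda r: (-abs(r[2]), r[3], r[1], r[0]))[:50]
    assert list(ranked["perturbagen"]) == [r[0] for r in oracle]


def test_same_gene_kd_and_oe_kept_separately():
    table = rows(("kd-x", "KD", -80.0, "GENE", None), ("oe-x", "OE", 60.0, "GENE", None))
    ranked = rank_regulators(filter_connectivity(table))
    assert len(ranked) == 2
    assert set(ranked["type"]) == {"KD", "OE"}


def test_rank_regulators_empty_input():
    assert rank_regulators(pd.DataFrame(
        columns=["perturbagen", "type", "score", "target", "moa_direction"])).empty


def test_filtering_idempotent():
    table = rows(
        ("a", "compound", -80.0, "T", None),
        ("b", "compound", -50.0, "T", None),
        ("c", "OE", 70.0, "U", None),
    )
    once = filter_connectivity(table)
    twice = filter_connectivity(once)
    pd.testing.assert_frame_equal(once, twice)
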