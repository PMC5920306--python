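import numpy as np
import pytest

from florphen.curation import CuratedAlignment
from florphen.errors import (CalibrationImpossibleError,
                             DivisionByZeroScoreError, GroupTooSmallError)
from florphen.scoring import (FunctionScoreModel, RatioScore,
                              build_prevalence_profile, calibrate_cutoff,
                              classify, compute_ratio, direction_labels,
                              group_mean_ratios, score_sequence)
from florphen.simulate import FamilySimParams, simulate_protein_family

from _oracles import (grid_search_cutoff, mean_score_by_hand,
                      prevalence_by_counting)
from conftest import make_curated


def test_prevalence_profile_trivial_columns():
    cur = make_curated({"a": "AA", "b": "AC", "q": "AA"},
                       {"a": "activator", "b": "activator", "q": "unknown"})
    prof = build_prevalence_profile(cur, "FT", {"activator"})
    assert prof.table[0] == {"A": 1.0}
    assert prof.table[1] == {"A": 0.5, "C": 0.5}


def test_prevalence_profile_matches_counting_oracle():
    rows = {"m1": "AYKCW-", "m2": "AYKXWD", "m3": "CYHAW-", "m4": "AYKAWD"}
    cur = make_curated({**rows, "q": "AYKAWD"},
                       {**{k: "repressor" for k in rows}, "q": "unknown"})
    prof = build_prevalence_profile(cur, "FT", {"repressor"})
    assert prof.table == prevalence_by_counting(list(rows.values()))


def test_profile_excludes_unknown_and_other_clades():
    cur = make_curated(
        {"a": "AA", "b": "AA", "u": "CC", "t": "GG"},
        {"a": "activator", "b": "activator", "u": "unknown", "t": "activator"},
        clade="FT")
    cur.base.clades["t"] = "TFL1"
    prof = build_prevalence_profile(cur, "FT", {"activator"})
    assert prof.member_ids == ["a", "b"]
    with pytest.raises(GroupTooSmallError):
        build_prevalence_profile(cur, "TFL1", {"activator"})


def test_score_extremes_and_hand_mean():
    members = {"m1": "AYKCWD", "m2": "AYKCWD"}
    cur = make_curated({**members, "same": "AYKCWD", "diff": "CWADEE"},
                       {**{k: "neutral" for k in members},
                        "same": "unknown", "diff": "unknown"})
    prof = build_prevalence_profile(cur, "FT", {"neutral"})
    assert score_sequence("same", cur, prof)[0] == pytest.approx(1.0)
    assert score_sequence("diff", cur, prof)[0] == pytest.approx(0.0)

    rows = {"m1": "AYKCW-", "m2": "AYCXWD", "m3": "CYHAW-", "m4": "AYKAWD"}
    cur2 = make_curated({**rows, "q": "AYHCXD"},
                        {**{k: "neutral" for k in rows}, "q": "unknown"})
    prof2 = build_prevalence_profile(cur2, "FT", {"neutral"})
    expected = mean_score_by_hand("AYHCXD",
                                  prevalence_by_counting(list(rows.values())))
    score, n_used = score_sequence("q", cur2, prof2)
    assert score == pytest.approx(expected)
    assert n_used == 5  # the 'X' column of the query is excluded


def test_identical_profiles_give_ratio_one():
    rows = {"a1": "AYKC", "a2": "AYCD", "q": "AYKD"}
    cur = make_curated(rows, {"a1": "neutral", "a2": "neutral", "q": "unknown"})
    prof = build_prevalence_profile(cur, "FT", {"neutral"})
    rs = compute_ratio("q", cur, prof, prof)
    assert rs.ratio == pytest.approx(1.0)


def test_ratio_division_by_zero():
    cur = make_curated({"a1": "AA", "a2": "AA", "b1": "CC", "b2": "CC",
                        "q": "CC"},
                       {"a1": "activator", "a2": "activator",
                        "b1": "repressor", "b2": "repressor", "q": "unknown"})
    in_p = build_prevalence_profile(cur, "FT", {"repressor"})
    out_p = build_prevalence_profile(cur, "FT", {"activator"})
    with pytest.raises(DivisionByZeroScoreError):
        compute_ratio("q", cur, in_p, out_p)  # q shares nothing with activators


def test_leave_one_out_excludes_self():
    # three activators; with LOO the member's own row must not inflate in-score
    cur = make_curated({"a1": "YA", "a2": "YA", "a3": "WA",
                        "r1": "HA", "r2": "HA"},
                       {"a1": "activator", "a2": "activator",
                        "a3": "activator", "r1": "repressor",
                        "r2": "repressor"})
    in_p = build_prevalence_profile(cur, "FT", {"activator"})
    out_p = build_prevalence_profile(cur, "FT", {"repressor"})
    rs_loo = compute_ratio("a3", cur, in_p, out_p, leave_one_out=True)
    # a3's W occurs in no *other* activator: (0 + 1) / 2 columns
    assert rs_loo.in_score == pytest.approx(0.5)
    rs_self = compute_ratio("a3", cur, in_p, out_p, leave_one_out=False)
    assert rs_self.in_score == pytest.approx((1 / 3 + 1) / 2)


def test_ratio_invariant_under_member_duplication():
    rows = {"a1": "AYK", "a2": "AYC", "r1": "HWC", "r2": "HWK", "q": "AYK"}
    labels = {"a1": "activator", "a2": "activator", "r1": "repressor",
              "r2": "repressor", "q": "unknown"}
    cur = make_curated(rows, labels)
    dup_rows = dict(rows)
    dup_labels = dict(labels)
    for k in ("a1", "a2", "r1", "r2"):
        dup_rows[k + "_copy"] = rows[k]
        dup_labels[k + "_copy"] = labels[k]
    cur_dup = make_curated(dup_rows, dup_labels)
    rs = compute_ratio("q", cur,
                       build_prevalence_profile(cur, "FT", {"activator"}),
                       build_prevalence_profile(cur, "FT", {"repressor"}))
    rs_dup = compute_ratio("q", cur_dup,
                           build_prevalence_profile(cur_dup, "FT", {"activator"}),
                           build_prevalence_profile(cur_dup, "FT", {"repressor"}))
    assert rs_dup.ratio == pytest.approx(rs.ratio)


def test_scores_lie_in_unit_interval_on_synthetic_family():
    aln, _ = simulate_protein_family(FamilySimParams(seed=21))
    cur = CuratedAlignment.identity(aln)
    _, _, _, ratios = group_mean_ratios(cur, "FT", "activator")
    for rs in ratios.values():
        assert 0.0 <= rs.in_score <= 1.0
        assert 0.0 <= rs.out_score <= 1.0
        assert rs.ratio > 0


def test_calibrate_cutoff_examples_and_oracle():
    assert calibrate_cutoff([(0.9, True), (1.0, True),
                             (0.5, False), (0.6, False)]) == pytest.approx(0.61)
    rng = np.random.default_rng(13)
    for _ in range(50):
        members = list(rng.uniform(0.8, 1.4, rng.integers(2, 10)))
        nonmembers = list(rng.uniform(0.5, 1.1, rng.integers(2, 10)))
        if max(members) < min(nonmembers):
            continue
        labeled = [(r, True) for r in members] + [(r, False) for r in nonmembers]
        cut = calibrate_cutoff(labeled)
        assert cut == pytest.approx(grid_search_cutoff(labeled))
        # zero false member calls by construction
        assert all(r < cut for r in nonmembers)


def test_calibrate_separated_classes_classify_perfectly():
    labeled = [(1.2, True), (1.1, True), (0.9, False), (0.8, False)]
    cut = calibrate_cutoff(labeled)
    for r, is_member in labeled:
        assert (r >= cut) == is_member


def test_calibration_impossible():
    with pytest.raises(CalibrationImpossibleError):
        calibrate_cutoff([(0.5, True), (0.9, False)])


def test_classify_boundary_convention():
    rs = RatioScore("AaFTL2", "TFL1", "repressor", 0.09, 0.0909, 0.99, 132)
    assert classify(rs, 0.98).call == "member"
    rs_eq = RatioScore("x", "TFL1", "repressor", 0.1, 0.1, 0.98, 132)
    assert classify(rs_eq, 0.98).call == "member"
    rs_below = RatioScore("x", "TFL1", "repressor", 0.1, 0.1, 0.97, 132)
    assert classify(rs_below, 0.98).call == "non-member"


def test_direction_labels():
    assert direction_labels("activator") == ({"activator"},
                                             {"repressor", "neutral"})
    with pytest.raises(ValueError):
        direction_labels("neutral")


def test_group_means_separate_with_planted_signal():
    aln, _ = simulate_protein_family(FamilySimParams(seed=3))
    cur = CuratedAlignment.identity(aln)
    m_mean, n_mean, test, _ = group_mean_ratios(cur, "FT", "activator")
    assert m_mean > n_mean
    assert test.p_value < 0.001


def test_no_signal_drives_mean_ratios_to_one():
    # averaged over seeds so Monte-Carlo noise (sd ~0.014 per class mean at
    # n=40) is small against the 0.02 band around the signal-free limit of 1
    m_means, n_means = [], []
    for seed in range(5):
        params = FamilySimParams(seed=seed, n_per_group={"activator": 40,
                                                         "repressor": 40},
                                 n_signal_columns=0)
        aln, _ = simulate_protein_family(params)
        cur = CuratedAlignment.identity(aln)
        m_mean, n_mean, _, _ = group_mean_ratios(cur, "FT", "activator")
        m_means.append(m_mean)
        n_means.append(n_mean)
    assert abs(np.mean(m_means) - 1.0) < 0.02
    assert abs(np.mean(n_means) - 1.0) < 0.02


def test_model_results_summary_and_query_classification():
    aln, _ = simulate_protein_family(
        FamilySimParams(seed=2, n_queries=1, query_group="activator"))
    cur = CuratedAlignment.identity(aln)
    res = FunctionScoreModel(cur, "FT", "activator").fit()
    call = res.classify_query("query_00")
    assert call.call == "member"
    text = res.summary()
    assert "cut-off" in text and "activator" in text.lower()
    assert res.member_mean > res.nonmember_mean
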