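import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from florphen.errors import DataConsistencyError, MissingEventError
from florphen.phenology import (PhenologyRecord, bonferroni_gate,
                                dominance_assessment, mann_whitney_u,
                                phase_lengths, reproductive_output_summary)
from florphen.simulate import PhenoSimParams, simulate_phenology

from _oracles import exact_mw_p_two_sided


def _rec(pid="p1", pop="native", bud=35, pollen=47, pistil=53, **kw):
    return PhenologyRecord(plant_id=pid, population=pop, day_male_bud=bud,
                           day_first_pollen=pollen, day_first_pistil=pistil,
                           **kw)


def test_phase_arithmetic():
    p = phase_lengths(_rec())
    assert (p.veg_male_init, p.male_maturation,
            p.veg_female_maturation, p.dichogamy) == (35, 12, 53, 6)


def test_negative_dichogamy_allowed():
    p = phase_lengths(_rec(pistil=45))
    assert p.dichogamy == -2


def test_missing_event_raises():
    with pytest.raises(MissingEventError):
        phase_lengths(PhenologyRecord(plant_id="x", population="native",
                                      day_male_bud=30))


def test_phase_conservation_on_generated_records():
    records = simulate_phenology(PhenoSimParams(seed=6))
    assert records
    for r in records:
        p = phase_lengths(r)
        assert p.veg_male_init + p.male_maturation + p.dichogamy == \
            p.veg_female_maturation


def test_generated_cohort_recovers_phase_means():
    params = PhenoSimParams(seed=12)
    for pop in params.populations:
        params.populations[pop]["n"] = 200
    records = simulate_phenology(params)
    native = [phase_lengths(r) for r in records if r.population == "native"]
    n = len(native)
    # recovery of the generator's inputs (phase means in days); the female
    # phase follows by additivity of the three components
    for attr, mean, sd in [("veg_male_init", 66.8, 6.0),
                           ("male_maturation", 12.9, 3.0),
                           ("dichogamy", 2.2, 2.0)]:
        vals = [getattr(p, attr) for p in native]
        assert abs(np.mean(vals) - mean) < 3 * sd / np.sqrt(n) + 0.5
    female = [p.veg_female_maturation for p in native]
    assert np.mean(female) == pytest.approx(66.8 + 12.9 + 2.2, abs=1.5)


def test_mann_whitney_exact_example():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "mann-whitney (exact)"


def test_mann_whitney_identical_multisets():
    res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.statistic == pytest.approx(8.0)  # n^2/2
    assert res.p_value >= 0.99


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.data())
def test_mann_whitney_matches_enumeration_for_small_samples(data):
    """Exact p agrees with full enumeration of rank assignments, n <= 5."""
    n_a = data.draw(st.integers(1, 5))
    n_b = data.draw(st.integers(1, 5))
    pool = data.draw(st.permutations(range(20)))
    a = [float(v) for v in pool[:n_a]]
    b = [float(v) for v in pool[n_a:n_a + n_b]]
    res = mann_whitney_u(a, b)
    assert res.p_value == pytest.approx(exact_mw_p_two_sided(a, b))


def test_mann_whitney_null_rejection_rate():
    """Asymptotic-path type-I error sits within 2 Monte-Carlo SE of 5%."""
    rng = np.random.default_rng(0)
    n_sim = 2000
    rejections = sum(
        mann_whitney_u(rng.normal(size=30), rng.normal(size=30)).p_value < 0.05
        for _ in range(n_sim))
    rate = rejections / n_sim
    mc_se = np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rate - 0.05) <= 2 * mc_se


def test_bonferroni_gate_examples():
    # p=1e-4 with m=12: *** needs p < 8.3e-5, so the code stops at **
    assert bonferroni_gate(0.0001, 12) == "**"
    assert bonferroni_gate(0.5, 7) == "ns"
    assert bonferroni_gate(0.04, 1) == "*"
    assert bonferroni_gate(0.0009, 1) == "***"


@settings(deadline=None, derandomize=True, max_examples=40)
@given(p=st.floats(1e-8, 1.0), m1=st.integers(1, 30), m2=st.integers(1, 30))
def test_bonferroni_gate_monotone_in_m(p, m1, m2):
    strength = {"ns": 0, "*": 1, "**": 2, "***": 3}
    lo, hi = sorted([m1, m2])
    assert strength[bonferroni_gate(p, hi)] <= strength[bonferroni_gate(p, lo)]


def test_dominance_identical_samples_inconclusive():
    x = [30.0] * 10 + [31.0] * 10
    call = dominance_assessment(x, list(x), list(x), m=12)
    assert call.verdict == "inconclusive"


def test_dominance_recovers_planted_dominant_early():
    rng = np.random.default_rng(4)
    hits = 0
    for _ in range(20):
        early = list(np.round(rng.normal(35, 6, 30)))
        late = list(np.round(rng.normal(65, 6, 30)))
        f1 = list(np.round(rng.normal(35, 6, 30)))
        if dominance_assessment(early, late, f1, m=12).verdict == "dominant-early":
            hits += 1
    assert hits >= 18


def test_dominance_overdominant_early():
    rng = np.random.default_rng(5)
    early = list(np.round(rng.normal(35, 3, 30)))
    late = list(np.round(rng.normal(65, 3, 30)))
    f1 = list(np.round(rng.normal(20, 3, 30)))
    call = dominance_assessment(early, late, f1, m=12)
    assert call.verdict == "overdominant-early"


def test_dominance_additive():
    rng = np.random.default_rng(6)
    early = list(np.round(rng.normal(30, 3, 40)))
    late = list(np.round(rng.normal(70, 3, 40)))
    f1 = list(np.round(rng.normal(50, 3, 40)))
    assert dominance_assessment(early, late, f1, m=12).verdict == "additive"


def _fruit_records(counts_a, counts_b, weight=5.0):
    recs = []
    for i, c in enumerate(counts_a):
        recs.append(_rec(f"n{i}", "native", n_fruits=int(c),
                         total_fruit_weight_mg=c * weight))
    for i, c in enumerate(counts_b):
        recs.append(_rec(f"i{i}", "invasive", n_fruits=int(c),
                         total_fruit_weight_mg=c * weight))
    return recs


def test_reproductive_output_percent_reduction():
    # symmetric offsets -> exact cohort means 381 (n=15) and 91 (n=27)
    a = [381 + d for d in range(-7, 8)]
    b = [91 + d for d in range(-13, 14)]
    summ = reproductive_output_summary(_fruit_records(a, b))
    assert summ.mean_fruits["native"] == pytest.approx(381)
    assert summ.mean_fruits["invasive"] == pytest.approx(91)
    assert summ.percent_reduction_fruits == pytest.approx(76.1, abs=0.1)
    assert summ.fruit_test.significance_code == "***"


def test_reproductive_output_identical_populations():
    summ = reproductive_output_summary(
        _fruit_records([100, 110, 120], [100, 110, 120]))
    assert summ.percent_reduction_fruits == pytest.approx(0.0)


def test_reproductive_output_consistency_error():
    recs = _fruit_records([100, 100], [100, 100])
    recs.append(_rec("bad", "native", n_fruits=0, total_fruit_weight_mg=5.0))
    with pytest.raises(DataConsistencyError):
        reproductive_output_summary(recs)


def test_simulated_fruit_counts_recover_means():
    params = PhenoSimParams(seed=9)
    params.populations["native"]["n"] = 200
    params.populations["invasive"]["n"] = 200
    del params.populations["F1"]
    records = simulate_phenology(params)
    for pop, mean, k in [("native", 381.0, 5.0), ("invasive", 91.0, 5.0)]:
        counts = [r.n_fruits for r in records if r.population == pop]
        se = np.sqrt(mean + mean ** 2 / k) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - mean) < 3 * se
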