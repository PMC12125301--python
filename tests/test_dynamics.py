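"""Paired clone matching, dynamics classification, and patient summaries."""

import numpy as np
import pytest

from _oracles import hypergeom_two_sided_p
from tcrdyn._stats import pearson_ols
from tcrdyn.clonotype import CloneTable
from tcrdyn.dynamics import (
    CloneDynamics,
    classify_dynamics_exact_test,
    classify_dynamics_foldchange,
    correlate_summaries,
    exact_test_pvalue,
    match_clones,
    post_frequency_partition,
    summarize_patient,
)


def _dyn(pre_count, post_count, pre_total, post_total, patient="p"):
    pf, qf = pre_count / pre_total, post_count / post_total
    return CloneDynamics(
        patient_id=patient,
        clonotype_key="k",
        pre_count=pre_count,
        post_count=post_count,
        pre_freq=pf,
        post_freq=qf,
        fold_change=(qf / pf) if pre_count and post_count else None,
        origin="pre_existing" if pre_count else "new",
    )


def test_match_set_algebra():
    pre = CloneTable("pre", {"A": 10, "B": 5})
    post = CloneTable("post", {"A": 30, "C": 4})
    dyn = {d.clonotype_key: d for d in match_clones(pre, post, "p1")}
    assert dyn["A"].origin == "pre_existing"
    assert dyn["A"].fold_change == pytest.approx((30 / 34) / (10 / 15))
    assert dyn["B"].dynamics_class == "disappeared"
    assert dyn["C"].origin == "new" and dyn["C"].dynamics_class == "new"


def test_match_identity_gives_unit_fold():
    table = CloneTable("s", {"A": 30, "B": 25})
    for d in match_clones(table, table):
        assert d.fold_change == pytest.approx(1.0)
        assert classify_dynamics_foldchange(d, min_cells=20) == "unchanged"


def test_match_refuses_mixed_key_levels():
    pre = CloneTable("pre", {"A": 1}, key_level="nt")
    post = CloneTable("post", {"A": 1}, key_level="aa")
    with pytest.raises(ValueError, match="key-level"):
        match_clones(pre, post)


@pytest.mark.parametrize(
    "fold,label",
    [(0.4, "decreased"), (0.5, "unchanged"), (1.0, "unchanged"),
     (2.0, "unchanged"), (2.1, "increased")],
)
def test_foldchange_boundaries(fold, label):
    """Cut-offs: increased >2-fold, decreased <0.5-fold, boundaries unchanged."""
    pre_count = 100
    d = _dyn(pre_count, int(round(pre_count * fold)), 1000, 1000)
    assert classify_dynamics_foldchange(d) == label


def test_foldchange_example_frequencies():
    # pre 1% (25/2500) -> post 3% (75/2500): 3-fold increase
    d = _dyn(25, 75, 2500, 2500)
    assert classify_dynamics_foldchange(d) == "increased"


def test_size_filter_marks_not_evaluable():
    d = _dyn(12, 15, 1000, 1000)
    assert classify_dynamics_foldchange(d, min_cells=20) == "not_evaluable"
    assert d.dynamics_class == "not_evaluable"
    # a sensitive clone that collapses post-treatment stays evaluable
    d2 = _dyn(40, 2, 1000, 1000)
    assert classify_dynamics_foldchange(d2, min_cells=20) == "decreased"


def test_foldchange_depth_invariance():
    """Scaling sequencing depth with proportional counts preserves classes."""
    for k in (2, 5, 10):
        a = _dyn(30, 90, 1000, 1000)
        b = _dyn(30, 90 * k, 1000, 1000 * k)
        assert classify_dynamics_foldchange(a) == classify_dynamics_foldchange(b)


def test_exact_test_against_enumeration_oracle(rng):
    """Conditional exact p equals direct hypergeometric pmf enumeration."""
    d = _dyn(10, 40, 1000, 1000)
    label = classify_dynamics_exact_test(d, 1000, 1000)
    # clone cells among pre draws: k=10 of N=1000 drawn from M=2000 with n=50
    p_oracle = hypergeom_two_sided_p(k=10, M=2000, n=50, N=1000)
    assert exact_test_pvalue(10, 40, 1000, 1000) == pytest.approx(
        p_oracle, rel=1e-9)
    assert p_oracle < 0.05
    assert np.log2((40 / 1000) / (10 / 1000)) == 2.0
    assert label == "increased"
    # random tables
    for _ in range(25):
        pre_c = int(rng.integers(0, 60))
        post_c = int(rng.integers(0, 60))
        p = exact_test_pvalue(pre_c, post_c, 500, 600)
        oracle = hypergeom_two_sided_p(
            k=pre_c, M=1100, n=pre_c + post_c, N=500)
        assert p == pytest.approx(oracle, rel=1e-8, abs=1e-12)


def test_exact_test_null_case():
    d = _dyn(30, 30, 1000, 1000)
    assert classify_dynamics_exact_test(d, 1000, 1000) == "unchanged"
    p_oracle = hypergeom_two_sided_p(k=30, M=2000, n=60, N=1000)
    assert p_oracle == pytest.approx(1.0, abs=1e-9)


def test_exact_test_rejects_impossible_totals():
    d = _dyn(30, 30, 1000, 1000)
    with pytest.raises(ValueError):
        classify_dynamics_exact_test(d, 20, 1000)


def test_classifiers_agree_on_extreme_folds():
    """Large clones with >=8-fold changes get the same class from both rules."""
    cases = [(100, 800), (150, 1600), (800, 100), (1600, 150)]
    for pre_count, post_count in cases:
        a = _dyn(pre_count, post_count, 10_000, 10_000)
        b = _dyn(pre_count, post_count, 10_000, 10_000)
        assert classify_dynamics_foldchange(a) == classify_dynamics_exact_test(
            b, 10_000, 10_000)


def test_post_frequencies_partition(small_cohort):
    """Every post cell is either a new or a pre-existing clone's."""
    from tcrdyn.simulate import counts_to_clone_table, sample_pair_counts, simulate_patient_truth

    cfg, _ = small_cohort
    truth = simulate_patient_truth(cfg, 0, with_sequences=False)
    pre, post = sample_pair_counts(cfg, truth, 0)
    dyn = match_clones(
        counts_to_clone_table(truth, pre, "pre"),
        counts_to_clone_table(truth, post, "post"),
    )
    new, pre_existing = post_frequency_partition(dyn)
    assert new + pre_existing == pytest.approx(1.0, abs=1e-9)


def test_summary_identity_patient():
    table = CloneTable("s", {"A": 30, "B": 25, "C": 1})
    summary = summarize_patient(match_clones(table, table, "p1"))
    assert summary.total_clone_size_change == pytest.approx(0.0)
    assert summary.new_clone_size == 0.0
    assert summary.group == "decreased"  # documented zero-tie convention


def test_summary_entirely_novel_post():
    pre = CloneTable("pre", {"A": 10})
    post = CloneTable("post", {"B": 6, "C": 4})
    summary = summarize_patient(match_clones(pre, post, "p1"))
    assert summary.new_clone_size == pytest.approx(1.0)
    assert summary.pre_existing_size_post == 0.0


def test_summary_recovers_generator_truth(small_cohort):
    """Measured new-clone burden tracks the planted burden."""
    from tcrdyn.simulate import counts_to_clone_table, sample_pair_counts, simulate_patient_truth

    cfg, _ = small_cohort
    planted, measured = [], []
    for i in range(8):
        truth = simulate_patient_truth(cfg, i, with_sequences=False)
        pre, post = sample_pair_counts(cfg, truth, i)
        dyn = match_clones(
            counts_to_clone_table(truth, pre, "pre"),
            counts_to_clone_table(truth, post, "post"),
            truth.patient_id,
        )
        planted_new = sum(
            c.post_freq for c in truth.clones if c.origin == "new")
        s = summarize_patient(dyn)
        planted.append(planted_new)
        measured.append(s.new_clone_size)
    # measured burden = planted burden + sampling-induced "new" clones, so it
    # is upward-biased but must remain strongly rank-correlated with truth
    assert all(m >= p - 0.05 for m, p in zip(measured, planted))
    assert pearson_ols(planted, measured).pearson_r > 0.5


def test_correlation_contracts():
    summaries = [
        type("S", (), {"patient_id": f"p{i}", "new_clone_size": v})()
        for i, v in enumerate([0.1, 0.2, 0.3, 0.4])
    ]
    scores = {f"p{i}": 2 - 3 * v for i, v in enumerate([0.1, 0.2, 0.3, 0.4])}
    res = correlate_summaries(summaries, scores)
    assert res.pearson_r == pytest.approx(-1.0)
    assert res.slope == pytest.approx(-3.0)
    with pytest.raises(ValueError):
        correlate_summaries(summaries[:2], scores)
    with pytest.raises(ValueError):
        correlate_summaries(summaries, {f"p{i}": 1.0 for i in range(4)})


def test_correlation_dies_under_permutation(rng):
    """Breaking the pairing destroys a perfect linear relation on average."""
    x = np.linspace(0, 1, 16)
    y = 2 * x + 1
    rs = []
    for _ in range(200):
        rs.append(pearson_ols(x, rng.permutation(y)).pearson_r)
    assert abs(np.mean(rs)) < 0.15
    assert pearson_ols(x, y).pearson_r == pytest.approx(1.0)
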