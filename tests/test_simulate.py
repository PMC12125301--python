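"""Synthetic-cohort generator: determinism, planted truth, and recounting."""

import filecmp

import numpy as np
import pytest

from tcrdyn.clonotype import build_clone_table
from tcrdyn.contig_io import assemble_clonotypes, read_contig_table
from tcrdyn.dynamics import classify_dynamics_foldchange, match_clones
from tcrdyn.simulate import (
    CohortConfig,
    PlantedFractions,
    counts_to_clone_table,
    generate_blood_counts,
    generate_repertoire_pair,
    sample_pair_counts,
    simulate_healthy_truth,
    simulate_patient_truth,
)


def test_config_validation():
    with pytest.raises(ValueError, match="budget"):
        CohortConfig(planted=PlantedFractions(0.5, 0.3, 0.2, 0.2))
    with pytest.raises(ValueError, match="cells_per_sample"):
        CohortConfig(cells_per_sample=50)
    with pytest.raises(ValueError, match="clone_size_law"):
        CohortConfig(clone_size_law="lognormal")


def test_truth_frequency_invariants():
    cfg = CohortConfig(seed=3, n_clones=1500, cells_per_sample=800)
    truth = simulate_patient_truth(cfg, 0, with_sequences=False)
    assert truth.pre_freqs().sum() == pytest.approx(1.0, abs=1e-9)
    assert truth.post_freqs().sum() == pytest.approx(1.0, abs=1e-9)
    for clone in truth.clones:
        assert (clone.origin == "new") == (clone.pre_freq == 0.0)
    burden = sum(c.post_freq for c in truth.clones if c.origin == "new")
    assert burden == pytest.approx(truth.new_clone_burden, abs=1e-9)


def test_seed_determinism_and_distinctness(tmp_path):
    cfg = CohortConfig(seed=11, n_clones=400, cells_per_sample=300, n_new_clones=10)
    p1, q1, _ = generate_repertoire_pair(cfg, 0, tmp_path / "a")
    p2, q2, _ = generate_repertoire_pair(cfg, 0, tmp_path / "b")
    assert filecmp.cmp(p1, p2, shallow=False)
    assert filecmp.cmp(q1, q2, shallow=False)
    other = CohortConfig(seed=12, n_clones=400, cells_per_sample=300, n_new_clones=10)
    p3, _, _ = generate_repertoire_pair(other, 0, tmp_path / "c")
    assert not filecmp.cmp(p1, p3, shallow=False)


def test_recounting_recovers_planted_frequencies(tmp_path):
    """Parsing emitted contig files reproduces planted clone frequencies
    within 3 multinomial standard errors (clones >= 1%)."""
    cfg = CohortConfig(seed=21)
    pre_path, post_path, truth = generate_repertoire_pair(cfg, 0, tmp_path)
    n = cfg.cells_per_sample
    for path, attr in ((pre_path, "pre_freq"), (post_path, "post_freq")):
        cells = assemble_clonotypes(read_contig_table(path))
        table = build_clone_table(cells, "s")
        assert table.total_cells == n
        checked = 0
        for clone in truth.clones:
            f = getattr(clone, attr)
            if f < 0.01:
                continue
            checked += 1
            obs = table.counts.get(clone.clonotype_key(), 0) / n
            se = np.sqrt(f * (1 - f) / n)
            assert abs(obs - f) <= 3 * se
        assert checked >= 1


def test_planted_fold_effects_are_recovered():
    """Sensitive/resistant clones passing the 20-cell filter classify to
    decreased/increased with high accuracy."""
    cfg = CohortConfig(seed=31)
    correct = total = 0
    for i in range(20):
        truth = simulate_patient_truth(cfg, i, with_sequences=False)
        pre, post = sample_pair_counts(cfg, truth, i)
        expect = {
            c.clonotype_key(): c.planted_class
            for c in truth.clones
            if c.planted_class in ("sensitive", "resistant")
        }
        dyn = match_clones(
            counts_to_clone_table(truth, pre, "pre"),
            counts_to_clone_table(truth, post, "post"),
        )
        for d in dyn:
            cls = expect.get(d.clonotype_key)
            if cls is None:
                continue
            label = classify_dynamics_foldchange(d)
            if label in ("not_evaluable", "new", "disappeared"):
                continue
            total += 1
            correct += label == ("increased" if cls == "resistant" else "decreased")
    assert total >= 30
    assert correct / total >= 0.95


def test_healthy_repertoire_is_less_clonal():
    cfg = CohortConfig(seed=41)
    rng = np.random.default_rng(0)
    from tcrdyn.clonotype import expanded_cell_fraction

    patient = simulate_patient_truth(cfg, 0, with_sequences=False)
    healthy = simulate_healthy_truth(cfg, 0)
    pc = rng.multinomial(cfg.cells_per_sample, patient.pre_freqs())
    hc = rng.multinomial(cfg.cells_per_sample, healthy.pre_freqs())
    fp = expanded_cell_fraction(counts_to_clone_table(patient, pc, "p"))
    fh = expanded_cell_fraction(counts_to_clone_table(healthy, hc, "h"))
    assert fp > fh


def test_blood_counts_couple_to_burden():
    cfg = CohortConfig(seed=51, n_clones=500, cells_per_sample=400)
    truths = [simulate_patient_truth(cfg, i, with_sequences=False) for i in range(10)]
    blood, reference = generate_blood_counts(cfg, truths)
    assert set(reference.analyte) == {"anc", "plt", "arc"}
    assert len(blood) == 20  # pre + post per patient
    # pre-treatment counts sit well below the reference median
    pre = blood[blood.timepoint == "pre"]
    for row in reference.itertuples():
        assert (pre[row.analyte] < row.median).all()
    # planted recovery reflects the negative coupling
    burdens = [t.new_clone_burden for t in truths]
    recoveries = [t.true_recovery for t in truths]
    assert np.corrcoef(burdens, recoveries)[0, 1] < 0


def test_new_clone_relatedness_plants_one_edit_variants():
    cfg = CohortConfig(seed=61, n_clones=150, cells_per_sample=300,
                       n_new_clones=15, new_clone_relatedness=1.0)
    truth = simulate_patient_truth(cfg, 0)
    from _oracles import edit_distance_dp

    pre_b = [c.cdr3b_aa for c in truth.clones if c.origin == "pre_existing"]
    for clone in truth.clones:
        if clone.origin == "new":
            assert min(edit_distance_dp(clone.cdr3b_aa, b) for b in pre_b) <= 1
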