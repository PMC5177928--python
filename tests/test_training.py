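"""Training: anchored-sensitivity objective, exhaustive length search,
annealed weight/matrix optimization, reproducibility."""

import numpy as np
import pytest

import hatpred.training as training
from conftest import brute_force_sn_at_sp
from hatpred.dataset import LabeledDataset, SiteAnnotation, SiteWindow, Substrate
from hatpred.scoring import HatModel, SubstitutionMatrix
from hatpred.synthetic import MotifSpec, make_motif_spec, sample_study
from hatpred.training import (
    TrainConfig,
    TrainingError,
    loo_objective,
    mutate_matrix,
    select_motif_length,
    train_model,
    train_weights,
)


def _win(residues, protein="P", pos=1, label="positive"):
    return SiteWindow(residues, len(residues) // 2, (protein, pos), label)


def _toy_dataset(pos_seqs, neg_seqs, m=1, n=1):
    positives = [_win(s, protein=f"P{i}", pos=i + 1) for i, s in enumerate(pos_seqs)]
    negatives = [
        _win(s, protein=f"N{i}", pos=i + 1, label="negative")
        for i, s in enumerate(neg_seqs)
    ]
    return LabeledDataset(hat="EP300", m=m, n=n, positives=positives,
                          negatives=negatives)


def _unit_model(dataset, matrix=None):
    return HatModel(
        hat=dataset.hat,
        m=dataset.m,
        n=dataset.n,
        matrix=matrix or SubstitutionMatrix.blosum62(),
        weights=np.ones(dataset.window_length, int),
        positives=dataset.positives,
    )


# ----------------------------------------------------------- loo_objective


def test_objective_perfect_separation_is_one():
    ds = _toy_dataset(["GKS", "GKS", "GKS"], ["WCW".replace("C", "K")] * 3)
    assert loo_objective(ds, _unit_model(ds), 0.9) == 1.0


def test_objective_identical_scores_is_zero():
    # zero matrix: every score 0; cutoff lands above the tied block
    ds = _toy_dataset(["GKS", "GKS"], ["AKA", "AKC"])
    model = _unit_model(ds, SubstitutionMatrix.zeros())
    assert loo_objective(ds, model, 0.9) == 0.0


def test_objective_matches_all_cutoffs_oracle():
    rng = np.random.default_rng(17)
    for trial in range(20):
        pos = rng.integers(0, 12, size=10).astype(float)
        neg = rng.integers(0, 12, size=90).astype(float)
        from hatpred.evaluation import sn_at_sp

        for anchor in (0.8, 0.9, 0.95):
            assert sn_at_sp(pos, neg, anchor) == pytest.approx(
                brute_force_sn_at_sp(pos, neg, anchor)
            )


def test_objective_needs_two_positives():
    ds = _toy_dataset(["GKS"], ["AKA"])
    with pytest.raises(TrainingError):
        loo_objective(ds, _unit_model(ds), 0.9)


# ---------------------------------------------------- select_motif_length


def _study_for_selection(seed=0):
    """Substrates whose positives share an exact 'WKW' core; negatives are
    surrounded by alanines, so (1,1) already separates perfectly."""
    substrates, annotations = [], []
    for i in range(6):
        seq = "A" * 10 + "WKW" + "A" * 10 + "K" + "A" * 10
        pid = f"P{i}"
        substrates.append(Substrate(pid, seq))
        annotations.append(SiteAnnotation(pid, 12, "EP300"))
    return substrates, annotations


def test_length_tiebreak_prefers_smallest_window():
    substrates, annotations = _study_for_selection()
    config = TrainConfig(m_range=(1, 4), n_range=(1, 4))
    assert select_motif_length(substrates, annotations, "EP300", config) == (1, 1)


def test_length_search_is_exhaustive(monkeypatch):
    calls = []
    original = training.sn_at_sp

    def counting(pos, neg, anchor):
        calls.append(1)
        return original(pos, neg, anchor)

    monkeypatch.setattr(training, "sn_at_sp", counting)
    substrates, annotations = _study_for_selection()
    select_motif_length(
        substrates, annotations, "EP300", TrainConfig(m_range=(1, 3), n_range=(1, 2))
    )
    assert len(calls) == 3 * 2


def test_length_covers_single_informative_downstream_position():
    spec = MotifSpec(
        hat_name="EP300",
        informative_positions={4: ("W", 0.9)},
        background={aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"},
    )
    study = sample_study(spec, n_substrates=40, sites_per_substrate=2,
                         seq_len=140, seed=5)
    config = TrainConfig(m_range=(1, 6), n_range=(1, 6))
    m, n = select_motif_length(study.substrates, study.annotations, "EP300", config)
    assert n >= 4


# ------------------------------------------------- train_weights / matrix


def _small_clean_dataset(seed=0, m=3, n=5):
    spec = make_motif_spec("crebbp-like", effect="clean")
    study = sample_study(spec, n_substrates=30, sites_per_substrate=2,
                         seq_len=150, seed=seed)
    from hatpred.dataset import build_dataset

    return build_dataset(study.substrates, study.annotations, "CREBBP", m, n)


def test_max_stagnation_zero_returns_unit_weights():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    config = TrainConfig(max_stagnation=0)
    weights, trace = train_weights(ds, model, config)
    assert (weights == 1).all()
    assert trace.rows == []


def test_weight_training_replay_is_deterministic():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    config = TrainConfig(seed=7, max_proposals=300)
    w1, t1 = train_weights(ds, model, config)
    w2, t2 = train_weights(ds, model, config)
    assert (w1 == w2).all()
    assert t1.rows == t2.rows


def test_weights_stay_non_negative():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    weights, _ = train_weights(ds, model, TrainConfig(seed=3, max_proposals=500))
    assert (weights >= 0).all()


def test_matrix_zero_iterations_is_blosum62():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    matrix, trace = mutate_matrix(ds, model, TrainConfig(max_stagnation=0))
    assert matrix == SubstitutionMatrix.blosum62()


def test_matrix_mutation_objective_not_below_baseline():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    baseline = loo_objective(ds, model, 0.9)
    config = TrainConfig(seed=5, max_proposals=500)
    matrix, trace = mutate_matrix(ds, model, config)
    tuned = loo_objective(
        ds,
        HatModel(ds.hat, ds.m, ds.n, matrix, model.weights, ds.positives),
        0.9,
    )
    assert tuned >= baseline - 1e-12


def test_matrix_mutation_replay_is_deterministic():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    config = TrainConfig(seed=9, max_proposals=300)
    m1, t1 = mutate_matrix(ds, model, config)
    m2, t2 = mutate_matrix(ds, model, config)
    assert m1 == m2
    assert t1.rows == t2.rows


def test_matrix_reserved_rows_stay_zero():
    ds = _small_clean_dataset()
    model = _unit_model(ds)
    matrix, _ = mutate_matrix(ds, model, TrainConfig(seed=1, max_proposals=400))
    assert (matrix.array[20:, :] == 0).all()
    assert (matrix.array[:, 20:] == 0).all()


# ------------------------------------------------------------ train_model


def test_train_model_refuses_single_positive():
    subs = [Substrate("P1", "MKKKA")]
    anns = [SiteAnnotation("P1", 2, "EP300")]
    with pytest.raises(TrainingError, match="at least 2"):
        train_model(subs, anns, "EP300")


def test_train_model_trace_monotone_and_reproducible(small_study):
    config = TrainConfig(m_range=(1, 4), n_range=(1, 4), max_proposals=400, seed=2)
    model1, trace1 = train_model(
        small_study.substrates, small_study.annotations, "CREBBP", config
    )
    best = trace1.best_so_far()
    assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))
    model2, trace2 = train_model(
        small_study.substrates, small_study.annotations, "CREBBP", config
    )
    assert model1.to_json() == model2.to_json()
    assert trace1.rows == trace2.rows


def test_train_model_thresholds_ordered(small_model):
    t = small_model.thresholds
    assert t["high"] >= t["medium"] >= t["low"]


def test_step_order_without_length_uses_midpoint_window(small_study):
    config = TrainConfig(
        m_range=(1, 3), n_range=(1, 3), step_order=("weights",), max_proposals=100
    )
    model, _ = train_model(
        small_study.substrates, small_study.annotations, "CREBBP", config
    )
    assert (model.m, model.n) == (2, 2)
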