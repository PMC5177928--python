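"""Similarity scoring: clamping, weighting, model means, LOO exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_similarity, random_window
from hatpred.dataset import SiteWindow
from hatpred.scoring import (
    HatModel,
    ScoringError,
    SubstitutionMatrix,
    model_score,
    pairwise_scores,
    peptide_similarity,
    score_dataset,
    weighted_similarity,
)


def _win(residues, protein="P", pos=1, label="positive", center=None):
    return SiteWindow(
        residues=residues,
        center_index=len(residues) // 2 if center is None else center,
        origin=(protein, pos),
        label=label,
    )


# ------------------------------------------------------ similarity basics


def test_identity_similarity_sums_diagonal(blosum):
    # G=6, K=5, S=4 on the BLOSUM62 diagonal
    assert peptide_similarity("GKS", "GKS", blosum) == 15


def test_negative_sum_clamps_to_zero(blosum):
    assert peptide_similarity("WWW", "CCC", blosum) == 0


def test_zero_matrix_scores_zero():
    zeros = SubstitutionMatrix.zeros()
    assert peptide_similarity("GKS", "AKA", zeros) == 0


def test_pad_and_unknown_are_neutral(blosum):
    assert peptide_similarity("*KX", "GKS", blosum) == blosum["K", "K"]


def test_length_mismatch_errors(blosum):
    with pytest.raises(ScoringError):
        peptide_similarity("GK", "GKS", blosum)


def test_weighted_examples(blosum):
    assert weighted_similarity("GKS", "GKS", blosum, [2, 1, 1]) == 21
    assert weighted_similarity("GKS", "GKS", blosum, [1, 1, 1]) == peptide_similarity(
        "GKS", "GKS", blosum
    )
    assert weighted_similarity("GKS", "GKS", blosum, [0, 0, 0]) == 0
    with pytest.raises(ScoringError, match="non-negative"):
        weighted_similarity("GKS", "GKS", blosum, [-1, 1, 1])


def test_blosum62_symmetry_before_mutation(blosum):
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = random_window(rng, 7)
        b = random_window(rng, 7)
        assert peptide_similarity(a, b, blosum) == peptide_similarity(b, a, blosum)


def test_weight_scaling_doubles_unclamped(blosum):
    rng = np.random.default_rng(4)
    for _ in range(25):
        a = random_window(rng, 5, allow_special=False)
        b = random_window(rng, 5, allow_special=False)
        w = rng.integers(0, 4, size=5)
        raw = int((w * blosum.array[[*map("ARNDCQEGHILKMFPSTWYV".index, a)],
                                    [*map("ARNDCQEGHILKMFPSTWYV".index, b)]]).sum())
        if raw > 0:
            assert weighted_similarity(a, b, blosum, 2 * w) == 2 * weighted_similarity(
                a, b, blosum, w
            )


@settings(max_examples=100, deadline=None)
@given(st.data())
def test_similarity_matches_brute_force(blosum, data):
    length = data.draw(st.integers(1, 15))
    seed = data.draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    a, b = random_window(rng, length), random_window(rng, length)
    w = rng.integers(0, 5, size=length).tolist()
    assert peptide_similarity(a, b, blosum) == brute_force_similarity(a, b, blosum)
    assert weighted_similarity(a, b, blosum, w) == brute_force_similarity(
        a, b, blosum, w
    )


def test_pairwise_scores_match_scalar_path(blosum):
    rng = np.random.default_rng(5)
    queries = [random_window(rng, 9) for _ in range(6)]
    refs = [random_window(rng, 9) for _ in range(4)]
    w = rng.integers(0, 3, size=9).tolist()
    grid = pairwise_scores(queries, refs, blosum, w)
    for i, q in enumerate(queries):
        for j, r in enumerate(refs):
            assert grid[i, j] == weighted_similarity(q, r, blosum, w)


# ---------------------------------------------------------- model scoring


def _model(positives, blosum, m=1, n=1, weights=None):
    return HatModel(
        hat="EP300",
        m=m,
        n=n,
        matrix=blosum,
        weights=np.ones(m + 1 + n, int) if weights is None else weights,
        positives=positives,
    )


def test_model_score_single_positive_is_self_similarity(blosum):
    p = _win("GKS")
    model = _model([p], blosum)
    assert model_score(p, model) == peptide_similarity("GKS", "GKS", blosum)


def test_model_score_is_mean_over_positives(blosum):
    p1, p2 = _win("GKS", pos=1), _win("AKA", pos=2)
    model = _model([p1, p2], blosum)
    expected = (
        peptide_similarity("GKG", "GKS", blosum)
        + peptide_similarity("GKG", "AKA", blosum)
    ) / 2
    assert model_score(_win("GKG", pos=3), model) == expected


def test_loo_exclusion_by_origin_not_sequence(blosum):
    # duplicate sequences from different proteins must NOT be excluded
    p1 = _win("GKS", protein="A", pos=1)
    p2 = _win("GKS", protein="B", pos=1)
    model = _model([p1, p2], blosum)
    loo = model_score(p1, model, exclude=("A", 1))
    assert loo == peptide_similarity("GKS", "GKS", blosum)  # p2 kept
    with pytest.raises(ScoringError):
        model_score(p1, _model([p1], blosum), exclude=("A", 1))


def test_loo_on_two_positives_scores_the_other(blosum):
    p1 = _win("GKS", protein="A", pos=1)
    p2 = _win("AKA", protein="B", pos=2)
    model = _model([p1, p2], blosum)
    assert model_score(p1, model, exclude=("A", 1)) == peptide_similarity(
        "GKS", "AKA", blosum
    )


def test_identical_positives_loo_independent_of_k(blosum):
    for k in (2, 3, 5):
        positives = [_win("GKS", protein=f"P{i}", pos=i + 1) for i in range(k)]
        model = _model(positives, blosum)
        score = model_score(positives[0], model, exclude=("P0", 1))
        assert score == peptide_similarity("GKS", "GKS", blosum)


# --------------------------------------------------------- score_dataset


def _dataset(positives, negatives, m=1, n=1):
    from hatpred.dataset import LabeledDataset

    return LabeledDataset(hat="EP300", m=m, n=n, positives=positives,
                          negatives=negatives)


def test_score_dataset_loo_needs_two_positives(blosum):
    ds = _dataset([_win("GKS")], [_win("AKA", label="negative")])
    model = _model([_win("GKS")], blosum)
    with pytest.raises(ScoringError):
        score_dataset(ds, model, loo=True)


def test_score_dataset_window_shape_mismatch(blosum):
    ds = _dataset([_win("GKS")], [], m=1, n=1)
    model = _model([_win("AAKAA")], blosum, m=2, n=2)
    with pytest.raises(ScoringError, match="does not match"):
        score_dataset(ds, model)


def test_non_loo_scores_dominate_loo_scores(blosum):
    """Including the maximal self-similarity can only raise the mean."""
    rng = np.random.default_rng(6)
    positives = [
        _win(random_window(rng, 5, allow_special=False), protein=f"P{i}", pos=i + 1)
        for i in range(6)
    ]
    ds = _dataset(positives, [], m=2, n=2)
    model = _model(positives, blosum, m=2, n=2)
    plain = score_dataset(ds, model, loo=False)["score"]
    loo = score_dataset(ds, model, loo=True)["score"]
    # self-similarity is maximal for BLOSUM62 (diagonal dominance)
    assert (plain.to_numpy() >= loo.to_numpy() - 1e-12).all()


def test_identical_positives_loo_equals_self_similarity(blosum):
    positives = [_win("GKS", protein=f"P{i}", pos=i + 1) for i in range(4)]
    ds = _dataset(positives, [])
    model = _model(positives, blosum)
    loo = score_dataset(ds, model, loo=True)["score"]
    assert (loo == peptide_similarity("GKS", "GKS", blosum)).all()


# ----------------------------------------------------------- persistence


def test_model_json_round_trip_bit_exact(blosum):
    model = HatModel(
        hat="KAT5",
        m=2,
        n=1,
        matrix=blosum,
        weights=np.array([3, 0, 1, 2]),
        positives=[_win("AAKA", protein="P1", pos=7, center=2)],
        thresholds={"high": 10.5, "medium": 8.0, "low": 6.25},
    )
    restored = HatModel.from_json(model.to_json())
    assert restored.hat == model.hat
    assert (restored.m, restored.n) == (model.m, model.n)
    assert restored.matrix == model.matrix
    assert (restored.weights == model.weights).all()
    assert restored.positives == model.positives
    assert restored.thresholds == model.thresholds
    assert restored.to_json() == model.to_json()


def test_threshold_ordering_enforced(blosum):
    with pytest.raises(ScoringError, match="high >= medium >= low"):
        HatModel(
            hat="KAT5",
            m=1,
            n=1,
            matrix=blosum,
            weights=np.ones(3, int),
            positives=[_win("GKS")],
            thresholds={"high": 1.0, "medium": 5.0, "low": 0.0},
        )
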