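"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (double loops, exhaustive
enumeration) and independent of the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from hatpred.alphabet import ALPHABET, PAD, RESIDUES, UNKNOWN
from hatpred.scoring import SubstitutionMatrix
from hatpred.synthetic import make_motif_spec, sample_study
from hatpred.training import TrainConfig, train_model

# ---------------------------------------------------------------- oracles


def brute_force_similarity(a: str, b: str, matrix: SubstitutionMatrix,
                           weights=None) -> int:
    """Independent double-loop scorer: per-position dict lookups, clamp last."""
    assert len(a) == len(b)
    if weights is None:
        weights = [1] * len(a)
    total = 0
    for x, y, w in zip(a, b, weights):
        total += w * matrix.array[ALPHABET.index(x), ALPHABET.index(y)]
    return max(0, int(total))


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise-comparison AUC with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == "positive"]
    neg = [s for s, l in zip(scores, labels) if l == "negative"]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_sn_at_sp(pos_scores, neg_scores, anchor) -> float:
    """Exhaustive all-cutoffs oracle for the anchored-sensitivity objective:
    try every candidate cutoff in ascending order and return Sn at the first
    one whose specificity (negatives strictly below) reaches the anchor."""
    neg = sorted(neg_scores)
    candidates = sorted(set(neg)) + [np.nextafter(max(neg), np.inf)]
    n = len(neg)
    for cut in candidates:
        below = sum(1 for s in neg if s < cut)
        if below / n >= anchor:
            return sum(1 for s in pos_scores if s >= cut) / len(pos_scores)
    raise AssertionError("unreachable")


def brute_force_rbh(a_hits, b_hits):
    """Exhaustive reciprocal-best pairing over explicit hit lists."""

    def best(hits, query):
        mine = [h for h in hits if h.query_id == query]
        if not mine:
            return None
        return min(mine, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)).subject_id

    pairs = set()
    for x in {h.query_id for h in a_hits}:
        y = best(a_hits, x)
        if y is not None and best(b_hits, y) == x:
            pairs.add((x, y))
    return sorted(pairs)


def random_window(rng: np.random.Generator, length: int, allow_special=True) -> str:
    pool = RESIDUES + (UNKNOWN + PAD if allow_special else "")
    return "".join(rng.choice(list(pool), size=length))


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def blosum() -> SubstitutionMatrix:
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def small_study():
    """A compact clean planted-motif study shared by predict/CLI tests."""
    spec = make_motif_spec("crebbp-like", effect="clean")
    return sample_study(spec, n_substrates=30, sites_per_substrate=2,
                        seq_len=150, seed=11)


@pytest.fixture(scope="session")
def small_model(small_study):
    """A quickly trained model on the small study (narrow window search)."""
    config = TrainConfig(m_range=(1, 6), n_range=(1, 6), max_proposals=600,
                         seed=11)
    model, trace = train_model(
        small_study.substrates, small_study.annotations, "CREBBP", config
    )
    return model
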