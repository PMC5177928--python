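"""Three-step model training: motif length selection, weight training and
matrix mutation, driven by a leave-one-out objective with simulated
annealing.

The objective is the LOO sensitivity at a fixed specificity anchor (default
Sp = 0.90).  Length selection is exhaustive over (m, n); the weight and
matrix steps propose random +/-1 moves on a single position weight or a
single residue-pair matrix entry and accept them when the objective improves,
or with probability exp(dSn/T) otherwise, under geometric cooling.  The
returned state is always the best seen, so the best-so-far objective is
monotone non-decreasing along the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .alphabet import N_RESIDUES, encode
from .dataset import (
    LabeledDataset,
    SiteAnnotation,
    Substrate,
    build_dataset,
)
from .evaluation import (
    _assemble_report,
    calibrate_thresholds,
    cutoff_at_specificity,
    sn_at_sp,
)
from .scoring import HatModel, SubstitutionMatrix, score_dataset

_EPS = 1e-12


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs.

    sp_anchor: specificity held fixed while sensitivity is optimized.
    m_range/n_range: inclusive bounds for the exhaustive window search.
    max_stagnation: consecutive rejected proposals before an annealing step
        stops; an accepted move (even a lateral or worsening one) resets the
        counter.  max_proposals is a hard cap guaranteeing termination even
        while the chain keeps accepting plateau moves — by the default cap
        the temperature has decayed below 1e-5 of sa_t0 and the chain is
        effectively greedy.
    sa_t0/sa_cooling: initial annealing temperature and geometric factor.
    step_order: order of the three steps; the length step always resets
        weights to 1 for the new window shape.
    """

    sp_anchor: float = 0.90
    m_range: tuple[int, int] = (1, 30)
    n_range: tuple[int, int] = (1, 30)
    max_stagnation: int = 500
    max_proposals: int = 2_000
    sa_t0: float = 0.05
    sa_cooling: float = 0.995
    seed: int = 0
    step_order: tuple[str, ...] = ("length", "weights", "matrix")

    def __post_init__(self) -> None:
        if not 0 < self.sp_anchor < 1:
            raise TrainingError("sp_anchor must be in (0, 1)")
        for lo, hi in (self.m_range, self.n_range):
            if not (1 <= lo <= hi <= 30):
                raise TrainingError("m/n ranges must lie within 1..30")
        if not 0 < self.sa_cooling < 1:
            raise TrainingError("sa_cooling must be in (0, 1)")
        if len(set(self.step_order)) != len(self.step_order) or not set(
            self.step_order
        ) <= {"length", "weights", "matrix"}:
            raise TrainingError(
                "step_order must be a permutation of a subset of "
                "{'length', 'weights', 'matrix'}"
            )


@dataclass
class TrainTrace:
    """Per-proposal log: (step, proposal, obj_before, obj_after, accepted, T)."""

    rows: list[tuple] = field(default_factory=list)

    def log(self, step, proposal, before, after, accepted, temperature) -> None:
        self.rows.append((step, proposal, before, after, bool(accepted), temperature))

    def extend(self, other: "TrainTrace") -> None:
        self.rows.extend(other.rows)

    def best_so_far(self) -> list[float]:
        """Running maximum of the objective over visited states."""
        best: list[float] = []
        cur = -np.inf
        for _, _, before, after, accepted, _ in self.rows:
            cur = max(cur, before)
            if accepted:
                cur = max(cur, after)
            best.append(cur)
        return best

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.rows,
            columns=[
                "step",
                "proposal",
                "objective_before",
                "objective_after",
                "accepted",
                "temperature",
            ],
        ).to_csv(path, sep="\t", index=False)


class _Engine:
    """Incremental LOO scorer over a fixed-window dataset.

    Keeps the unclamped weighted score of every window against every positive
    and updates it in O(affected entries) under single weight or matrix-entry
    moves, so each annealing proposal costs far less than full rescoring.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        matrix: SubstitutionMatrix,
        weights: Sequence[int],
    ):
        if len(dataset.positives) < 2:
            raise TrainingError("need at least 2 positive sites")
        if not dataset.negatives:
            raise TrainingError("need at least 1 negative site")
        self.L = dataset.window_length
        self.P = np.stack([encode(w.residues) for w in dataset.positives])
        self.Q = np.vstack(
            [self.P, np.stack([encode(w.residues) for w in dataset.negatives])]
        )
        self.n_pos = self.P.shape[0]
        self.n_neg = self.Q.shape[0] - self.n_pos
        self.matrix = matrix.copy()
        self.w = np.asarray(weights, dtype=np.int64).copy()
        if len(self.w) != self.L:
            raise TrainingError("weight vector length does not match window")
        M = self.matrix.array
        # per-position contribution of every (query, positive) pair
        self.contrib = np.empty((self.L, self.Q.shape[0], self.n_pos), dtype=np.int32)
        for i in range(self.L):
            self.contrib[i] = M[self.Q[:, i]][:, self.P[:, i]]
        self.raw = np.tensordot(self.w, self.contrib, axes=1)

    def bump_weight(self, j: int, delta: int) -> None:
        self.w[j] += delta
        self.raw += delta * self.contrib[j]

    def set_weights(self, weights: np.ndarray) -> None:
        self.w = np.asarray(weights, dtype=np.int64).copy()
        self.raw = np.tensordot(self.w, self.contrib, axes=1)

    def bump_matrix(self, a: int, b: int, delta: int) -> None:
        self.matrix.bump(a, b, delta)
        for i in range(self.L):
            rows = np.nonzero(self.Q[:, i] == a)[0]
            if rows.size == 0:
                continue
            cols = np.nonzero(self.P[:, i] == b)[0]
            if cols.size == 0:
                continue
            block = np.ix_(rows, cols)
            self.contrib[i][block] += delta
            if self.w[i]:
                self.raw[block] += delta * self.w[i]

    def loo_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(positive LOO scores, negative scores) under the current state."""
        clamped = np.maximum(self.raw, 0)
        pos_block = clamped[: self.n_pos]
        pos = (pos_block.sum(axis=1) - np.diagonal(pos_block)) / (self.n_pos - 1)
        neg = clamped[self.n_pos :].mean(axis=1)
        return pos, neg

    def objective(self, sp_anchor: float) -> float:
        pos, neg = self.loo_scores()
        return sn_at_sp(pos, neg, sp_anchor)

    def objective_pair(self, sp_anchor: float) -> tuple[float, float]:
        """(Sn at the anchored cutoff, normalized margin) for lexicographic
        comparison.

        The Sn objective is a step function with granularity 1/n_pos, so most
        single +/-1 proposals are exactly lateral.  The secondary margin —
        the positive mean minus the cutoff, divided by the summed score
        spreads — breaks those ties in favour of states that genuinely
        separate the classes; the normalization makes it invariant under
        uniform weight scaling, so it cannot be gamed by inflating all
        weights.
        """
        pos, neg = self.loo_scores()
        cutoff = cutoff_at_specificity(neg, sp_anchor)
        sn = float((pos >= cutoff).mean())
        denom = float(pos.std() + neg.std()) + 1e-9
        margin = float(pos.mean() - cutoff) / denom
        return sn, margin


def loo_objective(
    dataset: LabeledDataset, model: HatModel, sp_anchor: float = 0.90
) -> float:
    """LOO sensitivity at the cutoff anchored at ``sp_anchor`` specificity."""
    engine = _Engine(dataset, model.matrix, model.weights)
    return engine.objective(sp_anchor)


def select_motif_length(
    substrates: Sequence[Substrate],
    annotations: Sequence[SiteAnnotation],
    hat: str,
    config: TrainConfig | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[int, int]:
    """Exhaustively search (m, n) for the window maximizing the LOO objective
    with unit weights; ties break toward smaller m+n, then smaller m."""
    config = config or TrainConfig()
    matrix = matrix or SubstitutionMatrix.blosum62()
    m_lo, m_hi = config.m_range
    n_lo, n_hi = config.n_range
    dataset = build_dataset(substrates, annotations, hat, m_hi, n_hi)
    engine = _Engine(dataset, matrix, np.ones(dataset.window_length, dtype=np.int64))
    # cumulative per-position contributions make any sub-window's raw score a
    # difference of two slices
    cum = np.cumsum(engine.contrib, axis=0)
    center = m_hi  # index of the central lysine in the max window
    n_pos = engine.n_pos

    best: tuple[int, int] | None = None
    best_obj = -np.inf
    for m in range(m_lo, m_hi + 1):
        left = cum[center - m - 1] if m < m_hi else None
        for n in range(n_lo, n_hi + 1):
            raw = cum[center + n] if left is None else cum[center + n] - left
            clamped = np.maximum(raw, 0)
            pos_block = clamped[:n_pos]
            pos = (pos_block.sum(axis=1) - np.diagonal(pos_block)) / (n_pos - 1)
            neg = clamped[n_pos:].mean(axis=1)
            obj = sn_at_sp(pos, neg, config.sp_anchor)
            if best is None or obj > best_obj + _EPS:
                best, best_obj = (m, n), obj
            elif obj > best_obj - _EPS and (m + n, m) < (best[0] + best[1], best[0]):
                best = (m, n)
    assert best is not None
    return best


def _anneal(
    engine: _Engine,
    config: TrainConfig,
    rng: np.random.Generator,
    step: str,
    propose: Callable[[np.random.Generator], tuple | None],
    snapshot: Callable[[], object],
) -> tuple[object, TrainTrace]:
    """Shared annealing loop over single +/-1 proposals.

    ``propose(rng)`` returns (description, apply, revert), or None for a move
    rejected outright (it still counts toward stagnation and cooling).
    ``snapshot()`` captures the state being optimized; the best-seen snapshot
    is returned together with the proposal trace.

    States compare lexicographically as (Sn, margin); the annealing
    acceptance probability for worsening moves uses the Sn difference only.
    The trace logs the primary Sn objective.
    """
    trace = TrainTrace()
    temperature = config.sa_t0
    cur = best = engine.objective_pair(config.sp_anchor)
    best_state = snapshot()
    stagnation = 0
    proposals = 0
    while stagnation < config.max_stagnation and proposals < config.max_proposals:
        proposals += 1
        move = propose(rng)
        if move is None:
            trace.log(step, "rejected-outright", cur[0], cur[0], False, temperature)
            stagnation += 1
            temperature *= config.sa_cooling
            continue
        description, apply, revert = move
        before = cur
        apply()
        new = engine.objective_pair(config.sp_anchor)
        if new > cur:
            accepted = True
        else:
            accepted = rng.random() < np.exp(
                (new[0] - cur[0]) / max(temperature, 1e-300)
            )
        if accepted:
            cur = new
            stagnation = 0
        else:
            revert()
            stagnation += 1
        trace.log(step, description, before[0], new[0], accepted, temperature)
        if cur > best:
            best = cur
            best_state = snapshot()
        temperature *= config.sa_cooling
    return best_state, trace


def train_weights(
    dataset: LabeledDataset,
    model: HatModel,
    config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, TrainTrace]:
    """Anneal the position weights at a fixed window shape and matrix.

    Weights are non-negative integers; a -1 proposal on a zero weight is
    rejected outright.  Returns the best-seen weight vector and the trace.
    """
    config = config or TrainConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    engine = _Engine(dataset, model.matrix, model.weights)
    L = engine.L

    def propose(rng):
        j = int(rng.integers(L))
        delta = 1 if rng.random() < 0.5 else -1
        if delta < 0 and engine.w[j] == 0:
            return None
        return (
            f"w[{j}]{delta:+d}",
            lambda: engine.bump_weight(j, delta),
            lambda: engine.bump_weight(j, -delta),
        )

    best_w, trace = _anneal(
        engine, config, rng, "weights", propose, snapshot=lambda: engine.w.copy()
    )
    return np.asarray(best_w, dtype=np.int64), trace


def mutate_matrix(
    dataset: LabeledDataset,
    model: HatModel,
    config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SubstitutionMatrix, TrainTrace]:
    """Anneal single +/-1 mutations of residue-pair matrix entries.

    Only the 20x20 residue block is mutable; pad/unknown entries stay 0.  The
    matrix may become asymmetric (rows index the query residue).
    """
    config = config or TrainConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    engine = _Engine(dataset, model.matrix, model.weights)

    def propose(rng):
        a = int(rng.integers(N_RESIDUES))
        b = int(rng.integers(N_RESIDUES))
        delta = 1 if rng.random() < 0.5 else -1
        return (
            f"M[{a},{b}]{delta:+d}",
            lambda: engine.bump_matrix(a, b, delta),
            lambda: engine.bump_matrix(a, b, -delta),
        )

    best_matrix, trace = _anneal(
        engine, config, rng, "matrix", propose, snapshot=lambda: engine.matrix.copy()
    )
    return best_matrix, trace


def train_model(
    substrates: Sequence[Substrate],
    annotations: Sequence[SiteAnnotation],
    hat: str,
    config: TrainConfig | None = None,
) -> tuple[HatModel, TrainTrace]:
    """Run the configured training steps and calibrate prediction thresholds.

    Returns the trained model and the concatenated proposal trace.  Refuses
    to train a HAT with fewer than 2 positive sites.
    """
    config = config or TrainConfig()
    n_sites = len({(a.protein_id, a.position) for a in annotations if a.hat == hat})
    if n_sites < 2:
        raise TrainingError(
            f"{hat} has {n_sites} annotated site(s); at least 2 are required"
        )
    matrix = SubstitutionMatrix.blosum62()
    m = max(config.m_range[0], (config.m_range[0] + config.m_range[1]) // 2)
    n = max(config.n_range[0], (config.n_range[0] + config.n_range[1]) // 2)
    weights: np.ndarray | None = None
    dataset: LabeledDataset | None = None
    trace = TrainTrace()
    rng = np.random.default_rng(config.seed)

    def ensure_dataset() -> LabeledDataset:
        nonlocal dataset, weights
        if dataset is None:
            dataset = build_dataset(substrates, annotations, hat, m, n)
        if weights is None:
            weights = np.ones(dataset.window_length, dtype=np.int64)
        return dataset

    for step in config.step_order:
        if step == "length":
            m, n = select_motif_length(substrates, annotations, hat, config, matrix)
            dataset = build_dataset(substrates, annotations, hat, m, n)
            weights = np.ones(dataset.window_length, dtype=np.int64)
            obj = loo_objective(
                dataset,
                HatModel(hat, m, n, matrix, weights, dataset.positives),
                config.sp_anchor,
            )
            trace.log("length", f"(m,n)=({m},{n})", obj, obj, True, np.nan)
        elif step == "weights":
            ds = ensure_dataset()
            model = HatModel(hat, m, n, matrix, weights, ds.positives)
            weights, step_trace = train_weights(ds, model, config, rng)
            trace.extend(step_trace)
        elif step == "matrix":
            ds = ensure_dataset()
            model = HatModel(hat, m, n, matrix, weights, ds.positives)
            matrix, step_trace = mutate_matrix(ds, model, config, rng)
            trace.extend(step_trace)

    ds = ensure_dataset()
    model = HatModel(hat, m, n, matrix, weights, ds.positives)
    scores = score_dataset(ds, model, loo=True)
    report = _assemble_report(hat, "loo", scores)
    model.thresholds = calibrate_thresholds(report)
    return model, trace
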