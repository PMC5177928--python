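"""Peptide-similarity scoring.

The score of a query window against one reference window is the sum over
aligned positions of a substitution-matrix entry, optionally multiplied by a
per-position integer weight; a negative sum is clamped to zero.  The model
score of a query is the arithmetic mean of its (weighted, clamped) similarity
to every positive training peptide of the enzyme — with the query's own
peptide withheld during leave-one-out validation.

The substitution matrix starts as BLOSUM62 and may become asymmetric during
training: the query residue indexes rows, the training-peptide residue
indexes columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import alphabet
from .alphabet import N_RESIDUES, N_SYMBOLS, encode
from .dataset import LabeledDataset, SiteWindow


class ScoringError(ValueError):
    """Raised for shape mismatches or degenerate scoring inputs."""


class SubstitutionMatrix:
    """Integer substitution scores over the 22-symbol working alphabet.

    Rows index the query residue, columns the training-peptide residue; the
    reserved pad and unknown symbols score 0 against everything and are not
    mutable during training.
    """

    def __init__(self, array: np.ndarray):
        array = np.asarray(array, dtype=np.int32)
        if array.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ScoringError(
                f"matrix must be {N_SYMBOLS}x{N_SYMBOLS}, got {array.shape}"
            )
        self.array = array

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """The published BLOSUM62 scores, with pad/unknown rows zeroed."""
        src = substitution_matrices.load("BLOSUM62")
        arr = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.int32)
        for i, a in enumerate(alphabet.RESIDUES):
            for j, b in enumerate(alphabet.RESIDUES):
                arr[i, j] = int(src[a, b])
        return cls(arr)

    @classmethod
    def zeros(cls) -> "SubstitutionMatrix":
        return cls(np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.int32))

    def copy(self) -> "SubstitutionMatrix":
        return SubstitutionMatrix(self.array.copy())

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.array[alphabet.index_of(a), alphabet.index_of(b)])

    def bump(self, a: str | int, b: str | int, delta: int) -> None:
        """Add ``delta`` to one residue-pair entry (reserved symbols immutable)."""
        i = a if isinstance(a, (int, np.integer)) else alphabet.index_of(a)
        j = b if isinstance(b, (int, np.integer)) else alphabet.index_of(b)
        if i >= N_RESIDUES or j >= N_RESIDUES:
            raise ScoringError("pad/unknown entries are fixed at 0")
        self.array[i, j] += delta

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SubstitutionMatrix) and np.array_equal(
            self.array, other.array
        )

    def to_list(self) -> list[list[int]]:
        return self.array.tolist()

    @classmethod
    def from_list(cls, rows: list[list[int]]) -> "SubstitutionMatrix":
        return cls(np.asarray(rows, dtype=np.int32))


def _residues(window: SiteWindow | str) -> str:
    return window.residues if isinstance(window, SiteWindow) else window


def peptide_similarity(
    a: SiteWindow | str, b: SiteWindow | str, matrix: SubstitutionMatrix
) -> int:
    """Unweighted similarity of two equal-length windows, clamped at zero."""
    ra, rb = _residues(a), _residues(b)
    if len(ra) != len(rb):
        raise ScoringError(f"window lengths differ: {len(ra)} vs {len(rb)}")
    total = int(matrix.array[encode(ra), encode(rb)].sum())
    return max(0, total)


def weighted_similarity(
    a: SiteWindow | str,
    b: SiteWindow | str,
    matrix: SubstitutionMatrix,
    weights: Sequence[int],
) -> int:
    """Position-weighted similarity; the weighted sum is clamped at zero."""
    ra, rb = _residues(a), _residues(b)
    w = np.asarray(weights)
    if len(ra) != len(rb) or len(w) != len(ra):
        raise ScoringError(
            f"lengths disagree: windows {len(ra)}/{len(rb)}, weights {len(w)}"
        )
    if (w < 0).any():
        raise ScoringError("weights must be non-negative")
    total = int((w * matrix.array[encode(ra), encode(rb)]).sum())
    return max(0, total)


def pairwise_scores(
    queries: Sequence[SiteWindow | str],
    references: Sequence[SiteWindow | str],
    matrix: SubstitutionMatrix,
    weights: Sequence[int],
) -> np.ndarray:
    """Clamped weighted similarity of every query against every reference.

    Returns an integer array of shape (n_queries, n_references).
    """
    if not queries or not references:
        return np.zeros((len(queries), len(references)), dtype=np.int64)
    Q = np.stack([encode(_residues(q)) for q in queries])
    R = np.stack([encode(_residues(r)) for r in references])
    if Q.shape[1] != R.shape[1]:
        raise ScoringError("query and reference window lengths differ")
    w = np.asarray(weights, dtype=np.int64)
    if len(w) != Q.shape[1]:
        raise ScoringError("weight vector length does not match window length")
    if (w < 0).any():
        raise ScoringError("weights must be non-negative")
    raw = np.zeros((len(queries), len(references)), dtype=np.int64)
    M = matrix.array
    for i in range(Q.shape[1]):
        if w[i] == 0:
            continue
        raw += w[i] * M[Q[:, i]][:, R[:, i]]
    return np.maximum(raw, 0)


@dataclass
class HatModel:
    """A trained per-enzyme model: window shape, matrix, weights, references.

    ``thresholds`` maps tier names (high/medium/low) to score cutoffs
    calibrated at leave-one-out specificities of ~0.95/0.90/0.85.
    """

    hat: str
    m: int
    n: int
    matrix: SubstitutionMatrix
    weights: np.ndarray
    positives: list[SiteWindow]
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int64)
        length = self.m + 1 + self.n
        if len(self.weights) != length:
            raise ScoringError("weight vector length does not match (m, n)")
        for p in self.positives:
            if len(p) != length:
                raise ScoringError("positive peptide length does not match (m, n)")
        tiers = self.thresholds
        if tiers and not (
            tiers.get("high", np.inf)
            >= tiers.get("medium", -np.inf)
            >= tiers.get("low", -np.inf)
        ):
            raise ScoringError("thresholds must satisfy high >= medium >= low")

    @property
    def window_length(self) -> int:
        return self.m + 1 + self.n

    def cutoff(self, tier: str) -> float:
        """Score cutoff for a tier; the permissive 'all' tier is cutoff 0."""
        if tier == "all":
            return 0.0
        try:
            return self.thresholds[tier]
        except KeyError:
            raise ScoringError(
                f"model {self.hat} has no calibrated {tier!r} threshold"
            ) from None

    def to_json(self) -> str:
        payload = {
            "hat": self.hat,
            "m": self.m,
            "n": self.n,
            "matrix": self.matrix.to_list(),
            "weights": self.weights.tolist(),
            "positives": [
                {"window": p.residues, "protein_id": p.origin[0], "position": p.origin[1]}
                for p in self.positives
            ],
            "thresholds": self.thresholds,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HatModel":
        payload = json.loads(text)
        positives = [
            SiteWindow(
                residues=p["window"],
                center_index=payload["m"],
                origin=(p["protein_id"], p["position"]),
                label="positive",
            )
            for p in payload["positives"]
        ]
        return cls(
            hat=payload["hat"],
            m=payload["m"],
            n=payload["n"],
            matrix=SubstitutionMatrix.from_list(payload["matrix"]),
            weights=np.asarray(payload["weights"], dtype=np.int64),
            positives=positives,
            thresholds={k: float(v) for k, v in payload["thresholds"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "HatModel":
        return cls.from_json(Path(path).read_text())


def model_score(
    query: SiteWindow | str,
    model: HatModel,
    exclude: tuple[str, int] | None = None,
) -> float:
    """Mean weighted similarity of a query to the model's positive peptides.

    ``exclude`` withholds the positive whose (protein_id, position) origin
    matches — leave-one-out semantics keyed on identity, not on sequence.
    """
    references = [
        p for p in model.positives if exclude is None or p.origin != exclude
    ]
    if not references:
        raise ScoringError("no reference peptides left after exclusion")
    scores = pairwise_scores([query], references, model.matrix, model.weights)
    return float(scores.mean())


def score_dataset(dataset: LabeledDataset, model: HatModel, loo: bool = False):
    """Score every window of a dataset against a model.

    With ``loo=True`` each positive is scored against the remaining positives
    only; negatives are always scored against all positives.  Returns a
    pandas DataFrame with columns protein_id, position, label, score.
    """
    import pandas as pd

    if (dataset.m, dataset.n) != (model.m, model.n):
        raise ScoringError(
            f"dataset window ({dataset.m},{dataset.n}) does not match "
            f"model ({model.m},{model.n})"
        )
    n_ref = len(model.positives)
    if n_ref == 0 or (loo and n_ref < 2):
        raise ScoringError("too few positive reference peptides")
    rows = []
    pos_scores = pairwise_scores(
        dataset.positives, model.positives, model.matrix, model.weights
    ).astype(float)
    ref_origins = [p.origin for p in model.positives]
    for i, window in enumerate(dataset.positives):
        row = pos_scores[i]
        if loo:
            keep = [j for j, o in enumerate(ref_origins) if o != window.origin]
            if not keep:
                raise ScoringError("no reference peptides left after exclusion")
            score = row[keep].mean()
        else:
            score = row.mean()
        rows.append((*window.origin, "positive", float(score)))
    if dataset.negatives:
        neg_scores = pairwise_scores(
            dataset.negatives, model.positives, model.matrix, model.weights
        ).astype(float)
        for i, window in enumerate(dataset.negatives):
            rows.append((*window.origin, "negative", float(neg_scores[i].mean())))
    return pd.DataFrame(rows, columns=["protein_id", "position", "label", "score"])
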