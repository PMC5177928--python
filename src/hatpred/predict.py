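"""Apply trained models to sequences and acetylome site tables.

Prediction is tiered: the high/medium/low cutoffs of each model were
calibrated at LOO specificities of ~0.95/0.90/0.85, and the permissive
``all`` tier reports a score for every lysine with no stringency.  For
large-scale annotation of an acetylome the default mode scores only the
lysines listed in the site table — scanning whole proteomes ab initio
produces far too many false positives to be useful.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dataset import SiteAnnotation, Substrate, extract_window, lysine_positions
from .scoring import HatModel, model_score

TIERS = ("high", "medium", "low", "all")


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class Prediction:
    protein_id: str
    position: int
    window: str
    hat: str
    score: float
    tier: str


@dataclass
class AcetylomeSummary:
    """Counting summary of a large-scale annotation run."""

    n_sites_input: int = 0
    n_sites_annotated: int = 0
    n_proteins_input: int = 0
    n_proteins_annotated: int = 0
    hats_per_site: Counter = field(default_factory=Counter)
    hats_per_protein: Counter = field(default_factory=Counter)
    pairwise_site_overlap: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def site_coverage(self) -> float:
        return self.n_sites_annotated / self.n_sites_input if self.n_sites_input else 0.0

    def hats_per_site_fractions(self) -> dict[int, float]:
        total = sum(self.hats_per_site.values())
        return {k: v / total for k, v in sorted(self.hats_per_site.items())}

    def hats_per_protein_fractions(self) -> dict[int, float]:
        total = sum(self.hats_per_protein.values())
        return {k: v / total for k, v in sorted(self.hats_per_protein.items())}


def predict_protein(
    substrate: Substrate,
    models: Sequence[HatModel],
    tier: str = "medium",
) -> list[Prediction]:
    """Score every lysine of a substrate with every model; keep records whose
    score reaches the tier cutoff.  A sequence without lysines yields []."""
    if tier not in TIERS:
        raise PredictionError(f"tier must be one of {TIERS}, got {tier!r}")
    records: list[Prediction] = []
    for position in lysine_positions(substrate):
        for model in models:
            window = extract_window(substrate, position, model.m, model.n)
            score = model_score(window, model)
            if score >= model.cutoff(tier):
                records.append(
                    Prediction(
                        protein_id=substrate.id,
                        position=position,
                        window=window.residues,
                        hat=model.hat,
                        score=score,
                        tier=tier,
                    )
                )
    return records


def annotate_acetylome(
    site_table: Sequence[SiteAnnotation],
    substrates: Sequence[Substrate],
    models: Sequence[HatModel],
    tier: str = "high",
) -> tuple[list[Prediction], AcetylomeSummary]:
    """Assign candidate HATs to experimentally identified acetylation sites.

    Only the lysines listed in the site table are scored.  Rows pointing at a
    non-lysine residue are skipped with a warning.  Returns the per-site
    predictions and a counting summary (HATs-per-site distribution, pairwise
    overlaps).
    """
    if tier not in TIERS:
        raise PredictionError(f"tier must be one of {TIERS}, got {tier!r}")
    by_id = {s.id: s for s in substrates}
    sites = sorted({(a.protein_id, a.position) for a in site_table})
    predictions: list[Prediction] = []
    site_hats: dict[tuple[str, int], set[str]] = {}
    n_valid = 0
    for protein_id, position in sites:
        substrate = by_id.get(protein_id)
        if substrate is None:
            warnings.warn(f"site {protein_id}:{position} has no sequence; skipped")
            continue
        if (
            not 1 <= position <= len(substrate.sequence)
            or substrate.sequence[position - 1] != "K"
        ):
            warnings.warn(
                f"site {protein_id}:{position} is not a lysine in the given "
                "sequence; skipped"
            )
            continue
        n_valid += 1
        hits: set[str] = set()
        for model in models:
            window = extract_window(substrate, position, model.m, model.n)
            score = model_score(window, model)
            if score >= model.cutoff(tier):
                hits.add(model.hat)
                predictions.append(
                    Prediction(
                        protein_id=protein_id,
                        position=position,
                        window=window.residues,
                        hat=model.hat,
                        score=score,
                        tier=tier,
                    )
                )
        if hits:
            site_hats[(protein_id, position)] = hits

    summary = AcetylomeSummary(
        n_sites_input=n_valid,
        n_sites_annotated=len(site_hats),
        n_proteins_input=len({p for p, _ in sites if p in by_id}),
        n_proteins_annotated=len({p for (p, _) in site_hats}),
    )
    summary.hats_per_site.update(len(h) for h in site_hats.values())
    protein_hats: dict[str, set[str]] = {}
    for (protein_id, _), hats in site_hats.items():
        protein_hats.setdefault(protein_id, set()).update(hats)
    summary.hats_per_protein.update(len(h) for h in protein_hats.values())
    all_hats = sorted({m.hat for m in models})
    for a, b in combinations(all_hats, 2):
        summary.pairwise_site_overlap[(a, b)] = sum(
            1 for hats in site_hats.values() if a in hats and b in hats
        )
    return predictions, summary


def restrict_models_by_orthology(
    models: Sequence[HatModel], presence: "OrthologPresence | dict[str, bool]"
) -> list[HatModel]:
    """Keep only models whose HAT has a detected ortholog in the target
    species.  An empty selection is an error — there is nothing to predict."""
    flags = presence.present if hasattr(presence, "present") else presence
    kept = [m for m in models if flags.get(m.hat, False)]
    if not kept:
        raise PredictionError("no models remain after the orthology restriction")
    return kept


def write_predictions_tsv(predictions: Iterable[Prediction], path: str | Path) -> None:
    """TSV report: protein_id, position, hat, score (3 decimals), tier, window."""
    rows = [
        (p.protein_id, p.position, p.hat, f"{p.score:.3f}", p.tier, p.window)
        for p in predictions
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "position", "hat", "score", "tier", "window"]
    ).to_csv(path, sep="\t", index=False)
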