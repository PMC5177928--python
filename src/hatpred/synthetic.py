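"""Synthetic substrate sequences with planted position-specific motif signal.

The generator emulates the structure of a curated HAT-site table: substrate
proteins with annotated acetyl-lysines whose flanking residues carry a
controlled enrichment at chosen offsets (for example G at -1 and S at +1 in
the CREBBP-like preset, or lysines at +3..+5), over an i.i.d. background.
Every other lysine that occurs by chance in the background is a natural
negative, matching the labeling convention of the dataset module.

This is a statistical test harness, not a biological simulator: it plants a
single independent-position motif per enzyme and ignores protein structure,
disorder and compositional correlations of real proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .dataset import (
    SiteAnnotation,
    Substrate,
    read_fasta,
    read_site_table,
    write_fasta,
    write_site_table,
)

#: Enrichment probability of the target residue at an informative offset.
#: "clean" is a strong motif (well above the ~5% background frequency of any
#: residue but far from deterministic, as in real site logos); "weak" sits
#: near the detection limit of a study this size.
EFFECT_PROBABILITY = {"clean": 0.6, "weak": 0.4, "null": 0.0}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate SwissProt amino-acid frequencies (order of AA20).
SWISSPROT_FREQUENCIES = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0473, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

_PRESETS: dict[str, tuple[str, dict[int, str]]] = {
    # preset -> (hat name, informative offset -> enriched residue)
    "crebbp-like": ("CREBBP", {-1: "G", 1: "S", 3: "K", 4: "K", 5: "K"}),
    "ep300-like": ("EP300", {-1: "A", 1: "K", 3: "K", 4: "K", 5: "K"}),
    "kat2b-like": ("KAT2B", {-2: "G", -4: "G"}),
    "null": ("CREBBP", {}),
}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """Ground truth for one planted motif.

    ``informative_positions`` maps a window offset (negative = upstream,
    positive = downstream; 0 is the central lysine and is reserved) to the
    enriched residue and its enrichment probability; everywhere else residues
    follow ``background``.
    """

    hat_name: str
    informative_positions: Mapping[int, tuple[str, float]]
    background: Mapping[str, float]
    effect: str = "clean"

    def __post_init__(self) -> None:
        if 0 in self.informative_positions:
            raise SyntheticError("offset 0 is reserved for the central lysine")
        for offset, (residue, prob) in self.informative_positions.items():
            if residue not in AA20:
                raise SyntheticError(f"invalid residue {residue!r} at offset {offset}")
            if not 0 <= prob <= 1:
                raise SyntheticError(f"enrichment probability {prob} outside [0, 1]")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticError(f"background frequencies sum to {total}, not 1")

    def to_dict(self) -> dict:
        return {
            "hat_name": self.hat_name,
            "informative_positions": {
                str(k): list(v) for k, v in self.informative_positions.items()
            },
            "background": dict(self.background),
            "effect": self.effect,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MotifSpec":
        return cls(
            hat_name=payload["hat_name"],
            informative_positions={
                int(k): (v[0], float(v[1]))
                for k, v in payload["informative_positions"].items()
            },
            background=payload["background"],
            effect=payload.get("effect", "clean"),
        )


@dataclass
class SyntheticStudy:
    """A generated study: substrates, annotations and the ground truth."""

    substrates: list[Substrate]
    annotations: list[SiteAnnotation]
    truth: MotifSpec
    seed: int
    planted_sites: list[tuple[str, int]] = field(default_factory=list)


def make_motif_spec(
    preset: str, effect: str = "clean", background: str = "uniform"
) -> MotifSpec:
    """Build a preset motif spec.

    Presets: crebbp-like, ep300-like, kat2b-like, null.  ``effect`` sets the
    enrichment probability at informative offsets (clean=0.6, weak=0.4);
    ``background`` is 'uniform' or 'swissprot'.
    """
    if preset not in _PRESETS:
        raise SyntheticError(
            f"unknown preset {preset!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    if effect not in EFFECT_PROBABILITY:
        raise SyntheticError(
            f"unknown effect {effect!r}; available: {', '.join(EFFECT_PROBABILITY)}"
        )
    hat, offsets = _PRESETS[preset]
    prob = EFFECT_PROBABILITY["null" if preset == "null" else effect]
    informative = {} if preset == "null" else {o: (r, prob) for o, r in offsets.items()}
    if background == "uniform":
        freqs = {aa: 1.0 / 20.0 for aa in AA20}
    elif background == "swissprot":
        total = sum(SWISSPROT_FREQUENCIES.values())
        freqs = {aa: f / total for aa, f in SWISSPROT_FREQUENCIES.items()}
    else:
        raise SyntheticError("background must be 'uniform' or 'swissprot'")
    return MotifSpec(
        hat_name=hat,
        informative_positions=informative,
        background=freqs,
        effect="null" if preset == "null" else effect,
    )


#: Sites are planted at least this far apart so window labels stay unambiguous
#: up to the maximal (30, 30) window.
MIN_SITE_SPACING = 61


def sample_study(
    spec: MotifSpec,
    n_substrates: int = 60,
    sites_per_substrate: int = 3,
    seq_len: int = 300,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate substrates with planted sites; deterministic given the seed.

    Each substrate is split into ``sites_per_substrate`` equal blocks and one
    site is planted per block with a 30-residue margin, which keeps planted
    sites at least a maximal window apart.
    """
    block = seq_len // sites_per_substrate
    if block < MIN_SITE_SPACING + 1:
        raise SyntheticError(
            f"seq_len={seq_len} cannot host {sites_per_substrate} sites with "
            f"full windows; need at least {(MIN_SITE_SPACING + 1) * sites_per_substrate}"
        )
    rng = np.random.default_rng(seed)
    residues = np.array(list(AA20))
    probs = np.array([spec.background[aa] for aa in AA20])

    substrates: list[Substrate] = []
    annotations: list[SiteAnnotation] = []
    planted: list[tuple[str, int]] = []
    for s in range(n_substrates):
        protein_id = f"SYN{s:04d}"
        seq = rng.choice(residues, size=seq_len, p=probs)
        for b in range(sites_per_substrate):
            lo = b * block + 30
            hi = (b + 1) * block - 31
            center = int(rng.integers(lo, hi + 1))  # 0-based
            seq[center] = "K"
            for offset, (residue, prob) in spec.informative_positions.items():
                idx = center + offset
                if 0 <= idx < seq_len and rng.random() < prob:
                    seq[idx] = residue
            position = center + 1
            annotations.append(
                SiteAnnotation(
                    protein_id=protein_id,
                    position=position,
                    hat=spec.hat_name,
                    species_tag="synthetic",
                )
            )
            planted.append((protein_id, position))
        substrates.append(Substrate(id=protein_id, sequence="".join(seq)))
    return SyntheticStudy(
        substrates=substrates,
        annotations=annotations,
        truth=spec,
        seed=seed,
        planted_sites=planted,
    )


def shuffle_labels(study: SyntheticStudy, seed: int) -> SyntheticStudy:
    """Permutation control: move each annotation to a random lysine of the
    same substrate, destroying any association between motif and label."""
    rng = np.random.default_rng(seed)
    by_id = {s.id: s for s in study.substrates}
    new_annotations: list[SiteAnnotation] = []
    per_protein: dict[str, list[SiteAnnotation]] = {}
    for ann in study.annotations:
        per_protein.setdefault(ann.protein_id, []).append(ann)
    for protein_id, anns in per_protein.items():
        lysines = [
            i + 1 for i, ch in enumerate(by_id[protein_id].sequence) if ch == "K"
        ]
        chosen = rng.choice(len(lysines), size=len(anns), replace=False)
        for ann, pick in zip(anns, chosen):
            new_annotations.append(
                SiteAnnotation(
                    protein_id=protein_id,
                    position=lysines[int(pick)],
                    hat=ann.hat,
                    species_tag=ann.species_tag,
                )
            )
    return SyntheticStudy(
        substrates=study.substrates,
        annotations=new_annotations,
        truth=study.truth,
        seed=seed,
        planted_sites=study.planted_sites,
    )


def write_fixture(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write substrates.fa, sites.tsv and truth.json; round-trips losslessly
    through the dataset readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "substrates.fa",
        "sites": directory / "sites.tsv",
        "truth": directory / "truth.json",
    }
    write_fasta(study.substrates, paths["fasta"])
    write_site_table(study.annotations, paths["sites"])
    paths["truth"].write_text(
        json.dumps({"seed": study.seed, "spec": study.truth.to_dict()}, indent=1)
    )
    return paths


def read_fixture(directory: str | Path) -> SyntheticStudy:
    directory = Path(directory)
    truth = json.loads((directory / "truth.json").read_text())
    return SyntheticStudy(
        substrates=read_fasta(directory / "substrates.fa"),
        annotations=read_site_table(directory / "sites.tsv"),
        truth=MotifSpec.from_dict(truth["spec"]),
        seed=int(truth["seed"]),
    )
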