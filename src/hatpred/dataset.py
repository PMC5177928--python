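"""Substrate sequences, site annotations and labeled peptide datasets.

A *site window* is a peptide of ``m`` residues upstream and ``n`` residues
downstream of a central lysine; windows overhanging a terminus are padded
with ``*``.  For a given acetyltransferase (HAT), its annotated lysines in a
substrate are the positive examples and every other lysine in the same
substrate proteins is a negative example — including lysines annotated only
for a *different* HAT, since per-enzyme annotation is the only label
available.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import PAD

#: Canonical gene names of the seven modeled acetyltransferases.
HATS = ("CREBBP", "EP300", "HAT1", "KAT2A", "KAT2B", "KAT5", "KAT8")

#: Common aliases mapped to canonical names, used only for error messages.
HAT_ALIASES = {
    "CBP": "CREBBP",
    "P300": "EP300",
    "KAT3A": "CREBBP",
    "KAT3B": "EP300",
    "KAT1": "HAT1",
    "GCN5": "KAT2A",
    "GCN5L2": "KAT2A",
    "PCAF": "KAT2B",
    "TIP60": "KAT5",
    "HTATIP": "KAT5",
    "ESA1": "KAT5",
    "MOF": "KAT8",
    "MYST1": "KAT8",
}

SITE_TABLE_COLUMNS = ("protein_id", "position", "hat", "species")


class DatasetError(ValueError):
    """Raised for malformed inputs or degenerate datasets."""


@dataclass(frozen=True)
class Substrate:
    """A protein sequence keyed by its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatasetError(f"substrate {self.id!r} has an empty sequence")

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise DatasetError(
                f"position {position} outside {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated acetylation site: protein, 1-based lysine position, HAT."""

    protein_id: str
    position: int
    hat: str
    species_tag: str = ""


@dataclass(frozen=True)
class SiteWindow:
    """An extracted peptide window centred on a lysine."""

    residues: str
    center_index: int
    origin: tuple[str, int]
    label: str = "positive"

    def __post_init__(self) -> None:
        if not 0 <= self.center_index < len(self.residues):
            raise DatasetError("center index outside window")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Positive and negative windows for one HAT at a fixed window shape."""

    hat: str
    m: int
    n: int
    positives: list[SiteWindow] = field(default_factory=list)
    negatives: list[SiteWindow] = field(default_factory=list)

    @property
    def window_length(self) -> int:
        return self.m + 1 + self.n


def _validate_fasta_text(text: str) -> None:
    """Light structural validation so errors carry a line number."""
    saw_record = False
    header_line = None
    body_count = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and body_count == 0:
                raise DatasetError(f"FASTA record with no sequence at line {header_line}")
            if stripped == ">":
                raise DatasetError(f"empty FASTA header at line {lineno}")
            header_line = lineno
            body_count = 0
            saw_record = True
        else:
            if not saw_record:
                raise DatasetError(f"sequence before any FASTA header at line {lineno}")
            body_count += 1
    if header_line is not None and body_count == 0:
        raise DatasetError(f"FASTA record with no sequence at line {header_line}")
    if not saw_record:
        raise DatasetError("no FASTA records found")


def read_fasta(path: str | Path) -> list[Substrate]:
    """Read substrates from a FASTA file.

    Sequences are uppercased and ``*`` stop symbols stripped.  Structural
    problems (empty records, stray sequence lines) raise :class:`DatasetError`
    naming the offending line.
    """
    text = Path(path).read_text()
    _validate_fasta_text(text)
    substrates = []
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(record.seq).upper().replace("*", "")
        substrates.append(Substrate(id=record.id, sequence=seq))
    return substrates


def write_fasta(substrates: Iterable[Substrate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sub in substrates:
            fh.write(f">{sub.id}\n")
            for start in range(0, len(sub.sequence), 60):
                fh.write(sub.sequence[start : start + 60] + "\n")


def read_site_table(path: str | Path) -> list[SiteAnnotation]:
    """Read a tab-separated site annotation table.

    Columns: ``protein_id  position  hat  species``.  Duplicate
    (protein, position, hat) rows collapse to one; positions are 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_TABLE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise DatasetError(f"site table missing columns {missing} in {path}")
    if "species" not in df.columns:
        df["species"] = ""
    annotations: list[SiteAnnotation] = []
    seen: set[tuple[str, int, str]] = set()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            position = int(row.position)
        except (TypeError, ValueError):
            raise DatasetError(
                f"row {row_num}: position {row.position!r} is not an integer"
            ) from None
        if position < 1:
            raise DatasetError(f"row {row_num}: position must be 1-based, got {position}")
        hat = str(row.hat).strip()
        if hat not in HATS:
            hint = ""
            canonical = HAT_ALIASES.get(hat.upper())
            if canonical:
                hint = f"; did you mean {canonical}?"
            raise DatasetError(
                f"row {row_num}: unknown HAT {hat!r} (expected one of {', '.join(HATS)}){hint}"
            )
        key = (str(row.protein_id), position, hat)
        if key in seen:
            continue
        seen.add(key)
        species = "" if pd.isna(row.species) else str(row.species)
        annotations.append(
            SiteAnnotation(
                protein_id=str(row.protein_id),
                position=position,
                hat=hat,
                species_tag=species,
            )
        )
    return annotations


def write_site_table(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    rows = [
        (a.protein_id, a.position, a.hat, a.species_tag) for a in annotations
    ]
    pd.DataFrame(rows, columns=list(SITE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def extract_window(
    substrate: Substrate, position: int, m: int, n: int, label: str = "positive"
) -> SiteWindow:
    """Extract the length ``m+1+n`` window centred on a 1-based lysine position.

    Positions falling outside the sequence are filled with the ``*`` pad.
    """
    center = substrate.residue(position)
    if center != "K":
        raise DatasetError(
            f"residue at {substrate.id}:{position} is {center!r}, expected 'K'"
        )
    seq = substrate.sequence
    idx = position - 1
    left = seq[max(0, idx - m) : idx]
    right = seq[idx + 1 : idx + 1 + n]
    residues = PAD * (m - len(left)) + left + "K" + right + PAD * (n - len(right))
    return SiteWindow(
        residues=residues,
        center_index=m,
        origin=(substrate.id, position),
        label=label,
    )


def lysine_positions(substrate: Substrate) -> list[int]:
    """All 1-based lysine positions of a substrate."""
    return [i + 1 for i, ch in enumerate(substrate.sequence) if ch == "K"]


def build_dataset(
    substrates: Sequence[Substrate],
    annotations: Sequence[SiteAnnotation],
    hat: str,
    m: int,
    n: int,
) -> LabeledDataset:
    """Assemble the labeled dataset for one HAT.

    Positives are windows at this HAT's annotated positions; negatives are
    windows at every other lysine of the same substrate proteins.  The result
    is deterministic: windows are sorted by (protein_id, position).
    """
    if hat not in HATS:
        raise DatasetError(f"unknown HAT {hat!r}")
    by_id = {s.id: s for s in substrates}
    site_positions: dict[str, set[int]] = {}
    for ann in annotations:
        if ann.hat != hat:
            continue
        if ann.protein_id not in by_id:
            raise DatasetError(f"annotation references unknown protein {ann.protein_id!r}")
        site_positions.setdefault(ann.protein_id, set()).add(ann.position)
    if not site_positions:
        raise DatasetError(f"no annotated sites for {hat}: cannot build dataset")

    dataset = LabeledDataset(hat=hat, m=m, n=n)
    for protein_id in sorted(site_positions):
        substrate = by_id[protein_id]
        positives = site_positions[protein_id]
        for position in sorted(positives):
            dataset.positives.append(
                extract_window(substrate, position, m, n, label="positive")
            )
        for position in lysine_positions(substrate):
            if position in positives:
                continue
            dataset.negatives.append(
                extract_window(substrate, position, m, n, label="negative")
            )
    return dataset


def write_dataset_tsv(dataset: LabeledDataset, path: str | Path) -> None:
    """Dump a dataset as TSV: ``hat  protein_id  position  label  window``."""
    rows = [
        (dataset.hat, w.origin[0], w.origin[1], w.label, w.residues)
        for w in dataset.positives + dataset.negatives
    ]
    pd.DataFrame(
        rows, columns=["hat", "protein_id", "position", "label", "window"]
    ).to_csv(path, sep="\t", index=False)
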