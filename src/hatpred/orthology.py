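"""Reciprocal-best-hit (RBH) ortholog detection from similarity-search hits.

Two proteins in different species are called orthologs when each is the
other's best hit.  The similarity search itself (BLAST or equivalent) is
external; this module consumes its 12-column tabular output (outfmt 6:
query, subject, %identity, length, mismatches, gap opens, qstart, qend,
sstart, send, evalue, bitscore).  The best hit of a query is the subject
with the highest bitscore; ties break by lower e-value, then lexicographic
subject id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dataset import HATS


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise OrthologyError("e-value must be non-negative")


@dataclass
class OrthologPresence:
    """Per-species presence flags (and ortholog ids) for the seven HATs."""

    species: str
    present: dict[str, bool] = field(default_factory=dict)
    ortholog_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.present) - set(HATS)
        if unknown:
            raise OrthologyError(f"unknown HAT names {sorted(unknown)}")


OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_hit_table(path: str | Path, max_evalue: float | None = None) -> list[HitRecord]:
    """Read a 12-column BLAST-tabular hit file; optionally filter by e-value."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    if max_evalue is not None:
        df = df[df["evalue"] <= max_evalue]
    return [
        HitRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            bitscore=float(r.bitscore),
            evalue=float(r.evalue),
        )
        for r in df.itertuples(index=False)
    ]


def best_hits(table: Iterable[HitRecord]) -> dict[str, str]:
    """Best subject per query: highest bitscore, then lowest e-value, then
    lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for hit in table:
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    a_to_b: Iterable[HitRecord], b_to_a: Iterable[HitRecord]
) -> list[tuple[str, str]]:
    """Pairs (x, y) with best(x -> B) = y and best(y -> A) = x, sorted."""
    fwd = best_hits(a_to_b)
    rev = best_hits(b_to_a)
    return sorted((x, y) for x, y in fwd.items() if rev.get(y) == x)


def detect_hat_presence(
    rbh_pairs: Sequence[tuple[str, str]],
    hat_ids_in_reference: Mapping[str, str],
    species: str = "",
) -> OrthologPresence:
    """Mark each HAT present iff its reference protein id occurs in an RBH
    pair; records the partner id of present HATs."""
    by_ref = {ref_id: hat for hat, ref_id in hat_ids_in_reference.items()}
    presence = OrthologPresence(
        species=species, present={hat: False for hat in hat_ids_in_reference}
    )
    for a_id, b_id in rbh_pairs:
        hat = by_ref.get(a_id)
        if hat is not None:
            presence.present[hat] = True
            presence.ortholog_ids[hat] = b_id
    return presence


def write_presence_tsv(presences: Iterable[OrthologPresence], path: str | Path) -> None:
    rows = [
        (p.species, hat, int(flag), p.ortholog_ids.get(hat, ""))
        for p in presences
        for hat, flag in sorted(p.present.items())
    ]
    pd.DataFrame(rows, columns=["species", "hat", "present", "ortholog_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_presence_tsv(path: str | Path) -> dict[str, OrthologPresence]:
    df = pd.read_csv(path, sep="\t", dtype={"present": int})
    out: dict[str, OrthologPresence] = {}
    for species, group in df.groupby("species"):
        presence = OrthologPresence(species=str(species))
        for r in group.itertuples(index=False):
            presence.present[str(r.hat)] = bool(r.present)
            if r.present and isinstance(r.ortholog_id, str) and r.ortholog_id:
                presence.ortholog_ids[str(r.hat)] = r.ortholog_id
        out[str(species)] = presence
    return out
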