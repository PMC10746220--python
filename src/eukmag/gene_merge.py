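"""Per-locus reconciliation of ab initio and protein-evidence exon structures.

For each gene locus two exon tracks are available: an ab initio prediction
and a protein-evidence (alignment-backed) prediction.  When the two tracks
agree on exon count to at least 70% (min/max ratio), interior ab initio
exons with no corresponding evidence exon are deleted — the first and last
ab initio exons of the locus are always protected — and evidence-only
exons are added.  Below the agreement threshold only the additive step
runs (strict mode disables even that).  "Correspondence" between two exons
means same-strand coordinate overlap of at least ``min_overlap`` bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

DEFAULT_AGREEMENT_MIN = 0.70

AB_INITIO = "AB_INITIO"
EVIDENCE = "EVIDENCE"


@dataclass(frozen=True)
class Exon:
    contig: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    strand: str
    source: str = AB_INITIO

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneLocus:
    locus_id: str
    ab_exons: list[Exon] = field(default_factory=list)
    ev_exons: list[Exon] = field(default_factory=list)

    def __post_init__(self) -> None:
        for track in (self.ab_exons, self.ev_exons):
            _check_track(self.locus_id, track)
        everything = self.ab_exons + self.ev_exons
        if everything:
            contigs = {e.contig for e in everything}
            strands = {e.strand for e in everything}
            if len(contigs) > 1 or len(strands) > 1:
                raise ValueError(
                    f"locus {self.locus_id}: exons span multiple contigs/strands"
                )


def _check_track(locus_id: str, exons: Sequence[Exon]) -> None:
    for prev, cur in zip(exons, exons[1:]):
        if cur.start <= prev.end:
            raise ValueError(
                f"locus {locus_id}: track exons overlap or are unsorted "
                f"([{prev.start},{prev.end}] then [{cur.start},{cur.end}])"
            )


@dataclass
class MergedLocus:
    locus_id: str
    exons: list[Exon]
    provenance: list[str]
    agreement_ratio: float | None  # None when no evidence exons existed

    def __post_init__(self) -> None:
        if len(self.exons) != len(self.provenance):
            raise ValueError("provenance length must equal exon count")


def exon_correspondence(a: Exon, b: Exon, min_overlap: int = 1) -> bool:
    """True iff the two exons lie on the same strand and their intervals
    overlap by at least ``min_overlap`` bp.  Exons on different contigs
    cannot be compared."""
    if a.contig != b.contig:
        raise ValueError(f"exons on different contigs: {a.contig!r} vs {b.contig!r}")
    if a.strand != b.strand:
        return False
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    return overlap >= min_overlap


def _has_correspondent(exon: Exon, others: Sequence[Exon], min_overlap: int) -> bool:
    return any(exon_correspondence(exon, o, min_overlap) for o in others)


def _coalesce(exons: list[Exon]) -> tuple[list[Exon], list[str]]:
    """Sort and union overlapping intervals; an interval touched by any
    EVIDENCE exon keeps EVIDENCE provenance (alignment-backed)."""
    if not exons:
        return [], []
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged: list[Exon] = [exons[0]]
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end:
            source = EVIDENCE if EVIDENCE in (last.source, e.source) else AB_INITIO
            merged[-1] = replace(last, end=max(last.end, e.end), source=source)
        else:
            merged.append(e)
    return merged, [e.source for e in merged]


def merge_locus(
    locus: GeneLocus,
    agreement_min: float = DEFAULT_AGREEMENT_MIN,
    min_overlap: int = 1,
    strict: bool = False,
) -> MergedLocus:
    """Merge the two evidence tracks of one locus into a final gene structure.

    With no evidence exons the ab initio structure is returned unchanged
    (agreement undefined).  Otherwise the exon-count agreement ratio
    min(|ab|,|ev|)/max(|ab|,|ev|) decides the branch:

    * ratio >= ``agreement_min``: interior ab initio exons lacking a
      corresponding evidence exon are removed (the original first and last
      ab initio exons are never removed), then evidence-only exons are added;
    * ratio < ``agreement_min``: additive step only — unless ``strict``,
      in which case the ab initio structure is kept as is.

    The result is re-sorted and overlapping intervals are unioned.
    """
    ab, ev = locus.ab_exons, locus.ev_exons
    if not ev:
        return MergedLocus(
            locus.locus_id, list(ab), [e.source for e in ab], agreement_ratio=None
        )
    if not ab:
        return MergedLocus(
            locus.locus_id, list(ev), [e.source for e in ev], agreement_ratio=0.0
        )
    ratio = min(len(ab), len(ev)) / max(len(ab), len(ev))
    if ratio >= agreement_min:
        kept = [
            e
            for i, e in enumerate(ab)
            if i in (0, len(ab) - 1) or _has_correspondent(e, ev, min_overlap)
        ]
    else:
        kept = list(ab)
        if strict:
            merged, prov = _coalesce(kept)
            return MergedLocus(locus.locus_id, merged, prov, agreement_ratio=ratio)
    additions = [e for e in ev if not _has_correspondent(e, kept, min_overlap)]
    merged, prov = _coalesce(kept + additions)
    return MergedLocus(locus.locus_id, merged, prov, agreement_ratio=ratio)


def merge_tracks(
    ab_loci: dict[str, list[dict]],
    ev_loci: dict[str, list[dict]],
    agreement_min: float = DEFAULT_AGREEMENT_MIN,
    min_overlap: int = 1,
    strict: bool = False,
) -> dict[str, MergedLocus]:
    """Merge whole GFF3 tracks (as returned by ``read_gff3_exons``),
    matching loci by id; loci present in only one track pass through."""
    out: dict[str, MergedLocus] = {}
    for locus_id in sorted(set(ab_loci) | set(ev_loci)):
        ab = [_exon_from_dict(d, AB_INITIO) for d in ab_loci.get(locus_id, [])]
        ev = [_exon_from_dict(d, EVIDENCE) for d in ev_loci.get(locus_id, [])]
        locus = GeneLocus(locus_id, ab, ev)
        out[locus_id] = merge_locus(locus, agreement_min, min_overlap, strict)
    return out


def _exon_from_dict(d: dict, source: str) -> Exon:
    return Exon(d["contig"], int(d["start"]), int(d["end"]), d["strand"], source)


def merged_to_gff3_dicts(merged: dict[str, MergedLocus]) -> dict[str, list[dict]]:
    return {
        locus_id: [
            {
                "contig": e.contig,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
                "source": e.source,
            }
            for e in m.exons
        ]
        for locus_id, m in merged.items()
    }
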