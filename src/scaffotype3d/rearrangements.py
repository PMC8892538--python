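"""Classification of chromosome rearrangements from homologous synteny blocks.

Given HSBs of one target species against a reference, this module builds a
segment map (maximal runs of HSBs on a target scaffold sharing one reference
chromosome), counts fusions and fissions from karyotype accounting, detects
inversions as minority-orientation runs within segments, flags
translocations (a reference chromosome's material appearing non-colinearly
within one scaffold), and deduplicates inversions shared between species by
reciprocal overlap of their reference intervals.

Karyotype accounting identity: with ``N_seg`` segments over ``N_tgt``
distinct target scaffolds and ``N_ref`` distinct reference chromosomes,

    n_fusions  = N_seg - N_tgt
    n_fissions = N_seg - N_ref
    N_tgt      = N_ref - n_fusions + n_fissions

For the dog -> red fox comparison this reads 38 - 26 + 4 = 16 autosomal
scaffolds (diploid 2n=78 -> 2n=34).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .synteny import SyntenyBlock

__all__ = [
    "SegmentSpan",
    "RearrangementEvent",
    "RearrangementSummary",
    "build_segment_map",
    "count_fusions_fissions",
    "detect_inversions",
    "detect_translocations",
    "dedupe_shared_inversions",
    "summarize",
]

EventKind = Literal["inversion", "fusion", "fission", "translocation"]

SIZE_CLASS_BP = 1_000_000  # reporting split between "small" and "large" inversions


@dataclass(frozen=True)
class SegmentSpan:
    """A maximal run of HSBs on one target scaffold mapping to one ref chromosome."""

    tgt_scaffold: str
    order_index: int
    ref_chrom: str
    ref_interval: tuple[int, int]
    tgt_interval: tuple[int, int]
    orientation_majority: Literal["+", "-"]
    hsbs: tuple[SyntenyBlock, ...] = field(default=(), compare=False, repr=False)

    @property
    def ref_span(self) -> int:
        return self.ref_interval[1] - self.ref_interval[0]


@dataclass
class RearrangementEvent:
    kind: EventKind
    species: str
    ref_chrom: str
    ref_interval: tuple[int, int]
    tgt_scaffolds: tuple[str, ...]
    tgt_interval: tuple[int, int] | None
    size: int
    carriers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.carriers:
            self.carriers = (self.species,)


@dataclass
class RearrangementSummary:
    """Per-species rearrangement counts with the 1-Mb inversion size class."""

    per_species: dict[str, dict[str, int]]
    n_shared_deduped_inversions: int
    accounting_ok: bool


# ---------------------------------------------------------------------------


def build_segment_map(hsbs: Sequence[SyntenyBlock]) -> list[SegmentSpan]:
    """Group consecutive same-reference-chromosome HSBs along each scaffold.

    Consecutive HSBs on a target scaffold with the same ``ref_chrom`` merge
    into one segment regardless of orientation; the segment's majority
    orientation is the orientation carrying the larger total reference span.
    """
    by_scaffold: dict[str, list[SyntenyBlock]] = {}
    for h in hsbs:
        by_scaffold.setdefault(h.tgt_scaffold, []).append(h)

    segments: list[SegmentSpan] = []
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda h: h.tgt_start)
        run: list[SyntenyBlock] = []
        order = 0
        for h in ordered:
            if run and h.ref_chrom == run[-1].ref_chrom:
                run.append(h)
            else:
                if run:
                    segments.append(_make_segment(scaffold, order, run))
                    order += 1
                run = [h]
        if run:
            segments.append(_make_segment(scaffold, order, run))
    return segments


def _make_segment(scaffold: str, order: int, run: list[SyntenyBlock]) -> SegmentSpan:
    plus = sum(h.ref_span for h in run if h.orientation == "+")
    minus = sum(h.ref_span for h in run if h.orientation == "-")
    return SegmentSpan(
        tgt_scaffold=scaffold,
        order_index=order,
        ref_chrom=run[0].ref_chrom,
        ref_interval=(min(h.ref_start for h in run), max(h.ref_end for h in run)),
        tgt_interval=(min(h.tgt_start for h in run), max(h.tgt_end for h in run)),
        orientation_majority="+" if plus >= minus else "-",
        hsbs=tuple(run),
    )


def count_fusions_fissions(segments: Sequence[SegmentSpan]) -> tuple[int, int]:
    """Fusion/fission counts from segment-count accounting.

    The map should normally be restricted to autosomes; sex chromosomes are
    handled separately in summaries.
    """
    if not segments:
        return (0, 0)
    n_seg = len(segments)
    n_tgt = len({s.tgt_scaffold for s in segments})
    n_ref = len({s.ref_chrom for s in segments})
    n_fusions = n_seg - n_tgt
    n_fissions = n_seg - n_ref
    if n_fusions < 0 or n_fissions < 0:
        raise ValueError(
            f"malformed segment map: n_seg={n_seg}, n_tgt={n_tgt}, n_ref={n_ref}"
        )
    return n_fusions, n_fissions


def detect_inversions(
    hsbs: Sequence[SyntenyBlock],
    species: str = "target",
    min_size: int = 0,
) -> list[RearrangementEvent]:
    """Detect inversions as minority-orientation runs within segments.

    Within each segment, a maximal run of HSBs whose orientation is opposite
    to the segment's majority orientation is one inversion; its size is the
    reference span of the run.  A segment entirely in ``-`` orientation is a
    strand assignment of the whole fragment, not an inversion.
    """
    events: list[RearrangementEvent] = []
    for seg in build_segment_map(hsbs):
        majority = seg.orientation_majority
        run: list[SyntenyBlock] = []
        for h in list(seg.hsbs) + [None]:  # type: ignore[list-item]
            if h is not None and h.orientation != majority:
                run.append(h)
                continue
            if run:
                ref_lo = min(b.ref_start for b in run)
                ref_hi = max(b.ref_end for b in run)
                size = ref_hi - ref_lo
                if size >= min_size:
                    events.append(
                        RearrangementEvent(
                            kind="inversion",
                            species=species,
                            ref_chrom=seg.ref_chrom,
                            ref_interval=(ref_lo, ref_hi),
                            tgt_scaffolds=(seg.tgt_scaffold,),
                            tgt_interval=(
                                min(b.tgt_start for b in run),
                                max(b.tgt_end for b in run),
                            ),
                            size=size,
                        )
                    )
                run = []
    return events


def detect_translocations(
    segments: Sequence[SegmentSpan], species: str = "target"
) -> list[RearrangementEvent]:
    """Flag reference material appearing non-colinearly within a scaffold.

    Two signatures are reported, both marking an internal rearrangement of
    a (possibly fused) scaffold rather than an inversion:

    * two or more non-adjacent segments on one target scaffold mapping to
      the same reference chromosome (material interleaved with another
      chromosome);
    * within one segment, a break in the monotone reference order of the
      majority-orientation HSBs (a transposed piece; minority-orientation
      HSBs are inversions and are excluded from the order check).
    """
    events: list[RearrangementEvent] = []
    by_scaffold: dict[str, list[SegmentSpan]] = {}
    for s in segments:
        by_scaffold.setdefault(s.tgt_scaffold, []).append(s)
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda s: s.order_index)
        seen: set[str] = set()
        for seg in ordered:
            if seg.ref_chrom in seen:
                events.append(
                    RearrangementEvent(
                        kind="translocation",
                        species=species,
                        ref_chrom=seg.ref_chrom,
                        ref_interval=seg.ref_interval,
                        tgt_scaffolds=(scaffold,),
                        tgt_interval=seg.tgt_interval,
                        size=seg.ref_span,
                    )
                )
            seen.add(seg.ref_chrom)
            majority = [h for h in seg.hsbs if h.orientation == seg.orientation_majority]
            sign = 1 if seg.orientation_majority == "+" else -1
            for prev, nxt in zip(majority, majority[1:]):
                if sign * (nxt.ref_start - prev.ref_start) < 0:
                    events.append(
                        RearrangementEvent(
                            kind="translocation",
                            species=species,
                            ref_chrom=seg.ref_chrom,
                            ref_interval=(nxt.ref_start, nxt.ref_end),
                            tgt_scaffolds=(scaffold,),
                            tgt_interval=(nxt.tgt_start, nxt.tgt_end),
                            size=nxt.ref_span,
                        )
                    )
    return events


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def dedupe_shared_inversions(
    events: Iterable[RearrangementEvent], min_reciprocal_overlap: float = 0.5
) -> list[RearrangementEvent]:
    """Collapse inversions shared between species into single events.

    Inversions from different species whose reference intervals reciprocally
    overlap by at least ``min_reciprocal_overlap`` are merged into one event
    listing all carrier species.  Merging is transitive (union-find over the
    pairwise overlap graph).
    """
    evs = [e for e in events if e.kind == "inversion"]
    parent = list(range(len(evs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(evs)):
        for j in range(i + 1, len(evs)):
            if evs[i].ref_chrom != evs[j].ref_chrom:
                continue
            if _reciprocal_overlap(evs[i].ref_interval, evs[j].ref_interval) >= min_reciprocal_overlap:
                parent[find(i)] = find(j)

    groups: dict[int, list[RearrangementEvent]] = {}
    for i, e in enumerate(evs):
        groups.setdefault(find(i), []).append(e)

    out: list[RearrangementEvent] = []
    for members in groups.values():
        rep = max(members, key=lambda e: e.size)
        carriers = tuple(sorted({c for m in members for c in m.carriers}))
        out.append(
            RearrangementEvent(
                kind="inversion",
                species=rep.species,
                ref_chrom=rep.ref_chrom,
                ref_interval=rep.ref_interval,
                tgt_scaffolds=rep.tgt_scaffolds,
                tgt_interval=rep.tgt_interval,
                size=rep.size,
                carriers=carriers,
            )
        )
    out.sort(key=lambda e: (e.ref_chrom, e.ref_interval))
    return out


def summarize(
    events: Iterable[RearrangementEvent],
    segments_by_species: dict[str, Sequence[SegmentSpan]],
) -> RearrangementSummary:
    """Per-species rearrangement counts with karyotype-accounting check."""
    events = list(events)
    per_species: dict[str, dict[str, int]] = {}
    accounting_ok = True
    species_names = sorted(
        set(segments_by_species) | {e.species for e in events}
    )
    for sp in species_names:
        inv = [e for e in events if e.species == sp and e.kind == "inversion"]
        counts = {
            "n_inversions": len(inv),
            "n_inversions_lt_1Mb": sum(1 for e in inv if e.size < SIZE_CLASS_BP),
            "n_fusions": 0,
            "n_fissions": 0,
            "n_translocations": sum(
                1 for e in events if e.species == sp and e.kind == "translocation"
            ),
        }
        segs = segments_by_species.get(sp)
        if segs:
            fus, fis = count_fusions_fissions(segs)
            counts["n_fusions"], counts["n_fissions"] = fus, fis
            n_tgt = len({s.tgt_scaffold for s in segs})
            n_ref = len({s.ref_chrom for s in segs})
            if n_tgt != n_ref - fus + fis:
                accounting_ok = False
        per_species[sp] = counts
    deduped = dedupe_shared_inversions(events)
    return RearrangementSummary(
        per_species=per_species,
        n_shared_deduped_inversions=len(deduped),
        accounting_ok=accounting_ok,
    )
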