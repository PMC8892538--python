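"""Homologous synteny block (HSB) construction from pairwise alignment blocks.

Raw whole-genome alignment blocks (e.g. LastZ/axtChain output) between a
target assembly and a reference assembly are parsed, filtered for short
scaffolds, and chained into homologous synteny blocks at a configurable
resolution: colinear blocks on the same (reference chromosome, target
scaffold, orientation) triple separated by less than one resolution unit on
both genomes are merged, and merged blocks spanning less than the resolution
on either genome are discarded.

All coordinates are 0-based half-open, target coordinates always on the
forward strand; the aligned orientation is carried as ``+``/``-`` on the
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "AlignmentBlock",
    "SyntenyBlock",
    "AssemblyIndex",
    "SyntenyError",
    "read_blocks",
    "filter_scaffolds",
    "chain_blocks",
    "write_hsbs",
    "read_hsbs",
]

DEFAULT_RESOLUTION = 300_000
DEFAULT_MIN_SCAFFOLD_LEN = 50_000

Orientation = Literal["+", "-"]


class SyntenyError(ValueError):
    """Raised for malformed alignment input or invalid coordinates."""


@dataclass(frozen=True)
class AlignmentBlock:
    """One gap-free pairwise aligned interval with orientation."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_scaffold: str
    tgt_start: int
    tgt_end: int
    orientation: Orientation

    def __post_init__(self) -> None:
        if self.ref_start < 0 or self.tgt_start < 0:
            raise SyntenyError(f"negative coordinate in block {self}")
        if self.ref_end <= self.ref_start:
            raise SyntenyError(
                f"reference end {self.ref_end} <= start {self.ref_start} "
                f"on {self.ref_chrom}"
            )
        if self.tgt_end <= self.tgt_start:
            raise SyntenyError(
                f"target end {self.tgt_end} <= start {self.tgt_start} "
                f"on {self.tgt_scaffold}"
            )
        if self.orientation not in ("+", "-"):
            raise SyntenyError(f"orientation must be + or -, got {self.orientation!r}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def tgt_span(self) -> int:
        return self.tgt_end - self.tgt_start


@dataclass(frozen=True)
class SyntenyBlock:
    """A chained, resolution-filtered homologous segment pair."""

    id: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_scaffold: str
    tgt_start: int
    tgt_end: int
    orientation: Orientation
    resolution: int
    n_source_blocks: int

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def tgt_span(self) -> int:
        return self.tgt_end - self.tgt_start

    def as_alignment_block(self) -> AlignmentBlock:
        return AlignmentBlock(
            self.ref_chrom,
            self.ref_start,
            self.ref_end,
            self.tgt_scaffold,
            self.tgt_start,
            self.tgt_end,
            self.orientation,
        )


@dataclass
class AssemblyIndex:
    """Scaffold id -> length map with a minimum-length analysis filter.

    Scaffolds shorter than ``min_scaffold_len`` (default 50 kb) are excluded
    from downstream analysis; the boundary is inclusive-keep (a scaffold of
    exactly the threshold length is retained).
    """

    lengths: dict[str, int] = field(default_factory=dict)
    min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise SyntenyError(f"scaffold {name!r} has non-positive length {length}")

    def passes(self, scaffold: str) -> bool:
        return self.lengths[scaffold] >= self.min_scaffold_len

    @classmethod
    def from_tsv(cls, path: str | Path, min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN) -> "AssemblyIndex":
        lengths: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SyntenyError(f"{path}:{lineno}: expected 'scaffold<TAB>length'")
            lengths[parts[0]] = int(parts[1])
        return cls(lengths, min_scaffold_len)


# ---------------------------------------------------------------------------
# Readers


def read_blocks(path: str | Path, format: str = "bedpair_tsv") -> list[AlignmentBlock]:
    """Read pairwise alignment blocks from disk.

    ``bedpair_tsv``: 7 tab-separated columns per line, ``#`` comments:
    ref_chrom ref_start ref_end tgt_scaffold tgt_start tgt_end strand.

    ``ucsc_chain``: UCSC chain format; each chain is decomposed into its
    gap-free aligned segments and minus-strand query coordinates are
    converted to forward-strand 0-based half-open intervals.
    """
    if format == "bedpair_tsv":
        return _read_bedpair(Path(path))
    if format == "ucsc_chain":
        return _read_chain(Path(path))
    raise SyntenyError(f"unknown alignment format {format!r}")


def _read_bedpair(path: Path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SyntenyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            block = AlignmentBlock(
                ref_chrom=parts[0],
                ref_start=int(parts[1]),
                ref_end=int(parts[2]),
                tgt_scaffold=parts[3],
                tgt_start=int(parts[4]),
                tgt_end=int(parts[5]),
                orientation=parts[6],  # type: ignore[arg-type]
            )
        except SyntenyError as exc:
            raise SyntenyError(f"{path}:{lineno}: {exc}") from None
        except ValueError:
            raise SyntenyError(f"{path}:{lineno}: coordinates must be integers") from None
        blocks.append(block)
    return blocks


def _read_chain(path: Path) -> list[AlignmentBlock]:
    """Decompose UCSC chains into gap-free aligned segments.

    Chain convention: the *target* genome of the chain is treated as the
    reference assembly and the *query* as the target scaffold assembly.
    Query coordinates of minus-strand chains are given on the reversed
    strand; they are flipped to forward-strand via pos' = qSize - pos.
    """
    blocks: list[AlignmentBlock] = []
    header: list[str] | None = None
    t_pos = q_pos = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            header = line.split()
            if len(header) < 12:
                raise SyntenyError(f"{path}:{lineno}: malformed chain header")
            t_pos = int(header[5])
            q_pos = int(header[10])
            continue
        if header is None:
            raise SyntenyError(f"{path}:{lineno}: alignment line before chain header")
        fields_ = line.split()
        try:
            size = int(fields_[0])
            dt = int(fields_[1]) if len(fields_) > 1 else 0
            dq = int(fields_[2]) if len(fields_) > 2 else 0
        except ValueError:
            raise SyntenyError(f"{path}:{lineno}: malformed chain data line") from None
        t_name, q_name = header[2], header[7]
        q_size = int(header[8])
        q_strand = header[9]
        if q_strand == "-":
            tgt_start, tgt_end = q_size - (q_pos + size), q_size - q_pos
        else:
            tgt_start, tgt_end = q_pos, q_pos + size
        blocks.append(
            AlignmentBlock(
                ref_chrom=t_name,
                ref_start=t_pos,
                ref_end=t_pos + size,
                tgt_scaffold=q_name,
                tgt_start=tgt_start,
                tgt_end=tgt_end,
                orientation="-" if q_strand == "-" else "+",
            )
        )
        t_pos += size + dt
        q_pos += size + dq
        if len(fields_) == 1:
            header = None
    return blocks


def filter_scaffolds(
    blocks: Iterable[AlignmentBlock], index: AssemblyIndex
) -> list[AlignmentBlock]:
    """Drop blocks on scaffolds shorter than the index's minimum length."""
    blocks = list(blocks)
    missing = sorted({b.tgt_scaffold for b in blocks} - set(index.lengths))
    if missing:
        raise SyntenyError(f"scaffolds absent from assembly index: {', '.join(missing)}")
    return [b for b in blocks if index.passes(b.tgt_scaffold)]


# ---------------------------------------------------------------------------
# Chaining


def _diagonal_ok(prev: AlignmentBlock, nxt: AlignmentBlock, resolution: int) -> bool:
    """Can nxt extend a chain ending at prev (same group, ref-sorted order)?"""
    ref_gap = nxt.ref_start - prev.ref_end
    if ref_gap < 0 or ref_gap >= resolution:
        return False
    if prev.orientation == "+":
        tgt_gap = nxt.tgt_start - prev.tgt_end
    else:
        # minus strand: target coordinates decrease as reference increases
        tgt_gap = prev.tgt_start - nxt.tgt_end
    return 0 <= tgt_gap < resolution


def chain_blocks(
    blocks: Sequence[AlignmentBlock],
    resolution: int = DEFAULT_RESOLUTION,
) -> list[SyntenyBlock]:
    """Chain colinear alignment blocks into HSBs at the given resolution.

    Blocks sharing (ref_chrom, tgt_scaffold, orientation) and consistent in
    diagonal order on both genomes are merged greedily when the inter-block
    gap is below ``resolution`` on both genomes.  Merged blocks whose span
    is below ``resolution`` on either genome are discarded.  Surviving
    blocks overlapping on the reference are resolved by keeping the longer
    ref-span block and trimming the other; output is sorted by
    (ref_chrom, ref_start).
    """
    if resolution <= 0:
        raise SyntenyError(f"resolution must be positive, got {resolution}")
    survivors = [(b, 1) for b in blocks]
    # overlap trimming can shrink a block below the span filter or open a
    # mergeable gap, so the merge/filter/trim pass runs to a fixed point
    for _ in range(20):
        nxt = _chain_pass(survivors, resolution)
        stable = [t[0] for t in nxt] == [t[0] for t in survivors]
        survivors = nxt
        if stable:
            break
    return [
        SyntenyBlock(
            id=i,
            ref_chrom=blk.ref_chrom,
            ref_start=blk.ref_start,
            ref_end=blk.ref_end,
            tgt_scaffold=blk.tgt_scaffold,
            tgt_start=blk.tgt_start,
            tgt_end=blk.tgt_end,
            orientation=blk.orientation,
            resolution=resolution,
            n_source_blocks=n,
        )
        for i, (blk, n) in enumerate(survivors, 1)
    ]


def _chain_pass(
    items: list[tuple[AlignmentBlock, int]], resolution: int
) -> list[tuple[AlignmentBlock, int]]:
    """One merge -> min-span filter -> overlap-trim pass."""
    groups: dict[tuple[str, str, str], list[tuple[AlignmentBlock, int]]] = {}
    for b, n in items:
        groups.setdefault((b.ref_chrom, b.tgt_scaffold, b.orientation), []).append((b, n))

    merged: list[tuple[AlignmentBlock, int]] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda t: (t[0].ref_start, t[0].ref_end))
        chain: list[tuple[AlignmentBlock, int]] = []
        for b, n in group:
            if chain and _diagonal_ok(chain[-1][0], b, resolution):
                chain.append((b, n))
            else:
                if chain:
                    merged.append(_merge_chain(chain))
                chain = [(b, n)]
        if chain:
            merged.append(_merge_chain(chain))

    survivors = [
        (blk, n)
        for blk, n in merged
        if blk.ref_span >= resolution and blk.tgt_span >= resolution
    ]
    survivors = _resolve_ref_overlaps(survivors)
    survivors.sort(key=lambda t: (t[0].ref_chrom, t[0].ref_start))
    return survivors


def _merge_chain(chain: list[tuple[AlignmentBlock, int]]) -> tuple[AlignmentBlock, int]:
    first = chain[0][0]
    span = AlignmentBlock(
        ref_chrom=first.ref_chrom,
        ref_start=min(b.ref_start for b, _ in chain),
        ref_end=max(b.ref_end for b, _ in chain),
        tgt_scaffold=first.tgt_scaffold,
        tgt_start=min(b.tgt_start for b, _ in chain),
        tgt_end=max(b.tgt_end for b, _ in chain),
        orientation=first.orientation,
    )
    return span, sum(n for _, n in chain)


def _resolve_ref_overlaps(
    survivors: list[tuple[AlignmentBlock, int]]
) -> list[tuple[AlignmentBlock, int]]:
    """Trim reference overlaps, keeping the longer ref-span block intact.

    Ties are broken in favour of the block with the smaller ref_start.
    """
    by_chrom: dict[str, list[tuple[AlignmentBlock, int]]] = {}
    for item in survivors:
        by_chrom.setdefault(item[0].ref_chrom, []).append(item)
    out: list[tuple[AlignmentBlock, int]] = []
    for chrom in sorted(by_chrom):
        items = sorted(
            by_chrom[chrom], key=lambda t: (-t[0].ref_span, t[0].ref_start)
        )
        kept: list[tuple[AlignmentBlock, int]] = []
        for blk, n in items:
            for other, _ in kept:
                if blk.ref_start < other.ref_end and other.ref_start < blk.ref_end:
                    # trim blk away from other on the reference
                    if blk.ref_start < other.ref_start:
                        new_start, new_end = blk.ref_start, other.ref_start
                    else:
                        new_start, new_end = other.ref_end, blk.ref_end
                    if new_end <= new_start:
                        blk = None  # type: ignore[assignment]
                        break
                    blk = replace(blk, ref_start=new_start, ref_end=new_end)
            if blk is not None:
                kept.append((blk, n))
        out.extend(kept)
    return out


# ---------------------------------------------------------------------------
# HSB TSV I/O

_HSB_COLUMNS = (
    "ref_chrom ref_start ref_end tgt_scaffold tgt_start tgt_end "
    "orientation id n_source_blocks"
).split()


def write_hsbs(hsbs: Iterable[SyntenyBlock], path: str | Path) -> None:
    lines = ["#" + "\t".join(_HSB_COLUMNS)]
    for h in hsbs:
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    h.ref_chrom,
                    h.ref_start,
                    h.ref_end,
                    h.tgt_scaffold,
                    h.tgt_start,
                    h.tgt_end,
                    h.orientation,
                    h.id,
                    h.n_source_blocks,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_hsbs(path: str | Path, resolution: int = DEFAULT_RESOLUTION) -> list[SyntenyBlock]:
    hsbs: list[SyntenyBlock] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise SyntenyError(f"{path}:{lineno}: expected 9 columns")
        hsbs.append(
            SyntenyBlock(
                ref_chrom=parts[0],
                ref_start=int(parts[1]),
                ref_end=int(parts[2]),
                tgt_scaffold=parts[3],
                tgt_start=int(parts[4]),
                tgt_end=int(parts[5]),
                orientation=parts[6],  # type: ignore[arg-type]
                id=int(parts[7]),
                n_source_blocks=int(parts[8]),
                resolution=resolution,
            )
        )
    return hsbs
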