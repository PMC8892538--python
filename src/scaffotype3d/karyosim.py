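"""Synthetic karyotypes, rearrangement histories, and Hi-C contact matrices.

The generator produces everything the analysis modules consume, with exact
ground truth:

* an ancestor genome of a few chromosomes, with a planted two-state
  compartment profile (blocks of +1/-1 with geometrically distributed
  lengths, mean 8 bins, alternating sign);
* a rearrangement history (inversions, fusions, fissions, within-scaffold
  translocations) applied sequentially, yielding a target assembly, the
  applied events, and the exact alignment blocks between target and
  ancestor;
* per-scaffold Hi-C counts: Poisson draws around a power-law distance decay
  modulated by a multiplicative compartment checkerboard,

      E[count(i, j)] = R * max(|i-j|, 1)^(-alpha) * (1 + c * a_i * a_j)

  where ``a`` is the planted profile, ``alpha`` the decay exponent,
  ``c`` the compartment strength and ``R`` the expected count between
  adjacent bins.

Event breakpoints are bin-aligned and kept at least one spacing unit
(default two bin sizes) away from every earlier breakpoint, so each event
is unambiguously recoverable; histories violating spacing are rejected at
generation time.  All randomness flows through one seeded
``numpy.random.Generator``, so every output is reproducible bit for bit
from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .compartments import BinTable, ContactMatrix
from .rearrangements import RearrangementEvent
from .synteny import AlignmentBlock

__all__ = [
    "SimConfig",
    "SimTruth",
    "Piece",
    "make_genome",
    "apply_rearrangements",
    "random_history",
    "simulate_hic",
    "scaffold_profile",
    "write_run",
]

DEFAULT_BIN_SIZE = 500_000
DEFAULT_MEAN_BLOCK_BINS = 8.0


@dataclass
class SimConfig:
    """Generation parameters for one simulated dataset."""

    n_chroms: int = 4
    chrom_lengths: tuple[int, ...] | None = None
    bin_size: int = DEFAULT_BIN_SIZE
    decay_exponent: float = 1.0
    compartment_strength: float = 0.3
    reads_per_bin: float = 50.0
    mean_block_bins: float = DEFAULT_MEAN_BLOCK_BINS
    min_breakpoint_spacing: int | None = None  # default 2 * bin_size
    min_state_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_breakpoint_spacing is None:
            self.min_breakpoint_spacing = 2 * self.bin_size
        if not 0 <= self.compartment_strength < 1:
            raise ValueError("compartment_strength must be in [0, 1)")
        if self.chrom_lengths is not None:
            self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
            for length in self.chrom_lengths:
                if length < 4 * self.bin_size:
                    raise ValueError(
                        f"chromosome length {length} below 4 x bin_size"
                    )
            if length_mod := [x for x in self.chrom_lengths if x % self.bin_size]:
                raise ValueError(f"lengths must be bin-aligned, got {length_mod}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Piece:
    """A contiguous ancestor interval inside a target scaffold."""

    anc_chrom: str
    anc_start: int
    anc_end: int
    orientation: Literal["+", "-"]

    @property
    def length(self) -> int:
        return self.anc_end - self.anc_start

    def flipped(self) -> "Piece":
        return Piece(
            self.anc_chrom,
            self.anc_start,
            self.anc_end,
            "-" if self.orientation == "+" else "+",
        )


Scaffolds = dict[str, list[Piece]]


@dataclass
class SimTruth:
    """Ground truth of one simulated history."""

    events: list[dict]
    truth_blocks: list[AlignmentBlock]
    profile: dict[str, np.ndarray]  # ancestor chrom -> per-bin +1/-1
    scaffolds: Scaffolds = field(default_factory=dict)

    def event_counts(self) -> dict[str, int]:
        counts = {"inversion": 0, "fusion": 0, "fission": 0, "translocation": 0}
        for e in self.events:
            counts[e["kind"]] += 1
        return counts

    def as_rearrangement_events(self, species: str = "sim") -> list[RearrangementEvent]:
        out = []
        for e in self.events:
            out.append(
                RearrangementEvent(
                    kind=e["kind"],
                    species=species,
                    ref_chrom=e.get("anc_chrom", "NA"),
                    ref_interval=tuple(e.get("anc_interval", (0, 0))),
                    tgt_scaffolds=tuple(e.get("scaffolds", ())),
                    tgt_interval=None,
                    size=int(e.get("size", 0)),
                )
            )
        return out


# ---------------------------------------------------------------------------
# Ancestor genome


def make_genome(config: SimConfig) -> tuple[dict[str, int], dict[str, np.ndarray]]:
    """Generate the ancestor assembly and its planted compartment profile.

    Profile blocks have geometrically distributed lengths (mean
    ``mean_block_bins``) and strictly alternating sign; the first block's
    sign is a fair coin flip.  A chromosome is redrawn until each
    compartment state covers at least ``min_state_fraction`` of its bins —
    a near-single-state chromosome carries no recoverable checkerboard and
    is not representative of real autosomes.  Deterministic given the
    config seed.
    """
    rng = config.rng()
    if config.chrom_lengths is not None:
        lengths = list(config.chrom_lengths)
    else:
        # 30-60 Mb chromosomes: modest but chromosome-like at 500-kb bins
        n_bins = rng.integers(60, 121, size=config.n_chroms)
        lengths = [int(n) * config.bin_size for n in n_bins]
    ancestor = {f"chr{i + 1}": length for i, length in enumerate(lengths)}
    profile: dict[str, np.ndarray] = {}
    p = 1.0 / config.mean_block_bins
    for chrom, length in ancestor.items():
        n = length // config.bin_size + (1 if length % config.bin_size else 0)
        for _ in range(1000):
            a = np.empty(n)
            sign = rng.choice([-1.0, 1.0])
            i = 0
            while i < n:
                block = int(rng.geometric(p))
                a[i : i + block] = sign
                sign = -sign
                i += block
            minority = min((a > 0).mean(), (a < 0).mean())
            if minority >= config.min_state_fraction:
                break
        profile[chrom] = a
    return ancestor, profile


# ---------------------------------------------------------------------------
# Rearrangement machinery


def _split_pieces(pieces: list[Piece], pos: int) -> tuple[list[Piece], list[Piece]]:
    """Split a piece list at scaffold coordinate pos (must fall on or inside pieces)."""
    left: list[Piece] = []
    right: list[Piece] = []
    cursor = 0
    for piece in pieces:
        if cursor + piece.length <= pos:
            left.append(piece)
        elif cursor >= pos:
            right.append(piece)
        else:
            off = pos - cursor
            if piece.orientation == "+":
                left.append(
                    Piece(piece.anc_chrom, piece.anc_start, piece.anc_start + off, "+")
                )
                right.append(
                    Piece(piece.anc_chrom, piece.anc_start + off, piece.anc_end, "+")
                )
            else:
                left.append(
                    Piece(piece.anc_chrom, piece.anc_end - off, piece.anc_end, "-")
                )
                right.append(
                    Piece(piece.anc_chrom, piece.anc_start, piece.anc_end - off, "-")
                )
        cursor += piece.length
    return left, right


def _scaffold_length(pieces: list[Piece]) -> int:
    return sum(p.length for p in pieces)


def apply_rearrangements(
    ancestor: dict[str, int],
    events: Sequence[dict],
    profile: dict[str, np.ndarray] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> tuple[dict[str, int], SimTruth]:
    """Apply a scripted event list to the ancestor genome.

    Events are dicts with a ``kind`` key:

    * ``{"kind": "inversion", "scaffold": s, "start": x, "end": y}``
    * ``{"kind": "fusion", "scaffolds": [s1, s2]}``
    * ``{"kind": "fission", "scaffold": s, "pos": x}``
    * ``{"kind": "translocation", "scaffold": s, "start": x, "end": y,
      "insert": t}`` — excise [x, y) and reinsert with its left edge at
      post-excision coordinate t.

    Coordinates are scaffold coordinates at the time the event applies, and
    must be multiples of ``bin_size`` so the planted per-bin profile stays
    well defined.  Scaffolds start as copies of the ancestor chromosomes
    (same names); fissions mint ``<name>_p``/``<name>_q`` arms and fusions
    ``fus<N>`` products.
    """
    scaffolds: Scaffolds = {
        chrom: [Piece(chrom, 0, length, "+")] for chrom, length in ancestor.items()
    }
    applied: list[dict] = []
    counter = [0]
    for ev in events:
        applied.append(_apply_event(scaffolds, ev, bin_size, counter))

    target = {name: _scaffold_length(pieces) for name, pieces in scaffolds.items()}
    truth = SimTruth(
        events=applied,
        truth_blocks=_truth_blocks(scaffolds),
        profile=dict(profile or {}),
        scaffolds=scaffolds,
    )
    return target, truth


def _check_cut(pos: int, bin_size: int) -> None:
    if pos % bin_size:
        raise ValueError(f"breakpoint {pos} is not a multiple of bin size {bin_size}")


def _apply_event(
    scaffolds: Scaffolds, ev: dict, bin_size: int, counter: list[int]
) -> dict:
    """Apply one event to the scaffold state in place; return the event record."""
    kind = ev["kind"]
    record = dict(ev)
    if kind == "inversion":
        s = ev["scaffold"]
        start, end = int(ev["start"]), int(ev["end"])
        _check_cut(start, bin_size)
        _check_cut(end, bin_size)
        if not 0 <= start < end <= _scaffold_length(scaffolds[s]):
            raise ValueError(f"inversion interval out of range on {s}")
        left, rest = _split_pieces(scaffolds[s], start)
        mid, right = _split_pieces(rest, end - start)
        scaffolds[s] = left + [p.flipped() for p in reversed(mid)] + right
        record["size"] = end - start
        record["scaffolds"] = (s,)
        if len({p.anc_chrom for p in mid}) == 1:
            record["anc_chrom"] = mid[0].anc_chrom
            record["anc_interval"] = (
                min(p.anc_start for p in mid),
                max(p.anc_end for p in mid),
            )
    elif kind == "fusion":
        s1, s2 = ev["scaffolds"]
        counter[0] += 1
        name = ev.get("name", f"fus{counter[0]}")
        junction = _scaffold_length(scaffolds[s1])
        scaffolds[name] = scaffolds.pop(s1) + scaffolds.pop(s2)
        record["scaffolds"] = (s1, s2)
        record["name"] = name
        record["size"] = 0
        record["junction"] = junction
    elif kind == "fission":
        s = ev["scaffold"]
        pos = int(ev["pos"])
        _check_cut(pos, bin_size)
        if not 0 < pos < _scaffold_length(scaffolds[s]):
            raise ValueError(f"fission position out of range on {s}")
        left, right = _split_pieces(scaffolds[s], pos)
        del scaffolds[s]
        scaffolds[f"{s}_p"], scaffolds[f"{s}_q"] = left, right
        record["scaffolds"] = (s,)
        record["size"] = 0
    elif kind == "translocation":
        s = ev["scaffold"]
        start, end, insert = int(ev["start"]), int(ev["end"]), int(ev["insert"])
        for pos in (start, end, insert):
            _check_cut(pos, bin_size)
        left, rest = _split_pieces(scaffolds[s], start)
        mid, right = _split_pieces(rest, end - start)
        remainder = left + right
        if not 0 <= insert <= _scaffold_length(remainder):
            raise ValueError(f"translocation insert point out of range on {s}")
        pre, post = _split_pieces(remainder, insert)
        scaffolds[s] = pre + mid + post
        record["scaffolds"] = (s,)
        record["size"] = end - start
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return record


def _truth_blocks(scaffolds: Scaffolds) -> list[AlignmentBlock]:
    """Maximal conserved segments between each scaffold and the ancestor."""
    blocks: list[AlignmentBlock] = []
    for name in sorted(scaffolds):
        cursor = 0
        run: list[tuple[Piece, int]] = []  # (piece, scaffold start)
        for piece in scaffolds[name] + [None]:  # type: ignore[list-item]
            if run:
                prev, prev_pos = run[-1]
                contiguous = (
                    piece is not None
                    and piece.anc_chrom == prev.anc_chrom
                    and piece.orientation == prev.orientation
                    and (
                        piece.anc_start == prev.anc_end
                        if piece.orientation == "+"
                        else piece.anc_end == prev.anc_start
                    )
                )
                if not contiguous:
                    first_piece, first_pos = run[0]
                    blocks.append(
                        AlignmentBlock(
                            ref_chrom=first_piece.anc_chrom,
                            ref_start=min(p.anc_start for p, _ in run),
                            ref_end=max(p.anc_end for p, _ in run),
                            tgt_scaffold=name,
                            tgt_start=first_pos,
                            tgt_end=prev_pos + prev.length,
                            orientation=first_piece.orientation,
                        )
                    )
                    run = []
            if piece is not None:
                run.append((piece, cursor))
                cursor += piece.length
    return blocks


# ---------------------------------------------------------------------------
# Random histories


def random_history(
    ancestor: dict[str, int],
    n_events: int,
    rng: np.random.Generator,
    bin_size: int = DEFAULT_BIN_SIZE,
    spacing: int | None = None,
    kinds: Sequence[str] = ("inversion", "fusion", "fission"),
    max_tries: int = 200,
) -> list[dict]:
    """Sample a recoverable event history.

    Every cut is bin-aligned, falls strictly inside one current ancestor
    piece with at least ``spacing`` (default two bins) clearance from the
    piece boundaries, inversions stay shorter than half their piece, and
    fusions never place material of one ancestor chromosome twice on a
    scaffold.  Event proposals violating the constraints are re-drawn; a
    history that cannot be extended is truncated (rare at default sizes).
    """
    if spacing is None:
        spacing = 2 * bin_size
    events: list[dict] = []
    state: Scaffolds = {
        chrom: [Piece(chrom, 0, length, "+")] for chrom, length in ancestor.items()
    }
    counter = [0]
    for _ in range(n_events):
        placed = False
        for _ in range(max_tries):
            kind = str(rng.choice(list(kinds)))
            ev = _propose(state, kind, rng, bin_size, spacing)
            if ev is None:
                continue
            # advance the shadow state so later proposals stay consistent
            _apply_event(state, ev, bin_size, counter)
            events.append(ev)
            placed = True
            break
        if not placed:
            break
    return events


def _strand_balance_ok(pieces: list[Piece], delta_chrom: str = "", delta: int = 0) -> bool:
    """True if forward-strand material strictly dominates every chromosome.

    ``delta`` bp may be shifted from + to - on ``delta_chrom`` to pre-check
    a proposed inversion.  Keeping + in the majority everywhere guarantees
    each planted inversion is recoverable as a minority-orientation run.
    """
    balance: dict[str, int] = {}
    for p in pieces:
        balance[p.anc_chrom] = balance.get(p.anc_chrom, 0) + (
            p.length if p.orientation == "+" else -p.length
        )
    if delta_chrom:
        balance[delta_chrom] = balance.get(delta_chrom, 0) - 2 * delta
    return all(v > 0 for v in balance.values())


def _propose(
    state: Scaffolds,
    kind: str,
    rng: np.random.Generator,
    bin_size: int,
    spacing: int,
) -> dict | None:
    names = sorted(state)
    if kind == "inversion" or kind == "translocation":
        s = str(rng.choice(names))
        pieces = state[s]
        # choose a piece large enough for margins
        candidates = []
        cursor = 0
        for p in pieces:
            # events go on forward-strand pieces only: an inversion nested in
            # already-inverted material, or a move of it, is not recoverable
            # as one event from block orientations and order alone
            if p.length >= 4 * spacing and p.orientation == "+":
                candidates.append((cursor, p))
            cursor += p.length
        if not candidates:
            return None
        offset, piece = candidates[int(rng.integers(len(candidates)))]
        lo = offset + spacing
        hi = offset + piece.length - spacing
        max_len = min((piece.length // 2) // bin_size * bin_size, hi - lo)
        if max_len < spacing:
            return None
        length = int(rng.integers(spacing // bin_size, max_len // bin_size + 1)) * bin_size
        start_max = hi - length
        if start_max < lo:
            return None
        start = int(rng.integers(lo // bin_size, start_max // bin_size + 1)) * bin_size
        if kind == "inversion":
            signed = length if piece.orientation == "+" else -length
            if not _strand_balance_ok(pieces, piece.anc_chrom, signed):
                return None
            return {"kind": "inversion", "scaffold": s, "start": start, "end": start + length}
        # translocation: reinsert elsewhere within the same piece, >= spacing away
        rem_lo = offset + spacing
        rem_hi = offset + piece.length - length - spacing
        options = [
            t * bin_size
            for t in range(rem_lo // bin_size, rem_hi // bin_size + 1)
            if abs(t * bin_size - start) >= spacing
        ]
        if not options:
            return None
        insert = int(rng.choice(options))
        return {
            "kind": "translocation",
            "scaffold": s,
            "start": start,
            "end": start + length,
            "insert": insert,
        }
    if kind == "fusion":
        if len(names) < 2:
            return None
        i, j = rng.choice(len(names), size=2, replace=False)
        s1, s2 = names[int(i)], names[int(j)]
        chroms1 = [p.anc_chrom for p in state[s1]]
        chroms2 = [p.anc_chrom for p in state[s2]]
        if set(chroms1) & set(chroms2):
            return None  # would create a confounded same-chromosome repeat
        return {"kind": "fusion", "scaffolds": [s1, s2]}
    if kind == "fission":
        s = str(rng.choice(names))
        cursor = 0
        cuts: list[int] = []
        for p in state[s]:
            # cut only inside forward-strand pieces: splitting an inverted
            # piece across scaffolds would split one planted inversion into
            # two apparent ones
            if p.orientation == "+":
                lo, hi = cursor + spacing, cursor + p.length - spacing
                cuts.extend(
                    t * bin_size for t in range(-(-lo // bin_size), hi // bin_size + 1)
                )
            cursor += p.length
        # keep + in the majority on both products, so no planted inversion
        # can turn into the majority strand of a shrunken scaffold
        cuts_arr = np.array(cuts, dtype=np.int64)
        rng.shuffle(cuts_arr)
        for pos in cuts_arr:
            left, right = _split_pieces(state[s], int(pos))
            if _strand_balance_ok(left) and _strand_balance_ok(right):
                return {"kind": "fission", "scaffold": s, "pos": int(pos)}
        return None
    raise ValueError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# Hi-C simulation


def scaffold_profile(
    truth: SimTruth, scaffold: str, bin_size: int = DEFAULT_BIN_SIZE
) -> np.ndarray:
    """The planted profile carried onto a target scaffold's bins."""
    pieces = truth.scaffolds[scaffold]
    values: list[float] = []
    for piece in pieces:
        anc = truth.profile[piece.anc_chrom]
        lo = piece.anc_start // bin_size
        hi = -(-piece.anc_end // bin_size)
        seg = anc[lo:hi]
        values.extend(seg[::-1] if piece.orientation == "-" else seg)
    return np.asarray(values)


def expected_contacts(profile: np.ndarray, config: SimConfig) -> np.ndarray:
    """Expected contact counts lambda_ij for a planted profile.

    lambda_ij = R * max(|i-j|, 1)^(-alpha) * (1 + c * a_i * a_j); the
    diagonal uses the distance-1 decay value.
    """
    n = len(profile)
    i, j = np.indices((n, n))
    s = np.maximum(np.abs(i - j), 1).astype(float)
    return (
        config.reads_per_bin
        * s ** (-config.decay_exponent)
        * (1.0 + config.compartment_strength * np.outer(profile, profile))
    )


def simulate_hic(
    scaffold: str,
    scaffold_length: int,
    profile: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> ContactMatrix:
    """Poisson Hi-C counts with power-law decay and compartment checkerboard."""
    table = BinTable(scaffold, scaffold_length, config.bin_size)
    n = table.n_bins
    if len(profile) != n:
        raise ValueError(f"profile has {len(profile)} bins, scaffold has {n}")
    lam = expected_contacts(profile, config)
    upper = np.triu(rng.poisson(lam).astype(float))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(bin_table=table, counts=counts)


# ---------------------------------------------------------------------------
# Run directory export


def write_run(
    out_dir: str | Path,
    config: SimConfig,
    ancestor: dict[str, int],
    target: dict[str, int],
    truth: SimTruth,
    matrices: dict[str, ContactMatrix] | None = None,
) -> None:
    """Write a simulated dataset as plain-text files plus a manifest."""
    from .compartments import write_contacts
    from .synteny import AlignmentBlock  # noqa: F401

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["#ref_chrom\tref_start\tref_end\ttgt_scaffold\ttgt_start\ttgt_end\tstrand"]
    for b in truth.truth_blocks:
        lines.append(
            f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.tgt_scaffold}"
            f"\t{b.tgt_start}\t{b.tgt_end}\t{b.orientation}"
        )
    (out / "truth_blocks.tsv").write_text("\n".join(lines) + "\n")

    ev_lines = ["#kind\tdetail"]
    for e in truth.events:
        ev_lines.append(f"{e['kind']}\t{json.dumps({k: v for k, v in e.items() if k != 'kind'}, default=str)}")
    (out / "truth_events.tsv").write_text("\n".join(ev_lines) + "\n")

    prof_lines = []
    for chrom, a in truth.profile.items():
        for k, v in enumerate(a):
            start = k * config.bin_size
            prof_lines.append(f"{chrom}\t{start}\t{start + config.bin_size}\t{v:+.0f}")
    (out / "planted_profile.bedgraph").write_text("\n".join(prof_lines) + "\n")

    for assembly, fname in ((ancestor, "ancestor.tsv"), (target, "target.tsv")):
        (out / fname).write_text(
            "\n".join(f"{k}\t{v}" for k, v in sorted(assembly.items())) + "\n"
        )

    if matrices:
        for scaffold, mat in matrices.items():
            write_contacts(mat, out / f"contacts_{scaffold}.tsv")

    manifest = {
        "seed": config.seed,
        "bin_size": config.bin_size,
        "decay_exponent": config.decay_exponent,
        "compartment_strength": config.compartment_strength,
        "reads_per_bin": config.reads_per_bin,
        "n_chroms": len(ancestor),
        "n_scaffolds": len(target),
        "events": truth.event_counts(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
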