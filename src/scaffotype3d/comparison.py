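"""Cross-species comparison of compartment eigenvector profiles.

Target-species eigenvectors are lifted onto reference coordinates through
homologous synteny blocks: each reference bin takes the value of the target
bin its midpoint maps to, and within minus-orientation HSBs the bin order is
reversed.  Values are reordered, never negated — the A/B identity of a locus
does not depend on which strand the assembly happens to show.

Lifted profiles are then scored per orthologous segment (Pearson r) and
scanned for compartment shifts: runs of consecutive bins where the two
species' eigenvector signs disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .compartments import BinTable, EigenProfile
from .rearrangements import SegmentSpan
from .synteny import SyntenyBlock

__all__ = [
    "LiftedProfile",
    "CompartmentShift",
    "liftover_profile",
    "segment_similarity",
    "call_compartment_shifts",
    "write_lifted_bedgraph",
]

DEFAULT_MIN_RUN = 2
DEFAULT_MIN_BINS = 10
MIN_BIN_COVERAGE = 0.5


@dataclass
class LiftedProfile:
    """A target profile expressed on reference bins, with provenance."""

    ref_chrom: str
    bin_size: int
    values: np.ndarray  # NaN where no HSB covers the reference bin
    # per-bin (tgt_scaffold, tgt_bin, was_inverted); None where missing
    provenance: list[tuple[str, int, bool] | None]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def as_profile(self) -> EigenProfile:
        table = BinTable(
            self.ref_chrom,
            len(self.values) * self.bin_size,
            self.bin_size,
            self.valid,
        )
        return EigenProfile(bin_table=table, values=self.values)


@dataclass(frozen=True)
class CompartmentShift:
    ref_chrom: str
    ref_interval: tuple[int, int]
    species: str
    direction: Literal["A->B", "B->A"]
    n_bins: int


def liftover_profile(
    profile: EigenProfile,
    hsbs: Sequence[SyntenyBlock],
    ref_chrom: str | None = None,
    ref_length: int | None = None,
) -> LiftedProfile:
    """Lift a target-scaffold profile onto reference coordinates.

    Only HSBs whose target scaffold matches the profile's scaffold are used.
    A reference bin gets a value when an HSB covers at least half of it and
    the bin midpoint falls inside the HSB; the midpoint is mapped through
    the HSB (reversed for minus orientation) to a target bin.
    """
    scaffold = profile.bin_table.scaffold
    bin_size = profile.bin_table.bin_size
    use = [h for h in hsbs if h.tgt_scaffold == scaffold]
    if ref_chrom is not None:
        use = [h for h in use if h.ref_chrom == ref_chrom]
    if not use:
        import warnings

        warnings.warn(f"no HSB maps scaffold {scaffold!r} onto the reference")
        n = 0 if ref_length is None else -(-ref_length // bin_size)
        return LiftedProfile(
            ref_chrom=ref_chrom or "NA",
            bin_size=bin_size,
            values=np.full(n, np.nan),
            provenance=[None] * n,
        )
    if ref_chrom is None:
        chroms = {h.ref_chrom for h in use}
        if len(chroms) > 1:
            raise ValueError(
                f"scaffold {scaffold!r} maps to multiple reference chromosomes "
                f"{sorted(chroms)}; pass ref_chrom="
            )
        ref_chrom = use[0].ref_chrom
    if ref_length is None:
        ref_length = max(h.ref_end for h in use)
    n = -(-ref_length // bin_size)
    values = np.full(n, np.nan)
    provenance: list[tuple[str, int, bool] | None] = [None] * n

    for i in range(n):
        bin_start = i * bin_size
        bin_end = min(bin_start + bin_size, ref_length)
        mid = (bin_start + bin_end) // 2
        best, best_ov = None, 0
        for h in use:
            ov = min(bin_end, h.ref_end) - max(bin_start, h.ref_start)
            if ov > best_ov:
                best, best_ov = h, ov
        if best is None or best_ov < (bin_end - bin_start) * MIN_BIN_COVERAGE:
            continue
        if not (best.ref_start <= mid < best.ref_end):
            continue
        offset = mid - best.ref_start
        if best.orientation == "+":
            tgt_pos = best.tgt_start + offset
        else:
            tgt_pos = best.tgt_end - 1 - offset
        tgt_bin = tgt_pos // bin_size
        if 0 <= tgt_bin < len(profile.values):
            values[i] = profile.values[tgt_bin]
            provenance[i] = (scaffold, int(tgt_bin), best.orientation == "-")
    return LiftedProfile(
        ref_chrom=ref_chrom, bin_size=bin_size, values=values, provenance=provenance
    )


def segment_similarity(
    ref_profile: EigenProfile,
    lifted: LiftedProfile,
    segments: Sequence[SegmentSpan],
    min_bins: int = DEFAULT_MIN_BINS,
) -> dict[SegmentSpan, float | None]:
    """Pearson r between reference and lifted values within each segment.

    Segments with fewer than ``min_bins`` overlapping valid bins are
    reported as not-assessed (None).
    """
    out: dict[SegmentSpan, float | None] = {}
    bin_size = lifted.bin_size
    for seg in segments:
        if seg.ref_chrom != lifted.ref_chrom:
            out[seg] = None
            continue
        lo = seg.ref_interval[0] // bin_size
        hi = -(-seg.ref_interval[1] // bin_size)
        hi = min(hi, len(lifted.values), len(ref_profile.values))
        if hi <= lo:
            out[seg] = None
            continue
        a = ref_profile.values[lo:hi]
        b = lifted.values[lo:hi]
        both = np.isfinite(a) & np.isfinite(b)
        if both.sum() < min_bins or a[both].std() == 0 or b[both].std() == 0:
            out[seg] = None
            continue
        out[seg] = float(np.corrcoef(a[both], b[both])[0, 1])
    return out


def call_compartment_shifts(
    ref_profile: EigenProfile,
    lifted: LiftedProfile,
    species: str = "target",
    min_run: int = DEFAULT_MIN_RUN,
) -> list[CompartmentShift]:
    """Runs of >= min_run bins whose A/B signs disagree between species.

    Both profiles must already be sign-oriented with the reference as
    anchor.  Direction is read off the reference sign (positive = A): a run
    where the reference is A and the target B is reported as ``A->B``.
    """
    n = min(len(ref_profile.values), len(lifted.values))
    a = np.sign(ref_profile.values[:n])
    b = np.sign(lifted.values[:n])
    disagree = np.isfinite(a) & np.isfinite(b) & (a != 0) & (b != 0) & (a != b)
    shifts: list[CompartmentShift] = []
    i = 0
    while i < n:
        if not disagree[i]:
            i += 1
            continue
        j = i
        while j < n and disagree[j]:
            j += 1
        if j - i >= min_run:
            # direction from the majority reference sign over the run
            ref_sign = np.sign(a[i:j].sum()) or 1.0
            shifts.append(
                CompartmentShift(
                    ref_chrom=lifted.ref_chrom,
                    ref_interval=(i * lifted.bin_size, j * lifted.bin_size),
                    species=species,
                    direction="A->B" if ref_sign > 0 else "B->A",
                    n_bins=j - i,
                )
            )
        i = j
    return shifts


def write_lifted_bedgraph(lifted: LiftedProfile, path: str | Path) -> None:
    lines = []
    for i in np.flatnonzero(lifted.valid):
        start = int(i) * lifted.bin_size
        lines.append(
            f"{lifted.ref_chrom}\t{start}\t{start + lifted.bin_size}\t{lifted.values[i]:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
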