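"""Cross-species scaffold orthology tables and fragment naming (3DCS).

The final product of 3D comparative scaffotyping is a look-up table: for
each reference chromosome, the ordered list of target-species scaffolds (or
subchromosomal scaffold fragments) orthologous to it.  A scaffold that maps
to more than one reference segment is split into lettered fragments
("3a", "3b", ...) in order of their position along the scaffold; the
fragments of one reference chromosome are rendered joined by ``+``
("3a+7a+8a").

The module also encodes the naming recommendation rules: adopt the
reference nomenclature only when every reference chromosome is a 1:1 whole
scaffold in every species; otherwise name scaffolds by size rank; and
reject reference genomes with 90% or less of their sequence anchored to
chromosomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .rearrangements import SegmentSpan

__all__ = [
    "FragmentName",
    "OrthologyFragment",
    "ScaffotypeTable",
    "NamingReport",
    "TableError",
    "assign_orthology",
    "name_fragments",
    "parse_table1",
    "emit_table1",
    "summarize_table",
    "recommend_naming",
    "load_packaged_table",
    "load_packaged_metadata",
]

WARN_SIMILARITY = 0.5
ANCHORED_FRACTION_GATE = 0.9

_FRAGMENT_RE = re.compile(r"^([A-Za-z_.\-]*\d+)([a-z]*)$")


class TableError(ValueError):
    """Raised for malformed orthology-table input."""


@dataclass(frozen=True, order=True)
class FragmentName:
    """A scaffold identifier with an optional fragment letter ('3', 'b' -> 3b)."""

    scaffold: str
    letter: str = ""

    def __str__(self) -> str:
        return f"{self.scaffold}{self.letter}"

    @classmethod
    def parse(cls, token: str) -> "FragmentName":
        m = _FRAGMENT_RE.match(token)
        if not m:
            raise TableError(f"malformed fragment token {token!r}")
        return cls(m.group(1), m.group(2))


@dataclass
class OrthologyFragment:
    species: str
    tgt_scaffold: str
    fragment_letter: str
    ref_chrom: str
    ref_interval: tuple[int, int]
    tgt_interval: tuple[int, int]
    order_on_ref: int
    eig_similarity: float | None = None
    low_similarity: bool = False

    @property
    def name(self) -> FragmentName:
        return FragmentName(self.tgt_scaffold, self.fragment_letter)


@dataclass
class ScaffotypeTable:
    """Reference chromosome -> per-species ordered fragment names."""

    species: list[str]
    ref_chroms: list[str]
    entries: dict[str, dict[str, list[FragmentName]]]
    metadata: dict[str, int] = field(default_factory=dict)  # species -> 2n
    fragments: list[OrthologyFragment] = field(default_factory=list)

    def entry(self, ref_chrom: str, species: str) -> list[FragmentName]:
        return self.entries.get(ref_chrom, {}).get(species, [])

    def autosomes(self) -> list[str]:
        return [c for c in self.ref_chroms if c.upper() != "X"]


@dataclass
class NamingReport:
    reference_accepted: bool
    full_one_to_one: bool
    recommendation: str
    message: str


# ---------------------------------------------------------------------------
# Building tables from segment maps


def assign_orthology(
    segment_maps: Mapping[str, Sequence[SegmentSpan]],
    similarities: Mapping[str, Mapping[SegmentSpan, float | None]] | None = None,
    warn_threshold: float = WARN_SIMILARITY,
    metadata: Mapping[str, int] | None = None,
) -> ScaffotypeTable:
    """Turn per-species segment maps into an orthology table.

    Each segment becomes one fragment, listed per reference chromosome in
    reference-coordinate order.  Overlapping reference claims from one
    species are a conflict error — assignments must be unambiguous.
    Fragments whose eigenvector similarity falls below ``warn_threshold``
    are flagged, not removed.  Fragment letters are assigned afterwards by
    :func:`name_fragments`.
    """
    fragments: list[OrthologyFragment] = []
    for species in sorted(segment_maps):
        segs = list(segment_maps[species])
        by_chrom: dict[str, list[SegmentSpan]] = {}
        for s in segs:
            by_chrom.setdefault(s.ref_chrom, []).append(s)
        for chrom, chrom_segs in by_chrom.items():
            chrom_segs.sort(key=lambda s: s.ref_interval)
            for a, b in zip(chrom_segs, chrom_segs[1:]):
                if b.ref_interval[0] < a.ref_interval[1]:
                    raise TableError(
                        f"{species}: overlapping claims on {chrom}: "
                        f"{a.tgt_scaffold}{a.ref_interval} vs {b.tgt_scaffold}{b.ref_interval}"
                    )
            for order, seg in enumerate(chrom_segs):
                sim = None
                if similarities and species in similarities:
                    sim = similarities[species].get(seg)
                fragments.append(
                    OrthologyFragment(
                        species=species,
                        tgt_scaffold=seg.tgt_scaffold,
                        fragment_letter="",
                        ref_chrom=chrom,
                        ref_interval=seg.ref_interval,
                        tgt_interval=seg.tgt_interval,
                        order_on_ref=order,
                        eig_similarity=sim,
                        low_similarity=sim is not None and sim < warn_threshold,
                    )
                )

    ref_chroms = sorted({f.ref_chrom for f in fragments})
    table = ScaffotypeTable(
        species=sorted(segment_maps),
        ref_chroms=ref_chroms,
        entries={},
        metadata=dict(metadata or {}),
        fragments=fragments,
    )
    return name_fragments(table)


def _letter(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, 27 -> ab, ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def name_fragments(table: ScaffotypeTable) -> ScaffotypeTable:
    """Assign fragment letters and rebuild the rendered entries.

    A scaffold that carries a single segment gets no letter; with k >= 2
    segments, letters a..(k) are assigned by ascending target start.  The
    assignment depends only on target coordinates, so it is stable under
    any reordering of the input.
    """
    by_scaffold: dict[tuple[str, str], list[OrthologyFragment]] = {}
    for f in table.fragments:
        by_scaffold.setdefault((f.species, f.tgt_scaffold), []).append(f)
    for frags in by_scaffold.values():
        if len(frags) == 1:
            frags[0].fragment_letter = ""
            continue
        frags.sort(key=lambda f: f.tgt_interval)
        for i, f in enumerate(frags):
            f.fragment_letter = _letter(i)

    entries: dict[str, dict[str, list[FragmentName]]] = {}
    for chrom in table.ref_chroms:
        entries[chrom] = {}
        for species in table.species:
            frags = [
                f
                for f in table.fragments
                if f.ref_chrom == chrom and f.species == species
            ]
            frags.sort(key=lambda f: f.order_on_ref)
            entries[chrom][species] = [f.name for f in frags]
    table.entries = entries
    return table


# ---------------------------------------------------------------------------
# Table text format (Table 1 shape)


def parse_table1(text: str) -> ScaffotypeTable:
    """Parse the tab-separated orthology-table format.

    First non-comment line is the header: ``ref_chrom`` then one species
    name per column.  Each following row holds the reference chromosome and
    one entry per species; entries are ``+``-joined fragment names and are
    whitespace-tolerant (spaces around ``+`` are ignored).  A trailing
    ``(2n=NN)`` in a species header is stored as metadata.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: list[str] | None = None
    species: list[str] = []
    metadata: dict[str, int] = {}
    ref_chroms: list[str] = []
    entries: dict[str, dict[str, list[FragmentName]]] = {}
    for row_no, raw in enumerate(lines, 1):
        if raw.lstrip().startswith("#") and header is not None:
            continue
        cols = [c.strip() for c in raw.lstrip("#").rstrip("\n").split("\t")]
        if header is None:
            header = cols
            for name in cols[1:]:
                m = re.match(r"^(.*?)\s*\(2n\s*=\s*(\d+)\)\s*$", name)
                if m:
                    species.append(m.group(1).strip())
                    metadata[m.group(1).strip()] = int(m.group(2))
                else:
                    species.append(name)
            continue
        if len(cols) != len(header):
            raise TableError(
                f"row {row_no}: expected {len(header)} columns, got {len(cols)}"
            )
        chrom = cols[0]
        ref_chroms.append(chrom)
        entries[chrom] = {}
        for sp, cell in zip(species, cols[1:]):
            entries[chrom][sp] = _parse_entry(cell, row_no, sp)
    if header is None:
        raise TableError("empty table")
    return ScaffotypeTable(
        species=species, ref_chroms=ref_chroms, entries=entries, metadata=metadata
    )


def _parse_entry(cell: str, row_no: int, species: str) -> list[FragmentName]:
    cell = cell.strip()
    if not cell or cell in {"-", "."}:
        return []
    out = []
    for token in cell.split("+"):
        token = token.strip()
        if not token:
            continue
        try:
            out.append(FragmentName.parse(token))
        except TableError as exc:
            raise TableError(f"row {row_no}, species {species!r}: {exc}") from None
    return out


def emit_table1(table: ScaffotypeTable) -> str:
    """Render the canonical tab-separated table text.

    Fragments are joined with ``+`` and no surrounding spaces; parsing the
    emitted text reproduces the table exactly.
    """
    header = ["ref_chrom"]
    for sp in table.species:
        if sp in table.metadata:
            header.append(f"{sp} (2n={table.metadata[sp]})")
        else:
            header.append(sp)
    lines = ["\t".join(header)]
    for chrom in table.ref_chroms:
        row = [chrom]
        for sp in table.species:
            row.append("+".join(str(f) for f in table.entry(chrom, sp)))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Summaries and naming recommendation


def _is_one_to_one(entry: list[FragmentName]) -> bool:
    """One whole (unlettered) scaffold — a 1:1 chromosome ortholog."""
    return len(entry) == 1 and entry[0].letter == ""


def summarize_table(
    table: ScaffotypeTable, groups: Mapping[str, Sequence[str]] | None = None
) -> dict:
    """Summary statistics in the shape the orthology analysis reports.

    Per species group: the number of reference autosomes that are 1:1 (one
    whole scaffold) in *every* group member, and the min/max fragment count
    per reference chromosome over the group.  Also per-species distinct
    scaffold counts.
    """
    if groups is None:
        groups = {"all": table.species}
    out: dict = {"groups": {}, "per_species_scaffolds": {}}
    for sp in table.species:
        scaffolds = {
            f.scaffold for chrom in table.ref_chroms for f in table.entry(chrom, sp)
        }
        out["per_species_scaffolds"][sp] = len(scaffolds)
    for gname, members in groups.items():
        members = [m for m in members if m in table.species]
        n_1to1 = 0
        for chrom in table.autosomes():
            if members and all(
                _is_one_to_one(table.entry(chrom, sp)) for sp in members
            ):
                n_1to1 += 1
        counts = [
            len(table.entry(chrom, sp))
            for chrom in table.ref_chroms
            for sp in members
            if table.entry(chrom, sp)
        ]
        out["groups"][gname] = {
            "n_autosomes_one_to_one": n_1to1,
            "min_fragments_per_chrom": min(counts) if counts else 0,
            "max_fragments_per_chrom": max(counts) if counts else 0,
        }
    return out


def recommend_naming(
    table: ScaffotypeTable, reference_metadata: Mapping[str, object]
) -> NamingReport:
    """Apply the scaffold-naming rules.

    The reference genome must have more than 90% of its sequence anchored
    to chromosomes; reference-name adoption is recommended only with a full
    complement of 1:1 chromosome orthologs across every species, otherwise
    scaffolds should be named by size rank.
    """
    anchored = float(reference_metadata.get("anchored_fraction", 0.0))  # type: ignore[arg-type]
    ref_name = str(reference_metadata.get("name", "reference"))
    if anchored <= ANCHORED_FRACTION_GATE:
        return NamingReport(
            reference_accepted=False,
            full_one_to_one=False,
            recommendation="choose-different-reference",
            message=(
                f"{ref_name}: only {anchored:.0%} of sequence anchored to "
                f"chromosomes; a reference needs > {ANCHORED_FRACTION_GATE:.0%} "
                "anchored and a known karyotype"
            ),
        )
    full = all(
        _is_one_to_one(table.entry(chrom, sp))
        for chrom in table.ref_chroms
        for sp in table.species
    )
    if full:
        return NamingReport(
            reference_accepted=True,
            full_one_to_one=True,
            recommendation="adopt-reference-names",
            message=(
                f"full complement of 1:1 chromosome orthologs to {ref_name}; "
                "scaffolds may adopt the reference chromosome nomenclature"
            ),
        )
    return NamingReport(
        reference_accepted=True,
        full_one_to_one=False,
        recommendation="size-rank-naming",
        message=(
            "not all chromosomes are 1:1 across species; name scaffolds by "
            "size rank and relate them through the orthology table"
        ),
    )


# ---------------------------------------------------------------------------
# Packaged carnivore table


def load_packaged_table() -> ScaffotypeTable:
    """The carnivore orthology table shipped with the package (cat reference)."""
    text = (
        resources.files("scaffotype3d").joinpath("data/table1_carnivores.tsv").read_text()
    )
    return parse_table1(text)


def load_packaged_metadata() -> dict[str, dict]:
    """Species groups and diploid numbers for the packaged carnivore table."""
    text = (
        resources.files("scaffotype3d").joinpath("data/species_groups.tsv").read_text()
    )
    groups: dict[str, list[str]] = {}
    diploid: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sp, group, n2 = line.split("\t")
        groups.setdefault(group, []).append(sp)
        diploid[sp] = int(n2)
    return {"groups": groups, "diploid_numbers": diploid}
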