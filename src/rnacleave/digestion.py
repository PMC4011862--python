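"""Complete single-pass RNase digestion of a structure model.

The digestion model is deliberately idealised, matching how probing
results are usually interpreted on a gel:

* the enzyme has equal access to every recognised structural motif — each
  recognised residue is cut, with no kinetic or occupancy modelling;
* digestion is single-pass: all implied bonds are cut simultaneously and
  the resulting fragments are not further substrates (the structure that
  made a residue a substrate no longer exists after fragmentation);
* enzymes in a panel are never pooled — each enzyme is a separate
  reaction, one lane per enzyme as on a probing gel.

A cleavage site at a molecule terminus (a 3'-cut at the last residue, or
a 5'-cut at the first) is recorded as a site but cuts no internal bond
and therefore creates no fragment boundary.

Fragments shorter than ``min_fragment_length`` (default 2 nt) are kept in
the result with ``short_flag`` set: they still appear on gels and maps
but are excluded from downstream analyses such as uniqueness and the
pass-filter counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .enzymes import CutSide, RnaseSpec, build_panel, residue_recognized
from .structure_io import SecondaryStructure

DEFAULT_MIN_FRAGMENT_LENGTH = 2


@dataclass(frozen=True)
class CleavageSite:
    """A recognised residue and the phosphodiester bond it implies.

    ``bond`` is the (i, i+1) bond that is cut, or ``None`` when the site
    sits at a terminus and no internal bond exists.
    """

    position: int
    enzyme: str
    bond: tuple[int, int] | None


@dataclass
class Fragment:
    """A digestion product: a contiguous slice of the parent sequence."""

    start: int
    end: int
    sequence: str
    enzyme: str
    short_flag: bool = False
    occurrence_count: int = 1
    length_unique_in_lane: bool = True
    unique_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Lane:
    """One enzyme's digest: its sites and 5'->3' ordered fragments."""

    spec: RnaseSpec
    sites: list[CleavageSite]
    fragments: list[Fragment]

    @property
    def enzyme(self) -> str:
        return self.spec.name

    def analysis_fragments(self) -> list[Fragment]:
        """Fragments passing the minimum-length filter."""
        return [f for f in self.fragments if not f.short_flag]


@dataclass
class DigestResult:
    """Per-enzyme digests of one structure model."""

    structure: SecondaryStructure
    lanes: dict[str, Lane] = field(default_factory=dict)
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH


def cut_bond(spec: RnaseSpec, position: int, length: int) -> tuple[int, int] | None:
    """The internal bond cut by ``spec`` at a recognised ``position``.

    3'-cutters cleave the bond (position, position + 1); 5'-cutters the
    bond (position - 1, position).  Returns ``None`` at a terminus.
    """
    if spec.cut_side is CutSide.THREE_PRIME:
        return (position, position + 1) if position < length else None
    return (position - 1, position) if position > 1 else None


def find_cleavage_sites(structure: SecondaryStructure, spec: RnaseSpec) -> list[CleavageSite]:
    """All recognised positions for ``spec``, in ascending order."""
    sites = []
    for pos in range(1, structure.length + 1):
        if residue_recognized(spec, structure, pos):
            sites.append(
                CleavageSite(position=pos, enzyme=spec.name,
                             bond=cut_bond(spec, pos, structure.length))
            )
    return sites


def digest(
    structure: SecondaryStructure,
    spec: RnaseSpec,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> Lane:
    """Complete single-pass digest of ``structure`` with one enzyme.

    Every internal bond implied by a cleavage site is cut simultaneously;
    the fragments tile the parent exactly (coordinates are contiguous and
    lengths sum to the parent length).
    """
    sites = find_cleavage_sites(structure, spec)
    n = structure.length
    cut_after = sorted({site.bond[0] for site in sites if site.bond is not None})
    boundaries = [0] + cut_after + [n]
    fragments = []
    for left, right in zip(boundaries, boundaries[1:]):
        start, end = left + 1, right
        seq = structure.sequence.residues[start - 1 : end]
        fragments.append(
            Fragment(
                start=start,
                end=end,
                sequence=seq,
                enzyme=spec.name,
                short_flag=(end - start + 1) < min_fragment_length,
            )
        )
    return Lane(spec=spec, sites=sites, fragments=fragments)


def digest_panel(
    structure: SecondaryStructure,
    specs: Iterable[RnaseSpec],
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> DigestResult:
    """Independent per-enzyme digests (one lane per enzyme, never pooled)."""
    panel = build_panel(specs)
    result = DigestResult(structure=structure, min_fragment_length=min_fragment_length)
    for spec in panel:
        result.lanes[spec.name] = digest(structure, spec, min_fragment_length)
    find_unique_fragments(result)
    return result


def count_occurrences(parent: str, sub: str) -> int:
    """Occurrences of ``sub`` in ``parent``, counting overlaps.

    Overlapping occurrences count because a hybridisation probe cannot
    distinguish overlapping sites either.
    """
    if not sub:
        return 0
    count = start = 0
    while True:
        idx = parent.find(sub, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def find_unique_fragments(result: DigestResult) -> list[Fragment]:
    """Flag unambiguously identifiable fragments; return the unique ones.

    A fragment is unique iff (a) its sequence occurs exactly once as a
    substring of the parent, and (b) its length differs from every other
    analysis-grade fragment in the same lane, so the band is
    distinguishable on a gel.  Both sub-criteria are stored per fragment
    (``occurrence_count``, ``length_unique_in_lane``) so either can be
    applied on its own.  Short-flagged fragments are never unique.
    """
    parent = result.structure.sequence.residues
    unique: list[Fragment] = []
    for lane in result.lanes.values():
        analysis = lane.analysis_fragments()
        length_counts: dict[int, int] = {}
        for frag in analysis:
            length_counts[frag.length] = length_counts.get(frag.length, 0) + 1
        for frag in lane.fragments:
            frag.occurrence_count = count_occurrences(parent, frag.sequence)
            frag.length_unique_in_lane = length_counts.get(frag.length, 0) == 1
            frag.unique_flag = (
                not frag.short_flag
                and frag.occurrence_count == 1
                and frag.length_unique_in_lane
            )
            if frag.unique_flag:
                unique.append(frag)
    return unique


def digest_statistics(result: DigestResult) -> list[dict]:
    """Per-enzyme summary rows: sites, fragments, filter and unique counts."""
    rows = []
    for lane in result.lanes.values():
        analysis = lane.analysis_fragments()
        rows.append(
            {
                "enzyme": lane.enzyme,
                "n_sites": len(lane.sites),
                "site_positions": [s.position for s in lane.sites],
                "n_fragments": len(lane.fragments),
                "n_pass_filter": len(analysis),
                "n_unique": sum(1 for f in lane.fragments if f.unique_flag),
            }
        )
    return rows


def format_statistics_table(result: DigestResult) -> str:
    """Tab-delimited statistics table, one row per enzyme lane."""
    header = ["enzyme", "n_sites", "site_positions", "n_fragments", "n_pass_filter", "n_unique"]
    lines = ["\t".join(header)]
    for row in digest_statistics(result):
        lines.append(
            "\t".join(
                [
                    row["enzyme"],
                    str(row["n_sites"]),
                    ",".join(str(p) for p in row["site_positions"]) or "-",
                    str(row["n_fragments"]),
                    str(row["n_pass_filter"]),
                    str(row["n_unique"]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def format_fragment_table(lane: Lane) -> str:
    """Tab-delimited fragment table for one lane."""
    header = ["enzyme", "start", "end", "length", "sequence", "short_flag", "unique_flag"]
    lines = ["\t".join(header)]
    for frag in lane.fragments:
        lines.append(
            "\t".join(
                [
                    frag.enzyme,
                    str(frag.start),
                    str(frag.end),
                    str(frag.length),
                    frag.sequence,
                    str(int(frag.short_flag)),
                    str(int(frag.unique_flag)),
                ]
            )
        )
    return "\n".join(lines) + "\n"
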