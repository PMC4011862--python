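"""Visual outputs: schematic gel, digestion map, annotated sequence listing.

Migration on the schematic gel follows the standard log-length model for
denaturing gels: with a ladder spanning [Lmin, Lmax],

    migration(L) = (log10(Lmax) - log10(L)) / (log10(Lmax) - log10(Lmin))

so the shortest ladder band migrates to 1 (bottom of the gel) and the
longest to 0 (the well).  Fragment lengths outside the ladder span are
clamped with a warning.  Co-migrating equal-length fragments in one lane
merge into a single band carrying a multiplicity label — on a real gel
they are one band of higher intensity.

All renderers are pure functions of their inputs; re-rendering the same
digest is byte-identical.  SVG is emitted directly (SVG 1.1, no external
drawing dependency); text maps use a fixed-width ruler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from xml.etree import ElementTree as ET

from .digestion import DigestResult, Lane
from .enzymes import RnaseSpec, residue_recognized
from .structure_io import SecondaryStructure, write_dotbracket

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass(frozen=True)
class Band:
    """One gel band: merged fragments of equal length in one lane."""

    length: int
    migration: float
    multiplicity: int

    @property
    def label(self) -> str:
        tag = f"{self.length} nt"
        return tag if self.multiplicity == 1 else f"{tag} ×{self.multiplicity}"


@dataclass(frozen=True)
class GelLane:
    enzyme: str
    bands: tuple[Band, ...]


def default_ladder(parent_length: int) -> list[int]:
    """Decade ladder 10, 20, ... rounded up to cover the parent length."""
    top = max(20, 10 * math.ceil(parent_length / 10))
    return list(range(10, top + 1, 10))


def migration(length: int, lmin: int, lmax: int) -> float:
    """Normalised migration distance of a band of ``length`` nt."""
    if lmin >= lmax:
        raise ValueError("ladder must span at least two distinct lengths")
    value = (math.log10(lmax) - math.log10(length)) / (math.log10(lmax) - math.log10(lmin))
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"fragment length {length} nt outside ladder span [{lmin}, {lmax}]; "
            "band clamped to the gel edge",
            stacklevel=2,
        )
    return min(1.0, max(0.0, value))


def simulate_gel(
    result: DigestResult, ladder: list[int] | None = None
) -> tuple[list[GelLane], GelLane]:
    """Build gel lanes for each enzyme plus a ladder lane."""
    if not result.lanes:
        raise ValueError("digest result has no lanes")
    rungs = sorted(ladder) if ladder else default_ladder(result.structure.length)
    lmin, lmax = rungs[0], rungs[-1]
    lanes = []
    for lane in result.lanes.values():
        counts: dict[int, int] = {}
        for frag in lane.fragments:
            counts[frag.length] = counts.get(frag.length, 0) + 1
        bands = tuple(
            Band(length=length, migration=migration(length, lmin, lmax), multiplicity=k)
            for length, k in sorted(counts.items(), reverse=True)
        )
        lanes.append(GelLane(enzyme=lane.enzyme, bands=bands))
    ladder_lane = GelLane(
        enzyme="ladder",
        bands=tuple(
            Band(length=length, migration=migration(length, lmin, lmax), multiplicity=1)
            for length in sorted(rungs, reverse=True)
        ),
    )
    return lanes, ladder_lane


def render_gel_svg(lanes: list[GelLane], ladder_lane: GelLane) -> str:
    """Draw the schematic gel (ladder lane first) as an SVG document."""
    lane_width, gel_height, margin = 70, 360, 30
    all_lanes = [ladder_lane] + lanes
    width = margin * 2 + lane_width * len(all_lanes)
    height = gel_height + margin * 2
    svg = ET.Element(
        "svg",
        {"xmlns": SVG_NS, "version": "1.1", "width": str(width), "height": str(height)},
    )
    ET.SubElement(
        svg, "rect",
        {"x": "0", "y": "0", "width": str(width), "height": str(height), "fill": "#f8f8f8"},
    )
    for idx, lane in enumerate(all_lanes):
        x0 = margin + idx * lane_width
        label = ET.SubElement(
            svg, "text",
            {"x": str(x0 + lane_width / 2), "y": str(margin - 10),
             "text-anchor": "middle", "font-size": "12"},
        )
        label.text = lane.enzyme
        for band in lane.bands:
            y = margin + band.migration * gel_height
            ET.SubElement(
                svg, "rect",
                {"x": str(x0 + 8), "y": f"{y:.2f}", "width": str(lane_width - 16),
                 "height": "4", "fill": "#222",
                 "class": "band"},
            )
            text = ET.SubElement(
                svg, "text",
                {"x": str(x0 + lane_width - 4), "y": f"{y + 4:.2f}",
                 "text-anchor": "start", "font-size": "9", "fill": "#555"},
            )
            text.text = band.label
    return ET.tostring(svg, encoding="unicode")


def _ruler(n: int) -> list[str]:
    """Two fixed-width ruler lines: tens markers and position ticks."""
    ticks = "".join("|" if i % 10 == 0 else ("." if i % 5 == 0 else " ")
                    for i in range(1, n + 1))
    numbers = [" "] * n
    for i in range(10, n + 1, 10):
        label = str(i)
        start = i - len(label)
        numbers[start:i] = list(label)
    return ["".join(numbers), ticks]


def render_digest_map_text(result: DigestResult) -> str:
    """Fixed-width map: ruler, sequence, one interval line per lane.

    Analysis-grade fragments are drawn with ``=`` runs, short-flagged
    fragments with ``#``, and cleavage-site bonds marked ``/`` between
    fragments (the character after each fragment end).
    """
    n = result.structure.length
    lines = _ruler(n)
    lines.append(result.structure.sequence.residues)
    for lane in result.lanes.values():
        row = [" "] * n
        for frag in lane.fragments:
            fill = "#" if frag.short_flag else "="
            for pos in range(frag.start, frag.end + 1):
                row[pos - 1] = fill
        lines.append("".join(row) + f"  {lane.enzyme}")
        site_row = [" "] * n
        for site in lane.sites:
            site_row[site.position - 1] = "/"
        lines.append("".join(site_row) + f"  {lane.enzyme} sites")
    return "\n".join(lines) + "\n"


def render_digest_map_svg(result: DigestResult) -> str:
    """Per-lane fragment intervals over a sequence ruler, as SVG."""
    n = result.structure.length
    scale = max(2.0, 760 / n)
    margin, row_height = 40, 26
    width = int(margin * 2 + n * scale)
    height = margin * 2 + row_height * (len(result.lanes) + 1)
    svg = ET.Element(
        "svg",
        {"xmlns": SVG_NS, "version": "1.1", "width": str(width), "height": str(height)},
    )
    axis_y = margin
    ET.SubElement(
        svg, "line",
        {"x1": str(margin), "y1": str(axis_y), "x2": f"{margin + n * scale:.2f}",
         "y2": str(axis_y), "stroke": "#333", "stroke-width": "1"},
    )
    for pos in range(10, n + 1, 10):
        x = margin + (pos - 0.5) * scale
        tick = ET.SubElement(
            svg, "text",
            {"x": f"{x:.2f}", "y": str(axis_y - 6), "text-anchor": "middle",
             "font-size": "9", "fill": "#333"},
        )
        tick.text = str(pos)
    for row, lane in enumerate(result.lanes.values(), start=1):
        y = axis_y + row * row_height
        name = ET.SubElement(
            svg, "text",
            {"x": "4", "y": f"{y + 10:.2f}", "font-size": "11"},
        )
        name.text = lane.enzyme
        for frag in lane.fragments:
            x = margin + (frag.start - 1) * scale
            w = frag.length * scale
            cls = "short" if frag.short_flag else "product"
            fill = "#000000" if frag.short_flag else "#2e8b57"
            ET.SubElement(
                svg, "rect",
                {"x": f"{x:.2f}", "y": f"{y:.2f}", "width": f"{w - max(1.0, scale * 0.15):.2f}",
                 "height": "12", "fill": fill, "class": cls,
                 "data-start": str(frag.start), "data-end": str(frag.end)},
            )
        for site in lane.sites:
            x = margin + (site.position - 0.5) * scale
            ET.SubElement(
                svg, "line",
                {"x1": f"{x:.2f}", "y1": f"{y - 4:.2f}", "x2": f"{x:.2f}",
                 "y2": f"{y:.2f}", "stroke": "#c0392b", "stroke-width": "1",
                 "class": "site"},
            )
    return ET.tostring(svg, encoding="unicode")


def annotate_structure(structure: SecondaryStructure, spec: RnaseSpec) -> list[str]:
    """Per-residue class ('recognized' / 'unrecognized') for one enzyme."""
    return [
        "recognized" if residue_recognized(spec, structure, pos) else "unrecognized"
        for pos in range(1, structure.length + 1)
    ]


def render_annotated_structure_text(structure: SecondaryStructure, spec: RnaseSpec) -> str:
    """Sequence, dot-bracket and a marker line (* = recognised residue)."""
    classes = annotate_structure(structure, spec)
    markers = "".join("*" if c == "recognized" else " " for c in classes)
    db = write_dotbracket(structure, include_header=False).splitlines()[1]
    return "\n".join(
        [
            f"# {spec.name}: {spec.note or 'recognised residues marked with *'}",
            structure.sequence.residues,
            db,
            markers,
        ]
    ) + "\n"


def render_annotated_structure_svg(structure: SecondaryStructure, spec: RnaseSpec) -> str:
    """Colour-annotated linear sequence listing for one enzyme, as SVG."""
    classes = annotate_structure(structure, spec)
    per_row = 50
    n = structure.length
    rows = (n + per_row - 1) // per_row
    char_w, row_h, margin = 12, 34, 30
    width = margin * 2 + per_row * char_w
    height = margin * 2 + rows * row_h
    svg = ET.Element(
        "svg",
        {"xmlns": SVG_NS, "version": "1.1", "width": str(width), "height": str(height),
         "font-family": "monospace"},
    )
    title = ET.SubElement(svg, "text", {"x": str(margin), "y": "18", "font-size": "12"})
    title.text = f"{spec.name} recognition map"
    for pos in range(1, n + 1):
        row, col = divmod(pos - 1, per_row)
        x = margin + col * char_w
        y = margin + row * row_h + 14
        cls = classes[pos - 1]
        text = ET.SubElement(
            svg, "text",
            {"x": str(x), "y": str(y), "font-size": "13", "class": cls,
             "fill": "#000000" if cls == "recognized" else "#2e8b57"},
        )
        text.text = structure.sequence.base(pos)
    return ET.tostring(svg, encoding="unicode")
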