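"""Invert digestion products into per-residue pairing constraints.

The inverse problem of digestion simulation: given the reference sequence
and the product sequences obtained with each enzyme, infer for every
residue whether it was paired, unpaired, or cannot be decided, then emit
mfold constraint commands.

Evidence model
--------------
Every occurrence of a product in the reference is located (all
occurrences, counting overlaps, with equal weight — the experiment cannot
tell them apart).  A product occupying ``[s..e]`` implies two cut bonds:
one at its 3' end and one just upstream of its 5' start.  For a 3'-cutter
the residue carrying the enzyme's required pairing status is the residue
5' of the cut bond, so:

* if ``e < N``: residue ``e`` has the enzyme's required status
  (``fragment_end`` evidence);
* if ``s > 1``: residue ``s - 1`` has the required status
  (``fragment_start_upstream`` evidence).

No evidence is emitted at the molecule termini — there is no bond beyond
position N or before position 1 to cut.  An evidence residue whose base
is not in the enzyme's recognised set marks a chemically impossible
cleavage; such items are reported and excluded from resolution, since
they indicate a mislabelled product and would poison the constraint set.

Conflict resolution applies three ordered rules per residue when evidence
disagrees: (1) the status backed by the strictly longest source fragment
wins; (2) at equal maximum length, the status backed by more fragments
wins; (3) at equal length and count the status is set to undefined.  A
residue decided from partially inconsistent evidence carries a note.

Interior inference (opt-in, off by default): under complete digestion, a
recognised residue strictly inside a product was necessarily *not* in the
enzyme's required pairing state — otherwise it would have been cut.  When
enabled, each such residue contributes opposite-status evidence with the
enclosing fragment as source, resolved by the same three rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .enzymes import CutSide, PairingRequirement, RnaseSpec, build_panel
from .errors import AlphabetError, CompatibilityError, ReferenceLengthError
from .structure_io import RnaSequence

DEFAULT_MAX_REFERENCE_LENGTH = 200
MIN_PRODUCT_LENGTH = 2


class Status(str, Enum):
    PAIRED = "paired"
    UNPAIRED = "unpaired"
    UNDEFINED = "undefined"


_REQUIREMENT_STATUS = {
    PairingRequirement.PAIRED: Status.PAIRED,
    PairingRequirement.UNPAIRED: Status.UNPAIRED,
}
_OPPOSITE = {Status.PAIRED: Status.UNPAIRED, Status.UNPAIRED: Status.PAIRED}


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of per-residue pairing evidence from a product boundary."""

    residue: int
    implied_status: Status
    enzyme: str
    fragment_sequence: str
    fragment_length: int
    occurrence_start: int
    boundary_kind: str  # fragment_end | fragment_start_upstream | interior


@dataclass
class ResidueStatusArray:
    """Per-residue paired/unpaired/undefined verdicts for a reference."""

    reference: RnaSequence
    statuses: list[Status]
    notes: list[str | None]
    excluded_evidence: list[EvidenceItem] = field(default_factory=list)

    @classmethod
    def undefined(cls, reference: RnaSequence) -> "ResidueStatusArray":
        n = reference.length
        return cls(reference=reference, statuses=[Status.UNDEFINED] * n, notes=[None] * n)

    def status(self, position: int) -> Status:
        return self.statuses[position - 1]

    def set_status(self, position: int, status: Status, note: str | None = None) -> None:
        """Override a residue verdict (the array is user-editable before
        constraints are formatted)."""
        self.statuses[position - 1] = status
        self.notes[position - 1] = note

    def coverage(self) -> float:
        """Fraction of residues with a non-undefined verdict."""
        defined = sum(1 for s in self.statuses if s is not Status.UNDEFINED)
        return defined / len(self.statuses)

    def format_table(self) -> str:
        """Tab-delimited per-residue table: position, base, status, note."""
        lines = ["position\tbase\tstatus\tnote"]
        for i, (status, note) in enumerate(zip(self.statuses, self.notes), start=1):
            lines.append(
                f"{i}\t{self.reference.base(i)}\t{status.value}\t{note or '-'}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Constraint:
    """One mfold constraint command covering a run of residues."""

    kind: str  # force_paired | prohibit_paired
    start: int
    run_length: int

    def to_line(self) -> str:
        code = "F" if self.kind == "force_paired" else "P"
        return f"{code} {self.start} 0 {self.run_length}"


def validate_products(
    reference: RnaSequence | str,
    products: Mapping[str, Sequence[str]],
    max_length: int = DEFAULT_MAX_REFERENCE_LENGTH,
) -> dict[str, list[str]]:
    """Normalise and validate per-enzyme product lists against the reference.

    Products shorter than 2 nt are dropped with a warning (they carry no
    usable boundary information and are omitted from analysis).  A product
    absent from the reference raises :class:`CompatibilityError`; a
    reference longer than ``max_length`` raises
    :class:`ReferenceLengthError`.
    """
    ref = reference if isinstance(reference, RnaSequence) else RnaSequence.from_string(reference)
    if ref.length > max_length:
        raise ReferenceLengthError(
            f"reference is {ref.length} nt; constraint inference accepts at most "
            f"{max_length} nt"
        )
    validated: dict[str, list[str]] = {}
    for enzyme, seqs in products.items():
        kept: list[str] = []
        for raw in seqs:
            try:
                product = RnaSequence.from_string(raw).residues
            except AlphabetError as exc:
                # a non-RNA product can never occur in the reference
                raise CompatibilityError(
                    f"{enzyme} product {raw.strip()!r} is not an RNA sequence: {exc}"
                ) from exc
            if len(product) < MIN_PRODUCT_LENGTH:
                warnings.warn(
                    f"{enzyme} product {product!r} is shorter than "
                    f"{MIN_PRODUCT_LENGTH} nt and was omitted from the analysis",
                    stacklevel=2,
                )
                continue
            if product not in ref.residues:
                raise CompatibilityError(
                    f"{enzyme} product {product!r} does not occur in the reference sequence"
                )
            kept.append(product)
        validated[enzyme] = kept
    return validated


def _occurrences(reference: str, product: str) -> list[int]:
    """1-based start positions of all (overlapping) occurrences."""
    starts = []
    idx = reference.find(product)
    while idx != -1:
        starts.append(idx + 1)
        idx = reference.find(product, idx + 1)
    return starts


def locate_fragments(
    reference: RnaSequence,
    product: str,
    spec: RnaseSpec,
    interior_inference: bool = False,
) -> tuple[list[EvidenceItem], list[EvidenceItem]]:
    """Evidence from every occurrence of one product.

    Returns ``(usable, excluded)``: excluded items are those whose
    evidence residue's base the enzyme does not recognise (the implied
    cleavage is chemically impossible for that enzyme).
    """
    n = reference.length
    implied = _REQUIREMENT_STATUS[spec.requirement]
    usable: list[EvidenceItem] = []
    excluded: list[EvidenceItem] = []

    def emit(residue: int, status: Status, start: int, kind: str) -> None:
        item = EvidenceItem(
            residue=residue,
            implied_status=status,
            enzyme=spec.name,
            fragment_sequence=product,
            fragment_length=len(product),
            occurrence_start=start,
            boundary_kind=kind,
        )
        if kind == "interior" or reference.base(residue) in spec.recognized_residues:
            usable.append(item)
        else:
            excluded.append(item)

    for s in _occurrences(reference.residues, product):
        e = s + len(product) - 1
        if spec.cut_side is CutSide.THREE_PRIME:
            if e < n:
                emit(e, implied, s, "fragment_end")
            if s > 1:
                emit(s - 1, implied, s, "fragment_start_upstream")
            if interior_inference:
                for i in range(s, e):  # bonds (i, i+1) internal to the product
                    if reference.base(i) in spec.recognized_residues:
                        emit(i, _OPPOSITE[implied], s, "interior")
        else:  # 5'-cutter: cleavage at residue p cuts bond (p-1, p)
            if e < n:
                emit(e + 1, implied, s, "fragment_end")
            if s > 1:
                emit(s, implied, s, "fragment_start_upstream")
            if interior_inference:
                for i in range(s + 1, e + 1):  # bonds (i-1, i) internal
                    if reference.base(i) in spec.recognized_residues:
                        emit(i, _OPPOSITE[implied], s, "interior")
    return usable, excluded


def resolve_status(
    reference: RnaSequence,
    evidence: Iterable[EvidenceItem],
) -> ResidueStatusArray:
    """Apply the three ordered decision rules per residue.

    Deterministic and invariant to evidence order: the decision depends
    only on the multiset of (status, fragment length) pairs per residue.
    """
    array = ResidueStatusArray.undefined(reference)
    by_residue: dict[int, list[EvidenceItem]] = {}
    for item in evidence:
        by_residue.setdefault(item.residue, []).append(item)
    for residue, items in by_residue.items():
        support: dict[Status, list[EvidenceItem]] = {}
        for item in items:
            support.setdefault(item.implied_status, []).append(item)
        if len(support) == 1:
            status = next(iter(support))
            array.set_status(residue, status)
            continue
        paired_items = support[Status.PAIRED]
        unpaired_items = support[Status.UNPAIRED]
        max_paired = max(i.fragment_length for i in paired_items)
        max_unpaired = max(i.fragment_length for i in unpaired_items)
        conflict = (
            f"conflicting evidence: paired from {len(paired_items)} fragment(s) "
            f"(longest {max_paired} nt), unpaired from {len(unpaired_items)} "
            f"fragment(s) (longest {max_unpaired} nt)"
        )
        if max_paired != max_unpaired:
            winner = Status.PAIRED if max_paired > max_unpaired else Status.UNPAIRED
            array.set_status(residue, winner, f"decided by fragment length; {conflict}")
        elif len(paired_items) != len(unpaired_items):
            winner = Status.PAIRED if len(paired_items) > len(unpaired_items) else Status.UNPAIRED
            array.set_status(residue, winner, f"decided by fragment count; {conflict}")
        else:
            array.set_status(residue, Status.UNDEFINED, f"unresolved; {conflict}")
    return array


def format_mfold_constraints(array: ResidueStatusArray) -> list[Constraint]:
    """Run-length encode the status array into mfold constraint commands.

    Maximal runs of unpaired residues become ``P i 0 k`` (prohibit
    pairing); runs of paired residues become ``F i 0 k`` (force pairing).
    Undefined residues emit nothing.
    """
    constraints: list[Constraint] = []
    n = len(array.statuses)
    i = 0
    while i < n:
        status = array.statuses[i]
        if status is Status.UNDEFINED:
            i += 1
            continue
        j = i
        while j + 1 < n and array.statuses[j + 1] is status:
            j += 1
        kind = "force_paired" if status is Status.PAIRED else "prohibit_paired"
        constraints.append(Constraint(kind=kind, start=i + 1, run_length=j - i + 1))
        i = j + 1
    return constraints


def constraint_lines(constraints: Sequence[Constraint]) -> str:
    return "\n".join(c.to_line() for c in constraints) + ("\n" if constraints else "")


def infer_constraints(
    reference: RnaSequence | str,
    products: Mapping[str, Sequence[str]],
    panel: Iterable[RnaseSpec],
    max_length: int = DEFAULT_MAX_REFERENCE_LENGTH,
    interior_inference: bool = False,
) -> tuple[ResidueStatusArray, list[Constraint]]:
    """End-to-end inference: validate, locate, resolve, format.

    ``products`` maps enzyme names to lists of product sequences; each
    product is attributed to the enzyme whose list it arrived in.  The
    returned status array can be edited (``set_status``) and
    :func:`format_mfold_constraints` re-run to regenerate commands.
    """
    ref = reference if isinstance(reference, RnaSequence) else RnaSequence.from_string(reference)
    specs = {spec.name: spec for spec in build_panel(panel)}
    missing = set(products) - set(specs)
    if missing:
        raise CompatibilityError(
            f"product list(s) for enzyme(s) not in the panel: {', '.join(sorted(missing))}"
        )
    validated = validate_products(ref, products, max_length=max_length)
    evidence: list[EvidenceItem] = []
    excluded: list[EvidenceItem] = []
    for enzyme, product_list in validated.items():
        spec = specs[enzyme]
        for product in product_list:
            usable, impossible = locate_fragments(
                ref, product, spec, interior_inference=interior_inference
            )
            evidence.extend(usable)
            excluded.extend(impossible)
    for item in excluded:
        warnings.warn(
            f"{item.enzyme} product {item.fragment_sequence!r} at position "
            f"{item.occurrence_start} implies a chemically impossible cleavage at "
            f"residue {item.residue} ({ref.base(item.residue)}); evidence excluded",
            stacklevel=2,
        )
    array = resolve_status(ref, evidence)
    array.excluded_evidence = excluded
    return array, format_mfold_constraints(array)
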