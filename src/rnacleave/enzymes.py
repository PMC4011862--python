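"""Structure-specific RNase cleavage models.

Each enzyme is reduced to three parameters: the set of residues it
recognises, the pairing state the residue must be in (single-stranded
probes such as RNase T1 versus the double-strand probe RNase V1), and the
side of the recognised residue on which the phosphodiester bond is cut.
All the classical probing endonucleases cut 3' of the recognised residue;
the cut side is configurable for user-defined enzymes.

"Paired" is taken strictly from the pair table of the structure model.
RNase V1's true preference for helical stacking context is not modelled —
a residue with a partner is a V1 substrate, one without is not.

Built-in specificities follow the probing literature:

========  ==================  =========
enzyme    recognised          pairing
========  ==================  =========
T1        G                   unpaired
A         C, U                unpaired
U2        A                   unpaired
CL3       C                   unpaired
PhyM      A, U                unpaired
T2        A, C, G, U          unpaired
S1        A, C, G, U          unpaired
V1        A, C, G, U          paired
CVR       alias of V1 (cobra venom ribonuclease)
========  ==================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import EnzymeLookupError, ValidationError
from .structure_io import RNA_ALPHABET, SecondaryStructure


class PairingRequirement(str, Enum):
    PAIRED = "paired"
    UNPAIRED = "unpaired"


class CutSide(str, Enum):
    THREE_PRIME = "3prime"
    FIVE_PRIME = "5prime"


@dataclass(frozen=True)
class RnaseSpec:
    """Cleavage model for one structure-specific RNase."""

    name: str
    recognized_residues: frozenset[str]
    requirement: PairingRequirement
    cut_side: CutSide = CutSide.THREE_PRIME
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("enzyme name must be non-empty")
        if not self.recognized_residues:
            raise ValidationError(f"enzyme {self.name!r}: recognized residue set is empty")
        bad = set(self.recognized_residues) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"enzyme {self.name!r}: invalid residues {', '.join(sorted(bad))}"
            )

    def recognizes(self, base: str, paired: bool) -> bool:
        if base not in self.recognized_residues:
            return False
        return paired == (self.requirement is PairingRequirement.PAIRED)


def _builtin(name: str, residues: str, requirement: PairingRequirement, note: str) -> RnaseSpec:
    return RnaseSpec(
        name=name,
        recognized_residues=frozenset(residues),
        requirement=requirement,
        cut_side=CutSide.THREE_PRIME,
        note=note,
    )


BUILTIN_ENZYMES: dict[str, RnaseSpec] = {
    spec.name: spec
    for spec in (
        _builtin("T1", "G", PairingRequirement.UNPAIRED,
                 "cleaves 3' of unpaired guanosines"),
        _builtin("A", "CU", PairingRequirement.UNPAIRED,
                 "cleaves 3' of unpaired pyrimidines"),
        _builtin("T2", "ACGU", PairingRequirement.UNPAIRED,
                 "cleaves 3' of any unpaired residue (slight A preference not modelled)"),
        _builtin("S1", "ACGU", PairingRequirement.UNPAIRED,
                 "single-strand-specific nuclease; cleaves any unpaired residue"),
        _builtin("U2", "A", PairingRequirement.UNPAIRED,
                 "cleaves 3' of unpaired adenosines"),
        _builtin("CL3", "C", PairingRequirement.UNPAIRED,
                 "cleaves 3' of unpaired cytidines"),
        _builtin("PhyM", "AU", PairingRequirement.UNPAIRED,
                 "cleaves 3' of unpaired A and U"),
        _builtin("V1", "ACGU", PairingRequirement.PAIRED,
                 "cobra venom nuclease; cleaves paired (double-stranded) residues"),
        _builtin("CVR", "ACGU", PairingRequirement.PAIRED,
                 "cobra venom ribonuclease, alias of V1"),
    )
}

_BUILTIN_BY_CASEFOLD = {name.casefold(): spec for name, spec in BUILTIN_ENZYMES.items()}


def builtin_enzyme(name: str) -> RnaseSpec:
    """Look up a built-in enzyme by name (case-insensitive)."""
    spec = _BUILTIN_BY_CASEFOLD.get(name.casefold())
    if spec is None:
        available = ", ".join(sorted(BUILTIN_ENZYMES))
        raise EnzymeLookupError(f"unknown enzyme {name!r}; available: {available}")
    return spec


def make_custom_enzyme(
    name: str,
    residues: Iterable[str],
    requirement: PairingRequirement | str,
    cut_side: CutSide | str = CutSide.THREE_PRIME,
    note: str = "",
) -> RnaseSpec:
    """Build a user-defined enzyme, usable anywhere a built-in is."""
    req = PairingRequirement(requirement)
    side = CutSide(cut_side)
    residue_set = frozenset(str(r).upper().replace("T", "U") for r in residues)
    return RnaseSpec(
        name=name,
        recognized_residues=residue_set,
        requirement=req,
        cut_side=side,
        note=note,
    )


def residue_recognized(spec: RnaseSpec, structure: SecondaryStructure, position: int) -> bool:
    """True iff the residue at ``position`` (1-based) is a substrate of ``spec``.

    The base must be in the enzyme's recognised set and the residue's
    pairing state in the structure must match the enzyme's requirement.
    """
    if not 1 <= position <= structure.length:
        raise IndexError(f"position {position} out of range 1..{structure.length}")
    return spec.recognizes(structure.sequence.base(position), structure.is_paired(position))


def load_enzyme_file(path: str | Path) -> list[RnaseSpec]:
    """Load user enzyme definitions from a YAML file.

    The file is a list of mappings with keys ``name``, ``residues``
    (string or list), ``pairing`` (``paired``/``unpaired``) and optional
    ``cut_side`` (``3prime``/``5prime``) and ``note``::

        - name: X
          residues: GA
          pairing: unpaired
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ValidationError(f"enzyme file {path}: expected a list of enzyme entries")
    specs = []
    for entry in data:
        if not isinstance(entry, Mapping):
            raise ValidationError(f"enzyme file {path}: each entry must be a mapping")
        try:
            specs.append(
                make_custom_enzyme(
                    name=str(entry["name"]),
                    residues=entry["residues"],
                    requirement=entry["pairing"],
                    cut_side=entry.get("cut_side", CutSide.THREE_PRIME),
                    note=str(entry.get("note", "")),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"enzyme file {path}: missing key {exc}") from exc
    return specs


def build_panel(specs: Iterable[RnaseSpec]) -> list[RnaseSpec]:
    """Validate an enzyme panel: non-empty, unique names."""
    panel = list(specs)
    if not panel:
        raise ValidationError("enzyme panel is empty")
    seen: set[str] = set()
    for spec in panel:
        if spec.name in seen:
            raise ValidationError(f"duplicate enzyme name in panel: {spec.name!r}")
        seen.add(spec.name)
    return panel
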