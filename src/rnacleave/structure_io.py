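"""Sequences and secondary-structure models: CT, dot-bracket and FASTA I/O.

An RNA secondary structure is held as a sequence plus a pair table: a
1-based mapping from each position to its partner position, with 0 meaning
unpaired.  This matches the mfold CT convention, and every coordinate used
downstream (cleavage sites, fragments, constraints) is 1-based inclusive.

Supported formats:

* mfold CT — header line ``<length> <title>`` followed by one six-column
  record per residue (index, base, previous, next, partner, natural index).
  The previous/next columns are redundant and ignored on read; they are
  written canonically on output.
* Vienna dot-bracket — an optional ``>`` header, a sequence line, and a
  structure line of ``(``, ``)`` and ``.``.  Pseudoknot bracket alphabets
  (``[``, ``{``, letters) are rejected rather than silently dropped:
  thermodynamic folders such as mfold emit only pseudoknot-free models,
  so extra bracket types indicate input this tool cannot interpret.
* FASTA or bare sequence text for plain sequences.  DNA ``T`` is accepted
  and normalised to ``U`` (users routinely paste cDNA-derived sequences);
  whitespace and digits are stripped so numbered sequence blocks copied
  from GenBank-style flat files parse unchanged.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import (
    AlphabetError,
    ConsistencyError,
    FormatError,
    UnsupportedNotationError,
    UnsupportedStructureError,
)

RNA_ALPHABET = frozenset("ACGU")

_STRIP_RE = re.compile(r"[\s\d]+")


def _normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Strip whitespace/digits, upper-case, map T to U, validate alphabet."""
    cleaned = _STRIP_RE.sub("", raw).upper().replace("T", "U")
    bad = set(cleaned) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context} contains non-RNA characters: {', '.join(sorted(bad))}"
        )
    return cleaned


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with an identifier.

    ``residues`` is an upper-case string over {A, C, G, U}; construction
    through :meth:`from_string` performs normalisation (T->U, case,
    whitespace/digit stripping).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError("sequence must contain at least one residue")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence contains non-RNA characters: {', '.join(sorted(bad))}"
            )

    @classmethod
    def from_string(cls, raw: str, id: str = "") -> "RnaSequence":
        return cls(id=id, residues=_normalize_residues(raw))

    @property
    def length(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} out of range 1..{self.length}")
        return self.residues[position - 1]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence plus its pair table.

    ``pairs[i]`` (1-based, exposed through :meth:`partner`) is the partner
    of position *i*, or 0 if unpaired.  The table is validated on
    construction: symmetric, irreflexive, in range.
    """

    sequence: RnaSequence
    pairs: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        n = self.sequence.length
        if len(self.pairs) != n:
            raise ConsistencyError(
                f"pair table has {len(self.pairs)} entries for {n} residues"
            )
        for i, j in enumerate(self.pairs, start=1):
            if j == i:
                raise ConsistencyError(f"position {i} pairs with itself")
            if not 0 <= j <= n:
                raise ConsistencyError(f"partner {j} of position {i} out of range")
            if j != 0 and self.pairs[j - 1] != i:
                raise ConsistencyError(
                    f"asymmetric pairing: {i} -> {j} but {j} -> {self.pairs[j - 1]}"
                )

    @property
    def length(self) -> int:
        return self.sequence.length

    def partner(self, position: int) -> int:
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} out of range 1..{self.length}")
        return self.pairs[position - 1]

    def is_paired(self, position: int) -> bool:
        return self.partner(position) != 0

    def pair_map(self) -> dict[int, int]:
        """Pair table as a dict {position: partner-or-0}, 1-based."""
        return {i: j for i, j in enumerate(self.pairs, start=1)}


def parse_ct(text: str) -> SecondaryStructure:
    """Parse mfold CT content into a :class:`SecondaryStructure`.

    Raises :class:`FormatError` on malformed records or a length mismatch,
    :class:`ConsistencyError` on asymmetric pairing and
    :class:`AlphabetError` on non-RNA bases.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT input")
    header = lines[0].split()
    try:
        declared = int(header[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"CT header must start with the residue count: {lines[0]!r}") from exc
    title = " ".join(header[1:])
    records = lines[1:]
    if len(records) != declared:
        raise FormatError(
            f"CT header declares {declared} residues but {len(records)} records follow"
        )
    bases: list[str] = []
    partners: list[int] = []
    for lineno, line in enumerate(records, start=1):
        cols = line.split()
        if len(cols) < 6:
            raise FormatError(f"CT record line {lineno + 1} has {len(cols)} columns, expected 6")
        try:
            idx = int(cols[0])
            partner = int(cols[4])
        except ValueError as exc:
            raise FormatError(f"non-numeric field in CT record line {lineno + 1}") from exc
        if idx != lineno:
            raise FormatError(
                f"CT record {lineno + 1} has index {idx}, expected {lineno}"
            )
        base = _normalize_residues(cols[1], context=f"CT record {lineno + 1}")
        if len(base) != 1:
            raise FormatError(f"CT record {lineno + 1} base field is not a single residue")
        bases.append(base)
        partners.append(partner)
    seq = RnaSequence(id=title, residues="".join(bases))
    return SecondaryStructure(sequence=seq, pairs=tuple(partners))


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse two-line Vienna dot-bracket (optional ``>`` header) content."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    name = ""
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) < 2:
        raise FormatError("dot-bracket input needs a sequence line and a structure line")
    seq_line, struct_line = lines[0], lines[1]
    if len(struct_line) != len(seq_line):
        raise FormatError(
            f"structure line length {len(struct_line)} differs from sequence length {len(seq_line)}"
        )
    unsupported = set(struct_line) - set("().")
    if unsupported:
        raise UnsupportedNotationError(
            "unsupported bracket characters "
            f"{', '.join(sorted(unsupported))}; only pseudoknot-free '(', ')', '.' notation is accepted"
        )
    seq = RnaSequence.from_string(seq_line, id=name)
    pairs = [0] * seq.length
    stack: list[int] = []
    for i, ch in enumerate(struct_line, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j - 1] = i
            pairs[i - 1] = j
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(sequence=seq, pairs=tuple(pairs))


def write_ct(structure: SecondaryStructure, title: str | None = None) -> str:
    """Write a structure as mfold CT text; ``parse_ct`` round-trips it."""
    n = structure.length
    name = title if title is not None else (structure.sequence.id or "structure")
    out = [f"{n} {name}"]
    for i in range(1, n + 1):
        nxt = i + 1 if i < n else 0
        out.append(
            f"{i} {structure.sequence.base(i)} {i - 1} {nxt} {structure.partner(i)} {i}"
        )
    return "\n".join(out) + "\n"


def write_dotbracket(structure: SecondaryStructure, include_header: bool = True) -> str:
    """Write Vienna dot-bracket text.

    Raises :class:`UnsupportedStructureError` if the pair table contains
    crossing pairs (a pseudoknot), which plain bracket notation cannot
    express.
    """
    n = structure.length
    chars = ["."] * n
    stack: list[int] = []
    for i in range(1, n + 1):
        j = structure.partner(i)
        if j > i:
            stack.append(j)
            chars[i - 1] = "("
        elif 0 < j < i:
            if not stack or stack[-1] != i:
                raise UnsupportedStructureError(
                    f"crossing pairs involving position {i}: structure is pseudoknotted"
                )
            stack.pop()
            chars[i - 1] = ")"
    lines = []
    if include_header and structure.sequence.id:
        lines.append(f">{structure.sequence.id}")
    lines.append(structure.sequence.residues)
    lines.append("".join(chars))
    return "\n".join(lines) + "\n"


def parse_fasta(text: str, id: str = "") -> RnaSequence:
    """Parse FASTA or bare sequence text into a single :class:`RnaSequence`.

    Multi-record FASTA uses the first record only, with a warning: the
    digestion workflow operates on one molecule at a time.  Bare text may
    contain whitespace and position numbers, which are stripped.
    """
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise FormatError("no FASTA records found")
        if len(records) > 1:
            warnings.warn(
                f"FASTA input has {len(records)} records; using the first "
                f"({records[0].id}) only",
                stacklevel=2,
            )
        rec = records[0]
        return RnaSequence.from_string(str(rec.seq), id=rec.id)
    return RnaSequence.from_string(text, id=id)
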