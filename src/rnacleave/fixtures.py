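"""Seeded random structures and synthetic digestion experiments.

Everything the package does can be exercised without external data: this
module generates pseudoknot-free secondary structures of controlled
length and pairing density, digests them with an enzyme panel, and
returns the product lists together with the hidden true structure so that
constraint inference can be scored against ground truth.

Generated structures are structurally valid but not thermodynamically
realistic: pairs are inserted by random nested sampling, not by energy
minimisation.  Sequences are uniform over {A, C, G, U}; when a sampled
pair is not complementary, the 3' partner is rewritten to a complementary
base (Watson–Crick, plus G·U wobble unless disabled), which slightly
enriches complementarity at paired positions — as base-pairing does in
real molecules.

All randomness is seeded through ``random.Random``; no global state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .digestion import DEFAULT_MIN_FRAGMENT_LENGTH, DigestResult, digest_panel
from .enzymes import RnaseSpec, builtin_enzyme
from .errors import ValidationError
from .structure_io import RnaSequence, SecondaryStructure

_MIN_LOOP = 3  # minimum hairpin loop: |j - i| > 3 for a pair (i, j)

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of one synthetic structure / experiment.

    ``pairing_density`` is the target fraction of residues that are
    paired; for short molecules or high densities it is approximated
    best-effort (nested insertion can exhaust legal slots).
    """

    length: int = 150
    pairing_density: float = 0.4
    seed: int = 0
    panel: tuple[str, ...] = ("T1", "A", "V1", "T2")
    allow_gu: bool = True
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("length must be >= 1")
        if not 0.0 <= self.pairing_density <= 1.0:
            raise ValidationError("pairing density must be in [0, 1]")


def random_structure(config: FixtureConfig) -> SecondaryStructure:
    """Random pseudoknot-free structure, deterministic per seed.

    A uniform random sequence is drawn first; pairs (i, j) are then
    inserted one at a time at random, rejecting candidates that would
    cross an existing pair, re-use a paired position, or close a hairpin
    loop shorter than 3 nt, until the target density is reached or an
    attempt budget is exhausted.
    """
    rng = random.Random(config.seed)
    n = config.length
    bases = [rng.choice("ACGU") for _ in range(n)]
    pairs = [0] * n
    target_pairs = int(round(config.pairing_density * n / 2))
    attempts = 0
    budget = 200 * max(1, target_pairs)
    placed = 0
    while placed < target_pairs and attempts < budget:
        attempts += 1
        i = rng.randrange(1, n + 1)
        j = rng.randrange(1, n + 1)
        if i > j:
            i, j = j, i
        if j - i <= _MIN_LOOP:
            continue
        if pairs[i - 1] or pairs[j - 1]:
            continue
        if not _nestable(pairs, i, j):
            continue
        bi = bases[i - 1]
        complements = [_WC[bi]]
        if config.allow_gu and bi in _WOBBLE:
            complements.append(_WOBBLE[bi])
        if bases[j - 1] not in complements:
            bases[j - 1] = rng.choice(complements)
        pairs[i - 1], pairs[j - 1] = j, i
        placed += 1
    seq = RnaSequence(id=f"synthetic-seed{config.seed}", residues="".join(bases))
    return SecondaryStructure(sequence=seq, pairs=tuple(pairs))


def _nestable(pairs: list[int], i: int, j: int) -> bool:
    """True if adding pair (i, j) keeps the pair set pseudoknot-free."""
    for a, b in ((p, q) for p, q in enumerate(pairs, start=1) if q > p):
        inside_a = i < a < j
        inside_b = i < b < j
        if inside_a != inside_b:
            return False
    return True


@dataclass
class SyntheticExperiment:
    """A simulated probing experiment with its hidden ground truth."""

    reference: RnaSequence
    products: dict[str, list[str]]
    structure: SecondaryStructure
    digest: DigestResult = field(repr=False, default=None)  # type: ignore[assignment]


def synthetic_experiment(config: FixtureConfig) -> SyntheticExperiment:
    """Digest a random structure and collect per-enzyme product lists.

    Products are the analysis-grade (non-short) fragment sequences of
    each lane, in 5'->3' order, duplicates retained — an experimenter
    sequencing every band would likewise recover repeats.
    """
    structure = random_structure(config)
    panel = [builtin_enzyme(name) for name in config.panel]
    result = digest_panel(structure, panel, min_fragment_length=config.min_fragment_length)
    products = {
        lane.enzyme: [f.sequence for f in lane.analysis_fragments()]
        for lane in result.lanes.values()
    }
    return SyntheticExperiment(
        reference=structure.sequence,
        products=products,
        structure=structure,
        digest=result,
    )
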