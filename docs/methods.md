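# Methods

## Digestion model

A secondary-structure model is a sequence over {A, C, G, U} with a
1-based pair table (0 = unpaired) validated for symmetry and
irreflexivity — the CT convention; all downstream coordinates are 1-based
inclusive.  An enzyme is (recognised residues, required pairing state,
cut side).  Pairing state is read strictly from the pair table: RNase
V1's real preference for helical stacking context is not modelled, and
each paired residue is treated independently of its partner.

Digestion is **complete and single-pass**: every recognised residue is
cut (equal access to all motifs, no kinetics or partial-digestion
ladders), all implied bonds are cut simultaneously, and products are not
re-digested — the structural context that made a residue a substrate no
longer exists after fragmentation.  A 3′-cut at the last residue (or a
5′-cut at the first) is still reported as a cleavage site but cuts no
internal bond.  Consequences used as invariants: a lane with k internal
cuts has exactly k + 1 fragments; fragments tile the parent; for any
structure the V1 and T2 site sets partition all positions.

Enzymes in a panel are never pooled: each lane is one reaction, as in a
probing experiment.  Fragments shorter than `min_fragment_length`
(default 2 nt, the shortest product meaningfully recoverable from a gel)
are retained with a `short_flag` for display but excluded from analyses.

**Uniqueness.**  A fragment is flagged unique when (a) its sequence
occurs exactly once in the parent (overlapping occurrences counted — a
hybridisation probe cannot distinguish overlapping sites) and (b) no
other analysis-grade fragment in the lane has the same length, so its
band is unambiguous on a gel.  Both sub-criteria are stored per fragment
(`occurrence_count`, `length_unique_in_lane`) so either can be applied
alone.

## Constraint inference

Products are validated first: the reference is capped at 200 nt
(parameterisable), products are normalised like sequences (T→U,
upper-case), sub-2-nt products are dropped with a warning, and a product
absent from the reference is an error.

Every occurrence of a product in the reference contributes evidence with
equal weight.  For a 3′-cutter, an occurrence [s..e] implies the
enzyme's required pairing state at residue e (if e < N) and at residue
s − 1 (if s > 1) — the residues 5′ of the two cut bonds.  No evidence is
emitted at the molecule termini, where no bond exists.  Evidence residues
whose base the enzyme does not recognise mark chemically impossible
cleavages; they are warned about and excluded from resolution, since
they indicate a mislabelled product.  Products are attributed to the
enzyme whose list they arrived in; no cross-enzyme reassignment.

Conflicts are resolved per residue by three ordered rules: (1) the
status supported by the strictly longest source fragment wins; (2) at
equal maximum length, the status supported by more fragments wins; (3) a
balanced conflict is `undefined`.  Rule 1 compares the single longest
fragment per status — this ordering makes rule 3's tie condition (same
count *and* same length) reachable.  Any residue decided from partially
inconsistent evidence carries a note.  Resolution is deterministic and
invariant to evidence order.

**Interior inference (opt-in, default off).**  Under complete digestion,
a recognised residue strictly inside a product cannot have been in the
enzyme's required pairing state, so it implies the opposite status.
This is a strictly stronger reading of the experiment than boundary
evidence, valid only for genuinely complete digests, hence a flag
(`--interior-inference`).

Non-undefined statuses are run-length encoded into mfold web-server
constraint commands: `P i 0 k` prohibits pairing of residues i..i+k−1,
`F i 0 k` forces pairing.  Encoding is lossless: decoding the commands
reproduces the non-undefined statuses exactly.  The status array can be
edited before re-encoding, mirroring an interactive review of the calls.

## Rendering

Gel migration uses the standard log-length model for denaturing gels,
normalised so the shortest ladder rung migrates to 1 and the longest to
0; lengths outside the ladder span clamp with a warning.  The default
ladder is 10, 20, … rounded up to the parent length (minimum two rungs).
Equal-length fragments in a lane merge into one band with a multiplicity
label, as they would co-migrate.  Band intensity is uniform.  Structure
drawings are linear annotated listings plus dot-bracket; no 2-D layout
engine.  All renderers are pure functions; SVG 1.1 is emitted directly
via the standard library's XML tools.

## Synthetic data

The fixture generator draws a uniform random sequence and inserts
pseudoknot-free pairs by rejection sampling (random (i, j) with loop
≥ 3 nt, no crossing, no re-use) until a target pairing density is
approximated; when a sampled pair is non-complementary the 3′ partner is
rewritten to a Watson–Crick or (optionally) G·U complement.  Everything
is seeded through `random.Random`; no global state.  Default study
conditions: length 180 (under the 200-nt inference cap), densities
0.2/0.4/0.6 spanning loosely to tightly structured RNAs, panel
{T1, A, V1, T2} — the standard single/double-strand probing combination.
These structures are *not* thermodynamically realistic (no stacking
statistics, no helix-length distribution from energy minimisation), so
passing round-trip tests demonstrates the correctness of the
digestion/inference logic, not expected accuracy on real probing data,
where digestion is partial and band calling is noisy.

## Known limitations

* The all-occurrences, equal-weight evidence rule is faithful to how a
  sequence-only experiment reads, but it makes complete-digest round
  trips noisy: short (2–3 nt) products of the low-specificity enzymes
  (T2, S1, V1) recur spuriously across a ~200-nt reference and plant
  false evidence, which is often uncontested — helix interiors receive
  no true boundary evidence at all, because the V1 fragments inside a
  stack are 1 nt and fall below the analysis filter.  Restricting input
  to products whose sequence occurs exactly once in the reference makes
  every verdict provably consistent with the true structure (this is a
  tested property); in practice, feeding only confidently assigned,
  longer bands is the right protocol.  Interior inference reduces, but
  does not eliminate, the noise.
* No partial digestion, no kinetic efficiency, no cleavage-site sequence
  context beyond single-residue identity.
* No pseudoknots anywhere: pseudoknotted dot-bracket input is rejected,
  and the generator produces only nested pairings.
* Structure prediction itself is out of scope: models come from mfold or
  ViennaRNA, and the emitted constraints are meant to be fed back into
  those tools.
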