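# rnacleave

Enzymatic probing with structure-specific ribonucleases remains the most
widely accessible way to interrogate RNA secondary structure: an
end-labelled RNA is partially digested with nucleases of known structural
specificity (RNase T1 cuts unpaired G, RNase A unpaired pyrimidines,
nuclease S1/RNase T2 any single-stranded residue, cobra-venom RNase V1
double-stranded residues) and the products are read off a sequencing gel.
`rnacleave` connects these experiments to computational structure models
in both directions:

* **digest mode** — given a secondary-structure model (mfold CT or Vienna
  dot-bracket), simulate a complete single-pass digest for each enzyme in
  a panel: cleavage sites, fragment tables, a schematic gel, a digestion
  map, and a uniqueness analysis that marks fragments usable as
  structure-specific probe or primer targets.
* **infer mode** — given the reference sequence and the product sequences
  observed with each enzyme, invert the digestion logic into per-residue
  `paired` / `unpaired` / `undefined` verdicts and emit mfold constraint
  commands (`F i 0 k` force-pair, `P i 0 k` prohibit-pair) ready to paste
  into a constrained folding run.

## Model

A structure is a sequence $s_1..s_N$ with a pair table $p$, $p_i \in
\{0, 1..N\}$ ($p_i = 0$: unpaired; symmetric, irreflexive).  An enzyme is
a triple (recognised residues $R \subseteq \{A,C,G,U\}$, required pairing
state, cut side).  Residue $i$ is a substrate iff $s_i \in R$ and the
pairing state of $p_i$ matches; a 3′-cutter then cleaves the bond
$(i, i+1)$ when it exists.  Digestion is complete and single-pass: all
implied bonds are cut simultaneously and products are not re-digested, so
a lane with $k$ internal cuts has exactly $k+1$ fragments that tile the
parent.  Fragments shorter than 2 nt are flagged and excluded from
analyses (they are retained for display).

Inference reverses this: every occurrence of a product $[s..e]$ in the
reference implies the enzyme's required pairing state at the residue 5′
of each cut bond — residue $e$ (if $e < N$) and residue $s-1$ (if
$s > 1$).  Conflicts are resolved per residue by three ordered rules:
longest supporting fragment wins; at equal length the larger number of
supporting fragments wins; a balanced conflict is `undefined` (with a
note whenever the evidence was partially inconsistent).  Evidence whose
residue the enzyme cannot chemically cleave is reported and excluded.

## Worked example

Digest a 14-nt model (7 unstructured residues followed by a hairpin) with
RNase T1 and RNase V1:

```
$ printf '>hp\nAGCAUGGGGAAACC\n.......((...))\n' > model.db
$ rnacleave digest --structure model.db --enzyme T1 --enzyme V1 --out out
$ cat out/statistics.tsv
enzyme  n_sites  site_positions  n_fragments  n_pass_filter  n_unique
T1      3        2,6,7           4            3              3
V1      4        8,9,13,14       4            2              2
```

T1 finds its three unpaired Gs (positions 2, 6, 7 — the paired Gs at 8–9
are protected); the terminal-adjacent cut at 7 plus the two internal cuts
yield four fragments, of which the 1-nt `G` is short-flagged
(`out/fragments_T1.tsv`).  V1 cuts the paired residues 8, 9, 13, 14.
Feeding T1's products back through inference recovers the single-stranded
calls and the mfold commands:

```
$ printf '>ref\nAGCAUGG\n' > ref.fa; printf 'AG\nCAUG\n' > t1.txt
$ rnacleave infer --reference ref.fa --products T1:t1.txt --out inf
$ cat inf/constraints.txt
P 2 0 1
P 6 0 1
```

i.e. residues 2 and 6 (the G's whose 3′ bonds produced the two fragment
boundaries) are prohibited from pairing; all other residues stay
undefined — boundary evidence says nothing about them.

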