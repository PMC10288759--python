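# circguide

Design toolkit for **circular guide RNAs (cgRNAs)** for CRISPR/Cas12a and
CasRx (Cas13d).

Free guide RNAs are degraded within hours by cellular exonucleases, which
limits the efficiency and durability of Cas12a/CasRx editing. Expressing the
guide as a **circle** removes the free ends: a Pol III (U6+27) transcript
carries the guide flanked by Twister ribozymes whose autocatalytic cleavage
leaves termini that the ubiquitous endogenous ligase RtcB joins into a
covalently closed ring. Because Cas12a and CasRx self-process their guides
out of longer transcripts, they can excise a functional crRNA from the
circle. The catch is structural: the ribozymes, the guide scaffold (direct
repeat) and the flexible linkers between them must all fold correctly *in
each other's presence*, so linker sequences have to be screened.

`circguide` is the in-silico half of that workflow, usable from Python
(`import circguide`), via the `examples/` scripts, or the `circguide` CLI:

* **constructs** — assemble every cassette topology (mature `U6+27`,
  unprocessed `Pre` = spacer flanked by two scaffolds, linear/circular `Sp1`
  ± F30-Broccoli, screened-linker circles `C-L1…C-L8`, `d27` and
  5′/3′-extended variants, multiplexed arrays) with exact 0-based half-open
  coordinate bookkeeping, and derive the post-ligation circle.
* **folding** — deterministic secondary-structure prediction: a bundled
  nearest-neighbor MFE engine and a Nussinov maximum-base-pair engine (both
  with circular folding via the doubled-sequence reduction), a brute-force
  enumeration oracle for testing, and an adapter for an external `RNAfold`.
* **screening** — the digital linker-library pipeline: enumerate or sample
  libraries of linkers (10-nt polyAC core + 5–7 random bases per side), fold
  each precursor, keep candidates whose ribozyme/scaffold **structure motifs**
  are intact, rank by ΔG, group by structural similarity (coarse shapes or
  base-pair distance), confirm with a second engine, and select per group the
  most stable doubly-correct linker pair.
* **quantify** — the editing-outcome statistics: specificity index
  SI = Σon/(Σon+Σoff) over cleavage-site read counts, FACS cleavage
  efficiency E = mNeonGreen⁻mCherry⁺/mCherry⁺, expression fold change (with a
  2^−ΔΔCt helper), and guide half-life by log-linear OLS on a
  transcription-shutoff time course (t½ = ln2/k).

## Worked example

```bash
$ python examples/fold_guide.py
GGGAAAACCC
(((....))) (-1.44 kcal/mol, builtin-mfe)

rotated AACCCGGGAA
linear   : 1 pairs
circular : 3 pairs (stem rejoined across the origin; frame offset 5)
```

The hairpin's stem is broken when the sequence is rotated and folded as a
linear molecule, but circular folding rejoins it across the origin — the
reason circle design must fold circles as circles.

```bash
$ python examples/quantify_editing.py
specificity index U6+27  : 0.996
specificity index C-Sp1  : 0.986
specificity index C-L7   : 0.985
...
half-life circular_gRNA :  30.09 h  (k=0.023/h, r2=0.966)
half-life linear_gRNA   :   2.04 h  (k=0.340/h, r2=1.000)
```

Specificity indices near 1 mean almost all cleavage reads are on-target;
the synthetic decay series recovers a fast-decaying linear guide and a
far more stable circle.

A screen from the shell (parts registries are YAML; the bundled fixture
registry stands in for the real part sequences, which are user-supplied):

```bash
circguide fixtures --out-dir fx --seed 0
circguide screen --spacer ACCACAACCAAACCACCAACCAC --parts fx/parts.yaml \
    --library 64 --seed 7 --top-n 10 --report screen.tsv
```

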