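# Methods

This note records the model as implemented, the parameters that matter, the
numerical choices made where the published procedure left room, and what the
synthetic-fixture tests do and do not establish.

## Solvent accessibility

ASA is computed with the Shrake–Rupley sphere-point method: 960 points per
atom on a deterministic spiral lattice, probe radius 1.4 Å. Both numbers are
config keys (`point_density`, `probe_radius`). Determinism is a contract —
identical input and config give bit-identical ASA, which propagates to
byte-identical prediction files.

Van der Waals radii are element-based (C 1.70, N 1.55, O 1.52, S 1.80,
Se 1.90, P 1.80 Å; fallback 1.80), shipped as `data/vdw_radii.tsv` and
replaceable via `radius_table_path`. Hydrogens in input files are discarded;
only heavy atoms enter ASA and patch geometry.

RASA uses the theoretical Gly-X-Gly maximum-ASA reference (Tien et al. 2013
theoretical values, `data/max_asa.tsv`); ratios above 100% clamp to 100.
Residue types without a reference yield a missing RASA and are excluded from
patch-centre candidacy.

Two states are computed per chain of a complex: *complexed* (all chains
present) and *isolated* (the chain alone). For a monomer the states
coincide, which the tests assert exactly.

## Patch decomposition

The growth procedure is run to a fixed point, so the within-sweep visiting
order cannot affect membership; an invariant test compares it against an
unoptimised brute-force implementation on random micro-structures.

Degenerate-geometry policies:

- a residue without a Cα has no solvent vector and *fails* every angle test
  (it is never pulled in beyond being a centre) — conservative;
- a zero-length geometry vector (perfectly symmetric neighbourhood, which
  occurs in flat synthetic grids) *passes* the angle test (angle defined 0),
  keeping flat fixtures connected;
- ties in the 10-nearest-neighbour selection break toward the lower file
  index; centre-atom ASA ties break toward the first atom in file order.

The candidate set is held at atom granularity with residue-level angle
tests; on connected surfaces this reproduces both the residue-level and
atom-level readings of the procedure.

Default patch radius is 14 Å (the shipped model's radius); 9 Å is available
via config.

## Labelling

Interface: isolated-minus-complexed RASA ≥ 10 percentage points (RASA units,
not Å²). The patch interface fraction sums isolated-state RASA over *all*
patch members as literally defined — the sums are not restricted to a
surface subset. A patch whose members all have zero RASA (unreachable for
real centres) gets fraction 0 with a warning.

U (rim) patches are carried through every output; only the training-set
assembler and the patch-level evaluator drop them.

## Propensity table

"Surface residue" for the surface fractions and mean surface ASA means
isolated-state RASA ≥ 10% and not interface; the 10% floor mirrors the
threshold under which residues are considered buried at prediction time.
Residue types absent from either the interface or the surface set have an
undefined log-ratio and evaluate as missing; the acceptance-style sign test
therefore plants a *predominantly* interface type (90/10), not an
exclusively interface one, whose propensity would be undefined rather than
positive. The table used at prediction time is the one frozen inside the
trained model, never recomputed from query structures.

## Conservation

The Valdar (2001) weighted sum-of-pairs score is computed per alignment
column: sequence weights are mean pairwise matrix distances (favouring
divergent sequences), pairs are scored with a PET91-family substitution
matrix (Biopython's JONES) shifted to non-negative and diagonal-normalised
(m(a,b)/√(m(a,a)·m(b,b)), clipped to [0,1]) so that every identity scores
exactly 1 and a fully conserved column scores exactly 1. A plain min–max
normalisation would leave the diagonal uneven and identical columns scoring
below 1; the diagonal normalisation was chosen for that reason. A custom
matrix TSV may be supplied. Gap pairs score 0; all-gap columns score 0;
columns where the target is gapped are skipped in the mapping to residues.
When all sequences are identical the pair weights vanish and uniform weights
are substituted.

Alignments are consumed as pre-built aligned FASTA files with an optional
metadata sidecar — there is no network access. The admission filters still
apply: FEP families need ≥ 10 sequences in total (the target plus nine
others); homologue sets drop hits with E-value > 0.01 or
putative/predicted/hypothetical descriptions, need ≥ 10 survivors, and keep
at most the 200 best by ascending E-value. A rejected alignment makes the
corresponding feature missing for the whole chain, which the forest handles
by imputation.

## Structural features

Disulphides: Sγ–Sγ distance strictly below 2.25 Å, intra-chain only.

Hydrogen bonds (intra-chain): backbone amide hydrogens are rebuilt at 1.0 Å
from N along the external bisector of the C(prev)–N and Cα–N bonds; with a
computable hydrogen the rule is H···A ≤ 2.5 Å and a 90–180° angle at the
hydrogen; otherwise (side-chain donors — side-chain hydrogens are never
built — prolines, and chain-start residues) D···A ≤ 3.35 Å with a 90–180°
angle antecedent–donor–acceptor. The donor/acceptor chemistry table is
package data (`data/hbond_chemistry.tsv`).

Secondary structure: a Kabsch–Sander-style assignment. Backbone H-bonds are
scored with the standard electrostatic energy (0.084·332·(1/d_ON + 1/d_CH −
1/d_OH − 1/d_CN) kcal/mol, H placed anti to the preceding carbonyl) with the
−0.5 kcal/mol cutoff and ≥ 2 residue separation. Two consecutive i→i+4
turns mark residues i+1..i+4 as H; bridge *ladders* (≥ 2 consecutive bridge
residues, parallel or antiparallel) mark E; isolated single bridges and
3₁₀/π-like patterns fall to C. Helix takes precedence over sheet. Residues
missing backbone atoms are coil. An external per-residue assignment can be
supplied as a TSV override.

The patch class uses 20% boundaries on the member percentages α (helix) and
β (sheet): H if α > 20 and β ≤ 20; E if α ≤ 20 and β > 20; EH if both
exceed 20; C otherwise. The four regions are exhaustive and mutually
exclusive; the class is expanded to four binary indicator columns for the
forest.

Planarity uses *all atoms of all member residues* (the more inclusive
reading of "all atoms of the patch"; patch membership is defined per
residue, so set-P-only would depend on sweep internals). It equals the
square root of the smallest eigenvalue of the centred coordinate covariance;
fewer than 3 atoms or a collinear set return 0 with a warning.

## Learning

scikit-learn `RandomForestClassifier`, 100 trees, 3 features per split,
seeded. Missing values (the two conservation columns) are imputed with
training-set column means stored in the model file; an alternative
fractional-instances scheme is not implemented. The model file (joblib)
freezes the forest, the feature schema, the imputation means, the propensity
table, the patch radius, the seed and a format-version tag; loading a
mismatched version is refused.

Prediction scores are *per-tree hard votes* (fraction of trees voting
interface), not averaged leaf probabilities; a patch is called interface
when the score exceeds 0.5, so an exact 50/50 tie resolves to non-interface,
favouring specificity.

Residue mapping: a patch's label and score go to its centre residue. All
surface residues (isolated RASA ≥ 10%) that are not patch centres — the
whole 10–25% band, closing the stated 20–25% gap, which we read as a typo —
are forced non-interface with score 0; buried residues (< 10%) receive no
prediction.

Cross-validation comes in two forms: a plain stratified k-fold over patch
rows (`cross_validate`), and the corpus form used for acceptance
(`cross_validate_corpus`), which holds out whole complexes together and
rebuilds the propensity table from each fold's training complexes before
re-evaluating the propensity column. The second form exists because the
propensity table is itself fit to the training labels: building it once on
the full corpus leaks enough composition noise to lift a signal-free corpus
well above MCC 0. Folds whose test split holds a single class report
undefined metrics and are excluded from the unweighted fold mean. Undefined
measures (zero denominators) are reported as NA, never as 0.

## Synthetic fixtures

The generator emulates exactly the geometric situations the pipeline's rules
respond to, not real protein chemistry:

- helices and strands are built from ideal torsions (φ,ψ = −57,−47 and
  −139,135) with textbook bond geometry; the antiparallel sheet's partner
  strand uses a rigid placement frozen from a deterministic scan that
  maximises sheet assignment on the fixture itself;
- flat residue grids use chemically minimal residues (N, Cα, C, O plus one
  or two side-chain carbons) spaced so that row neighbours form peptide-bond
  contacts; residue *identity* is free and is how compositional signal is
  planted (hydrophobic pool ILE/LEU/VAL/MET at interfaces vs polar pool
  LYS/GLU/ASP/SER elsewhere, 80/20 enrichment so every type occurs in both
  sets and the propensity log-ratio stays defined);
- the two-slab complex hovers a denser "occluder" slab (umbrella-tipped side
  chains) 4 Å above one end of a long open slab, which strips ≥ 10 RASA
  points from every covered residue and none from the far columns; at 50 Å
  nothing is labelled interface. The occluder chain carries no patch rows in
  corpus training — it is scaffolding;
- the pocket (U-shape) fixture backs each wall with a dense Cα layer so the
  two walls' solvent vectors oppose each other while their side-chain tips
  remain in atomic contact — the situation the solvent-angle test exists
  for.

A green end-to-end test therefore establishes that the pipeline recovers a
*compositional* interface signal planted at realistic effect size, and that
it does not manufacture signal from geometry alone (the zero-signal corpus
cross-validates near MCC 0). It does not establish performance on real
structures: real side chains, packing, conservation signal and obligate vs
transient interface chemistry are all outside the generator.

## Known limitations

- No mmCIF input, symmetry-generated assemblies, or nucleic-acid chains.
- Conservation requires externally produced alignments; no BLAST/Muscle or
  database queries are performed.
- The vote threshold of the original predictor is not published; majority
  vote with ties to non-interface is assumed.
- Published benchmark numbers require thousands of external structures and
  live conservation resources and are not reproducible at this scale; the
  test suite is property-based instead.
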