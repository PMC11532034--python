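# Methods

This note documents the models and procedures behind `alpscan`, the
parameters that matter, the design choices made where conventions were
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Conventions

All residue coordinates are 1-based inclusive; conversions to 0-based
half-open indexing are internal to individual functions. Sequences are
uppercase over the 20 standard amino acids plus `X` (unknown). `X` scores 0
on every hydrophobicity scale, never counts as an identity match, and is
excluded from composition and logo censuses. Domain tables are
tab-separated with a mandatory header
(`protein_id  domain_type  start  end  source`) and `#` comments; no
interchange format exists for ALP domain annotations, so this dialect is a
package convention.

## Membrane-anchor detection

ALPs are anchored by membrane-anchoring domains (MADs) of three kinds, all
called from sequence alone.

**Transmembrane helices.** A classic hydropathy-plot scan: the
Kyte–Doolittle mean of a 19-residue window centered at each position,
threshold 1.6. Maximal runs of above-threshold centers become candidate
segments; overlapping segments merge. This window/threshold pair is the
standard setting for membrane-spanning segment detection on this scale.
Dedicated HMM-based topology predictors are more specific; externally
produced TM annotations (`source = external`) can be imported and then take
precedence over the scan. A candidate is *N-terminal* when it starts within
the first 40 residues and *C-terminal* when it ends within the last 40.

**Short hydrophobic helices.** Real repertoires contain terminal
hydrophobic helices of fewer than 20 residues that full TM predictors
reject but that likely still insert into the bilayer. Candidates are
maximal segments of 10–19 residues within the terminal 60 residues whose
mean Fauchère–Pliška hydrophobicity (the HeliQuest "hydrophobicity index")
exceeds 1 — the index value typical of genuine TM helices on this scale.
Segments contained in a TM candidate are not reported twice; among
overlapping survivors the highest-index segment wins.

**Amphipathic helices.** The Eisenberg hydrophobic moment
μH = |Σₖ Hₖ·exp(i·k·δ)|/N with δ = 100° per residue, on Fauchère–Pliška
values, over 18-residue windows (the HeliQuest analysis window). Windows in
the terminal 60 residues with μH ≥ 0.5 qualify; chains of overlapping
qualifying windows collapse to the single maximal-moment window. Note the
useful identity: any 18-residue homopolymer has μH exactly 0, because
18 × 100° ≡ 0 (mod 360°) makes the unit vectors cancel.

**Precedence.** When candidate intervals overlap by at least half of the
lower-priority candidate, TM > short hydrophobic > amphipathic. The 60-
residue terminal span, the 10-residue di-basic flank and this precedence
rule are package conventions — the phenomena are described in the
literature without numeric cutoffs.

**Di-basic motifs.** Within 10 residues upstream of an N-terminal TM start
(or downstream of a C-terminal TM end), the first pair matching `KK`
(di-lysine), `KN`/`NK` (lysine→asparagine substitution), or a
{K,R} × {K,R,N,D} variant is reported with its side. These pairs mark the
cytoplasmic face and hence hint at helix orientation. Internal TM helices
are not scanned: without a terminal assignment the cytoplasmic side is
undefined.

A protein may legitimately yield zero MADs and still flows through every
downstream stage.

## Architecture strings and classification

Domains sorted by start are transcribed to letters (MAD→`t`, RBH→`r`,
ABD→`a`, pseudomurein-binding→`b`, transglutaminase→`g`, other→`o`).
Non-MAD domains must not overlap; MADs may overlap structural domains.

**Distance.** Levenshtein edit distance on the raw (uncompressed) strings,
divided by the longer length; two empty strings are at distance 0. Raw
strings make repeat-count differences count, so `traaaaa` and `traa`
separate only when repeat numbers diverge strongly. The edit distance is
computed with edlib. No published convention exists for a string metric
over architecture codes, so clustering outcomes (e.g. cluster counts)
should be treated as convention-dependent.

**Clustering.** DBSCAN over the precomputed distance matrix with eps 0.5
and minPts 1. With minPts 1 every point is core, so the result provably
equals single-linkage connected components at threshold 0.5 — the test
suite checks this equivalence against an independent union-find oracle.
Labels are renumbered by first occurrence in input order for
reproducibility.

**Classification.** On σ = the architecture with `t` removed:

1. no `a` and no `r` → **NOT_ALP** (discarded from the repertoire);
2. `g` present → **III** when there is no `r`, no `o`, and every `a`
   precedes the first `g` (`b` permitted anywhere); otherwise **Others**;
3. `o` or `b` present → **Others**;
4. both `a` and `r`: σ matching `r+a+` → **IA**, otherwise **IB**;
5. only `a` → **IIA**; only `r` → **IIB**.

Group IA/IB membership is decided purely by the ordering of non-anchor
symbols, regardless of MAD presence or position; anchorless proteins can
still be IA/IB. Interleavings such as `arar` are IB. `b` outside a TG
context routes to Others; inside a TG architecture it is tolerated in
group III, mirroring the co-occurrence of pseudomurein-binding repeats
with transglutaminase domains. Whether a group-III protein may carry an
additional `o` domain is unsettled; the cascade here routes such
architectures to Others.

## Repertoire statistics

The ALP-coding genome fraction is 100 × 3 × (pooled ALP residues) /
(genome bp), rounded half-up to one decimal. Stop codons are ignored:
including one per gene shifts the fraction by under 0.01 points at
megabase genome sizes, so the simpler convention is kept; it reproduces
the published 10.9% / 10.7% fractions from the published residue totals.
Note the published per-species mean lengths are not total/count for the
count given (67,292/49 ≈ 1,373, not 1,299); `mean_len` here is defined as
total/count.

Composition profiles pool residue counts over records; enrichment is
log2(frequency/background) for residues with positive background.

## Phylogenetics

Percent identity uses pairwise gap deletion: the denominator is the
columns where both rows are non-gap, the numerator the matching non-`X`
residues among them. A pair with no comparable columns scores 0 with a
warning. Distances are the simple complement d = 1 − pid/100, with no
saturation correction — appropriate at the within-repertoire divergences
these trees are used for, and the convention is isolated in
`identity_to_distance` if a corrected transform is wanted.

Neighbor joining follows the canonical Saitou–Nei agglomeration: select
the pair minimizing Q(i,j) = (k−2)·d(i,j) − r(i) − r(j), ties broken to
the lowest index pair; branch lengths from the standard formulas, with
negative estimates clamped to zero and the deficit moved to the sibling
edge so the pair's path length is preserved. On additive matrices the
algorithm is exact; the suite verifies topology and lengths to 1e-9
against random additive trees and cross-checks topologies against
scikit-bio's independent implementation. Two-taxon input yields a single
edge split evenly between the leaves.

Bootstrap: alignment columns are resampled with replacement, a tree is
built per replicate, and each internal bipartition of the full-data tree
is labeled with its replicate frequency × 100, rounded. Replicate r draws
from RNG substream (seed, r), so supports are reproducible under a fixed
seed and independent of evaluation order. Newick output carries branch
lengths on all edges and integer supports as internal node labels.

Clade identity tables average percent identities over all cross pairs for
group pairs, and over distinct pairs (excluding self) within groups; a
singleton group's within-mean is undefined and reported as missing.

## Logo matrices

Columns whose gap fraction exceeds 0.5 are removed first ("long gaps" have
no published threshold; 0.5 is the package convention, exposed in the
config). Retained columns get frequencies over non-gap, non-`X` residues,
entropy H = −Σ p·log2 p, and information log₂20 − H bits. No small-sample
correction is applied: the quantity is used for ranking conserved columns
within one alignment, not for cross-alignment comparison, and the
correction would subtract a constant at fixed row count.

## Synthetic data

The generator is the package's test bed: it emulates the documented
features of the real repertoires and retains the exact truth used.

* **Group proportions** default to the reported subgroup sizes (IA 40,
  IB 12, IIA 13, IIB 5, III 4, Others 13) plus 14 domain-free decoys,
  normalized. (The published subgroup sizes do not sum exactly to the
  91-protein repertoire — partially annotated proteins account for the
  slack — so proportions, not absolute counts, are matched.)
* **Architecture grammars** are the inverse of the classification rules
  (IA: `r^j a^k`; IB: at least one ABD N-terminal to the RBH block; IIA:
  1–17 ABDs; IIB: RBH repeats; III: ABDs, optional PMB, then TG; Others:
  templates containing an extra domain; decoys: neither ABD nor RBH), so
  the planted label is consistent with the emitted architecture by
  construction. RBH repeats span 1–7 and ABD repeats 1–27, the observed
  extremes.
* **Sequences.** ABDs are 80–120 residues with invariant glycines at five
  fixed offsets (the conserved loop glycines); RBH domains are 250–1,236
  residues with a conserved asparagine every 22 residues (the loop-Asn
  chain of β-helices). Domain interiors draw from a background with Asn
  and Thr boosted 2× (boost configurable); the interior distribution is
  compensated for the planted conserved residues so the domain-level
  composition matches the boosted target in expectation, making the
  configured boost recoverable as ≈1 bit of enrichment. Linkers draw from
  a polar alphabet (no K/R, no strong hydrophobics) so planted anchors are
  the only hydrophobic stretches and planted di-basic pairs are the first
  match in their flank.
* **Anchors.** N-terminal anchors are present except with probability
  5/91 (the observed no-MAD rate); a C-terminal TM is added with
  probability 11/91 (the observed dual-MAD rate). TM anchors are 20–28
  residues of L/I/V/F (observed TM length 24.0 ± 5.6); short hydrophobic
  anchors are 10–12 residues of L/F flanked by strongly hydrophilic guard
  residues, placing them above the short-helix index criterion but below
  the 19-window TM criterion by construction; amphipathic anchors are
  ideal 18-mers with one hydrophobic face. KK/KN/variant pairs are planted
  immediately upstream of N-terminal (downstream of C-terminal) TM
  anchors.
* **Determinism.** Protein i draws from RNG substream (seed, i); a fixed
  spec reproduces FASTA and tables byte for byte.

The ABD-alignment generator plants invariant glycine columns in a gap-free
core, induces clade structure by clade-specific consensus substitutions
(default half of the mutable columns), and adds per-sequence substitutions
at a configurable rate. A separate helper produces random binary trees
with edge lengths uniform on [0.05, 1] and returns their patristic
matrices — strictly additive inputs for NJ exactness checks.

**What passing these tests does not show.** Synthetic linkers are polar by
construction, so anchor detection is evaluated under favourable
signal-to-noise; real ALPs can contain hydrophobic patches inside
structural domains that produce extra internal TM calls, and real anchors
near the detection threshold will be missed. The generator plants i.i.d.
substitutions with no indels, alignment error or rate heterogeneity, so
bootstrap and logo behaviour on real alignments (with gaps and misaligned
repeats) will be noisier. Classification recovery measures rule/grammar
consistency, not the accuracy of upstream domain annotation, which in real
data comes from structure/profile searches outside this package's scope.

## Problem sizes

Default validation sizes: 500 proteins for classification recovery, 200
for anchor sensitivity and composition, 100 random additive trees (4–8
taxa), 50 strings for the clustering equivalence, 1,000 random 18-mers
for the moment oracle, 200 bootstrap replicates on 10–30 row alignments.
These sizes give stable estimates (the stochastic rates are at or near
100% across seeds) while keeping the full suite and the acceptance script
in the seconds range.

## Known limitations

* TM detection is a hydropathy scan, not a topology model; it reports no
  inside/outside orientation and can merge closely spaced helices
  separated by short polar loops (a 19-residue window cannot resolve
  loops much shorter than ~8 residues).
* The IA/IB rule decided purely by symbol ordering can disagree with
  manual curation for proteins whose published group assignment relied on
  information beyond domain order.
* Cluster counts from DBSCAN on architecture strings depend on the
  unpublished choice of string metric; they are reported but should not
  be compared across implementations.
* NJ uses uncorrected 1 − identity distances; deep divergences would need
  a saturation-corrected transform.
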