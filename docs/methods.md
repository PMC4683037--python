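# Methods

## Scope and conventions

All coordinates are 0-based half-open on the forward strand; minus-strand
features carry forward coordinates plus a strand flag. T and U are
interchangeable in every comparison (sequences are normalised to the DNA
alphabet internally; the input alphabet is preserved on output). N matches
nothing in exact mapping and counts as a mismatch everywhere else. Reported
percentages use half-up rounding to one decimal.

## Read classification

Reads are filtered to 18–30 nt inclusive, then mapped to the genome by exact
substring match on both strands (a per-length hash index; a minus-strand hit
stores the forward interval of the reverse complement). Classification
precedence is known miRNA → rRNA → tRNA → snoRNA → snRNA → other:

* known miRNA: Hamming distance ≤2 to a catalog mature of equal length —
  substitutions only, no indels, matching the way mature catalogs are
  searched for conserved homologs;
* structural RNAs: exact substring of a reference sequence.

The alternative order (structural RNAs first) is available via the
`precedence` argument; the default keeps a miRNA that collides with an rRNA
fragment in the miRNA row, which is the only order consistent with reporting
known miRNAs inside the non-coding hierarchy. A multi-mapping read
contributes its full count once to its category; all genomic hits are kept
for discovery. Summary percentages follow the source table's footnotes: the
mapped and CDS rows are relative to the 18–30 nt totals, each non-coding
category's reads column is relative to the non-coding total, and every
unique-column percentage is relative to the reads count of the same cell.

## Hairpin discovery

Windows are mature ± 150 nt (≈321 nt for a 21-nt read), clipped at
chromosome ends; minus-strand hits are folded on their own strand. Folding
uses the ViennaRNA nearest-neighbor model at 37 °C; an in-package Nussinov
maximum-pairing scorer serves as an energy-free structural oracle in tests.
The folded window is trimmed to the maximal simple stem-loop containing the
mature: from the mature's helix the pair list is walked inward to a single
terminal loop (branching disqualifies the candidate) and outward through
bulges/interior loops to the outermost enclosing pair. MFE, AMFE (|MFE| per
100 nt) and MFEI are computed on the trimmed, re-folded precursor. "MFEI
uses the precursor length" is a deliberate reading: with mature-length
normalisation the reported index range (≈0.2–3.75 in comparable data) is
unreachable, so precursor length is the default (the mature-length variant
is a one-line change at the call site). Likewise the window is defined by
its 150-nt flanks rather than a fixed 300-bp total, the two conventions
being inconsistent for reads ≠ 0 nt long.

Fold-back is operationalised as: ≥60% of mature bases paired, all partners
on the opposite arm of that single stem-loop. The miRNA* is the arm segment
pairing the mature with canonical 2-nt 3′ overhangs on both duplex ends,
extrapolated from the outermost paired mature bases (so terminal breathing
does not shift the star); it is "observed" when its exact sequence occurs in
the read set. A candidate whose mature is the star of a better-supported
candidate is suppressed — one duplex yields one miRNA, and the strand with
more reads is the mature.

The four calling criteria: mature 20–24 nt; fold-back precursor ≥45 nt;
strictly more than 5 reads in at least one library (mature reads only, the
star does not count); MFEI > 0.85 or star observed. Identical matures merge
into one miRNA with precursors suffixed -1, -2, … by genomic coordinate;
serials are assigned by the first precursor's coordinate, making the catalog
independent of input order. Same-strand hits closer than 50 nt collapse to
one locus. A perfectly palindromic planted stem maps the mature to both
strands and therefore yields two precursor records for one miRNA — visible
in the synthetic catalogs as paired orientations of the same locus.

## Expression

TPM is count / clean-library-total × 10⁶; no length normalisation, as
appropriate for fixed-length small-RNA counts. Log₂ uses pseudocount 1 and
detection requires TPM ≥ 1 in some library (both configurable; values chosen
as common small-RNA practice). A detected profile is differential when its
max-normalised minimum falls below 0.5 — equivalent to max/min > 2 when the
minimum is positive; all-zero rows are flagged, never called. The
"correlation index" for miRNA–target pairs is Pearson's r (the coefficient
type is otherwise unspecified in the underlying convention; Spearman can be
substituted via the public function), with the inverse-pair flag requiring
both fold-changes > 2 and r < −0.5 on max-normalised profiles; fold-changes
computed on TPM and normalised values agree because max-normalisation is a
positive row scaling. Hierarchical clustering is Euclidean/average-linkage
(common analysis-tool defaults) on rows and columns of Log₂TPM; PCA is a deterministic
SVD of centred column profiles with a fixed sign convention
(largest-magnitude loading positive). The Pfaffl ratio is
E_t^ΔCt_t / E_ref^ΔCt_ref with ΔCt = control − sample; at E = 2 exactly it
reduces to 2^ΔΔCt. Efficiencies must lie in (1, 3); values outside
1.8–2.05 are flagged, not rejected.

## Target prediction

Duplexes are ungapped and antiparallel: miRNA position i (1-based from the
5′ end) pairs site position L+1−i. Gaps are excluded because all positional
rules are stated on miRNA coordinates, which bulges would dislocate. G:U
counts 0.5 toward the mismatch totals (rules 1 and 5) but as a non-match for
the adjacency rules (2 and 3) and contributes no stacking energy —
conservative wherever the convention is silent. Rule 6 compares energy
magnitudes (|duplex| ≥ 0.75·|perfect|), the only meaningful reading for
negative quantities. Hybridisation energy is a Watson–Crick
nearest-neighbor stacking sum (Turner-style 37 °C parameters); only adjacent
matched pairs stack, so the energy ratio degrades monotonically as matches
are lost. Initiation terms cancel in the ratio and are omitted. The scan is
vectorised over all windows; each surviving window is re-scored through the
scalar alignment path, so the vector and scalar implementations cross-check
each other on every run.

Cleavage sits on the transcript positions opposite miRNA positions 10 and
11; both are counted as the slice (the data underdetermine which of the two
the cut follows). Degradome confirmation is a per-site binomial tail test:
with T tags on the transcript and k of them at the two slice positions,
p = P(X ≥ k), X ~ Binomial(T, 2/transcript length), confirmed at p < 0.05.
This explicit test stands in for heuristic tag-category schemes; its type-I
error is checked empirically against uniform tags. The three-method overlap
(Venn counts over miRNA–transcript pairs) is exercised with the rule scorer
under the default and a stricter preset (≤3 mismatches, energy ratio ≥0.85)
plus degradome confirmation; an external target-prediction service is not
reimplemented.

## Synthetic data

The generator emulates a three-time-point embryo experiment: a single
chromosome (default 60 kb) hosting structural-RNA genes (2 rRNA, 4 tRNA,
3 snoRNA, 3 snRNA), three protein-coding genes with CDS annotations, and
engineered hairpins — arm + loop + reverse-complement arm with 0–2 bulges
confined to the arm extension so the mature stays paired. Known matures are
21 nt; novel mature lengths follow the size-class mix (default 21:0.40,
24:0.35, other:0.25, echoing the twin 21/24-nt abundance peaks of embryo
libraries). First bases are biased at design time: A with probability 0.662
for 24-nt matures, U with 0.693 for shorter ones.

Every hairpin is planted generate-and-verify: the candidate plus its 150-nt
right context is run through the actual discovery code in its final genomic
position and resampled until the criteria verdicts equal the intent. Decoys
each violate exactly one criterion: a 19-nt mature; a trimmed precursor
under 45 nt; fixed counts of (5, 3, 2) reads; or a weak-MFEI fold-back built
on an {A,C}/{T,C} alphabet in which A:T columns pair weakly and C columns
cannot pair at all, keeping the stem real while |MFE| stays small and G+C%
high. Background reads are structural-RNA fragments, CDS fragments and
intergenic 24-mers whose windows are screened to be structurally incapable
of passing discovery. Abundances are log-normal intended TPM (clipped to
300–5000 so multinomial noise cannot flip calls), scaled so planted reads
occupy 1 − noise_fraction of each library; differential profiles get a
3–8-fold peak, non-differential ones stay within 1.3-fold. Counts are drawn
multinomially per library, so totals are exactly reads_per_library.

Target sites are planted by injecting specified mismatch/wobble edits into
the reverse complement of a chosen mature; intended verdicts for rules 1–5
are computed combinatorially from the edit list (independently of the
scanner), rule 6 from the energy model. Transcripts of differential miRNAs'
pass-intended sites get noise-free anti-correlated abundance profiles
(linearly flipped intended TPM). Degradome tags put a
Binomial(T, signal_fraction) share exactly at the canonical slice and the
rest uniform; transcripts without sites are uniform throughout.

What the generator does **not** emulate: sequencing error, adapters and
quality scores (reads are clean by construction); multi-locus miRNA
families; hairpins with large asymmetric bulges; isomiR heterogeneity;
transcript-level measurement noise in the anti-correlated profiles. Passing
tests therefore demonstrate correctness of the computational chain under
its stated definitions, not robustness to artefacts these steps do not
model.

## Problem sizes and determinism

The standard fixture is 20 pass hairpins, 5 decoys per criterion class,
8 known miRNAs and 10⁵ reads per library (seed 1) — small enough to fold and
scan in about a minute while leaving ≥30 expected counts per planted miRNA,
so recovery rates are measured, not assumed. Differential calling is
calibrated on 300 standalone profiles; degradome calibration uses 500 null
and 200 signal sites of 200 tags each. All randomness flows from
`numpy.random.default_rng` seeded from the configuration; identical
config + seed reproduces byte-identical outputs, and the pipeline's staged
runs resume from on-disk intermediates without changing any TSV.

## Known limitations

The published summary table cannot be reproduced in full: four of its cells
are internally inconsistent with their own printed counts (the 0 and 24 HAI
genome-mapping reads percentages are 0.1 off, and two known-miRNA unique
percentages are off by factors of 10–100 against every stated footnote
convention, as is the snRNA reads row where the accompanying prose agrees
with the recomputation). Exact-recomputation checks use cells that verify.
Hairpin verification makes generation O(attempts × fold cost); pathological
configurations (very high GC targets, tiny genomes) can exhaust the attempt
budget and raise rather than silently degrade.
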