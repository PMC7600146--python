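# Methods

## Codon-usage statistic

For a genome's set of complete CDS, each CDS contributes its
non-overlapping in-frame triplets; the first triplet is dropped by default
(`drop_start=True`) so initiator codons do not bias ATG/GTG/TTG counts.
Triplets containing ambiguous bases are excluded from the tally and counted
separately.  Relative frequencies are `f_i = n_i / N` over all 64 codons —
stop codons are genuine table entries, not discarded — and the phage/host
ratio is `r_i = f_i^phage / f_i^host` with the fixed classification
thresholds 0.9 and 1.1.  The thresholds define the statistic, so the API
and CLI expose them read-only.

Boundary behaviour is exact: classification compares the full-precision
ratio against the literal constants (`>= 1.1`, `>= 0.9`), and only the
printed TSV rounds (ratios to 3 decimals, frequencies to 6).  Codons with
zero host frequency have an undefined ratio: they are flagged, excluded
from ranking, and never silently mapped to infinity.  An optional
pseudocount (add a constant to every codon count before normalizing,
default off) is available for callers who need finite ratios everywhere;
it is deliberately not applied by default because it perturbs every
frequency.  Ranks sort by decreasing ratio with alphabetical tie-breaking,
making reports deterministic.

Phages can be analysed per-genome or pooled (all phage CDS concatenated
before counting).  Both modes are exposed because a joint phage-vs-host
figure can be produced either way and the two give slightly different
rankings; the pipeline records which mode a run used in its manifest.

## CDS completeness policy

A CDS is excluded from codon counting when it is incomplete.  Two checks
are always meaningful and on by default: an annotated partial-location
marker, and a length that is not a multiple of 3.  Two stricter checks are
available as flags: requiring a standard bacterial start codon (ATG, GTG,
TTG) and rejecting internal stop codons.  Exclusions are per-CDS and never
fatal; counts of excluded CDS are logged so a run can always account for
how many annotations it dropped.

A CDS counts as "functional" in genome summaries unless its product
qualifier is missing or matches hypothetical/unknown/uncharacterized
(case-insensitive).  This reconstructs the functional-vs-hypothetical
split of a typical phage annotation table from the annotations alone,
without re-running any homology search.

## tRNA concordance

Anticodons are consumed from annotations (plain 3-mers or GenBank-style
`(pos:..,aa:..,seq:..)` qualifiers; U is normalized to T) and decoded by
exact reverse complement only.  Wobble pairing is intentionally not
modeled: the question asked is the strict one-to-one reading
(anticodon ↔ its Watson–Crick codon), and a wobble mode would change which
codons count as covered.  "Phage-favoured" reuses the ratio classes
(r ≥ 1.1) rather than introducing a separate cutoff.  Codon adaptation
indices (tAI, CAI, RSCU, ENC) are out of scope.

## Growth-curve estimators

The latent period has no universal operational definition, so the package
adopts an explicit one: the last sampled time at which the replicate-mean
titer is still ≤ `rise_factor` (default 2.0) times the baseline mean.  It
is reported at sampling resolution — with 10-minute sampling the answer is
a multiple of 10 — which matches how such experiments are read off.

The baseline window defaults to every point before the titer first doubles
over the initial sample (shrunk once if the threshold recomputed from the
window mean moves the rise earlier); an explicit window is validated to be
flat (no internal rise beyond `rise_factor`).  The plateau is the longest
terminal run of mean-titer points whose relative spread `(max−min)/mean`
is ≤ 25% (configurable); at least two points are required, otherwise
estimation fails loudly rather than returning a burst from a single noisy
sample.

Burst size per replicate is `(mean plateau − mean baseline) / mean
baseline`, the baseline standing in for the concentration of infective
centers — the standard one-step assumption after adsorption and dilution.
No free-phage correction is applied.  The reported burst is the replicate
mean; the uncertainty is the SEM with the n−1 standard deviation.  Because
both estimators are ratios, the unknown absolute dilution of the sampled
culture cancels; absolute PFU/mL values are never interpreted.

MOI is the bookkeeping identity `titer × volume / cells`.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
phage biology.  Defaults describe the kind of system the package targets:
a GC-rich host (base codon distribution from independent per-base draws at
65% GC), phage-sized CDS sets (60 CDS of 100–300 codons ≈ 12k codons, the
scale of a 46-kb siphovirus genome), ~22% of CDS given functional product
annotations, and 77-nt tRNA features carrying the requested anticodon.

CDS bodies are i.i.d. codon draws from the (enriched, renormalized)
distribution with stop codons excluded from the body — synthetic CDS stay
biologically legal — and a fixed terminal TAA appended, so 64-codon tables
still see stop counts.  For a generated pair the expected ratio of every
sense codon is known in closed form: `r_i = e_i / Z`, where `e_i` is the
enrichment factor and `Z = Σ p_j e_j` the renormalization constant over
the host body distribution.  Terminal stops are excluded from the truth
map because their frequency is set by the CDS count, not the bias spec,
and is equal in expectation on both sides.  CDS are placed non-overlapping
on alternating strands with 20-nt random spacers, so strand-aware
extraction is exercised by construction.

Growth curves are deterministic steps — baseline until the latent time,
plateau `baseline × (1 + burst)` one sampling interval later, linear in
between — optionally observed through Poisson plaque counts at a plate
volume of 0.01 mL (baseline counts ≈ 100, comfortably above the ~30-count
regime where Poisson counting is the dominant noise).  What the generator
does **not** emulate: real codon correlation along genes, amino-acid
composition constraints, operon structure, adsorption kinetics, free-phage
background, or pipetting error beyond Poisson counting.  Passing tests
therefore demonstrate correctness of the statistics and estimators under
the stated model, not robustness to every artefact of bench data.

All randomness flows from one integer seed; independent child streams are
spawned per draw type (lengths, codons, spacers, tRNA bodies) so adding a
consumer does not perturb the rest.

## Numerical and format choices

Coordinates are 1-based inclusive (GenBank/GFF3 convention); minus-strand
CDS are reverse-complemented before any codon operation.  Sequences are
case-normalized on read and non-ACGT letters collapsed to N; GC% excludes
N from its denominator.  Multi-record inputs are pooled under one genome
id by concatenation with offset features, so draft host assemblies behave
like single genomes.  The GenBank writer pins the LOCUS date and all
JSON/TSV writers use fixed key ordering and float formats, making pipeline
runs byte-reproducible under identical config, inputs and seed.

## Problem sizes used in validation

Deterministic properties are checked on small inputs (tens of CDS).
Stochastic checks use sizes at which their tolerances are well separated
from the signal: frequency convergence at 2k–20k codons against binomial
standard errors; ratio-class recovery on pairs of 120k codons per side,
where a codon with probability ≥ 1/64 sits ≈3 standard errors from the
nearest class boundary and ≥95% agreement with the analytic classes is
expected; burst-size recovery over 100–500 independent simulated
experiments, where the Poisson-noise estimator mean lies within 2 SEM of
the simulated truth (the small positive bias from dividing by a noisy
baseline is an order of magnitude below the SEM at baseline plate counts
of ~100).

## Known limitations

Compound (joined) feature locations are flattened to their outer span;
genuine intron-containing genes are not expected in phage/bacterial
records but would be mis-extracted.  The concordance report interprets
nothing: whether an uncovered top-ranked codon means anything biologically
is outside the package's remit.  Absolute titer reproduction, adsorption
constants and full infection-cycle models are non-goals.
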