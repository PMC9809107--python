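# Methods

## Problem and model

A balanced reciprocal translocation t(A;B) exchanges the distal (telomeric)
segments of two non-homologous chromosomes, producing two derivative
chromosomes: der(A) = proximal A ⊕ distal B and der(B) = proximal B ⊕ distal A.
Carriers are phenotypically normal but form a meiotic quadrivalent that
segregates in several ways; only *alternate* segregation yields balanced
gametes ({A, B} or {der(A), der(B)}), while adjacent-1, adjacent-2 and 3:1
segregation yield gametes with partial aneuploidy. In a PGT-SR cycle the
embryos with unbalanced dosage on **both** translocation chromosomes
("reference embryos") are informative twice over: their copy-number boundaries
localize the breakpoints, and their exposed monosomic/trisomic regions reveal
which parental haplotype is physically linked to each derivative. That linkage
is what lets euploid embryos be split into balanced carriers and
translocation-free non-carriers — dosage alone cannot distinguish them.

The package implements this analysis end to end, with a pedigree simulator
supplying ground-truthed inputs, and two independent routes to each key
quantity:

- breakpoints: CNV-boundary consensus (kilobase window) vs split long-read
  junction clustering (single base);
- derivative haplotype: reference-embryo voting vs junction-spanning-read
  voting.

## Coordinate and junction conventions

All internal coordinates are 1-based inclusive; BED/BEDPE writers convert to
0-based half-open at the file boundary. The breakpoint position `bp` is the
last base of the fragment on the p-terminal side of the junction, so for a
q-arm exchange the proximal fragment is `[1, bp]` and for a p-arm exchange the
distal fragment is `[1, bp]`. Derivatives are built so telomeres face outward:
a q↔p exchange attaches the partner fragment inverted (minus-strand traversal),
q↔q and p↔p attach it directly. der(A) and der(B) partition every base of
A ∪ B exactly once; this invariant is enforced by construction and verified by
exhaustive per-base scans in the tests.

## Synthetic data generator

The simulator emulates, per embryo: a carrier gamete drawn from a configurable
segregation-mode mix combined with a normal partner gamete; true integer copy
number per segment (0–4), with optional mosaic events blending linearly
(gained fraction f ⇒ CN + f); binned read counts; SNP allele observations; and
long reads from the four carrier molecules (two normals, two derivatives).

Key parameters, defaults, and why:

- **Genome**: 2 chromosomes × 5 Mb, biallelic SNPs every 2 kb (carrier
  heterozygous at ~50% of sites, partner homozygous at ~70%), so a full
  pipeline runs in seconds while every flank still holds tens of informative
  SNPs.
- **Bin counts**: negative binomial with mean m·CN/2 and variance
  μ·(1 + dispersion) — a constant overdispersion factor over Poisson
  (gamma-Poisson with p = 1/(1+d)). Default dispersion 0.1; at the default
  100 counts per 25 kb bin this gives per-100 kb-bin CN noise of σ ≈ 0.10,
  the regime in which 1 Mb-scale embryo profiles visibly separate integer
  and mosaic states. `dispersion = 0` is a deterministic degenerate mode
  (counts = round(μ)) used for exact tests.
- **SNP observations**: each allele present in the embryo drops out
  independently with probability `ado` (default 0.05, in the range reported
  for WGA single-cell work); if all alleles at a site drop, one random
  survivor is kept (a site never reports nothing); genotyping errors replace
  an observed allele at rate 0.002. The partner transmits one allele per site,
  fixed per embryo.
- **Long reads**: lognormal lengths (mean 15 kb), Gaussian per-read mean
  qscores (12 ± 1.5) with an optional low-quality component centred at Q5 for
  the QC filter to remove; 8,000 reads by default, i.e. ~6× depth on the
  20 Mb carrier genome so each junction expects ~6 spanning reads (the
  detector requires 3). Reads crossing a derivative junction get two alignment
  blocks with the junction's breakend orientation and carry the SNP alleles of
  the haplotype physically on that molecule (derivatives carry H1 by default).

Not emulated — and therefore not demonstrated by passing tests: base-level
sequencing error and alignment ambiguity, locus-specific WGA amplification
bias, repetitive/gap regions (where real split-read mapping fails), and
within-arm crossover. Recombination appears only as the optional
flank-haplotype switch; real embryos recombine, which is why the caller
prefers SNPs nearest the breakpoint and reports per-flank evidence separately.

## Copy-number stage

Per-bin CN = 2 × count / median autosomal count. Segmentation is recursive
binary splitting: the least-squares optimal split is accepted if it changes
the segment mean by ≥ 0.3 CN with ≥ 3 bins per side; boundaries are reported
at the first bin of the right-hand segment. Raising the threshold can only
remove splits, never add them (tested). A fine-bin refinement pass
(25 kb bins, ±25 bins around each coarse boundary) mirrors clinical practice
of re-binning near candidate breakpoints.

Integer calls from segment means use deviation d = mean − 2: |d| < 0.2 normal;
0.2 ≤ |d| ≤ 0.7 mosaic (fraction = |d|, reported to whole percent);
|d| > 0.7 full gain/loss. The 0.2/0.7 cutoffs bracket the reported mosaic
range (~31–51%) with full calls outside it; they are configuration, not
biology.

Karyotype strings follow the clinical reporting dialect
(`46, XN, +2q(q14.3→q37.3,~118Mb,×3), …`) with floor-to-Mb size labels, pter/
qter tokens at termini, a band-less whole-arm form (`+17p(×3)`), and the sex
token masked as `XN` unless configured. Serialization∘parsing is the identity
(property-tested). Reference embryos are those with ≥ 1 non-mosaic unbalanced
segment on **each** translocation chromosome; mosaic-only events never
qualify.

## Breakpoint localization

*CNV consensus*: each reference embryo contributes the boundary of its
unbalanced region that faces the normal part of the chromosome (interstitial
regions contribute both edges). The representative is the modal position
(median on ties, then the smaller coordinate); support counts contributing
embryos; the half-window is max(bin width, half the spread of candidates
within 2 bins of the representative) — outliers from atypical segregants
count toward support but not toward the window. No re-snapping to a global
grid is applied: candidates come from segmentation and are already
bin-aligned.

*Split reads*: reads below mean qscore 7 are removed (strictly `< 7`; 7.0
passes). Every adjacent block pair on different chromosomes yields a breakend
candidate, canonically ordered; candidates cluster greedily within a 10 bp
tolerance per side under a modal representative, clusters under 3 supporting
reads are dropped, and reciprocal partners (opposite orientation, ≤ 1 bp
offset) are cross-linked as one translocation with two junctions. On
error-free reads recovery is exact to the base. The small tolerance suits
simulator-exact alignments and is configurable for noisier input.

Concordance between the routes is |Δposition| with a flag for falling inside
the CNV half-window.

## Haplotype phasing and carrier calls

Informative sites are carrier-heterozygous and partner-homozygous (a config
flag admits semi-informative sites with the dosage logic disabled) within
±2 Mb of a breakpoint. Phasing votes use only single-carrier-copy evidence:

- a reference embryo monosomic for distal X received der(X): its proximal-X
  observed carrier allele votes directly for the derivative haplotype;
- one trisomic for distal X received the normal homolog instead: its
  proximal-X allele votes for the complement;
- trisomic-region dosage is never used (both carrier haplotypes are present
  in adjacent-1 trisomies, so it carries no linkage information);
- monosomic-region sites serve as a cross-check (carrier allele absent).

Junction-spanning reads are physically derivative molecules, so every
informative allele they carry votes for the derivative haplotype of that
chromosome (per-SNP majority over reads, ties abstain). Linkage is emitted
only at ≥ 90% vote consistency; below that the stage raises rather than
guesses.

Euploid embryos are called by majority vote (≥ 80%) over ≥ 5 proximal-flank
informative SNPs per chromosome: derivative-linked on both chromosomes ⇒
carrier; normal-linked on both ⇒ non-carrier; anything else ⇒ inconclusive.
Sites where only the partner allele is visible (dropout, or the transmitted
carrier allele coincides with the partner allele) abstain, which makes the
vote ADO-tolerant. Unbalanced embryos are refused by precondition. The
5/80%/90% thresholds are configuration chosen so the recovery properties hold
with ≥ 20 informative SNPs per flank at ado = 0.1 on the toy genome.

## Numerical and tie-break choices

Deterministic everywhere: mode → median → smaller coordinate for all
representatives; ties in segmentation resolve to the smallest split index;
all randomness flows from one master seed through named spawned generators,
so config + seed determine every output byte (hashed in tests). Degenerate
inputs: all-zero counts, zero reads, zero reference embryos, zero informative
sites and non-euploid carrier-call requests all raise or return `inconclusive`
with explicit messages — never a silent guess.

## Problem sizes used in tests and analyses

The shipped analyses and the test suite run on the toy genome (2 × 5 Mb,
12–200 embryos, 8,000–12,000 reads), chosen so the full suite completes in a
few minutes on one CPU. The worked-example computations on the two real
pedigrees use only their published karyotype strings, window centers and
single-base breakpoints; per-embryo segment coordinates are synthetic
encodings of those published values (see `pgtsr.fixtures`), so the
reproduced quantities are the ones the published material determines:
reference-embryo sets, the four window centers, the concordance distances
(42,487 / 34,118 / 8,295 / 57,719 bp) and the ~35 Mb / ~118 Mb size labels.

## Known limitations

- The simulator's error model is deliberately thin (see above); accuracy
  numbers on synthetic data are upper bounds for real embryos.
- Robertsonian translocations, intrachromosomal rearrangements and
  breakpoints in assembly gaps are out of scope.
- The GRCh37 assumption for the fixture coordinates is isolated in
  `pgtsr.fixtures.GRCH37_LENGTHS`.
- Sex-chromosome dosage is not modelled beyond the masked `XN` token.
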