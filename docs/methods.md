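# Methods

## Amplicon model and the synthetic generator

A STELA amplicon is modelled on the sequenced G-rich strand as

    sub-telomere (with its chromosome-specific primer at the 5' end)
    + telomere repeat array (TTAGGG orientation, 5'->3' from the sub-telomere)
    + reverse complement of the telorette tag (27 nt)

The generator (`telostela.simulate`) draws each read from an
`AlleleTemplate`: the proximal units of the array follow the allele's fixed
TVR *fingerprint*; units beyond it are sampled i.i.d. from
`body_tvr_rates` (remaining mass canonical TTAGGG). Total array length is
Normal(`mean_len`, `sd_len`), truncated below at the fingerprint length and
rounded down to whole 6-nt units. Optional random-DNA insertion blocks
(≥ 18 nt) inside the array exercise insertion detection. Sub-telomeres are
random-but-fixed 300–500 nt sequences seeded deterministically per
chromosome-end label, each embedding the printed STELA primer verbatim;
real sub-telomeric references are not required for any downstream stage.

Sequencing noise is an independent per-base substitution/insertion/deletion
model (rates capped at 0.2; substitutions never retain the original base,
insertions add one random base). Four artifact classes are injected at
configurable rates before errors: *low_homology* (degenerate primer-like 5'
end on random DNA), *primer_swap* (5' primer of another chromosome end on
the original sub-telomere body), *no_subtel* (sub-telomere deleted),
*concatemer* (two complete amplicons ligated tag-to-primer). A single
top-level seed drives every draw, and a fixed config yields byte-identical
FASTQ + truth output.

What the generator does *not* emulate: PCR stutter and chimera kinetics,
per-reaction molecule sampling of the ~1,600 pooled PCRs per sample, PacBio
instrument-specific error profiles (errors are uniform and independent),
and real sub-telomeric sequence (paralogy, segmental duplications). Passing
tests therefore demonstrate correctness of the algorithms under a clean,
controlled read model — not robustness to every failure mode of real
libraries.

## Read QC

Primer and telorette detection is semi-global Levenshtein alignment (edlib
mode "HW": query aligned end-to-end, read ends free), on both strands, with
an edit budget of `max_err_frac` (default 0.2) of the query length.
Multiple occurrences are found by iterative masking of matched intervals
(edlib reports only best-scoring locations per pass); overlapping hits keep
the best score. Reads are first oriented primer-5' (reverse-complemented if
the best hit is on the minus strand), which makes classification invariant
to input strand.

Classification order is fixed, most-specific first:

1. **concatemer** — more than one non-overlapping sub-telomere-primer hit,
   or a telorette hit more than 30 nt from the 3' end;
2. **no_subtelomere** — no primer hit within budget *and* the 5' 150 nt
   match no sub-telomere reference at ≥ 80 % identity;
3. **low_homology** — a primer hit exists but the 5' 150 nt match no
   reference at ≥ 80 % identity;
4. **primer_swap** — best primer label ≠ best-matching reference label;
5. **retained** — otherwise, provided a telorette hit lies within 30 nt of
   the 3' end. A read failing only the telorette requirement falls back to
   low_homology (it is not a clean single product); on the generator's
   error model this path is essentially never taken below ~2 % error.

The 80 % identity threshold over 150 nt tolerates long-read error (~10 %
divergence would still pass) while random DNA scores ~60 %; 30 nt is the
3'-window within which a genuine terminal tag can wander due to indels.

## Segmentation

Every 6-mer window (step 1 nt) is scored by Levenshtein distance: 2 if
within 2 edits of TTAGGG (and at least as close to it as to CCCTAA — ties
break to the canonical orientation), 1 if within 2 edits of CCCTAA, else 0.
A 3-state HMM (background / forward-strand telomere / reverse-strand
telomere) is decoded with log-space Viterbi.

Emission probabilities are matched to the sliding-window score process
rather than set naively high: in a perfect repeat array only three of the
six hexamer rotations lie within edit distance 2 of the repeat, so a
telomeric state emits its own score with probability 0.50 and 0 with
probability 0.45; background emits 0 at 0.90. Self-transitions are 0.995.
With these numbers a background run inside the array must reach ~18 nt
before switching states beats staying — which is exactly the minimum
insertion length reported (`min_insertion_len` = 18 nt, three units);
shorter interruptions are absorbed as degenerate repeats. Viterbi (a single
hard path) is used rather than posterior decoding because spans are
reported as hard coordinates; parameters are fixed, not trained.

Two boundary refinements follow decoding. (i) The array start is snapped to
repeat phase: windows straddling the sub-telomere junction (any "xTTAGG")
and off-phase rotations sit at distance exactly 2, whereas a true unit
start from the variant alphabet is at distance ≤ 2 with in-phase successors
averaging ≤ 1; the earliest candidate passing that test wins (fallback:
minimal summed in-phase distance). (ii) When the telorette tag is detected
near the 3' end (≤ 20 % edits, within 30 nt of the end), the tag start
defines the distal array boundary and `trimmed_tel_len` excludes it. On
error-free synthetic reads both sub-telomere and trimmed telomere lengths
are recovered exactly; at 1 % substitution error ≥ 95 % of reads are within
6 nt (one unit).

## TVR profiling

The trimmed array is phased into consecutive units by dynamic programming
over unit lengths 4–8 nt, minimising (total edit distance to TTAGGG, total
|len − 6|, number of non-canonical units) lexicographically — ties thus
prefer 6-nt and then canonical units, and the units always concatenate back
to the exact input (arrays shorter than 4 nt become a single OFFSIZE unit).
Units are classified by exact match against the ten named hexamer classes,
OTHER_6 for any other hexamer, OFFSIZE for non-hexamers.

The allele fingerprint is the ordered class list of units lying entirely
within the proximal 100 nt (16 canonical units fit; a 17th would reach
102 nt). Reads are grouped into alleles by single-linkage agglomeration
over unit-level Levenshtein distance between patterns, merging while the
distance is ≤ 1; clusters are ranked by size with lexicographic
tie-breaking, so labels are independent of input order. This presumes the
proximal interspersion pattern is allele-characteristic, as it is in real
telomeres; fingerprints of reads from the same allele then differ only
through sequencing error.

Per-sample TVR proportions are read-averaged by default (each read
contributes its own per-unit class fractions; the profile is their mean);
`length_weighted=True` pools unit counts across reads instead — the two
conventions differ when read lengths vary. Parental-vs-ALT fold change per
class is (alt + ε)/(parental + ε) with pseudo-proportion ε defaulting to one
unit in the parental sample (1/total units), so classes absent from the
parental profile give finite ratios; the log10 ratio is reported alongside.
Note that because proportions sum to 1, enriching one variant necessarily
depresses the canonical proportion — fold changes near 1 are expected only
for classes whose generation rate is unchanged.

## Length dynamics

`AlleleMixture` fits Gaussian mixtures (scikit-learn EM, 20 random
restarts, seeded) to single-molecule length distributions; k is chosen by
BIC among 1..k_max (default 2, the two parental alleles) unless forced, with
a fallback to k = 1 below 10 molecules. Means are reported ascending with
approximate standard errors sd_k/√(n·w_k). Forcing k = 2 matters when the
two post-crisis alleles are closer than BIC can resolve (≈ 0.5 kb apart at
sd 0.3 kb).

`ErosionModel` regresses per-PD mean length on PD (OLS); ΔTel = −1000 ×
slope, so positive values mean shortening, reported with its standard error
and r².

`call_elongation` matches pre- and post-crisis mixture components by
minimal total mean displacement (nearest-matching when k differs), takes
the matched pair with the largest absolute change, and calls an event only
when that change is an increase above 0.4 kb — below the smallest extension
the models here are parameterised with (0.52 kb) and above paired-fit noise
on synthetic data (~0.2 kb). The symmetric matching makes the call
antisymmetric: swapping pre and post never emits a negative-extension
event. Allelic means are estimated by mixture on molecule lengths (a stated
substitution for densitometry gating of blots), validated by parameter
recovery: over 50 simulated bimodal datasets (components ≥ 5 sd apart,
n = 200) the mean absolute error of component means is < 0.1 kb.

`escape_rate` is printed-count arithmetic, 100·k/n, reported at mixed
precision (one decimal below 15 %, whole percent above).

## Study parameters and problem sizes

`telostela.study` transcribes the per-chromosome-end dynamics of the
ATRX-null crisis system (pre-crisis erosion 60/80 bp/PD at 17p/XpYp;
elongated post-crisis means 6.68/1.87/3.58/3.22/1.93 kb at
17p/XpYp/5p/7q/9p with extensions 5.40/1.06/1.9/1.14/0.52 kb) and the
crisis escape counts (6/52, 9/127, 33/149). Pre-crisis means never reported
directly are back-computed as post − extension; the non-elongated 17p
allele is fixed at 7.9 kb pre / 7.2 kb post. The parameter-recovery
simulations use n = 300 molecules per sample (sd 0.25–0.3 kb) and 6 PD
points × 100 molecules for erosion — sizes chosen to match the fits'
standard errors to the reporting precision of the transcribed values.
Simulation-based tests use 40–2,000 reads per sample with arrays of mean
300–600 nt, which keeps the whole suite fast while leaving every statistical
check at ≥ 3-standard-error resolution.

## Known limitations

- The HMM cannot distinguish an insertion composed of telomere-like
  sequence from the array proper, and insertions shorter than 18 nt are
  absorbed by design.
- Fingerprint-based allele assignment degrades when two alleles share
  their proximal 100 nt pattern (it merges them, as would any method using
  only that window).
- OFFSIZE units conflate all non-hexamer lengths; unit phasing near
  clustered indels is the DP optimum, not necessarily the biological event.
- Mixture standard errors are within-component plug-in estimates and
  ignore assignment uncertainty; they are slightly optimistic for
  overlapping components.
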