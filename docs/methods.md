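# Methods

## Reference model

Mature miRNAs are located inside their hairpins by exact substring search
(stem-matched hairpins first, then all hairpins; an explicit coordinates TSV
overrides the search). Coordinates are 0-based half-open and all sequences
live in DNA space (U→T); labels revert to RNA conventions only in reports
("NTA-U"). When a mature occurs at several positions the leftmost is used
with a warning; matures found in no hairpin are dropped and reported. The
arm is taken from a `-5p`/`-3p` id suffix when present, otherwise inferred
from the mature midpoint relative to the hairpin midpoint. The hairpin
bases immediately 3′ of the mature end (the *downstream template*) are the
arbiter between templated 3′ extension and non-templated addition.

## Preprocessing

The 3′ adapter is located by a seed-and-extend exact prefix scan: the
leftmost position where a prefix of the adapter covers ≥ 8 bases with ≤ 1
mismatch. Randomized-adapter layouts contribute `umi5_len` leading and
`umi3_len` trailing bases to the trimmed read; these are stripped and
concatenated into the UMI key. Inserts outside [16, 28] nt are discarded
and counted by reason. Collapsing counts distinct (insert, UMI) pairs when
deduplication is on, raw reads otherwise. UMI sequencing errors are *not*
corrected (no 1-mismatch clustering): at realistic depths the 10-nt UMI
space (~10⁶) makes collisions the smaller error term, and error-correction
would trade a small undercount for a systematic overcollapse. Quality
scores are parsed and ignored; classification is sequence-based.

## Classification

For each mature entry and each 5′ offset in [−5, +5], the read is matched
greedily along the hairpin from the shifted start; the maximal templated
match defines the 3′ shift and the residual suffix (≤ 3 nt) is the
candidate tail. Templated-first: a trailing base matching the downstream
template is never called NTA. Internal mismatches are admitted only in the
NucVar shape (both ends canonical, exactly one substitution at a
non-terminal position); terminal mismatches are end variants or tails.
Design choices that were genuinely open:

* **NTA on an imperfect 3′ end** (e.g. trimmed by one, then uridylated) is
  still NTA, with the shift recorded — uridylation of trimmed species is
  biologically expected. Configurable off (`allow_nta_on_shifted3`), in
  which case such reads fall to `mv`.
* **NTA requires a canonical 5′ end**; 5′ deviation plus a tail is `mv`.
  This keeps the classes disjoint.
* **Mixed tails** are `NTA-mixed` and excluded from the four NTA-X classes.
* **Multi-mapping**: all miRNAs tied at the minimal edit count receive
  weight 1/k (ids sorted lexicographically for deterministic output).
* **Tie-break** among a single miRNA's equal-edit candidates: hierarchy
  rank, then |shift5|, |shift3|, tail length, then the signed values — a
  total order, so identical inputs give identical calls.
* Reads failing every candidate (e.g. two internal mismatches) are
  `unassigned`, never force-fitted, and excluded from mapped totals.

The test suite checks the classifier against an independently written
brute-force oracle that enumerates every decomposition.

## Summary statistics

All percentages use miRNA-mapped reads as denominator. Composition tables
report per-sample percentages with per-group mean and sample sd (n−1);
group tables are means of per-sample percentages, not read-weighted means.
The NucVar spectrum splits substitutions into the 12 (ref>read) classes.
Per-miRNA uridylation is the percentage of that miRNA's reads carrying an
NTA-X tail; miRNAs under 10 reads are flagged low-coverage. Group
comparisons use the Welch (unequal-variance) two-sided t-test — the
conservative choice where equal variances cannot be assumed — with
degenerate zero-variance cases resolved explicitly (equal means → p = 1).
BH adjustment is implemented directly (step-up, q = min cummin p·m/rank)
and verified against statsmodels in the tests. The equality-of-capture
metric is the coefficient of variation, sample sd over mean.

## Differential uridylation and the intersection test

Per miRNA, WT and DKO per-sample uridylation percentages are compared by
Welch t-test; q-values are BH-adjusted across tested miRNAs
(those reaching 10 reads in every sample); a miRNA is differentially
uridylated when q < 0.05 and the WT/DKO fold change of mean uridylation is
≥ 1.5. The fold-change denominator is floored at 0.1 percentage points
(flagged) to avoid division blow-ups. Testing percentages rather than
uridylated-read counts matches the ratio character of the quantity.

The cross-study intersection is judged against a randomization null: for
each of `n_iter` (default 1000) iterations, each study's set size is drawn
uniformly without replacement from the universe and the draws intersected;
the empirical mean and sd give z = (observed − mean)/sd and O/E. The
universe defaults to the union of all studies' differentially uridylated
miRNAs; zero sd is flagged degenerate rather than producing an infinite z.
The closed form E = N·Π(sᵢ/N) (each element enters study i's random set
with probability sᵢ/N, independently across studies; linearity of
expectation) is exposed separately and the empirical mean is required to
converge to it in the tests.

## Target prediction

Canonical sites are the three standard seed-match types on the UTR
(5′→3′): 7mer-m8 = reverse complement of miRNA positions 2–8; 7mer-A1 =
reverse complement of positions 2–7 followed by A; 8mer = both. An 8mer is
reported once, not as its component 7mers; matches ending at the UTR
boundary count. TUMR sites are matched by the 3′-terminal window (default
8 nt, configurable) of the mono-uridylated sequence (mature + U), pairing
antiparallel with Watson–Crick or G:U wobble pairs (≤ 3 wobbles). The
window parameterisation is an operationalisation of tail-U pairing, not a
reconstruction of any particular external implementation. Orthology is
taken from shared gene ids in `gene|species` FASTA headers; a target is
conserved when a qualifying site exists in ≥ 15 of the 23 declared species.
No context++-style scoring and no 3′-supplementary pairing are attempted.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions.

**Reference**: random hairpins (60 nt) with up to two embedded arms
(20–23 nt) flanked by ≥ 4 nt of template on both sides; hairpins are
resampled until every mature occurs exactly once across all hairpins, so
classification ground truth is unambiguous.

**Pool mode** emulates an equimolar pool of chemically synthesised
canonical miRNAs: no enzymatic tails, no biological length variants; each
base substitutes uniformly with probability 0.003 (oligosynthesis error;
chosen between the published pool-level variant burden, which includes
protocol artifacts, and the much cleaner behaviour of high-QC spike-ins),
plus small 5′/3′ truncation rates (2%/1%). Any NTA call on pool reads is
by construction a classifier false positive; a substitution at the final
base is the structural source of that background and bounds it near the
per-base error rate.

**Cells mode** draws molecules from a class mix (default 45% canonical,
25% lv3pT, 10% NTA-U, 10% NTA-A, 5% NucVar, 5% lv3pE), with tail lengths
1–3 (0.7/0.2/0.1), substitutions from a T>C- and A>G-enriched spectrum
(0.30/0.25, remainder uniform — the RNA-editing signature), and per-miRNA
tail propensities drawn log-normally (sd 0.8; uridylation is strongly
miRNA-specific) with a 5× NTA-U propensity multiplier on 3p arms. NTA
molecules are only assigned to miRNAs whose downstream template differs
from the tail base, otherwise the variant would genuinely *be* a templated
extension. An optional TUT4/7 double-knockout mode converts each NTA-U
molecule, with its miRNA's uniform-random TUT4/7-dependence probability,
to NTA-A (the competing adenylase) or to canonical when adenylation is not
templatable — giving graded, per-miRNA fold changes rather than a uniform
knockdown.

**Library mechanics (both modes)**: per-sequence capture efficiency is
log-normal (`ligation_bias_sd`, default 0.25 ≈ randomized adapters; ~1
emulates fixed adapters) and is a *deterministic function of the insert
sequence* — ligation bias is systematic, so the same sequence is captured
equally well in every sample; samples are then resampled to depth with
those weights. PCR duplication is geometric (mean 3); 5N UMIs flank the
insert; the 3′ adapter is appended so the preprocessing stage is exercised
for real. `depth` counts pre-PCR molecules. The truth table records every
sequenced molecule, so truth proportions equal realized counts exactly.

**What the generator does not emulate**: quality-score-dependent sequencer
errors, indels, adapter chemistry beyond UMI lengths and bias sd,
cross-mapping between homologous miRNA families (references are random and
collision-free), and miRNA abundance skew. Passing tests therefore
demonstrate correctness of the pipeline's logic and statistics under
realistic class mixtures — not robustness to every artifact of real
libraries.

## Problem sizes and seeds

The test suite and the acceptance script run entirely on generated data:
references of 30–60 miRNAs, samples of 2×10⁴–5×10⁴ pre-PCR molecules, six
simulated WT-vs-DKO studies of 3–4 replicates per group at 20k–50k depth
(heterogeneous depth and replication is what makes the per-study
differentially-uridylated sets overlap only partially, as they do across
real laboratories), and 1000-iteration randomization nulls. Every random
draw derives from a single seed, so outputs are byte-reproducible.

## Known limitations

* The classifier assumes the reference is collision-free; paralogous
  families with shared or near-shared matures are handled by fractional
  weights, not by probabilistic reassignment.
* Differential uridylation uses per-sample percentages with a t-test, not
  a count model; with two replicates per group the Welch test has ~1 df
  and essentially no power after FDR control — three replicates are the
  practical minimum.
* No RPM or cross-library normalisation; percentages are within-sample by
  construction.
* The TUMR pairing window is a declared parameterisation; fidelity to any
  specific published tail-U script would need validation against it.
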