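# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted at the read boundary and back on write. A gene's TSS is `start`
on the + strand and `end − 1` on the − strand. Peak files are BED6+1 with
the summit stored as an offset from `start` (the dominant peak-caller
dialect); the absolute summit is reconstructed on read. Distances between
a summit and a transcriptional unit count bases between the summit and the
nearest base of the unit: a summit on a unit base is distance 0 (and
intragenic); the first flanking base is distance 1.

## Location classification

The summit — not the interval midpoint — is the reference point, matching
the summit-centric treatment of the motif windows. Containment in any unit
makes a peak intragenic; otherwise the stranded distance to the nearest
unit boundary assigns 5′/3′ proximal (≤ `flank_proximal_bp`) or distal
(≤ `flank_distal_bp`), and beyond the distal flank from every unit lies the
gene desert. Defaults: distal flank 100 kb; proximal/distal split 5 kb.
The 5-kb split is a conventional promoter-annotation choice, not a quantity
the upstream study fixes, and is configurable. Ties are deterministic:
smallest boundary distance, then the 5′ assignment, then lexicographic gene
id; among multiple containing genes, smallest |TSS distance| then gene id.
The signed TSS distance is oriented along the gene (negative = upstream).
The TSS-distance histogram clips the rare distance beyond ±100 kb (a distal
site measured across a long gene body) into its terminal bin so the profile
conserves the annotated-peak count.

## Differential expression stand-in

Expression is analyzed on the log₂ scale. The two-group test is Welch's t
per gene with Benjamini–Hochberg adjustment across all tested genes; the
original study's moderated (limma) statistics are deliberately out of
scope, and externally computed results tables are accepted anywhere a test
result is consumed. Filtering is adjusted p < 0.05 and fold change ≥ 1.5,
boundary inclusive; the comparison runs on the log₂ scale
(`log2fc ≥ log2(cutoff)`), which is algebraically identical and exact for
effects planted in log₂ units. Genes whose replicates are constant in both
groups have no defined t statistic; they are assigned p = 0 when the group
means differ and p = 1 otherwise (with a warning), which makes the
noiseless limit behave as the planted truth dictates.

NFAT-dependent sets come from the curdlan+FK506 vs curdlan contrast: genes
*down* under calcineurin inhibition are the NFAT-dependent up-set, and vice
versa. This keeps the NFAT sets independent of the stimulation sets, so
their overlap (the Venn summary) is informative; percentages are rounded
half-up to one decimal.

## Binding–expression integration

The bound indicator is TSS-anchored: a gene is bound when any summit lies
within `occupancy_distance_bp` (20 kb) of its TSS, boundary inclusive. The
occupancy curve sorts genes by log₂ fold change descending (ties by gene
id; rank 0 is the most up-regulated — the ordering is recorded in the
output) and slides a 50-gene window, step 1.

Cross-condition peak matching uses shared ids when present and otherwise
reciprocal-nearest summits within 200 bp on the same chromosome; peaks
unmatched in a condition get height 0 there. Direct-target calling adds a
pseudocount of 1 to heights before ratios (stabilizing absent peaks) and
requires, for some site within 30 kb of the TSS,
curdlan/untreated ≥ 1.5 and fk506/curdlan ≤ 1/1.5. The 1.5 symmetry with
the expression cutoff is a design choice — the study states no numeric
binding criterion. One call is emitted per (gene, qualifying peak); a gene
is a direct target when it has at least one call.

Height strata are half-open `[lo, hi)` with the last stratum closed at its
upper bound (so height 20 is "medium" and height 100 "very high"); heights
outside all strata go to a warned overflow stratum so strata always
partition the peaks. Each peak is associated to the nearest TSS within the
100-kb annotation flank (this association radius is not fixed by the study
and is configurable), and `fraction_activated` is the activated share of a
stratum's associated genes (NA when none).

## Motif analysis

Summit windows are `[summit − 100, summit + 100]`, i.e. exactly 201 bp,
clipped at chromosome ends. Peak sampling draws three groups of 600 ids,
uniform without replacement within each group, groups independent (a
`--disjoint` style constraint is not imposed; independent draws are the
default reading).

IUPAC scanning matches all (overlapping) offsets; minus-strand hits are
occurrences of the reverse complement reported at forward coordinates.
Enrichment compares the hit-bearing fraction of the foreground against
dinucleotide-shuffled copies (Altschul–Erickson random Eulerian walks, so
doublet counts are preserved exactly), with the add-one empirical p-value
`(1 + #{bg ≥ fg}) / (1 + n_shuffles)`; its floor is `1/(1+n_shuffles)`.

Motif discovery is a single-width OOPS EM: exactly one site per sequence,
uniform prior over offsets, 0-order background estimated from the input,
pseudocount 0.25 in the M-step, best of 5 seeded restarts, default width 6.
Because the pseudocounted M-step maximizes a Dirichlet-regularized
objective, that penalized objective — not the raw likelihood — is the
provably monotone quantity, and it is asserted non-decreasing every
iteration; convergence is a penalized-objective gain below `tol` (default
1e-6) within `max_iter` (default 200), otherwise the best iterate is
returned with a warning. No multi-width search, erasure, or E-value
calibration is attempted. Discovery on summits with motifs planted on
random strands can legitimately return either orientation of the motif.

Library scanning takes any JASPAR-format PWM set (the proprietary motif
database the study screened is replaced by user-supplied matrices). The
core is the 5 consecutive positions of maximal summed information content;
the core score min–max-normalizes the attained core column probabilities to
[0, 1], so a cutoff of 1.0 demands the modal base at every core position.

## ChIP-qPCR quantification

Percent input is `100 · E^((Ct_input − log_E(1/input_fraction)) − Ct_IP)`
with amplification efficiency E = 2.0 by default (perfect doubling;
per-primer efficiencies are accepted). Technical replicates are averaged on
the Ct scale before transformation. Relative occupancy divides by the
plate's own control region — each plate is normalized independently — and
fold changes divide by the untreated baseline.

## Synthetic data

The generator is a pure function of its parameters and seed and writes a
manifest of everything it planted (direct-target ids, DE memberships, motif
loci, per-condition target heights).

Defaults emulate the study's scale: 20 chromosomes × 25 Mb, 6,000
non-overlapping genes of 2–50 kb placed ≥ 1 kb apart with random strands,
~10,000 peaks per condition, 50 direct targets, and DE cardinalities
515/323 (stimulation up/down), 171/82 (NFAT-dependent), 135 common up (the
common-down count, 60, is not constrained by the study and is a free
parameter). Sequence (i.i.d. at 50% GC) is generated only on request —
coordinate-only genomes serve the annotation/integration analyses, while
motif work uses smaller sequenced genomes.

Expression: per-gene baseline U[4, 10] log₂ units, condition effects added,
Gaussian replicate noise (sd 0.25 log₂ by default), 5 replicates per
condition — enough for the unmoderated Welch+BH stand-in to have reasonable
power at the planted 1.5-log₂ effects, where the study's moderated
statistics needed fewer arrays. NFAT-dependent up-genes keep 25% of their
curdlan effect under FK506; NFAT-only genes carry a sub-threshold curdlan
effect that FK506 removes, so they surface only in the inhibitor contrast.
With noise off, the pipeline recovers every planted membership exactly.

Peaks: each direct-target gene receives an id-matched triplet whose summit
lies within 30 kb of its TSS, with heights untreated U[5, 15], curdlan
2.5–4× that, and FK506 0.2–0.45× curdlan — margins chosen so the +1
pseudocount can never push a planted target below the calling thresholds.
Because a call attaches to every gene within 30 kb of a qualifying summit,
target genes are drawn only from genes whose TSS is more than 60 kb from
every other TSS; planted recovery is then exact by construction, which is
what the recovery tests certify. Decoys are flat (condition-invariant,
heights U[0, 100] so all four strata are populated), induced-but-
FK506-insensitive, or qualifying-but-distant (> 30 kb from every TSS).
Summits keep ≥ 500 bp separation — real callers merge closer events — which
also keeps reciprocal-nearest matching unambiguous in the jittered mode
(per-condition ids, summits offset ≤ 50 bp) that exercises the positional
matcher. The full-dataset generator additionally plants condition-flat
peaks near 60% of the stimulation-up genes, reproducing the
binding-among-upregulated-genes enrichment the occupancy curve displays;
flat heights keep these out of the direct-target calls.

Motifs: a configurable fraction of peaks (default 0.8) receives one
concrete realization of `NANWGGAAAANN` overwritten at a uniform offset
within ±100 bp of the summit, random strand, positions recorded.

**What passing tests do and do not show.** The generator reproduces the
*statistical couplings* the analyses assume — threshold-crossing effect
sizes, binding/expression association, monotone height–activation odds,
planted motif instances — but not read-level noise, fragment-size effects,
copy-number or mappability artifacts, correlated replicate structure, or
realistic genome composition. Exact planted recovery therefore certifies
the algebra and thresholds of the pipeline, not its robustness to
real-data artifacts; the noisy-replicate runs show graceful degradation
(e.g. 161/171 NFAT-up genes recovered at sd 0.25) rather than field
performance.

## Problem sizes and numerics

The analysis drivers and the reproduction script run the defaults above
(6,000 genes, ~10,000 peaks; motif discovery on 600-sequence groups of
201 bp; 100-shuffle enrichment on 200 sequences; 5,000-peak strata runs),
sizes at which every step completes in seconds on one core. Means of
identical floating-point replicates can round by 1 ulp, so "exact"
zero-noise fold-change checks are asserted at 1e-12; set-recovery checks
are exact. Percentages are rounded half-up (Decimal, not banker's
rounding) to match printed one-decimal values.
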