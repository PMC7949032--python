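# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind each `khbind` module.

## SELEX exclusive-k-mer enrichment

**Procedure.** Reads follow the fixed library geometry
`forward primer (23 nt) + insert (20 nt) + reverse primer (23 nt)`.
Trimming matches both primers anchored at the read ends, allowing up to
`max_mismatches` substitutions each (default 2) and no indels; the geometry
is fixed by the library, so unanchored or gapped matching would only admit
artefacts.  Inserts are decomposed into overlapping k-mers for each
k ∈ [k_min, k_max] (default 5–20), counted strand-specifically — the
selected species is single-stranded, so reverse-complement counting would
pool distinct molecules — and windows containing N are skipped.

**Statistics.** Exclusive k-mers (positive-pool k-mers absent from the
control) are ranked by positive count (ties: p ascending, then
lexicographic, for full determinism).  Each is tested with the one-sided
Fisher exact test on `[[c_pos, T_pos − c_pos], [0, T_ctrl]]`.  Two counting
modes exist because either could be meant by "number of times a k-mer
appears": `occurrence` (default; column totals are total k-mer occurrences)
and `presence` (reads containing the k-mer; totals are read counts).  With a
zero control count the one-sided hypergeometric tail collapses to a single
pmf term, C(T_pos, c)/C(T_pos+T_ctrl, c), evaluated in log space with
`gammaln` — exact, and fast enough to test hundreds of thousands of
exclusive k-mers.  The general-table path uses the exact hypergeometric
survival function.  BH adjustment pools all k jointly into a single family
by default (`per_k` is available); significance is q ≤ FDR with FDR = 0.05.

**Why signals emerge at k ≈ 7–8.** Short k-mers (k ≤ 6) almost surely occur
in a control pool of ~10⁵ k-mer windows, so the exclusivity rule removes
them; at large k nearly every k-mer is a singleton. The informative range is
where motif-bearing k-mers recur (through their planted core) yet their
random flanks keep them out of the control.

## Synthetic SELEX pools

Inserts are i.i.d. uniform over ACGT (the library is random; no composition
bias is modelled).  A planted motif overwrites `motif_length` positions at a
uniform offset in a Bernoulli(`enrichment_fraction`) subset of positive
inserts, preserving insert length and read geometry.  Qualities are dummy
Phred+33 "I".  Not modelled: PCR bias, sequencing errors, paired-end
structure, and multi-round enrichment dynamics — the generator emulates the
end-state contrast between pools, not the selection trajectory.  Passing
tests therefore demonstrate the statistics under idealized pools, not
robustness to amplification artefacts.

## NMR chemical-shift perturbation

**Combined shift.** Δδ = [(Δδ²_NH + Δδ²_N/25)/2]^½ (ppm); the 1/25 weight
reflects the larger dispersion of the ¹⁵N axis.  The same weighting (δN/5)
is used as the metric for nearest-neighbour peak matching when later
titration points arrive unassigned.  Matching is greedy by ascending
distance, each peak used once; a match with a second trajectory within 1.5×
the matched distance or within an absolute 0.05 weighted-ppm radius is
flagged ambiguous rather than silently resolved, because crossing peaks
cannot be disambiguated from positions alone.

**Isotherm.** Fast exchange makes the observed shift the population-weighted
average of free and bound states: Δδ(L) = Δδ_max · f_b(P, L, K_d).  The
default model keeps ligand depletion (quadratic single-site mass balance)
because protein at 0.2 mM is not negligible against mM-range K_d values; a
hyperbolic mode (f_b = L/(L+K_d)) is available for the protein-dilute
regime.  The bound fraction is evaluated as 2L/(b + √(b² − 4PL)) with
b = P+L+K_d — algebraically identical to the textbook (b − √·)/2P form but
immune to catastrophic cancellation as P → 0, where it reduces to the
hyperbola (verified numerically at P = 10⁻⁶·K_d to 1e-6 relative).

**Fitting.** Bounded nonlinear least squares (`scipy.optimize.least_squares`,
trf) with one shared K_d across selected residues and per-residue Δδ_max —
sharing mirrors standard practice of fitting the well-resolved loop glycines
jointly and stabilizes weakly saturated titrations.  K_d is bounded to
[1e-4, 1e3] mM and multi-started at {0.01, 0.1, 1, 10} mM to avoid local
minima; the best of the converged starts wins.  Standard errors come from
the Jacobian at the optimum (s²(JᵀJ)⁻¹ with s² = RSS/dof).  A fitted
saturation below 20% at the highest ligand point triggers a "K_d poorly
constrained" warning rather than a hard failure.

**Simulated titrations** use the molar-ratio grid 0, 0.2, 0.5, 1.0, 2.0,
5.0 at 0.2 mM protein with two residues ("84", "87", maximal shifts
0.12/0.10 ppm ¹H and 0.60/0.50 ppm ¹⁵N) by default.  Noise is additive
Gaussian with `noise_sd` ppm on the proton axis and 5·`noise_sd` on the
nitrogen axis, so the combined-shift noise is ≈ `noise_sd`.  In the recovery
studies "2% noise" means 2% of the observed maximal shift on the grid
(Δδ_max × saturation at the top point), i.e. relative to the measured
dynamic range — the usual meaning of percentage noise on a titration curve;
for weak binders the grid tops out well below full saturation and the
distinction matters.

## Equilibrium binding (EMSA / filter binding)

Fraction bound is bound/(bound+free) per lane (NaN, flagged, when both
vanish).  Dose-response fits use f([P]) = B_max·[P]ⁿ/(K_dⁿ + [P]ⁿ) with
n = 1 (hyperbolic, default) or free (Hill, bounded to [0.1, 10]).  Free
protein is equated with total protein: the labelled substrate is
sub-nanomolar against micromolar protein, so depletion is negligible — the
opposite regime from the NMR titrations, which is why the two modules use
different isotherms.  B_max is fitted (bounded ≤ 1.05) rather than pinned at
1 because incomplete shifting is routine.  Initialisation: B_max at the
maximal observed fraction, K_d at the first concentration crossing
half-maximum.  Fits with saturation < 20% of B_max at the top concentration
are flagged unreliable.

## Unwinding kinetics

% unwinding = 100·P′/(S′+P′) with P′ = max(0, P − P_ne) and
S′ = max(0, S − S_hd): the product band is background-corrected against the
no-enzyme control and the substrate band against the heat-denatured control;
negatives are clamped because background can exceed signal in noisy lanes.
The quantity is invariant to common rescaling of all intensities
(exposure/gain independence).

Rates use the reference-level convention: each time course gets an
unweighted OLS line over t ≤ max_time (free intercept; weighting is not
specified by the procedure and unit weights are the neutral choice); the
protein whose line is lowest at max_time (default 45 min) is the slowest,
its rate is defined as duplex_length/max_time, and its fitted level at
max_time is the reference; every faster protein's rate is
duplex_length / (time its line crosses the reference).  Crossing times
outside (0, max_time] are flagged as extrapolations; non-positive slopes
leave the rate undefined.  Reading the reference off the fitted line rather
than the raw endpoint keeps the whole procedure a function of the linear
fits.

**Simulated panels** (`gen_unwinding_panel`) sample the slowest protein over
[0, max_time] and each faster protein within its own linear phase (up to the
time it would reach 100%), as kinetic assays time fast enzymes.  Under this
convention the slowest protein's rate is duplex/max_time by definition, so
panels are built with that rate for the slowest member; recovery is then
exact at zero noise.  Single-course simulation converts the linear-to-
plateau % course into raw lane intensities (fixed 100-unit specific signal
plus constant backgrounds) so that the correction pipeline, not just the
arithmetic, is exercised; the synthetic no-enzyme and heat-denatured lanes
quantify to 0% and 100% by construction.

## Peak annotation

GTF (1-based closed) and BED (0-based half-open) conversions are confined to
the readers; all internal coordinates are 0-based half-open.  The promoter
is the strand-aware window [TSS − 2000, TSS + 500) by default and the
downstream window extends 3000 bp past the gene end — common defaults,
exposed as flags, since annotation-server window choices vary.  Each peak is
assigned by its midpoint with priority
promoter > 5′UTR > 3′UTR > exon > intron > downstream > intergenic;
intron needs no explicit intervals (gene span at lower priority than exon
does the subtraction).  Peaks on chromosomes absent from the annotation fall
back to intergenic with a warning.  Percentages sum to 100 by construction.

**Toy genome.** Genes are laid out evenly with alternating strand on one
chromosome (default 20 genes / 600 kb), three exons each, terminal exons
carrying 5′/3′UTRs sized so the promoter window cannot swallow the 5′UTR
entirely.  A per-base category map painted in ascending priority gives every
position its priority-resolved truth; peak midpoints are drawn uniformly
from the positions of the sampled category (default weights roughly follow
a promoter-heavy regulatory-binding profile: 45% promoter, 25% intergenic,
20% intron, the rest split among exon/UTRs/downstream).  Truth is therefore
unambiguous by construction, and the annotation test asks for ≥ 99%
agreement; genomes too crowded to host a requested category raise an error
rather than silently degrading.

## Determinism, sizes, and runtime choices

Every generator takes an explicit seed and is bit-reproducible.  The test
and acceptance workloads use 5,000+5,000-read pools for planted-motif
recovery (the condition under which one planted 4-mer at 30% enrichment
yields a clean FDR-significant exclusive k-mer), 2,000+2,000-read pools per
replicate for the 20-seed null calibration, 100 simulations per K_d for
titration recovery, and 100 seeds for noisy rate recovery — sizes chosen so
the statistical claims are well-resolved while a full run stays interactive.

## Limitations

* The SELEX test is an end-state two-pool contrast; round-by-round
  enrichment dynamics are neither simulated nor estimable from it.
* The exclusivity rule makes control-pool depth a hard sensitivity: deeper
  control pools strictly shrink the candidate set.
* Kd fits assume a single binding site and fast exchange throughout; slow or
  intermediate exchange would break the population-average model silently.
* The unwinding-rate convention ties the slowest protein's rate to the
  chosen endpoint; it is a comparative, not mechanistic, rate (no k_cat,
  step size, or processivity distribution).
* Peak categories depend on the promoter/downstream window defaults;
  distributions from real annotations are not comparable across window
  choices.
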