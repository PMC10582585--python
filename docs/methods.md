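# Methods

## Repeat model and calling rules

The unit of analysis is a protein ortholog of FOXP2 or FOXP1. Each carries
two major polyQ repeats, Q1 (N-terminal) and Q2 (C-terminal), separated by
a short conserved hinge peptide — `HPGKQAKE` in human FOXP2, `ALQVARQLLL`
in human FOXP1. The caller anchors on the hinge and reads the repeats
relative to it.

**Hinge search.** A sliding-window Hamming scan (substitutions only, no
indels) returns the window with the fewest mismatches, leftmost on ties.
The default tolerance is 2 mismatches; the hinge is a short conserved
peptide and indel-type variation in this region is handled downstream of
the hinge (as an extension), not inside it. Orthologs whose best window
exceeds the tolerance are flagged `no_hinge` and excluded from
classification and correlations, never silently dropped: every input
species appears exactly once in the repeat-call table, called or flagged.

**Q-run grammar.** A run is a maximal stretch of Q residues tolerating at
most one embedded histidine; the H must be interior (never first or last
residue of the run) and counts 1 toward the run length. This reflects the
treatment of an occasional single histidine as part of the polar polyQ
stretch rather than an interruption. Two histidines cannot be bridged by
one run.

**Q1.** Within a window upstream of the hinge (default 100 residues — wide
enough to cover the repeat region, narrow enough to exclude distal Q-runs
of the Q-rich N-terminus), the repeat region starts at the first run of at
least `min_run` (default 2) glutamines. If the region contains proline, Q1
is the run immediately N-terminal to the *first* proline (scanning N→C),
`q1_truncated_by_proline` is set, and all fragmented runs between that
proline and the hinge are ignored. Without proline, Q1 is the longest run
in the region (leftmost on ties).

**Q2 and the hinge extension.** Q2 is the longest run starting within a
window downstream of the hinge end (default 60 residues). The gap between
hinge end and Q2 start is canonical spacing when it is at most
`context_allowance` residues (default 4, config-exposed); a larger gap is
reported as `extension_len` with a `hinge_extension` flag and excluded from
Q2. This separates normal immediate context from insertions such as the
22-residue peptide found between hinge and Q2 in some predicted cetacean
FOXP2 sequences (likely a missed splice junction); that insertion leaves
Q1 and Q2 themselves unchanged, so flagged-but-called rows remain usable.

**Derived metrics and isoforms.** Per ortholog, the sum S = Q1+Q2 and
ratio R = Q1/Q2 are computed; the ratio is stored at full precision and
printed with two decimals (half-even) in tables. With several isoforms per
species, the one maximizing S is analyzed; flagged isoforms rank below all
called ones, and exact ties keep input order with an `isoform_tie` flag.

Degenerate inputs: a missing upstream or downstream run yields a flagged
call (`no_q1`/`no_q2`) with undefined sum/ratio — ratios are never formed
with a zero or missing Q2, so no division by zero can occur.

## Classification

Thresholds live in one config object and are interval conventions as much
as numbers, because the published descriptions use open inequalities that
leave boundary membership unstated. The conventions adopted: the
non-echolocating cluster requires a strict sum > 60 (s = 60 goes to the
USV branch); the FM2 cluster owns both of its printed endpoints [1, 2.1];
ratio bands are left-open/right-closed, so mammal-wide FOXP2 bands are
LOW (r ≤ 3.5), INTERMEDIATE (3.5 < r ≤ 4.5), HIGH (r > 4.5), and FOXP1
bands are EXTREME_LOW (r < 0.2), LOW ([0.2, 0.5)), MID ([0.5, 2)),
HIGH (r ≥ 2). Ratios above the chiropteran range and undefined ratios
return UNASSIGNED rather than an error, since real mammal panels contain
non-chiropteran ratios. The Collen call-type code mapping covers only the
published FM groupings (3, 7, 8, 10 → FM1; 4, 5, 6, 9 → FM2); other codes
raise rather than guess CF/NE membership.

## Binned group-mean correlations

Species are binned either by fixed thresholds (first bin closed at its
upper edge, interior bins left-open/right-closed, last bin open above —
matching the printed "≤ edge" first-bin inequality) or by rank into
equal-sized consecutive groups (stable sort; the non-missing count must
divide evenly, otherwise an error names n and the group size). Transforms
(identity or log10) apply per value *before* group means. Pearson's r is
computed over the per-bin mean pairs, with the two-sided p from the t
distribution with n_groups − 2 degrees of freedom. The p-value is reported
alongside r despite the small number of groups; it is never used for
filtering. Empty bins are dropped; fewer than two non-empty groups or zero
variance in either axis's group means is an error, not a silent NaN. When
several datasets report the same phenotype the maximum is taken for maxima
and body mass and the minimum for minima before binning.

Band contrasts use a one-way fixed-effects ANOVA computed from explicit
sums of squares, followed — only when the omnibus test is significant at
α — by the Student–Newman–Keuls stepdown: ordered group means, studentized
range statistic q = Δmean / √(MSW/n_h) with n_h the harmonic mean of the
two group sizes (the unbalanced-group convention adopted here), critical
values from the studentized-range distribution at the span of the ordered
range and the within-group degrees of freedom, and the stepdown rule that
a pair inside a non-significant wider range is itself non-significant.

## Assay quantification

**CD.** Mean residue ellipticity is `[θ] = θ·mw / (10·(n−1)·c·pl)` with θ
in mdeg, mw in g/mol, c in mg/mL and pl in cm; n < 2 is rejected (zero
divisor). Features: pointwise low-minus-high temperature subtraction
spectra (grids must match exactly), the 222/208 nm ellipticity ratio on
MRE values (> 1 is the coiled-coil signature; wavelengths resolve to the
nearest grid point within 1 nm, else an error — spectra are collected
every 0.5–1 nm), and melt curves of the 222 nm MRE normalized to the
lowest temperature (first point exactly 1).

**FRAP.** Double normalization: each series is divided by its own
pre-bleach mean (default 3 pre-bleach frames), then the bleached series is
divided pointwise by the mean of the normalized controls, cancelling any
multiplicative drift shared with the controls (verified as an invariance
test). Post-bleach points, with time measured from the first post-bleach
frame, are fit by bounded least squares to the single-exponential recovery
F(t) = F0 + (P − F0)(1 − exp(−t/τ)), F0 ∈ [0, 1], P ∈ [0, 1.5], τ > 0,
initialized from crude estimates (F0 = first post-bleach value, P = mean
of the last 10 points, τ from time to half recovery). Reported: τ,
t½ = τ·ln 2, plateau, and mobile fraction (P − F0)/(1 − F0) on the doubly
normalized scale where pre-bleach ≡ 1. A single-exponential model is used
because t½ and mobile fraction determine and are determined by it; a
double-exponential adds parameters the reported quantities do not
constrain. P < F0 flags `no_recovery` rather than erroring.

**Luciferase.** value = (firefly/Renilla) / mean over control wells of
(firefly/Renilla). The control-group mean of the outputs is exactly 1 for
every plate, and the outputs are invariant to common rescaling of either
channel. Non-positive Renilla readings are errors naming the well.

**Condensates and cochleae.** Relative condensate area is condensate area
over the nuclear/cell reference area (areas arrive as numbers; no image
segmentation here), optionally renormalized to a control mean. Cochlear
ratios are Euclidean landmark-pair distances: cochlear width over
basicranial width (CW/BW) and cochlear height over cochlear width.

## Synthetic data: what it emulates, what it does not

Generators are deterministic given their seed and every one returns a
truth table sufficient to assert downstream calls exactly.

*Orthologs* are built as `M + flank + Q1 (optional interior H) +
(P + Q-fragment)* + hinge + optional extension + Q2 + flank`, with flanks
drawn from an alphabet excluding Q, P and H so programmed runs stay
unambiguous. The default downstream flank (60 residues) covers the Q2
search window, which is also what makes the append-monotonicity property
hold: with a shorter flank, a long appended Q-run could enter the window
and, under the longest-run rule, become Q2.

*Panels* draw ratios uniformly over (0.5, 5.5) — spanning the observed
mammalian range from ultrasonic to infrasonic vocalizers — quantize each
to an integer (q1, q2) with q2 ∈ [2, 20] minimizing |q1/q2 − ratio|
(smallest q2 on ties; quantization error ≤ 0.05 over ratios in [0.3, 6]),
and set log10 frequency (kHz) = 2.0 − 0.35·ratio + N(0, 0.15) and log10
body mass (g) = 1.2 + 0.8·ratio + N(0, 0.15). The defaults give
frequencies from ~1 to ~70 kHz and masses from tens of grams to hundreds
of kilograms across the ratio range, with a strongly negative group-level
frequency correlation and a positive mass correlation, the qualitative
structure of the real panels. The expected group-level r for a model is
computed by direct Monte-Carlo simulation of the model in numpy,
independent of the pipeline path it is used to check.

*FRAP* traces follow the single-exponential model above (defaults
τ = 24.28 s, F0 = 0.1, P = 0.802, i.e. t½ = 16.83 s and mobile fraction
0.78, echoing the reported condensate dynamics), with multiplicative
Gaussian noise and an optional shared acquisition-bleaching decay. *CD*
spectra mix two fixed synthetic basis curves built so that every mixture
passes through the same value at 203 nm (an exact isodichroic point);
these are documented synthetic shapes with no claim of physical realism.
*Luciferase* plates draw Renilla per well log-normally and set
firefly = effect × Renilla × noise per group.

What the generators do **not** emulate: phylogenetic correlation between
species (panels are i.i.d. across species, so passing parameter-recovery
tests says nothing about phylogenetic non-independence in real data),
sequencing/prediction errors other than the modeled hinge extension,
realistic audiogram shapes, or CD band physics. Tests passing on these
fixtures demonstrate the correctness of the calling rules, normalizations
and statistics — not the biological claims themselves.

## Numerical choices and problem sizes

Ties in hinge search and run selection break leftmost; ratio printing uses
half-even rounding at 2 decimals while full precision is stored; the
studentized-range critical values are cached per (span, df, α) since null
simulations reuse a handful of them thousands of times. Test problem
sizes — a full programmed-architecture grid of ~8,800 orthologs, 20 panels
of 200 species, 200 noisy FRAP traces, 2,000 null ANOVA datasets — were
chosen so the whole suite completes in well under a minute while keeping
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- Ordinary (non-phylogenetic) correlations by design: no independent
  contrasts or PGLS, mirroring the analysis this package implements.
- The hinge mismatch tolerance (2) is a package default, not a published
  value; distant orthologs with more divergent hinges need a config
  override.
- Boundary membership at s = 60 and at interior band/bin edges follows the
  conventions above; published descriptions leave them unstated.
- The Q2 longest-run rule is not monotone under arbitrary suffix insertion
  when the downstream flank is shorter than the search window (see above).
- One embedded histidine per run is a hard grammar limit; a run with two
  histidines splits.
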