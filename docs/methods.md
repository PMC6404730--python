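# Methods

## The three-step affinity model

TBP–promoter recognition is modelled as slide → stop → bend.  For every
window *w* of length 15 inside the analysed region (by default the 70 bp
at TSS-relative offsets [−70, −1], gene strand 5'→3', the only strand
scanned) three raw scores are computed:

* **stop**: additive PWM score, Σⱼ pwm[base(wⱼ), j].  The default PWM is
  stored as per-position base frequencies and converted to natural-log
  odds against a uniform background at load time.  Its information is
  concentrated in the 7-bp TATAAAA core; flanking positions carry a weak
  G/C bias, matching the GC-rich context of human core promoters.
  Consensus: `GTATAAAAGGGGGGG`.
* **slide**: mean over the window's 14 overlapping dinucleotide steps of a
  step-deformability scale.
* **bend**: likewise for a bending-propensity scale.

The two dinucleotide scales are relative (dimensionless) tables dominated
by the TA and AT steps at which TBP kinks the duplex, with AA/TT and the
flexible CA/TG steps intermediate; both are symmetric under strand
complementation of the step (AA=TT, CA=TG).  They are shipped as
configuration (`src/tatamark/data/tbp_model.yaml`), not hard-coded, and a
user can substitute literature scales of their choice.

### Calibration

Each raw term is mapped to a common −ln K_D scale (K_D molar) by a linear
map Eᵢ = aᵢ + bᵢ·fᵢ.  The default is a two-point **anchored** calibration:
the PWM-consensus window maps to 20.7 (K_D = 1 nM, a literature-typical
strong TATA box) and a poly-G window to 13.8 (K_D = 1 µM, nonspecific
binding).  Two consequences are deliberate:

* At the consensus window the three calibrated terms coincide exactly, so
  δ = 0 there; single-base deviations from the consensus therefore produce
  small δ and large Z.  This is what makes the model sensitive to
  individual core-promoter SNPs.
* Each calibrated term is **saturated** at the strong-site anchor: a
  linear calibration is only meaningful inside its anchored range, and no
  window is predicted to bind more tightly than a consensus TATA box.
  Without the cap, long TA repeats would extrapolate above the consensus
  on the dinucleotide scales, and inserting a consensus site into an
  AT-rich background could *lower* the promoter's max-window score.  The
  cap applies to anchored calibrations; explicitly supplied (a, b)
  calibrations are left uncapped.

### Combination and uncertainty

The window estimate is the unweighted mean of the three calibrated terms;
the promoter estimate −ln K_D is the maximum over windows (leftmost on
ties) and δ = SD(E₁,E₂,E₃)/√3 at the maximizing window — the standard
error of the mean of three one-shot estimators.  δ is thus a
between-method disagreement, zero exactly when the three partial
estimates coincide.  Sequences are strict A/C/G/T; IUPAC codes are
rejected by default or, in lenient mode, resolved to the first base in
alphabetical order with a warning.

## Allele comparison

The minor allele is applied in place (substitutions preserve length;
indels re-anchor the sequence at its TSS-proximal end, pulling upstream
bases from a supplied 5' flank for net deletions and trimming the 5' end
for net insertions).  Z = |Δ(−ln K_D)| / √(δ²_wt + δ²_min), two-tailed
standard-normal p, α = 1 − p.  The two-tailed convention is conservative
and consistent with the α-as-confidence readout (Z = 2.51 ↦ α ≈ 0.988).
Significance threshold α ≥ 0.95 (Z ≥ 1.96).  If both δ are zero the score
is 0 for equal estimates and an error otherwise.  Rank bins are a
documented default: A ≥ 0.9999, B ≥ 0.999, C ≥ 0.99, D ≥ 0.95, E below.

## Marker rule and dichotomy statistics

Polarity is a required gene-level input (the underlying literature
curation is not computable); genes with no significant SNPs contribute
zero.  The tally conserves N_RES = N↑ + N↓ = N> + N< per system and in
total.

Binomial tests are exact; two-sided p-values use the doubling method
(2·min of the two tails, capped at 1), cross-checked in the test suite
against enumeration with exact rational arithmetic.  The neutral-drift
test puts the affinity-increasing count at success probability 0.2 (the
genome-wide ≈1:4 ratio of site-improving to site-damaging variants).  The
equal-split χ² is the 1-df goodness-of-fit statistic without continuity
correction — the published per-strain values (e.g. 13:7 → 1.80) are only
reproduced uncorrected (Yates would give 1.25).  The all-concordant
validation probability for n independent checks is the closed form 0.5ⁿ.
No multiple-testing correction is applied across systems.

## Contest scoring

The default rule is strict and conjunctive on totals pooled over a pair's
observations: a male is dominant iff it has strictly more attacks AND
strictly fewer submissive poses.  Ties or disagreement between the two
measures leave the pair unresolved; unresolved pairs are excluded from
the cross table and listed separately.  An attacks-only rule is available
as a configuration switch.

## Synthetic data

The generator's defaults are the study conditions: 231 genes, a Poisson
mean of 5052/231 ≈ 21.9 SNPs per 70-bp promoter, contest design
PT 31 / C57BL/6J 20 / YT 21 / DD 20 / A/He 23 (115 pairs) with BALB-sired
dominance probability p_dom = 79/115.  Remaining defaults were chosen
once as field-realistic: GC content 0.70 (human core promoters are
GC-rich, which also makes the AT-rich TATA island stand out on all three
model scales), an intact-motif fraction of 0.25 (roughly the TATA-bearing
share of human promoters) plus 0.125 carrying a one-base-damaged motif,
effect mix (0.15, 0.15, 0.70) and polarity mix 0.5.

Mechanics worth knowing:

* One seed spawns a fixed substream per generator (promoters, variants,
  annotations, contests), so each input is reproducible independently.
* A single substitution cannot create a TATA box in GC background, so
  motif-*creating* SNPs are realised as the restoring allele of a
  promoter that carries the consensus with exactly one damaged core base.
  `gen_variants` relocates motifs by scanning (exact match = intact, one
  core mismatch = damaged) and stays a pure function of its inputs.
* Contest observation counts are Poisson draws with winner/loser rate
  asymmetry (defaults 3.0/0.4 attacks, 0.3/2.5 submissive poses per
  observation, 14 observations), redrawn in the vanishingly rare case the
  pooled totals fail the conjunctive rule, so the scored winner always
  equals the drawn winner; only the winner identity is guaranteed, not
  count magnitudes.

What the generator does **not** emulate: real human promoter composition
and motif diversity (one canonical TATA PWM only), linkage and allele
frequencies, multi-allelic sites, SNP-specific polarity, or behavioural
time-course structure within contests.  Passing tests therefore
demonstrate correctness of the pipeline's logic and calibrated
sensitivity under controlled conditions, not predictive accuracy on real
genomes.

Under the default calibration the end-to-end direction recovery measured
in the test suite is ≈ 70–75% for motif-disrupting and motif-creating
SNPs versus ≈ 1–2% false-positive significance for background SNPs.  The
dominance/subordination balance property (50:50 polarity ⇒ balanced
tally) is tested in the ≈1-SNP-per-gene regime: polarity is gene-level,
so denser studies cluster correlated marker calls within genes and the
simple binomial reference becomes overdispersed.

## Numerical and interface choices

* Window scanning is vectorised (PWM gather + convolution over
  dinucleotide step values); results equal the brute-force per-window
  enumeration to floating-point accuracy (property-tested to 30 bp).
* Argmax ties resolve to the leftmost (most upstream) window.
* TSV is the primary tabular dialect with fixed column orders; a minimal
  VCF dialect is accepted for variants (CHROM/POS mapped through a
  per-gene TSS table, − strand alleles reverse-complemented), never
  emitted.
* Offsets are 1-based TSS-relative negative integers throughout.
* The test-suite and acceptance-script simulation sizes (e.g. 1000
  replicate contest studies, studies of 50–150 genes) were chosen to make
  the whole suite run in well under a minute of compute while keeping
  every statistical check at its stated resolution.

## Known limitations

* The affinity scale is anchored, not fitted: absolute K_D values are
  order-of-magnitude placements, and only allele *differences* carry
  meaning.  Reproducing any particular published K_D table is a non-goal.
* δ reflects disagreement among the three step estimators, not
  thermodynamic measurement error; with a different calibration the same
  sequence change can cross the significance threshold.
* Only TBP and one strand are modelled; promoters regulated through other
  core elements (Inr, DPE, CpG-island promoters without TATA) are
  invisible to the model.
* The contest rule is the pooled conjunctive asymmetry; per-day criteria
  or duration-based scoring are out of scope.
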