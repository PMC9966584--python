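# Methods

`probioscreen` implements a complete multi-criteria screen for probiotic
yeast candidates isolated from fish intestinal mucosa: strain dereplication
by RAPD fingerprinting, derivation of phenotypic traits from raw assay
readings, additive threshold scoring, a three-stage selection funnel, and
the supporting statistics. A seeded generator reproduces the screen's study
conditions for testing. This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Strain dereplication from RAPD fingerprints

A RAPD lane is a list of amplicon sizes (bp). Cross-lane band matching is
not part of any published protocol (gel software produces sizes; matching is
done by eye), so it is made explicit here: fragments are pooled, sorted, and
chained into bins — two fragments share a bin iff their sizes differ by at
most a relative tolerance of the smaller size, transitively (single
linkage). The default tolerance is 5%, a typical agarose sizing error. Each
lane contributes at most one presence per bin.

Binary fingerprints are compared with the Jaccard coefficient
(shared bands / union of bands; two failed lanes are incomparable and raise
an error rather than returning a value). UPGMA is implemented from scratch:
the closest pair of clusters is merged at height `distance / 2`, ties broken
by the lowest (row, column) index pair for determinism, and distances to the
merged cluster are size-weighted means — so every cluster-to-cluster
distance equals the mean of the original leaf distances, which the test
suite verifies against an independent naive agglomerator and against
average-linkage cophenetic distances from `scipy`.

The strain rule — isolates with **more than 85% similarity** are the same
strain — is applied on the dendrogram, not on raw pairwise values: tree
similarity of a merge at height `h` is `(1 − 2h) × 100` (the cophenetic
distance between leaves joined there is `2h`), and strains are the maximal
subtrees whose merges all strictly exceed the cutoff. A pair at exactly 85%
therefore splits. Fingerprints are only comparable within a species, so the
pipeline clusters per species and assigns globally unique pattern labels in
first-appearance order; labels are presentation artifacts and only the
partition is meaningful.

## Trait metrics

All thresholds are strict as stated, except where noted:

| trait | formula / rule | positive when |
|---|---|---|
| hydrophobicity (MATS) | `H% = (1 − A1/A0) × 100` vs xylene | > 20% (high > 80%; the 20 and 80 endpoints are "medium") |
| electron donor / acceptor | same formula vs chloroform / ethyl acetate | descriptive only |
| autoaggregation | `(1 − A(t)/A(0)) × 100`, t = 1 h and 24 h | > 20% at 1 h |
| biofilm (crystal violet) | mean blank-corrected OD600 of ≥ 3 wells | > 0.8 |
| enzymes (API-ZYM) | count of the 19 panel enzymes scored positive **or medium** | ≥ 8 (see below) |
| hemolysis | α/β lysis = hemolytic, γ = nonhemolytic | safety gate, not a point |
| antagonism | largest inhibition-halo diameter vs *Vibrio* spp. | > 1 mm |
| biomass | dry weight after 40 h culture, g/L | ≥ 1.0 g/L (see below) |
| polyamines | `(area − intercept)/slope`, scaled by extract volume, per mg dry weight | descriptive |

Two thresholds are implemented inclusively because the screen's own
criteria grid is only reproducible that way at the table's printed
precision: strains with exactly 8 active enzymes and a strain with biomass
printed as 1.00 g/L are both marked positive there. The grid is taken as
operative over the prose ("more than 8", "greater than 1").

Negative H% (A1 > A0, possible under measurement noise) is returned as
computed, flagged, and classified "low" — data are preserved and the
classification stays total. Biofilm wells subtract a per-plate blank before
the 0.8 rule (standard crystal-violet practice; switchable off). Replicates
aggregate as mean ± standard error throughout. Polyamine areas at or below
the calibration intercept report 0 ng/mg with a below-LOD flag, never a
negative concentration; the extract volume used in the ng/mg conversion is
an explicit parameter because no standard value exists. "Total polyamines"
is spermidine + spermine (+ putrescine when present) per compartment.

## The selection funnel

**Stage 1** (39 → 16): one representative per RAPD pattern, by highest mean
biomass, ties to the smallest isolate id. The reference dataset documents
two patterns whose recorded representative is not the top producer (C01
over C44 in one pattern, C17 over C38 in another, with no stated rule);
`step1_select` therefore accepts per-pattern overrides and the packaged
pipeline configuration carries exactly those two, so downstream tables keyed
by the recorded strain codes connect. Count-level behaviour is identical
either way.

**Stage 2** (16 → 7): hemolytic strains are gated out first (safety is a
hard gate, never an additive point — the additive total counts the flags as
displayed in the criteria grid, where a safe strain's hemolysis column
contributes nothing). A species whose best member's biomass falls below the
rare-species floor (default 0.7 g/L) is dropped entirely. Remaining strains
are ranked within species by total, ties broken by enzyme count, then
biomass, then id, and per-species quotas are taken. The default quotas
(2 / 3 / 2 for *C. haemuloni* / *C. parapsilosis* / *D. hansenii*) are
explicit configuration: "the strains with the most characteristics of each
species" does not by itself explain why a total of 3 is selected in one
species and rejected in another, so the ambiguity is surfaced as a
parameter rather than hidden in code. A species absent from a configured
quota map receives quota zero; with no quota map at all, every strain tied
with its species' best total is kept.

**Stage 3** (7 → 3): strains whose 24 h larval survival, or whose
hyposaline-stress survival, is significantly *below* the uninoculated
control (Dunnett, two-sided, α = 0.05) are excluded. This is a
non-inferiority reading — matching or exceeding the control passes, and a
strain significantly above control is obviously retained. Polyamine
comparisons are reported as supporting evidence and never exclude a strain.
Endpoint percentages per replicate vessel (not hourly values) enter the
comparison.

## Statistics

The omnibus path mirrors small-assay practice: Shapiro–Wilk on pooled
within-group residuals (per-group samples of size 2–3 are too small to test
alone) and Levene across groups; both pass → one-way ANOVA, with Tukey HSD
when significant; normality fails → a Johnson transformation is attempted
and the checks re-run; otherwise Kruskal–Wallis with Bonferroni-adjusted
pairwise Mann–Whitney comparisons. A group with fewer than 2 replicates
forces the nonparametric path with a warning. Every branch taken is
recorded in the result, and group letters are a maximal-clique compact
letter display consistent with the pairwise decisions. α = 0.05 throughout.

The Johnson transformation uses the percentile method: S_B, S_L and S_U
candidates are fitted at a grid of fit points (z ∈ {0.25 … 1.25}) and the
candidate maximizing the Shapiro–Wilk p-value of the transformed sample is
kept, falling back to identity when nothing improves normality. It requires
at least 8 observations; below that the nonparametric path is used.

Dunnett's many-to-one test is computed in-package: the observed
treatment-vs-control t statistics are compared against `n_mc = 100,000`
seeded Monte Carlo draws of their joint null distribution (shared control
mean and shared pooled variance — the correlated multivariate-t structure),
giving family-wise adjusted p-values `P(max_j |T_j| ≥ |t_i|)`. The analytic
bound `p_adjusted ≥ p_unadjusted` is enforced exactly, and a Bonferroni
p-value is reported as a conservative cross-check. The test suite checks
the implementation against `scipy.stats.dunnett` (quadrature), against the
two-sample t-test in the single-treatment reduction, and against a
noncentral-t power oracle. A note on power: with triplicate groups
(df = 6) the two-sided Dunnett critical value is ≈ 3.1, so even a true
3-SE shift is detected only about half the time — small in vivo assays
genuinely have that little power, and the simulation reproduces it.

## The synthetic generator

`synthetic_data.simulate_dataset` emits every table the pipeline consumes,
deterministically for a given seed (each component draws from its own
substream, `default_rng([seed, component_index])`, so adding a component
never perturbs another).

Noise models, simplest consistent with replicate standard errors:
truncated-normal assay replicates (replicate SD chosen so the SE of the
replicate mean equals the configured SE), per-hour binomial thinning for
larval survival at the constant hazard implied by the configured endpoint
fraction, deterministic categorical enzyme panels, and chromatographic peak
areas produced through configured true standard curves with multiplicative
lognormal noise (CV 5%), so the quantification path can be tested for
inversion.

Band templates draw fragment sizes from a geometrically spaced pool
(ratio 1.10 over 100–3000 bp) so neighbouring candidate sizes never fall
within the 5% binning tolerance. Size jitter is lognormal with CV 0.5%
(within-gel sizing repeatability). Band dropout defaults to 0.005 per band:
the 85% cut is unforgiving on short fingerprints — a single 12-band lane
that loses two bands sits at 10/12 = 0.833 on its own — so reliable
(≥ 95%) recovery of planted strains requires the per-lane probability of a
double dropout, ≈ C(12,2)·p², to stay near 10⁻³. Expected within-strain
Jaccard similarity under dropout p is (1−p)/(1+p) per the
independent-thinning formula, which the tests verify by simulation.
Default templates carry 24 bands (three complementary dropouts still leave
21/24 = 0.875, above the cut) at a pairwise divergence of at least 5 band
edits, keeping cross-strain similarity well below 85%.

The default calibration *is* the study's conditions: 16 strains with the
reported per-strain biomass means and SEs and the reported enzyme profiles;
39 isolates distributed over the reported pattern memberships; triplicate
assays (duplicate for hydrophobicity); safety assays of 3 beakers × 100
larvae over 24 h for the seven stage-2 strains plus control, stress assays
of 3 dishes × 10 larvae over 8 h. Quantities the study reports only
graphically or as grand means carry plausible stand-ins flagged
`non_paper` in the config: adhesion panel means consistent with every
reported classification; per-strain pellet/supernatant polyamine totals
whose grand means equal the reported 333.05 and 180.07 ng/mg exactly, with
pellet spermidine ≈ spermine and supernatant spermine ≈ 7× spermidine as
reported; a 34% control survival (the reported C10 effect is 54%, "20%
more than control") with the C32 safety effect at 12% and the three
stress-harmful strains at 18% vs a 73% stressed control.

What passing tests on synthetic data do **not** show: the generator has no
gel-to-gel calibration drift, no correlated band intensities, no
plate-position effects, no non-constant larval hazards, and no taxonomic
misassignment — recovery rates on real gels and real assays will be lower.

## Numerical choices and degenerate inputs

- Threshold comparisons at the biofilm 0.8 boundary guard against float
  representation of the replicate mean (ε = 10⁻⁹).
- The earliest time wins ties for the growth-curve maximum.
- Empty cells in input tables surface as absent values and binarization
  fails loudly, listing the missing criteria — zero is a legal measurement
  and is never used as a sentinel.
- Two all-zero fingerprints raise an undefined-similarity error.
- A constant sample cannot be Johnson-transformed (error), and a
  zero-variance pooled estimate in Dunnett degrades to ±∞/0 t statistics
  rather than dividing by zero.
- Problem sizes in the test suite: brute-force UPGMA oracle up to n = 10
  leaves; planted-strain recovery over 200 seeds (k = 5, 3 isolates per
  strain); null calibration of the omnibus decision path over 1,000
  triplicate draws; Dunnett Monte Carlo at 20,000 draws in simulations and
  100,000 in production use.

## Known limitations

- The funnel reproduces the documented rules, not the authors' judgment;
  the two stage-1 representative overrides and the stage-2 quotas encode
  decisions the source screen made without stating a rule.
- The Dunnett adjustment is Monte Carlo, so adjusted p-values carry
  ~10⁻³-scale seed-dependent noise (the analytic lower bound is exact).
- Band binning assumes sizes from a shared ladder calibration; systematic
  cross-gel size bias is not modelled or corrected.
- The 15-vs-16 pattern-count discrepancy in the source material (the prose
  total appears to exclude the single Basidiomycete isolate) is left as
  reported: the package reports the full partition and per-species counts.
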