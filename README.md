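# probioscreen

Multi-criteria in vitro screening of probiotic yeast candidates from fish
intestinal mucosa: RAPD strain typing, phenotypic trait scoring, a
three-stage selection funnel, and the supporting statistics — with a
seeded synthetic-data generator reproducing the study conditions.

## The problem

Marine fish larvae suffer high early mortality, and host-derived
("autochthonous") yeasts are promising probiotics because they adhere to
the gut mucosa, secrete digestive enzymes and polyamines, and resist the
antibacterials used in aquaculture. Screening wild isolates is a funnel
problem: many culture isolates are the same strain; candidate strains must
grow well, be safe (nonhemolytic, harmless to larvae), and show
adhesion-related surface properties. This package implements that funnel as
a reusable, tested pipeline for the reference screen of 39 yeast isolates
(*Candida haemuloni*, *C. parapsilosis*, *Debaryomyces* spp.,
*Naganishia* sp.) cultured from the intestines of healthy adult cobia
(*Rachycentron canadum*).

## The method

1. **Dereplication.** RAPD-PCR lanes (fragment sizes, bp) are binned across
   lanes (5% relative tolerance, single-linkage chaining), compared with the
   Jaccard coefficient `J = |A∩B| / |A∪B|`, and clustered with UPGMA
   (average linkage, built from scratch, deterministic tie-breaking).
   Isolates with tree similarity `(1 − cophenetic distance) × 100 > 85%`
   are one strain; one representative per pattern (highest biomass)
   advances — 39 isolates → 16 strains.
2. **Trait scoring.** Each strain is scored one point per criterion met:
   biomass ≥ 1 g/L; ≥ 8 active API-ZYM enzymes (medium counts as active);
   inhibition halo > 1 mm against *Vibrio* pathogens; crystal-violet
   biofilm OD₆₀₀ > 0.8; autoaggregation > 20% at 1 h; MATS hydrophobicity
   `H% = (1 − A₁/A₀) × 100 > 20%` vs xylene. Hemolysis (α/β vs γ) is a
   hard safety gate, not a point. Per-species quotas (2/3/2) with
   enzyme-count tie-breaks give 16 → 7.
3. **In vivo vetting.** Strains whose 24 h larval survival or
   hyposaline-stress survival falls significantly below an uninoculated
   control (Dunnett's many-to-one test, adjusted by seeded Monte Carlo on
   the multivariate-t null) are excluded: 7 → 3. Polyamine quantification
   (dansylated standard curves, ng per mg dry weight) is reported as
   supporting evidence.
4. **Statistics.** Group comparisons follow an assumption-checked path:
   Shapiro–Wilk + Levene → ANOVA/Tukey; non-normal data get a Johnson
   transformation (S_B/S_L/S_U, percentile method) or fall back to
   Kruskal–Wallis with Bonferroni-adjusted pairwise comparisons; results
   carry compact letter displays.

The reference tables (isolate identifications, pattern/biomass grid,
19-enzyme panels, criteria grid) ship as TSV fixtures; quantities the
source reports only graphically ship as labelled `*_synthetic.tsv`
stand-ins consistent with every reported classification. See
`docs/methods.md` for models, parameters and design decisions.

## Worked example

Run the full funnel on the packaged reference dataset:

```sh
$ probioscreen run --out report/
{
  "tool_version": "0.1.0",
  "seed": 42,
  "config_hash": "df435895f3f0458b",
  "mode": "fixtures",
  "stage_counts": {
    "isolates": 39,
    "stage1": 16,
    "stage2": 7,
    "stage3": 3
  },
  "final_selected": [
    "C27",
    "C10",
    "C28"
  ]
}
```

39 isolates collapse to 16 RAPD-distinct strains; quota scoring keeps 7
(C01, C27, C31, C32, C46, C10, C28); the larval safety and stress
comparisons exclude C32 (reduced survival) and C01, C31, C46 (reduced
stress survival), leaving *C. haemuloni* C27 and *D. hansenii* C10 and C28
as the candidate probiotics. `report/` receives the strain table, trait
panel, per-stage selection table with per-strain rule annotations, the
statistics JSON, the dendrogram (Newick) and a checksummed run manifest.

Other subcommands: `simulate` (synthetic bundle + ground truth),
`type-rapd` (lanes → clusters + dendrogram), `stats` (omnibus or
`--control` Dunnett on a long-format TSV), `select`, `validate`. The
library surface mirrors the pipeline: `rapd_typing.upgma`,
`trait_metrics.hydrophobicity_percent`, `selection_funnel.step2_select`,
`group_stats.dunnett_vs_control`, `synthetic_data.simulate_dataset`, ...

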