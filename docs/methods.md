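# Methods

## The analysis in brief

The package evaluates a diallelic SNP (osteopontin c.495C>T, genotypes
CC/CT/TT typed by PCR–RFLP) as a marker of resistance to subclinical
ketosis (SCK) in dairy cows. SCK is defined from blood β-hydroxybutyrate
(BHB): status 1 when BHB ≥ 1.0 mmol/L (inclusive), else 0. The analytic
chain is: contamination filtering → threshold classification → 2×3
contingency table (status × genotype, column order CT, CC, TT) →
direct-count frequencies → Pearson χ² with noncentral-χ² power →
Weight-of-Evidence scoring with category merging → ROC evaluation of a
genotype-derived score.

## In-silico PCR–RFLP model

The assay simulator is deliberately minimal: primers match exactly (no
mismatch or thermodynamic model — the assay uses a fixed validated primer
pair, so primer design is out of scope), and digestion is complete. MnlI is
modeled from catalogue values as recognition `CCTC` with cut offsets 7
(top strand) / 6 (bottom strand) downstream of the site's 3' end in the
site's own orientation. Only top-strand cut coordinates are used to compute
fragment lengths, because gel electrophoresis reads out single-strand
lengths of double-stranded fragments; for a site found on the bottom strand
(a `GAGG` occurrence top-strand) the cut coordinate therefore runs leftward
(`i − 7`). Cut positions at or outside the amplicon ends are discarded.
Coordinates are 0-based half-open. Genotype calling compares distinct band
lengths (co-migrating fragments collapse into one band) with a configurable
gel tolerance in bp, default 0 for in-silico bands: a homozygote matches one
allele's ladder, a heterozygote the union of both; anything else is
uncallable rather than guessed.

Fragment sizes are always *predicted from sequence*, never hard-coded: the
assay's real amplicon coordinates are not published, so the packaged test
substrate is a synthetic reference (labelled synthetic in code and output)
in which the two allele templates differ at exactly one position and the T
allele completes a `CCTC` site. Which real allele gains the site is
unknown; the allele→ladder mapping is an input everywhere.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the analysis
assumes; its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_animals` | 979 | initial test-day records |
| `allele_freq_C` | 1305/1954 ≈ 0.668 | gene-counting estimate from the observed genotype counts |
| `penetrance` | CC 25/410, CT 23/485, TT 1/82 | P(SCK \| genotype), the observed per-genotype case fractions |
| `bhb_healthy_mean`, `bhb_healthy_sd` | 0.47, 0.24 mmol/L | healthy BHB moments (first-lactation values) |
| `bhb_sck_min` | 1.0 mmol/L | diagnostic threshold; SCK BHB starts here |
| `bhb_sck_scale` | 0.4 mmol/L | scale of the exponential excess above threshold |
| `contamination_rate` | 2/979 | i.i.d. probability a record's ketosis test is void |
| `lactation_weights` | 326:291:197:87:50:28 | group sizes of lactations 1–5 and ≥6 |

Genotypes are i.i.d. Hardy–Weinberg (p², 2pq, q²). Disease status is
Bernoulli per animal with the genotype's penetrance. BHB is a two-component
mixture chosen so labels and measurements are coherent with the threshold
*by construction*: healthy animals draw from a normal truncated to
(0, threshold), SCK animals from threshold + Exponential(scale). The
distributional form of BHB is a modeling choice of this package — only
means/SDs of the real cohort are known — so the mixture should be read as a
test harness for the thresholding stage, not as a claim about BHB biology.
One anomalous reported lactation-5 BHB summary (13.22 ± 92.87 mmol/L) is
treated as a data artifact and not emulated; all lactation groups reuse the
first-lactation moments. Milk covariates are normals (SCC log-normal,
moment-matched) with first-lactation moments; they are carried through the
schema but play no role in the association chain. Contaminated records lose
their BHB value, which is what makes them unanalyzable downstream.

A single integer seed drives everything; per-stage substreams are spawned
deterministically (`SeedSequence.spawn`), so a fixed seed yields a
bit-identical cohort CSV. What the generator does **not** emulate: repeated
test-days per cow, herd/pedigree structure, genotype–covariate correlation,
genotyping error. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and its behavior under the assumed sampling model,
not robustness to those real-data features.

## Statistical choices

**Frequencies** are direct counts (genotype: column total / N; allele: gene
counting). The pipeline computes the gene-counting allele frequency
(C ≈ 0.668 on the packaged counts) and reports the externally published
rounded 0.71 as a *consistency warning*: the two are incompatible given the
genotype counts, and the package does not pick a winner.

**Test and power.** The association test is the Pearson χ² test of
independence on the 2×3 table, no continuity correction, df = 2 (the
canonical choice for this design; the source analysis does not name its
test). Effect size is Cohen's w = √(χ²/N); power is
P(X > χ²₀.₉₅,₂) for X ~ noncentral χ²(2, N·w²), which reduces to α at
w = 0. Degenerate margins raise rather than returning NaN.

**Weight of Evidence.** Goods = healthy (status 0), bads = SCK (status 1);
this orientation makes higher WoE mean higher probability of health, which
matches the resistance reading of the TT genotype given the counts. The
×100 scale is kept. Zero cells: default policy adds 0.5 to both cells of
the affected category only (denominators stay at the raw margins) and warns;
an `error` policy is available. The packaged counts contain no zero cell,
so the default never alters the headline analysis. The balance identity
Σ(relfreq_goods − relfreq_bads) = 0 holds exactly for tables without zero
cells (continuity correction perturbs it by design). Merging is greedy
nearest-pair on |ΔWoE| with a configurable gap (default 30 WoE units, which
pools CC with CT on the packaged counts and leaves TT separate, the pooled
WoE recomputed from pooled counts); ties break toward the leftmost pair in
CT, CC, TT order. Pooled WoE always lies between the members' WoE values
(mediant inequality).

**ROC.** Standard definitions: sensitivity = TP/P, specificity = TN/N for
the rule score ≥ threshold ⇒ positive, one point per distinct score, plus
the sweep endpoints (sens 0/spec 1 and sens 1/spec 0). The published verbal
definitions of sensitivity and specificity for this analysis are mutually
contradictory as printed and cannot be implemented; an orientation flag
(`positive = "resistant" | "sck"`) covers both readings. AUC is trapezoidal
over (1−specificity, sensitivity) and equals Mann–Whitney concordance with
ties counted half. The optimal cutoff minimizes the Euclidean distance to
the (0, 1) corner; exact ties prefer higher sensitivity, then higher
threshold. Score modes: `binary_TT` (indicator), `woe_score` (category
WoE), `probability` = σ(logit(base rate) + WoE/100) — the cohort prevalence
of the positive class updated by the WoE as a log-likelihood ratio; the
baseline is echoed in output metadata. `woe_score` and `probability` are
strictly monotone transforms of each other and give identical AUC;
`binary_TT` collapses CT and CC to one level, so its AUC generally differs
and instead satisfies the one-vertex identity AUC = (sens + spec)/2. A
previously reported probability cutoff of 0.758 for this marker comes from
an unreported underlying model and is not derivable from the published
counts; the package reports its own cutoff on its own probability scale and
makes no comparison.

## Numerical and testing choices

- Tolerances: WoE and IV are checked against hand arithmetic at 1e-9; AUC
  against the O(n²) concordance oracle at 1e-12; χ² against the Σ(O−E)²/E
  oracle at 1e-10.
- The Monte-Carlo check of the noncentral-χ² power routine (w = 0.3,
  n = 100, α = 0.05, 50 000 replicates) uses an alternative with a
  case-control-skewed outcome margin (0.8/0.2; genotype margin
  0.5/0.3/0.2). Finite-sample multinomial power is alternative-specific:
  this shape — the most disease-skewed feasible at w = 0.3, chosen to
  resemble the case-control imbalance of the application (whose own
  0.95/0.05 margin admits no w = 0.3 alternative of this form) — agrees
  with the asymptotic noncentral value to ~0.002, which is what the
  approximation's n·w² noncentrality is meant to summarize.
- Parameter-recovery testing runs 100 seeded replicates at n = 50 000:
  each replicate must recover all three penetrances within 3 binomial
  standard errors and rank TT highest by WoE; ≥ 99/100 must succeed. These
  problem sizes keep the whole suite around ten seconds while leaving
  Monte-Carlo error well below every tolerance used.
- Determinism: the full pipeline is byte-identical under a fixed seed
  (report JSON compared as bytes in tests); the packaged counts path is
  randomness-free.

## Known limitations

- Single-locus, single-test design: no multiple-testing correction (none is
  needed), no kinship/pedigree correction, no covariate adjustment — the
  χ²/WoE analysis treats animals as exchangeable.
- The ROC of a three-level (or binary) genotype score is necessarily coarse;
  AUC near 0.56 on the packaged counts reflects the marker's modest
  marginal discrimination, and the "optimal cutoff" on such a curve has few
  candidate points.
- WoE on three categories with a rare genotype (TT bads = 1) has high
  sampling variance in the rare cell; the continuity policy exists for
  simulated tables where that cell is empty.
- The in-silico assay ignores partial digestion, star activity, and gel
  mobility artifacts; `tolerance` crudely stands in for gel resolution.
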