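# Methods

## Pipeline model and assumptions

The screen treats protein–protein interaction potential as a property of
domain content: protein P is a putative interactor of the query protein Q if
P carries at least one Pfam domain known (from structural evidence) to
contact one of Q's domains. This is deliberately qualitative — no binding
affinity, expression level, abundance weighting or cellular accessibility
enters the screen. The virtual metaproteome construction likewise assumes
that a genus observed in a community profile contributes all database
proteins of that genus, which over-counts (not every species/strain is
present) and under-counts (unannotated organisms are invisible) in ways the
screen cannot resolve. Results are therefore a *microbial signature* for
comparison between groups, not an inventory.

Concrete contracts:

* Genus matching is case-insensitive exact string equality. Profile entries
  without an unambiguous genus have no match and silently contribute
  nothing, mirroring the exclusion of sequence clusters that cannot be
  assigned below higher ranks.
* A protein is retained once regardless of how many partner domains (or
  copies) it carries; occurrence counts O(d,c) likewise count carrier
  proteins, not domain copies.
* Venn partitioning uses accession identity. Proteins of a genus shared by
  two groups are the *same records* in both proteomes, which is exactly how
  cross-group overlap arises.
* Relative abundances are parsed and carried on the taxa profile but do not
  weight any downstream statistic (a deliberate hook for future work).

## Occurrence statistics

The chance model is E(d,c) = f(d)·N(c): expected carriers scale linearly
with proteome size at a domain-specific background rate. The published
expected values this package ships as reference data are proportional to the
group proteome sizes across every row (max deviation 1.2 %, recomputed by
`scripts/acceptance.py`), which is what motivated this form.

* `background_mode: pooled` (default) estimates f(d) = Σ_c O(d,c) / Σ_c N(c).
  The row test then reduces to the classical chi-squared homogeneity test on
  carrier counts, and df = k−1 is the appropriate convention.
* `background_mode: external` reads rates (or carrier/corpus counts) from a
  file, emulating a whole-database reference corpus; expectations are then
  externally fixed and `df_mode: k` is available. The two anchor reference
  rows used in the acceptance tests classify identically under either df
  convention.

The Pearson statistic sums over the k carrier cells only (not the
complementary non-carrier cells); at the carriage rates relevant here
(f ≪ 1) this differs from the full 2×k homogeneity statistic by a factor
≈ (1−f) and the null calibration measured by the acceptance suite is
indistinguishable from nominal.

Classification thresholds (all config keys, defaults in parentheses):
`alpha_sig` (0.01) for `significant`, `ns_threshold` (0.5) for
`not_significant`, p in between → `intermediate`; rows with zero carriers
everywhere are `absent`; rows with fewer than `near_zero_min` (10) total
carriers are `near_zero` and excluded from testing — the source screen
excluded a handful of domains "with a frequency close to zero" without
stating a cutoff, so the cutoff is explicit configuration here, not a
constant. One reference row (PF13405, O = 60/56/58 vs E = 55/50/49) falls in
the intermediate band (p ≈ 0.24) and is reported as computed rather than
forced into the significant/not-significant dichotomy of the source table's
caption. No multiple-testing correction is applied across domain rows (the
reference table reports raw chi-squared classes); Yates correction is not
used (k > 2 one-dimensional fit).

## GO enrichment

"Classic" term-by-term Fisher on true-path-propagated annotations:

* Propagation closes each protein's direct annotation set under `is_a`
  ancestry. Annotations to unknown or obsolete terms are skipped with a
  warning (configurable to an error). Other relation types (`part_of`, ...)
  are not propagated.
* Universe: the group's virtual proteome restricted to proteins with ≥ 1
  propagated annotation in the namespace under test (the standard choice;
  configurable to the screened set itself). Study: screened interactors in
  that universe.
* One-sided enrichment only: p = P(X ≥ observed) for X hypergeometric.
  Depletion is out of scope.
* BH adjustment within each namespace independently. Because the source
  conventions conflict (workflow text: q ≤ 0.01; table caption: p < 0.01),
  both flags are emitted per row (`sig_q`, `sig_p`) and neither is silently
  preferred; `q_max` and `alpha_sig` control them.
* DAG-decorrelating algorithms (topGO's weight/elim) are not implemented;
  this is a documented divergence — parent terms of a genuinely enriched
  leaf will often co-appear as enriched.

## Synthetic data generator

`SimulationConfig` defaults encode the study conditions the pipeline
targets: three groups (CT/CD/UC) with 15 genera shared by all three and
13/9/8 group-specific genera; a 50-domain catalogue at uniform carriage rate
f = 0.01 of which the first 20 form the partner set (giving a realistic
~18 % interactor fraction); 50 proteins per genus by default (tests and the
acceptance script scale this up to ~10,000 proteins per group where the
statistical checks require it, and down where they don't); a ~30-term GO DAG
with one root per namespace, ≤ 2 parents per term, 3 leaf annotations per
protein drawn uniformly and closed upward so fixtures are true-path
consistent by construction.

Domain assignment is independent Bernoulli per catalogue domain (multi-domain
proteins arise naturally; ~5 % of present domains are duplicated to exercise
multiset handling). Because shared-genus proteins are identical records in
every group that carries the genus, a per-(domain, group) rate effect is
applied to the proteins of genera *exclusive* to that group; the truth
record stores the resulting effective per-group rates, e.g. a 3× effect in
CT dilutes to ≈ 1.93× at the default 15-shared/13-exclusive layout. Planted
GO enrichments follow the same rule: a dedicated molecular-function leaf is
annotated at `planted_go_base_rate` (0.05) everywhere and at `factor` times
that on the target group's exclusive interactors.

The truth record contains the *empirical* per-group carrier counts and
planted-term contingency counts actually sampled, not just the parameters,
so recovery tests compare pipeline output against generator bookkeeping
exactly. Infeasible configurations (rate × factor outside [0, 1]) fail
before any file is written; identical seeds produce byte-identical files.

What the generator does **not** emulate: read-level 16S noise, abundance
dynamics, phylogenetic correlation between genera, realistic domain
co-occurrence structure, GO annotation bias. Passing tests demonstrate the
statistical machinery is correct under the stated sampling model, not that
real-database results are insensitive to annotation quality.

## Numerical and design choices

* Null calibration of the chi-squared classifier is checked on groups with
  *disjoint* genus sets (3 × 10,000 proteins, 50 domains, 20 seeds): the
  homogeneity test assumes independent groups, and shared-genus proteins
  contribute identical counts to every group, deflating the statistic. With
  the overlapping default layout the test is conservative by construction —
  a property of virtual-proteome overlap worth knowing when interpreting
  real runs, and a documented limitation, not a defect of the test.
* Monte-Carlo validation of the chi-squared tail conditions on the row total
  (multinomial null, 100,000 draws) at expected counts of 200–1000 per cell,
  where the asymptotic approximation should hold to within the Monte-Carlo
  resolution (3 standard errors).
* Fisher tails are validated against exact integer enumeration
  (`math.comb`) over *all* 2×2 tables with margins ≤ 25.
* hmmscan hits are retained at independent e-value ≤ 0.01 by default
  (`evalue_max`), a common Pfam working threshold; the source workflow
  states none.
* Domain identity is the Pfam accession with version suffixes stripped;
  names are carried as labels only.
* The interaction map is always a file input (packaged S100B table as the
  default); no live database download.
* All writers sort lexicographically; reruns are byte-identical except the
  manifest timestamp, which is isolated to one line.
* Degenerate inputs: empty taxa profiles yield empty-but-valid tables
  throughout; empty study sets yield empty enrichment with a warning; a
  zero-size group makes its expectation column zero and the affected rows
  are excluded from testing rather than crashing.

## Known limitations

* Presence-based screening ignores copy number and abundance entirely.
* The pooled background couples f(d) to the groups under comparison; with
  strong effects in a large group the pooled rate shifts and direction
  profiles are relative to that pooled baseline.
* Classic Fisher on a propagated DAG produces correlated term p-values up
  each lineage.
* Genus-level taxonomy is the resolution floor: strain/species differences
  within a genus are invisible.
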