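# Methods

## Sequence-based function prediction

### Input model

The unit of analysis is a labelled, aligned amino-acid matrix: equal-length
rows over the 20 standard residues, the gap symbol `-`, and `X` for missing
or ambiguous data (all non-standard letters — B, Z, J, U, O — are folded
into `X` on read, with a logged count, so downstream code has a single
missing-data symbol).  Each sequence carries a functional label
(`activator`, `repressor`, `neutral`, `unknown`) reflecting experimental
evidence on flowering time, and a clade (`FT`, `TFL1`, `MFT`, `unknown`).
Function prediction always operates within one clade: comparing across
clades would pick up positions reflecting evolutionary history rather than
function.  Unknown-function sequences are the queries; they never
contribute to consensus sequences, prevalence profiles, or calibration.

### Conserved-block curation

`curate_alignment` is a simplified conserved-block selector in the style of
the classic curation tools.  Each column is classified by the count of its
most frequent non-gap residue: *flank-grade* at ≥ `min_flank_frac` (default
0.85) of sequences, *conserved* at more than half (`floor(n/2)+1`
sequences, or a user fraction in (0.5, 1]), else *nonconserved*.  With
`allow_gaps=False` any gapped column is nonconserved.  Runs of more than
`max_nonconserved_run` (default 8) nonconserved columns are removed; the
surviving stretches are trimmed so they start and end at flank-grade
columns; blocks shorter than `min_block_len` (default 10) are dropped.
Because every kept block begins and ends flank-grade and contains no
over-long nonconserved run, a second pass keeps everything — the procedure
is idempotent in a single pass (property-tested).  Ties for the most
frequent residue cannot change a column's class, since only the count
matters.  An identity ("skip") mode wraps externally curated alignments,
because exact reproduction of a published column set depends on external
tool versions; the kept-column map (curated index → original index) is
always recorded so positions can be reported in original coordinates.

### Consensus sequences and unique positions

A group consensus takes, per column, the symbol held by a strict majority
(> 50%, configurable) of the group's non-missing cells, gap counted as an
ordinary symbol; otherwise the column gets the no-consensus mark `.`.
A position is *unique* to a group when its consensus residue is a standard
amino acid that equals no other group's consensus residue at that column.
A gap or `.` in another group does **not** block uniqueness — "the residue
does not occur in that consensus" — but since a majority-free column may
still contain the residue in a minority of members, the stricter reading is
available as `no_consensus_blocks=True`.  Match fractions count the query's
exact matches over all unique positions; query `X` cells stay in the
denominator and never match, which makes the fraction conservative in the
presence of missing data.

### Prevalence-ratio scoring

For a direction (activator or repressor) within a clade, the in-group is
the confirmed proteins with that function and the out-group the confirmed
proteins without it (the two complementary labels); unknown-function
sequences join neither.  A profile stores, per column, the relative
frequency of every symbol among group members; `X` cells are excluded from
the denominator, gap is a scored 21st symbol (curation "allowing gaps"
retains gapped columns that can be group-diagnostic), and unobserved
residues have prevalence exactly 0 — no pseudocounts, since the score is
defined on raw prevalence.  A query's score under a profile is the mean
prevalence of its residues over scorable columns (query non-missing, both
profiles non-empty; both scores use the same column set so the ratio is
well defined).  The ratio in-score/out-score exceeds 1 when the query's
residues are systematically more typical of the in-group.

Leave-one-out is on by default: a sequence of known function is removed
from any profile it is scored against before scoring.  Self-inclusion
inflates in-scores noticeably for small groups (a member of a 3-sequence
group contributes 1/3 of every column's counts); a flag restores
self-inclusion for exact-reproduction attempts against published scores.

The cut-off is calibrated on the labelled ratios: the smallest multiple of
the granularity (default 0.01, matching two-decimal reporting) strictly
greater than every non-member ratio.  With the inclusive decision rule
(ratio ≥ cutoff → member) this yields zero false member calls and, under
that constraint, the fewest false non-member calls; the inclusive boundary
means a cut-off of 0.98 calls a 0.98-ratio sequence a member.  If every
member ratio lies below every non-member ratio calibration fails loudly
(`CalibrationImpossibleError`) rather than returning a useless threshold.

`FunctionScoreModel.fit()` bundles the procedure: leave-one-out ratios for
every confirmed-function sequence, class means, a two-sided gated
two-sample test of the class difference, the calibrated cut-off, and query
classification via the returned results object.

### Y/H diagnostic

The single-residue diagnostic walks the reference row counting non-gap
residues to locate the alignment column of reference position *n*
(Arabidopsis FT 85 / TFL1 88), then reports the query symbol there:
Y → activator-like, H → repressor-like, anything else (including gap)
→ other.  The mapping depends only on the reference row, so adding or
removing other sequences, or inserting gap-only columns, cannot change the
reported residue.  If the caller states the expected reference residue and
the reference disagrees, the report is flagged invalid instead of guessing.

## qPCR expression

Mean normalized expression of a target against a reference gene in one
sample is `E_ref^mean(Ct_ref) / E_target^mean(Ct_target)`, with technical
replicates averaged on the Ct scale (MNE is defined on mean Ct) and
amplification efficiencies in fold per cycle, default 2.0 for all genes
(no efficiencies are assumed known; perfect doubling is the conventional
default).  MNEs of biological replicates are averaged per group into the
average relative expression with SE = sd/√n; a single replicate reports
SE 0 with a warning rather than an error, because some designs (pooled
early-timepoint samples) legitimately have few replicates.  Candidate
reference genes are ranked by the mean SE of the expression values computed
against them, ascending, ties broken alphabetically; a flag-free Ct-scale
variant was considered and rejected since the ranking should reflect the
quantity actually reported (expression values).

Two-group comparisons follow a test-selection gate: Shapiro-Wilk normality
on each group and median-centred Levene equal-variance, both at α = 0.05
(the checks themselves are conventional choices; groups smaller than 3 or
constant fail the gate).  If all pass, a pooled-variance two-sample t-test
in the stated direction; otherwise the Mann-Whitney U test.  The direction
is a required analysis input for one-tailed use; `None` gives a two-sided
test, under which identical groups return p = 1 on either path.

## Phenology

Phase lengths per plant: ♂1 = day of male bud, ♂2 = first pollen − male
bud, ♀ = first elongated pistil, dichogamy = ♀ − first pollen (negative
when the pistil precedes pollen).  By construction ♂1 + ♂2 + dichogamy = ♀
for every record.  Days are integers (daily inspection), so ties are
expected and midranks are mandatory.

The Mann-Whitney U statistic is computed from rank sums with midranks.  The
p-value is exact (full enumeration of the null U distribution) when both
groups have ≤ 8 observations and no ties — the limit balances fidelity and
runtime — and otherwise uses the normal approximation with tie correction
and continuity correction.  Tests are two-sided by default; one-sided is a
flag.  All-identical pooled data short-circuits to p = 1 (degenerate).

Significance codes apply Bonferroni correction to the per-comparison α:
the strongest of `*`/`**`/`***` with p < α/m for α ∈ {0.05, 0.01, 0.001},
else `ns`; the code is monotone in m.

Dominance of an F1 trait is decided from gated tests against both parents:
"equal to a parent" = ns after gating, "different" = any gated rejection.
Equal to the early parent and different from the late → dominant-early
(symmetrically dominant-late); different from both with the F1 mean between
the parents → additive; different from both with the F1 mean at or beyond
the early (late) parent → overdominant-early (-late); anything else —
notably equal to both parents — is inconclusive.  The decision table is a
formalization of narrative usage ("equally short as the invasive parent");
the mapping from failing-to-reject to "equal" is explicit and gated, not a
claim of demonstrated equivalence.

Reproductive output compares exactly two populations: mean fruit count,
mean individual fruit weight (total weight / count per plant, averaged),
percent reduction `100·(1 − mean_other/mean_reference)` with the reference
defaulting to the native population, and gated comparisons at m = 17.
A record with zero fruits but positive fruit weight is an input error.

## Synthetic-data generators

All generators are pure functions of their parameter object, which includes
the seed; identical parameters give identical output.

**Protein family.**  Defaults: three groups (activator/repressor/neutral) ×
15 members, length 130 — the scale of a curated PEBP family alignment — 12
signal columns per group (disjoint), signal fidelity 0.9, uniform
background over the 20 residues (an empirical distribution can be
supplied), gap rate 0.02 and `X` rate 0.01 as mild, realistic missingness.
Members draw background residues everywhere, then carry their group's
residue at each of its signal columns with probability = fidelity; gaps and
`X` are sprinkled last.  The planted truth (signal columns and residues) is
returned for recovery tests.  Because the background is uniform rather than
conserved, these alignments would be emptied by conserved-block curation;
synthetic families are therefore analysed uncurated (identity curation),
which exercises the same scoring machinery.  What this generator does *not*
emulate: phylogenetic correlation between sequences, realistic residue
composition, and the narrow ratio scale of real homologous families —
passing recovery tests shows the statistics behave as designed, not that
real families separate this widely.

**Ct tables.**  `Ct = base_ct − log_E(expression) + biological noise +
technical noise`, with biological noise drawn once per sample and gene (so
the target's noise is shared across the MNEs computed against different
references, as in a real plate) and technical noise per replicate.
Defaults follow a typical two-population qPCR design: two groups, 4 biological × 3 technical
replicates, efficiency 2.0, a 4-fold target induction, reference genes at
constant true expression with per-gene biological sds (TUA 0.35, TUB 0.12,
GAPDH 0.55 cycles; target 0.30, technical 0.15) — chosen so the stability
ranking has a planted winner while variability stays in the realistic
sub-cycle range.  At 4 biological replicates the SE estimates are noisy, so
the ranking's planted winner is only reliably recovered when the noise
separation is large; the recovery test states such a configuration
explicitly.

**Phenology cohorts.**  Event days are built additively from rounded normal
draws: male bud ~ N(♂1), pollen = bud + N(♂2) (clipped at ≥ 0 so pollen
never precedes the bud), pistil = pollen + N(dichogamy).  Rounding to whole
days reproduces the tie structure of daily scoring.  Defaults are the phase means reported for native and invasive
common-ragweed populations and their F1 (native 66.8/12.9/2.2 d, invasive
34.8/11.7/6.2 d, F1 34.3/9.3/1.6 d, with cohort sizes 20/36/111); the sds
are not printed and are set to realistic spreads of 6/3/2 d.  Note that the
reported native female-phase mean (77.5 d) is not the sum of the reported
components (81.9 d) — real cohorts have per-metric exclusions — so under
strict per-plant additivity the generator reproduces the three component
means and implies the female mean, which is what the recovery tests check.
Fruit counts are negative binomial (mean 381/91, dispersion 5 —
overdispersed counts), per-plant mean fruit weight truncated normal
(5.5/6.3 ± 1 mg).

## Numerical choices and problem sizes

- Cut-off grid arithmetic uses integer steps with a 1e-9 guard against
  floating-point drift, so a non-member ratio exactly on a grid point maps
  to the next grid value up.
- Ratio and score values are exact rational arithmetic in floating point
  (sums of counts/denominators); report files round to 6 decimals, and the
  round-trip tests assert at that precision.
- Column thresholds in curation use `ceil(frac·n − 1e-9)` so that e.g.
  0.85 × 20 = 17 exactly rather than 18.
- Simulation-backed checks use 20 seeds for classification accuracy and
  dominance recovery, 5 seeds for noiseless unique-position recovery and
  the signal-free null (the latter averaged across seeds so Monte-Carlo
  noise is small against its 0.02 band), 50 random sets for calibration
  against grid search, and 2,000 null simulations at n = 30 per group for
  the Mann-Whitney type-I rate — at that size the discrete U distribution
  is fine enough for the asymptotic path's size to sit at the nominal 5%,
  and it matches realistic cohort sizes.

## Known limitations

- The curator is a simplified block selector; it is not a bit-exact
  reimplementation of any published tool, and reproducing a specific
  published column count requires supplying that alignment via skip mode.
- Prevalence profiles need ≥ 2 members per group; clades with a single
  confirmed member of some function cannot be scored in that direction.
- The activator/repressor ratio assumes the out-group is non-degenerate;
  a query sharing no residue with the out-group raises rather than
  returning an infinite ratio.
- Amplification efficiencies are user inputs; the package does not estimate
  them from dilution series.
- Exact Mann-Whitney enumeration is limited to untied samples of ≤ 8 per
  group; beyond that the corrected normal approximation is used.
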