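# Methods

## The separation statistic

At one CpG site, let the two groups' methylation fractions have empirical
percentiles $Y_M^{(p)}$ and $Y_F^{(p)}$, computed as **nearest-rank order
statistics**: $Y^{(0)}$ is the minimum, and for $p > 0$, $Y^{(p)}$ is the
element at 1-based rank $\lceil p\,n/100 \rceil$ of the sorted sample.
Every percentile is therefore an observed value; no interpolation or
smoothing is involved, which keeps the statistic purely rank-based.

For each integer percentile $p$ in the grid $\{50, \dots, 100\}$, two
cross-tail inequalities are tested with **strict** comparisons (ties never
count as separation):

- $F>M$ branch: $Y_M^{(p)} < Y_F^{(100-p)}$ — the upper tail of M below
  the lower tail of F;
- $M>F$ branch: $Y_M^{(100-p)} > Y_F^{(p)}$.

Each directional statistic is the largest qualifying $p$, floored at 50
when no grid point qualifies, and $S$ is the larger of the two. The
direction label comes from the selector count
$\sum_{p=0}^{100} \mathbb{1}(Y_M^{(p)} < Y_F^{(100-p)})$: because the
indicator is monotone in $p$, the count is (for tie-free data) exactly one
more than the largest qualifying $p$ of the $F>M$ branch, so a count of at
most 50 labels the site $M>F$ and a larger count $F>M$. Defining $S$ as
the maximum of both branches, rather than letting the selector pick which
single branch to evaluate, is what guarantees the advertised range
$50 \le S \le 100$ for every input: under complete $M>F$ separation the
$F>M$ branch alone would sit below 50.

Consequences verified by property tests: $S$ is invariant under strictly
increasing transforms of the pooled data; swapping the group labels
preserves $S$ and flips the direction (exactly so for tie-free pooled
values — with ties the selector count is not complemented, so the
symmetry is only asserted on tie-free draws); $S = 100$ iff the supports
are disjoint; raising every value of one group by a constant can only
increase that group's directional statistic.

## Permutation inference

Under the sharp null hypothesis — group labels have no effect on any
sample's value — labels are exchangeable, and the randomization
distribution of $S$ is obtained by relabeling. The Monte-Carlo engine
draws `n_perm` uniform reassignments of the pooled sample into groups of
the observed sizes (simple shuffles, duplicates permitted; default
100,000) and computes $S$ for each with a single vectorized kernel. The
Fisherian p-value counts permuted statistics **as large or larger** than
the observed one. Two conventions:

- `add_one` (default): $(1 + k)/(B + 1)$, which treats the observed
  labeling as one more draw from the null; the p-value is never 0, the
  resolution floor is $1/(B+1)$, and the test is exactly valid.
- `plain`: $k/B$, the literal proportion, for literal replication of a
  proportion-based analysis; it can return 0.

For $\binom{n_m+n_f}{n_m}$ small, `exact_enumeration_test` enumerates
every distinct assignment and returns the exact randomization p-value;
the suite uses it as the oracle for the Monte-Carlo path. Exchangeability
is assumed across **all** samples: paired designs (e.g. twins) are not
modeled, matching the screening stance of permuting labels freely.

## Screening

`screen` applies the test to every probe of a beta-value matrix. Missing
values are dropped per site and group; a site with fewer than 2
non-missing values in either group is skipped with a recorded reason, so
probes read = records + skips always. By default one set of label
shuffles is shared across all complete-data probes (reproducible, fast,
and identical data then get identical p-values); probes with missing
values draw a deterministic per-probe sequence derived from the same
seed, and `share_permutations=False` gives every probe its own sequence.

Candidates satisfy $S \ge$ `s_min` (default 80) and $p <$ `p_max`
(default $10^{-5}$, reachable only with $\ge 10^5$ permutations under
`add_one`). No multiple-testing adjustment is applied: the screen is a
Fisherian fixed-threshold filter and emits raw p-values only; users
wanting FDR control can apply it downstream to the results table.
Covariates in the sample sheet (age, …) are carried through untouched for
external balance checks; the test never adjusts for them.

## Synthetic data

The generator emulates the structure the screen assumes: per-site
beta-distributed methylation for two groups. Site means are drawn from a
three-component mixture mimicking hypo-, hemi- and hyper-methylated
probes (weights 0.4/0.2/0.4, mean ranges 0.05–0.25, 0.40–0.60,
0.75–0.95), with per-site concentration $\nu = \alpha + \beta$ uniform on
[20, 80]; alternatively one fixed Beta$(\alpha,\beta)$ for every site.
Defaults use 385 samples per group, the balanced adult-cohort regime;
small unbalanced designs (15 vs 2) are equally valid inputs. A planted
effect shifts the elevated group's Beta **mean on the logit scale** by
`delta`, keeping $\nu$ fixed, so values never leave $[0,1]$ and the
effect resembles a methylation-scale shift. `delta` of about 1 is a
subtle shift, 3 a strong one, and 8 pushes the groups' sampled supports
apart at desk-scale sample sizes.

What the generator does **not** emulate: twin/family correlation,
cell-type composition, batch and probe-chemistry artifacts, or spatial
correlation along the genome. Passing tests therefore demonstrate
correctness and calibration of the statistic and its test under
independent beta-distributed data — not robustness to those real-data
features.

## Numerical and design choices

- The complement "$1-p$" of the percentile index is interpreted as
  $100-p$ on the percent scale, the only reading consistent with summing
  $p$ from 0 to 100.
- The quantile estimator is nearest-rank; smoothed estimators would break
  the always-an-observed-value property and are out of scope.
- Values are accepted as fractions [0,1] or percent [0,100]; `auto` unit
  detection treats any value above 1 as evidence of the percent scale,
  decided on the pooled values. Internally everything is a fraction.
- $S$ is integer-valued, so its null distribution is discrete, and
  attainable test levels are a coarse set that coarsens as groups grow:
  at 50 per group the attainable level nearest 0.05 is ≈ 0.045, while at
  385 per group the levels jump from ≈ 0.084 to ≈ 0.03. Calibration
  checks in the suite therefore use 50 per group, where the discreteness
  gap around conventional levels is small.
- Desk-scale problem sizes in the suite: 999 permutations (resolution
  floor $10^{-3}$) instead of 100,000, 500-site null calibration, and
  enumeration oracles at $n \le 6$ per group. These sizes keep the full
  validation cheap while exercising every code path; the defaults of the
  library remain the full-scale settings.
- Tie-break: when both directional statistics are equal (e.g. identical
  groups), $S$ is their common value and the direction label still comes
  from the selector count, which then defaults to $M>F$ for symmetric
  data. The label is meaningless at $S = 50$ and reported only for
  schema stability.

## Known limitations

- Power at the full thresholds requires $\ge 10^5$ permutations per site;
  the vectorized kernel handles this but a 450K-scale matrix at 100,000
  permutations is an overnight, not interactive, run on one core.
- The statistic's coarse discreteness at large $n$ (above) limits fine
  p-value resolution near conventional levels regardless of the number
  of permutations.
- No covariate adjustment, paired-design support, or FDR control by
  design; see the screening section.
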