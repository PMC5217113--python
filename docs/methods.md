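# Methods

`shscreen` analyzes pooled shRNA screens read out by amplicon sequencing,
with an in-vivo mouse-testis spermatogenesis screen as the motivating design:
a library of hairpin constructs (3–5 per gene, with positive-control,
negative-control and test genes) is transfected at low efficiency into a
large cell population, selection acts on each knockdown lineage, and
construct abundances before and after selection are compared by sequencing.

## Quantification model

**Counting.** A read is assigned to a construct iff the construct's declared
"unique half" hairpin sequence occurs verbatim in the read, on either strand.
There is no mismatch tolerance: amplicon reads cover the construct sequence
directly, and the manifest validator rejects any pool in which one unique
sequence equals, reverse-complements, or contains another (which would make
exact-substring assignment ambiguous).  Reads matching zero constructs are
tallied as unmapped; reads matching two or more are discarded and tallied as
multimapped — with a collision-free manifest this is a QC signal, not a
quantity worth apportioning.  Paired-end mates are mapped independently; the
package reports their count concordance and uses R1 by default.

**Aggregation and normalization.** The count of a biological sample is the
median over its technical sequencing libraries (robust to PCR jackpotting in
any one library; even counts use the mean-of-middle-two convention).  Counts
are scaled to reads per million (RPM).  The log2 fold change of construct
*c* in replicate *j* is

    lfc_cj = log2( RPM_sample(c) / RPM_input(c) )

with a pseudocount of 0.5 (configurable) added to every count — sample and
reference alike, folded into the library total — before scaling, so fold
changes stay finite at zero counts with minimal directional bias.  Each
experiment is normalized against its own sequenced input pool; fold-change
matrices from experiments sharing a pool design can then be merged
column-wise to accumulate biological replicates.

## Inference

**Per-construct test.** For each construct, its fold changes across
biological replicates (*m* values) are compared to the pooled fold changes
of all negative-control constructs across all replicates (*n* values) with a
Wilcoxon rank-sum test.  Pooling maximizes the null sample that a small
curated control set can provide; a negative-control construct under test is
excluded from its own null.  The p-value is exact (full enumeration of the
Mann–Whitney U null distribution via the standard counting recurrence) when
*m* + *n* ≤ 12 with no ties, otherwise a normal approximation with tie
correction and a 0.5 continuity correction.  The default is two-sided, with
the depleted/enriched direction taken from the sign of the construct median
minus the null median; exact ties are "neutral" and never count as depletion
hits.  No multiple-testing correction is applied by default — error control
comes from the fixed cutoff plus the two-hit rule, as is conventional for
small curated pools — but Benjamini–Hochberg across constructs is available
behind a config flag.

**Two-hit gene rule.** A gene is called essential iff at least `min_hits`
(default 2) of its constructs are significantly depleted (default α = 0.01).
Under low-MOI transfection, construct fold changes are independent under the
null, so a spurious pair costs roughly α² = 10⁻⁴; the package also exposes
the Binomial(k, α) tail P(X ≥ 2), which accounts for the number of
constructs per gene (≈ 9.8 × 10⁻⁴ at k = 5).  Enriched hits never
contribute to essentiality.

**Error rates.** With the control genes as labelled truth, the false
negative rate is the fraction of positive-control genes not called and the
false positive rate the fraction of negative-control genes called.  The
"negative" class includes both knockout-characterized-irrelevant genes and
never-characterized/non-expressed genes; the manifest declares classes
explicitly so any curation can be expressed.

## Design analyses

**Replicates.** `replicate_subsample_curve` draws random r-subsets of
replicate columns, reruns the tests, and records the smallest |median lfc|
among significantly depleted constructs — the minimum detectable effect at r
replicates — reported as median ± SD over draws (default 200; the single
full-size subset when r equals the replicate count).

**Coverage.** `coverage_power_curve` binomially thins every technical-
replicate table to a target mean reads/construct (keeping each read with
probability target/current — exactly uniform read subsampling), reruns the
whole pipeline, and reports the mean fraction of positive-control genes
recovered.  The input pool stays at full depth.  Thinning at the observed
coverage is the identity, so the curve endpoint with one draw equals the
plain analysis exactly.  No monotone smoothing is applied.

**Capacity.** `screen_capacity` is deterministic budget arithmetic:
cells transfected = total cells × efficiency; a minimum of *k* independently
transfected cells per construct caps the library at ⌊cells/k⌋ constructs.

## The synthetic screen generator

Each biological replicate is generated as:

1. transfected cells ~ Binomial(n_cells, efficiency); each transfected cell
   receives exactly one construct (strict low MOI), multinomially by the
   input-pool composition;
2. survival per construct ~ Binomial(n_c, clip(2^(s_c + ε), 0, 1)) with
   ε ~ N(0, bio_sd) per construct per replicate — s_c is the construct's
   log2 selection effect, the ground truth the pipeline tries to recover;
3. per technical replicate, each construct lineage gets a Gamma(shape,
   1/shape) amplification factor (mean 1; smaller shape = heavier PCR
   jackpotting), and reads are multinomial over the amplified mass with
   total = mean coverage × pool size.

The input pool is sequenced by a plain multinomial with no jackpot factor:
jackpotting models stochastic amplification of scarce genomic templates, and
the input pool is abundant plasmid DNA.  Selection acts once between
transfection and harvest; there is no stage structure within spermatogenesis.
All randomness flows from one master seed through named substreams, so any
screen is reproducible bit for bit.  `simulate_reads` can additionally
expand any count table into FASTQ (construct sequence at a random offset and
orientation inside fixed vector backbone, optional per-base substitution
errors), closing the loop through the exact-match counter.

Defaults emulate the pilot design: 1e8 cells, 2% transfection efficiency,
nine biological × three technical replicates, biological noise SD 0.3 log2
units, jackpot shape 2, coverage 3000 (5000 for the pilot-like preset).

**Preset designs.**  Three manifest/truth presets cover the validation
needs:

* *pilot-like* (119 constructs, 25 genes, 83 positive-class constructs):
  three positive genes are built "refractory" — exactly one effective
  construct — emulating noneffective RNAi, which is where a two-hit screen's
  false negatives come from; the other 14 positive genes carry ≥ 2 effective
  constructs with effects drawn uniformly in [−4, −1] log2 units.  The
  designed truth therefore makes 14 of 17 positives detectable at full
  depth, and the realized per-seed FNR fluctuates around that by a gene or
  so when borderline effects sit near the cutoff.
* *null* (45 constructs: 30 test over six 5-construct genes + 15 negative):
  every s_c = 0, used for type-I-error and two-hit calibration.
* *graded* (60 test + 15 negative constructs): test effects uniform on
  (−4, 0), so effects reach arbitrarily close to zero.  This is the design
  used for minimum-detectable-effect analyses: resolving "how weak an effect
  still clears significance" requires effects near the detection boundary,
  which a pool of only strong effects (the pilot preset's deliberate gap
  between 0 and −1) cannot provide — there the curve bottoms out at the
  weakest construct present and then jitters.

**What the generator does not emulate** — and hence what passing tests do
not establish about real screens: off-target knockdown (every construct's
effect is its target gene's), cell-type composition of the tissue and
stage-specific selection, index hopping or cross-library contamination,
input-pool composition drift between experiments, and overdispersion beyond
the single-gamma jackpot mechanism.  Error-rate and power numbers from
simulation characterize the statistical machinery under the stated noise
model, not the assay chemistry.

## Numerical choices

* Pseudocount 0.5, symmetric; configurable (0 allowed, with a warning, for
  pools with no zero counts).
* Exact rank-sum enumeration limit m + n ≤ 12; beyond it the tie- and
  continuity-corrected normal approximation (validated against enumeration
  and against an independent implementation in the tests).
* Two-sided p = 2·min(P≤, P≥), clamped to [0, 1].
* Depletion direction requires a strict median difference; exact ties are
  neutral.
* Subsample and thinning draws derive per-draw seeds from the master seed
  via fixed substream offsets; curves are reproducible bit for bit given
  (seed, n_draws).
* In monotonicity checks of the replicate curve, the subsampled entries
  (r < R, medians over ≥ 200 draws) are compared with a 0.05 tie tolerance;
  the r = R entry is a single deterministic subset with no draw averaging
  and ~0.1 jitter from the min-statistic's discreteness, so it is held to
  the coarser trend (no higher than the first resolvable entry) rather than
  the pairwise tolerance.

## Problem sizes used in the validation suite

Null calibration uses 1000 simulated 45-construct screens (9 replicates
each); coverage power uses the 119-construct pilot preset with 20 thinning
draws per coverage; replicate curves use 200 subsets per r.  These sizes
hold the Monte-Carlo error of every asserted quantity comfortably below the
assertion tolerances while keeping the default suite quick to run.

## Known limitations

* Exact-substring counting requires the manifest to declare the unique
  hairpin half; the package deliberately does not derive it from full
  hairpin sequences, and pools whose unique halves collide (either strand)
  are rejected rather than resolved.
* The pooled-null rank-sum test treats null constructs' fold changes as
  exchangeable; shared within-replicate noise induces slight dependence that
  the calibration tests bound empirically but the theory ignores.
* The α² two-hit arithmetic ignores constructs-per-gene; the binomial mode
  is provided, and the difference (~10×) matters when pools grow.
* Gene-level aggregation is the two-hit counting rule only; rank-aggregation
  or p-value-combination schemes are out of scope.
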