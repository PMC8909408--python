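# Methods

## The rating model

`peakrate` operates on an aligned, clustered peak table. A *feature
cluster* is taken to be the signal set of (ideally) one compound: members
co-elute and their per-sample intensity vectors correlate. Within that
assumption, two independent lines of evidence separate real parental
features from redundancy:

1. **Adduct correlations.** In positive-mode electrospray a neutral
   molecule M ionises as [M+H]⁺, [M+NH₄]⁺, [M+Na]⁺ and [M+K]⁺ at fixed
   offsets from M. The pairwise m/z differences between these forms are
   therefore known constants:

   | pair | Δ (Da) |
   |---|---|
   | [M+H]⁺ → [M+NH₄]⁺ | 17.026547 |
   | [M+H]⁺ → [M+Na]⁺ | 21.981942 |
   | [M+H]⁺ → [M+K]⁺ | 37.955882 |
   | [M+NH₄]⁺ → [M+Na]⁺ | 4.955395 |
   | [M+NH₄]⁺ → [M+K]⁺ | 20.929335 |
   | [M+Na]⁺ → [M+K]⁺ | 15.973940 |

   Offsets are electron-corrected cation masses (H⁺ 1.007276, NH₄⁺
   18.033823, Na⁺ 22.989218, K⁺ 38.963158 Da); the ~0.55 mDa electron
   correction matters at the 0.01 Da matching scale. A cluster-member pair
   whose m/z difference matches a rule within the adduct tolerance is a
   *candidate edge*; accepted edges label both ends and connected
   components of accepted edges form TRF correlation groups. Arbitrary
   rule sets (e.g. negative-mode, solvent clusters) can be supplied as
   (name, offset) specs plus pairs; all 21 pairs over 7 adduct types are
   expressible.

2. **MS2 containment.** An in-source fragment aligns as its own MS1
   feature but also appears as a product-ion peak in the MS2 spectrum of
   its (co-clustered, heavier) parent. A non-TRF member whose MS1 m/z
   occurs within the fragment tolerance in a larger cluster-mate's MS2 is
   removed as a fragment. The test is pure m/z existence — MS2 intensities
   are ignored by default — and single-pass: calls are evaluated against
   the original cluster state, so removal order cannot cascade.

Survivors without adduct evidence are SRFs. Each TRF group contributes one
representative — its most intense member — to the final table, encoding the
"one feature per metabolite" goal as a deterministic rule (ties break to
lower m/z, then lexicographic feature id) rather than a manual selection;
a group export remains available for human review.

## Conflict resolution for adduct labels

A feature may participate in candidate edges that imply contradictory
labels (dense clusters, near-coincident deltas). Resolution is exact: a
depth-first branch-and-bound over the deterministically ordered candidate
list finds the consistent edge subset maximising accepted-edge count, with
ties broken by minimal total absolute mass error and then by candidate
order. Greedy acceptance in ascending error — simpler and near-optimal —
was evaluated and rejected: on roughly 0.2% of random small clusters an
early low-error edge blocks a strictly larger consistent labelling.
Because realistic clusters yield few candidate edges, exact search costs
essentially nothing; clusters producing more than 20 candidates (far
beyond anything a correct upstream clustering produces) fall back to the
greedy rule to bound worst-case time.

Cluster membership itself is trusted as given. This is deliberate: when
upstream clustering wrongly merges unrelated co-eluting features whose
m/z difference happens to match a rule, the flagger *will* flag them —
a documented failure mode of correlation-based flagging that belongs to
the clustering, not the flagging rule. The opt-in strict mode re-checks
cluster cohesion (pairwise Pearson r ≥ 0.8 and ΔRT ≤ 0.03 min) and splits
incoherent clusters before flagging, trading recall for precision.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| adduct tolerance | 0.01 | Da | high-resolution QTOF mass accuracy at MS1 |
| fragment tolerance | 0.05 | Da | looser, since MS2 peaks are centroided at lower accuracy |
| min_blank_ratio | 0.8 | — | feature kept if max biological height ≥ 0.8 × mean blank height |
| max_class_rsd | 0.30 | fraction | best-class repeatability bound; classes with < 2 replicates skipped |
| min_pearson | 0.8 | — | cluster edge rule (biological samples only, raw heights, gaps as 0) |
| cluster_rt_tol | 0.03 | min | co-elution window for cluster edges and strict mode |
| intensity metric | mean over biological samples | — | robust to single-sample spikes; max-sample and QC-mean selectable |

Absolute Da tolerances (not ppm) are used throughout, matching how the
thresholds are specified in the tools this package interoperates with.

## Numerical and degenerate-case choices

* Pearson correlation of a constant (zero-variance) height vector is
  undefined; such features become singletons and are logged.
* A feature absent from the blank (mean blank height 0) survives the blank
  filter at any ratio; ratio 0 disables the filter. A class whose heights
  are all zero is treated as infinitely unstable (RSD = ∞).
* Filters attribute rather than delete: the feature row stays in the full
  table marked `interference`, preserving count conservation
  (input = TRF + SRF + fragment + interference at every stage boundary).
* All orderings (cluster ids, group ids, final table) are keyed on m/z, RT
  and feature id, so every result is invariant under input row permutation
  and identical inputs give byte-identical outputs.
* An owner must have larger precursor m/z than the fragment it removes;
  this physical constraint also excludes mutual-removal cycles.
* Spectrum-string parsing is total: malformed tokens are skipped with a
  warning, never raised; serialisation uses shortest-exact float form so
  read/write round-trips are lossless.

## The synthetic-data generator

The generator emulates the post-alignment, post-cleaning table of a
multi-class profiling study with planted ground truth. Per compound it
draws a neutral mass (100–1000 Da), retention time (1–30 min) and latent
abundance; emits the quasi-molecular ion (dropped with probability 0.1,
in which case ≥ 2 other adducts are forced so the compound remains
discoverable by correlation) and extra adducts (probability 0.35 each) at
exact offsets plus Gaussian jitter (default sd 2 mDa); and with
probability 0.3 plants 1–2 in-source fragments whose m/z (precursor minus
a neutral loss: water, formic acid, hexose, or a uniform deviate) is
inserted into the precursor's MS2. Intensities are compound latent
abundance × per-feature response × lognormal noise (CV 0.2), with a
between-class lognormal spread (sd 1.0 on the log scale) so within-compound
features correlate strongly across the 4 × 3 biological design; blanks are
near-zero for compound features, and half of the 60 uncorrelated noise
singletons are blank-dominated to exercise the blank filter; QCs are
per-feature biological means with 2% noise.

Two construction guards keep the planted truth recoverable by the stated
rules rather than by luck: a fragment's m/z is redrawn if it would fall
within 0.02 Da of any adduct-rule delta relative to any cluster member
(which would fake an adduct correlation) or within 0.2 Da of a member m/z
(which would collide with fragment screening); and decoy MS2 peaks are
kept ≥ 0.4 Da away from all member m/z values.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, multiply charged ions and dimers, cross-compound
co-elution (each compound is its own expected cluster), retention-time
drift between runs, and matrix-dependent ionisation suppression. Perfect
recovery on these fixtures therefore demonstrates correctness of the
rating rules under their own assumptions — not the expected accuracy on
real data, where cluster impurity is the dominant error source.

## Scoring conventions

Recovery metrics compare predicted attributions with planted roles.
Adduct-flag recall uses as denominator the *flaggable* features — adduct
forms of compounds with ≥ 2 such forms in one cluster — because an
isolated quasi-molecular ion exhibits no correlation by construction.
SRF precision/recall is computed over non-noise features: a retained
uncorrelated noise singleton is structurally indistinguishable from an
SRF, so noise that survives the blank filter is excluded from the SRF
comparison rather than counted against it. Empty-set conventions:
precision and recall are 1 when nothing was predicted/expected. Cluster
agreement is the pair-counting Rand index against the expected partition.

## Problem sizes

The benchmark study used by `scripts/acceptance.py` and the test suite is
200 compounds (~540 features) with the defaults above; oracle-equivalence
checks run 1000 random clusters of ≤ 6 members (adducts) and ≤ 8 members
(fragments) against exhaustive references. The whole suite completes in a
few seconds; the sizes were chosen as the smallest at which every failure
mode observed during development (label conflicts, dropped quasi-molecular
ions, fragment/adduct ambiguity) occurs many times per run.

## Known limitations

* Singly charged ions only; charge-state deconvolution, dimers
  ([2M+H]⁺) and isotope-pattern annotation are out of scope (dimer
  offsets can be supplied as custom specs, but neutral-mass
  back-calculation then reports the dimer mass).
* Fragment screening never looks across clusters, so a fragment split
  from its parent by the upstream clustering is unrecoverable here.
* Whether to compare candidates against the MS2 of already-removed
  fragments is answered with single-pass semantics (no cascade); a
  cascading variant could call more fragments at higher risk of chains of
  false removals.
* The blank statistic is the mean over blank injections and the
  biological statistic is the max over all samples — conservative
  retention that favours keeping class-specific features.
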