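# Methods

`sedanet` analyses multi-condition functional connectomes — one correlation
matrix per subject per condition — through the graph-theoretic pipeline used
in sedation/consciousness studies: percolation-thresholded graph
construction, signed Louvain modularity with consensus partitioning, the hub
disruption index κ, rich-club detection against a degree-preserving null,
and repeated-measures statistics. A synthetic-study generator with planted
ground truth makes every stage testable without imaging data.

## Graph construction

Edges are pairwise Pearson correlations between ROI time series (signed,
zero diagonal). Graphs are compared at fixed *cost densities*: the top
`round(d · N(N−1)/2)` edges by **signed** weight are retained (`round` is
half-to-even; ties are broken by ascending `(i, j)` order, which makes edge
sets nested across densities). Ranking by signed rather than absolute value
keeps the strongest positive coupling backbone; an `rank: absolute` config
mode is available for the alternative convention. The percolation threshold
is the smallest density (1%-step search grid by default) at which every
matrix in the study is fully connected; the analysis grid then runs from the
percolation value rounded up to the nearest 2% step to 50% in 2% steps
(18 levels when percolation is at 16%).

## Signed modularity and consensus

Community structure is found by maximising the asymmetric signed quality

    Q = Q⁺ − s⁻/(s⁺+s⁻) · Q⁻ ,
    Q± = (1/s±) Σᵢⱼ [w±ᵢⱼ − γ s±ᵢ s±ⱼ / s±] δ(cᵢ, cⱼ) ,

with `W±` the positive/negative parts, `s±ᵢ` their nodal strengths, `s±`
their total weight and γ = 1 by default. Positive within-community weight is
rewarded at full rate; negative within-community weight is penalised at a
rate shrinking with the negative-weight share; with no negative weights this
is Newman–Girvan weighted modularity. The optimiser is a Louvain two-phase
greedy scheme operating directly on the signed modularity matrix, so local
moves, aggregation and empty-community isolation all use the same quality;
the sweep order is shuffled per seed, and the best of 10 restarts is kept
(exhaustive search confirms it attains the global optimum on all ≤ 8-node
test graphs). The participation coefficient `Pᵢ = 1 − Σₘ (κᵢₘ/kᵢ)²` uses
positive weights only, because the classic coefficient is undefined for
mixed-sign strengths; this is config-visible.

Consensus partitioning follows the association–reclustering scheme: the
agreement matrix over all (subject × density) partitions of a condition is
thresholded at τ = 0.5 (τ is not fixed by the protocol the pipeline
emulates; 0.5 is the common default), reclustered with best-of-10 Louvain,
and iterated (at most 10 times) until all restarts agree.

## Hub disruption index

Nodal strength is the signed sum of a node's correlations on the full,
unthresholded matrix. For a condition pair (reference → target), κ is the
OLS slope of per-node strength change against reference strength: at subject
level, each subject's change against that subject's own reference strengths;
at group level, the across-subject mean change against the mean reference
strength. Negative κ means hubs lose and non-hubs gain connectivity. An
alternative x-axis convention (x = target-condition strength) exists in the
literature and is available as `kappa_x_axis: target`; the reference-side
convention is the default.

## Rich-club

φ(k) is the edge density among nodes of degree > k on the binarized graph at
the percolation density. It is normalised by its mean over 100
Maslov–Sneppen surrogates (double-edge swaps, 10 attempts per edge —
standard mixing heuristic; degree sequence preserved exactly), with
one-sided add-one permutation p-values `(1 + #{φ_surr ≥ φ})/(n_surr + 1)`
(never zero, valid at 100 surrogates). Significant k-levels require
φ_norm > 1 and p < α (0.05); the club is the node set of degree > k*, with
k* the maximum significant k (gaps in the significant range are reported
but do not affect k*). Detection runs on the group-average baseline matrix
and, identically, per subject; each subject's baseline club defines the node
set whose mean signed weight ("club strength") is tracked across that
subject's three condition matrices. A membership count per node across
subjects summarises the common rich-club. Subjects with no detectable club
fall back to the group club with a logged warning.

## Statistics

The one-way repeated-measures ANOVA uses the textbook sum-of-squares
decomposition with the Greenhouse–Geisser sphericity estimate
`ε = tr(V)²/((k−1)tr(V²))`, `V = C S Cᵀ` with C an orthonormal contrast
basis, and F referred to `(ε(k−1), ε(n−1)(k−1))` degrees of freedom
(ε clipped to [1/(k−1), 1]; ε = 1 exactly at k = 2). Post-hocs are paired
t-tests with Bonferroni adjustment `min(1, p·#pairs)`. Pearson correlations
report `t = r√((n−2)/(1−r²))` with one- or two-tailed p; the drug- and
behaviour-change correlations default to one-tailed because the printed
(r, p) pairs they emulate at n = 19 are one-tailed (r = 0.44 → p ≈ 0.029).
Difference scores (moderate − light) are computed subject-wise before
correlating, and ΔQ/ΔP are taken at the first grid density (the percolation
level). All three operations agree with `pingouin` within 1e−8 in the test
suite; `pingouin` is an oracle only, never the implementation.

## Synthetic-study generator

The generator emulates the data structure of a 19-subject, 3-condition
(baseline B / light L / moderate M sedation), ~258-ROI, ~140-volume study:

* **Covariance**: block-modular correlation matrix (4 equal blocks by
  default; r_within = 0.5, r_between = 0.1), unit diagonal, repaired to the
  nearest PSD correlation matrix by eigenvalue clipping + diagonal
  renormalisation (an already-valid matrix is returned bit-exactly).
  The top decile of each block (by construction, its last ⌈10%⌉ nodes) are
  hubs; their off-block entries are raised by `hub_boost` (0.25) per hub
  endpoint, so hub–hub entries gain twice the boost — this is what makes the
  hubs interconnect beyond their degree and plants a detectable rich-club.
* **Condition effect**: strengths are driven to
  `sᵢ + κ(sᵢ − mean s)` by iterative symmetric row/column rescaling followed
  by PSD repair; the realised slope (stored as `achieved_kappa`) lands
  within ±0.05 of the request. Defaults plant κ = −0.2 (B→L) and −0.4
  (B→M) plus a 20% attenuation of hub–hub entries in both sedation
  conditions.
* **Subjects**: off-diagonal N(0, 0.02²) jitter per subject and condition,
  PSD-repaired — the between-subject variance feeding the ANOVAs.
* **Time series**: zero-mean multivariate normal draws (eigen-factor), T =
  140 by default.
* **Behaviour**: the error-count change between the two sedation conditions
  is `round(a·z + b·η + c)` with z the subject's standardised planted
  club-strength change, `a/√(a²+b²)` equal to the target correlation (−0.7
  by default), η standard normal, and c/σ the error-change mean/SD (3 ± 3;
  the emulated task's error scale is not published, so these are config).
  Base error counts are ~5 ± 1.5, floored at 0; plasma concentrations are
  drawn as N(0.6, 0.1²) and N(1.2, 0.1²) µg/mL, floored at 0.

What the generator does **not** model: haemodynamics, physiological noise,
head motion, autocorrelated BOLD spectra, or spatial embedding. Passing
tests therefore demonstrate correctness of the graph/statistics machinery
and recoverability of planted effects under idealised noise — not robustness
to fMRI artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at 16–60 nodes, 8–19 subjects and T =
8–300 (the full pipeline defaults to 120 nodes, 19 × 3 panels, T = 140,
which completes in a few minutes on one CPU); Monte-Carlo counts are 10–25
seeds for detection/recovery properties and 200 replicates for the
behaviour-correlation calibration. Degenerate inputs are flagged rather than
raised where a downstream consumer can proceed (infinite-F ANOVA,
zero-variance post-hoc pairs, undetected rich-club); zero-variance signals,
constant regressors and singleton clubs raise named errors. All randomness
flows from a single master seed through per-stage seed derivation
(`SeedSequence` keyed by stage name), so reports are byte-identical per
seed.

## Known limitations

* **Baseline-club selection bias.** Because the club is detected on each
  subject's *baseline* graph, chance-favoured members inflate baseline club
  strength relative to the other conditions (regression to the mean). Under
  a null study with no condition effects the club-strength ANOVA therefore
  stays significant even though κ and the Q/P ANOVAs are quiet. This
  circularity is intrinsic to the baseline-defined-club procedure the
  pipeline reproduces; condition differences in club strength should be
  interpreted against this bias, e.g. by comparing the two sedation
  conditions to each other rather than to baseline.
* The behaviour correlation measured from finite time series is attenuated
  relative to its planted value, because between-subject club-strength
  differences (jitter SD 0.02) are of the same order as correlation
  sampling noise at T = 140; recovery tests therefore validate the planted
  coupling against the generator's ground truth.
* φ(k) monotonicity in k is not asserted anywhere — it does not hold in
  general.
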