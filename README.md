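# sedanet

Graph-theoretic analysis of multi-condition functional connectomes:
percolation-thresholded brain graphs, signed Louvain modularity with
consensus partitioning, the hub disruption index (κ), rich-club detection
against degree-preserving surrogates, and repeated-measures statistics —
plus a synthetic-study generator with planted ground truth.

## Who this is for

Studies that scan the same participants under several conditions (e.g.
baseline rest and two levels of pharmacological sedation) and ask how the
*topology* of the functional connectome changes: does the community
structure survive, do hubs reorganise, does the rich-club weaken, and do
those changes track drug levels or behaviour? `sedanet` implements that
pipeline end-to-end on ROI time series or precomputed correlation matrices,
and — because subject fMRI is rarely shareable — ships a generator that
plants each effect (partition, hubs, κ slope, rich-club, behaviour coupling)
so every stage can be validated against known truth.

## The quantities it computes

* **Connectivity**: Pearson correlation matrices per subject-condition;
  proportional (cost-density) thresholding by signed weight; the
  *percolation threshold* — the smallest density at which every graph in the
  study is connected — and a 2%-step density grid from there to 50%.
* **Modularity**: signed Louvain maximising
  `Q = Q⁺ − s⁻/(s⁺+s⁻)·Q⁻` (negative weights penalised asymmetrically),
  γ = 1, best of 10 restarts; participation coefficient
  `Pᵢ = 1 − Σₘ(κᵢₘ/kᵢ)²`; agreement-matrix consensus partitions per
  condition.
* **Hub disruption**: κ, the OLS slope of per-node strength change
  (target − reference condition) on reference strength — negative κ means
  hubs lose while non-hubs gain connectivity.
* **Rich-club**: φ(k) (edge density among nodes of degree > k), normalised
  by 100 Maslov–Sneppen surrogates with one-sided permutation p-values; the
  club is the node set above the maximum significant k; its mean signed
  strength is tracked across conditions.
* **Statistics**: repeated-measures ANOVA with Greenhouse–Geisser
  correction, Bonferroni paired post-hocs, and one-/two-tailed Pearson
  correlations of condition differences against drug concentration and task
  errors.

See `docs/methods.md` for formulas, defaults, assumptions and limitations.

## Worked example

```python
from sedanet import RunConfig, run

cfg = RunConfig(seed=9, n_subjects=8, n_nodes=40, n_timepoints=120,
                n_surrogates=30, n_restarts=5, grid_step=0.05)
rep = run(cfg)
print(f"percolation density: {rep.percolation_density:.2f}")
for pair in ("B->L", "B->M"):
    print(f"group kappa {pair}: {rep.kappa[pair]['group']['kappa']:+.3f}")
a = rep.stats["anova"]["club_strength"]
print(f"club strength ANOVA: F({a['df1']:.2f},{a['df2']:.2f}) = {a['F']:.1f}, "
      f"p = {a['p']:.2g}")
```

Output:

```
percolation density: 0.24
group kappa B->L: -0.315
group kappa B->M: -0.468
club strength ANOVA: F(1.95,13.67) = 55.4, p = 3e-07
```

This simulated study plants κ = −0.2 (baseline→light) and −0.4
(baseline→moderate) plus a 20% attenuation of hub–hub connectivity in the
sedation conditions. The recovered group κ is negative for both pairs (the
measured values also absorb the club attenuation, so they sit below the
planted slopes), and the club-strength ANOVA picks up the planted weakening
of the rich-club. Setting the planted effects to zero
(`kappa_light=0, kappa_moderate=0, club_attenuation=0`) yields |κ| < 0.1
and non-significant Q/P ANOVAs.

The same pipeline runs from the shell:

```bash
sedanet simulate --config cfg.yaml --out study/   # write panels + design
sedanet analyze  --config cfg.yaml --in study/ --out results/
sedanet report   --in results/                    # JSON -> Markdown tables
```

The YAML config mirrors `RunConfig` field-for-field (`seed`, `n_subjects`,
`n_nodes`, `gamma`, `n_restarts`, `n_surrogates`, `alpha`, `tails`,
`grid_step`, `rank`, planted-effect parameters, ...). Matrices are TSV with
label headers; the design table is CSV (`subject,condition,plasma_ugml,errors`);
reports are JSON plus CSV tables.

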