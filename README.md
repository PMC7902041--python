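# ocuqtl

From raw ocular perfusion traces to a quantitative-trait-locus scan.

`ocuqtl` implements, as a tested and reusable pipeline, the analysis that
links corneoscleral biomechanics to genetics in recombinant inbred (RI)
mouse panels: per-step ocular compliance estimated by two independent
methods, reference-compliance fitting, volume normalisation, quality
control, strain aggregation, heritability, Haley–Knott interval mapping
with permutation thresholds, and the thin-shell effective corneoscleral
modulus. A synthetic-data module generates stepped-pressure perfusion
experiments and BXD-like RI genotypes with known ground truth, so every
stage is verifiable without any external data.

It is written for vision scientists and biomechanics groups who measure
whole-eye pressure–volume behaviour with a stepped-pressure perfusion rig and
want a reproducible, scriptable route from traces to mapped loci.

## The model

Ocular compliance is φ = dV/dP of the whole eye. Over a perfusion the
pressure dependence of compliance is described by the empirical law

    φ(P) = φ_r (P_r + γ) / (P + γ)

where φ_r is the compliance at the reference pressure P_r = 13 mmHg (normal
mouse IOP) and γ a non-linearity constant. Each pressure step of a trace
yields one φ estimate by two routes:

* **Volume Filling (VF)** — ΔV = ∫(Q_in − C·P) dt over the step divided by
  the plateau pressure change ΔP (C is the outflow facility, estimated once
  per eye from plateau flow-vs-pressure regression). A secant estimate;
  ascending and descending steps are both used.
* **Step Response (SR)** — a least-squares fit of the measured pressure
  transient to the lumped-parameter circuit model
  φ(P)·dP/dt = (P_applied − P)/R_needle − C·P, with the local compliance φ
  and γ free. Ascending steps only.

Per-step estimates are pooled by a weighted fit of the law above, giving
φ_r ± SE; dividing by ocular volume (mass / 1.103 mg/μl) gives the
normalised compliance φ_norm in nl/mmHg/μl. After QC (top-15%-uncertainty
filter, best eye of each pair, 1.5·IQR within-strain outliers), strain means
φ̄_norm feed:

* heritability H² = V_g/(V_g + V_e), with V_g the SD of strain means and
  V_e the mean within-strain SD (dispersions, as conventionally reported for
  this trait);
* a Haley–Knott genome scan: LRS = n·ln(RSS₀/RSS₁) of strain means on
  expected allele dosage (sib-mated RI expansion R = 4r/(1+6r), Haldane map
  function), with genome-wide suggestive (p < 0.63) and significant
  (p < 0.05) thresholds from permutations and ±1 Mb candidate windows around
  peak-bounding markers;
* the effective tensile modulus of the corneoscleral shell, treated as a
  thin-walled sphere: E = (3R/4t)(V/φ + P), with central corneal thickness
  as the thickness surrogate.

## Worked example

Simulate a small study and run the whole pipeline:

```python
from ocuqtl import harness

cfg = harness.RunConfig(
    simulate=harness.SimulateBlock(n_strains=6, n_eyes_per_strain=2),
    n_perm=200, seed=11, outdir="demo_out",
)
res = harness.run_pipeline(cfg)
print(res["qc_report"].to_string(index=False))
```

prints the QC ledger of the run:

```
method  eyes_in  flagged_high_uncertainty  flagged_not_best_eye  flagged_strain_outlier  kept
    SR       12                         2                     5                       0     5
    VF       12                         2                     4                       0     6
```

Twelve simulated eyes enter per method; two fall in the top 15% of
uncertainty on φ_r, one eye of each remaining pair is set aside, nothing is
an IQR outlier, and the survivors are averaged per strain. `demo_out/` then
holds the per-eye records, strain phenotype tables, heritability, genome
scans with thresholds, peaks with candidate windows, effective moduli and a
Bland–Altman VF-vs-SR comparison, plus a machine-readable `run_summary.json`
whose counts reconcile (in = kept + flagged at every stage).

The same pipeline is available from the shell:

```sh
ocuqtl simulate --config run.yaml --outdir simdata   # traces + genotypes
ocuqtl estimate simdata/traces simdata/metadata.csv  # per-eye compliance
ocuqtl run --config run.yaml                         # full pipeline
```

Exit codes distinguish configuration (2), data (3) and convergence (4)
failures.

## Documentation

`docs/methods.md` describes the forward models, estimators, QC conventions,
mapping statistics, default parameters and known limitations.
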