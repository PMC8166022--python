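# mlcdn

Multiple-layer cell line–drug response networks (ML-CDN) for predicting
anti-cancer drug response (normalized IC50) from heterogeneous cell line
and drug data layers.

## The problem

Pharmacogenomic screens measure the potency (IC50) of hundreds of drugs in
panels of cancer cell lines, but the response matrix is incomplete and new
samples — freshly profiled cell lines or patient tumours — have no response
data at all. The ML-CDN approach exploits two regularities: *similar cell
lines respond similarly to the same drug*, and *similar drugs act similarly
on the same cell line*. It represents each side as a similarity network
(cell lines by pathway activity, copy-number status or mutation status;
drugs by structural fingerprints, target profiles or pan-cancer sensitivity
profiles), optionally fuses the layers with Similarity Network Fusion
(SNF), and predicts every response as a kernel-weighted average over the
observed bipartite graph.

## The model

For a pair (C, D) with observed pairs Ω, the predicted response is

    R̂(C, D) = Σ_{(Cᵢ, Dⱼ) ∈ Ω \ {(C, D)}}  w(C, Cᵢ) · w(D, Dⱼ) · R(Cᵢ, Dⱼ)
              ─────────────────────────────────────────────────────────────
              Σ_{(Cᵢ, Dⱼ) ∈ Ω \ {(C, D)}}  w(C, Cᵢ) · w(D, Dⱼ)

with Gaussian decay weights

    w(C, Cᵢ) = exp( −(1 − ρ(C, Cᵢ))² / 2σ² ),
    w(D, Dⱼ) = exp( −(1 − ρ(D, Dⱼ))² / 2τ² ),

where ρ is the similarity from the chosen networks. The two bandwidths
(σ, τ) are fitted by exhaustive grid search (0 to 1, step 0.01) minimizing
the sum of squared leave-target-out errors J(σ, τ) = Σ_Ω (R − R̂)². A new
sample S enters through its pathway-activity correlation ρ(S, Cᵢ) with the
training cell lines; its predictions sum over all of Ω with no exclusion.

## Worked example

```python
import mlcdn as mc

# a synthetic 50-cell-line x 40-drug screen with planted block structure
ds = mc.generate(mc.SynthConfig(seed=1))

csn = mc.build_csn("path", ds.cell_layers["path"])
dsnf = mc.fuse_networks(
    [mc.build_dsn(l, ds.drug_layers[l]) for l in ("stru", "targ", "sens")]
)

res = mc.MLCDN(ds.response, csn, dsnf).fit()
print(res.summary())
r, rmse = mc.truth_eval(ds, res.predict())
print(f"masked-entry r vs ground truth: {r:.3f} (rmse {rmse:.3f})")
```

prints

```
ML-CDN fit (exhaustive decay-parameter grid search)
==================================
                        value
----------------------------------
Cell lines                      50
Drugs                           40
Observed pairs                1600
CSN layer           path (pearson)
DSN layer              fused (snf)
sigma (cell decay)             0.1
tau (drug decay)               0.2
J (SSE at optimum)         18.7944
In-sample Pearson r         0.9902
In-sample RMSE              0.1084
----------------------------------
masked-entry r vs ground truth: 0.999 (rmse 0.038)
```

The fitted bandwidths say how sharply influence decays with dissimilarity
on each side; the in-sample figures score the leave-target-out predictions
of the 1600 observed pairs; the last line scores the 400 *unobserved*
entries against the noiseless block means the generator planted, i.e. pure
signal recovery.

The same pipeline is scriptable from the shell (`mlcdn simulate`,
`build-csn`, `build-dsn`, `fuse`, `fit`, `cv`, `predict`, `predict-new`,
`compare-models`, `associate`); every stage reads and writes plain TSV/JSON
files.

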