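# foodwebtopo

Tools for asking whether the *shape* of a food web's degree distribution
predicts how it collapses under disturbance.

Ecological networks span a continuum between two idealised topologies: a
**random** web, where trophic links are spread homogeneously and the
degree distribution p(k) is binomial/Gaussian-like, and a **scale-free**
web, where a few hub species concentrate most links and p(k) is
heavy-tailed (≈ k^−γ).  Which side of that continuum a web sits on
matters: hub-dominated webs tolerate random species loss but collapse
abruptly once hubs are targeted, while homogeneous webs respond more
gradually.  This package implements the full analysis chain for that
question on collections of empirical or synthetic food webs.

## What it computes

1. **Fuzzy classification.**  For each web, the non-cumulative,
   non-binned degree histogram p(k) is fitted by least squares
   (Nelder–Mead, multi-start) with a generalised power law
   P_PL(k) = a·k^b + c and a generalised Gaussian
   P_G(k) = a·exp(−(k−μ)²/(2σ²)) + b.  The Pearson correlation between
   fitted and observed frequencies gives membership scores R_PL and R_G
   (R_G censored to 0 unless both flanks of the bell are inside the
   observed degree range: μ + σ/3 > 0 and k_max > μ + σ).  Clipped to
   [0, 1], the scores place the web in a plane whose corners (1, 0) and
   (0, 1) are the pure topologies; the Euclidean distances **D2PG** and
   **D2PL** to those corners are the classification.

2. **Robustness.**  Species are removed one at a time with probability
   graded by an intentionality parameter I — per degree class K,
   P_E(K|I) ∝ (1−I)^(k_max−K)·N_K, so I = 0 is uniform removal and I → 1
   targets hubs.  After each removal, any non-basal species left with no
   surviving resource goes secondarily extinct (iterated to a fixpoint).
   **R50 = E/S** is the fraction of primary removals needed to extinguish
   half the web; the drop of its mean curve over the I grid is
   characterised by a cumulative Weibull y = a(1 − exp(−b·x^c)), whose b
   and c describe the collapse shape (c > 1: sigmoid/threshold).

3. **Pressure regression.**  Distances to the pure topologies are
   regressed against a per-web disturbance covariate, raw and after
   equal-width binning with an optimised bin count (the largest count
   whose binned fit keeps |R| > 0.8, with a flagged fallback otherwise).

A synthetic-data module generates webs from both topology families with
known parameters (Bernoulli links; configuration-model power-law degrees
wired into an acyclic trophic order), plants disturbance relations with
known slope, and provides analytic fixtures (star, chain, complete webs)
whose degree sequences, cascades and R50 are hand-traceable.

## Worked example

```python
import foodwebtopo as ft

web = ft.generate_scalefree_web(S=200, gamma=2.5, seed=1)
profile, pl_fit, g_fit = ft.classify_web(web, seed=0)
print(profile)
# TopologyProfile(R_G=0.0, R_PL=0.9980..., D2PG=1.4128..., D2PL=0.0019...)

curve = ft.robustness_curve(web, n_reps=100, seed=0)
print(round(curve.r50_mean[0], 3), round(curve.r50_mean[-1], 3))
# 0.285 0.127
wb = ft.fit_weibull(curve)
print(round(wb.b, 2), round(wb.c, 2))
# 3.0 0.4
```

The web lands next to the pure scale-free corner (D2PL ≈ 0.002, R_G
censored to 0 because its one-sided heavy-tailed histogram has no left
Gaussian flank), and its robustness falls from R50 ≈ 0.29 under random
removal to ≈ 0.13 under near-deterministic hub targeting — it loses over
half its robustness to a targeted attack.

The same chain as a scripted analysis lives under `analysis/`
(`01_simulate_webs.py` → `04_pressure_regression.py`), writing its tables
to `results/analysis/`.  On the default 40-web cohort it prints, among
other things:

```
scale-free: mean R_G=0.100 R_PL=0.999 D2PG=1.372 D2PL=0.100 | correct side 95%
random: mean R_G=0.893 R_PL=0.188 D2PG=0.254 D2PL=1.218 | correct side 100%
D2PG: raw slope=+0.496 (R=+0.96)  binned slope=+0.468 (R=+0.95, 30 bins)
```

i.e. the two generator families separate cleanly in the plane, and a
planted disturbance slope of +0.5 on D2PG is recovered by both the raw
and the binned regression.

There is also a CLI for directory-level runs:

```bash
foodweb-topo simulate --out data/ --seed 42
foodweb-topo all --input data/ --out results/ --seed 42
```

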