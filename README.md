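# bacushape

Three-dimensional shape complexity of bones via optimal alpha shapes, and a
phylogenetic comparative toolkit for asking what drives that complexity —
built around the carnivoran baculum (the bone of the glans penis), whose
grooves, hooks and rugosities vary spectacularly across species while
classical landmark morphometrics has almost nothing homologous to digitize.

## Who this is for

Evolutionary morphologists with CT volumes or photogrammetric meshes of
irregular skeletal elements, and comparative biologists who want the
downstream statistics — phylogenetic signal, multi-regime trait models over
stochastic character maps, Bayesian phylogenetic regression, Bayes-factor
coevolution tests, regional repeated-measures comparisons — in one tested,
seedable pipeline. Every stage also runs on synthetic data with known
ground truth, so the whole chain is verifiable end to end without any
museum scans.

## The metric

For a solid represented by N uniform interior points (scale-normalized so
its true volume V_ref = 1), the alpha complex at radius α keeps the
Delaunay tetrahedra with circumsphere radius < α; its volume V(α) rises
monotonically from 0 to the convex-hull volume. The **optimal alpha** α\*
solves

&nbsp;&nbsp;&nbsp;&nbsp;V(α\*) = V_ref,

and **complexity = 1/α\***: a near-convex rod is matched by a coarse fit
(low complexity), while a deeply grooved or hooked bone demands a fine fit
(high complexity). Regional scores fit the same metric to three equal spans
(proximal / midshaft / distal) of the first principal axis.

The comparative layer models a log10 trait on a phylogeny: Pagel's λ with a
likelihood-ratio test; BM1/BMS/OU1/OUM/OUMV likelihoods on regime-painted
trees with AICc + Akaike-weight selection across stochastic character maps;
MCMC PGLS with λ estimated jointly (slope significance = posterior mass
crossing zero); dependent-vs-independent bivariate Brownian models scored
by stepping-stone marginal likelihoods and logBF; and Greenhouse–Geisser
corrected repeated-measures ANOVA for within-bone regional contrasts.
See `docs/methods.md` for model details and conventions.

## Worked example

```python
from bacushape.alpha_complexity import optimal_alpha
from bacushape.shape_io import normalize
from bacushape.synthetic_shapes import ShapeSpec, make_baculum

for label, kw in [("plain rod", {}),
                  ("+groove", dict(groove_depth=0.45)),
                  ("+groove+hook", dict(groove_depth=0.45, hook_angle=240.0))]:
    spec = ShapeSpec(kind="baculum", curvature_angle=0.3, n=30_000, seed=17, **kw)
    pc = normalize(make_baculum(spec))
    res = optimal_alpha(pc)
    print(f"{label:14s} complexity={res.complexity:6.3f}  ceiling={res.at_ceiling}")
```

Output (from `analysis/01_shape_complexity_ladder.py`, which also adds
sphere and torus references):

```
sphere             complexity=   0.468 (alpha*=2.1374, ceiling=True)
torus              complexity=   1.727 (alpha*=0.5789, ceiling=False)
rod_plain          complexity=   0.256 (alpha*=3.9075, ceiling=True)
rod_groove         complexity=   6.369 (alpha*=0.1570, ceiling=False)
rod_groove_hook    complexity=   6.864 (alpha*=0.1457, ceiling=False)
```

Reading it: the plain rod is effectively convex — the search hits its
ceiling and reports the minimum measurable complexity for that sampling.
Carving a ventral groove forces a 25× finer fit (complexity 6.37), and a
tight distal hook refines it further (6.86). The torus sits between: one
large concavity, no fine detail.

On the comparative side, `analysis/03_regime_model_selection.py` simulates
a 3-regime social-system history, evolves log-complexity under OUMV, refits
the Mk model, samples 10 stochastic maps and fits all five models on each:

```
model  n_valid  mean_aicc  delta_aicc  weight
  BM1       10     80.959      73.189   0.000
  BMS       10     63.179      55.408   0.000
  OU1       10     83.091      75.321   0.000
  OUM       10     32.739      24.969   0.000
 OUMV       10      7.771       0.000   1.000
```

— the generating model class wins decisively, and single-regime models are
ruled out, which is exactly the qualitative pattern such analyses report on
real bacula.

## Layout

```
src/bacushape/        library: shape_io, alpha_complexity, synthetic_shapes,
                      trait_sim, phylo_models, comparative_stats, trees,
                      pipeline, cli
analysis/             numbered narrative drivers (01–05) writing results/
tests/                pytest suite incl. acceptance checks
scripts/acceptance.py recomputes the headline numbers from scratch
```

A `bacushape` CLI wraps the common entry points
(`complexity`, `simulate-shape`, `simulate-traits`, `phylosig`, `run`).

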