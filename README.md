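# cicdyn

Quantitative comparison of Ras-pathway perturbations through the
spatiotemporal dynamics of nuclear **Capicua (Cic)** in early *Drosophila*
embryos.

Cic is a transcriptional repressor whose nuclear levels are pushed down by
Ras/ERK signalling at the embryo poles. In the syncytial blastoderm its
pattern is shaped by three processes: spatially uniform synthesis, localised
nuclear export at the poles, and nuclear divisions that periodically empty
the nuclei. Time-lapse movies of a Cic-Venus fusion therefore show a
pattern that is high in the mid-body, low at the poles, and punctuated by
mitoses. This package implements a pipeline that turns such movies into a
small set of interpretable, statistically comparable numbers per embryo —
and ships a fully ground-truth-annotated synthetic-embryo generator so the
entire pipeline is testable without any imaging data.

## The model

The central object is the **space-time matrix** `X` (a kymograph): column
*j* is the dorsal anteroposterior (AP) intensity profile at frame *j*,
sampled on fractional egg length *L* ∈ [0, 1] (anterior at 0). The working
hypothesis is separability,

```
X(x, t) ≈ S(x) · a(t),
```

tested via the singular value decomposition. The best rank-one
approximation is σ₁u₁v₁ᵀ, and its quality is the **accuracy ratio**

```
r = σ₁ / sqrt(Σᵢ σᵢ²) = ‖X‖₂ / ‖X‖_F ,
```

which equals 1 exactly when `X` has rank one. The unit-norm first left
singular vector u₁ is the **spatial mode**; projecting the movie onto it,
a(t) = u₁ᵀX, gives the **temporal amplitude**. Downstream summaries:

- **Mitotic dips / alignment** — nuclear divisions drive a(t) to near
  zero; dips are detected as prominent local minima, embryos are aligned
  by shifting time so the 13th-division dip sits at t = 0, and point-wise
  ensemble means ± SD follow.
- **Cycle-14 amplitude** — mean of a(t) over the cycle-14 plateau window;
  reduced in backgrounds with constitutive Ras/ERK activation.
- **Boundary position λ** — a Hill fit
  `f(x) = baseline + (plateau − baseline)·xⁿ/(λⁿ + xⁿ)` to the anterior
  40% of the spatial mode; λ is the egg-length position of half-maximal
  Cic accumulation, n the boundary sharpness.
- **Recovery time** — per-nucleus cycle-14 traces are fitted with
  `I(t) = plateau·(1 − e^{−t/τ})`; both τ and t½ = τ·ln 2 are reported.
- **Genotype comparison** — two-tailed Student's t-tests (pooled variance
  by default, Welch by flag) with the conventional coding
  \*P<0.05, \*\*P<0.005, \*\*\*P<0.0005.

The synthetic generator produces embryos obeying exactly this model: a
double-sigmoid AP profile (plateau mid-body, Hill boundaries, residual
pole floor), first-order post-mitotic recovery across nuclear cycles
10–14, multiplicative + additive imaging noise, rendered either as
kymographs or as full elliptical-embryo TIFF movies with Gaussian-spot
nuclei in the dorsal band.

## Worked example

```python
import cicdyn as cd

stm, truth = cd.simulate_embryo(seed=1)     # noisy wild-type-like kymograph
analysis = cd.analyze_embryo(stm)

print(analysis.decomposition.accuracy_ratio)   # 0.9983
print(analysis.events.dip_frames)              # [ 22  48  78 112]
print(analysis.hill_fit.lambda_half)           # 0.1198
print(analysis.cycle14_mean_amplitude)         # 100.3
```

Reading the numbers: the accuracy ratio 0.9983 says the kymograph is
rank-one to within the imaging noise, so the separable description is
appropriate. The four dips at 11, 24, 39 and 56 min are the divisions
entering cycles 11–14 (the last one is the 13th division, the alignment
anchor). The fitted boundary λ = 0.120 and the cycle-14 amplitude 100.3
recover this embryo's generating parameters (λ = 0.12, plateau = 100).

Single-cell recovery, same style:

```python
traces = cd.make_nuclear_traces(seed=1, n_nuclei=20)
taus = [cd.estimate_recovery(t).tau for t in traces]
# mean 3.05 min, SD 0.20 — generator value 3.0 min
```

The same steps are available as estimator classes that compose with
scikit-learn (`RankOneDecomposer`, `HillBoundaryFit`,
`ExponentialRecovery`, `KymographExtractor`: `fit`/`transform`/`predict`,
fitted attributes with trailing underscores), and from the shell:

```bash
cicdyn --seed 1 simulate -n 3 -o sim/        # kymograph CSVs + truth JSON
cicdyn extract movie.tif -o kymo.csv         # TIFF movie -> kymograph
cicdyn decompose kymo.csv -o dec.json
cicdyn --seed 1 run-all -n 8 -o results/     # all genotypes + comparisons
```

CSV dialect: first column `position` (fractional egg length), one column
per frame with the time in minutes as header. Movies are single-channel
multi-frame TIFF stacks, one embryo per file.

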