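# Methods

## The dimensional model and its reduction

The dimensional model tracks proinflammatory macrophages M1, profibrotic
macrophages M2 and activated fibroblasts F:

```
Ṁ1 = lY + E12 − d1·M1
Ṁ2 = rH·M2·F·(Y+Y0)/(M2+K) − E12 − d2·M2
Ḟ  = gH·M2·F·(F0−F) − d3·F,     E12 = −k12·M1 + k21·M2·Y
```

Inflammation Y and hypoxia H are exogenous drivers: recruitment of
proinflammatory cells scales with Y, while both growth terms (profibrotic
proliferation, fibroblast activation) are gated by H. The switching term
E12 exchanges the two macrophage phenotypes; with switching much faster
than turnover the exchange equilibrates, pinning the split at
M1/M2 = (k21/k12)·Y. This quasi-steady state removes one variable
(M = M1 + M2) and the `qss_inflammation_link` diagnostic exposes the
implied inflammation Y = (k12/k21)·M1/M2. During dimensional integration
the link is *not* enforced — Y stays an exogenous constant — because the
link is an emergent property that the fast-switching limit must produce
on its own (and tests verify it does, to 1% at k/d = 500).

**Non-dimensionalization.** The package fixes one explicit map: time by
1/d1, macrophages by l·Y0/d1, fibroblasts by F0, inflammation by Y0.
This yields

```
λ = (k21/k12)·Y0,  δ1 = d2/d1,  δ2 = d3/d1,  α = r·F0/l,  β = g·l·Y0·F0/d1²
```

and the reduced system of the README. Two remarks:

* λ carries the inflammation scale Y0 because k21 acts per unit
  *dimensional* inflammation; at the reference scale Y0 = 1 it reduces to
  the bare switching ratio k21/k12.
* the proliferation-saturation denominator rescales to
  `m + κ(1+λy)` with shape factor κ = K·d1/(l·Y0). The canonical reduced
  form assumes κ = 1, i.e. the inhibition scale K equals the recruitment
  balance l·Y0/d1. `reduce_model` returns κ in its scale report and flags
  non-canonical inputs instead of silently coercing them; all reduced-model
  analyses take the canonical form as given.

The state space is forward-invariant on {m ≥ 0, 0 ≤ f ≤ 1}: ḟ vanishes
at f = 0, equals −δ2 < 0 at f = 1, and ṁ = y ≥ 0 at m = 0. f is read as
a fraction of the fibrotic carrying capacity F0, which is what the
logistic factor (1−f) encodes.

## Equilibria and stability

The healthy state (m = y(1+λy)/(λy+δ1), f = 0) always exists. Interior
equilibria lie on the non-trivial fibroblast nullcline
f(m) = 1 − δ2(1+λy)/(βHm); substituting it into ṁ = 0 and clearing
denominators gives a quadratic in m, so at most two interior fixed points
exist. `find_steady_states` nevertheless locates them by a generic
bracketing scan (2048 panels, brentq refinement to relative tolerance
1e−12) over an interval bounded by the quadratic's Cauchy root bound
1 + max(|b/a|, |c/a|) — the bound is rigorous, so no root can escape the
scan window. Roots with f outside (0,1) are unphysical and discarded;
roots within 1e−6 relative distance are merged; a root coinciding with
the healthy state (the transcritical point) is not double-counted.

Stability comes from the analytic Jacobian (checked against central
finite differences to 1e−6). Eigenvalue real parts below 1e−8 in
magnitude are classed `nonhyperbolic` rather than guessed. The healthy
state is stable iff H < H_cr = (δ2/β)(λ + δ1/y); at y = 0 the threshold
is +∞ (sentinel). The inverse form y_cr = δ1/((β/δ2)H − λ) is returned
as `None` when (β/δ2)H ≤ λ — below that hypoxia level no inflammation
can destabilize the healthy state, consistent with the limit
H_cr → λδ2/β at very high inflammation.

## Phases, boundaries, separatrix

Phase labels come from stability alone: I = healthy stable, no stable
fibrotic state; II = both stable; III = healthy unstable, fibrotic
stable. Anything else (e.g. healthy unstable with no stable interior
root found) is reported `unresolved`, never coerced. The II/III boundary
is the analytic curve H = H_cr(y); the I/II boundary (birth of the
stable fibrotic state, a fold) has no closed form here and is located by
bisection on the stable-fibrotic-existence predicate. Both curves are
exported separately since either may be wanted on a diagram.

The demo grid (y log-spaced in [0.05, 10], H linear in [0, 2], baseline
parameters λ=1, δ1=1, δ2=0.5, α=1, β=4) shows all three phases. The
baseline values are a package choice for tests and demos — the analyses
accept arbitrary positive parameters, and no calibration to culture
kinetics is attempted.

In Phase II the basin boundary is the saddle's stable manifold, traced
by integrating backwards in time from two seeds offset ±1e−7 along the
stable eigenvector, stopping at the domain boundary or after 500 time
units. Classification of a query point uses the signed side of the
nearest polyline segment, with the sign convention calibrated on the
healthy equilibrium; validation is by forward integration
(`attractor_of`: chunked integration until the state dwells a full 10
time units inside a 1e−3 ball around a known stable equilibrium, horizon
500). The hot/cold label for a fibrotic state compares its macrophage
level with the healthy level at the same environment; the multiple
(default 2×) is a configuration knob because the distinction is
qualitative.

## Robustness sweep

`robustness_sweep` perturbs the five reduced parameters log-uniformly
(default: factor in [0.5, 1.5]) and asks, per draw, whether the (y, H)
plane still exhibits all three phases with the I→II→III ordering along
increasing H. Probing is column-wise and adaptive: Phase I at H = 0,
Phase III just above H_cr and at a few multiples of it, Phase II at a
ladder of H fractions below H_cr. The ladder matters: the bistable band
sits somewhere inside (0, H_cr) and the transcritical direction at H_cr
is parameter-dependent, so no single near-boundary probe (and no fixed
(y,H) raster) finds it reliably. Passing `H_max`/`y_window` restricts
the probes and turns the question into visibility inside a display
window — a materially different and stricter question, since thin bands
drift out of any fixed window under large parameter changes.

## Signature overlap

All overlap quantities are exact rational counts against the ex vivo set
E: explained = |E ∩ ∪Sᵢ|/|E|; univocal fractions count genes in exactly
one signature, grouped by that signature's discriminating variable;
shared matrix entries are |E ∩ Sᵢ ∩ Sⱼ|/|E|; pathway contributions are
computed within each pathway's ex vivo slice. The partition identity
explained = univocal + multiply-explained holds to 1e−12 by
construction and is asserted in tests. Gene matching is exact string
comparison after configurable upper-casing — alias resolution would
require an external database and is out of scope.

Threshold semantics are boundary-inclusive (FDR ≤ 0.05; |logFC| ≥ 1,
p ≤ 0.01). The "comparison of comparisons" at levels 2 and 3 pairs
conditions differing only in the declared axis and applies a declared
set operation; the default `venn` mode emits the unique/shared/unique
partition, and the applied mode is recorded in the derived-set keys.
Directional concordance filtering when counting a gene as explained is
available in principle through the signature `direction` field but off
by default.

The pre-ranked enrichment score is the maximum deviation of the weighted
running sum (weight exponent 1 by default; members advance by
|score|^w normalized, non-members retreat by 1/(N−N_hit)). Significance
uses gene-label permutations — equivalently uniform redraws of the
member positions — with p = (1 + #{ES at least as extreme, same
sign})/(1 + n_perm). The p-value is one-sided on the observed sign, so
under the null P(p ≤ a) ≈ 2a; the type-I calibration test asserts
exactly that. For tiny universes an exhaustive mode enumerates every
membership arrangement and returns the exact tail fraction, which is the
oracle the Monte-Carlo p is tested against. The screen retains
signatures passing both the permutation threshold (default p ≤ 0.05)
and a minimum-overlap requirement (default ≥ 1 gene).

The study's 44-condition design is generated as a declared factorial
minus an exclusion list; which four cells of the 48-cell factorial were
absent cannot be derived from the design coding, so the shipped
exclusion list is an explicitly non-authoritative demo choice. The count
of in vitro signatures is likewise taken as input data, not re-derived.

## Spatial statistics

Densities are counts over caller-supplied compartment areas (default:
the full 466 × 349 µm ROI = 0.162634 mm²; the "surrounding" compartment
should receive ROI minus glomerulus area). Neighborhood profiles collect,
for each focal cell, all other cells within an inclusive Euclidean
radius (default 7.5 µm, kd-tree accelerated but bit-identical to the
all-pairs scan), and average per-cell relative frequencies. Focal cells
with no neighbor are excluded from mean/SD — their frequency is 0/0 —
and reported separately. No edge correction is applied; neighborhoods
are implicitly clipped by the data extent. The frequency denominator
counts the six named phenotypes by default; including "other" is a flag.

## Synthetic data

Generators are pure functions of (spec, seed). The planted-overlap
generator allocates ex vivo genes to signatures by bookkeeping (univocal
genes to exactly one signature of the requested variable, shared genes
to exactly two, fillers from outside the ex vivo set), so its ground
truth is exact and every target fraction must be a multiple of
1/n_exvivo — infeasible specs fail loudly with the violated constraint.
Ranked instances draw null logFC from a standard normal (only rank
structure matters to the screen) and shift the planted set additively.
Point patterns are homogeneous Poisson per phenotype, or Thomas
processes (Poisson parents, Gaussian-displaced Poisson offspring) for
clustered phenotypes, on the standard ROI.

What the generators do *not* emulate: correlated expression between
genes, library-size or count-noise structure upstream of DEG calling,
anisotropy or tissue-boundary effects in the point patterns, and
measured signature sizes/overlap structure of the real culture data.
Passing tests therefore demonstrate correctness of the statistics and
calibration of the screens under the stated generative assumptions, not
biological conclusions about real tissue.

## Problem sizes and numerical defaults

Default analysis sizes — 100×100 phase grids, 200-draw robustness
sweeps, 100-start basin validation, 1000-permutation screens, ROI-scale
point patterns (hundreds to ~2000 cells) — are chosen so every stage
completes in seconds on one core while keeping Monte-Carlo standard
errors well inside the asserted tolerances. Integration uses adaptive
RK45 (LSODA for the stiff dimensional form) at rtol 1e−8/atol 1e−10;
two solver families agree to 1e−6 on baseline runs.

## Known limitations

Mean-field, non-spatial, deterministic dynamics only (no stochastic or
spatially-resolved variants). No continuation of the fold curve in two
parameters and no center-manifold analysis at nonhyperbolic points.
Whether fibrotic equilibria can be unstable foci in some parameter
corners is reported as computed (the classifier distinguishes
node/focus) without asserting a taxonomy. The SBML export of the reduced
model is not implemented; parameters travel as JSON/YAML.
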