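# Methods

## Scope and data model

The package analyses molecules represented purely at the level of
(composition, functional-group class, HOMO–LUMO gap, polarizability).
Compositions run over the element vocabulary {C, Cl, H, N, O, S} with at
most 7 heavy (non-hydrogen) atoms by default — the small-organic sector of
chemical compound space covered by QM7-X-style datasets. Polarizabilities
are mean (isotropic) values in atomic units (Bohr³); a full symmetric 3×3
tensor may be carried alongside, in which case the scalar must equal one
third of its trace (relative tolerance 1e-8). Gaps are Kohn–Sham-style
HOMO–LUMO gaps in eV, used as a proxy for the optical gap. The canonical
on-disk format is a CSV with fixed column order `id, C, Cl, H, N, O, S,
fg_class, gap, alpha[, axx, axy, axz, ayy, ayz, azz]`; absent optional
values are empty cells, never 0, because 0 is a legal polarizability only in
degenerate toy inputs. Element symbols are case-sensitive ("CL" is
rejected) to avoid silent C/Cl confusion.

## Atomic-additive polarizability model

`alpha_pred = m + Σ_i C_i n_i`. Built-in coefficient tables (Bohr³):

| set          | m    | C     | Cl    | H    | N    | O    | S     |
|--------------|------|-------|-------|------|------|------|-------|
| bosque       | 2.14 | 10.20 | 14.60 | 1.17 | 6.95 | 3.85 | 20.20 |
| refit        | 1.71 | 10.10 | 12.70 | 0.87 | 7.88 | 4.00 | 19.10 |
| no_intercept | 0.00 | 10.37 | 13.00 | 0.88 | 8.11 | 4.24 | 19.37 |

The intercept is a fitting artifact (a molecule with no atoms should have
zero polarizability); it is retained because including or omitting it
changes neither the fit quality nor the coefficients meaningfully, and the
intercept-bearing form is the conventional one.

Re-fitting is ordinary least squares of reference α on the six count
columns (plus a constant column when requested), solved by an SVD-based
orthogonal decomposition (`numpy.linalg.lstsq`); on well-conditioned inputs
this agrees with the normal-equations solution to much better than 1e-8. No
regularisation. An element whose count is constant across the dataset makes
the design rank-deficient and raises a `SingularityError` naming the
element rather than silently producing an unidentifiable coefficient.

Diagnostics are computed **in-sample** (fit and evaluation on the same
records): R² is the coefficient of determination `1 − SS_res/SS_tot`, MAPE
is `100/n · Σ |pred − ref| / ref` (references must be strictly positive; a
non-positive reference is an error, not a skipped point), MAE is the mean
absolute residual. A cross-validation split is deliberately not the default
reporting protocol; the model has seven parameters and ~10³–10⁴ training
rows, so in-sample and held-out metrics differ negligibly.

Because the model sees only counts, all structural isomers of one formula
collapse onto a single prediction. `isomer_degeneracy` tabulates, per exact
composition, the shared prediction next to the min/max/range of the
references — the model's irreducible error floor within a formula.

## Physical models

* **Sum-over-states**: `α = 2 Σ_n |⟨0|x|n⟩|² / (E_n − E_0)` for a finite
  level system; evaluated for a single Cartesian component (not the ⅓-trace
  average), which is the natural convention for one-dimensional toy systems
  and is documented as such. Serves as the brute-force oracle for the
  two-state identities.
* **Quantum Drude oscillator**: `α = q²/(μω²)`; its gap in atomic units is
  ω, and its ground-to-first squared transition dipole is `q²/(2μω)`.
  Selection rules make the QDO exactly a two-state system, so the Unsøld
  form below is exact for it — the identity is tested to machine precision.
* **Unsøld approximation**: `α = 2S/ΔE` with S the summed squared
  transition dipole and ΔE a single average excitation energy. Encodes the
  would-be inverse proportionality α ∝ 1/ΔE_HL that the data analysis shows
  is *not* realised across chemical compound space.
* **Tensor invariants**: mean `tr α/3` and anisotropy
  `Δα = sqrt(½[(αxx−αyy)² + (αyy−αzz)² + (αzz−αxx)²] + 3(αxy²+αyz²+αzx²))`.
  The anisotropy is implemented as this standard rotational invariant
  (including the off-diagonal terms) because it is the only common form
  that is independent of molecular orientation; both invariants are tested
  under random orthogonal conjugation to 1e-10.

### Topping work-function model

For a square lattice of adsorbed dipoles the work-function change is a
Helmholtz dipole-layer term damped by mutual depolarization:

```
Δφ = E_h · 4π μ0 θ / d̃²  ·  [ 1 + 9 α̃′ θ^{3/2} / d̃³ ]⁻¹
```

with μ0 the molecular dipole moment converted Debye → atomic units
(1 D = 0.393430 e·a₀), d̃ the lattice constant in **ångström**, α̃′ the
effective adsorbed-state polarizability as a volume in ångström³
(1 Bohr³ = 0.148185 Å³), θ ∈ [0, 1] the fractional coverage, 9 the
square-lattice dipole-sum constant, and E_h = 27.2114 eV. The
depolarization ratio is dimensionless and identical in any consistent unit
system. The Helmholtz prefactor is the package's **reporting convention**,
chosen for comparability with published adsorbate-layer screening numbers:
it evaluates the dipole term with the lattice constant on the ångström
scale, which exceeds a strictly SI/atomic-unit-consistent evaluation by the
fixed factor (1 Å/1 a₀)⁻² ≈ 3.57. Two things follow. First, *relative*
statements — which candidate shifts the work function most, the ratio of
the screen's endpoints, all monotonicity properties — are entirely
convention-independent, since only the depolarization ratio varies between
candidates at fixed (μ0, d, θ). Second, absolute Δφ values carry this
convention and should be compared only against numbers reported on the same
scale. The function's contract (zero at θ = 0, linear in μ0 in the
α′ → 0 Helmholtz limit, strictly decreasing in α′) is tested directly.

The effective polarizability of an adsorbed molecule is taken as a fixed
multiple of the free-molecule value (default enhancement factor 10, the
order-of-magnitude enhancement typical of adsorbed species); the factor is
a screen parameter, not a fitted quantity.

## Property-space statistics

The two-sample Kolmogorov–Smirnov statistic (`scipy.stats.ks_2samp`,
statistic only — KS is used as a distribution *distance*, never as a test,
so no p-values are reported) measures the separation of two
class-conditional distributions on one axis. The clustering strength of an
axis is the **unweighted mean of the KS statistic over all unordered class
pairs**. Pairwise averaging is the simplest symmetric aggregation; a
class-vs-complement convention would be an alternative, and reports should
treat the absolute average as tied to this choice (the *contrast* between
axes is robust to it). Records without a single class label are excluded
upstream: the analysis is only meaningful for molecules bearing exactly one
functional group.

Global (gap, α) association is the Pearson correlation and its square over
all records carrying both values. Composition slices summarise both axes
over all records of an exact formula, exposing the complementary pattern:
within one formula the polarizability spread is narrow (composition pins α)
while the gap spread is wide (functional groups move ΔE_HL).

## Design screen

Pipeline: element filter → additive α prediction → closed gap window
`|gap − center| ≤ halfwidth` (the boundary test tolerates float
representation error so decimal endpoint gaps are kept) → quartile
representatives → Topping Δφ per representative with
α′ = enhancement_factor × α_pred. Quartile representatives target the
12.5th/37.5th/62.5th/87.5th percentiles of the predicted-α distribution —
the mid-points of the four quartile bins, the canonical discretisation when
four concrete molecules must stand for four quartiles — choosing for each
target the member with the smallest |α − target|, ties broken toward lower
α and then lexicographically smaller id, keeping representatives distinct
whenever the window allows. The screen is fully deterministic. The reported
`phi_range` spans the four representatives' Δφ values; by monotonicity of
the depolarization term its maximum is attained at the *least* polarizable
representative.

## Synthetic data generator

The generator encodes the two mechanisms the analysis is built to detect:

* **Gap ← functionality.** Each molecule draws a class uniformly from
  eleven functional-group classes (aldehyde, ketone, hydrazone, oxime,
  carbonitrile, enol ether, dialkyl ether, primary/secondary alcohol,
  primary/secondary amine) and a gap from a class-specific normal
  distribution (truncated positive). Anchored locations: aldehydes
  6.5 ± 0.10 eV; primary alcohols 7.5 ± 0.15 eV so that ±2 sd spans
  7.2–7.8 eV. The other nine means (hydrazone 5.8, oxime 6.2, secondary
  amine 6.65, ketone 6.8, primary amine 6.9, enol ether 7.0, secondary
  alcohol 7.35, dialkyl ether 8.0, carbonitrile 8.3 eV) are invented,
  chemically plausible defaults — carbonyl n→π* transitions low, ether and
  alcohol n→σ* high, nitriles highest — and are design constants of the
  generator, not measurements.
* **α ← composition.** `alpha = m + Σ C_i n_i + s(class, composition) +
  ε`, truncated positive, with the ground truth defaulting to the `refit`
  coefficient table. The structure residual `s ~ N(0, 3.0 a.u.)` is drawn
  once per (class, composition) pair and reused — a crude stand-in for the
  systematic, isomer-dependent part of the additive model's error — and
  `ε ~ N(0, 2.0 a.u.)` is independent noise. Together they put the
  generator's additive-model MAE near the ~3 a.u. scale typical of real
  small-organic reference data.

Compositions are drawn as a uniform heavy-atom count (from the class's
required-element count, and at least 2, up to `max_heavy = 7`), one atom of
each class-required element, remaining heavy atoms from a carbon-rich
distribution (C 0.70, N 0.10, O 0.10, S 0.05, Cl 0.05), and hydrogens from
the crude valence rule `H = 2·heavy + 2 − 2u`, `u ~ Uniform{0..3}` (degrees
of unsaturation), clipped at zero. One `numpy` Generator seeded by a single
integer drives every draw, so a configuration reproduces byte-identical
datasets.

**What the generator does and does not emulate.** It reproduces the
statistical *structure* the analysis assumes — class-clustered gaps,
composition-dominated polarizabilities, isomer spread, ≤7 heavy atoms — but
not chemistry: no molecular graphs exist, hydrogen counts ignore
element-specific valences (compositions like CH₆O can occur), class labels
constrain composition only through required elements, and real composition
frequencies are not matched. Consequently, passing tests demonstrate the
*statistical machinery* (estimators recover generative truth; the KS
contrast detects the encoded asymmetry); they do not certify accuracy
claims on real quantum-chemical data, which require the corresponding
external dataset.

## Numerical choices and degenerate inputs

* OLS: `numpy.linalg.lstsq` with `rcond=None`; rank checked explicitly
  before solving; residuals returned per record in input order.
* KS: statistic computed exactly over merged sample points; empty samples
  are errors; classes need ≥ 2 usable records (error names the class).
* Gap window boundaries closed, with a 1e-12-relative guard for float
  representation of decimal endpoints.
* Quartile tie-break: (|α − target|, α, id) lexicographic — fully
  deterministic.
* Truncations (gap > 0, α > 0) are resample loops; at default parameters
  they essentially never trigger.
* Round-trip I/O serialises floats to 12 significant digits; symmetric
  tensors store 6 components.

## Problem sizes used in the shipped checks

The test suite and reference script use synthetic datasets of 10²–10⁴
molecules — comfortably the regime where OLS on seven parameters and
pairwise KS over eleven classes are stable — with 20-replicate averages
for the error-decay check at n ∈ {500, 2000, 8000}. These sizes were chosen
as the smallest that make the statistical assertions sharp (e.g. null KS
averages well below 0.1 need ~10³ points per class).

## Known limitations

* The additive model cannot separate isomers by construction and degrades
  for larger, more polarizable (especially conjugated) systems, where
  polarizability grows non-additively.
* The Unsøld/QDO inverse-gap intuition is exact only for effective
  two-state systems; the package's own statistics show it does not transfer
  to chemically diverse sets.
* The Topping screen treats the adsorbed layer as point dipoles on an ideal
  square lattice with a coverage-independent enhancement factor; its
  absolute Δφ scale is a reporting convention (see above).
* Functional-group *detection* is out of scope: class labels are consumed
  as input (e.g. from a Checkmol/Open Babel workflow) or generated
  synthetically; no structure perception is performed.
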