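# Methods

## Thermal model

Downcore temperature is modelled as the steady state of one-dimensional
heat transport with conduction and upward pore-fluid advection,
κT″(z) + wT′(z) = 0, depth z in metres positive downward, T(0) = T_top
(bottom-water temperature), T(L) = T_bottom. The closed form is an
exponential profile controlled by the Peclet number Pe = wL/κ; Pe → 0
recovers the linear conductive limit, which the implementation switches to
below Pe = 10⁻¹². Pe > 700 is rejected (the exponential would over/underflow)
with advice to rescale.

Parameters and defaults: κ = 3×10⁻⁷ m² s⁻¹ (sandy sediments),
w = 0.021 m h⁻¹ (converted internally to m s⁻¹), L = 0.2 m, output
resolution dz = 10⁻⁴ m (100 µm). w < 0 (downward flow) is outside the
model's domain and rejected: the setting is hydrothermal discharge.

The finite-difference cross-check solves the same boundary-value problem
with second-order central differences (first-order upwinding engages if
the cell Peclet number w·dz/κ reaches 2, which the defaults never
approach), and by default Richardson-extrapolates solutions at dz and dz/2
to cancel the leading O(dz²) term. Plain central differences at 100 µm
leave ~8×10⁻⁶ °C of discretisation error at Pe ≈ 3.9; the extrapolated
solution agrees with the closed form to ~2×10⁻¹⁰ °C. The convergence test
uses the un-extrapolated solver so that the observed order (≈ 4× error
reduction per dz halving) is meaningful.

Fitting: with ≥ 2 probe readings below the surface, (w, T_bottom) are
estimated by bounded least squares (w ∈ [0, 1] m h⁻¹); with exactly one
interior reading and a supplied T_bottom, w is recovered by Brent
bracketing on the strictly monotone map w ↦ T(z₀). Zero-gradient data
(all readings at T_top) make w unidentifiable and raise an error rather
than returning an arbitrary value. Sampling horizons given in cm are
assigned the temperature at their midpoint by linear interpolation on the
model grid.

## Lipid nomenclature

Annotation strings follow a compact shorthand grammar
(`[headgroup-][Uns-][H-][nMe-]CORE[-rings|-Cren][(C:D/C:D)]`), parsed into
typed records (core type, headgroup, rings, extra methyls, double bonds,
acyl chains). Structural bounds are enforced at parse time: ≤ 5 rings for
regular GDGTs with the pentacyclic member written `-Cren` (crenarchaeol,
encoded as 5 ring-equivalents with a flag, since its fifth ring is a
cyclohexane), ≤ 4 rings and no crenarchaeol for H-shaped GDGTs, ≤ 2 extra
methyls for regular and ≤ 4 for H-shaped tetraethers, ≤ 4 double bonds
for unsaturated tetraethers. Archaeal polar headgroups are exclusively
glycosidic (G/2G); a name with no headgroup is a core (headgroup-free)
lipid, permitted only for archaeal species. Sphingolipid classes (sPA,
sPE, sPG, sPI and the unresolved sP-Uk1–4, kept as opaque tokens) pair
with a ceramide core; all other non-archaeal classes are diacylglycerol
lipids whose chains may be annotated per-chain `(16:0/18:1)` or sum-level
`(34:1)` (cardiolipin is collapsed to a summed two-chain composition).
Singly methylated species accept both the `Me` and `1Me` spellings; the
canonical serializer emits `Me` for regular and `1Me` for H-shaped
tetraethers, matching the printed class lists. Serialization round-trips:
`parse(canonical_name(s)) == s`. The 17 archaeal + 19 non-archaeal
compound-class labels ship as package data
(`data/class_registry.tsv`).

Bare `Uns-GDGT` names without a `:d` suffix parse as minimally
unsaturated (one double bond); the canonical form always writes the
`-rings:double_bonds` suffix.

## Quantification

concentration = (peak_response / IS_response) × IS_amount /
(RF(class) × dry_mass). The response factor multiplies the denominator: an
analyte class responding RF-fold stronger than the internal standard per
unit mass must be divided by RF. RFs are class-level with species-level
overrides accepted under the full annotation string; classes without an
entry fall back to RF = 1 with a logged warning. Non-detects are absent
rows; an explicit zero peak response is kept as a measured zero
concentration, which matters for diversity counting. Relative abundances
are computed per sample within three scopes (of total polar, within
domain, within compound class); core-pool lipids never enter polar
denominators, and zero-total groups emit no rows.

A single internal-standard scaling is assumed across chromatographic
methods; cross-method response differences are absorbed into the
class-level response factors.

## Structural indices

All tetraether indices are abundance-weighted means of a structural count
over a filtered pool — the standard ring-index convention, adopted here as
the normative definition for rings (Ring), double bonds (Uns) and extra
methyls (MIX), each computed for regular vs H-shaped GDGTs and for the
polar vs core pool separately (the core pool mirrors the polar split; the
two core families are not merged). Inclusion rules: unsaturated
tetraethers, annotated ring- and methyl-free, are excluded from Ring and
MIX denominators but define Uns together with their saturated
counterparts; crenarchaeol is excluded from the GDGT Ring index by
default because its fifth ring is not a cyclopentane (`include_cren=True`
admits it at 5 ring-equivalents). Weighted indices are scale-invariant
and bounded by the extremes of their count; both properties are tested,
and every index is checked against an independent brute-force oracle that
iterates parsed species records.

%H-GDGT is 100 × (H-GDGT + H-nMe-GDGT) / total archaeal polar lipids.
Lipid diversity counts distinct polar-pool species at nonzero
concentration per domain. Chain metrics are within-class weighted means
of the per-lipid totals (both chains summed — the default convention; a
per-chain alternative halves the totals). Undefined values (empty pools,
zero denominators) are carried as explicit missing values, never as
zeros.

## Correlation screen

Spearman's rho is the Pearson correlation of mid-ranks (ties averaged).
Two-sided p-values come from exact enumeration of all n! rank
permutations for tie-free n ≤ 9 (the observed |rho| is compared with a
10⁻¹² slack so ties at the observed value count), and otherwise from the
t-approximation t = rho·√((n−2)/(1−rho²)) on n−2 degrees of freedom; at
|rho| = 1, where t diverges, the exact enumeration bound 2/n! is reported.
Significance tiers use strict thresholds (p < 0.001 / 0.01 / 0.05, else
n.s.). Missing values are removed pairwise per index; indices with < 3
complete pairs or zero variance are flagged undefined rather than
guessed. No multiple-testing correction is applied to the tiers; a
Benjamini–Hochberg column is emitted as supplementary, non-normative
output.

## Synthetic data generator

The generator emulates the study design the analysis assumes: 5 stations,
2-cm horizons to 20 cm, one seeded horizon dropout (49 samples),
horizon-midpoint temperatures from the closed-form thermal model with
station bottom temperatures (20, 55, 75, 90, 101) °C, T_top = 18 °C,
w = 0.021 m h⁻¹ at the four vent-influenced stations and w = 0 at the
reference station. Probe tables are exact model values at 5-cm intervals.

Composition is built hierarchically at each sample temperature
(normalised to x ∈ [0,1] over 18–101 °C): a logistic archaeal share of
total polar lipids (0.25 → 0.85); a logistic H-shaped share of archaeal
lipids (0.05 → 0.75); binomial methylation of H-GDGTs with per-position
probability rising 0.05 → 0.60 in the polar pool and falling 0.40 → 0.10
in the core pool; flat polar-GDGT ring distribution (the configured null
trend) against a falling core-GDGT and rising H-GDGT ring distribution;
unimodal tetraether unsaturation peaking near 40 °C; sphingolipid class
totals peaking near 60 °C; bacterial chain-variant weights tilted
exponentially toward longer, more unsaturated chains as temperature rises
(reversed unsaturation for the G, PME and PDME classes); and a
deterministic richness thinning that removes rare bacterial chain
variants at high temperature, encoding declining bacterial diversity in
the means rather than only in the noise. These trend directions are
configuration (`TrendConfig`), not code constants, and are exported as
per-index signs in the ground truth.

Noise: class totals carry multiplicative log-normal noise (sd 0.3 on the
log scale); within-class weights are Dirichlet-jittered (concentration
50 × base weights); species below the detection limit are dropped as
absent rows. Magnitudes are order-of-magnitude choices for
sediment-lipid data (total polar pool 0.5 µg g⁻¹). The detection limit
defaults to 10⁻⁵ µg g⁻¹: a higher cut interacts with the composition
trends by truncating the rare high-ring tail preferentially where
archaeal totals are small (low temperature), which would leak a spurious
positive slope into the flat-configured ring index; 10⁻⁵ sits below that
interaction for the default concentration scale.

Peak responses are back-computed through the quantification formula with
known internal-standard amounts and a fixed class-level response-factor
table, so `quantify()` inverts the generator exactly (noise lives
upstream of peak encoding). Everything is driven by one integer seed; a
fixed seed reproduces byte-identical tables.

What the generator does *not* emulate: mass spectra, retention behaviour,
adducts and co-elution; annotation errors; degradation/preservation
kinetics of fossil lipids; spatial correlation between adjacent horizons
beyond the shared temperature profile; depth-dependence of total biomass.
Passing recovery tests therefore demonstrate that the pipeline's
statistics faithfully recover trends of the configured shapes and
magnitudes under compositional noise — not that real sediments exhibit
them.

## Problem sizes and numerical choices

Temperature profiles use 2,001 grid points (100 µm over 20 cm). The index
oracle comparison runs 1,000 random 20-species compositions at 10⁻¹²
relative tolerance. The Spearman null calibration enumerates 5,040
permutations per replicate for 2,000 seeded n = 7 replicates. The
end-to-end recovery study uses 100 seeded replicates of the 49-sample
design; each replicate runs the full generate → quantify → index → screen
chain (~1 s). Group fractions are validated to 10⁻¹² absolute; boundary
temperatures to 10⁻⁹ °C.

## Known limitations

- The exact-permutation path is limited to n ≤ 9 without ties; tied data
  always use the t-approximation, which is only asymptotically calibrated.
- Single-point velocity inversion requires an externally supplied bottom
  temperature; with only one reading, (w, T_bottom) are jointly
  unidentifiable.
- Class response factors are treated as known constants; uncertainty in
  the calibration table propagates directly into concentrations and is
  not modelled.
- The thermal model is 1-D, steady, and homogeneous in κ; tidal
  transients and lateral fluid pathways are out of scope.
- Core-lipid Ring/MIX indices are computed per core family (regular vs
  H-shaped) and never pooled; studies that merge the families will not be
  directly comparable.
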