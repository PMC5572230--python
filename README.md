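# thermolipids

Analysis pipeline for **microbial membrane-lipid adaptation along sediment
thermal gradients**, aimed at environmental lipidomics of hydrothermally
influenced marine sediments: sites where upward-venting pore fluids create
steep downcore temperature gradients (here 18–101 °C over 20 cm) and where
archaea and bacteria remodel their membrane lipids with temperature.

The package takes (a) sparse temperature-probe readings per station, (b)
annotated HPLC-MS lipid peak tables, and (c) a response-factor table, and
produces per-sample lipid concentrations, structural lipid indices, and a
rank-correlation screen of every index against in-situ temperature. A
seeded synthetic-data generator with known ground truth stands in for
field data, so the entire pipeline is testable end to end.

## What it computes

**Downcore temperature.** At steady state with upward pore-fluid velocity
*w* and thermal diffusivity *κ*, temperature obeys κT″ + wT′ = 0 with
Dirichlet boundaries, giving

T(z) = T_top + (T_bottom − T_top) · (1 − e^(−Pe·z/L)) / (1 − e^(−Pe)),  Pe = wL/κ.

With κ = 3×10⁻⁷ m² s⁻¹ (sandy sediment), w = 0.021 m h⁻¹ and L = 0.2 m,
Pe ≈ 3.89: steep near-surface warming that flattens downcore. The module
also fits (w, T_bottom) from probe readings — including the single-point
case (one interior reading plus boundaries), solved by bisection on the
monotone map w ↦ T(z₀).

**Quantification.** Peak responses are scaled by a co-extracted internal
standard (di-C21:0 PC convention) and a class response factor RF:

c = (peak/IS_response) · IS_amount / (RF · dry_mass)   [µg (g dry sed)⁻¹].

**Structural indices.** Abundance-weighted means over tetraether pools —
Ring (cyclopentane rings, 0–5 for GDGT / 0–4 for H-GDGT), Uns (double
bonds), MIX (extra biphytane methyls) — split by regular vs H-shaped core
and polar vs core pool; %H-GDGT of archaeal polar lipids; archaeal
fraction; per-domain lipid diversity; and within-class weighted mean chain
length and unsaturation for bacterial acyl-chain classes.

**Correlation screen.** Two-sided Spearman rank correlation of every index
against horizon-midpoint temperature, with exact permutation enumeration
for small tie-free n and the t-approximation otherwise, tiered as
p < 0.001 / 0.01 / 0.05 / n.s.

## Worked example

```python
import thermolipids as tl

# thermal model at the reference parameters
print(tl.ThermalModelParams().peclet)          # 3.8888888888888893

# invert w from a single 40 °C reading at 5 cm (boundaries 18/101 °C)
fit = tl.fit_profile([(0.05, 40.0)], t_top=18.0, t_bottom=101.0, length=0.2)
print(fit.params.w)                            # 0.0008564930819139111 m/h

# synthetic study: 5 stations x 2-cm horizons, 49 samples, 18-101 °C
ds = tl.generate_dataset(seed=7)
report = tl.recovery_report(ds)                # full pipeline + screen
print(report[report.index_name.isin(
    ['archaeal_fraction', 'pct_HGDGT', 'ring_GDGT_polar'])])
```

which prints (abridged):

```
       index_name  true_sign       rho  p_two_sided   n    tier
archaeal_fraction          1  0.981735 1.585104e-35  49 p<0.001
        pct_HGDGT          1  0.972653 1.888712e-31  49 p<0.001
  ring_GDGT_polar          0 -0.027245 8.525817e-01  49      ns
```

The archaeal share of polar lipids and the H-shaped tetraether percentage
rise strongly and significantly with temperature (their configured
generator trends), while the flat-configured polar GDGT ring index is
correctly non-significant.

The same run from a shell:

```sh
thermolipids run --seed 7 --out results/
```

writes `profiles.tsv`, `abundance.tsv`, `composition_by_class.tsv`,
`indices.tsv`, `correlations.tsv` and a heat-map-ready class × temperature
bin table. `thermolipids simulate`, `thermal`, `quantify`, `indices`,
`correlate` and `report` expose the individual stages.

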