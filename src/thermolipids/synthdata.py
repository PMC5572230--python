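"""Seeded synthetic datasets for a sediment thermal-gradient lipidomics study.

The generator emulates the statistical structure the analysis assumes:
five stations cored to 20 cm and sliced into 2-cm horizons (one horizon
dropped at random, for 49 samples), downcore temperatures from the steady
advection-diffusion model spanning 18-101 deg C, and a species-level lipid
composition whose class totals and within-class structural weights respond
to temperature through configurable monotone or unimodal trends:

* the archaeal share of polar lipids and the H-shaped tetraether share of
  archaeal lipids rise logistically with temperature;
* extra biphytane methylation of polar H-GDGTs rises (and of core H-GDGTs
  falls) with temperature, while the polar regular-GDGT ring distribution
  stays flat;
* tetraether unsaturation is unimodal around 40 deg C and sphingolipid
  classes peak near 60 deg C;
* bacterial acyl chains lengthen, and for most classes desaturate, with
  temperature, while bacterial species richness declines.

Species concentrations are class mean x Dirichlet-jittered within-class
weights x log-normal class noise, cut at a detection limit; peak responses
are back-computed through the internal-standard quantification formula
with known IS amounts and response factors, so quantification inverts the
generator exactly.  Everything is driven by one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nomenclature import NONARCHAEAL_CLASSES
from .thermal import ThermalModelParams, steady_profile_closed_form, temperature_at

__all__ = [
    "TrendConfig",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "recovery_report",
    "default_response_factors",
]


def _logistic(x: np.ndarray | float, lo: float, hi: float, mid: float, width: float):
    return lo + (hi - lo) / (1.0 + np.exp(-(x - mid) / width))


def _bump(x, lo: float, hi: float, mid: float, width: float):
    return lo + (hi - lo) * np.exp(-0.5 * ((x - mid) / width) ** 2)


def _binom_weights(n: int, p: float) -> np.ndarray:
    k = np.arange(n + 1)
    return np.array([math.comb(n, int(i)) for i in k]) * p**k * (1 - p) ** (n - k)


@dataclass(frozen=True)
class TrendConfig:
    """Temperature-response parameters of the generator.

    All logistic/bump positions are on the normalised temperature scale
    x = (T - 18) / (101 - 18).
    """

    # archaeal vs bacterial polar split (logistic increasing)
    arch_frac_lo: float = 0.25
    arch_frac_hi: float = 0.85
    arch_frac_mid: float = 0.45
    arch_frac_width: float = 0.15
    # H-shaped share of archaeal polar lipids (logistic increasing)
    h_share_lo: float = 0.05
    h_share_hi: float = 0.75
    h_share_mid: float = 0.50
    h_share_width: float = 0.12
    # unsaturated share of the polar GDGT pool (unimodal, peak ~40 deg C)
    uns_polar_lo: float = 0.02
    uns_polar_hi: float = 0.30
    uns_peak_c: float = 40.0
    uns_width_c: float = 12.0
    # per-biphytane-position methylation probabilities (Binomial(4, p))
    p_me_polar: tuple[float, float] = (0.05, 0.60)   # lo at 18 C, hi at 101 C
    p_me_core: tuple[float, float] = (0.40, 0.10)    # decreasing
    # per-position ring probabilities
    p_ring_gdgt_polar: tuple[float, float] = (0.30, 0.30)  # flat
    p_ring_gdgt_core: tuple[float, float] = (0.35, 0.15)   # decreasing
    p_ring_hgdgt: tuple[float, float] = (0.15, 0.40)       # increasing, both pools
    uns_core: tuple[float, float] = (0.25, 0.04)           # decreasing
    # bacterial chain-weight exponents (0 = uniform over variants)
    gamma_chain: tuple[float, float] = (0.0, 1.8)
    gamma_db_pos: tuple[float, float] = (0.0, 1.8)
    gamma_db_neg: tuple[float, float] = (0.9, -0.9)
    #: DAG classes whose unsaturation falls with temperature
    uns_negative_classes: tuple[str, ...] = ("G", "PME", "PDME")
    # deterministic richness thinning of bacterial chain variants
    richness_tau: tuple[float, float] = (0.03, 0.15)
    # sphingolipid class-total bump (peak ~60 deg C)
    sphingo_peak_c: float = 60.0
    sphingo_width_c: float = 15.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and noise model of the synthetic dataset."""

    n_stations: int = 5
    n_horizons: int = 10          # 2-cm slices to 20 cm
    horizon_cm: float = 2.0
    n_dropout: int = 1            # random horizons removed (49 samples total)
    t_top: float = 18.0
    t_bottoms: tuple[float, ...] = (20.0, 55.0, 75.0, 90.0, 101.0)
    w_m_h: tuple[float, ...] = (0.0, 0.021, 0.021, 0.021, 0.021)
    kappa: float = 3e-7
    dz: float = 1e-4
    probe_interval_cm: float = 5.0
    total_polar_ug_g: float = 0.5     # mean total polar lipid concentration
    core_pool_scale: float = 0.4      # archaeal core pool relative to polar
    class_noise_sd: float = 0.3       # log-normal sd on class totals
    dirichlet_strength: float = 50.0  # within-class compositional jitter
    detection_limit_ug_g: float = 1e-5
    is_response: float = 1e6
    is_amount_ug: float = 10.0
    dry_mass_g: tuple[float, float] = (30.0, 60.0)  # uniform range
    seed: int = 0
    trends: TrendConfig = field(default_factory=TrendConfig)

    def __post_init__(self):
        if len(self.t_bottoms) != self.n_stations or len(self.w_m_h) != self.n_stations:
            raise ValueError("t_bottoms and w_m_h must have one entry per station")
        if self.class_noise_sd < 0 or self.dirichlet_strength <= 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.n_dropout < self.n_stations * self.n_horizons:
            raise ValueError("n_dropout out of range")


#: configured monotone trend sign per index (+1 rising, -1 falling, 0 flat
#: or non-monotone); chain metrics are per-class and appended dynamically.
BASE_TREND_SIGNS: dict[str, int] = {
    "archaeal_fraction": +1,
    "pct_HGDGT": +1,
    "ring_GDGT_polar": 0,
    "ring_GDGT_core": -1,
    "ring_HGDGT_polar": +1,
    "ring_HGDGT_core": +1,
    "uns_GDGT_polar": 0,
    "uns_GDGT_core": -1,
    "mix_GDGT_polar": 0,
    "mix_GDGT_core": 0,
    "mix_HGDGT_polar": +1,
    "mix_HGDGT_core": -1,
    "archaeal_diversity": +1,
    "bacterial_diversity": -1,
}

_DAG_CLASSES = ("G", "SQ", "2G", "BL", "OL", "PDME", "PME", "PE", "PG", "PC", "CL")
_SPHINGO_CLASSES = ("sPA", "sP-Uk1", "sP-Uk2", "sP-Uk3", "sP-Uk4", "sPI", "sPE", "sPG")
#: bacterial class totals: falling, unimodal(OL), flat, sphingo bump
_FALLING_CLASSES = ("G", "SQ", "2G", "BL", "PDME", "PME", "PE", "PG")

_CHAIN_CARBONS = (30, 32, 34, 36)
_CHAIN_DB = (0, 1, 2)
_SPHINGO_CARBONS = (32, 34, 36)
_SPHINGO_DB = (0, 1)


def trend_signs(config: SyntheticConfig) -> dict[str, int]:
    """Configured sign of every index's temperature trend."""
    signs = dict(BASE_TREND_SIGNS)
    neg = set(config.trends.uns_negative_classes)
    for cls in _DAG_CLASSES + _SPHINGO_CLASSES:
        signs[f"chain_len_{cls}"] = +1
        signs[f"uns_{cls}"] = -1 if cls in neg else +1
    return signs


def _interp(pair: tuple[float, float], x: float) -> float:
    return pair[0] + (pair[1] - pair[0]) * x


def _mean_composition(temperature_c: float, cfg: SyntheticConfig) -> dict[str, float]:
    """Deterministic mean concentration (ug/g) of every species at one
    temperature.  Returns {annotation string: concentration}."""
    tr = cfg.trends
    x = float(np.clip((temperature_c - 18.0) / (101.0 - 18.0), 0.0, 1.0))
    out: dict[str, float] = {}

    total = cfg.total_polar_ug_g
    a = float(_logistic(x, tr.arch_frac_lo, tr.arch_frac_hi, tr.arch_frac_mid,
                        tr.arch_frac_width))
    arch_total, bact_total = total * a, total * (1.0 - a)

    # ---- archaeal polar pool -------------------------------------------
    h = float(_logistic(x, tr.h_share_lo, tr.h_share_hi, tr.h_share_mid,
                        tr.h_share_width))
    u = float(_bump(temperature_c, tr.uns_polar_lo, tr.uns_polar_hi,
                    tr.uns_peak_c, tr.uns_width_c))
    nonh_total = arch_total * (1.0 - h)
    nonh_shares = {
        "G-AR": 0.12, "G-GDGT": 0.42, "2G-GDGT": 0.10, "G-Uns-GDGT": u / (1 - u),
        "G-Me-GDGT": 0.12, "G-2Me-GDGT": 0.07, "2G-Me-GDGT": 0.05,
        "2G-2Me-GDGT": 0.03,
    }
    norm = sum(nonh_shares.values())
    p_ring = _interp(tr.p_ring_gdgt_polar, x)
    ring4 = _binom_weights(4, p_ring)
    ring2 = _binom_weights(2, p_ring)
    db_w = _binom_weights(3, 0.35)  # double-bond variants 1..4
    for cls, share in nonh_shares.items():
        cls_total = nonh_total * share / norm
        if cls == "G-AR":
            out["G-AR"] = cls_total
        elif cls == "G-Uns-GDGT":
            for d, wt in zip(range(1, 5), db_w):
                out[f"G-Uns-GDGT-0:{d}"] = cls_total * wt
        elif cls in ("G-GDGT", "2G-GDGT"):
            # ring variants 0..4 plus a crenarchaeol tail on the G form
            cren = 0.08 if cls == "G-GDGT" else 0.0
            for r, wt in zip(range(5), ring4):
                out[f"{cls}-{r}"] = cls_total * (1 - cren) * wt
            if cren:
                out[f"{cls}-Cren"] = cls_total * cren
        else:  # methylated regular GDGTs, rings 0..2
            for r, wt in zip(range(3), ring2):
                out[f"{cls}-{r}"] = cls_total * wt

    h_total = arch_total * h
    p_me = _interp(tr.p_me_polar, x)
    me_w = _binom_weights(4, p_me)
    ring_h = _binom_weights(2, _interp(tr.p_ring_hgdgt, x))
    for k, wk in enumerate(me_w):
        # diglycosidic H-forms observed only up to 3 extra methyls
        g_frac = 1.0 if k == 4 else 0.8
        for hg, frac in (("G", g_frac), ("2G", 1.0 - g_frac)):
            if frac == 0.0:
                continue
            cls = f"{hg}-H-GDGT" if k == 0 else f"{hg}-H-{k}Me-GDGT"
            for r, wr in zip(range(3), ring_h):
                out[f"{cls}-{r}"] = h_total * wk * frac * wr

    # ---- archaeal core pool --------------------------------------------
    core_total = arch_total * cfg.core_pool_scale
    core_h = core_total * h
    core_nonh = core_total * (1.0 - h)
    u_core = max(_interp(tr.uns_core, x), 0.0)
    ring4c = _binom_weights(4, _interp(tr.p_ring_gdgt_core, x))
    for r, wt in zip(range(5), ring4c):
        out[f"GDGT-{r}"] = core_nonh * (1 - u_core) * 0.92 * wt
    out["GDGT-Cren"] = core_nonh * (1 - u_core) * 0.08
    for d, wt in zip(range(1, 5), db_w):
        out[f"Uns-GDGT-0:{d}"] = core_nonh * u_core * wt
    me_wc = _binom_weights(4, _interp(tr.p_me_core, x))
    ring_hc = _binom_weights(2, _interp(tr.p_ring_hgdgt, x))
    for k, wk in enumerate(me_wc):
        cls = "H-GDGT" if k == 0 else f"H-{k}Me-GDGT"
        for r, wr in zip(range(3), ring_hc):
            out[f"{cls}-{r}"] = core_h * wk * wr

    # ---- bacterial polar pool ------------------------------------------
    shares: dict[str, float] = {}
    for cls in _DAG_CLASSES:
        if cls in _FALLING_CLASSES:
            shares[cls] = float(_logistic(x, 0.12, 0.02, 0.5, 0.15))
        elif cls == "OL":
            shares[cls] = float(_bump(temperature_c, 0.02, 0.12, 37.0, 12.0))
        else:  # PC, CL persist across the gradient
            shares[cls] = 0.10
    for cls in _SPHINGO_CLASSES:
        shares[cls] = float(
            _bump(temperature_c, 0.01, 0.08, tr.sphingo_peak_c, tr.sphingo_width_c)
        )
    share_norm = sum(shares.values())

    g_cl = _interp(tr.gamma_chain, x)
    tau = _interp(tr.richness_tau, x)
    for cls, share in shares.items():
        cls_total = bact_total * share / share_norm
        sphingo = cls in _SPHINGO_CLASSES
        carbons = _SPHINGO_CARBONS if sphingo else _CHAIN_CARBONS
        dbs = _SPHINGO_DB if sphingo else _CHAIN_DB
        g_db = _interp(
            tr.gamma_db_neg if cls in tr.uns_negative_classes else tr.gamma_db_pos, x
        )
        weights: dict[str, float] = {}
        for c in carbons:
            for d in dbs:
                wt = math.exp(g_cl * (c - 33) / 2.0 + g_db * d)
                if sphingo:
                    name = f"{cls}-CER({c - 16}:{d}/16:0)"
                else:
                    name = f"{cls}-DAG({c}:{d})"
                weights[name] = wt
        wsum = sum(weights.values())
        # deterministic richness thinning: rare variants fall out at high T
        kept = {n: w for n, w in weights.items() if w / wsum >= tau}
        ksum = sum(kept.values())
        for name, wt in kept.items():
            out[name] = cls_total * wt / ksum

    return out


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for recovery testing."""

    station_params: dict[str, ThermalModelParams]
    sample_temperature_c: pd.Series      # sample_id -> deg C
    trend_signs: dict[str, int]
    true_concentrations: pd.DataFrame    # sample_id, lipid, concentration_ug_g
    intended_concentrations: pd.DataFrame  # post-noise, pre-peak-encoding
    dropped_samples: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticDataset:
    peaks: pd.DataFrame
    metadata: pd.DataFrame
    probes: pd.DataFrame
    response_factors: pd.DataFrame
    ground_truth: GroundTruth
    config: SyntheticConfig


def default_response_factors() -> pd.DataFrame:
    """Class-level response factors: a fixed laboratory calibration table
    cycling through plausible values (the IS itself defines RF = 1)."""
    from .nomenclature import ARCHAEAL_CLASSES

    cycle = (0.8, 1.0, 1.25, 1.5, 0.9)
    labels = list(ARCHAEAL_CLASSES) + list(NONARCHAEAL_CLASSES)
    # archaeal core classes share the label of their headgroup-free family
    labels += ["GDGT", "Uns-GDGT", "H-GDGT"] + [f"H-{k}Me-GDGT" for k in range(1, 5)]
    return pd.DataFrame(
        {"class_label": labels, "rf": [cycle[i % len(cycle)] for i in range(len(labels))]}
    )


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate one seeded synthetic dataset.

    Returns the peak table, sample metadata, probe readings and response
    factors consumed by the analysis pipeline, plus the ground truth
    (thermal parameters, per-sample temperatures, configured trend signs
    and the noise-free / intended concentrations).
    """
    cfg = config or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)

    # ---- thermal layer --------------------------------------------------
    stations = [f"S{i + 1}" for i in range(cfg.n_stations)]
    station_params: dict[str, ThermalModelParams] = {}
    profiles = {}
    probe_rows = []
    for st, tb, w in zip(stations, cfg.t_bottoms, cfg.w_m_h):
        params = ThermalModelParams(
            kappa=cfg.kappa, w=w, t_top=cfg.t_top, t_bottom=tb,
            length=cfg.n_horizons * cfg.horizon_cm / 100.0, dz=cfg.dz,
        )
        station_params[st] = params
        profiles[st] = steady_profile_closed_form(params, station=st)
        depth = 0.0
        while depth <= cfg.n_horizons * cfg.horizon_cm + 1e-9:
            probe_rows.append(
                (st, depth, temperature_at(profiles[st], depth, depth))
            )
            depth += cfg.probe_interval_cm
    probes = pd.DataFrame(probe_rows, columns=["station", "depth_cm", "temperature_C"])

    # ---- samples --------------------------------------------------------
    all_samples = []
    for st in stations:
        for i in range(cfg.n_horizons):
            top = i * cfg.horizon_cm
            bottom = top + cfg.horizon_cm
            sid = f"{st}_{int(top):02d}-{int(bottom):02d}"
            all_samples.append((sid, st, top, bottom))
    drop_idx = rng.choice(len(all_samples), size=cfg.n_dropout, replace=False)
    dropped = tuple(all_samples[i][0] for i in sorted(drop_idx))
    samples = [s for i, s in enumerate(all_samples) if i not in set(drop_idx)]

    temps = pd.Series(
        {sid: temperature_at(profiles[st], top, bottom)
         for sid, st, top, bottom in samples},
        name="temperature_C",
    )

    # ---- composition layer ---------------------------------------------
    rf_table = default_response_factors()
    rf_map = dict(zip(rf_table["class_label"], rf_table["rf"]))
    from .quantification import _species_info  # class lookup shares the cache

    true_rows, noisy_rows, peak_rows, meta_rows = [], [], [], []
    for sid, st, top, bottom in samples:
        t_c = float(temps[sid])
        mean = _mean_composition(t_c, cfg)
        dry_mass = float(rng.uniform(*cfg.dry_mass_g))
        meta_rows.append(
            (sid, st, top, bottom, cfg.is_response, cfg.is_amount_ug, dry_mass)
        )
        # group species by compound class for the noise model
        by_class: dict[str, list[tuple[str, float]]] = {}
        for name, conc in mean.items():
            if conc <= 0:
                continue
            cls = _species_info(name)[2]
            by_class.setdefault(cls, []).append((name, conc))
            if conc >= cfg.detection_limit_ug_g:
                true_rows.append((sid, name, conc))
        for cls, members in by_class.items():
            names = [n for n, _ in members]
            w = np.array([c for _, c in members])
            cls_total = w.sum() * float(
                rng.lognormal(0.0, cfg.class_noise_sd)
            )
            if len(names) == 1:
                jitter = np.ones(1)
            else:
                jitter = rng.dirichlet(cfg.dirichlet_strength * w / w.sum())
            conc = cls_total * jitter
            for name, c in zip(names, conc):
                if c < cfg.detection_limit_ug_g:
                    continue  # below detection: absent row
                noisy_rows.append((sid, name, c))
                rf = rf_map.get(name, rf_map.get(cls, 1.0))
                peak = c * rf * dry_mass / cfg.is_amount_ug * cfg.is_response
                peak_rows.append((sid, name, peak))

    peaks = pd.DataFrame(peak_rows, columns=["sample_id", "lipid", "peak_response"])
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "station", "depth_top_cm", "depth_bottom_cm",
                 "is_response", "is_amount_ug", "dry_mass_g"],
    )
    truth = GroundTruth(
        station_params=station_params,
        sample_temperature_c=temps,
        trend_signs=trend_signs(cfg),
        true_concentrations=pd.DataFrame(
            true_rows, columns=["sample_id", "lipid", "concentration_ug_g"]
        ),
        intended_concentrations=pd.DataFrame(
            noisy_rows, columns=["sample_id", "lipid", "concentration_ug_g"]
        ),
        dropped_samples=dropped,
    )
    return SyntheticDataset(peaks, metadata, probes, rf_table, truth, cfg)


def recovery_report(dataset: SyntheticDataset) -> pd.DataFrame:
    """Run the full analysis on a synthetic dataset and tabulate, per
    index, the configured trend sign against the estimated correlation.

    Columns: ``index_name, true_sign, rho, p_two_sided, n, tier, method,
    sign_match`` (sign_match is NaN for indices configured flat).
    """
    from .indices import compute_index_table
    from .quantification import quantify
    from .stats import correlation_screen

    abundance = quantify(dataset.peaks, dataset.metadata, dataset.response_factors)
    index_table = compute_index_table(abundance)
    screen = correlation_screen(index_table, dataset.ground_truth.sample_temperature_c)
    signs = dataset.ground_truth.trend_signs
    screen = screen.copy()
    screen["true_sign"] = screen["index_name"].map(signs)
    est_sign = np.sign(screen["rho"])
    screen["sign_match"] = np.where(
        screen["true_sign"].isin((1, -1)) & screen["rho"].notna(),
        est_sign == screen["true_sign"],
        np.nan,
    )
    cols = ["index_name", "true_sign", "rho", "p_two_sided", "n", "tier",
            "method", "sign_match"]
    return screen[cols]
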