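"""End-to-end orchestration: probes -> profiles -> abundances -> indices
-> correlations, with tabular (TSV) report output.

Every stage writes one machine-readable table:

* ``profiles.tsv``             fitted downcore temperature grids
* ``abundance.tsv``            per-sample lipid concentrations (ug/g)
* ``composition_by_class.tsv`` percent of total polar lipids per class
* ``indices.tsv``              long-format structural index table
* ``correlations.tsv``         Spearman screen against temperature

plus ``run_log.txt`` recording package/library versions, the seed and the
configuration used.  Inputs are either the three TSVs of a real study
(probe readings, peak table, sample metadata, optional response factors)
or a seeded synthetic dataset.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .indices import compute_index_table
from .nomenclature import load_class_registry
from .quantification import (
    quantify,
    read_peak_table,
    read_response_factors,
    read_sample_metadata,
    relative_abundance,
)
from .stats import correlation_screen
from .synthdata import SyntheticConfig, SyntheticDataset, generate_dataset
from .thermal import fit_profile, temperature_at

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "heatmap_table", "fit_station_profiles"]

DEFAULT_BINS = tuple(np.arange(18.0, 101.0 + 1e-9, 10.0)) + (101.0,)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str = "thermolipids_run"
    # input tables (None -> generate synthetically from `seed`)
    peaks_path: str | None = None
    metadata_path: str | None = None
    probes_path: str | None = None
    response_factors_path: str | None = None
    # thermal model
    kappa: float = 3e-7          # m^2 s^-1
    t_top: float = 18.0          # deg C; used when no 0-cm probe reading
    profile_dz: float = 1e-4     # m
    # index options
    include_cren: bool = False
    chain_convention: str = "total"
    # correlation options
    correlation_method: str = "auto"
    # heat-map table
    temperature_bins: tuple[float, ...] = DEFAULT_BINS
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "temperature_bins" in raw:
            raw["temperature_bins"] = tuple(raw["temperature_bins"])
        return cls(**raw)


def fit_station_profiles(
    probes: pd.DataFrame,
    kappa: float = 3e-7,
    t_top_default: float = 18.0,
    dz: float = 1e-4,
):
    """Fit one steady temperature profile per station from probe readings.

    The shallowest reading at 0 cm (if present) fixes the top boundary;
    remaining readings constrain (w, T_bottom) by least squares, or w
    alone by root finding when only a single interior reading exists
    (then the deepest/only reading also supplies T_bottom if at depth L).
    """
    from .thermal import steady_profile_closed_form

    profiles = {}
    reports = {}
    for st, grp in probes.groupby("station", sort=True):
        grp = grp.sort_values("depth_cm")
        depths_m = grp["depth_cm"].to_numpy(float) / 100.0
        temps = grp["temperature_C"].to_numpy(float)
        length = float(depths_m.max())
        if length <= 0:
            raise ValueError(f"station {st}: no downcore probe readings")
        if depths_m[0] == 0.0:
            t_top = float(temps[0])
            meas = list(zip(depths_m[1:], temps[1:]))
        else:
            t_top = t_top_default
            meas = list(zip(depths_m, temps))
        if len(meas) == 1 and meas[0][0] >= length - 1e-12:
            # single reading at the bottom: diffusive profile through it
            report = fit_profile([meas[0]], kappa=kappa, t_top=t_top,
                                 length=length, t_bottom=meas[0][1], dz=dz)
        else:
            report = fit_profile(meas, kappa=kappa, t_top=t_top,
                                 length=length, dz=dz)
        profiles[st] = steady_profile_closed_form(report.params, station=st)
        reports[st] = report
    return profiles, reports


def heatmap_table(
    composition: pd.DataFrame, bins: tuple[float, ...] = DEFAULT_BINS
) -> pd.DataFrame:
    """Mean percent-of-total-polar per compound class per temperature bin.

    ``composition`` needs columns ``sample_id, temperature_C,
    compound_class, pct_of_total_polar``.  Rows follow the compound-class
    registry order; empty bins are omitted (logged).  Bin intervals are
    left-closed, with the final edge included.
    """
    edges = np.asarray(sorted(set(bins)), float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    comp = composition.copy()
    idx = np.digitize(comp["temperature_C"], edges, right=False) - 1
    idx = np.where(
        np.isclose(comp["temperature_C"], edges[-1]), len(edges) - 2, idx
    )
    outside = (idx < 0) | (idx > len(edges) - 2)
    if outside.any():
        logger.info("heatmap_table: %d rows outside the bin range dropped",
                    int(outside.sum()))
        comp, idx = comp[~outside], idx[~outside]
    comp["bin_low_C"] = edges[idx]
    comp["bin_high_C"] = edges[idx + 1]
    # mean over samples in the bin: missing classes in a sample count as 0 %
    per_sample = comp.pivot_table(
        index=["bin_low_C", "bin_high_C", "sample_id"],
        columns="compound_class", values="pct_of_total_polar",
        aggfunc="sum", fill_value=0.0,
    )
    binned = per_sample.groupby(["bin_low_C", "bin_high_C"]).mean()
    long = binned.reset_index().melt(
        id_vars=["bin_low_C", "bin_high_C"],
        var_name="compound_class", value_name="mean_pct_of_total_polar",
    )
    order = dict(
        zip(load_class_registry()["class_label"], load_class_registry()["registry_order"])
    )
    long["registry_order"] = long["compound_class"].map(order)
    long = long.sort_values(
        ["bin_low_C", "registry_order", "compound_class"]
    ).drop(columns="registry_order")
    return long.reset_index(drop=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: RunConfig, dataset: SyntheticDataset | None = None
) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle.

    If no input paths are configured and no pre-built dataset is passed,
    a synthetic dataset is generated from ``config.seed``.  Returns the
    report tables keyed by output name.  Deterministic: identical inputs
    produce identical tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("inputs")
        if dataset is None and config.peaks_path is None:
            dataset = generate_dataset(SyntheticConfig(seed=config.seed))
        if dataset is not None:
            peaks, metadata, probes = dataset.peaks, dataset.metadata, dataset.probes
            rf = dataset.response_factors
        else:
            peaks = read_peak_table(config.peaks_path)
            metadata = read_sample_metadata(config.metadata_path)
            probes = pd.read_csv(config.probes_path, sep="\t")
            rf = (
                read_response_factors(config.response_factors_path)
                if config.response_factors_path
                else None
            )
            if rf is None:
                logger.warning("no response-factor table given; RF = 1 throughout")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    try:
        stage("thermal")
        profiles, fit_reports = fit_station_profiles(
            probes, kappa=config.kappa, t_top_default=config.t_top,
            dz=config.profile_dz,
        )
        profiles_tsv = pd.concat([p.to_frame() for p in profiles.values()])
        sample_temp = pd.Series(
            {
                row.sample_id: temperature_at(
                    profiles[row.station], row.depth_top_cm, row.depth_bottom_cm
                )
                for row in metadata.itertuples()
            },
            name="temperature_C",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'thermal' failed: {exc}") from exc

    try:
        stage("quantification")
        abundance = quantify(peaks, metadata, rf)
        comp = relative_abundance(abundance, "of_total")
        comp = comp[comp["pool"] == "polar"].copy()
        comp["pct_of_total_polar"] = 100.0 * comp["fraction"]
        comp["temperature_C"] = comp["sample_id"].map(sample_temp)
        comp_by_class = (
            comp.groupby(
                ["sample_id", "station", "temperature_C", "domain", "compound_class"],
                as_index=False,
            )["pct_of_total_polar"].sum()
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'quantification' failed: {exc}") from exc

    try:
        stage("indices")
        index_table = compute_index_table(
            abundance,
            include_cren=config.include_cren,
            chain_convention=config.chain_convention,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'indices' failed: {exc}") from exc

    try:
        stage("correlation")
        correlations = correlation_screen(
            index_table, sample_temp, method=config.correlation_method
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'correlation' failed: {exc}") from exc

    stage("report")
    heat = heatmap_table(comp_by_class, config.temperature_bins)
    tables = {
        "profiles": profiles_tsv,
        "abundance": abundance,
        "composition_by_class": comp_by_class,
        "indices": index_table,
        "correlations": correlations,
        "heatmap": heat,
    }
    for name, df in tables.items():
        _write(df, out / f"{name}.tsv")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"thermolipids {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config: {config}\n")
        for st, rep in fit_reports.items():
            fh.write(
                f"fit {st}: w={rep.params.w:.6g} m/h, "
                f"T_bottom={rep.params.t_bottom:.4f} C, method={rep.method}\n"
            )
    return tables
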