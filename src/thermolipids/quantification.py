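"""Internal-standard quantification of annotated lipid peak tables.

HPLC-MS peak responses are converted to absolute concentrations by scaling
against a co-extracted internal standard (IS) of known mass — here the
di-C21:0 phosphatidylcholine convention — correcting for the class response
factor (RF) and normalising to dry sediment mass:

    concentration = (peak_response / is_response) * is_amount
                    / (RF(class) * dry_mass)          [ug per g dry sediment]

The RF is the detector response per unit mass of an analyte class relative
to the IS; a class responding RF-fold stronger than the IS therefore
divides.  Tables are plain pandas DataFrames with documented columns, read
and written as TSV/CSV.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd

from .nomenclature import compound_class, parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "annotate_lipids",
    "quantify",
    "total_polar_lipids",
    "relative_abundance",
    "read_peak_table",
    "read_sample_metadata",
    "read_response_factors",
]

PEAK_COLUMNS = ("sample_id", "lipid", "peak_response")
METADATA_COLUMNS = (
    "sample_id", "station", "depth_top_cm", "depth_bottom_cm",
    "is_response", "is_amount_ug", "dry_mass_g",
)


@lru_cache(maxsize=4096)
def _species_info(name: str):
    sp = parse_lipid_name(name)
    return sp.domain.value, sp.pool.value, compound_class(sp)


def annotate_lipids(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``domain``, ``pool`` and ``compound_class`` columns derived from
    the ``lipid`` annotation strings (parse errors propagate)."""
    info = table["lipid"].map(_species_info)
    out = table.copy()
    out["domain"] = info.map(lambda t: t[0])
    out["pool"] = info.map(lambda t: t[1])
    out["compound_class"] = info.map(lambda t: t[2])
    return out


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns {sorted(missing)}")
    return df


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata {path} lacks columns {sorted(missing)}")
    return df


def read_response_factors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    missing = {"class_label", "rf"} - set(df.columns)
    if missing:
        raise ValueError(f"response-factor table {path} lacks columns {sorted(missing)}")
    return df


def quantify(
    peaks: pd.DataFrame,
    metadata: pd.DataFrame,
    response_factors: pd.DataFrame | dict | None = None,
) -> pd.DataFrame:
    """Convert peak responses to concentrations in ug per g dry sediment.

    Parameters
    ----------
    peaks
        Columns ``sample_id, lipid, peak_response`` (detector units >= 0).
    metadata
        One row per sample: ``sample_id, station, depth_top_cm,
        depth_bottom_cm, is_response, is_amount_ug, dry_mass_g``.
    response_factors
        Mapping or DataFrame (``class_label, rf``) of class-level response
        factors; species-level overrides may be given under the lipid's
        full annotation string.  Classes without an entry fall back to
        RF = 1 with a logged warning.

    Returns
    -------
    DataFrame with one row per (sample, lipid): the peak columns plus
    ``domain, pool, compound_class, station, depth_top_cm, depth_bottom_cm,
    concentration_ug_g``.
    """
    peaks = annotate_lipids(peaks)
    if peaks.duplicated(["sample_id", "lipid"]).any():
        dup = peaks[peaks.duplicated(["sample_id", "lipid"])].iloc[0]
        raise ValueError(
            f"duplicate peak row for sample {dup['sample_id']!r} lipid {dup['lipid']!r}"
        )
    if (peaks["peak_response"] < 0).any():
        raise ValueError("peak_response must be >= 0")

    meta = metadata.set_index("sample_id")
    unknown = set(peaks["sample_id"]) - set(meta.index)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    for col in ("is_response", "is_amount_ug", "dry_mass_g"):
        if meta[col].isna().any() or (meta[col] <= 0).any():
            raise ValueError(f"metadata column {col} must be present and > 0")

    if response_factors is None:
        rf_map: dict[str, float] = {}
    elif isinstance(response_factors, pd.DataFrame):
        rf_map = dict(zip(response_factors["class_label"], response_factors["rf"]))
    else:
        rf_map = dict(response_factors)
    if any(v <= 0 for v in rf_map.values()):
        raise ValueError("response factors must be > 0")

    def lookup_rf(row) -> float:
        # species-level override wins over class-level
        if row["lipid"] in rf_map:
            return float(rf_map[row["lipid"]])
        if row["compound_class"] in rf_map:
            return float(rf_map[row["compound_class"]])
        return np.nan

    rf = peaks.apply(lookup_rf, axis=1)
    missing_classes = sorted(peaks.loc[rf.isna(), "compound_class"].unique())
    if missing_classes:
        logger.warning(
            "no response factor for classes %s; assuming RF = 1", missing_classes
        )
    rf = rf.fillna(1.0)

    sm = meta.loc[peaks["sample_id"]]
    conc = (
        peaks["peak_response"].to_numpy()
        / sm["is_response"].to_numpy()
        * sm["is_amount_ug"].to_numpy()
        / (rf.to_numpy() * sm["dry_mass_g"].to_numpy())
    )
    out = peaks.copy()
    out["station"] = sm["station"].to_numpy()
    out["depth_top_cm"] = sm["depth_top_cm"].to_numpy()
    out["depth_bottom_cm"] = sm["depth_bottom_cm"].to_numpy()
    out["concentration_ug_g"] = conc
    return out.drop(columns=["peak_response"])


def total_polar_lipids(abundance: pd.DataFrame, sample_id) -> float:
    """Total polar-pool lipid concentration of one sample, ug per g."""
    if sample_id not in set(abundance["sample_id"]):
        raise KeyError(f"unknown sample {sample_id!r}")
    rows = abundance[
        (abundance["sample_id"] == sample_id) & (abundance["pool"] == "polar")
    ]
    return float(rows["concentration_ug_g"].sum())


def relative_abundance(abundance: pd.DataFrame, grouping: str = "of_total") -> pd.DataFrame:
    """Derive relative-abundance compositions from an abundance table.

    grouping
        ``of_total``      — fraction of the sample's total polar lipids;
        ``within_domain`` — fraction of the sample's archaeal (resp.
        non-archaeal) polar total;
        ``within_class``  — fraction of the lipid's compound-class total.

    Core-pool lipids are excluded from all polar denominators and carry
    their own within-class normalisation.  Groups whose total is zero emit
    no rows (logged).
    """
    if grouping not in ("of_total", "within_domain", "within_class"):
        raise ValueError(f"unknown grouping {grouping!r}")
    ab = abundance.copy()
    if grouping == "of_total":
        keys = ["sample_id", "pool"]
    elif grouping == "within_domain":
        keys = ["sample_id", "pool", "domain"]
    else:
        keys = ["sample_id", "pool", "compound_class"]
    totals = ab.groupby(keys)["concentration_ug_g"].transform("sum")
    zero = totals == 0
    if zero.any():
        dropped = ab.loc[zero, keys].drop_duplicates()
        logger.info(
            "relative_abundance(%s): %d group(s) with zero total emit no rows",
            grouping, len(dropped),
        )
    out = ab[~zero].copy()
    out["fraction"] = (
        out["concentration_ug_g"].to_numpy() / totals[~zero].to_numpy()
    )
    return out
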