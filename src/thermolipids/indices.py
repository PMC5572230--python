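"""Structural lipid indices for temperature-response screening.

Archaeal tetraether pools are summarised by abundance-weighted means of a
structural count — cyclopentane(-equivalent) rings (Ring index), double
bonds (Uns index) and additional biphytane methyl groups (MIX index) —
computed separately for regular and H-shaped GDGTs and for the polar
(headgroup-bearing) and core pools.  Bacterial acyl-chain classes are
summarised by within-class weighted mean chain length and unsaturation,
and each domain by its lipid diversity (number of distinct polar species
detected).  All weighted indices are scale-invariant in the concentrations
and bounded by the extremes of the underlying structural count.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

from .nomenclature import (
    CoreType,
    H_GDGT_CLASSES,
    parse_lipid_name,
)

__all__ = [
    "structural_table",
    "archaeal_fraction",
    "pct_hgdgt",
    "ring_index",
    "unsaturation_index",
    "mix_index",
    "lipid_diversity",
    "class_chain_metrics",
    "compute_index_table",
    "TETRAETHER_INDEX_NAMES",
]

#: (index_name, weighting column, core filter, pool) for the tetraether suite
TETRAETHER_INDEX_NAMES: tuple[tuple[str, str, str, str], ...] = (
    ("ring_GDGT_polar", "n_rings", "GDGT", "polar"),
    ("ring_GDGT_core", "n_rings", "GDGT", "core"),
    ("ring_HGDGT_polar", "n_rings", "H_GDGT", "polar"),
    ("ring_HGDGT_core", "n_rings", "H_GDGT", "core"),
    ("uns_GDGT_polar", "n_double_bonds", "GDGT", "polar"),
    ("uns_GDGT_core", "n_double_bonds", "GDGT", "core"),
    ("mix_GDGT_polar", "n_methyls", "GDGT", "polar"),
    ("mix_GDGT_core", "n_methyls", "GDGT", "core"),
    ("mix_HGDGT_polar", "n_methyls", "H_GDGT", "polar"),
    ("mix_HGDGT_core", "n_methyls", "H_GDGT", "core"),
)


@lru_cache(maxsize=4096)
def _structure(name: str):
    sp = parse_lipid_name(name)
    return (
        sp.core_type.value,
        sp.n_rings,
        int(sp.is_cren),
        sp.n_methyls,
        sp.n_double_bonds,
        sp.total_chain_carbons,
        len(sp.chains),
    )

_STRUCT_COLS = [
    "core_type", "n_rings", "is_cren", "n_methyls", "n_double_bonds",
    "chain_carbons", "n_chain_pairs",
]


def structural_table(abundance: pd.DataFrame) -> pd.DataFrame:
    """Annotated abundance table plus per-species structural count columns."""
    out = abundance.drop(columns=_STRUCT_COLS, errors="ignore").copy()
    struct = pd.DataFrame(
        [_structure(n) for n in out["lipid"]], columns=_STRUCT_COLS, index=out.index
    )
    return pd.concat([out, struct], axis=1)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    total = weights.sum()
    if total <= 0 or len(values) == 0:
        return math.nan, 0
    return float(np.dot(values, weights) / total), int((weights > 0).sum() or len(values))


def archaeal_fraction(sample: pd.DataFrame) -> tuple[float, int]:
    """Archaeal share of the total polar lipid concentration, in [0, 1]."""
    polar = sample[sample["pool"] == "polar"]
    total = polar["concentration_ug_g"].sum()
    if total <= 0:
        return math.nan, 0
    arch = polar.loc[polar["domain"] == "archaeal", "concentration_ug_g"].sum()
    return float(arch / total), int(len(polar))


def pct_hgdgt(sample: pd.DataFrame) -> tuple[float, int]:
    """Percentage of H-shaped tetraethers (incl. H-nMe) among archaeal
    polar lipids."""
    arch = sample[(sample["pool"] == "polar") & (sample["domain"] == "archaeal")]
    total = arch["concentration_ug_g"].sum()
    if total <= 0:
        return math.nan, 0
    h = arch.loc[
        arch["compound_class"].isin(H_GDGT_CLASSES), "concentration_ug_g"
    ].sum()
    return float(100.0 * h / total), int(len(arch))


def _tetraether_pool(
    sample: pd.DataFrame, core_filter: str, pool: str
) -> pd.DataFrame:
    core = CoreType.H_GDGT.value if core_filter in ("H_GDGT", "HGDGT") else CoreType.GDGT.value
    return sample[(sample["core_type"] == core) & (sample["pool"] == pool)]


def ring_index(
    sample: pd.DataFrame,
    core_filter: str = "GDGT",
    pool: str = "polar",
    include_cren: bool = False,
) -> tuple[float, int]:
    """Abundance-weighted mean number of cyclopentane-equivalent rings.

    Unsaturated tetraethers are excluded (they are annotated ring-free);
    crenarchaeol (whose fifth ring is a cyclohexane) is excluded unless
    ``include_cren``, in which case it enters with 5 ring-equivalents.
    """
    rows = _tetraether_pool(sample, core_filter, pool)
    rows = rows[rows["n_double_bonds"] == 0]
    if not include_cren:
        rows = rows[rows["is_cren"] == 0]
    return _weighted_mean(
        rows["n_rings"].to_numpy(float), rows["concentration_ug_g"].to_numpy(float)
    )


def unsaturation_index(
    sample: pd.DataFrame, core_filter: str = "GDGT", pool: str = "polar"
) -> tuple[float, int]:
    """Abundance-weighted mean number of double bonds over saturated and
    unsaturated tetraethers of the filtered core type."""
    rows = _tetraether_pool(sample, core_filter, pool)
    return _weighted_mean(
        rows["n_double_bonds"].to_numpy(float),
        rows["concentration_ug_g"].to_numpy(float),
    )


def mix_index(
    sample: pd.DataFrame, core_filter: str = "GDGT", pool: str = "polar"
) -> tuple[float, int]:
    """Abundance-weighted mean number of additional biphytane methyl groups
    over methylated and unmethylated tetraethers of the filtered core type
    (unsaturated species excluded, as for the Ring index)."""
    rows = _tetraether_pool(sample, core_filter, pool)
    rows = rows[rows["n_double_bonds"] == 0]
    return _weighted_mean(
        rows["n_methyls"].to_numpy(float), rows["concentration_ug_g"].to_numpy(float)
    )


def lipid_diversity(sample: pd.DataFrame, domain: str) -> tuple[float, int]:
    """Number of distinct polar lipid species detected (> 0 concentration)
    in the given domain.  Explicit zero concentrations are measured
    non-detections and do not count."""
    rows = sample[
        (sample["pool"] == "polar")
        & (sample["domain"] == domain)
        & (sample["concentration_ug_g"] > 0)
    ]
    n = int(rows["lipid"].nunique())
    return float(n), n


def class_chain_metrics(
    sample: pd.DataFrame, class_label: str, convention: str = "total"
) -> tuple[tuple[float, float], int]:
    """Within-class weighted mean (chain length, unsaturation) of an
    acyl-chain compound class.

    ``convention='total'`` sums over both chains of each lipid (the
    per-lipid total); ``'per_chain'`` halves the totals, treating every
    annotation as a two-chain lipid (sum-level CL included).
    """
    if convention not in ("total", "per_chain"):
        raise ValueError(f"unknown chain convention {convention!r}")
    rows = sample[
        (sample["compound_class"] == class_label) & (sample["pool"] == "polar")
    ]
    if len(rows) and not rows["core_type"].isin(
        (CoreType.DAG.value, CoreType.CERAMIDE.value)
    ).all():
        raise ValueError(f"class {class_label!r} is not an acyl-chain class")
    w = rows["concentration_ug_g"].to_numpy(float)
    cl, n = _weighted_mean(rows["chain_carbons"].to_numpy(float), w)
    db, _ = _weighted_mean(rows["n_double_bonds"].to_numpy(float), w)
    if convention == "per_chain" and not math.isnan(cl):
        cl, db = cl / 2.0, db / 2.0
    return (cl, db), n


def compute_index_table(
    abundance: pd.DataFrame,
    include_cren: bool = False,
    chain_convention: str = "total",
) -> pd.DataFrame:
    """Compute every structural index for every sample.

    Returns a long-format DataFrame ``sample_id, index_name, value,
    n_lipids_used`` with one row per defined (sample, index); undefined
    values (empty pools) are carried as NaN with ``n_lipids_used = 0``.
    Chain metrics produce one ``chain_len_<class>`` and one
    ``uns_<class>`` index per acyl-chain class observed anywhere in the
    table, so every sample reports the same index set.
    """
    table = structural_table(abundance)
    chain_classes = sorted(
        table.loc[
            table["core_type"].isin((CoreType.DAG.value, CoreType.CERAMIDE.value)),
            "compound_class",
        ].unique()
    )
    records: list[tuple] = []
    for sample_id, sample in table.groupby("sample_id", sort=True):
        def emit(name: str, value: float, n: int) -> None:
            records.append((sample_id, name, value, n))

        v, n = archaeal_fraction(sample)
        emit("archaeal_fraction", v, n)
        v, n = pct_hgdgt(sample)
        emit("pct_HGDGT", v, n)
        for name, _count, core, pool in TETRAETHER_INDEX_NAMES:
            if name.startswith("ring_"):
                v, n = ring_index(sample, core, pool, include_cren=include_cren)
            elif name.startswith("uns_"):
                v, n = unsaturation_index(sample, core, pool)
            else:
                v, n = mix_index(sample, core, pool)
            emit(name, v, n)
        v, n = lipid_diversity(sample, "archaeal")
        emit("archaeal_diversity", v, n)
        v, n = lipid_diversity(sample, "nonarchaeal")
        emit("bacterial_diversity", v, n)
        for cls in chain_classes:
            (cl, db), n = class_chain_metrics(sample, cls, convention=chain_convention)
            emit(f"chain_len_{cls}", cl, n)
            emit(f"uns_{cls}", db, n)
    return pd.DataFrame(
        records, columns=["sample_id", "index_name", "value", "n_lipids_used"]
    )
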