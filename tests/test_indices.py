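"""Structural index engine against an independent brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_abundance
from thermolipids.indices import (
    archaeal_fraction,
    class_chain_metrics,
    compute_index_table,
    lipid_diversity,
    mix_index,
    pct_hgdgt,
    ring_index,
    structural_table,
    unsaturation_index,
)
from thermolipids.nomenclature import CoreType, Pool, parse_lipid_name

# ---------------------------------------------------------------------------
# Brute-force oracle: iterate species records, no pandas, no shared code path
# ---------------------------------------------------------------------------

def oracle_weighted(rows, count_attr, core_type, pool, include_cren=False,
                    exclude_uns=True):
    num = den = 0.0
    for name, conc in rows:
        sp = parse_lipid_name(name)
        if sp.core_type is not core_type or sp.pool.value != pool:
            continue
        if exclude_uns and sp.n_double_bonds > 0:
            continue
        if count_attr == "n_rings" and sp.is_cren and not include_cren:
            continue
        num += getattr(sp, count_attr) * conc
        den += conc
    return num / den if den > 0 else math.nan


def oracle_uns(rows, core_type, pool):
    return oracle_weighted(rows, "n_double_bonds", core_type, pool,
                           exclude_uns=False)


def oracle_chain(rows, class_label):
    from thermolipids.nomenclature import compound_class

    num_c = num_d = den = 0.0
    for name, conc in rows:
        sp = parse_lipid_name(name)
        if sp.pool is not Pool.POLAR or compound_class(sp) != class_label:
            continue
        num_c += sp.total_chain_carbons * conc
        num_d += sp.total_chain_unsaturations * conc
        den += conc
    if den == 0:
        return math.nan, math.nan
    return num_c / den, num_d / den


def random_composition(rng, catalogue, k=25):
    names = rng.choice(catalogue, size=min(k, len(catalogue)), replace=False)
    return [(str(n), float(rng.lognormal(0, 1))) for n in names]


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

def test_ring_index_weighted_mean_example():
    ab = structural_table(make_abundance([("G-GDGT-0", 1.0), ("G-GDGT-4", 1.0)]))
    val, n = ring_index(ab, "GDGT", "polar")
    assert val == pytest.approx(2.0) and n == 2
    val, _ = ring_index(structural_table(make_abundance([("G-GDGT-0", 5.0)])))
    assert val == 0.0


def test_ring_index_cren_flag():
    ab = structural_table(make_abundance([("G-GDGT-0", 1.0), ("G-GDGT-Cren", 1.0)]))
    assert ring_index(ab, "GDGT", "polar", include_cren=False)[0] == 0.0
    assert ring_index(ab, "GDGT", "polar", include_cren=True)[0] == pytest.approx(2.5)


def test_unsaturation_index_example():
    ab = structural_table(
        make_abundance([("G-GDGT-0", 1.0), ("G-Uns-GDGT-0:4", 1.0)])
    )
    assert unsaturation_index(ab, "GDGT", "polar")[0] == pytest.approx(2.0)
    # adding a saturated species strictly decreases the index
    ab2 = structural_table(
        make_abundance(
            [("G-GDGT-0", 1.0), ("G-Uns-GDGT-0:4", 1.0), ("G-GDGT-1", 1.0)]
        )
    )
    assert unsaturation_index(ab2, "GDGT", "polar")[0] < 2.0


def test_mix_index_example():
    ab = structural_table(
        make_abundance([("G-H-GDGT-0", 1.0), ("G-H-2Me-GDGT-0", 1.0)])
    )
    assert mix_index(ab, "H_GDGT", "polar")[0] == pytest.approx(1.0)
    all4 = structural_table(make_abundance([("G-H-4Me-GDGT-0", 2.0)]))
    assert mix_index(all4, "H_GDGT", "polar")[0] == pytest.approx(4.0)


def test_archaeal_fraction_and_complement():
    ab = structural_table(
        make_abundance([("G-GDGT-0", 0.25), ("PC-DAG(32:1)", 0.75)])
    )
    val, _ = archaeal_fraction(ab)
    assert val == pytest.approx(0.25)
    all_arch = structural_table(make_abundance([("G-AR", 1.0)]))
    assert archaeal_fraction(all_arch)[0] == 1.0
    all_bact = structural_table(make_abundance([("PC-DAG(32:1)", 1.0)]))
    assert archaeal_fraction(all_bact)[0] == 0.0


def test_pct_hgdgt_scope():
    ab = structural_table(
        make_abundance([("G-H-GDGT-0", 1.0), ("G-GDGT-0", 3.0)])
    )
    assert pct_hgdgt(ab)[0] == pytest.approx(25.0)
    # bacterial lipids leave the value unchanged
    ab2 = structural_table(
        make_abundance(
            [("G-H-GDGT-0", 1.0), ("G-GDGT-0", 3.0), ("PC-DAG(32:1)", 10.0)]
        )
    )
    assert pct_hgdgt(ab2)[0] == pytest.approx(25.0)
    only_h = structural_table(make_abundance([("2G-H-3Me-GDGT-1", 1.0)]))
    assert pct_hgdgt(only_h)[0] == pytest.approx(100.0)


def test_lipid_diversity_rules():
    ab = structural_table(
        make_abundance(
            [("G-AR", 1.0), ("G-GDGT-0", 0.5), ("G-GDGT-1", 0.2),
             ("2G-GDGT-0", 0.0),      # explicit zero: measured, not counted
             ("GDGT-0", 1.0),          # core pool: not counted
             ("PC-DAG(32:1)", 1.0)]
        )
    )
    assert lipid_diversity(ab, "archaeal")[0] == 3
    assert lipid_diversity(ab, "nonarchaeal")[0] == 1


def test_class_chain_metrics_examples():
    ab = structural_table(make_abundance([("PC-DAG(32:1)", 1.0)]))
    (cl, db), n = class_chain_metrics(ab, "PC")
    assert (cl, db) == (32.0, 1.0) and n == 1
    ab = structural_table(
        make_abundance([("PC-DAG(30:0)", 1.0), ("PC-DAG(34:2)", 1.0)])
    )
    (cl, db), _ = class_chain_metrics(ab, "PC")
    assert cl == pytest.approx(32.0) and db == pytest.approx(1.0)
    # adding OL lipids changes no PC metric
    ab2 = structural_table(
        make_abundance(
            [("PC-DAG(30:0)", 1.0), ("PC-DAG(34:2)", 1.0), ("OL-DAG(36:3)", 9.0)]
        )
    )
    (cl2, db2), _ = class_chain_metrics(ab2, "PC")
    assert (cl2, db2) == (pytest.approx(cl), pytest.approx(db))
    (clh, dbh), _ = class_chain_metrics(ab, "PC", convention="per_chain")
    assert clh == pytest.approx(16.0) and dbh == pytest.approx(0.5)


def test_isoprenoid_class_rejected_for_chain_metrics():
    ab = structural_table(make_abundance([("G-GDGT-0", 1.0)]))
    with pytest.raises(ValueError, match="not an acyl-chain class"):
        class_chain_metrics(ab, "G-GDGT")


# ---------------------------------------------------------------------------
# Oracle equivalence and weighted-mean properties on random compositions
# ---------------------------------------------------------------------------

def test_weighted_indices_match_bruteforce_oracle(species_catalogue):
    rng = np.random.default_rng(42)
    for _ in range(200):
        rows = random_composition(rng, species_catalogue)
        ab = structural_table(make_abundance(rows))
        for core, key in ((CoreType.GDGT, "GDGT"), (CoreType.H_GDGT, "H_GDGT")):
            for pool in ("polar", "core"):
                pairs = [
                    (ring_index(ab, key, pool)[0],
                     oracle_weighted(rows, "n_rings", core, pool)),
                    (unsaturation_index(ab, key, pool)[0],
                     oracle_uns(rows, core, pool)),
                    (mix_index(ab, key, pool)[0],
                     oracle_weighted(rows, "n_methyls", core, pool)),
                ]
                for got, want in pairs:
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, rel=1e-12)
        (cl, db), _ = class_chain_metrics(ab, "PC")
        ocl, odb = oracle_chain(rows, "PC")
        for got, want in ((cl, ocl), (db, odb)):
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)


def test_scale_invariance_and_bounds(species_catalogue):
    rng = np.random.default_rng(9)
    for _ in range(50):
        rows = random_composition(rng, species_catalogue)
        scaled = [(n, c * 137.0) for n, c in rows]
        ab, ab_s = structural_table(make_abundance(rows)), structural_table(
            make_abundance(scaled)
        )
        for fn, args, bound in [
            (ring_index, ("GDGT", "polar"), (0, 5)),
            (ring_index, ("H_GDGT", "polar"), (0, 4)),
            (mix_index, ("GDGT", "polar"), (0, 2)),
            (mix_index, ("H_GDGT", "polar"), (0, 4)),
            (unsaturation_index, ("GDGT", "polar"), (0, 4)),
        ]:
            v1, v2 = fn(ab, *args)[0], fn(ab_s, *args)[0]
            if math.isnan(v1):
                assert math.isnan(v2)
                continue
            assert v1 == pytest.approx(v2, rel=1e-12)
            assert bound[0] <= v1 <= bound[1]


def test_diversity_monotone_under_new_species():
    rows = [("G-AR", 1.0), ("G-GDGT-0", 1.0)]
    base = lipid_diversity(structural_table(make_abundance(rows)), "archaeal")[0]
    grown = lipid_diversity(
        structural_table(make_abundance(rows + [("G-GDGT-3", 0.1)])), "archaeal"
    )[0]
    assert grown == base + 1


# ---------------------------------------------------------------------------
# Index table assembly
# ---------------------------------------------------------------------------

def test_compute_index_table_shape_and_stability(default_abundance):
    table = compute_index_table(default_abundance)
    n_samples = default_abundance["sample_id"].nunique()
    assert n_samples == 49
    counts = table.groupby("index_name")["sample_id"].count()
    assert (counts == n_samples).all()
    # permutation of input rows leaves the output identical
    shuffled = default_abundance.sample(frac=1.0, random_state=0)
    table2 = compute_index_table(shuffled)
    pd.testing.assert_frame_equal(
        table.reset_index(drop=True), table2.reset_index(drop=True)
    )


def test_all_bacterial_sample_has_missing_archaeal_indices():
    ab = structural_table(
        make_abundance([("PC-DAG(32:1)", 1.0), ("OL-DAG(30:0)", 0.5)])
    )
    table = compute_index_table(ab).set_index("index_name")
    assert math.isnan(table.loc["pct_HGDGT", "value"])
    assert math.isnan(table.loc["ring_GDGT_polar", "value"])
    assert table.loc["bacterial_diversity", "value"] == 2
    assert table.loc["archaeal_diversity", "value"] == 0
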