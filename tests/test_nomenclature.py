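"""Parser, serializer and classification of lipid annotation strings."""

import pytest
from hypothesis import given, settings, strategies as st

from thermolipids.nomenclature import (
    ARCHAEAL_CLASSES,
    NONARCHAEAL_CLASSES,
    CoreType,
    Domain,
    LipidParseError,
    LipidSerializationError,
    LipidSpecies,
    Pool,
    canonical_name,
    classify_domain,
    compound_class,
    load_class_registry,
    parse_lipid_name,
)


@pytest.mark.parametrize(
    "name, checks",
    [
        ("G-AR", dict(core_type=CoreType.AR_DIETHER, domain=Domain.ARCHAEAL,
                      pool=Pool.POLAR, n_rings=0)),
        ("2G-H-2Me-GDGT-1", dict(core_type=CoreType.H_GDGT, n_methyls=2, n_rings=1)),
        ("PC-DAG(16:0/18:1)", dict(core_type=CoreType.DAG, domain=Domain.NONARCHAEAL,
                                   chains=((16, 0), (18, 1)), n_double_bonds=1)),
        ("G-GDGT-Cren", dict(n_rings=5, is_cren=True)),
        ("G-Uns-GDGT-0:3", dict(core_type=CoreType.GDGT, n_double_bonds=3, n_rings=0)),
        ("GDGT-0", dict(pool=Pool.CORE, domain=Domain.ARCHAEAL)),
        ("H-4Me-GDGT-2", dict(pool=Pool.CORE, n_methyls=4, n_rings=2)),
        ("sPG-CER(18:0/16:1)", dict(core_type=CoreType.CERAMIDE, n_double_bonds=1)),
        ("CL-DAG(64:2)", dict(chains=((64, 2),), domain=Domain.NONARCHAEAL)),
        ("sP-Uk2-CER(18:0/16:0)", dict(core_type=CoreType.CERAMIDE)),
    ],
)
def test_parse_populates_structural_fields(name, checks):
    sp = parse_lipid_name(name)
    for attr, expected in checks.items():
        assert getattr(sp, attr) == expected, attr


@pytest.mark.parametrize(
    "bad",
    [
        "G-H-GDGT-5",        # H-GDGT rings exceed 4
        "G-GDGT-6",          # rings exceed 5
        "G-GDGT-5",          # pentacyclic must be written -Cren
        "G-3Me-GDGT-0",      # regular GDGT methyls exceed 2
        "H-5Me-GDGT-0",      # H-GDGT methyls exceed 4
        "G-Uns-GDGT-0:5",    # double bonds exceed 4
        "G-H-Cren",          # malformed core token
        "g-AR",              # case-sensitive tokens
        "PC-DAG",            # missing chains
        "PC-GDGT-0",         # phospho headgroup on an archaeal core
        "DAG(16:0/18:1)",    # non-archaeal lipids have no core pool
        "G-AR-1",            # archaeol carries no rings
        "sPE-DAG(16:0/18:1)",  # sphingo headgroup requires ceramide core
        "H-GDGT-Cren",       # crenarchaeol is not H-shaped
        "",
    ],
)
def test_parse_rejects_invalid_names(bad):
    with pytest.raises(LipidParseError):
        parse_lipid_name(bad)


def test_parse_error_names_token_and_position():
    with pytest.raises(LipidParseError, match="rings exceed 4"):
        parse_lipid_name("G-H-GDGT-5")
    err = None
    try:
        parse_lipid_name("G-H-GDGT-5")
    except LipidParseError as exc:
        err = exc
    assert err.token == "5" and err.position == len("G-H-GDGT-")


def test_round_trip_on_full_catalogue(species_catalogue):
    for name in species_catalogue:
        sp = parse_lipid_name(name)
        assert canonical_name(sp) == name
        assert parse_lipid_name(canonical_name(sp)) == sp


def test_alternate_methyl_spellings_normalise():
    # 'G-1Me-GDGT' and 'G-Me-GDGT' denote the same monomethylated species
    assert parse_lipid_name("G-1Me-GDGT-0") == parse_lipid_name("G-Me-GDGT-0")
    assert canonical_name(parse_lipid_name("G-1Me-GDGT-0")) == "G-Me-GDGT-0"
    assert canonical_name(parse_lipid_name("G-H-Me-GDGT-0")) == "G-H-1Me-GDGT-0"


def test_serialize_rejects_invariant_violations():
    with pytest.raises(LipidSerializationError):
        canonical_name(LipidSpecies(core_type=CoreType.GDGT, n_rings=7))
    with pytest.raises(LipidSerializationError):
        canonical_name(LipidSpecies(core_type=CoreType.H_GDGT, is_cren=True, n_rings=4))
    with pytest.raises(LipidSerializationError):
        canonical_name(LipidSpecies(core_type=CoreType.DAG))  # chains required


def test_compound_class_partitions_catalogue(species_catalogue):
    """Every species maps to exactly one class; the polar fixture classes
    recover the full 17 + 19 registry."""
    seen_arch, seen_bact = set(), set()
    for name in species_catalogue:
        sp = parse_lipid_name(name)
        cls = compound_class(sp)
        assert isinstance(cls, str) and cls
        if sp.pool is Pool.POLAR:
            if classify_domain(sp) is Domain.ARCHAEAL:
                assert cls in ARCHAEAL_CLASSES
                seen_arch.add(cls)
            else:
                assert cls in NONARCHAEAL_CLASSES
                seen_bact.add(cls)
    assert seen_arch == set(ARCHAEAL_CLASSES) and len(seen_arch) == 17
    assert seen_bact == set(NONARCHAEAL_CLASSES) and len(seen_bact) == 19


def test_registry_matches_class_constants():
    reg = load_class_registry()
    assert len(reg) == 36
    arch = reg[reg["domain"] == "archaeal"]["class_label"].tolist()
    bact = reg[reg["domain"] == "nonarchaeal"]["class_label"].tolist()
    assert arch == list(ARCHAEAL_CLASSES)
    assert bact == list(NONARCHAEAL_CLASSES)


def test_classify_domain_examples():
    assert classify_domain(parse_lipid_name("G-AR")) is Domain.ARCHAEAL
    assert classify_domain(parse_lipid_name("sPI-CER(18:0/16:0)")) is Domain.NONARCHAEAL
    assert classify_domain(parse_lipid_name("CL-DAG(32:1/32:1)")) is Domain.NONARCHAEAL


@settings(max_examples=300, derandomize=True)
@given(data=st.data())
def test_single_token_mutations_rejected_or_distinct(data):
    """Mutating one character of a valid name either fails to parse or
    parses to a different species (the grammar has no silent aliases
    beyond the documented methyl spellings)."""
    names = [
        "G-AR", "2G-H-2Me-GDGT-1", "G-GDGT-Cren", "PC-DAG(16:0/18:1)",
        "sPG-CER(18:0/16:1)", "G-Uns-GDGT-0:3", "H-4Me-GDGT-2",
    ]
    name = data.draw(st.sampled_from(names))
    pos = data.draw(st.integers(min_value=0, max_value=len(name) - 1))
    repl = data.draw(st.sampled_from("GH2Ms-:()015xq"))
    mutated = name[:pos] + repl + name[pos + 1:]
    if mutated == name:
        return
    original = parse_lipid_name(name)
    try:
        sp = parse_lipid_name(mutated)
    except LipidParseError:
        return
    # '1Me'/'Me' are documented alternate spellings of the same species
    if sp == original:
        assert canonical_name(sp) != mutated
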