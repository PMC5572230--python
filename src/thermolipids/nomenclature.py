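"""Lipid data model and annotation-string grammar.

Environmental lipidomics studies report intact polar lipids (IPLs) and core
lipids with a compact shorthand, e.g. ``2G-H-2Me-GDGT-1`` for a diglycosidic
H-shaped dimethylated tetraether with one cyclopentane ring, or
``PC-DAG(16:0/18:1)`` for a phosphatidylcholine diacylglycerol lipid.  This
module defines a typed structural record for one lipid species and a strict,
round-tripping parser/serializer for the shorthand.

Grammar (tokens are case-sensitive, joined by ``-``)::

    name     := [headgroup-] [Uns-] [H-] [nMe-] CORE [ringsuffix] [chains]
    headgroup:= G | 2G | SQ | BL | OL | PA | PE | PME | PDME | PG | PC | PI
               | CL | sPA | sPE | sPG | sPI | sP-Uk1..sP-Uk4
    CORE     := AR | GDGT | DAG | CER
    ringsuffix := -<r>            (r cyclopentane rings, tetraethers only)
                | -Cren          (crenarchaeol: 4 cyclopentane + 1 cyclohexane)
                | -<r>:<d>       (unsaturated tetraethers: rings + double bonds)
    chains   := (C:D/C:D) | (C:D)   (acyl/sphingoid chains; sum-level allowed)

Archaeal cores are ``AR`` (archaeol, a C20/C20 diether) and ``GDGT``
(optionally ``H``-shaped, methylated or unsaturated); ``DAG`` and ``CER``
(ceramide, used by the sphingolipid classes) are non-archaeal.  A name with
no headgroup denotes a core (headgroup-free) lipid, which the grammar
permits only for archaeal species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable

__all__ = [
    "Domain",
    "Pool",
    "CoreType",
    "Phospho",
    "Amino",
    "HeadgroupSpec",
    "LipidSpecies",
    "LipidParseError",
    "LipidSerializationError",
    "parse_lipid_name",
    "canonical_name",
    "classify_domain",
    "compound_class",
    "load_class_registry",
    "ARCHAEAL_CLASSES",
    "NONARCHAEAL_CLASSES",
]


class Domain(str, Enum):
    ARCHAEAL = "archaeal"
    NONARCHAEAL = "nonarchaeal"


class Pool(str, Enum):
    POLAR = "polar"
    CORE = "core"


class CoreType(str, Enum):
    AR_DIETHER = "AR_diether"
    GDGT = "GDGT"
    H_GDGT = "H_GDGT"
    DAG = "DAG"
    CERAMIDE = "ceramide"


class Phospho(str, Enum):
    NONE = "none"
    PA = "PA"
    PE = "PE"
    PME = "PME"
    PDME = "PDME"
    PG = "PG"
    PC = "PC"
    PI = "PI"
    CL = "CL"


class Amino(str, Enum):
    NONE = "none"
    OL = "OL"
    BL = "BL"


class LipidParseError(ValueError):
    """Raised when an annotation string violates the grammar.

    Carries the offending token and its character position in the input.
    """

    def __init__(self, name: str, token: str, position: int, reason: str):
        self.name = name
        self.token = token
        self.position = position
        self.reason = reason
        super().__init__(
            f"cannot parse lipid name {name!r}: {reason} "
            f"(token {token!r} at position {position})"
        )


class LipidSerializationError(ValueError):
    """Raised when a species record violates a structural invariant."""


@dataclass(frozen=True)
class HeadgroupSpec:
    """Polar headgroup of one lipid species.

    The empty headgroup (all fields at their defaults) marks a core lipid.
    ``opaque_label`` holds class tokens whose structure is unresolved
    (the glycosylated phosphatidyl sphingolipids sP-Uk1..4).
    """

    n_glycosyl: int = 0
    phospho: Phospho = Phospho.NONE
    amino: Amino = Amino.NONE
    sulfo: bool = False
    is_sphingo_variant: bool = False
    opaque_label: str | None = None

    @property
    def is_empty(self) -> bool:
        return (
            self.n_glycosyl == 0
            and self.phospho is Phospho.NONE
            and self.amino is Amino.NONE
            and not self.sulfo
            and self.opaque_label is None
        )

    def validate(self) -> None:
        if self.n_glycosyl not in (0, 1, 2):
            raise LipidSerializationError(
                f"n_glycosyl must be 0, 1 or 2, got {self.n_glycosyl}"
            )
        exclusive = sum(
            [
                self.phospho is not Phospho.NONE,
                self.amino is not Amino.NONE,
                self.sulfo,
                self.opaque_label is not None,
            ]
        )
        if exclusive > 1:
            raise LipidSerializationError(
                "at most one of phospho/amino/sulfo/opaque per headgroup"
            )
        if exclusive and self.n_glycosyl and self.opaque_label is None:
            raise LipidSerializationError(
                "glycosyl count combines only with the opaque sphingolipid tokens"
            )


EMPTY_HEADGROUP = HeadgroupSpec()

_ARCHAEAL_CORES = frozenset({CoreType.AR_DIETHER, CoreType.GDGT, CoreType.H_GDGT})
_CHAIN_CORES = frozenset({CoreType.DAG, CoreType.CERAMIDE})


@dataclass(frozen=True)
class LipidSpecies:
    """Structural record of one annotated lipid species."""

    core_type: CoreType
    headgroup: HeadgroupSpec = EMPTY_HEADGROUP
    n_rings: int = 0
    is_cren: bool = False
    n_methyls: int = 0
    n_double_bonds: int = 0
    chains: tuple[tuple[int, int], ...] = ()

    @property
    def domain(self) -> Domain:
        return classify_domain(self)

    @property
    def pool(self) -> Pool:
        return Pool.CORE if self.headgroup.is_empty else Pool.POLAR

    @property
    def canonical_name(self) -> str:
        return canonical_name(self)

    @property
    def is_unsaturated_tetraether(self) -> bool:
        return self.core_type is CoreType.GDGT and self.n_double_bonds > 0

    @property
    def total_chain_carbons(self) -> int:
        return sum(c for c, _ in self.chains)

    @property
    def total_chain_unsaturations(self) -> int:
        return sum(d for _, d in self.chains)

    def validate(self) -> None:
        """Check every structural invariant; raise LipidSerializationError."""
        self.headgroup.validate()
        ct = self.core_type
        if ct is CoreType.GDGT:
            if not 0 <= self.n_rings <= 5:
                raise LipidSerializationError(
                    f"GDGT ring count {self.n_rings} outside 0..5"
                )
            if self.is_cren and self.n_rings != 5:
                raise LipidSerializationError("crenarchaeol implies 5 ring-equivalents")
            if self.n_rings == 5 and not self.is_cren:
                raise LipidSerializationError(
                    "pentacyclic GDGT is encoded as crenarchaeol (is_cren=True)"
                )
            if self.n_methyls > 2:
                raise LipidSerializationError(
                    f"regular GDGT carries at most 2 extra methyls, got {self.n_methyls}"
                )
            if self.n_double_bonds > 4:
                raise LipidSerializationError(
                    f"unsaturated tetraethers carry at most 4 double bonds, "
                    f"got {self.n_double_bonds}"
                )
            if self.n_double_bonds and self.n_methyls:
                raise LipidSerializationError(
                    "unsaturated and methylated GDGT variants are mutually exclusive"
                )
        elif ct is CoreType.H_GDGT:
            if not 0 <= self.n_rings <= 4:
                raise LipidSerializationError(
                    f"H-GDGT ring count {self.n_rings} outside 0..4"
                )
            if self.is_cren:
                raise LipidSerializationError("H-GDGT cannot be crenarchaeol")
            if self.n_methyls > 4:
                raise LipidSerializationError(
                    f"H-GDGT carries at most 4 extra methyls, got {self.n_methyls}"
                )
            if self.n_double_bonds:
                raise LipidSerializationError("H-GDGT variants are saturated")
        else:
            if self.n_rings or self.is_cren:
                raise LipidSerializationError(f"{ct.value} carries no rings")
            if self.n_methyls:
                raise LipidSerializationError(
                    "extra biphytane methyls occur only on GDGT/H-GDGT"
                )
        if ct in _CHAIN_CORES:
            if not self.chains:
                raise LipidSerializationError(f"{ct.value} requires acyl chains")
            if len(self.chains) > 2:
                raise LipidSerializationError("at most 2 chain pairs (sum-level for CL)")
            if any(c <= 0 or d < 0 for c, d in self.chains):
                raise LipidSerializationError("chain (C:D) must have C>0, D>=0")
            if self.n_double_bonds != self.total_chain_unsaturations:
                raise LipidSerializationError(
                    "n_double_bonds must equal the summed chain unsaturations"
                )
            if self.headgroup.is_empty:
                raise LipidSerializationError("core pool exists only for archaeal lipids")
        elif self.chains:
            raise LipidSerializationError("isoprenoidal cores carry no acyl chains")
        if ct is CoreType.AR_DIETHER and self.n_double_bonds:
            raise LipidSerializationError("archaeol is saturated")
        if ct in _ARCHAEAL_CORES and not self.headgroup.is_empty:
            if self.headgroup.n_glycosyl not in (1, 2) or not (
                self.headgroup.phospho is Phospho.NONE
                and self.headgroup.amino is Amino.NONE
                and not self.headgroup.sulfo
                and self.headgroup.opaque_label is None
            ):
                raise LipidSerializationError(
                    "archaeal polar lipids carry glycosidic headgroups only (G or 2G)"
                )
        if ct is CoreType.CERAMIDE and not (
            self.headgroup.is_sphingo_variant or self.headgroup.opaque_label
        ):
            raise LipidSerializationError(
                "ceramide cores pair with sphingolipid headgroups (sPX / sP-UkN)"
            )
        if self.headgroup.is_sphingo_variant and ct is not CoreType.CERAMIDE:
            raise LipidSerializationError("sphingolipid headgroups require a ceramide core")


# --------------------------------------------------------------------------
# Headgroup token table
# --------------------------------------------------------------------------

_SPHINGO_PHOSPHO = {"sPA": Phospho.PA, "sPE": Phospho.PE, "sPG": Phospho.PG,
                    "sPI": Phospho.PI}

_PHOSPHO_TOKENS = {p.value: p for p in Phospho if p is not Phospho.NONE}

_OPAQUE_TOKENS = ("sP-Uk1", "sP-Uk2", "sP-Uk3", "sP-Uk4")


def _headgroup_from_token(token: str) -> HeadgroupSpec | None:
    if token == "G":
        return HeadgroupSpec(n_glycosyl=1)
    if token == "2G":
        return HeadgroupSpec(n_glycosyl=2)
    if token == "SQ":
        return HeadgroupSpec(sulfo=True)
    if token in ("OL", "BL"):
        return HeadgroupSpec(amino=Amino(token))
    if token in _PHOSPHO_TOKENS:
        return HeadgroupSpec(phospho=_PHOSPHO_TOKENS[token])
    if token in _SPHINGO_PHOSPHO:
        return HeadgroupSpec(phospho=_SPHINGO_PHOSPHO[token], is_sphingo_variant=True)
    if token in _OPAQUE_TOKENS:
        return HeadgroupSpec(opaque_label=token, is_sphingo_variant=True)
    return None


def _headgroup_token(hg: HeadgroupSpec) -> str:
    if hg.is_empty:
        return ""
    if hg.opaque_label:
        return hg.opaque_label
    if hg.n_glycosyl:
        return "G" if hg.n_glycosyl == 1 else "2G"
    if hg.sulfo:
        return "SQ"
    if hg.amino is not Amino.NONE:
        return hg.amino.value
    if hg.is_sphingo_variant:
        return "s" + hg.phospho.value
    return hg.phospho.value


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"""^
    (?:(?P<hg>2G|G|SQ|OL|BL|PDME|PME|PA|PE|PG|PC|PI|CL|sPA|sPE|sPG|sPI|sP-Uk[1-4])-)?
    (?P<uns>Uns-)?
    (?P<h>H-)?
    (?:(?P<nme>\d?)Me-)?
    (?P<core>AR|GDGT|DAG|CER)
    (?:-(?P<suffix>Cren|\d+(?::\d+)?))?
    (?:\((?P<chains>\d+:\d+(?:/\d+:\d+)?)\))?
    $""",
    re.VERBOSE,
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse an annotation string into a :class:`LipidSpecies`.

    The parser is strict: tokens are case-sensitive and any count outside
    the structural bounds (rings, methyls, double bonds) raises
    :class:`LipidParseError` naming the offending token.
    """
    if not isinstance(name, str) or not name:
        raise LipidParseError(str(name), str(name), 0, "empty or non-string name")
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidParseError(name, name, 0, "does not match the lipid name grammar")

    hg_token = m.group("hg")
    headgroup = EMPTY_HEADGROUP if hg_token is None else _headgroup_from_token(hg_token)
    if headgroup is None:  # pragma: no cover - regex restricts tokens
        raise LipidParseError(name, hg_token, 0, "unknown headgroup token")

    core_token = m.group("core")
    is_h = m.group("h") is not None
    is_uns = m.group("uns") is not None
    nme_group = m.group("nme")
    n_methyls = 0
    if nme_group is not None:
        n_methyls = int(nme_group) if nme_group else 1

    suffix = m.group("suffix")
    chains_str = m.group("chains")

    def err(token: str, reason: str) -> LipidParseError:
        return LipidParseError(name, token, name.find(token), reason)

    if core_token == "AR":
        if is_h or is_uns or n_methyls or suffix or chains_str:
            raise err(core_token, "archaeol admits no H/Uns/Me/ring/chain tokens")
        species = LipidSpecies(core_type=CoreType.AR_DIETHER, headgroup=headgroup)
    elif core_token == "GDGT":
        if chains_str:
            raise err(chains_str, "tetraethers carry no acyl-chain specification")
        core_type = CoreType.H_GDGT if is_h else CoreType.GDGT
        n_rings, n_db, is_cren = 0, 0, False
        if suffix == "Cren":
            if is_h:
                raise err(suffix, "crenarchaeol is not H-shaped")
            if is_uns or n_methyls:
                raise err(suffix, "crenarchaeol admits no Uns/Me tokens")
            n_rings, is_cren = 5, True
        elif suffix is not None:
            if ":" in suffix:
                if not is_uns:
                    raise err(suffix, "double-bond suffix requires the Uns token")
                r_str, d_str = suffix.split(":")
                n_rings, n_db = int(r_str), int(d_str)
            else:
                n_rings = int(suffix)
        if is_uns:
            if is_h:
                raise err("Uns", "unsaturated tetraethers are not H-shaped")
            if n_methyls:
                raise err("Uns", "unsaturated tetraethers are unmethylated")
            if n_db == 0:
                n_db = 1  # bare Uns-GDGT: minimally unsaturated
            if n_db > 4:
                raise err(suffix or "Uns", "Uns-GDGT double bonds exceed 4")
        max_rings = 4 if is_h else 5
        if n_rings > max_rings:
            raise err(suffix or core_token,
                      f"{'H-' if is_h else ''}GDGT rings exceed {max_rings}")
        if n_rings == 5 and not is_cren:
            raise err(suffix, "pentacyclic GDGT is written -Cren")
        if n_methyls > (4 if is_h else 2):
            raise err(f"{nme_group}Me", "methyl count outside structural bounds")
        species = LipidSpecies(
            core_type=core_type, headgroup=headgroup, n_rings=n_rings,
            is_cren=is_cren, n_methyls=n_methyls, n_double_bonds=n_db,
        )
    else:  # DAG or CER
        if is_h or is_uns or n_methyls or suffix:
            raise err(core_token, "acyl-chain lipids admit no H/Uns/Me/ring tokens")
        if not chains_str:
            raise err(core_token, "acyl-chain lipids require a (C:D[/C:D]) suffix")
        if hg_token is None:
            raise err(core_token, "non-archaeal lipids require a headgroup (polar pool)")
        chains = tuple(
            (int(c), int(d))
            for c, d in (pair.split(":") for pair in chains_str.split("/"))
        )
        if any(c == 0 for c, _ in chains):
            raise err(chains_str, "chain carbon number must be positive")
        core_type = CoreType.CERAMIDE if core_token == "CER" else CoreType.DAG
        species = LipidSpecies(
            core_type=core_type, headgroup=headgroup, chains=chains,
            n_double_bonds=sum(d for _, d in chains),
        )

    try:
        species.validate()
    except LipidSerializationError as exc:
        raise err(core_token, str(exc)) from exc
    return species


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def canonical_name(species: LipidSpecies) -> str:
    """Serialize a species to its canonical annotation string.

    Round-trips: ``parse_lipid_name(canonical_name(s)) == s``.  The methyl
    token follows the field convention: ``Me`` for singly methylated regular
    GDGTs, ``1Me`` for H-shaped ones.
    """
    try:
        species.validate()
    except LipidSerializationError:
        raise
    parts: list[str] = []
    hg = _headgroup_token(species.headgroup)
    if hg:
        parts.append(hg)
    ct = species.core_type
    if ct is CoreType.AR_DIETHER:
        parts.append("AR")
        return "-".join(parts)
    if ct in _CHAIN_CORES:
        core = "CER" if ct is CoreType.CERAMIDE else "DAG"
        chain_str = "/".join(f"{c}:{d}" for c, d in species.chains)
        return "-".join(parts + [core]) + f"({chain_str})"
    # tetraethers
    if species.n_double_bonds:
        parts.append("Uns")
    if ct is CoreType.H_GDGT:
        parts.append("H")
    if species.n_methyls:
        if ct is CoreType.H_GDGT:
            parts.append(f"{species.n_methyls}Me")
        else:
            parts.append("Me" if species.n_methyls == 1 else f"{species.n_methyls}Me")
    parts.append("GDGT")
    if species.is_cren:
        suffix = "Cren"
    elif species.n_double_bonds:
        suffix = f"{species.n_rings}:{species.n_double_bonds}"
    else:
        suffix = str(species.n_rings)
    return "-".join(parts) + "-" + suffix


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_domain(species: LipidSpecies) -> Domain:
    """Archaeal iff the core is an isoprenoidal ether lipid."""
    if species.core_type in _ARCHAEAL_CORES:
        return Domain.ARCHAEAL
    return Domain.NONARCHAEAL


def compound_class(species: LipidSpecies) -> str:
    """Map a species to its compound-class label.

    Archaeal polar classes combine the glycosidic headgroup with the
    tetraether family (e.g. ``2G-H-2Me-GDGT``); archaeal core classes drop
    the headgroup.  Non-archaeal classes are named by headgroup alone
    (``PC``, ``SQ``, ``sPG``, ...).  Every parseable name maps to exactly
    one class.
    """
    if species.core_type in _CHAIN_CORES:
        return _headgroup_token(species.headgroup)
    parts = []
    hg = _headgroup_token(species.headgroup)
    if hg:
        parts.append(hg)
    if species.core_type is CoreType.AR_DIETHER:
        parts.append("AR")
        return "-".join(parts)
    if species.n_double_bonds:
        parts.append("Uns")
    if species.core_type is CoreType.H_GDGT:
        parts.append("H")
    if species.n_methyls:
        if species.core_type is CoreType.H_GDGT:
            parts.append(f"{species.n_methyls}Me")
        else:
            parts.append("Me" if species.n_methyls == 1 else f"{species.n_methyls}Me")
    parts.append("GDGT")
    return "-".join(parts)


#: The 17 archaeal polar-lipid class labels, in heat-map registry order.
ARCHAEAL_CLASSES: tuple[str, ...] = (
    "G-AR", "G-GDGT", "2G-GDGT", "G-Uns-GDGT", "G-Me-GDGT", "G-2Me-GDGT",
    "2G-Me-GDGT", "2G-2Me-GDGT", "G-H-GDGT", "2G-H-GDGT", "G-H-1Me-GDGT",
    "G-H-2Me-GDGT", "G-H-3Me-GDGT", "G-H-4Me-GDGT", "2G-H-1Me-GDGT",
    "2G-H-2Me-GDGT", "2G-H-3Me-GDGT",
)

#: The 19 non-archaeal polar-lipid class labels, in registry order.
NONARCHAEAL_CLASSES: tuple[str, ...] = (
    "G", "SQ", "2G", "BL", "OL", "PDME", "PME", "PE", "PG", "PC", "CL",
    "sPA", "sP-Uk1", "sP-Uk2", "sP-Uk3", "sP-Uk4", "sPI", "sPE", "sPG",
)

#: H-shaped tetraether polar classes (numerator of the %H-GDGT index).
H_GDGT_CLASSES: tuple[str, ...] = tuple(
    c for c in ARCHAEAL_CLASSES if "-H-" in c
)


def load_class_registry():
    """Load the shipped compound-class registry as a DataFrame.

    Columns: ``class_label``, ``domain``, ``core_type``, ``registry_order``.
    """
    import pandas as pd

    with resources.files("thermolipids.data").joinpath("class_registry.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def example_species_for_class(label: str) -> LipidSpecies:
    """Return a representative parseable species for a registry class label."""
    if label in NONARCHAEAL_CLASSES:
        if label.startswith("sP"):
            return parse_lipid_name(f"{label}-CER(18:0/16:0)")
        return parse_lipid_name(f"{label}-DAG(16:0/18:1)")
    if label == "G-AR":
        return parse_lipid_name("G-AR")
    if "Uns" in label:
        return parse_lipid_name(f"{label}-0:2")
    return parse_lipid_name(f"{label}-0")
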