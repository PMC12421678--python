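"""Topology of the branched 26-unit softwood (spruce) lignin chain.

Softwood milled-wood lignin is represented here as a single representative
macromolecule: 26 guaiacyl repeat units joined by interunit linkages, with a
small set of terminal-group modifications (carboxyl/aldehyde/ketone variants)
placed on specific repeat units, and two aliphatic alpha-O-gamma ether
linkages that create branch points.  The chain is stored as an undirected
annotated graph; atom-level 3-D geometry is out of scope.

From the chain the module derives a linkage census, the chain molar mass
(from per-residue formulas, with a configurable condensation loss per
linkage), and condensed-phase system compositions (number of water molecules
required to hit a target moisture weight fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .constants import ATOMIC_MASS, WATER_MOLAR_MASS
from .exceptions import ConfigurationError, DomainError, StructuralIntegrityError

__all__ = [
    "MonomerUnit",
    "Linkage",
    "LigninChainGraph",
    "SystemComposition",
    "build_reference_chain",
    "linkage_census",
    "chain_molar_mass",
    "assemble_system_spec",
    "LINKAGE_KINDS",
    "MODIFICATIONS",
    "GUAIACYL_FORMULA",
    "MODIFICATION_FORMULA_DELTAS",
]

LINKAGE_KINDS = (
    "beta-O-4",
    "alpha-O-gamma",
    "beta-5",
    "beta-beta",
    "5-5",
    "4-O-5",
    "beta-1",
    "other",
)

MODIFICATIONS = (
    "gamma-carboxyl",
    "gamma-aldehyde",
    "alpha-aldehyde-trunc",
    "alpha-ketone",
    "beta-ketone",
)

#: In-chain guaiacyl residue formula (coniferyl-alcohol-derived C10 unit).
GUAIACYL_FORMULA = {"C": 10, "H": 12, "O": 3}

#: Element-count deltas applied by each terminal-group modification.
#: gamma-carboxyl: CH2OH -> COOH; gamma-aldehyde: CH2OH -> CHO;
#: alpha-aldehyde-trunc: side chain truncated to an alpha-CHO (beta and gamma
#: carbons removed); alpha-/beta-ketone: CHOH -> C=O at the named position.
MODIFICATION_FORMULA_DELTAS = {
    "gamma-carboxyl": {"H": -2, "O": +1},
    "gamma-aldehyde": {"H": -2},
    "alpha-aldehyde-trunc": {"C": -2, "H": -4, "O": -1},
    "alpha-ketone": {"H": -2},
    "beta-ketone": {"H": -2},
}


def formula_mass(formula: dict) -> float:
    """Molar mass (g/mol) of an element-count formula."""
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guarded by fixed tables
        raise ConfigurationError(f"no atomic mass for element {exc}") from exc


def default_monomer_mass_table() -> dict:
    """Mass table: base residue mass per lignol class + per-modification deltas."""
    table = {"guaiacyl": formula_mass(GUAIACYL_FORMULA)}
    for mod, delta in MODIFICATION_FORMULA_DELTAS.items():
        table[mod] = formula_mass(delta)
    return table


@dataclass(frozen=True)
class MonomerUnit:
    """One phenylpropanoid repeat unit of the chain."""

    index: int
    lignol_class: str = "guaiacyl"
    terminal_mods: frozenset = field(default_factory=frozenset)
    ring_substituents: str = ""

    def __post_init__(self):
        object.__setattr__(self, "terminal_mods", frozenset(self.terminal_mods))
        unknown = self.terminal_mods - set(MODIFICATIONS)
        if unknown:
            raise ConfigurationError(f"unknown terminal modifications: {sorted(unknown)}")

    def formula(self) -> dict:
        """Element counts of this residue including its modifications."""
        if self.lignol_class != "guaiacyl":
            raise ConfigurationError(
                f"no formula for lignol class {self.lignol_class!r}"
            )
        counts = dict(GUAIACYL_FORMULA)
        for mod in self.terminal_mods:
            for el, delta in MODIFICATION_FORMULA_DELTAS[mod].items():
                counts[el] = counts.get(el, 0) + delta
        return counts


@dataclass(frozen=True)
class Linkage:
    """An interunit bond between two repeat units."""

    kind: str
    from_unit: int
    to_unit: int

    def __post_init__(self):
        if self.kind not in LINKAGE_KINDS:
            raise ConfigurationError(f"unknown linkage kind {self.kind!r}")
        if self.from_unit == self.to_unit:
            raise StructuralIntegrityError("linkage endpoints must differ")


@dataclass
class LigninChainGraph:
    """Annotated undirected graph of a lignin macromolecule."""

    units: list
    linkages: list
    monomer_mass_table: dict = field(default_factory=default_monomer_mass_table)

    def __post_init__(self):
        indices = [u.index for u in self.units]
        if len(set(indices)) != len(indices):
            raise StructuralIntegrityError("unit indices must be unique")
        index_set = set(indices)
        for link in self.linkages:
            if link.from_unit not in index_set or link.to_unit not in index_set:
                raise StructuralIntegrityError(
                    f"linkage {link} references a unit outside the chain"
                )

    def __len__(self) -> int:
        return len(self.units)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for unit in self.units:
            g.add_node(unit.index, lignol_class=unit.lignol_class,
                       terminal_mods=sorted(unit.terminal_mods))
        for link in self.linkages:
            g.add_edge(link.from_unit, link.to_unit, kind=link.kind)
        return g

    def is_connected(self) -> bool:
        if not self.units:
            return False
        return nx.is_connected(nx.Graph(self.to_networkx()))

    def unit(self, index: int) -> MonomerUnit:
        for u in self.units:
            if u.index == index:
                return u
        raise KeyError(index)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": [
                {
                    "index": u.index,
                    "lignol_class": u.lignol_class,
                    "terminal_mods": sorted(u.terminal_mods),
                    "ring_substituents": u.ring_substituents,
                }
                for u in self.units
            ],
            "linkages": [
                {"kind": lk.kind, "from_unit": lk.from_unit, "to_unit": lk.to_unit}
                for lk in self.linkages
            ],
            "monomer_mass_table": dict(self.monomer_mass_table),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LigninChainGraph":
        units = [
            MonomerUnit(
                index=u["index"],
                lignol_class=u.get("lignol_class", "guaiacyl"),
                terminal_mods=frozenset(u.get("terminal_mods", ())),
                ring_substituents=u.get("ring_substituents", ""),
            )
            for u in payload["units"]
        ]
        linkages = [
            Linkage(kind=lk["kind"], from_unit=lk["from_unit"], to_unit=lk["to_unit"])
            for lk in payload["linkages"]
        ]
        table = payload.get("monomer_mass_table") or default_monomer_mass_table()
        return cls(units=units, linkages=linkages, monomer_mass_table=table)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "LigninChainGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def edge_list(self) -> list:
        """(from_unit, to_unit, kind) triples, one per linkage."""
        return [(lk.from_unit, lk.to_unit, lk.kind) for lk in self.linkages]


#: Table-1-style terminal-group placements: modification -> repeat units.
REFERENCE_MODIFICATIONS = {
    "gamma-carboxyl": (1,),
    "gamma-aldehyde": (7,),
    "alpha-aldehyde-trunc": (11,),
    "alpha-ketone": (21, 26),
    "beta-ketone": (22,),
}


def build_reference_chain(twelve_three_reading: str = "12-13") -> LigninChainGraph:
    """Build the fixed 26-unit reference chain.

    The backbone joins consecutive units 1..26 by beta-O-4 linkages; two
    aliphatic alpha-O-gamma ether linkages create the branch points, between
    units 2 and 9 and (by default) between units 12 and 13.  The second
    placement is configurable because the source tabulation is ambiguous:
    ``twelve_three_reading="12-3"`` instead links units 12 and 3.

    Deterministic: repeated calls return equal chains.
    """
    if twelve_three_reading not in ("12-13", "12-3"):
        raise DomainError("twelve_three_reading must be '12-13' or '12-3'")
    mods_by_unit: dict[int, set] = {}
    for mod, indices in REFERENCE_MODIFICATIONS.items():
        for idx in indices:
            mods_by_unit.setdefault(idx, set()).add(mod)
    units = [
        MonomerUnit(index=i, lignol_class="guaiacyl",
                    terminal_mods=frozenset(mods_by_unit.get(i, ())))
        for i in range(1, 27)
    ]
    linkages = [Linkage("beta-O-4", i, i + 1) for i in range(1, 26)]
    linkages.append(Linkage("alpha-O-gamma", 2, 9))
    if twelve_three_reading == "12-13":
        linkages.append(Linkage("alpha-O-gamma", 12, 13))
    else:
        linkages.append(Linkage("alpha-O-gamma", 12, 3))
    return LigninChainGraph(units=units, linkages=linkages)


def linkage_census(chain: LigninChainGraph) -> dict:
    """Count linkages by kind.  Raises on a disconnected chain."""
    if not chain.is_connected():
        raise StructuralIntegrityError("chain graph is not connected")
    census: dict = {}
    for link in chain.linkages:
        census[link.kind] = census.get(link.kind, 0) + 1
    return census


def chain_molar_mass(chain: LigninChainGraph,
                     condensation_loss_per_linkage: float = 0.0) -> float:
    """Molar mass of the chain in g/mol.

    Sums per-residue masses from the chain's mass table and subtracts the
    configured condensation loss once per linkage (default 0: table entries
    are treated as in-chain residue masses).
    """
    table = chain.monomer_mass_table
    total = 0.0
    for unit in chain.units:
        if unit.lignol_class not in table:
            raise ConfigurationError(
                f"mass table lacks lignol class {unit.lignol_class!r}"
            )
        mass = table[unit.lignol_class]
        for mod in unit.terminal_mods:
            if mod not in table:
                raise ConfigurationError(f"mass table lacks modification {mod!r}")
            mass += table[mod]
        total += mass
    total -= condensation_loss_per_linkage * len(chain.linkages)
    if total <= 0:
        raise ConfigurationError("chain molar mass must be strictly positive")
    return total


@dataclass(frozen=True)
class SystemComposition:
    """Counts of chains and water molecules for one condensed-phase system."""

    n_chains: int
    chain_molar_mass: float
    moisture_wt_pct: float
    n_water: int
    water_molar_mass: float = WATER_MOLAR_MASS

    @property
    def achieved_moisture_wt_pct(self) -> float:
        water_mass = self.n_water * self.water_molar_mass
        lignin_mass = self.n_chains * self.chain_molar_mass
        return 100.0 * water_mass / (water_mass + lignin_mass)


def assemble_system_spec(n_chains: int, moisture_wt_pct: float,
                         chain: LigninChainGraph | None = None,
                         chain_mass: float | None = None) -> SystemComposition:
    """Number of water molecules needed for a target moisture weight fraction.

    n_water = round( mc/(100-mc) * n_chains * M_chain / M_water ).
    """
    if not 0 <= moisture_wt_pct < 100:
        raise DomainError("moisture_wt_pct must lie in [0, 100)")
    if n_chains < 1:
        raise DomainError("n_chains must be at least 1")
    if chain_mass is None:
        chain_mass = chain_molar_mass(chain if chain is not None
                                      else build_reference_chain())
    if moisture_wt_pct == 0:
        n_water = 0
    else:
        ratio = moisture_wt_pct / (100.0 - moisture_wt_pct)
        n_water = round(ratio * n_chains * chain_mass / WATER_MOLAR_MASS)
    return SystemComposition(
        n_chains=n_chains,
        chain_molar_mass=chain_mass,
        moisture_wt_pct=moisture_wt_pct,
        n_water=int(n_water),
    )
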