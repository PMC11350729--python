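"""Kinetic schemes: species, reversible mass-action reactions and built-in models.

Conventions
-----------
Concentrations are in uM, time in s. Bimolecular rate constants carry units of
uM^-1 s^-1, unimolecular ones s^-1 (the reporting layer multiplies second-order
constants by 1e6 when M^-1 s^-1 values are wanted). Each species declares how
many copies of each conserved moiety it contains (E = enzyme, S = substrate,
I = ImGP, A = AICAR); every reaction must balance those counts, which is what
makes total enzyme/ligand conservation an exact structural property of the
integrated equations rather than a numerical accident.

Built-in schemes
----------------
ONE_STEP        E + S <=> ES                      (k1, k-1)
INDUCED_FIT     E + S <=> ES <=> E*S              (k1, k-1; kconf, k-conf)
                ligand binds the open/detached enzyme first, then the
                active-site loop closes over it.
CONF_SELECTION  E <=> E* ; E* + S <=> E*S         (kconf, k-conf; k1, k-1)
                the conformational change precedes binding.
TERNARY         product binding with loop closure over the ternary complex:
                E + I <=> EI, E + A <=> EA, EA + I <=> EIA, EI + A <=> EIA,
                EIA <=> EIA*                       (k2/k-2, k3/k-3, k4/k-4)
                By default ImGP binding to E and to EA shares k2/k-2 and
                AICAR binding to E and to EI shares k3/k-3 (the simplest
                model in which the two binding sites are independent until
                the loop closes); ``tied=False`` introduces separate
                constants k2b/k-2b and k3b/k-3b for binding to the binary
                complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .util import ValidationError

BUILTIN_IDS = ("ONE_STEP", "INDUCED_FIT", "CONF_SELECTION", "TERNARY", "CUSTOM")


@dataclass(frozen=True)
class Species:
    """A chemical species with its conserved-moiety composition."""

    name: str
    role: str  # "enzyme-state" | "ligand" | "complex"
    moiety_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ("enzyme-state", "ligand", "complex"):
            raise ValidationError(f"species {self.name!r}: unknown role {self.role!r}")
        if any(c < 0 for c in self.moiety_counts.values()):
            raise ValidationError(f"species {self.name!r}: negative moiety count")
        total = sum(self.moiety_counts.values())
        if self.role == "complex" and total < 2:
            raise ValidationError(
                f"species {self.name!r}: a complex must contain >= 2 moieties"
            )

    @property
    def total_moieties(self) -> int:
        return sum(self.moiety_counts.values())


@dataclass(frozen=True)
class Reaction:
    """A reversible elementary reaction; kf/kr name entries of a parameter set.

    A rate-constant value of exactly 0 marks that direction as disabled
    (irreversible reaction).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kf_name: str
    kr_name: str

    def __post_init__(self):
        if not (1 <= len(self.reactants) <= 2 and 1 <= len(self.products) <= 2):
            raise ValidationError(f"reaction {self.label}: 1-2 reactants and products only")

    @property
    def label(self) -> str:
        return "+".join(self.reactants) + "<=>" + "+".join(self.products)


class RateParameterSet:
    """Named rate constants with optional standard errors.

    Derived equilibrium quantities (KD1 = k-1/k1, K4 = k4/k-4, ...) are
    recomputed from the stored constants on every access, never cached.
    """

    def __init__(self, values: dict[str, float], stderr: dict[str, float] | None = None):
        bad = [k for k, v in values.items() if v < 0]
        if bad:
            raise ValidationError(f"negative rate constants: {bad}")
        self.values = dict(values)
        self.stderr = dict(stderr or {})

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str, default: float | None = None):
        return self.values.get(name, default)

    def kd(self, kf_name: str, kr_name: str) -> float:
        """Dissociation constant k_off/k_on for a binding step (uM)."""
        return self.values[kr_name] / self.values[kf_name]

    @property
    def KD1(self) -> float:
        return self.kd("k1", "k-1")

    @property
    def K4(self) -> float:
        """Equilibrium constant of the loop-closing step (dimensionless)."""
        return self.values["k4"] / self.values["k-4"]

    def replace(self, **updates) -> "RateParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return RateParameterSet(vals, self.stderr)

    def to_dict(self) -> dict:
        return {"values": dict(self.values), "stderr": dict(self.stderr)}

    def __repr__(self):
        body = ", ".join(f"{k}={v:g}" for k, v in self.values.items())
        return f"RateParameterSet({body})"


@dataclass
class KineticScheme:
    """A validated set of species and reversible mass-action reactions."""

    species: list[Species]
    reactions: list[Reaction]
    builtin_id: str = "CUSTOM"

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate species names: {dup}")
        if self.builtin_id not in BUILTIN_IDS:
            raise ValidationError(f"unknown builtin_id {self.builtin_id!r}")
        self._index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for name in rxn.reactants + rxn.products:
                if name not in self._index:
                    raise ValidationError(f"reaction {rxn.label}: unknown species {name!r}")
            for m in self.moieties:
                lhs = sum(self[n].moiety_counts.get(m, 0) for n in rxn.reactants)
                rhs = sum(self[n].moiety_counts.get(m, 0) for n in rxn.products)
                if lhs != rhs:
                    raise ValidationError(
                        f"reaction {rxn.label}: moiety {m!r} unbalanced ({lhs} vs {rhs})"
                    )

    def __getitem__(self, name: str) -> Species:
        return self.species[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def moieties(self) -> list[str]:
        out: list[str] = []
        for s in self.species:
            for m in s.moiety_counts:
                if m not in out:
                    out.append(m)
        return out

    def conservation_vectors(self) -> dict[str, np.ndarray]:
        """Per-moiety stoichiometric vectors c with c @ dx/dt = 0 identically."""
        return {
            m: np.array([s.moiety_counts.get(m, 0) for s in self.species], float)
            for m in self.moieties
        }

    def rate_names(self) -> list[str]:
        out: list[str] = []
        for r in self.reactions:
            for n in (r.kf_name, r.kr_name):
                if n not in out:
                    out.append(n)
        return out

    def enzyme_species(self, moiety: str = "E") -> list[str]:
        return [s.name for s in self.species if s.moiety_counts.get(moiety, 0) > 0]

    def complex_species(self) -> list[str]:
        return [s.name for s in self.species if s.role == "complex"]

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "builtin_id": self.builtin_id,
            "species": [
                {"name": s.name, "role": s.role, "moiety_counts": dict(s.moiety_counts)}
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "kf": r.kf_name,
                    "kr": r.kr_name,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "KineticScheme":
        species = [
            Species(d["name"], d["role"], dict(d.get("moiety_counts", {})))
            for d in doc["species"]
        ]
        reactions = [
            Reaction(tuple(d["reactants"]), tuple(d["products"]), d["kf"], d["kr"])
            for d in doc["reactions"]
        ]
        return cls(species, reactions, doc.get("builtin_id", "CUSTOM"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "KineticScheme":
        return cls.from_dict(yaml.safe_load(text))


def _sp(name, role, **counts):
    return Species(name, role, counts)


def build_scheme(
    builtin_id: str | None = None,
    species: list[Species] | None = None,
    reactions: list[Reaction] | None = None,
    tied: bool = True,
) -> KineticScheme:
    """Construct and validate a kinetic scheme.

    Either pass one of the built-in ids (see module docstring) or a custom
    species + reaction list. ``tied`` controls whether TERNARY shares the
    binding constants between apo enzyme and binary complexes.
    """
    if builtin_id is None or builtin_id == "CUSTOM":
        if species is None or reactions is None:
            raise ValidationError("custom scheme needs species and reactions")
        return KineticScheme(list(species), list(reactions), "CUSTOM")

    if builtin_id == "ONE_STEP":
        return KineticScheme(
            [
                _sp("E", "enzyme-state", E=1),
                _sp("S", "ligand", S=1),
                _sp("ES", "complex", E=1, S=1),
            ],
            [Reaction(("E", "S"), ("ES",), "k1", "k-1")],
            "ONE_STEP",
        )
    if builtin_id == "INDUCED_FIT":
        return KineticScheme(
            [
                _sp("E", "enzyme-state", E=1),
                _sp("S", "ligand", S=1),
                _sp("ES", "complex", E=1, S=1),
                _sp("E*S", "complex", E=1, S=1),
            ],
            [
                Reaction(("E", "S"), ("ES",), "k1", "k-1"),
                Reaction(("ES",), ("E*S",), "kconf", "k-conf"),
            ],
            "INDUCED_FIT",
        )
    if builtin_id == "CONF_SELECTION":
        return KineticScheme(
            [
                _sp("E", "enzyme-state", E=1),
                _sp("E*", "enzyme-state", E=1),
                _sp("S", "ligand", S=1),
                _sp("E*S", "complex", E=1, S=1),
            ],
            [
                Reaction(("E",), ("E*",), "kconf", "k-conf"),
                Reaction(("E*", "S"), ("E*S",), "k1", "k-1"),
            ],
            "CONF_SELECTION",
        )
    if builtin_id == "TERNARY":
        k2b, km2b = ("k2", "k-2") if tied else ("k2b", "k-2b")
        k3b, km3b = ("k3", "k-3") if tied else ("k3b", "k-3b")
        return KineticScheme(
            [
                _sp("E", "enzyme-state", E=1),
                _sp("I", "ligand", I=1),
                _sp("A", "ligand", A=1),
                _sp("EI", "complex", E=1, I=1),
                _sp("EA", "complex", E=1, A=1),
                _sp("EIA", "complex", E=1, I=1, A=1),
                _sp("EIA*", "complex", E=1, I=1, A=1),
            ],
            [
                Reaction(("E", "I"), ("EI",), "k2", "k-2"),
                Reaction(("E", "A"), ("EA",), "k3", "k-3"),
                Reaction(("EA", "I"), ("EIA",), k2b, km2b),
                Reaction(("EI", "A"), ("EIA",), k3b, km3b),
                Reaction(("EIA",), ("EIA*",), "k4", "k-4"),
            ],
            "TERNARY",
        )
    raise ValidationError(f"unknown builtin_id {builtin_id!r}")
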