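"""Declarative kinetic reaction schemes for ligand migration in heme proteins.

A :class:`NetworkModel` is a list of states and first-order / bimolecular
transitions between them.  Two presets are provided:

* :func:`build_cygb_scheme` — the minimal CO-rebinding / ligand-migration
  scheme for cytoglobin: after photolysis the CO sits in a primary docking
  site (P1) from which it can rebind to the iron, migrate sequentially to
  deeper internal sites (P2..P5), or escape to the solvent.  The
  pentacoordinated deoxy protein (Cygb_p) is in equilibrium with the
  bis-histidyl hexacoordinated form (Cygb_h); an optional innermost site H6
  is reached concurrently with His coordination, and an optional secondary
  exit to the solvent exists from P5.
* :func:`build_nod_scheme` — the NO-dioxygenase mechanism: oxy protein + NO
  form a ferric-peroxynitrite intermediate that decays to the ferric (met)
  product.

Conventions
-----------
* Bimolecular transitions name the ligand pool as ``ligand_partner`` and
  consume one free ligand.
* A *first-order* transition may also name the pool as ``ligand_partner``:
  this marks a step that releases the docked ligand into the solvent
  (e.g. escape from the primary docking site).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "StateSpec",
    "Transition",
    "NetworkModel",
    "RateSet",
    "SchemeError",
    "RateValidationError",
    "build_cygb_scheme",
    "build_nod_scheme",
    "stoichiometry_matrix",
    "validate_rates",
    "model_to_yaml",
    "model_from_yaml",
]

STATE_KINDS = frozenset(
    {"bound", "docked", "deoxy_penta", "deoxy_hexa", "ligand_pool",
     "ferric_intermediate", "product"}
)

#: default observable weight per state kind for the photolysis survival
#: signal (fraction of unliganded photoproduct): every unliganded heme
#: state contributes 1, the CO complex and the free-ligand pool contribute 0.
DEFAULT_OBSERVABLE_WEIGHT = {
    "bound": 0.0,
    "docked": 1.0,
    "deoxy_penta": 1.0,
    "deoxy_hexa": 1.0,
    "ligand_pool": 0.0,
    "ferric_intermediate": 1.0,
    "product": 0.0,
}


class SchemeError(ValueError):
    """Structural problem in a reaction scheme."""


class RateValidationError(ValueError):
    """Rate set inconsistent with its companion model."""


@dataclass(frozen=True)
class StateSpec:
    name: str
    kind: str
    observable_weight: float | None = None

    def __post_init__(self):
        if self.kind not in STATE_KINDS:
            raise SchemeError(f"unknown state kind {self.kind!r}")
        w = self.observable_weight
        if w is not None and w < 0:
            raise SchemeError("observable weight must be >= 0")

    @property
    def weight(self) -> float:
        if self.observable_weight is not None:
            return self.observable_weight
        return DEFAULT_OBSERVABLE_WEIGHT[self.kind]


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate_symbol: str
    order: str = "first"  # "first" | "bimolecular"
    ligand_partner: str | None = None

    def __post_init__(self):
        if self.source == self.target:
            raise SchemeError(
                f"transition {self.rate_symbol!r}: source equals target")
        if self.order not in ("first", "bimolecular"):
            raise SchemeError(f"unknown transition order {self.order!r}")
        if self.order == "bimolecular" and self.ligand_partner is None:
            raise SchemeError(
                f"bimolecular transition {self.rate_symbol!r} must name a "
                "ligand partner")


@dataclass(frozen=True)
class NetworkModel:
    states: tuple[StateSpec, ...]
    transitions: tuple[Transition, ...]
    label: str = ""

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(names) != len(set(names)):
            raise SchemeError("state names must be unique")
        symbols = [t.rate_symbol for t in self.transitions]
        if len(symbols) != len(set(symbols)):
            raise SchemeError("rate symbols must be unique per transition")
        known = set(names)
        for t in self.transitions:
            for endpoint in (t.source, t.target):
                if endpoint not in known:
                    raise SchemeError(
                        f"transition {t.rate_symbol!r} references undeclared "
                        f"state {endpoint!r}")
            if t.ligand_partner is not None and t.ligand_partner not in known:
                raise SchemeError(
                    f"transition {t.rate_symbol!r} names undeclared ligand "
                    f"partner {t.ligand_partner!r}")
        pools = [s.name for s in self.states if s.kind == "ligand_pool"]
        if any(t.order == "bimolecular" for t in self.transitions):
            if len(pools) != 1:
                raise SchemeError(
                    "schemes with bimolecular steps need exactly one "
                    "ligand_pool state")

    # -- convenience views ------------------------------------------------
    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def protein_states(self) -> tuple[StateSpec, ...]:
        return tuple(s for s in self.states if s.kind != "ligand_pool")

    @property
    def pool_state(self) -> StateSpec | None:
        for s in self.states:
            if s.kind == "ligand_pool":
                return s
        return None

    @property
    def rate_symbols(self) -> tuple[str, ...]:
        return tuple(t.rate_symbol for t in self.transitions)

    def transition(self, symbol: str) -> Transition:
        for t in self.transitions:
            if t.rate_symbol == symbol:
                return t
        raise KeyError(symbol)

    def expected_units(self) -> dict[str, str]:
        """Map rate symbol -> unit string implied by the transition order."""
        return {
            t.rate_symbol: ("M^-1 s^-1" if t.order == "bimolecular" else "s^-1")
            for t in self.transitions
        }


@dataclass
class RateSet:
    """Named microscopic rate constants at a single temperature.

    ``units`` maps each symbol to "s^-1" (first order) or "M^-1 s^-1"
    (bimolecular).  ``provenance`` optionally records, per symbol, whether a
    preset value is a published constant ("printed"), derived from published
    quantities ("derived"), or a plausible placeholder ("placeholder").
    """

    values: dict[str, float]
    temperature_K: float = 293.15
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature must be > 0 K")
        for sym, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"rate {sym!r} must be positive and finite, got {v!r}")

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]

    def with_values(self, **updates: float) -> "RateSet":
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

CO_POOL = "CO_solvent"


def build_cygb_scheme(variant: str = "wt", site5_exit: bool = True,
                      hexa_site6: bool = True) -> NetworkModel:
    """Minimal ligand-migration scheme for CO rebinding to cytoglobin.

    Parameters
    ----------
    variant:
        ``"wt"`` includes the pentacoordinate/bis-histidyl equilibrium
        (Cygb_p <-> Cygb_h); ``"HE7Q"`` (distal-His mutant) removes Cygb_h
        and the innermost site H6 together with their transitions.
    site5_exit:
        include a secondary first-order exit to the solvent from the deepest
        docking site P5 (symbol ``k_2p``).
    hexa_site6:
        include the innermost docking site H6, reached from P5 concurrently
        with bis-histidyl coordination (symbols ``k_h``/``k_-h``).  Invalid
        for the HE7Q variant, which cannot hexacoordinate.
    """
    if variant not in ("wt", "HE7Q"):
        raise SchemeError(f"unknown variant {variant!r}")
    if variant == "HE7Q" and hexa_site6:
        raise SchemeError(
            "hexa_site6 requires the distal histidine; invalid for HE7Q")

    states = [
        StateSpec("CygbCO", "bound"),
        StateSpec("P1", "docked"),
        StateSpec("P2", "docked"),
        StateSpec("P3", "docked"),
        StateSpec("P4", "docked"),
        StateSpec("P5", "docked"),
        StateSpec("Cygb_p", "deoxy_penta"),
    ]
    transitions = [
        Transition("P1", "CygbCO", "k_-1"),
        Transition("P1", "Cygb_p", "k_2", ligand_partner=CO_POOL),
        Transition("Cygb_p", "P1", "k_-2", order="bimolecular",
                   ligand_partner=CO_POOL),
        Transition("P1", "P2", "k_c"),
        Transition("P2", "P1", "k_-c"),
        Transition("P2", "P3", "k_3"),
        Transition("P3", "P2", "k_-3"),
        Transition("P3", "P4", "k_4"),
        Transition("P4", "P3", "k_-4"),
        Transition("P4", "P5", "k_5"),
        Transition("P5", "P4", "k_-5"),
    ]
    if variant == "wt":
        states.append(StateSpec("Cygb_h", "deoxy_hexa"))
        transitions += [
            Transition("Cygb_p", "Cygb_h", "k_b"),
            Transition("Cygb_h", "Cygb_p", "k_-b"),
        ]
        if hexa_site6:
            states.append(StateSpec("H6", "docked"))
            transitions += [
                Transition("P5", "H6", "k_h"),
                Transition("H6", "P5", "k_-h"),
            ]
    if site5_exit:
        transitions.append(
            Transition("P5", "Cygb_p", "k_2p", ligand_partner=CO_POOL))
    states.append(StateSpec(CO_POOL, "ligand_pool"))
    return NetworkModel(tuple(states), tuple(transitions),
                        label=f"Cygb CO rebinding ({variant})")


NO_POOL = "NO_solvent"


def build_nod_scheme() -> NetworkModel:
    """NO dioxygenase mechanism: O2-protein + NO -> Fe(III)-ONOO- -> met + NO3-."""
    states = (
        StateSpec("O2Cygb", "bound", observable_weight=1.0),
        StateSpec("FeOONO", "ferric_intermediate"),
        StateSpec("metCygb", "product"),
        StateSpec(NO_POOL, "ligand_pool"),
    )
    transitions = (
        Transition("O2Cygb", "FeOONO", "k_a", order="bimolecular",
                   ligand_partner=NO_POOL),
        Transition("FeOONO", "metCygb", "k_b_nod"),
    )
    return NetworkModel(states, transitions, label="NO dioxygenase")


# ---------------------------------------------------------------------------
# Structure / validation
# ---------------------------------------------------------------------------

def stoichiometry_matrix(model: NetworkModel) -> np.ndarray:
    """Integer state-by-transition stoichiometry matrix.

    Each column carries -1 at the source and +1 at the target (protein
    states); the ligand-pool row gets -1 when a bimolecular step consumes a
    free ligand and +1 when a first-order step releases one to the pool.
    """
    idx = {s.name: i for i, s in enumerate(model.states)}
    S = np.zeros((len(model.states), len(model.transitions)), dtype=int)
    for j, t in enumerate(model.transitions):
        S[idx[t.source], j] -= 1
        S[idx[t.target], j] += 1
        if t.ligand_partner is not None:
            if t.order == "bimolecular":
                S[idx[t.ligand_partner], j] -= 1
            else:
                S[idx[t.ligand_partner], j] += 1
    return S


def validate_rates(model: NetworkModel, rates: RateSet) -> RateSet:
    """Check a rate set against a model; return it unchanged if consistent.

    Raises :class:`RateValidationError` naming the first missing symbol,
    non-positive value, or unit-class mismatch; extra symbols are also
    rejected so typos cannot pass silently.
    """
    expected = model.expected_units()
    missing = sorted(set(expected) - set(rates.values))
    if missing:
        raise RateValidationError(f"missing rate symbol(s): {', '.join(missing)}")
    extra = sorted(set(rates.values) - set(expected))
    if extra:
        raise RateValidationError(f"extra rate symbol(s): {', '.join(extra)}")
    for sym, unit in expected.items():
        v = rates.values[sym]
        if not np.isfinite(v) or v <= 0:
            raise RateValidationError(f"rate {sym!r} must be positive, got {v!r}")
        declared = rates.units.get(sym)
        if declared is not None and declared != unit:
            raise RateValidationError(
                f"unit-class mismatch for {sym!r}: declared {declared!r}, "
                f"model requires {unit!r}")
    return rates


# ---------------------------------------------------------------------------
# Serialization (YAML dialect; round-trip exact)
# ---------------------------------------------------------------------------

def model_to_yaml(model: NetworkModel) -> str:
    doc = {
        "label": model.label,
        "states": [
            {"name": s.name, "kind": s.kind,
             **({"observable_weight": s.observable_weight}
                if s.observable_weight is not None else {})}
            for s in model.states
        ],
        "transitions": [
            {"source": t.source, "target": t.target,
             "rate_symbol": t.rate_symbol, "order": t.order,
             **({"ligand_partner": t.ligand_partner}
                if t.ligand_partner is not None else {})}
            for t in model.transitions
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> NetworkModel:
    doc = yaml.safe_load(text)
    states = tuple(
        StateSpec(d["name"], d["kind"], d.get("observable_weight"))
        for d in doc["states"]
    )
    transitions = tuple(
        Transition(d["source"], d["target"], d["rate_symbol"],
                   d.get("order", "first"), d.get("ligand_partner"))
        for d in doc["transitions"]
    )
    return NetworkModel(states, transitions, label=doc.get("label", ""))
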