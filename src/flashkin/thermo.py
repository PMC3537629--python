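"""Transition-state (Eyring) analysis and ligand-migration energetics.

Under transition-state theory a first-order rate constant obeys

    k(T) = (k_B T / h) * exp(-dH/(R T) + dS/R)

so ln(k/T) is linear in 1/T with slope -dH/R and intercept
ln(k_B/h) + dS/R.  Fitting rate constants measured at several temperatures
(the "Eyring plot") yields the activation enthalpy dH (kJ/mol) and entropy
dS (J/(mol K)); the activation free energy at temperature T is
dG = dH - T*dS, equivalently dG = -R T ln(k h/(k_B T)).

A chain of reversible steps with forward/reverse rate constants defines a
multi-well free-energy profile: the barrier on each side of a transition
state follows from the Eyring relation, and well levels are propagated by
path consistency from a reference well pinned at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._constants import KB_OVER_H, R_GAS

__all__ = [
    "EyringEntry",
    "EyringParams",
    "FreeEnergyProfile",
    "eyring_fit",
    "eyring_rate",
    "activation_free_energy",
    "derive_keq",
    "derive_kon",
    "free_energy_profile",
]


@dataclass(frozen=True)
class EyringEntry:
    """Activation parameters for one rate constant."""

    dH_kJ_mol: float
    dS_J_molK: float
    stderr_dH_kJ_mol: float = 0.0
    stderr_dS_J_molK: float = 0.0


#: activation parameters per rate symbol
EyringParams = dict[str, EyringEntry]


def eyring_fit(temps_K, rates) -> EyringEntry:
    """Linear Eyring regression of ln(k/T) on 1/T.

    Requires at least three temperatures; order of the (T, k) pairs is
    irrelevant.
    """
    T = np.asarray(temps_K, dtype=float)
    k = np.asarray(rates, dtype=float)
    if T.size != k.size:
        raise ValueError("temperature and rate lists must match in length")
    if T.size < 3:
        raise ValueError("Eyring fit needs >= 3 temperatures")
    if np.any(T <= 0) or np.any(k <= 0):
        raise ValueError("temperatures and rates must be > 0")
    x = 1.0 / T
    y = np.log(k / T)
    res = stats.linregress(x, y)
    dH = -res.slope * R_GAS / 1e3
    dS = R_GAS * (res.intercept - np.log(KB_OVER_H))
    return EyringEntry(
        dH_kJ_mol=dH,
        dS_J_molK=dS,
        stderr_dH_kJ_mol=res.stderr * R_GAS / 1e3,
        stderr_dS_J_molK=R_GAS * res.intercept_stderr,
    )


def eyring_rate(entry: EyringEntry, T: float) -> float:
    """Rate constant predicted by the Eyring equation at temperature T (K)."""
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    return KB_OVER_H * T * np.exp(
        -entry.dH_kJ_mol * 1e3 / (R_GAS * T) + entry.dS_J_molK / R_GAS)


def activation_free_energy(entry: EyringEntry, T: float) -> float:
    """Activation free energy dG = dH - T*dS, in kJ/mol."""
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    return entry.dH_kJ_mol - T * entry.dS_J_molK / 1e3


def _dg_from_rate(k: float, T: float) -> float:
    """Barrier height (kJ/mol) implied by a first-order rate at T."""
    return -R_GAS * T * np.log(k / (KB_OVER_H * T)) / 1e3


def derive_keq(k_fwd: float, k_rev: float) -> tuple[float, float]:
    """Equilibrium constant K = k_fwd/k_rev.

    Returns ``(K_2sf, K_full)``: the value rounded to two significant
    figures (the convention used when quoting these constants) alongside
    full precision.
    """
    if not (k_fwd > 0 and k_rev > 0):
        raise ValueError("rates must be > 0")
    K = k_fwd / k_rev
    exponent = np.floor(np.log10(K))
    K2 = round(K / 10 ** exponent, 1) * 10 ** exponent
    return float(K2), float(K)


def derive_kon(k_neg2: float, k_neg1: float, k2: float, kc: float) -> float:
    """Overall bimolecular association constant k_ON (M^-1 s^-1).

    The ligand enters from the solvent at ``k_neg2`` and, once in the
    primary docking site, binds with probability k_-1/(k_-1 + k_2 + k_c)
    (rebinding vs escape vs onward migration), giving

        k_ON = k_-2 * k_-1 / (k_-1 + k_2 + k_c).

    This branching-ratio estimate neglects return from deeper sites, which
    only delays rebinding without changing the entry flux.
    """
    for v in (k_neg2, k_neg1, k2, kc):
        if not v > 0:
            raise ValueError("all rates must be > 0")
    return k_neg2 * k_neg1 / (k_neg1 + k2 + kc)


@dataclass
class FreeEnergyProfile:
    """Multi-well free-energy landscape along the ligand-migration path."""

    wells: list[str]
    delta_G_kJmol: list[float]            # per well, reference pinned at 0
    barrier_fwd_kJmol: list[float]        # per step i: well i -> i+1
    barrier_rev_kJmol: list[float]        # per step i: well i+1 -> i
    temperature_K: float
    reference: str = ""
    meta: dict = field(default_factory=dict)

    def well_dG(self, label: str) -> float:
        return self.delta_G_kJmol[self.wells.index(label)]


def free_energy_profile(wells, step_rates, T: float = 293.15,
                        reference: str | None = None) -> FreeEnergyProfile:
    """Free-energy profile from forward/reverse rates along a chain of wells.

    Parameters
    ----------
    wells:
        ordered well labels along the migration path.
    step_rates:
        for each consecutive pair of wells, a ``(k_fwd, k_rev)`` tuple of
        first-order rate constants (s^-1).
    reference:
        well whose free energy is set to 0 (default: the first well).

    Well levels are obtained by path consistency,
    dG(i+1) = dG(i) + dG_fwd(i) - dG_rev(i) = dG(i) - R T ln(k_fwd/k_rev),
    which makes them independent of the traversal direction.
    """
    wells = list(wells)
    if len(wells) < 2:
        raise ValueError("a profile needs at least two wells")
    if len(step_rates) != len(wells) - 1:
        raise ValueError(
            f"chain broken: {len(wells)} wells require {len(wells)-1} "
            f"rate pairs, got {len(step_rates)}")
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    reference = wells[0] if reference is None else reference
    if reference not in wells:
        raise ValueError(f"reference well {reference!r} not in chain")

    fwd, rev, dg = [], [], [0.0]
    for k_f, k_r in step_rates:
        if not (k_f > 0 and k_r > 0):
            raise ValueError("step rates must be > 0")
        gf = _dg_from_rate(k_f, T)
        gr = _dg_from_rate(k_r, T)
        fwd.append(gf)
        rev.append(gr)
        dg.append(dg[-1] + gf - gr)
    shift = dg[wells.index(reference)]
    dg = [g - shift for g in dg]
    return FreeEnergyProfile(wells=wells, delta_G_kJmol=dg,
                             barrier_fwd_kJmol=fwd, barrier_rev_kJmol=rev,
                             temperature_K=T, reference=reference)
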