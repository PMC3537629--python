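"""Physical constants and the CO solubility table.

Eyring convention: transmission coefficient 1, prefactor k_B*T/h.
"""

# Gas constant, J/(mol K) (CODATA)
R_GAS = 8.314462618

# k_B / h in K^-1 s^-1 (Eyring prefactor per kelvin)
KB_OVER_H = 2.08366e10

CELSIUS_OFFSET = 273.15

# Approximate Henry-law solubility of CO in water, mol/L per atm of CO,
# anchored at 1.0e-3 M/atm at 20 C; linear interpolation between nodes.
CO_SOLUBILITY_TABLE = (
    (273.15, 1.42e-3),
    (278.15, 1.30e-3),
    (283.15, 1.21e-3),
    (288.15, 1.10e-3),
    (293.15, 1.00e-3),
    (298.15, 0.92e-3),
    (303.15, 0.85e-3),
    (308.15, 0.79e-3),
    (313.15, 0.74e-3),
    (318.15, 0.70e-3),
)


def co_molar_from_atm(p_atm: float, temperature_K: float = 293.15,
                      table=CO_SOLUBILITY_TABLE) -> float:
    """CO molar concentration in equilibrium with a given CO partial pressure.

    Linear interpolation in the solubility table; clamped at the table edges.
    """
    if p_atm < 0:
        raise ValueError("CO partial pressure must be >= 0")
    ts = [t for t, _ in table]
    ss = [s for _, s in table]
    T = temperature_K
    if T <= ts[0]:
        sol = ss[0]
    elif T >= ts[-1]:
        sol = ss[-1]
    else:
        for i in range(len(ts) - 1):
            if ts[i] <= T <= ts[i + 1]:
                f = (T - ts[i]) / (ts[i + 1] - ts[i])
                sol = ss[i] + f * (ss[i + 1] - ss[i])
                break
    return p_atm * sol
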