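"""Unit conversions between laboratory and internal model units.

The neck model works internally in thermal units: energies in kBT, lengths
in nm, surface densities in nm^-2 and tensions/energy-densities in
kBT nm^-2.  Laboratory values are typically quoted in N/m (tension),
FisB um^-2 (surface density) and J (energy); the conversions are exact at
a configured absolute temperature.
"""

from __future__ import annotations

KB_JOULE_PER_KELVIN = 1.380649e-23
DEFAULT_TEMPERATURE_K = 298.0


def kbt_joules(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kB*T in joules at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_JOULE_PER_KELVIN * temperature


#: supported (from, to) pairs and their converter factories; each factory
#: takes the temperature and returns a multiplicative factor.
_CONVERSIONS = {
    # tension: 1 N/m = 1 J/m^2 = 1e-18 J/nm^2
    ("N/m", "kBT/nm^2"): lambda T: 1e-18 / kbt_joules(T),
    ("kBT/nm^2", "N/m"): lambda T: kbt_joules(T) / 1e-18,
    # surface density
    ("um^-2", "nm^-2"): lambda T: 1e-6,
    ("nm^-2", "um^-2"): lambda T: 1e6,
    # energy
    ("J", "kBT"): lambda T: 1.0 / kbt_joules(T),
    ("kBT", "J"): lambda T: kbt_joules(T),
}

#: tolerated aliases for unit names as they appear in config files
_ALIASES = {
    "n/m": "N/m",
    "kbt/nm^2": "kBT/nm^2",
    "kbt nm^-2": "kBT/nm^2",
    "kbt*nm^-2": "kBT/nm^2",
    "um-2": "um^-2",
    "per_um2": "um^-2",
    "nm-2": "nm^-2",
    "per_nm2": "nm^-2",
    "j": "J",
    "kbt": "kBT",
}


def _canon(unit: str) -> str:
    return _ALIASES.get(unit.strip().lower(), unit.strip())


def convert_units(
    value: float,
    from_unit: str,
    to_unit: str,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Convert ``value`` between supported unit pairs.

    Supported pairs: N/m <-> kBT/nm^2, um^-2 <-> nm^-2, J <-> kBT.
    Identity conversions (same unit) are allowed for any known unit.
    """
    fu, tu = _canon(from_unit), _canon(to_unit)
    if fu == tu:
        return value
    try:
        factor = _CONVERSIONS[(fu, tu)](temperature)
    except KeyError:
        supported = ", ".join(f"{a} -> {b}" for a, b in _CONVERSIONS)
        raise ValueError(
            f"unsupported unit conversion {from_unit!r} -> {to_unit!r}; "
            f"supported: {supported}"
        ) from None
    return value * factor
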