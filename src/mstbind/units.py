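"""Concentration unit handling.

Everything inside the package is μmol/l.  Instrument exports and the
literature mix nmol/l, μmol/l and mmol/l, so converters normalize at the
I/O boundary only.
"""

from __future__ import annotations

from .equilibria import check_concentration

__all__ = ["to_umol_per_l", "UNIT_FACTORS"]

#: Multiplicative factor from each accepted unit to μmol/l.
UNIT_FACTORS: dict[str, float] = {
    "nmol/l": 1.0e-3,
    "umol/l": 1.0,
    "µmol/l": 1.0,
    "μmol/l": 1.0,
    "mmol/l": 1.0e3,
    "nM": 1.0e-3,
    "uM": 1.0,
    "µM": 1.0,
    "μM": 1.0,
    "mM": 1.0e3,
}


def to_umol_per_l(value: float, unit: str = "umol/l") -> float:
    """Convert ``value`` expressed in ``unit`` to μmol/l.

    >>> to_umol_per_l(100, "nmol/l")
    0.1
    """
    try:
        factor = UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(UNIT_FACTORS)}"
        ) from None
    return check_concentration(float(value) * factor, "concentration")
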