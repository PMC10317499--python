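"""Concentration unit handling.

Efficiency is a ratio of logarithms of dissociation constants referenced to a
1 M standard state, so it is sensitive to the unit in which concentrations are
expressed. All internal computation is therefore carried out in molar, and
any quantity entering from a file or a user-facing API must declare its unit
explicitly. Unknown units raise rather than passing through silently.
"""

from __future__ import annotations

import numpy as np

#: multiplicative factor that converts the named unit to molar
_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
}


class UnitError(ValueError):
    """Raised for unknown or undeclared concentration units."""


def unit_factor(unit: str) -> float:
    """Return the molar conversion factor for ``unit`` (e.g. ``'uM'`` -> 1e-6)."""
    try:
        return _TO_MOLAR[unit]
    except KeyError:
        raise UnitError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(set(_TO_MOLAR) - {chr(0xb5) + 'M'})}"
        ) from None


def to_molar(value, unit: str):
    """Convert a concentration (scalar or array) in ``unit`` to molar."""
    return np.asarray(value, dtype=float) * unit_factor(unit)


def from_molar(value, unit: str):
    """Convert a molar concentration to ``unit``."""
    return np.asarray(value, dtype=float) / unit_factor(unit)
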