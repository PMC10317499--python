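"""Shipped physical constants and background-mutation fold table.

The values live in a versioned JSON resource (``data/constants.json``) so a
user can inspect or override them without touching code. Conventions:

* RT = 0.59 kcal/mol (23 degC); binding free energies are RT*ln(Kd / 1 M),
  i.e. the standard state is 1 M.
* The wild-type unliganded gating equilibrium constant L0 is 7.4e-7 at
  -100 mV and falls e-fold per 60 mV of depolarization.  The value used for
  +70 mV recordings carrying the compensating eS450W background is stored as
  its own measured constant, 5.2e-7 (see the JSON ``notes``).
"""

from __future__ import annotations

import json
from importlib import resources

RT_DEFAULT = 0.59  # kcal/mol at 23 degC
STANDARD_STATE_M = 1.0


def _load(name: str) -> dict:
    with resources.files("etachan.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_constants() -> dict:
    """Return the shipped constants table (RT, L0 variants, fold table)."""
    return _load("constants.json")


def load_reference_measurements() -> dict:
    """Return the shipped table of published CRC measurements used by checks."""
    return _load("reference_measurements.json")


_C = load_constants()

L0_WT_MINUS100MV: float = _C["L0"]["wt_-100mV"]          # 7.4e-7
L0_WT_PLUS70MV_S450W: float = _C["L0"]["wt_+70mV_eS450W"]  # 5.2e-7
E_FOLD_MV: float = _C["e_fold_mV"]
BACKGROUND_FOLDS: dict[str, float] = dict(_C["background_folds"])
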