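"""Referencing liganded measurements to the wild-type unliganded gating scale.

CRCs for weak agonists or deactivating mutants are often measured on
"background" constructs that raise the unliganded gating constant L0 so that
clusters of openings become measurable.  Because only L0 is changed (binding
is untouched), the apparent di-liganded gating constant from PO^max is simply
the wild-type-referenced L2 multiplied by the background's L0 fold increase:
dividing it out recovers the corrected L2.  Membrane depolarization lowers L0
e-fold per 60 mV, which composes with the mutation folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import BACKGROUND_FOLDS, E_FOLD_MV, L0_WT_MINUS100MV
from .core import DomainError, _require_positive

__all__ = [
    "BackgroundSpec",
    "l0_at_voltage",
    "background_fold",
    "correct_l2",
]


def l0_at_voltage(
    L0_ref: float,
    V_ref: float,
    V: float,
    e_fold_mV: float = E_FOLD_MV,
) -> float:
    """Unliganded gating constant at membrane potential ``V`` (mV).

    L0 falls e-fold per ``e_fold_mV`` of depolarization:
    ``L0_ref * exp(-(V - V_ref)/e_fold_mV)``.
    """
    _require_positive(L0_ref=L0_ref, e_fold_mV=e_fold_mV)
    return L0_ref * math.exp(-(V - V_ref) / e_fold_mV)


@dataclass(frozen=True)
class BackgroundSpec:
    """A combination of L0-scaling background mutations plus a holding voltage.

    ``fold_table`` maps mutation name -> L0 fold change (>0); the shipped
    table covers eS450W (1.0 by construction: it exactly compensates the
    -100 -> +70 mV depolarization), eL269F (179), eE181W (5.5) and
    dV269A (250) and can be extended or overridden per instance.
    """

    mutations: tuple[str, ...] = ()
    voltage: float = -100.0
    V_ref: float = -100.0
    L0_ref: float = L0_WT_MINUS100MV
    e_fold_mV: float = E_FOLD_MV
    fold_table: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_FOLDS))

    def __post_init__(self):
        for name, f in self.fold_table.items():
            if not f > 0:
                raise DomainError(f"fold for {name!r} must be positive, got {f!r}")

    def combined_fold(self) -> float:
        return background_fold(self)

    def l0(self, apply_voltage: bool = False) -> float:
        """Effective L0 of the construct: reference L0 times the mutation folds,
        optionally voltage-corrected from ``V_ref`` to ``voltage``."""
        base = (
            l0_at_voltage(self.L0_ref, self.V_ref, self.voltage, self.e_fold_mV)
            if apply_voltage
            else self.L0_ref
        )
        return base * self.combined_fold()


def background_fold(spec: BackgroundSpec) -> float:
    """Combined L0 fold change: the product of member folds (1.0 if empty).

    Mutations are assumed non-interacting, so folds multiply and the result
    is order-independent.  Unknown mutations raise by name.
    """
    fold = 1.0
    for m in spec.mutations:
        if m not in spec.fold_table:
            raise DomainError(f"unknown background mutation {m!r}; add it to fold_table")
        fold *= spec.fold_table[m]
    return fold


def correct_l2(L2_apparent: float, fold: float) -> float:
    """Remove a background's L0 scaling from an apparent L2: L2/fold."""
    _require_positive(L2_apparent=L2_apparent, fold=fold)
    return L2_apparent / fold
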