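"""Bind-and-gate equilibrium model for a two-site ligand-gated channel.

The receptor switches spontaneously between a resting closed (C) and an
active open (O) conformation. An agonist A binds weakly to C (equilibrium
dissociation constant KdC, "low affinity") and strongly to O (KdO, "high
affinity"). With two equivalent and independent neurotransmitter sites the
activation pathway is ``A + C <-> AC <-> A2C <-> A2O`` and the gating
equilibrium constants with 0/1/2 agonists bound (L0, L1, L2) close a
thermodynamic cycle with the binding steps:

    L2 / L0 = (KdC / KdO)^2        (two sites)
    L1 / L0 =  KdC / KdO           (one site)

From a concentration-response curve (CRC) the measurable quantities are the
asymptote PO^max and midpoint EC50; given L0 these invert in closed form to
KdC, KdO and the binding free energies

    dG_LA = RT ln(KdC / 1 M),   dG_HA = RT ln(KdO / 1 M)   [kcal/mol]

from which agonist efficacy (lambda = dG_HA - dG_LA) and efficiency

    eta = 1 - dG_LA / dG_HA

follow.  Efficiency is the fraction of the agonist's total binding energy
delivered to the local "hold" rearrangement that initiates gating; it is also
recoverable as m/(m+2) from the slope m of an efficiency plot
(log L2 vs log 1/KdC).

All concentrations are molar; see :mod:`etachan.units` for declared-unit
conversion at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import RT_DEFAULT

__all__ = [
    "ActivationConstants",
    "EnergyProfile",
    "CRCParameters",
    "gating_constant_from_po",
    "po_from_gating_constant",
    "kdc_from_ec50",
    "ec50_from_constants",
    "kdo_from_cycle",
    "coupling_constant",
    "binding_energy",
    "kd_from_energy",
    "efficiency",
    "efficiency_from_kd",
    "efficacy_lambda",
    "eta_from_slope",
    "slope_from_eta",
    "po_curve",
    "predict_crc",
    "profile_sems_from_kd",
    "profile_sems_from_crc",
]


class DomainError(ValueError):
    """Input outside the physical domain of an operation."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise DomainError(f"{name} must be positive and finite, got {value!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationConstants:
    """Equilibrium constants of the two-site activation scheme.

    Attributes
    ----------
    L0, L2 : dimensionless gating equilibrium constants (unliganded,
        di-liganded); L1 is the mono-liganded constant, derived.
    KdC, KdO : molar dissociation constants for the closed and open states.
    c : coupling constant KdC/KdO; L2/L0 == c**2 for two sites.
    """

    L0: float
    L2: float
    KdC: float
    KdO: float
    c: float = field(default=float("nan"))
    L1: float = field(default=float("nan"))

    def __post_init__(self):
        _require_positive(L0=self.L0, L2=self.L2, KdC=self.KdC, KdO=self.KdO)
        c = self.KdC / self.KdO
        if math.isnan(self.c):
            object.__setattr__(self, "c", c)
        elif not math.isclose(self.c, c, rel_tol=1e-9):
            raise DomainError(f"c={self.c} inconsistent with KdC/KdO={c}")
        if not math.isclose(self.L2 / self.L0, c * c, rel_tol=1e-9):
            raise DomainError(
                f"cycle violated: L2/L0={self.L2 / self.L0:.6g} but (KdC/KdO)^2={c * c:.6g}"
            )
        if math.isnan(self.L1):
            object.__setattr__(self, "L1", self.L0 * c)

    @classmethod
    def from_kd(cls, KdC: float, KdO: float, L0: float) -> "ActivationConstants":
        """Build a cycle-consistent constant set from (KdC, KdO, L0)."""
        _require_positive(KdC=KdC, KdO=KdO, L0=L0)
        c = KdC / KdO
        return cls(L0=L0, L2=L0 * c * c, KdC=KdC, KdO=KdO)


@dataclass(frozen=True)
class EnergyProfile:
    """Binding free energies, efficacy and efficiency of one agonist.

    ``dG_LA``/``dG_HA`` are RT*ln(Kd/1M) for the resting and open states
    (kcal/mol); ``lam`` = dG_HA - dG_LA is the efficacy; ``eta`` =
    1 - dG_LA/dG_HA is the efficiency.
    """

    dG_LA: float
    dG_HA: float
    lam: float
    eta: float
    RT: float = RT_DEFAULT

    @classmethod
    def from_kd(cls, KdC: float, KdO: float, RT: float = RT_DEFAULT) -> "EnergyProfile":
        dg_la = binding_energy(KdC, RT)
        dg_ha = binding_energy(KdO, RT)
        return cls(
            dG_LA=dg_la,
            dG_HA=dg_ha,
            lam=efficacy_lambda(dg_ha, dg_la),
            eta=efficiency(dg_la, dg_ha),
            RT=RT,
        )


@dataclass(frozen=True)
class CRCParameters:
    """Descriptors of a measured concentration-response curve.

    EC50 in molar; PO asymptotes in (0,1); nH the Hill coefficient.  The
    ``*_sem`` fields carry first-order standard errors where available.
    """

    EC50: float
    POmax: float
    nH: float = 1.0
    POmin: float = 0.0
    EC50_sem: float = 0.0
    POmax_sem: float = 0.0
    nH_sem: float = 0.0
    POmin_sem: float = 0.0

    def __post_init__(self):
        _require_positive(EC50=self.EC50, nH=self.nH)
        # equality POmin == POmax is the degenerate flat curve of a
        # non-coupling ligand (KdO == KdC); anything inverted is rejected
        if not (0 <= self.POmin <= self.POmax < 1):
            raise DomainError(
                f"require 0 <= POmin <= POmax < 1, got POmin={self.POmin}, POmax={self.POmax}"
            )


# ---------------------------------------------------------------------------
# closed-form conversions
# ---------------------------------------------------------------------------

def gating_constant_from_po(po: float) -> float:
    """Gating equilibrium constant L from an open-probability asymptote.

    L = po/(1-po); e.g. the di-liganded L2 from PO^max or the unliganded L0
    from PO^min.
    """
    if not (0 < po < 1):
        raise DomainError(f"open probability must lie in (0, 1), got {po!r}")
    return po / (1.0 - po)


def po_from_gating_constant(L: float) -> float:
    """Inverse of :func:`gating_constant_from_po`: PO = L/(1+L)."""
    _require_positive(L=L)
    return L / (1.0 + L)


def kdc_from_ec50(ec50: float, L2: float) -> float:
    """Resting-state dissociation constant from CRC midpoint and L2.

    Solving PO(EC50) = PO^max/2 for the two-site curve gives the half-max
    normalized concentration x = EC50/KdC = (1+sqrt(L2+2))/(1+L2), hence

        KdC = EC50 * (L2 + 1) / (1 + sqrt(L2 + 2)).
    """
    _require_positive(ec50=ec50, L2=L2)
    return ec50 * (L2 + 1.0) / (1.0 + math.sqrt(L2 + 2.0))


def ec50_from_constants(KdC: float, L2: float) -> float:
    """CRC midpoint from KdC and L2 (inverse of :func:`kdc_from_ec50`)."""
    _require_positive(KdC=KdC, L2=L2)
    return KdC * (1.0 + math.sqrt(L2 + 2.0)) / (L2 + 1.0)


def kdo_from_cycle(KdC: float, L2: float, L0: float) -> float:
    """Open-state dissociation constant via cycle closure.

    c = sqrt(L2/L0) and KdO = KdC/c.  L2 < L0 (c < 1, inverse agonism) is
    permitted.
    """
    _require_positive(KdC=KdC, L2=L2, L0=L0)
    return KdC / math.sqrt(L2 / L0)


def coupling_constant(KdC: float, KdO: float) -> float:
    """Coupling constant c = KdC/KdO (fold increase in affinity on opening)."""
    _require_positive(KdC=KdC, KdO=KdO)
    return KdC / KdO


def binding_energy(Kd: float, RT: float = RT_DEFAULT) -> float:
    """Binding free energy RT*ln(Kd / 1 M) in the units of RT (kcal/mol).

    ``Kd`` must be molar; sub-molar Kd gives a negative (favorable) energy.
    """
    _require_positive(Kd=Kd, RT=RT)
    return RT * math.log(Kd)


def kd_from_energy(dG: float, RT: float = RT_DEFAULT) -> float:
    """Invert :func:`binding_energy`: Kd = exp(dG/RT) molar."""
    _require_positive(RT=RT)
    return math.exp(dG / RT)


def efficiency(dG_LA: float, dG_HA: float) -> float:
    """Agonist efficiency eta = 1 - dG_LA/dG_HA.

    The fraction of the total binding energy (dG_HA) delivered to the hold
    rearrangement (dG_HA - dG_LA).  Independent of RT and of logarithm base,
    but the underlying Kd values must be molar (1 M standard state).
    """
    if dG_HA == 0:
        raise DomainError("dG_HA must be nonzero")
    return 1.0 - dG_LA / dG_HA


def efficiency_from_kd(KdC: float, KdO: float) -> float:
    """eta directly from molar dissociation constants: 1 - ln KdC / ln KdO."""
    _require_positive(KdC=KdC, KdO=KdO)
    if KdO == 1.0:
        raise DomainError("KdO = 1 M puts dG_HA at the standard state (zero)")
    return 1.0 - math.log(KdC) / math.log(KdO)


def efficacy_lambda(dG_HA: float, dG_LA: float) -> float:
    """Efficacy lambda = dG_HA - dG_LA (kcal/mol); equals -RT*ln(c)."""
    return dG_HA - dG_LA


def eta_from_slope(m: float) -> float:
    """Efficiency from the slope m of an efficiency plot: eta = m/(m+2)."""
    if not (m > 0):
        raise DomainError(f"efficiency-plot slope must be positive, got {m!r}")
    return m / (m + 2.0)


def slope_from_eta(eta: float) -> float:
    """Inverse of :func:`eta_from_slope`: m = 2*eta/(1-eta)."""
    if not (0 < eta < 1):
        raise DomainError(f"eta must lie in (0, 1), got {eta!r}")
    return 2.0 * eta / (1.0 - eta)


def po_curve(A, KdC: float, L2: float, n_sites: int = 2):
    """Theoretical open probability along the main activation pathway.

    With x = A/KdC:

    * two sites:  PO = x^2 L2 / (1 + 2x + x^2 + x^2 L2)
    * one site:   PO = x  L1 / (1 + x + x L1)   (pass L1 as ``L2``)

    Vectorized over ``A`` (molar, >= 0).  Monotone nondecreasing with limit
    L/(1+L) at infinite concentration; the unliganded baseline (L0 pathway)
    is neglected, matching the CRC inversion's assumptions.
    """
    _require_positive(KdC=KdC, L2=L2)
    x = np.asarray(A, dtype=float) / KdC
    if np.any(x < 0):
        raise DomainError("concentrations must be >= 0")
    if n_sites == 2:
        po = x * x * L2 / (1.0 + 2.0 * x + x * x + x * x * L2)
    elif n_sites == 1:
        po = x * L2 / (1.0 + x + x * L2)
    else:
        raise DomainError(f"n_sites must be 1 or 2, got {n_sites!r}")
    return po if po.ndim else float(po)


def predict_crc(KdC: float, KdO: float, L0: float) -> CRCParameters:
    """Forward-predict CRC parameters from (KdC, KdO, L0).

    L2 = L0*(KdC/KdO)^2, PO^max = L2/(1+L2), PO^min = L0/(1+L0) and
    EC50 from :func:`ec50_from_constants`.
    """
    ac = ActivationConstants.from_kd(KdC, KdO, L0)
    return CRCParameters(
        EC50=ec50_from_constants(ac.KdC, ac.L2),
        POmax=po_from_gating_constant(ac.L2),
        POmin=po_from_gating_constant(ac.L0),
        nH=1.0,
    )


# ---------------------------------------------------------------------------
# first-order (delta method) error propagation
# ---------------------------------------------------------------------------

def _eta_partials(KdC: float, KdO: float) -> tuple[float, float]:
    lnC, lnO = math.log(KdC), math.log(KdO)
    return (-1.0 / (KdC * lnO), lnC / (KdO * lnO * lnO))


def profile_sems_from_kd(
    KdC: float,
    KdO: float,
    sem_KdC: float,
    sem_KdO: float,
    RT: float = RT_DEFAULT,
) -> dict[str, float]:
    """Delta-method sems of c, dG_LA, dG_HA, lambda and eta from (KdC, KdO).

    Inputs are molar with independent standard errors; partial derivatives are
    the analytic derivatives of the closed forms.
    """
    _require_positive(KdC=KdC, KdO=KdO)
    if sem_KdC < 0 or sem_KdO < 0:
        raise DomainError("sems must be nonnegative")
    if KdO == 1.0:
        raise DomainError("KdO at the 1 M standard state has dG_HA = 0")
    vC, vO = sem_KdC**2, sem_KdO**2
    d_eta_C, d_eta_O = _eta_partials(KdC, KdO)
    # c = KdC/KdO
    sem_c = math.sqrt(vC / KdO**2 + vO * (KdC / KdO**2) ** 2)
    sem_dg_la = RT * sem_KdC / KdC
    sem_dg_ha = RT * sem_KdO / KdO
    sem_lam = math.hypot(sem_dg_la, sem_dg_ha)
    sem_eta = math.sqrt(vC * d_eta_C**2 + vO * d_eta_O**2)
    return {
        "c": sem_c,
        "dG_LA": sem_dg_la,
        "dG_HA": sem_dg_ha,
        "lam": sem_lam,
        "eta": sem_eta,
    }


def profile_sems_from_crc(
    EC50: float,
    POmax: float,
    sem_EC50: float,
    sem_POmax: float,
    L0: float,
    fold: float = 1.0,
    RT: float = RT_DEFAULT,
    cov_EC50_POmax: float = 0.0,
) -> dict[str, float]:
    """Delta-method sems for the full CRC -> constants -> energies chain.

    The chain is L2 = (POmax/(1-POmax))/fold, KdC = EC50*(L2+1)/(1+sqrt(L2+2)),
    c = sqrt(L2/L0), KdO = KdC/c, then energies and eta.  ``cov_EC50_POmax``
    carries the estimation covariance of the two CRC parameters (they are
    strongly correlated when both come from one fit; pass 0 for independent
    tabulated values).  L0 and the background fold are treated as exact.
    Returns sems for L2, KdC, KdO, c, dG_LA, dG_HA, lam and eta.
    """
    _require_positive(EC50=EC50, L0=L0, fold=fold)
    if not (0 < POmax < 1):
        raise DomainError(f"POmax must lie in (0,1), got {POmax!r}")
    if sem_EC50 < 0 or sem_POmax < 0:
        raise DomainError("sems must be nonnegative")

    L2 = (POmax / (1.0 - POmax)) / fold
    dL2_dp = 1.0 / (fold * (1.0 - POmax) ** 2)

    s = math.sqrt(L2 + 2.0)
    g = (L2 + 1.0) / (1.0 + s)
    dg_dL2 = ((1.0 + s) - (L2 + 1.0) / (2.0 * s)) / (1.0 + s) ** 2

    KdC = EC50 * g
    dKdC_dE = g
    dKdC_dp = EC50 * dg_dL2 * dL2_dp

    c = math.sqrt(L2 / L0)
    dc_dp = dL2_dp / (2.0 * c * L0)

    KdO = KdC / c
    dKdO_dE = dKdC_dE / c
    dKdO_dp = dKdC_dp / c - KdC * dc_dp / c**2

    d_eta_C, d_eta_O = _eta_partials(KdC, KdO)
    deta_dE = d_eta_C * dKdC_dE + d_eta_O * dKdO_dE
    deta_dp = d_eta_C * dKdC_dp + d_eta_O * dKdO_dp

    dlam_dE = RT * (dKdO_dE / KdO - dKdC_dE / KdC)
    dlam_dp = RT * (dKdO_dp / KdO - dKdC_dp / KdC)

    vE, vp, cEp = sem_EC50**2, sem_POmax**2, cov_EC50_POmax

    def _sem(dE: float, dp: float) -> float:
        return math.sqrt(max(vE * dE * dE + vp * dp * dp + 2.0 * cEp * dE * dp, 0.0))

    return {
        "L2": abs(dL2_dp) * sem_POmax,
        "KdC": _sem(dKdC_dE, dKdC_dp),
        "KdO": _sem(dKdO_dE, dKdO_dp),
        "c": abs(dc_dp) * sem_POmax,
        "dG_LA": _sem(RT * dKdC_dE / KdC, RT * dKdC_dp / KdC),
        "dG_HA": _sem(RT * dKdO_dE / KdO, RT * dKdO_dp / KdO),
        "lam": _sem(dlam_dE, dlam_dp),
        "eta": _sem(deta_dE, deta_dp),
    }
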