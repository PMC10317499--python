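"""Hill fitting of concentration-response curves and conversion to profiles.

A CRC is a set of (agonist concentration, cluster open probability) points.
The midpoint and maximum are estimated with the monophasic Hill equation

    PO([A]) = POmin + (POmax - POmin) / (1 + (EC50/[A])^nH)

and (EC50, POmax) are then inverted through the bind-and-gate closed forms
(:mod:`etachan.core`) into equilibrium constants and an energy profile.  nH is
fitted (bounded) because it carries information about the shape, but it is not
used downstream: the site count is known a priori.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from . import core
from .constants import RT_DEFAULT
from .core import (
    ActivationConstants,
    CRCParameters,
    DomainError,
    EnergyProfile,
    profile_sems_from_crc,
)
from .units import to_molar

__all__ = [
    "CRCPoint",
    "CRCDataset",
    "HillCurve",
    "HillFit",
    "fit_hill",
    "crc_to_profile",
    "profile_from_crc_params",
]


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the curve (e.g. all PO equal)."""


class CRCPoint(NamedTuple):
    """One CRC observation: molar concentration, PO estimate, optional sem/n."""

    A: float
    po: float
    sem: float = float("nan")
    n: int = 1


@dataclass
class CRCDataset:
    """Labelled CRC measurements for one agonist/construct.

    ``points`` is a DataFrame with columns ``A`` (molar), ``po`` and optional
    ``sem``/``n``; it is sorted by concentration on construction.  At least
    three distinct concentrations are required for fitting.
    """

    label: str
    points: pd.DataFrame
    background: str = ""
    voltage: float = -100.0

    def __post_init__(self):
        df = pd.DataFrame(self.points).copy()
        if not {"A", "po"}.issubset(df.columns):
            raise ValueError("points must have columns 'A' and 'po'")
        if (df["A"] < 0).any():
            raise DomainError("concentrations must be >= 0")
        if ((df["po"] < 0) | (df["po"] > 1)).any():
            raise DomainError("po values must lie in [0, 1]")
        self.points = df.sort_values("A", kind="stable").reset_index(drop=True)

    @classmethod
    def from_arrays(cls, label, concentrations, po, unit="M", sem=None, **kw):
        df = pd.DataFrame({"A": to_molar(concentrations, unit), "po": np.asarray(po, float)})
        if sem is not None:
            df["sem"] = np.asarray(sem, float)
        return cls(label=label, points=df, **kw)

    @property
    def concentrations(self) -> np.ndarray:
        return self.points["A"].to_numpy()

    @property
    def po(self) -> np.ndarray:
        return self.points["po"].to_numpy()


def _hill(a, po_max, log10_ec50, nh, po_min):
    ec50 = 10.0**log10_ec50
    with np.errstate(divide="ignore"):
        ratio = np.where(a > 0, (ec50 / np.where(a > 0, a, 1.0)) ** nh, np.inf)
    return po_min + (po_max - po_min) / (1.0 + ratio)


class HillCurve(BaseEstimator, RegressorMixin):
    """Least-squares monophasic Hill fit of PO versus concentration.

    Parameters
    ----------
    n_h : "free" or float
        Fit the Hill coefficient within ``nh_bounds`` (default) or fix it.
    po_min : float
        Zero-concentration asymptote, fixed (liganded baselines are ~1e-6,
        effectively zero).
    weighting : None or "inverse_variance"
        Unweighted least squares by default; inverse-variance uses the
        per-point sems passed to :meth:`fit`.
    nh_bounds : (low, high)
        Box bounds on a free Hill coefficient.

    Fitted attributes: ``po_max_``, ``ec50_``, ``n_h_`` with ``*_sem_``
    companions, ``params_`` (:class:`~etachan.core.CRCParameters`), ``cov_``,
    ``rss_``, ``converged_``, ``ec50_in_range_``.
    """

    def __init__(self, n_h="free", po_min=0.0, weighting=None, nh_bounds=(0.5, 3.0)):
        self.n_h = n_h
        self.po_min = po_min
        self.weighting = weighting
        self.nh_bounds = nh_bounds

    # -- starting rule: POmax from the top of the data, EC50 from log
    #    interpolation to the half-max crossing, nH = 1.5.
    def _start(self, a, y):
        po_max0 = float(np.max(y))
        half = self.po_min + 0.5 * (po_max0 - self.po_min)
        pos = a > 0
        la, ya = np.log10(a[pos]), y[pos]
        above = np.nonzero(ya >= half)[0]
        if len(above) == 0 or above[0] == 0:
            log_ec50_0 = float(np.median(la))
        else:
            i, j = above[0] - 1, above[0]
            frac = (half - ya[i]) / (ya[j] - ya[i]) if ya[j] != ya[i] else 0.5
            log_ec50_0 = float(la[i] + frac * (la[j] - la[i]))
        return po_max0, log_ec50_0

    def fit(self, X, y, sample_sem=None):
        a = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if a.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if len(np.unique(a)) < 3:
            raise DegenerateDataError("need >= 3 distinct concentrations")
        if np.ptp(y) == 0:
            raise DegenerateDataError("all po values identical; curve not identifiable")
        if np.any((y < 0) | (y > 1)):
            raise DomainError("po values must lie in [0, 1]")

        po_max0, log_ec50_0 = self._start(a, y)
        po_max0 = min(max(po_max0, 1e-4), 1.0 - 1e-9)
        free_nh = self.n_h == "free"
        if free_nh:
            p0 = [po_max0, log_ec50_0, 1.5]
            lo = [1e-9, log_ec50_0 - 12.0, self.nh_bounds[0]]
            hi = [1.0 - 1e-12, log_ec50_0 + 12.0, self.nh_bounds[1]]
            f = lambda A, pm, le, nh: _hill(A, pm, le, nh, self.po_min)
        else:
            nh_fixed = float(self.n_h)
            p0 = [po_max0, log_ec50_0]
            lo = [1e-9, log_ec50_0 - 12.0]
            hi = [1.0 - 1e-12, log_ec50_0 + 12.0]
            f = lambda A, pm, le: _hill(A, pm, le, nh_fixed, self.po_min)

        sigma = None
        if self.weighting == "inverse_variance":
            if sample_sem is None:
                raise ValueError("inverse_variance weighting requires per-point sems")
            sigma = np.asarray(sample_sem, dtype=float).reshape(-1)
            if np.any(sigma <= 0):
                raise ValueError("sems must be positive for inverse-variance weighting")
        elif self.weighting is not None:
            raise ValueError(f"unknown weighting {self.weighting!r}")

        self.converged_ = True
        self.message_ = ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    f, a, y, p0=p0, bounds=(lo, hi), sigma=sigma,
                    absolute_sigma=sigma is not None, maxfev=20000,
                )
        except RuntimeError as err:  # flagged, never silent
            self.converged_ = False
            self.message_ = str(err)
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((len(p0), len(p0)), np.nan)

        self.po_max_ = float(popt[0])
        self.ec50_ = float(10.0 ** popt[1])
        self.n_h_ = float(popt[2]) if free_nh else float(self.n_h)
        self.cov_ = pcov
        sems = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.po_max_sem_ = float(sems[0])
        self.ec50_sem_ = float(math.log(10.0) * self.ec50_ * sems[1])
        self.n_h_sem_ = float(sems[2]) if free_nh else 0.0

        resid = y - f(a, *popt)
        self.rss_ = float(resid @ resid)
        pos = a[a > 0]
        self.ec50_in_range_ = bool(
            pos.size and pos.min() / 10.0 <= self.ec50_ <= pos.max() * 10.0
        )
        self.params_ = CRCParameters(
            EC50=self.ec50_,
            POmax=self.po_max_,
            POmin=self.po_min,
            nH=self.n_h_,
            EC50_sem=self.ec50_sem_,
            POmax_sem=self.po_max_sem_,
            nH_sem=self.n_h_sem_,
        )
        return self

    def predict(self, X):
        a = np.asarray(X, dtype=float).reshape(-1)
        return _hill(a, self.po_max_, math.log10(self.ec50_), self.n_h_, self.po_min)


@dataclass(frozen=True)
class HillFit:
    """Result container for a fitted CRC."""

    params: CRCParameters
    rss: float
    converged: bool
    ec50_in_range: bool
    cov: np.ndarray = field(repr=False)
    message: str = ""


def fit_hill(
    dataset: CRCDataset,
    nH_mode: str = "free",
    weighting=None,
) -> HillFit:
    """Fit a :class:`CRCDataset` with the Hill equation.

    ``nH_mode`` is ``"free"`` (bounded [0.5, 3]) or ``"fixed"`` (nH = 1);
    ``weighting`` as in :class:`HillCurve`.
    """
    est = HillCurve(n_h=("free" if nH_mode == "free" else 1.0), weighting=weighting)
    sem = dataset.points["sem"].to_numpy() if "sem" in dataset.points else None
    est.fit(dataset.concentrations, dataset.po, sample_sem=sem)
    return HillFit(
        params=est.params_,
        rss=est.rss_,
        converged=est.converged_,
        ec50_in_range=est.ec50_in_range_,
        cov=est.cov_,
        message=est.message_,
    )


def profile_from_crc_params(
    EC50: float,
    POmax: float,
    L0: float,
    fold: float = 1.0,
    RT: float = RT_DEFAULT,
    sem_EC50: float = 0.0,
    sem_POmax: float = 0.0,
    cov_EC50_POmax: float = 0.0,
) -> dict:
    """Invert (EC50, POmax) into constants, energies and eta with sems.

    Steps: apparent L2 = POmax/(1-POmax); corrected L2 = apparent/fold
    (removing the background's L0 scaling); KdC from the EC50 closed form;
    KdO by cycle closure with the wild-type-referenced L0; energies and eta
    from the molar Kd values; sems by the delta method.
    """
    if not (0 < POmax < 1):
        raise DomainError(f"POmax must lie in (0,1), got {POmax!r}")
    L2_apparent = core.gating_constant_from_po(POmax)
    L2 = L2_apparent / fold
    KdC = core.kdc_from_ec50(EC50, L2)
    KdO = core.kdo_from_cycle(KdC, L2, L0)
    ac = ActivationConstants(L0=L0, L2=L2, KdC=KdC, KdO=KdO)
    ep = EnergyProfile.from_kd(KdC, KdO, RT)
    sems = profile_sems_from_crc(
        EC50, POmax, sem_EC50, sem_POmax, L0, fold, RT, cov_EC50_POmax=cov_EC50_POmax
    )
    return {
        "EC50": EC50,
        "POmax": POmax,
        "L2_apparent": L2_apparent,
        "L2": L2,
        "KdC": KdC,
        "KdO": KdO,
        "c": ac.c,
        "dG_LA": ep.dG_LA,
        "dG_HA": ep.dG_HA,
        "lam": ep.lam,
        "eta": ep.eta,
        "constants": ac,
        "profile": ep,
        "sems": sems,
    }


def crc_to_profile(
    fit: HillFit,
    L0: float,
    l2_correction_fold: float = 1.0,
    RT: float = RT_DEFAULT,
) -> dict:
    """Convert a :class:`HillFit` into activation constants and energies.

    The Hill fit's (EC50, POmax) estimation covariance is carried into the
    delta-method sems (fit parameter order: POmax, log10 EC50[, nH]).
    """
    p = fit.params
    cov = 0.0
    if fit.cov is not None and np.all(np.isfinite(fit.cov[:2, :2])):
        cov = float(fit.cov[0, 1]) * math.log(10.0) * p.EC50  # d EC50/d log10EC50
    return profile_from_crc_params(
        p.EC50,
        p.POmax,
        L0,
        fold=l2_correction_fold,
        RT=RT,
        sem_EC50=p.EC50_sem,
        sem_POmax=p.POmax_sem,
        cov_EC50_POmax=cov,
    )
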