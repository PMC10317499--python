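"""Population-level efficiency statistics.

Three complementary estimates of a class-average efficiency are implemented:

* the efficiency plot, log10 L2 = log10 L0 + m * log10(1/KdC), whose slope m
  gives eta = m/(m+2) (with the intercept pinned at log10 L0 when the
  unliganded gating constant is known a priori);
* the energy-correlation plot, dG_LA versus dG_HA, whose slope s gives
  eta = 1 - s (useful when mutations shift L0 so the intercept is not shared);
* the mean of per-member eta values.

For noiseless data from a single class all three coincide.  Populations of
eta values are partitioned into discrete classes by x-means: k-means at each
candidate k, scored by the corrected Akaike information criterion, with the
constraint that every class keep at least two members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import DomainError, eta_from_slope

__all__ = [
    "EfficiencyFit",
    "EfficiencyLine",
    "fit_efficiency_plot",
    "EnergyCorrelationFit",
    "EnergyCorrelation",
    "fit_energy_correlation",
    "ClassSet",
    "EtaXMeans",
    "xmeans_classify",
    "pearson_correlation",
    "compare_slopes_ancova",
]


# ---------------------------------------------------------------------------
# efficiency plot (fixed or free intercept)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyFit:
    m: float
    intercept: float
    intercept_fixed: bool
    eta: float
    r: float
    p: float
    n: int


class EfficiencyLine(BaseEstimator):
    """Straight-line fit of log10 L2 versus log10(1/KdC).

    ``intercept``: a float fixes the line through (0, intercept) — pass
    log10(L0) when L0 is known a priori; ``None`` fits it.  Fitted
    attributes: ``m_``, ``intercept_``, ``eta_`` (= m/(m+2)), ``r_``, ``p_``.
    """

    def __init__(self, intercept=None):
        self.intercept = intercept

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape or len(x) < 2:
            raise DomainError("need >= 2 (log 1/KdC, log L2) points")
        if np.ptp(x) == 0:
            raise DomainError("degenerate abscissae: all KdC identical")
        if self.intercept is not None:
            b = float(self.intercept)
            m = float(np.sum(x * (y - b)) / np.sum(x * x))
        else:
            m, b = (float(v) for v in np.polyfit(x, y, 1))
        self.m_ = m
        self.intercept_ = b
        self.eta_ = eta_from_slope(m)
        if len(x) >= 3 and np.ptp(y) > 0:
            self.r_, self.p_ = pearson_correlation(x, y)
        else:
            self.r_, self.p_ = float("nan"), float("nan")
        self.n_ = len(x)
        return self

    def predict(self, X):
        return self.intercept_ + self.m_ * np.asarray(X, dtype=float).reshape(-1)


def fit_efficiency_plot(log10_inv_kdc, log10_L2, logL0=None) -> EfficiencyFit:
    """Fit an efficiency plot; ``logL0`` (log10) fixes the intercept if given.

    KdC must be molar for the resulting eta to be meaningful.
    """
    est = EfficiencyLine(intercept=logL0).fit(log10_inv_kdc, log10_L2)
    return EfficiencyFit(
        m=est.m_,
        intercept=est.intercept_,
        intercept_fixed=logL0 is not None,
        eta=est.eta_,
        r=est.r_,
        p=est.p_,
        n=est.n_,
    )


# ---------------------------------------------------------------------------
# energy correlation (dG_LA vs dG_HA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyCorrelationFit:
    slope: float
    intercept: float
    eta: float
    r: float
    p: float
    n: int


class EnergyCorrelation(BaseEstimator):
    """OLS of weak (dG_LA) on strong (dG_HA) binding energy; eta = 1 - slope."""

    def fit(self, X, y):
        ha = np.asarray(X, dtype=float).reshape(-1)
        la = np.asarray(y, dtype=float).reshape(-1)
        if ha.shape != la.shape or len(ha) < 2:
            raise DomainError("need >= 2 (dG_LA, dG_HA) pairs")
        if np.ptp(ha) == 0:
            raise DomainError("degenerate abscissae: all dG_HA identical")
        slope, intercept = (float(v) for v in np.polyfit(ha, la, 1))
        self.slope_ = slope
        self.intercept_ = intercept
        self.eta_ = 1.0 - slope
        if len(ha) >= 3 and np.ptp(la) > 0:
            self.r_, self.p_ = pearson_correlation(ha, la)
        else:
            self.r_, self.p_ = float("nan"), float("nan")
        self.n_ = len(ha)
        return self


def fit_energy_correlation(dG_LA, dG_HA) -> EnergyCorrelationFit:
    """Fit dG_LA versus dG_HA pairs; returns slope and eta = 1 - slope."""
    est = EnergyCorrelation().fit(dG_HA, dG_LA)
    return EnergyCorrelationFit(
        slope=est.slope_,
        intercept=est.intercept_,
        eta=est.eta_,
        r=est.r_,
        p=est.p_,
        n=est.n_,
    )


# ---------------------------------------------------------------------------
# x-means classification of eta values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSet:
    """An x-means partition of 1-D eta values.

    Classes are ordered by ascending mean; ``assignments`` holds the class
    index of each input value in input order.
    """

    assignments: np.ndarray = field(repr=False)
    k: int
    means: np.ndarray
    sds: np.ndarray
    sizes: np.ndarray
    ssr: float
    aicc: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "sd": self.sds, "n": self.sizes})


def _aicc(n: int, ssr: float, sizes) -> float:
    """Corrected AIC of a k-class partition under the classification likelihood.

    The model is a shared-variance Gaussian classification mixture: each point
    belongs to the class it was assigned to, contributing its class proportion
    nj/n and a Gaussian density with sigma^2 = SSR/n.  Parameters counted:
    k centers + 1 variance.  Without the membership term, splitting any
    Gaussian class cuts its SSR by ~64% and the criterion over-splits at
    small n.  When the small-sample correction is undefined (n <= k'+1)
    plain AIC is used.
    """
    k = len(sizes)
    kp = k + 1
    sigma2 = max(ssr, 1e-300) / n  # SSR = 0 (identical values) -> ties, lower k wins
    membership = sum(nj * math.log(nj / n) for nj in sizes)
    minus2ll = -2.0 * membership + n * math.log(2.0 * math.pi * sigma2) + n
    aic = minus2ll + 2 * kp
    if n - kp - 1 <= 0:
        return aic
    return aic + 2 * kp * (kp + 1) / (n - kp - 1)


class EtaXMeans(BaseEstimator, ClusterMixin):
    """x-means partition of scalar values with an AICc model-size rule.

    k-means is run at every k in [1, k_max] (``n_restarts`` seeded
    initializations each); solutions containing a class with fewer than
    ``min_size`` members are discarded; the surviving k with the lowest AICc
    wins, ties broken by lower SSR then lower k.  Values are sorted
    internally, making the result invariant to input order.
    """

    def __init__(self, k_max=8, min_size=2, n_restarts=32, random_state=0):
        self.k_max = k_max
        self.min_size = min_size
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        v = np.asarray(X, dtype=float).reshape(-1)
        if len(v) < 4:
            raise DomainError("need >= 4 values to classify")
        order = np.argsort(v, kind="stable")
        vs = v[order].reshape(-1, 1)
        n = len(v)

        candidates = []
        for k in range(1, self.k_max + 1):
            if k * self.min_size > n:
                break
            sizes = np.array([n])
            if k == 1:
                labels = np.zeros(n, dtype=int)
                ssr = float(np.sum((vs - vs.mean()) ** 2))
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # duplicate points at high k
                    km = KMeans(
                        n_clusters=k,
                        n_init=self.n_restarts,
                        random_state=self.random_state,
                    ).fit(vs)
                labels = km.labels_
                ssr = float(km.inertia_)
                sizes = np.bincount(labels, minlength=k)
                if sizes.min() < self.min_size:
                    continue
            candidates.append((_aicc(n, ssr, sizes), ssr, k, labels))

        if not candidates:
            raise DomainError("no admissible partition honours the minimum class size")
        aicc, ssr, k, labels_sorted = min(candidates, key=lambda t: (t[0], t[1], t[2]))

        # order classes by ascending mean and map labels back to input order
        means = np.array([vs[labels_sorted == j].mean() for j in range(k)])
        rank = np.argsort(means, kind="stable")
        remap = np.empty(k, dtype=int)
        remap[rank] = np.arange(k)
        relabelled = remap[labels_sorted]
        assignments = np.empty(n, dtype=int)
        assignments[order] = relabelled

        self.labels_ = assignments
        self.k_ = k
        self.class_means_ = np.array([v[assignments == j].mean() for j in range(k)])
        self.class_sds_ = np.array(
            [v[assignments == j].std(ddof=1) if (assignments == j).sum() > 1 else 0.0
             for j in range(k)]
        )
        self.class_sizes_ = np.bincount(assignments, minlength=k)
        self.ssr_ = ssr
        self.aicc_ = aicc
        return self

    def predict(self, X):
        v = np.asarray(X, dtype=float).reshape(-1)
        return np.argmin(np.abs(v[:, None] - self.class_means_[None, :]), axis=1)


def xmeans_classify(values, k_max=8, min_size=2, seed=0, n_restarts=32) -> ClassSet:
    """Partition eta values into classes; see :class:`EtaXMeans`."""
    est = EtaXMeans(
        k_max=k_max, min_size=min_size, n_restarts=n_restarts, random_state=seed
    ).fit(values)
    return ClassSet(
        assignments=est.labels_,
        k=est.k_,
        means=est.class_means_,
        sds=est.class_sds_,
        sizes=est.class_sizes_,
        ssr=est.ssr_,
        aicc=est.aicc_,
    )


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------

def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-tailed t-distributed p-value."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(x) < 3 or x.shape != y.shape:
        raise DomainError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_slopes_ancova(groups: dict) -> tuple[float, float]:
    """Test whether regression slopes differ between labelled groups.

    ``groups`` maps label -> (x, y) arrays.  Fits the common-slope model
    ``y ~ x + group`` against the per-group-slope model ``y ~ x * group`` and
    returns the F statistic and p-value of the interaction (standard ANCOVA
    homogeneity-of-slopes test).
    """
    if len(groups) < 2:
        raise DomainError("need >= 2 groups")
    frames = []
    for label, (x, y) in groups.items():
        x = np.asarray(x, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) < 3:
            raise DomainError(f"group {label!r} has < 3 points")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": str(label)}))
    df = pd.concat(frames, ignore_index=True)
    reduced = smf.ols("y ~ x + C(g)", data=df).fit()
    full = smf.ols("y ~ x * C(g)", data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise DomainError("singular design: interaction model not identifiable")
    tss = float(np.var(df["y"])) * len(df)
    if reduced.ssr <= 1e-12 * max(tss, 1.0):
        # the common-slope model already fits exactly: no slope heterogeneity
        return 0.0, 1.0
    table = sm.stats.anova_lm(reduced, full)
    return float(table["F"].iloc[1]), float(table["Pr(>F)"].iloc[1])
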