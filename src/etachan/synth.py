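"""Ground-truth synthetic data: kinetic schemes, dwell sequences, CRCs, populations.

Everything the analysis pipeline consumes can be generated here from known
truth, so each stage has a seeded recovery test:

* :func:`scheme_from_constants` turns equilibrium truth (KdC, KdO, L0) into a
  detailed-balanced rate scheme for the two-site activation pathway
  ``C <-> AC <-> A2C <-> A2O`` plus a desensitized state A2D entered from
  A2O (long inter-cluster gaps).  Only the equilibrium constants matter for
  the analysis targets; the kinetic scales are design choices picked so that
  open/shut sojourns and desensitized gaps are well separated at
  tcrit = 20 ms.
* :func:`simulate_intervals` draws an exact continuous-time Markov trajectory
  and aggregates it into alternating open/shut dwell intervals.
* :func:`simulate_crc` produces noisy CRC datasets, either by Gaussian noise
  on the theoretical PO or by running the full dwell-analysis chain per
  concentration.
* :func:`generate_population` plants eta classes (default: the five observed
  class means) for clustering and regression recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dwell as dw
from .constants import L0_WT_PLUS70MV_S450W
from .core import ActivationConstants, DomainError, _require_positive, po_curve
from .crc import CRCDataset

__all__ = [
    "DEFAULT_SCALES",
    "DEFAULT_CLASS_MEANS",
    "DEFAULT_CLASS_SDS",
    "RateScheme",
    "TruthRecord",
    "scheme_from_constants",
    "stationary_distribution",
    "stationary_po",
    "simulate_intervals",
    "simulate_crc",
    "generate_population",
    "write_scenario",
]

#: kinetic scales (s^-1 or M^-1 s^-1): association to C at 1e8 per site,
#: association to O at the diffusion limit, di-liganded opening 5e4,
#: unliganded closing 5e3, desensitization from A2O 20 in / 2 out.
DEFAULT_SCALES = {
    "kon_C": 1e8,
    "kon_O": 1e9,
    "f2": 5e4,
    "b0": 5e3,
    "kdes": 20.0,
    "kres": 2.0,
}

#: planted eta class means/sds: the five observed agonist efficiency classes
DEFAULT_CLASS_MEANS = (0.32, 0.41, 0.45, 0.51, 0.55)
DEFAULT_CLASS_SDS = (0.035, 0.005, 0.014, 0.008, 0.015)


@dataclass
class RateScheme:
    """An aggregated-Markov activation scheme.

    ``transitions`` holds (i, j, rate, conc_order): the effective rate is
    ``rate * A**conc_order`` (conc_order is 1 for association steps, else 0).
    """

    state_names: tuple[str, ...]
    transitions: list[tuple[int, int, float, int]]
    open_states: frozenset[int]
    desensitized_states: frozenset[int]
    constants: ActivationConstants
    scales: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def main_pathway_states(self) -> list[int]:
        """Indices of the C -> AC -> A2C -> A2O pathway (CRC inversion model)."""
        keep = {"C", "AC", "A2C", "A2O"}
        return [i for i, s in enumerate(self.state_names) if s in keep]

    def q_matrix(self, A: float) -> np.ndarray:
        """Generator matrix at agonist concentration ``A`` (molar)."""
        if A < 0:
            raise DomainError("concentration must be >= 0")
        q = np.zeros((self.n_states, self.n_states))
        for i, j, rate, order in self.transitions:
            q[i, j] += rate * (A**order)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def scheme_from_constants(
    KdC: float,
    KdO: float,
    L0: float,
    scales: dict | None = None,
    full_cycle: bool = False,
) -> RateScheme:
    """Build a detailed-balanced rate scheme from equilibrium truth.

    Dissociation rates follow from the association scales and the Kd values
    (koff_C = kon_C*KdC, koff_O = kon_O*KdO); the di-liganded closing rate is
    b2 = f2/L2 with L2 = L0*(KdC/KdO)^2, placing the agonist dependence on
    gating in the opening direction.  ``full_cycle=True`` adds the unliganded
    and mono-liganded open states (O, AO) with f1/b1 = L1 = L0*(KdC/KdO) and
    open-state binding, closing the thermodynamic cycle explicitly; the
    default five-state scheme is the main pathway plus desensitization.
    """
    s = dict(DEFAULT_SCALES)
    if scales:
        unknown = set(scales) - set(s)
        if unknown:
            raise DomainError(f"unknown scale keys: {sorted(unknown)}")
        s.update(scales)
    for name, v in s.items():
        if not v > 0:
            raise DomainError(f"scale {name!r} must be positive, got {v!r}")
    ac = ActivationConstants.from_kd(KdC, KdO, L0)
    koff_C = s["kon_C"] * ac.KdC
    koff_O = s["kon_O"] * ac.KdO
    b2 = s["f2"] / ac.L2

    names = ["C", "AC", "A2C", "A2O", "A2D"]
    idx = {n: i for i, n in enumerate(names)}
    tr: list[tuple[int, int, float, int]] = [
        (idx["C"], idx["AC"], 2.0 * s["kon_C"], 1),
        (idx["AC"], idx["C"], koff_C, 0),
        (idx["AC"], idx["A2C"], s["kon_C"], 1),
        (idx["A2C"], idx["AC"], 2.0 * koff_C, 0),
        (idx["A2C"], idx["A2O"], s["f2"], 0),
        (idx["A2O"], idx["A2C"], b2, 0),
        (idx["A2O"], idx["A2D"], s["kdes"], 0),
        (idx["A2D"], idx["A2O"], s["kres"], 0),
    ]
    open_states = {idx["A2O"]}

    if full_cycle:
        for extra in ("O", "AO"):
            idx[extra] = len(names)
            names.append(extra)
        f0 = ac.L0 * s["b0"]
        f1 = ac.L1 * b2
        tr += [
            (idx["C"], idx["O"], f0, 0),
            (idx["O"], idx["C"], s["b0"], 0),
            (idx["AC"], idx["AO"], f1, 0),
            (idx["AO"], idx["AC"], b2, 0),
            (idx["O"], idx["AO"], 2.0 * s["kon_O"], 1),
            (idx["AO"], idx["O"], koff_O, 0),
            (idx["AO"], idx["A2O"], s["kon_O"], 1),
            (idx["A2O"], idx["AO"], 2.0 * koff_O, 0),
        ]
        open_states |= {idx["O"], idx["AO"]}

    scheme = RateScheme(
        state_names=tuple(names),
        transitions=tr,
        open_states=frozenset(open_states),
        desensitized_states=frozenset({idx["A2D"]}),
        constants=ac,
        scales={**s, "koff_C": koff_C, "koff_O": koff_O, "b2": b2},
    )
    _assert_detailed_balance(scheme)
    return scheme


def _assert_detailed_balance(scheme: RateScheme, A: float = 1.0) -> None:
    """Hard check: Kolmogorov's criterion on every fundamental cycle.

    For a reversible scheme, around any cycle the product of clockwise rates
    equals the product of counter-clockwise rates.  Cycles contain equally
    many binding and unbinding steps, so the agonist concentration cancels
    and A = 1 M is a valid probe.  Exact in the rates (no stationary solve),
    so a tight relative tolerance applies.
    """
    import networkx as nx

    q = scheme.q_matrix(A)
    g = nx.Graph()
    g.add_nodes_from(range(scheme.n_states))
    for i, j, _, _ in scheme.transitions:
        if q[j, i] <= 0:
            raise AssertionError(
                f"irreversible transition {scheme.state_names[i]}->{scheme.state_names[j]}"
            )
        g.add_edge(i, j)
    for cycle in nx.cycle_basis(g):
        fwd = bwd = 1.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            fwd *= q[a, b]
            bwd *= q[b, a]
        if not np.isclose(fwd, bwd, rtol=1e-9):
            names = "->".join(scheme.state_names[s] for s in cycle)
            raise AssertionError(f"detailed balance violated on cycle {names}")
    c = scheme.constants
    if not np.isclose(c.L2 / c.L0, (c.KdC / c.KdO) ** 2, rtol=1e-9):
        raise AssertionError("cycle constraint L2/L0 = (KdC/KdO)^2 violated")


def stationary_distribution(
    scheme: RateScheme, A: float, states: list[int] | None = None
) -> np.ndarray:
    """Stationary distribution of the generator (optionally of a sub-model).

    ``states`` restricts the generator to the given indices (e.g. the main
    activation pathway); the returned vector is indexed like ``states`` (or
    all states) and sums to 1.
    """
    q = scheme.q_matrix(A)
    if states is not None:
        q = q[np.ix_(states, states)]
        q = q - np.diag(np.diag(q))
        np.fill_diagonal(q, -q.sum(axis=1))
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return pi


def stationary_po(scheme: RateScheme, A: float, main_pathway: bool = True) -> float:
    """Open probability from the stationary distribution.

    With ``main_pathway=True`` the generator is restricted to
    C/AC/A2C/A2O — the sub-model the CRC inversion assumes — and the result
    equals :func:`~etachan.core.po_curve` to numerical precision.  Otherwise
    the full scheme excluding desensitized occupancy is used.
    """
    if main_pathway:
        states = scheme.main_pathway_states()
        pi = stationary_distribution(scheme, A, states=states)
        is_open = np.array([s in scheme.open_states for s in states])
    else:
        keep = [i for i in range(scheme.n_states) if i not in scheme.desensitized_states]
        pi = stationary_distribution(scheme, A, states=keep)
        is_open = np.array([s in scheme.open_states for s in keep])
    return float(pi[is_open].sum())


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth attached to every synthetic fixture."""

    KdC: float
    KdO: float
    L0: float
    L2: float
    eta: float
    seed: int
    concentrations: tuple[float, ...] = ()
    po_theory: tuple[float, ...] = ()

    @classmethod
    def from_kd(cls, KdC, KdO, L0, seed=0, concentrations=()):
        from .core import efficiency_from_kd

        ac = ActivationConstants.from_kd(KdC, KdO, L0)
        conc = tuple(float(a) for a in concentrations)
        po = tuple(float(po_curve(a, ac.KdC, ac.L2)) for a in conc)
        return cls(
            KdC=ac.KdC, KdO=ac.KdO, L0=ac.L0, L2=ac.L2,
            eta=efficiency_from_kd(ac.KdC, ac.KdO),
            seed=seed, concentrations=conc, po_theory=po,
        )

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("KdC", "KdO", "L0", "L2", "eta", "seed", "concentrations", "po_theory")}
        return json.dumps(d, indent=1)


def simulate_intervals(
    scheme: RateScheme,
    A: float,
    n_events: int,
    seed: int = 0,
    start_state: str = "C",
) -> dw.DwellSequence:
    """Exact stochastic simulation aggregated to open/shut dwell intervals.

    Holding times are exponential in the current state's total exit rate and
    jumps categorical; sojourns in the same conductance class are merged into
    one interval.  ``n_events`` counts aggregated intervals.  Durations are
    returned in ms.
    """
    if n_events < 1:
        raise DomainError("n_events must be >= 1")
    q = scheme.q_matrix(A)
    n = scheme.n_states
    exit_rates = -np.diag(q)
    probs = q.copy()
    np.fill_diagonal(probs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = probs / exit_rates[:, None]
    cum = np.cumsum(probs, axis=1)
    is_open = np.array([i in scheme.open_states for i in range(n)])

    rng = np.random.default_rng(seed)
    state = scheme.state_names.index(start_state)
    states_out: list[int] = []
    durs_out: list[float] = []
    cur_class = bool(is_open[state])
    cur_dur = 0.0
    # draw in batches for speed
    batch = 4096
    exp_draws = rng.exponential(size=batch)
    uni_draws = rng.random(size=batch)
    ptr = 0
    while len(states_out) < n_events:
        if ptr >= batch:
            exp_draws = rng.exponential(size=batch)
            uni_draws = rng.random(size=batch)
            ptr = 0
        rate = exit_rates[state]
        if rate <= 0:  # absorbing (cannot happen in shipped schemes)
            raise DomainError(f"absorbing state {scheme.state_names[state]}")
        cur_dur += exp_draws[ptr] / rate
        nxt = int(np.searchsorted(cum[state], uni_draws[ptr] * cum[state][-1]))
        ptr += 1
        if is_open[nxt] != cur_class:
            states_out.append(dw.OPEN if cur_class else dw.SHUT)
            durs_out.append(cur_dur * 1e3)  # s -> ms
            cur_class = bool(is_open[nxt])
            cur_dur = 0.0
        state = nxt
    return dw.DwellSequence(
        states=np.array(states_out[:n_events], dtype=int),
        durations=np.array(durs_out[:n_events], dtype=float),
        origin="simulated",
    )


def simulate_crc(
    truth: TruthRecord,
    concentrations,
    noise: dict | None = None,
    seed: int = 0,
    scales: dict | None = None,
) -> CRCDataset:
    """Generate a CRC dataset from truth.

    ``noise``: ``{"mode": "gaussian", "sd": s}`` adds truncated-to-[0,1]
    Gaussian noise to the theoretical PO (sd 0 reproduces it exactly);
    ``{"mode": "dwell", "n_events": N, "td": ..., "tcrit": ...}`` runs the
    full simulate -> dead time -> clusters -> mixture fit -> PO chain per
    concentration.
    """
    noise = dict(noise or {"mode": "gaussian", "sd": 0.0})
    mode = noise.pop("mode", "gaussian")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    rng = np.random.default_rng(seed)

    if mode == "gaussian":
        sd = float(noise.pop("sd", 0.0))
        po = np.asarray(po_curve(conc, truth.KdC, truth.L2), dtype=float)
        if sd > 0:
            po = np.clip(po + rng.normal(0.0, sd, size=po.shape), 0.0, 1.0)
    elif mode == "dwell":
        n_events = int(noise.pop("n_events", 10_000))
        td = float(noise.pop("td", 0.002))
        tcrit = float(noise.pop("tcrit", 20.0))
        scheme = scheme_from_constants(truth.KdC, truth.KdO, truth.L0, scales=scales)
        po = np.empty(len(conc))
        for i, a in enumerate(conc):
            seq = simulate_intervals(
                scheme, a, n_events, seed=int(rng.integers(2**31 - 1))
            )
            res = dw.analyze_intervals(seq, td=td, tcrit=tcrit, seed=seed)
            po[i] = res["po"]
    else:
        raise DomainError(f"unknown noise mode {mode!r}")
    if noise:
        raise DomainError(f"unknown noise keys: {sorted(noise)}")

    return CRCDataset.from_arrays(
        label=f"synthetic_eta={truth.eta:.3f}", concentrations=conc, po=po, unit="M"
    )


def generate_population(
    class_means=DEFAULT_CLASS_MEANS,
    class_sds=DEFAULT_CLASS_SDS,
    n_per_class: int = 5,
    kdc_range: tuple[float, float] = (1e-6, 1e-2),
    L0: float = L0_WT_PLUS70MV_S450W,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant a labelled eta-class population of agonist truth records.

    Per member, eta is drawn from its class Normal (redrawn if outside (0,1))
    and KdC log-uniformly over ``kdc_range`` (molar); KdO follows from
    ln KdO = ln KdC/(1 - eta) and L2 from the cycle.  Returns a DataFrame
    with columns label, class_true, eta, KdC_M, KdO_M, L2, dG_LA, dG_HA.
    """
    from .core import binding_energy, efficiency_from_kd

    means = np.asarray(class_means, dtype=float)
    sds = np.asarray(class_sds, dtype=float)
    if np.any((means <= 0) | (means >= 1)):
        raise DomainError("class means must lie in (0, 1)")
    if len(means) != len(sds):
        raise DomainError("class_means and class_sds must have equal length")
    _require_positive(L0=L0, n_per_class=n_per_class)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(kdc_range[0]), np.log(kdc_range[1])

    rows = []
    for ci, (mu, sd) in enumerate(zip(means, sds)):
        for j in range(n_per_class):
            eta = rng.normal(mu, sd) if sd > 0 else mu
            while not (0 < eta < 1):
                eta = rng.normal(mu, sd)
            kdc = float(np.exp(rng.uniform(lo, hi)))
            kdo = float(np.exp(np.log(kdc) / (1.0 - eta)))
            l2 = L0 * (kdc / kdo) ** 2
            assert np.isclose(efficiency_from_kd(kdc, kdo), eta, rtol=0, atol=1e-12)
            rows.append(
                {
                    "label": f"class{ci}_m{j}",
                    "class_true": ci,
                    "eta": float(eta),
                    "KdC_M": kdc,
                    "KdO_M": kdo,
                    "L2": l2,
                    "dG_LA": binding_energy(kdc),
                    "dG_HA": binding_energy(kdo),
                }
            )
    return pd.DataFrame(rows)


def dwell_chain_eta_recovery(
    KdC: float = 174e-6,
    KdO: float = 29e-9,
    L0: float = L0_WT_PLUS70MV_S450W,
    n_events: int = 10_000,
    n_concentrations: int = 6,
    td: float = 0.002,
    tcrit: float = 20.0,
    seed: int = 0,
) -> dict:
    """Full synthetic validation chain: truth -> intervals -> CRC -> eta.

    Builds the detailed-balanced scheme from (KdC, KdO, L0), simulates
    ``n_events`` dwell intervals at each of ``n_concentrations`` log-spaced
    concentrations (four-fold steps bracketing the EC50 up to saturation),
    runs dead-time resolution, tcrit segmentation and mixture fitting to get
    per-concentration cluster PO, Hill-fits the resulting CRC and inverts it
    back to an energy profile.  Returns truth, estimates and the eta error.
    """
    from .core import ec50_from_constants, efficiency_from_kd
    from .crc import CRCDataset, crc_to_profile, fit_hill

    truth = TruthRecord.from_kd(KdC, KdO, L0, seed=seed)
    scheme = scheme_from_constants(KdC, KdO, L0)
    ec50 = ec50_from_constants(KdC, truth.L2)
    conc = ec50 * 4.0 ** np.arange(-1, n_concentrations - 1)
    rng = np.random.default_rng(seed)
    po = []
    for a in conc:
        seq = simulate_intervals(scheme, a, n_events, seed=int(rng.integers(2**31 - 1)))
        with np.errstate(all="ignore"):
            res = dw.analyze_intervals(seq, td=td, tcrit=tcrit, seed=seed)
        po.append(res["po"])
    ds = CRCDataset.from_arrays("dwell_chain", conc, po, unit="M")
    fit = fit_hill(ds)
    prof = crc_to_profile(fit, L0)
    eta_true = efficiency_from_kd(KdC, KdO)
    return {
        "truth": truth,
        "concentrations": conc,
        "po": np.asarray(po),
        "fit": fit,
        "profile": prof,
        "eta_true": eta_true,
        "eta_est": prof["eta"],
        "eta_error": prof["eta"] - eta_true,
    }


def write_scenario(
    out_dir,
    truth: TruthRecord,
    crc: CRCDataset,
    intervals: dw.DwellSequence | None = None,
    name: str = "scenario",
) -> dict[str, Path]:
    """Write a fixture triple (CRC CSV, optional interval CSV, truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{name}_seed{truth.seed}"
    paths: dict[str, Path] = {}

    crc_df = pd.DataFrame(
        {
            "label": crc.label,
            "concentration": crc.concentrations,
            "concentration_unit": "M",
            "po": crc.po,
        }
    )
    paths["crc"] = out / f"{stem}_crc.csv"
    crc_df.to_csv(paths["crc"], index=False)

    if intervals is not None:
        df = intervals.to_frame()
        df["sweep_id"] = 0
        paths["intervals"] = out / f"{stem}_intervals.csv"
        df.to_csv(paths["intervals"], index=False)

    paths["truth"] = out / f"{stem}_truth.json"
    paths["truth"].write_text(truth.to_json())
    return paths
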