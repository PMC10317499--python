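"""End-to-end orchestration: ingest -> fit -> correct -> profile -> classify.

Also hosts the reference checks that recompute the shipped table of published
CRC-derived constants through the package's own closed forms and compare at
printed precision.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from decimal import Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core
from .backgrounds import BackgroundSpec, background_fold
from .constants import (
    RT_DEFAULT,
    L0_WT_MINUS100MV,
    L0_WT_PLUS70MV_S450W,
    load_reference_measurements,
)
from .crc import crc_to_profile, fit_hill
from .io import read_crc_csv, write_json_report, write_profiles_csv
from .population import xmeans_classify

logger = logging.getLogger("etachan")

__all__ = ["PipelineConfig", "run_pipeline", "run_reference_checks", "printed_tolerance"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    ``l0_mode``: "constant" uses ``l0_value`` directly; "voltage" applies the
    e-fold/60 mV rule from (-100 mV, 7.4e-7) to ``voltage_mV``.  Background
    mutations multiply L0 out of the apparent L2 before inversion.
    """

    crc_csv: str
    out_dir: str = "etachan_out"
    concentration_unit: str | None = None
    l0_mode: str = "constant"
    l0_value: float = L0_WT_PLUS70MV_S450W
    voltage_mV: float = -100.0
    background_mutations: tuple[str, ...] = ()
    nH_mode: str = "free"
    weighting: str | None = None
    rt: float = RT_DEFAULT
    k_max: int = 8
    min_class_size: int = 2
    seed: int = 0

    _KNOWN = None  # filled after class creation

    def __post_init__(self):
        if self.l0_mode not in ("constant", "voltage"):
            raise ValueError(f"unknown l0_mode {self.l0_mode!r}")
        if self.nH_mode not in ("free", "fixed"):
            raise ValueError(f"unknown nH_mode {self.nH_mode!r}")
        if not self.l0_value > 0:
            raise ValueError("l0_value must be positive")
        self.background_mutations = tuple(self.background_mutations)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def effective_l0(self) -> float:
        from .backgrounds import l0_at_voltage

        if self.l0_mode == "voltage":
            return l0_at_voltage(L0_WT_MINUS100MV, -100.0, self.voltage_mV)
        return self.l0_value


def run_pipeline(config: PipelineConfig) -> dict:
    """Run ingest -> Hill fit -> background correction -> profile -> classify.

    Per-dataset failures are logged and quarantined (the run continues);
    outputs are a profile CSV, a class-report JSON and the returned summary
    dict.  Deterministic given the config and seed.
    """
    datasets = read_crc_csv(config.crc_csv, default_unit=config.concentration_unit)
    if not datasets:
        raise ValueError("no CRC datasets found in input")
    l0 = config.effective_l0()
    fold = background_fold(BackgroundSpec(mutations=config.background_mutations))

    rows, failures = [], {}
    for label, ds in datasets.items():
        try:
            fit = fit_hill(ds, nH_mode=config.nH_mode, weighting=config.weighting)
            prof = crc_to_profile(fit, l0, l2_correction_fold=fold, RT=config.rt)
            sems = prof["sems"]
            rows.append(
                {
                    "label": label,
                    "EC50_M": prof["EC50"],
                    "EC50_sem": fit.params.EC50_sem,
                    "POmax": prof["POmax"],
                    "POmax_sem": fit.params.POmax_sem,
                    "nH": fit.params.nH,
                    "L2": prof["L2"],
                    "KdC_M": prof["KdC"],
                    "KdC_sem": sems["KdC"],
                    "KdO_M": prof["KdO"],
                    "KdO_sem": sems["KdO"],
                    "c": prof["c"],
                    "c_sem": sems["c"],
                    "dG_LA": prof["dG_LA"],
                    "dG_HA": prof["dG_HA"],
                    "lam": prof["lam"],
                    "eta": prof["eta"],
                    "eta_sem": sems["eta"],
                    "converged": fit.converged,
                    "ec50_in_range": fit.ec50_in_range,
                }
            )
        except Exception as err:  # quarantine, keep going
            logger.warning("dataset %s failed: %s", label, err)
            failures[label] = str(err)

    if not rows:
        raise ValueError("every dataset failed; nothing to report")
    profiles = pd.DataFrame(rows)

    classes = None
    if len(profiles) >= 4:
        cs = xmeans_classify(
            profiles["eta"].to_numpy(),
            k_max=config.k_max,
            min_size=config.min_class_size,
            seed=config.seed,
        )
        profiles["eta_class"] = cs.assignments
        classes = {
            "k": cs.k,
            "means": cs.means,
            "sds": cs.sds,
            "sizes": cs.sizes,
            "ssr": cs.ssr,
            "aicc": cs.aicc,
        }

    out = Path(config.out_dir)
    paths = {
        "profiles_csv": write_profiles_csv(profiles, out / "profiles.csv"),
    }
    report = {
        "config": {k: v for k, v in asdict(config).items() if not k.startswith("_")},
        "l0": l0,
        "background_fold": fold,
        "n_datasets": len(datasets),
        "n_failed": len(failures),
        "failures": failures,
        "profiles": profiles.to_dict(orient="records"),
        "classes": classes,
    }
    paths["report_json"] = write_json_report(report, out / "report.json")
    report["paths"] = paths
    return report


# ---------------------------------------------------------------------------
# reference checks against the shipped table of published constants
# ---------------------------------------------------------------------------

def printed_tolerance(printed: str, rel: float = 0.01) -> float:
    """max(rel * |value|, half a unit in the last printed digit)."""
    d = Decimal(printed)
    half_last = 0.5 * float(Decimal(1).scaleb(d.as_tuple().exponent))
    return max(rel * abs(float(d)), half_last)


def _check(name, computed, printed: str) -> dict:
    ref = float(printed)
    tol = printed_tolerance(printed)
    return {
        "check": name,
        "computed": float(computed),
        "reference": ref,
        "tolerance": tol,
        "passed": bool(abs(computed - ref) <= tol),
    }


def run_reference_checks() -> pd.DataFrame:
    """Recompute tabulated constants through the closed forms and compare.

    Covers: the ACh binding energies from its Kd pair; the predicted ACh
    PO^max from the cycle with wild-type L0; the BzTMA KdC from its CRC
    parameters; coupling constants and efficiencies recomputed from the
    tabulated (KdC, KdO) pairs for the internally consistent rows; and the
    triple-background L0 fold product.  Tolerance is printed precision:
    max(1% relative, half a unit in the last printed digit).
    """
    ref = load_reference_measurements()
    ach = ref["ach_reference"]
    checks = []

    kdc = ach["kdc_uM"] * 1e-6
    kdo = ach["kdo_nM"] * 1e-9
    checks.append(_check("ACh dG_LA (kcal/mol)", core.binding_energy(kdc), "-5.1"))
    checks.append(_check("ACh dG_HA (kcal/mol)", core.binding_energy(kdo), "-10.2"))
    checks.append(
        _check("ACh predicted POmax", core.predict_crc(kdc, kdo, ach["L0_-100mV"]).POmax, "0.96")
    )

    # BzTMA inversion: EC50/POmax -> KdC (no L0-scaling background)
    bztma = next(a for a in ref["agonists"] if a["label"] == "BzTMA")
    l2 = core.gating_constant_from_po(bztma["pomax"])
    kdc_bztma = core.kdc_from_ec50(bztma["ec50_uM"] * 1e-6, l2)
    checks.append(_check("BzTMA KdC (uM)", kdc_bztma * 1e6, "930"))

    # c and eta recomputed from tabulated Kd pairs (consistent rows only)
    anchors = [
        ("Dec", None, ("643", "0.41")),
        ("TriMA", None, (None, "0.57")),
        ("BzTMA", None, (None, "0.51")),
        ("D200A", "ACh", (None, "0.37")),
        ("D200A", "CCh", ("153", "0.36")),
        ("D200A", "Ebt", ("69", "0.30")),
        ("K145A", "ACh", (None, "0.44")),
        ("K145A", "TMA", ("184", "0.43")),
    ]
    rows = {a["label"]: a for a in ref["agonists"]}
    rows |= {(m["mutation"], m["agonist"]): m for m in ref["mutants"]}
    for label, agonist, (c_ref, eta_ref) in anchors:
        row = rows[label if agonist is None else (label, agonist)]
        name = label if agonist is None else f"{label}/{agonist}"
        kdc = row["kdc_uM"] * 1e-6
        kdo = row["kdo_nM"] * 1e-9
        if c_ref is not None:
            checks.append(_check(f"{name} c", core.coupling_constant(kdc, kdo), c_ref))
        if eta_ref is not None:
            checks.append(_check(f"{name} eta", core.efficiency_from_kd(kdc, kdo), eta_ref))

    fold = background_fold(BackgroundSpec(mutations=("eL269F", "eE181W", "dV269A")))
    checks.append(_check("triple background L0 fold", fold, "2.5e5"))
    return pd.DataFrame(checks)
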