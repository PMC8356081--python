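"""Benchmark harness comparing the constructions of A on one pedigree.

Times are reported for orientation only and are machine-dependent; the
correctness columns (RMSE against the tabular oracle, iteration counts)
are deterministic given the pedigree and seeds, and identical across
machines.
"""

from __future__ import annotations

import json
import logging
import time
import tracemalloc
from dataclasses import dataclass, field

import numpy as np

from . import kinship_factors as kf
from . import nrm_direct as nd
from . import nrm_inverse_solvers as ns
from .pedigree_core import PedigreeTable, read_pedigree
from .pedigree_sim import SimulationConfig, mask_parents, simulate_pedigree
from .storage_stats import rmse_lower

log = logging.getLogger("nrmkit.bench")

#: method name -> callable(ped, F, ainv) -> (A, extras)
METHODS = {
    "tabular": lambda ped, F, ainv: (nd.nrm_tabular(ped), {}),
    "array": lambda ped, F, ainv: (nd.nrm_tabular_array(ped), {}),
    "tdt": lambda ped, F, ainv: (nd.nrm_tdt(ped, F), {}),
    "tdt-tinv": lambda ped, F, ainv: (nd.nrm_tdt_via_tinv(ped, F), {}),
    "iterd": lambda ped, F, ainv: _iterd(ped),
    "llt": lambda ped, F, ainv: (nd.nrm_llt(ped), {}),
    "bygen": lambda ped, F, ainv: (nd.nrm_by_generation(ped), {}),
    "solve": lambda ped, F, ainv: (ns.nrm_solve(ainv), {}),
    "columns": lambda ped, F, ainv: (ns.nrm_solve_columns(ainv), {}),
    "fbs": lambda ped, F, ainv: (ns.nrm_fbs(ainv), {}),
    "cholinv": lambda ped, F, ainv: (ns.nrm_chol_inv(ainv), {}),
    "pcg-jacobi": lambda ped, F, ainv: _pcg(ainv, "jacobi", ped, F),
    "pcg-d": lambda ped, F, ainv: _pcg(ainv, "D", ped, F),
    "pcg-d0": lambda ped, F, ainv: _pcg(ainv, "D0", ped, F),
    "pcg-none": lambda ped, F, ainv: _pcg(ainv, "none", ped, F),
}


def _iterd(ped):
    A, state = nd.nrm_iter_d(ped)
    return A, {"iterations": state.iterations}


def _pcg(ainv, kind, ped, F):
    minv = ns.make_preconditioner(kind, ainv=ainv, ped=ped, F=F)
    A, info = ns.nrm_pcg(ainv, minv=minv)
    return A, {
        "iterations": int(info["iterations"].sum()),
        "failed_columns": len(info["failed_columns"]),
    }


@dataclass
class BenchPlan:
    """What to benchmark: a pedigree source, methods and repetitions."""

    pedigree: str | None = None  # path to a pedigree file, or None to simulate
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    methods: tuple = tuple(METHODS)
    repetitions: int = 1
    out: str | None = None

    def __post_init__(self):
        if not self.methods:
            raise ValueError("plan needs at least one method")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}")


def _load_pedigree(plan: BenchPlan) -> PedigreeTable:
    if plan.pedigree is not None:
        return read_pedigree(plan.pedigree)
    cfg = SimulationConfig(**plan.sim)
    log.info("simulating pedigree with seed %d", cfg.seed)
    ped = simulate_pedigree(cfg)
    return mask_parents(
        ped, cfg.missing_dam_rate, cfg.missing_sire_rate, seed=cfg.seed + 1
    )


def run_benchmark(plan: BenchPlan) -> dict:
    """Run every method of the plan and report time, memory, and RMSE.

    The tabular construction provides the reference matrix for RMSE.
    Failures are recorded per method and the run continues.
    """
    ped = _load_pedigree(plan)
    F = kf.inbreeding(ped)
    ainv = kf.build_ainv(ped, F)
    A_ref = nd.nrm_tabular(ped)
    report = {"n": ped.n, "methods": {}}
    for name in plan.methods:
        times = []
        entry: dict = {}
        try:
            for _ in range(plan.repetitions):
                tracemalloc.start()
                t0 = time.perf_counter()
                A, extras = METHODS[name](ped, F, ainv)
                times.append(time.perf_counter() - t0)
                _, peak = tracemalloc.get_traced_memory()
                tracemalloc.stop()
            entry.update(extras)
            entry["rmse"] = rmse_lower(A, A_ref)
            entry["peak_bytes"] = int(peak)
            entry["seconds"] = {
                "min": float(np.min(times)),
                "median": float(np.median(times)),
                "max": float(np.max(times)),
            }
        except Exception as exc:  # failures recorded, run continues
            tracemalloc.stop()
            entry["error"] = f"{type(exc).__name__}: {exc}"
            log.warning("method %s failed: %s", name, exc)
        report["methods"][name] = entry
    if plan.out:
        with open(plan.out, "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def format_report(report: dict) -> str:
    """Human-readable table of a benchmark report."""
    lines = [f"pedigree size n = {report['n']}",
             f"{'method':<12} {'median s':>10} {'RMSE':>10}  notes"]
    for name, e in report["methods"].items():
        if "error" in e:
            lines.append(f"{name:<12} {'-':>10} {'-':>10}  {e['error']}")
            continue
        notes = ", ".join(
            f"{k}={v}" for k, v in e.items()
            if k not in {"rmse", "seconds", "peak_bytes"}
        )
        lines.append(
            f"{name:<12} {e['seconds']['median']:>10.3f} {e['rmse']:>10.2e}  {notes}"
        )
    return "\n".join(lines)
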