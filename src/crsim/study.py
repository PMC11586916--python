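"""Monte-Carlo driver for operating characteristics of the similarity test.

A *cell* is one configuration (scenario, sample sizes, censoring, threshold
Delta, method); running a cell repeats dataset generation + test N times and
reports the rejection proportion with its binomial Monte-Carlo standard
error sqrt(p(1-p)/N) and the mean censored percentage.  Per-replication
seeds are pre-derived from the root seed, so results do not depend on the
worker count when running in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .estimation import CensoringModel
from .simulate import SCENARIO_FAMILIES, ScenarioSpec, generate_scenario_dataset, scenario_spec
from .testing import iup_test, similarity_test

__all__ = ["StudyConfig", "run_cell", "run_table", "run_cells_shared_data"]


@dataclass
class StudyConfig:
    """Full study: the cross product of sample sizes, censorings, thresholds."""

    scenario: int
    n_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(200, 200), (250, 300), (300, 300), (250, 450), (300, 500), (500, 500)]
    )
    deltas: list[float] = field(default_factory=list)
    censorings: list[str] = field(default_factory=lambda: ["administrative:90"])
    N: int = 1000
    B: int = 250
    alpha: float = 0.05
    method: str = "global"  # "global" | "iup"
    seed: int = 0
    tau: float = 90.0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["n_pairs"] = [tuple(p) for p in raw.get("n_pairs", [])] or None
        if raw["n_pairs"] is None:
            del raw["n_pairs"]
        return cls(**raw)

    def cells(self):
        for n1, n2 in self.n_pairs:
            for cens in self.censorings:
                for delta in self.deltas:
                    yield {"n1": n1, "n2": n2, "censoring": cens, "delta": delta}


def _one_rep(spec: ScenarioSpec, families, delta, method, B, alpha, censoring, seed_seq):
    rng = np.random.default_rng(seed_seq)
    ds = generate_scenario_dataset(spec, rng)
    if method == "global":
        res = similarity_test(
            ds.group(1), ds.group(2), families, delta, B, alpha, censoring, rng,
            tau=spec.model1.tau,
        )
        reject, failed = res.reject, res.n_failed
    else:
        res = iup_test(
            ds.group(1), ds.group(2), families, delta, B, alpha, censoring, rng,
            tau=spec.model1.tau,
        )
        reject, failed = res.reject, sum(t.n_failed for t in res.per_transition)
    return bool(reject), ds.censored_fraction, failed


def run_cell(
    scenario: int,
    n1: int,
    n2: int,
    delta: float,
    censoring: CensoringModel | str | None,
    method: str = "global",
    N: int = 1000,
    B: int = 250,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    tau: float = 90.0,
    n_jobs: int = 1,
) -> dict:
    """N seeded replications of dataset generation + test for one cell."""
    if isinstance(censoring, str):
        censoring = CensoringModel.parse(censoring)
    spec = scenario_spec(scenario, n1, n2, censoring, tau)
    families = SCENARIO_FAMILIES[scenario]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(N)
    cens_arg = censoring
    if n_jobs == 1:
        rows = [
            _one_rep(spec, families, delta, method, B, alpha, cens_arg, c)
            for c in children
        ]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_rep)(spec, families, delta, method, B, alpha, cens_arg, c)
            for c in children
        )
    rejects = np.array([r[0] for r in rows])
    cens_frac = np.array([r[1] for r in rows])
    p = float(rejects.mean())
    return {
        "scenario": scenario,
        "n1": n1,
        "n2": n2,
        "censoring": _cens_label(censoring, tau),
        "delta": delta,
        "method": method,
        "N": N,
        "B": B,
        "reject_prop": p,
        "mc_se": float(np.sqrt(p * (1 - p) / N)),
        "censored_pct": float(100 * cens_frac.mean()),
        "failures": int(sum(r[2] for r in rows)),
    }


def _cens_label(censoring: CensoringModel | None, tau: float) -> str:
    if censoring is None or censoring.kind == "administrative":
        t = censoring.tau if censoring is not None else tau
        return f"administrative:{t:g}"
    return f"{censoring.family}:{censoring.params[0]:g}"


def run_table(config: StudyConfig, n_jobs: int = 1) -> pd.DataFrame:
    """All cells of a study; deterministic for a given config.seed
    regardless of parallelism (each cell gets a pre-spawned seed stream)."""
    cells = list(config.cells())
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(cells))
    rows = [
        run_cell(
            config.scenario,
            cell["n1"],
            cell["n2"],
            cell["delta"],
            cell["censoring"],
            config.method,
            config.N,
            config.B,
            config.alpha,
            stream,
            config.tau,
            n_jobs,
        )
        for cell, stream in zip(cells, streams)
    ]
    return pd.DataFrame(rows)


def run_cells_shared_data(
    spec: ScenarioSpec,
    tests: list[dict],
    N: int,
    B: int = 250,
    alpha: float = 0.05,
    censoring: CensoringModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, float]:
    """Evaluate several (delta, method) tests on the SAME N simulated
    datasets (one dataset per replication, fresh bootstrap per test).

    ``tests`` is a list of {"delta": float, "method": "global"|"iup"}.
    Returns (per-test table, mean censored %).  Sharing the datasets mirrors
    reporting level and power columns of one simulation run side by side.
    """
    families = SCENARIO_FAMILIES[spec.meta.get("scenario", 1)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(N)
    rejects = np.zeros((len(tests), N), dtype=bool)
    cens_frac = np.zeros(N)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        ds = generate_scenario_dataset(spec, rng)
        cens_frac[r] = ds.censored_fraction
        g1, g2 = ds.group(1), ds.group(2)
        for i, t in enumerate(tests):
            if t.get("method", "global") == "global":
                res = similarity_test(
                    g1, g2, families, t["delta"], B, alpha, censoring, rng,
                    tau=spec.model1.tau,
                )
                rejects[i, r] = res.reject
            else:
                res = iup_test(
                    g1, g2, families, t["delta"], B, alpha, censoring, rng,
                    tau=spec.model1.tau,
                )
                rejects[i, r] = res.reject
    rows = []
    for i, t in enumerate(tests):
        p = float(rejects[i].mean())
        rows.append(
            {
                "delta": t["delta"],
                "method": t.get("method", "global"),
                "N": N,
                "B": B,
                "reject_prop": p,
                "mc_se": float(np.sqrt(p * (1 - p) / N)),
            }
        )
    return pd.DataFrame(rows), float(100 * cens_frac.mean())
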