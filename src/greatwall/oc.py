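"""Operating characteristics: replicate trials and aggregate.

Per-replicate seeds are derived from the master seed and the replicate
index, so serial and parallel execution give bitwise-identical summaries
and two designs offered the same replicate index share stage-1 random
numbers (common random numbers where their decision paths coincide).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig, TrialResult, run_trial
from .dose_grid import DoseCombo
from .scenarios import Scenario


@dataclass
class OCSummary:
    """Aggregated operating characteristics over simulation replicates."""

    scenario: str
    variant: str
    n_reps: int
    seed: int
    sel_pct: np.ndarray          # per-dose selection %, shape (J, K)
    nosel_pct: float             # early termination or No-Go
    nogo_pct: float              # the No-Go share of nosel_pct
    early_term_pct: float        # the early-termination share
    pat_pct: np.ndarray          # per-dose patient allocation %
    mean_n: float
    correct_sel_pct: float | None  # vs. the scenario's true ODC set, if known

    def sel(self, d: DoseCombo | tuple) -> float:
        j, k = d
        return float(self.sel_pct[j - 1, k - 1])

    def mc_se(self, pct: float) -> float:
        """Monte-Carlo standard error (percentage points) of a reported %."""
        p = pct / 100.0
        return float(100.0 * np.sqrt(p * (1.0 - p) / self.n_reps))

    def to_frame(self) -> pd.DataFrame:
        """One row per dose plus a no-selection row, Table-2 style."""
        J, K = self.sel_pct.shape
        rows = []
        for j in range(J, 0, -1):
            for k in range(1, K + 1):
                rows.append(
                    {
                        "dose": DoseCombo(j, k).label,
                        "sel_pct": round(float(self.sel_pct[j - 1, k - 1]), 2),
                        "pat_pct": round(float(self.pat_pct[j - 1, k - 1]), 2),
                    }
                )
        rows.append({"dose": "none", "sel_pct": round(self.nosel_pct, 2), "pat_pct": 0.0})
        df = pd.DataFrame(rows)
        df["scenario"] = self.scenario
        df["variant"] = self.variant
        df["mean_n"] = round(self.mean_n, 2)
        return df

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "variant": self.variant,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "sel_pct": self.sel_pct.tolist(),
            "nosel_pct": self.nosel_pct,
            "nogo_pct": self.nogo_pct,
            "early_term_pct": self.early_term_pct,
            "pat_pct": self.pat_pct.tolist(),
            "mean_n": self.mean_n,
            "correct_sel_pct": self.correct_sel_pct,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(rep)])


def _run_rep(scenario, config, master_seed, rep) -> TrialResult:
    return run_trial(scenario, config, _replicate_seed(master_seed, rep))


def simulate_oc(
    scenario: Scenario,
    config: DesignConfig,
    n_reps: int,
    seed: int,
    workers: int = 1,
) -> OCSummary:
    """Run ``n_reps`` independent replicates and aggregate Table-2 metrics."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    config.validate()
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers, batch_size=256)(
            delayed(_run_rep)(scenario, config, seed, r) for r in range(n_reps)
        )
    else:
        results = [_run_rep(scenario, config, seed, r) for r in range(n_reps)]
    return aggregate(results, scenario, config, seed)


def aggregate(
    results: list[TrialResult], scenario: Scenario, config: DesignConfig, seed: int
) -> OCSummary:
    J, K = scenario.J, scenario.K
    n_reps = len(results)
    sel = np.zeros((J, K))
    pat = np.zeros((J, K))
    n_total = 0
    nogo = 0
    early = 0
    correct = 0
    odc_set = set(scenario.true_odc)
    for r in results:
        pat += r.n_by_dose
        n_total += r.n_total
        if r.selected is not None:
            sel[r.selected.j - 1, r.selected.k - 1] += 1
            if r.selected in odc_set:
                correct += 1
        elif r.no_selection_reason == "no-go":
            nogo += 1
        else:
            early += 1
    sel_pct = 100.0 * sel / n_reps
    nosel_pct = 100.0 * (nogo + early) / n_reps
    return OCSummary(
        scenario=scenario.name,
        variant=config.variant,
        n_reps=n_reps,
        seed=seed,
        sel_pct=sel_pct,
        nosel_pct=float(nosel_pct),
        nogo_pct=float(100.0 * nogo / n_reps),
        early_term_pct=float(100.0 * early / n_reps),
        pat_pct=100.0 * pat / max(n_total, 1),
        mean_n=n_total / n_reps,
        correct_sel_pct=float(100.0 * correct / n_reps) if odc_set else None,
    )


def compare_designs(
    scenario: Scenario,
    config: DesignConfig,
    n_reps: int,
    seed: int,
    variants: tuple[str, ...] = ("greatwall", "conv1"),
    workers: int = 1,
) -> dict[str, OCSummary]:
    """Side-by-side operating characteristics under common random numbers.

    Every variant sees the same per-replicate seed stream, so stage-1
    trajectories coincide across designs within each replicate.
    """
    return {
        v: simulate_oc(scenario, config.with_variant(v), n_reps, seed, workers)
        for v in variants
    }


def summary_table(summaries: dict[str, OCSummary]) -> pd.DataFrame:
    """Stack per-variant summaries into one long-format table."""
    return pd.concat([s.to_frame() for s in summaries.values()], ignore_index=True)
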