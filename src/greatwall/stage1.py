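"""Stage 1: divide-and-conquer toxicity escalation and the admissible set A1.

Escalation along each sub-path uses a single-agent stopping rule: treat one
cohort at a dose, continue while the observed DLT fraction stays below the
boundary ψ, and build a "wall" (excluding the upward cone) the first time it
reaches it.  The boundary is optimal for the simple-vs-simple test of a
well-tolerated DLT rate φ_T against an over-toxic rate ρ·φ_T, maximizing the
equal-prior correct-decision probability — the same framework that yields
the BOIN escalation boundaries.
"""

from __future__ import annotations

import math
from typing import Protocol

import numpy as np
from scipy.stats import binom

from .data import TrialData
from .dose_grid import DoseCombo, DoseGrid, build_subpath
from .estimation import beta_tail


class OutcomeSource(Protocol):
    """Yields early outcomes for patients treated at a requested dose."""

    def draw(self, dose: DoseCombo, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (y_eff, y_tox, survival_times) for ``n`` new patients."""
        ...


def compute_psi(phi_t: float, rho: float) -> float:
    """Optimal stopping boundary on the observed DLT fraction.

    ψ = log[(1-φ_T)/(1-ρφ_T)] / log[ρ(1-φ_T)/(1-ρφ_T)]; maximizes the
    correct-decision probability for H0: p_T = φ_T vs H1: p_T = ρφ_T and
    always lies strictly between the two rates.
    """
    if not 0.0 < phi_t < 1.0:
        raise ValueError("phi_t must be a probability in (0, 1)")
    if rho <= 1.0:
        raise ValueError("rho must exceed 1")
    if rho * phi_t >= 1.0:
        raise ValueError("over-toxic rate not a probability")
    num = math.log((1.0 - phi_t) / (1.0 - rho * phi_t))
    den = math.log(rho * (1.0 - phi_t) / (1.0 - rho * phi_t))
    return num / den


def psi_objective(ld: int, psi: float, phi_t: float, rho: float) -> float:
    """Correct-decision probability of boundary ``psi`` with ``ld`` patients.

    Under equal priors on the two simple hypotheses:
    P(ψ) = ½·P(p̂ < ψ | φ_T) + ½·P(p̂ ≥ ψ | ρφ_T), with "stop" declared as
    soon as the observed fraction reaches ψ.  The continue region is
    x <= b where b is the largest DLT count with x/ld < ψ.
    """
    if ld < 1:
        raise ValueError("ld must be at least 1")
    # largest integer count strictly below ld*psi (tie x/ld == psi stops)
    b = math.ceil(ld * psi) - 1
    p_continue_h0 = binom.cdf(b, ld, phi_t) if b >= 0 else 0.0
    p_stop_h1 = 1.0 - (binom.cdf(b, ld, rho * phi_t) if b >= 0 else 0.0)
    return 0.5 * float(p_continue_h0) + 0.5 * float(p_stop_h1)


def escalation_decision(x_tox: int, l: int, psi: float) -> str:
    """"continue" while the observed DLT fraction stays below ψ, else "wall"."""
    if l < 1:
        raise ValueError("need at least one treated patient")
    return "continue" if x_tox / l < psi else "wall"


def efficacy_admissible(
    x_eff: int, l: int, phi_e: float, cutoff: float = 0.05
) -> bool:
    """Early-efficacy screen: posterior mass above φ_E must exceed the cutoff.

    Beta(1, 1) prior on the response rate; with no data the prior tail
    1 - φ_E applies, so untested efficacy never fails the screen outright.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    return beta_tail(x_eff, l, phi_e) > cutoff


def run_stage1(
    source: OutcomeSource,
    grid: DoseGrid,
    config,
    data: TrialData | None = None,
) -> tuple[DoseGrid, TrialData, int]:
    """Walk the sub-paths, building walls, until exhaustion or budget stop.

    Treats exactly one cohort at each visited dose starting from the minimal
    remaining combination; on a wall, excludes the upward cone and restarts
    on the next sub-path.  Stops when every combination is tried/excluded or
    the remaining stage-1 budget cannot fund another full cohort.  Doses
    never reached stay untried and are not part of AT,1.
    """
    if data is None:
        data = TrialData(grid.J, grid.K)
    psi = compute_psi(config.phi_t, config.rho)
    c = config.cohort_size
    n_used = 0
    paths = list(config.subpaths) if getattr(config, "subpaths", None) else None

    while True:
        remaining = grid.untried()
        if not remaining:
            break
        if paths is not None:
            while paths:
                cand = [DoseCombo(*d) for d in paths.pop(0)]
                path = [d for d in cand if d in remaining]
                if path:
                    break
            else:
                break
        else:
            path = build_subpath(remaining)
        wall_hit = False
        for d in path:
            if grid.status(d).value != "untried":
                continue
            if n_used + c > config.n1:
                return grid, data, n_used
            y_eff, y_tox, times = source.draw(d, c)
            if y_tox.size != c:
                raise ValueError("outcome source exhausted mid-cohort")
            data.add(
                d, y_eff, y_tox, times, stage=1,
                record_efficacy=config.collect_stage1_efficacy,
            )
            n_used += c
            if escalation_decision(int(y_tox.sum()), c, psi) == "continue":
                grid.mark_safe(d)
            else:
                grid.mark_wall(d)
                wall_hit = True
                break
        if paths is None and not wall_hit and not grid.untried():
            break
    return grid, data, n_used


def admissible_set_A1(grid: DoseGrid, data: TrialData, config) -> list[DoseCombo]:
    """Stage-1 admissible set: safe under the Great Wall and not futile.

    Filters AT,1 by the early-efficacy posterior screen on stage-1 data;
    returned in (j, k) order.
    """
    out = []
    for d in sorted(grid.safe_set()):
        x_eff, l = data.eff_counts(d)
        if efficacy_admissible(x_eff, l, config.phi_e, config.admissibility_cutoff):
            out.append(d)
    return out
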