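"""Three-stage trial orchestration and design variants.

``run_trial`` executes one complete trial: divide-and-conquer escalation
(stage 1), equal randomization over the admissible set with utility-based
candidate refinement (stage 2), and survival-driven final selection with a
Go/No-Go gate (stage 3).  Two comparator variants share stage 1: ``conv1``
stops after stage 2 and selects the utility argmax (no survival data), and
``greatwall-m`` skips stage 2, spending the combined stage-2/3 budget on
randomization within A1 before survival-based selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .data import TrialData
from .dose_grid import DoseCombo, DoseGrid
from .estimation import (
    UtilityScores,
    below_contour_mask,
    isotonic_2d,
    km_survival,
    mean_utility_estimate,
    mtd_contour,
    posterior_mean_toxicity,
    safety_elimination_mask,
)
from .scenarios import Scenario, ScenarioSampler
from .stage1 import admissible_set_A1, efficacy_admissible, run_stage1

VARIANTS = ("greatwall", "greatwall-m", "conv1")


@dataclass
class DesignConfig:
    """All tuning constants of the design.

    phi_t        well-tolerated DLT probability (escalation target)
    rho          over-toxic multiplier (> 1); rho*phi_t is the rate deemed
                 excessive
    phi_e        lower limit for the early-efficacy response rate
    admissibility_cutoff
                 posterior-tail cutoff of the efficacy screen
    gamma        candidate-set flexibility: keep doses with estimated mean
                 utility >= gamma * max
    scores       utility scores for the four joint outcomes
    n1, n2, n3   maximum sample sizes of the three stages
    cohort_size  stage-1 cohort size
    tau          survival follow-up window / landmark, months
    phi_s        Go/No-Go floor on the landmark survival estimate
    variant      'greatwall', 'greatwall-m' or 'conv1'
    tox_prior    Beta prior for the smoothed toxicity estimates fed to the
                 isotonic step (None = raw proportions)
    elimination  safety-exclusion rule inside the MTD contour:
                 'posterior' (eliminate when Pr(p_T > phi_t | data) > the
                 elimination cutoff, Beta(1,1) prior) or 'threshold'
                 (isotonized estimate >= rho*phi_t)
    elimination_cutoff
                 posterior cutoff of the 'posterior' rule
    collect_stage1_efficacy
                 whether stage-1 patients contribute efficacy outcomes
    subpaths     optional clinician-specified escalation paths, a list of
                 ordered (j, k) lists; default is leftmost-column-then-top-row
    """

    phi_t: float = 0.3
    rho: float = 1.4
    phi_e: float = 0.25
    admissibility_cutoff: float = 0.05
    gamma: float = 0.7
    scores: UtilityScores = field(default_factory=UtilityScores)
    n1: int = 18
    n2: int = 36
    n3: int = 20
    cohort_size: int = 3
    tau: float = 6.0
    phi_s: float = 0.3
    variant: str = "greatwall"
    tox_prior: tuple[float, float] | None = (0.05, 0.05)
    elimination: str = "posterior"
    elimination_cutoff: float = 0.95
    collect_stage1_efficacy: bool = True
    subpaths: list | None = None

    def validate(self) -> None:
        if not 0.0 < self.phi_t < 1.0:
            raise ValueError("phi_t must be in (0, 1)")
        if self.rho <= 1.0 or self.rho * self.phi_t >= 1.0:
            raise ValueError("need rho > 1 with rho*phi_t < 1")
        if not 0.0 < self.phi_e < 1.0:
            raise ValueError("phi_e must be in (0, 1)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if min(self.n1, self.n2, self.n3, self.cohort_size) < 1:
            raise ValueError("sample sizes must be positive")
        if self.tau <= 0:
            raise ValueError("follow-up window must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.elimination not in ("posterior", "threshold"):
            raise ValueError("elimination must be 'posterior' or 'threshold'")

    @classmethod
    def from_dict(cls, payload: dict) -> "DesignConfig":
        payload = dict(payload)
        if "scores" in payload and not isinstance(payload["scores"], UtilityScores):
            payload["scores"] = UtilityScores(**payload["scores"])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_variant(self, variant: str) -> "DesignConfig":
        return replace(self, variant=variant)


@dataclass
class TrialResult:
    """Outcome of one simulated or conducted trial."""

    selected: DoseCombo | None
    go: bool
    terminal_stage: int
    n_total: int
    no_selection_reason: str | None
    odc_candidate: DoseCombo | None  # best dose pre Go/No-Go, if any
    n_by_dose: np.ndarray
    n_by_stage_dose: np.ndarray
    sets: dict
    estimates: dict
    variant: str

    @property
    def no_selection(self) -> bool:
        return self.selected is None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "selected": list(self.selected) if self.selected else None,
            "go": self.go,
            "terminal_stage": self.terminal_stage,
            "n_total": self.n_total,
            "no_selection_reason": self.no_selection_reason,
            "odc_candidate": list(self.odc_candidate) if self.odc_candidate else None,
            "n_by_dose": self.n_by_dose.tolist(),
            "n_by_stage_dose": self.n_by_stage_dose.tolist(),
            "sets": {k: [list(d) for d in v] for k, v in self.sets.items()},
            "estimates": self.estimates,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def randomize_equal(
    n: int, doses: list[DoseCombo], rng: np.random.Generator
) -> dict[DoseCombo, int]:
    """Equal randomization of ``n`` patients across ``doses``.

    Each dose receives floor(n/m); the remainder goes one patient each to
    distinct doses drawn uniformly without replacement, so allocations
    differ by at most 1 and always sum to ``n``.
    """
    if not doses:
        raise ValueError("cannot randomize over an empty dose set")
    if n < 0:
        raise ValueError("n must be non-negative")
    m = len(doses)
    base, rem = divmod(n, m)
    alloc = {d: base for d in doses}
    if rem:
        for i in rng.choice(m, size=rem, replace=False):
            alloc[doses[int(i)]] += 1
    return alloc


def admissible_set_A2(
    at2: list[DoseCombo], data: TrialData, config: DesignConfig
) -> list[DoseCombo]:
    """Stage-2 admissible set: AT,2 filtered by the pooled efficacy screen."""
    out = []
    for d in at2:
        x_eff, l = data.eff_counts(d)
        if efficacy_admissible(x_eff, l, config.phi_e, config.admissibility_cutoff):
            out.append(d)
    return out


def candidate_set_C2(
    utilities: dict[DoseCombo, float], a2: list[DoseCombo], gamma: float
) -> list[DoseCombo]:
    """Doses within ``gamma`` of the maximum estimated mean utility."""
    if not a2:
        return []
    u_max = max(utilities[d] for d in a2)
    return [d for d in a2 if utilities[d] >= gamma * u_max]


def candidate_set_C3(
    c2: list[DoseCombo], data: TrialData, grid: DoseGrid, config: DesignConfig
) -> list[DoseCombo]:
    """C2 pruned by the final MTD contour on all cumulative toxicity data."""
    if not c2:
        return []
    mtd = _contour(data, grid, config)
    return [d for d in c2 if mtd[d.j - 1] >= d.k - 1]


def _contour(data: TrialData, grid: DoseGrid, config: DesignConfig) -> np.ndarray:
    est = posterior_mean_toxicity(data.x_tox, data.n, config.tox_prior)
    iso = isotonic_2d(est, data.n.astype(float))
    # stage-1 walls are permanent; other tried doses (including any demoted
    # by partial-order implication) are reassessed from the pooled data
    excluded = np.zeros((grid.J, grid.K), dtype=bool)
    for d in grid.walls():
        excluded[d.j - 1, d.k - 1] = True
    if config.elimination == "posterior":
        excluded |= safety_elimination_mask(
            data.x_tox, data.n, config.phi_t, config.elimination_cutoff
        )
        return mtd_contour(iso, config.phi_t, excluded=excluded)
    return mtd_contour(iso, config.phi_t, rho=config.rho, excluded=excluded)


def toxicity_admissible_set_AT2(
    data: TrialData, grid: DoseGrid, config: DesignConfig
) -> list[DoseCombo]:
    """Tried doses at or below the row-wise MTD contour."""
    mtd = _contour(data, grid, config)
    mask = below_contour_mask(mtd, data.tried_mask())
    return [DoseCombo(int(j) + 1, int(k) + 1) for j, k in zip(*np.nonzero(mask))]


def _utilities(
    doses: list[DoseCombo], data: TrialData, scores: UtilityScores
) -> dict[DoseCombo, float]:
    return {
        d: mean_utility_estimate(*data.joint_counts(d), scores) for d in doses
    }


def select_odc(
    c3: list[DoseCombo],
    km: dict[DoseCombo, float],
    utilities: dict[DoseCombo, float],
) -> DoseCombo | None:
    """Argmax of landmark survival over C3.

    Ties break by higher estimated utility, then lower total dose level
    j + k, then lower drug-A level.
    """
    if not c3:
        return None
    return max(c3, key=lambda d: (km[d], utilities.get(d, 0.0), -(d.j + d.k), -d.j))


def go_nogo(psi_s_hat: float, phi_s: float) -> str:
    """'Go' iff the landmark survival estimate strictly exceeds the floor."""
    return "Go" if psi_s_hat > phi_s else "NoGo"


def _draw_alloc(sampler, alloc, data: TrialData, stage: int, rng) -> int:
    n_used = 0
    for d in sorted(alloc):
        m = alloc[d]
        if m <= 0:
            continue
        y_eff, y_tox, times = sampler.draw(d, m, rng)
        data.add(d, y_eff, y_tox, times, stage=stage)
        n_used += m
    return n_used


def _km_landmark(data: TrialData, doses, tau: float) -> dict[DoseCombo, float]:
    """KM landmark estimates with administrative censoring at ``tau``.

    Each patient is followed to min(event time, tau); with censoring only at
    the window end the product-limit estimate at tau equals the fraction of
    times exceeding tau.
    """
    out = {}
    for d in doses:
        t, ev = data.survival_sample(d)
        events = ev & (t <= tau)
        obs = np.maximum(np.minimum(t, tau), 1e-12)
        out[d] = km_survival(obs, events, tau)
    return out


def _no_selection(
    reason: str, stage: int, grid: DoseGrid, data: TrialData, config: DesignConfig,
    sets: dict, estimates: dict | None = None,
) -> TrialResult:
    return TrialResult(
        selected=None,
        go=False,
        terminal_stage=stage,
        n_total=data.total_n,
        no_selection_reason=reason,
        odc_candidate=None,
        n_by_dose=data.n.copy(),
        n_by_stage_dose=data.n_stage.copy(),
        sets=sets,
        estimates=estimates or {},
        variant=config.variant,
    )


def run_trial(truth, config: DesignConfig, seed) -> TrialResult:
    """Execute one trial replicate against a Scenario or outcome source.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; three
    independent substreams are derived for the three stages so that
    variants sharing a stage consume identical random numbers there
    (common random numbers across designs).
    """
    config.validate()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng1, rng2, rng3 = (np.random.default_rng(s) for s in ss.spawn(3))

    if isinstance(truth, Scenario):
        sampler = ScenarioSampler(truth, rng1)
        J, K = truth.J, truth.K
    else:
        sampler = truth
        J, K = sampler.J, sampler.K

    grid = DoseGrid(J, K)
    data = TrialData(J, K)

    # ---- stage 1: divide-and-conquer escalation ------------------------
    stage1_source = _StageSource(sampler, rng1)
    run_stage1(stage1_source, grid, config, data)
    sets: dict[str, list[DoseCombo]] = {"AT1": sorted(grid.safe_set())}
    a1 = admissible_set_A1(grid, data, config)
    sets["A1"] = a1
    if not a1:
        return _no_selection("stage1-admissible-set-empty", 1, grid, data, config, sets)

    if config.variant == "greatwall-m":
        return _run_combined_randomization(sampler, grid, data, config, sets, rng2)

    # ---- stage 2: equal randomization over A1 --------------------------
    budget2 = config.n2 + (config.n3 if config.variant == "conv1" else 0)
    alloc2 = randomize_equal(budget2, a1, rng2)
    _draw_alloc(sampler, alloc2, data, 2, rng2)

    at2 = toxicity_admissible_set_AT2(data, grid, config)
    sets["AT2"] = at2
    a2 = admissible_set_A2(at2, data, config)
    sets["A2"] = a2
    if not a2:
        return _no_selection("stage2-admissible-set-empty", 2, grid, data, config, sets)

    utilities = _utilities(a2, data, config.scores)

    if config.variant == "conv1":
        best = max(a2, key=lambda d: (utilities[d], -(d.j + d.k), -d.j))
        return TrialResult(
            selected=best,
            go=True,
            terminal_stage=2,
            n_total=data.total_n,
            no_selection_reason=None,
            odc_candidate=best,
            n_by_dose=data.n.copy(),
            n_by_stage_dose=data.n_stage.copy(),
            sets=sets,
            estimates={"utility": {d.label: utilities[d] for d in a2}},
            variant=config.variant,
        )

    c2 = candidate_set_C2(utilities, a2, config.gamma)
    sets["C2"] = c2

    # ---- stage 3: survival-based selection -----------------------------
    alloc3 = randomize_equal(config.n3, c2, rng3)
    _draw_alloc(sampler, alloc3, data, 3, rng3)

    c3 = candidate_set_C3(c2, data, grid, config)
    sets["C3"] = c3
    if not c3:
        return _no_selection("final-contour-empty", 3, grid, data, config, sets)

    utilities_final = _utilities(c3, data, config.scores)
    km = _km_landmark(data, c3, config.tau)
    d_opt = select_odc(c3, km, utilities_final)
    decision = go_nogo(km[d_opt], config.phi_s)
    estimates = {
        "km": {d.label: km[d] for d in c3},
        "utility": {d.label: utilities_final[d] for d in c3},
    }
    return TrialResult(
        selected=d_opt if decision == "Go" else None,
        go=decision == "Go",
        terminal_stage=3,
        n_total=data.total_n,
        no_selection_reason=None if decision == "Go" else "no-go",
        odc_candidate=d_opt,
        n_by_dose=data.n.copy(),
        n_by_stage_dose=data.n_stage.copy(),
        sets=sets,
        estimates=estimates,
        variant=config.variant,
    )


def _run_combined_randomization(
    sampler, grid, data, config, sets, rng
) -> TrialResult:
    """Variant without stage 2: randomize n2+n3 within A1, select on survival."""
    a1 = sets["A1"]
    alloc = randomize_equal(config.n2 + config.n3, a1, rng)
    _draw_alloc(sampler, alloc, data, 2, rng)

    mtd = _contour(data, grid, config)
    pruned = [d for d in a1 if mtd[d.j - 1] >= d.k - 1]
    final = admissible_set_A2(pruned, data, config)
    sets["final"] = final
    if not final:
        return _no_selection("final-set-empty", 3, grid, data, config, sets)
    utilities = _utilities(final, data, config.scores)
    km = _km_landmark(data, final, config.tau)
    d_opt = select_odc(final, km, utilities)
    decision = go_nogo(km[d_opt], config.phi_s)
    return TrialResult(
        selected=d_opt if decision == "Go" else None,
        go=decision == "Go",
        terminal_stage=3,
        n_total=data.total_n,
        no_selection_reason=None if decision == "Go" else "no-go",
        odc_candidate=d_opt,
        n_by_dose=data.n.copy(),
        n_by_stage_dose=data.n_stage.copy(),
        sets=sets,
        estimates={"km": {d.label: km[d] for d in final}},
        variant=config.variant,
    )


class _StageSource:
    """Adapter binding a sampler to one stage's random stream."""

    def __init__(self, sampler, rng):
        self._sampler = sampler
        self._rng = rng

    def draw(self, dose, n):
        return self._sampler.draw(dose, n, self._rng)
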