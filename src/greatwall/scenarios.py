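"""Generative truth for simulation studies.

Joint binary (early efficacy, DLT) outcomes follow a Gumbel-type bivariate
Bernoulli model with given marginals and an association parameter;
progression-free survival times are Weibull, calibrated per dose so that the
survivor function at the landmark window equals the scenario's true
landmark PFS probability.  Eight built-in 2 x 3 scenarios span null cases
(everything too toxic, or safe but futile for survival), aligned and
misaligned utility/survival optima, and a two-ODC plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .dose_grid import DoseCombo


class JointOutcomeProbs(NamedTuple):
    """π(a, b) = P(Y_E = a, Y_T = b); field order (1,0), (1,1), (0,0), (0,1)."""

    p10: float
    p11: float
    p00: float
    p01: float


def gumbel_joint(p_eff: float, p_tox: float, phi: float) -> JointOutcomeProbs:
    """Bivariate Bernoulli with given marginals and Gumbel association.

    π(a,b) = pE^a (1-pE)^(1-a) · pT^b (1-pT)^(1-b)
             + (-1)^(a+b) · pE(1-pE) pT(1-pT) · (e^φ - 1)/(e^φ + 1).

    φ = 0 recovers independence; positive φ makes response and DLT co-occur
    more often.  Marginals are preserved exactly for any φ.
    """
    assoc = (np.exp(phi) - 1.0) / (np.exp(phi) + 1.0)
    term = p_eff * (1.0 - p_eff) * p_tox * (1.0 - p_tox) * assoc
    p11 = p_eff * p_tox + term
    p10 = p_eff * (1.0 - p_tox) - term
    p01 = (1.0 - p_eff) * p_tox - term
    p00 = (1.0 - p_eff) * (1.0 - p_tox) + term
    probs = JointOutcomeProbs(p10=p10, p11=p11, p00=p00, p01=p01)
    if any(p < -1e-12 or p > 1.0 + 1e-12 for p in probs):
        raise ValueError("association incompatible with marginals")
    return JointOutcomeProbs(*(min(max(p, 0.0), 1.0) for p in probs))


def weibull_scale_from_pfs(shape: float, target_s: float, tau: float) -> float:
    """Weibull scale λ such that P(T > tau) equals ``target_s``.

    λ = τ / (-ln s)^(1/κ).  Degenerate landmark probabilities 0 and 1 have
    no finite calibration.
    """
    if not 0.0 < target_s < 1.0:
        raise ValueError("landmark survival probability must be in (0, 1)")
    if shape <= 0 or tau <= 0:
        raise ValueError("shape and landmark time must be positive")
    return tau / (-np.log(target_s)) ** (1.0 / shape)


@dataclass(frozen=True)
class Scenario:
    """True per-dose probabilities driving one simulation setting.

    Matrices are indexed [j-1, k-1] with j the drug-A level counted from the
    lowest dose.  ``pfs`` is the true landmark (tau-month) progression-free
    survival probability; ``true_odc`` lists the optimal dose combination(s)
    the design should select (empty for null scenarios).
    """

    name: str
    p_tox: np.ndarray
    p_eff: np.ndarray
    pfs: np.ndarray
    true_utility: np.ndarray
    true_odc: tuple[DoseCombo, ...] = ()
    gumbel_phi: float = 0.5
    weibull_shape: float = 1.0
    tau: float = 6.0

    def __post_init__(self):
        for name in ("p_tox", "p_eff", "pfs", "true_utility"):
            m = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, m)
            if m.shape != self.p_tox.shape:
                raise ValueError("scenario matrices must share dimensions")
            if np.any((m < 0) | (m > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def J(self) -> int:
        return self.p_tox.shape[0]

    @property
    def K(self) -> int:
        return self.p_tox.shape[1]

    def at(self, d: DoseCombo) -> tuple[float, float, float]:
        i = (d.j - 1, d.k - 1)
        return float(self.p_tox[i]), float(self.p_eff[i]), float(self.pfs[i])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "p_tox": self.p_tox.tolist(),
            "p_eff": self.p_eff.tolist(),
            "pfs": self.pfs.tolist(),
            "true_utility": self.true_utility.tolist(),
            "true_odc": [list(d) for d in self.true_odc],
            "gumbel_phi": self.gumbel_phi,
            "weibull_shape": self.weibull_shape,
            "tau": self.tau,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Scenario":
        return cls(
            name=payload.get("name", "custom"),
            p_tox=np.asarray(payload["p_tox"], dtype=float),
            p_eff=np.asarray(payload["p_eff"], dtype=float),
            pfs=np.asarray(payload["pfs"], dtype=float),
            true_utility=np.asarray(
                payload.get("true_utility", payload["p_eff"]), dtype=float
            ),
            true_odc=tuple(DoseCombo(*d) for d in payload.get("true_odc", [])),
            gumbel_phi=float(payload.get("gumbel_phi", 0.5)),
            weibull_shape=float(payload.get("weibull_shape", 1.0)),
            tau=float(payload.get("tau", 6.0)),
        )


class ScenarioSampler:
    """Vectorized per-dose outcome generator for a scenario.

    Joint (Y_E, Y_T) categories are multinomial under the Gumbel joint
    probabilities; survival is Weibull calibrated to the dose's landmark
    PFS, drawn independently of the early outcomes.
    """

    def __init__(self, scenario: Scenario, rng: np.random.Generator):
        self.scenario = scenario
        self.rng = rng
        self.J = scenario.J
        self.K = scenario.K
        self._joint: dict[tuple[int, int], np.ndarray] = {}
        self._scale: dict[tuple[int, int], float] = {}
        for j in range(1, scenario.J + 1):
            for k in range(1, scenario.K + 1):
                pt, pe, s = scenario.at(DoseCombo(j, k))
                jp = gumbel_joint(pe, pt, scenario.gumbel_phi)
                self._joint[(j, k)] = np.asarray(jp, dtype=float)
                self._scale[(j, k)] = weibull_scale_from_pfs(
                    scenario.weibull_shape, s, scenario.tau
                )

    def draw(self, dose: DoseCombo, n: int, rng: np.random.Generator | None = None):
        rng = self.rng if rng is None else rng
        probs = self._joint[(dose.j, dose.k)]
        cats = rng.choice(4, size=n, p=probs)  # 0:(1,0) 1:(1,1) 2:(0,0) 3:(0,1)
        y_eff = cats <= 1
        y_tox = (cats == 1) | (cats == 3)
        times = self._scale[(dose.j, dose.k)] * rng.weibull(
            self.scenario.weibull_shape, size=n
        )
        return y_eff, y_tox, times


def draw_patient(
    scenario: Scenario, dose: DoseCombo, rng: np.random.Generator
) -> tuple[int, int, float]:
    """Single-patient draw: (Y_E, Y_T, survival time in months)."""
    sampler = ScenarioSampler(scenario, rng)
    y_eff, y_tox, t = sampler.draw(dose, 1)
    return int(y_eff[0]), int(y_tox[0]), float(t[0])


def _sc(name, rows, odc):
    """Rows are listed top-down (highest drug-A level first), as printed."""
    rows = rows[::-1]  # store with j ascending
    p_tox = np.array([[c[0] for c in r] for r in rows])
    p_eff = np.array([[c[1] for c in r] for r in rows])
    util = np.array([[c[2] for c in r] for r in rows])
    pfs = np.array([[c[3] for c in r] for r in rows])
    return Scenario(
        name=name, p_tox=p_tox, p_eff=p_eff, pfs=pfs, true_utility=util,
        true_odc=tuple(DoseCombo(*d) for d in odc),
    )


def scenario_library() -> dict[int, Scenario]:
    """The eight built-in 2 x 3 scenarios (cells are (pT, pE, utility, PFS))."""
    lib = {
        1: _sc("scenario-1", [
            [(0.60, 0.20, 0.28, 0.25), (0.67, 0.40, 0.37, 0.50), (0.75, 0.30, 0.28, 0.40)],
            [(0.50, 0.10, 0.26, 0.20), (0.62, 0.20, 0.27, 0.40), (0.68, 0.30, 0.31, 0.50)],
        ], odc=[]),
        2: _sc("scenario-2", [
            [(0.25, 0.45, 0.57, 0.10), (0.40, 0.55, 0.57, 0.15), (0.50, 0.50, 0.50, 0.20)],
            [(0.10, 0.40, 0.60, 0.05), (0.35, 0.50, 0.56, 0.10), (0.45, 0.50, 0.52, 0.25)],
        ], odc=[]),
        3: _sc("scenario-3", [
            [(0.20, 0.53, 0.64, 0.35), (0.40, 0.40, 0.48, 0.25), (0.50, 0.40, 0.44, 0.40)],
            [(0.10, 0.55, 0.69, 0.55), (0.35, 0.60, 0.62, 0.35), (0.45, 0.60, 0.58, 0.20)],
        ], odc=[(1, 1)]),
        4: _sc("scenario-4", [
            [(0.10, 0.30, 0.54, 0.35), (0.15, 0.60, 0.70, 0.65), (0.45, 0.55, 0.55, 0.40)],
            [(0.05, 0.20, 0.50, 0.20), (0.10, 0.40, 0.60, 0.40), (0.40, 0.40, 0.48, 0.45)],
        ], odc=[(2, 2)]),
        5: _sc("scenario-5", [
            [(0.15, 0.40, 0.58, 0.45), (0.20, 0.60, 0.68, 0.25), (0.45, 0.45, 0.49, 0.35)],
            [(0.10, 0.20, 0.48, 0.20), (0.15, 0.30, 0.52, 0.25), (0.40, 0.30, 0.42, 0.40)],
        ], odc=[(2, 1)]),
        6: _sc("scenario-6", [
            [(0.10, 0.60, 0.72, 0.42), (0.25, 0.60, 0.66, 0.42), (0.48, 0.65, 0.60, 0.30)],
            [(0.08, 0.30, 0.55, 0.25), (0.18, 0.55, 0.66, 0.60), (0.42, 0.55, 0.56, 0.35)],
        ], odc=[(1, 2)]),
        7: _sc("scenario-7", [
            [(0.12, 0.20, 0.47, 0.20), (0.15, 0.58, 0.69, 0.40), (0.17, 0.62, 0.70, 0.40)],
            [(0.08, 0.14, 0.45, 0.20), (0.12, 0.30, 0.53, 0.25), (0.14, 0.60, 0.70, 0.65)],
        ], odc=[(1, 3)]),
        8: _sc("scenario-8", [
            [(0.06, 0.20, 0.50, 0.25), (0.10, 0.40, 0.60, 0.40), (0.12, 0.70, 0.77, 0.65)],
            [(0.02, 0.10, 0.45, 0.20), (0.05, 0.20, 0.50, 0.35), (0.10, 0.28, 0.53, 0.65)],
        ], odc=[(1, 3), (2, 3)]),
    }
    return lib
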