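"""Accumulated patient-level outcome data, aggregated per dose combination.

Toxicity (DLT) counts are kept for every treated patient; joint
(efficacy, toxicity) counts are kept only for patients whose early-efficacy
outcome is collected (a design option allows discarding stage-1 efficacy).
Survival times are stored per dose for the Kaplan-Meier step.
"""

from __future__ import annotations

import numpy as np

from .dose_grid import DoseCombo


class TrialData:
    """Per-dose running totals over a J x K grid (0-based arrays internally)."""

    N_STAGES = 3

    def __init__(self, J: int, K: int):
        self.J = J
        self.K = K
        self.n = np.zeros((J, K), dtype=int)        # all treated patients
        self.n_eff = np.zeros((J, K), dtype=int)    # with efficacy recorded
        self.x_tox = np.zeros((J, K), dtype=int)
        # joint counts over efficacy-recorded patients: (Y_E=a, Y_T=b)
        self.x10 = np.zeros((J, K), dtype=int)
        self.x11 = np.zeros((J, K), dtype=int)
        self.x00 = np.zeros((J, K), dtype=int)
        self.x01 = np.zeros((J, K), dtype=int)
        self.n_stage = np.zeros((self.N_STAGES, J, K), dtype=int)
        self._times: dict[tuple[int, int], list[np.ndarray]] = {}
        self._events: dict[tuple[int, int], list[np.ndarray]] = {}

    def _idx(self, d: DoseCombo) -> tuple[int, int]:
        return d.j - 1, d.k - 1

    def add(
        self,
        d: DoseCombo,
        y_eff: np.ndarray,
        y_tox: np.ndarray,
        times: np.ndarray,
        stage: int,
        record_efficacy: bool = True,
        events: np.ndarray | None = None,
    ) -> None:
        """Record a batch of patients.

        ``times`` are latent event times (simulation) or observed follow-up
        times (conduct mode); ``events`` flags observed progression/death,
        defaulting to all-events for fully observed simulated times.
        """
        y_eff = np.asarray(y_eff, dtype=bool)
        y_tox = np.asarray(y_tox, dtype=bool)
        times = np.asarray(times, dtype=float)
        m = y_tox.size
        if y_eff.size != m or times.size != m:
            raise ValueError("outcome arrays must share length")
        i = self._idx(d)
        self.n[i] += m
        self.x_tox[i] += int(y_tox.sum())
        self.n_stage[stage - 1][i] += m
        if record_efficacy:
            self.n_eff[i] += m
            self.x10[i] += int((y_eff & ~y_tox).sum())
            self.x11[i] += int((y_eff & y_tox).sum())
            self.x00[i] += int((~y_eff & ~y_tox).sum())
            self.x01[i] += int((~y_eff & y_tox).sum())
        self._times.setdefault(i, []).append(times)
        ev = np.ones(m, dtype=bool) if events is None else np.asarray(events, dtype=bool)
        self._events.setdefault(i, []).append(ev)

    # -- accessors -------------------------------------------------------

    def patients(self, d: DoseCombo) -> int:
        return int(self.n[self._idx(d)])

    def dlt_count(self, d: DoseCombo) -> int:
        return int(self.x_tox[self._idx(d)])

    def eff_counts(self, d: DoseCombo) -> tuple[int, int]:
        """(responders, efficacy-evaluable patients) at dose ``d``."""
        i = self._idx(d)
        return int(self.x10[i] + self.x11[i]), int(self.n_eff[i])

    def joint_counts(self, d: DoseCombo) -> tuple[int, int, int, int]:
        i = self._idx(d)
        return int(self.x10[i]), int(self.x11[i]), int(self.x00[i]), int(self.x01[i])

    def survival_sample(self, d: DoseCombo) -> tuple[np.ndarray, np.ndarray]:
        """(times, event flags) for every patient ever treated at ``d``."""
        i = self._idx(d)
        chunks = self._times.get(i, [])
        if not chunks:
            return np.empty(0), np.empty(0, dtype=bool)
        return np.concatenate(chunks), np.concatenate(self._events[i])

    @property
    def total_n(self) -> int:
        return int(self.n.sum())

    def tried_mask(self) -> np.ndarray:
        return self.n > 0
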