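"""Conduct mode: replay a real trial's records and recommend the next action.

Input is a patient-level table with columns ``patient_id, stage, j, k,
y_tox, y_eff, time_days, event`` in enrollment order.  Stage-1 rows are
replayed through the escalation walk (verifying that the recorded doses
match the walk the design would have taken); later stages are summarized
into the admissible/candidate-set machinery.  The result is a dict naming
the current stage and the next recommended action.
"""

from __future__ import annotations

import pandas as pd

from .data import TrialData
from .design import (
    DesignConfig,
    admissible_set_A2,
    candidate_set_C2,
    candidate_set_C3,
    go_nogo,
    select_odc,
    toxicity_admissible_set_AT2,
    _km_landmark,
    _utilities,
)
from .dose_grid import DoseCombo, DoseGrid
from .stage1 import admissible_set_A1, run_stage1

DAYS_PER_MONTH = 30.4375

REQUIRED_COLUMNS = ["patient_id", "stage", "j", "k", "y_tox", "y_eff", "time_days", "event"]


class _NeedMoreData(Exception):
    def __init__(self, dose: DoseCombo, missing: int):
        self.dose = dose
        self.missing = missing
        super().__init__(f"need {missing} more patients at {dose.label}")


class _RecordedSource:
    """Pops recorded stage-1 cohorts, checking they match the requested dose."""

    def __init__(self, rows: pd.DataFrame):
        self._rows = rows.reset_index(drop=True)
        self._pos = 0

    def draw(self, dose: DoseCombo, n: int):
        avail = len(self._rows) - self._pos
        if avail < n:
            raise _NeedMoreData(dose, n - avail)
        chunk = self._rows.iloc[self._pos : self._pos + n]
        recorded = {DoseCombo(int(r.j), int(r.k)) for r in chunk.itertuples()}
        if recorded != {dose}:
            raise ValueError(
                f"recorded doses {sorted(d.label for d in recorded)} do not match "
                f"the escalation walk (expected {dose.label})"
            )
        self._pos += n
        times = chunk["time_days"].to_numpy(dtype=float) / DAYS_PER_MONTH
        return (
            chunk["y_eff"].to_numpy(dtype=bool),
            chunk["y_tox"].to_numpy(dtype=bool),
            times,
        )


def _add_rows(data: TrialData, rows: pd.DataFrame, stage: int) -> None:
    for (j, k), grp in rows.groupby(["j", "k"]):
        data.add(
            DoseCombo(int(j), int(k)),
            grp["y_eff"].to_numpy(dtype=bool),
            grp["y_tox"].to_numpy(dtype=bool),
            grp["time_days"].to_numpy(dtype=float) / DAYS_PER_MONTH,
            stage=stage,
            events=grp["event"].to_numpy(dtype=bool),
        )


def next_action(records: pd.DataFrame, config: DesignConfig, J: int, K: int) -> dict:
    """Recommend the next trial action given the accumulated records."""
    config.validate()
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")

    grid = DoseGrid(J, K)
    data = TrialData(J, K)
    stage1_rows = records[records["stage"] == 1]
    source = _RecordedSource(stage1_rows)
    try:
        run_stage1(source, grid, config, data)
    except _NeedMoreData as need:
        return {
            "stage": 1,
            "action": "treat",
            "dose": need.dose.label,
            "n_patients": need.missing,
            "grid": grid.to_dict(),
        }

    a1 = admissible_set_A1(grid, data, config)
    if not a1:
        return {"stage": 1, "action": "terminate", "reason": "admissible set A1 empty"}

    stage2_rows = records[records["stage"] == 2]
    budget2 = config.n2 + (config.n3 if config.variant == "conv1" else 0)
    if len(stage2_rows) < budget2:
        return {
            "stage": 2,
            "action": "randomize",
            "doses": [d.label for d in a1],
            "n_patients": budget2 - len(stage2_rows),
        }
    _add_rows(data, stage2_rows, stage=2)

    at2 = toxicity_admissible_set_AT2(data, grid, config)
    a2 = admissible_set_A2(at2, data, config)
    if not a2:
        return {"stage": 2, "action": "terminate", "reason": "admissible set A2 empty"}
    utilities = _utilities(a2, data, config.scores)

    if config.variant == "conv1":
        best = max(a2, key=lambda d: (utilities[d], -(d.j + d.k), -d.j))
        return {"stage": 2, "action": "select", "dose": best.label, "decision": "Go"}

    c2 = candidate_set_C2(utilities, a2, config.gamma)
    stage3_rows = records[records["stage"] == 3]
    if len(stage3_rows) < config.n3:
        return {
            "stage": 3,
            "action": "randomize",
            "doses": [d.label for d in c2],
            "n_patients": config.n3 - len(stage3_rows),
        }
    _add_rows(data, stage3_rows, stage=3)

    c3 = candidate_set_C3(c2, data, grid, config)
    if not c3:
        return {"stage": 3, "action": "terminate", "reason": "candidate set C3 empty"}
    km = _km_landmark(data, c3, config.tau)
    d_opt = select_odc(c3, km, _utilities(c3, data, config.scores))
    decision = go_nogo(km[d_opt], config.phi_s)
    return {
        "stage": 3,
        "action": "select",
        "dose": d_opt.label,
        "decision": decision,
        "km": {d.label: round(km[d], 4) for d in c3},
    }
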