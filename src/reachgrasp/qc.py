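"""Trial-rejection and participant-exclusion rules.

A trial is valid only when it is a critical (non-catch) trial with no
linguistic error, no anticipated movement (reach onset before verb-stem onset,
i.e. onset < 0 on the trial clock), and successful segmentation. Participants
with fewer than half of their critical trials valid are excluded; exactly 50%
is retained (the rule is "less than").
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import EmptyAnalysisError
from .kinematics import TrialKinematics
from .trajio import TrialRecord


@dataclass(frozen=True)
class QCFlags:
    linguistic_error: bool = False
    anticipated_movement: bool = False
    segmentation_failure: bool = False
    catch_trial: bool = False

    @property
    def valid(self) -> bool:
        return not (
            self.linguistic_error
            or self.anticipated_movement
            or self.segmentation_failure
            or self.catch_trial
        )


def validate_trial(trial: TrialRecord, kin: TrialKinematics) -> QCFlags:
    """QC flags for one trial. Always returns flags, never raises.

    Anticipated movement is operationalized as a reach onset earlier than
    verb-stem onset (t = 0 on the trial clock): participants were instructed to
    move only once they recognized the verb, and the stem is the isolation
    point.
    """
    anticipated = False
    if kin.reach_window is not None:
        anticipated = kin.reach_window.onset_ms < 0.0
    return QCFlags(
        linguistic_error=bool(trial.linguistic_error),
        anticipated_movement=anticipated,
        segmentation_failure=bool(kin.segmentation_failure),
        catch_trial=bool(trial.condition.is_catch),
    )


def exclusion_report(params: pd.DataFrame, min_valid_fraction: float = 0.5) -> pd.DataFrame:
    """Per-subject valid-trial ratios over critical (non-catch) trials."""
    rows = []
    for subject_id, group in params.groupby("subject_id", sort=True):
        critical = group[~group["is_catch"].astype(bool)]
        n_critical = int(len(critical))
        n_valid = int(critical["valid"].astype(bool).sum())
        fraction = n_valid / n_critical if n_critical else 0.0
        rows.append(
            {
                "subject_id": subject_id,
                "n_critical": n_critical,
                "n_valid": n_valid,
                "fraction": fraction,
                "excluded": fraction < min_valid_fraction,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "n_critical", "n_valid",
                                       "fraction", "excluded"])


def filter_participants(
    params: pd.DataFrame, min_valid_fraction: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects whose valid/critical ratio is below the cutoff.

    Returns ``(filtered_params, report)``; raises ``EmptyAnalysisError`` when
    every subject is excluded.
    """
    report = exclusion_report(params, min_valid_fraction)
    keep = set(report.loc[~report["excluded"], "subject_id"])
    if not keep:
        raise EmptyAnalysisError(
            f"all subjects fall below {min_valid_fraction:.0%} valid trials"
        )
    filtered = params[params["subject_id"].isin(keep)].reset_index(drop=True)
    return filtered, report
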