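"""Per-experiment control normalization.

Readouts from different imaging sessions are not directly comparable
(laser power, staining efficiency and detector gain drift between days),
so every condition is expressed relative to the mean of the control
condition acquired in the same experiment. Statistics are then computed
on the normalized values across experiments.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError


def normalize_to_control(
    table: pd.DataFrame,
    value_col: str,
    control_label: str,
    *,
    condition_col: str = "condition",
    experiment_col: str = "experiment",
    out_col: str | None = None,
) -> pd.DataFrame:
    """Divide each value by the mean control value of the same experiment.

    Parameters
    ----------
    table : DataFrame
        Tidy table with one row per measured unit (junction, fit, ...).
    value_col : str
        Column holding the raw readout (e.g. ``v0_um_per_s``).
    control_label : str
        Value in ``condition_col`` identifying the control condition.

    Returns
    -------
    DataFrame
        Copy of ``table`` with an extra column (default
        ``value_col + "_norm"``) where the control condition averages to
        exactly 1 within every experiment.

    Raises
    ------
    ValidationError
        If the table is empty or any experiment lacks a control condition.
    """
    if table.empty:
        raise ValidationError("cannot normalize an empty table")
    for col in (value_col, condition_col, experiment_col):
        if col not in table.columns:
            raise ValidationError(f"missing required column {col!r}")
    out_col = out_col or f"{value_col}_norm"

    result = table.copy()
    control_means = (
        table[table[condition_col] == control_label]
        .groupby(experiment_col)[value_col]
        .mean()
    )
    missing = sorted(set(table[experiment_col]) - set(control_means.index))
    if missing:
        raise ValidationError(
            f"experiment(s) without a {control_label!r} control: {missing}"
        )
    zero = control_means[control_means == 0]
    if not zero.empty:
        raise ValidationError(
            f"control mean is zero in experiment(s): {sorted(zero.index)}"
        )
    result[out_col] = result[value_col] / result[experiment_col].map(control_means)
    return result
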