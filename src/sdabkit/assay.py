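"""Small assay statistics: knockdown quantification and differential ELISA.

Knockdown of a fluorescent target is quantified on a two-channel event
table: events are gated into transfected / untransfected subpopulations on
the mCherry channel, and the readout is the ratio of GFP medians expressed
as a percentage (optionally renormalized to a non-relevant control).
Differential ELISA positivity uses a ratio-plus-floor rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GatingError(ValueError):
    """A required subpopulation is empty after gating."""


@dataclass(frozen=True)
class KnockdownResult:
    percentage: float
    n_transfected: int
    n_untransfected: int
    median_transfected: float
    median_untransfected: float


def knockdown_percentage(
    events: pd.DataFrame, mcherry_threshold: float
) -> KnockdownResult:
    """100 x median(GFP | transfected) / median(GFP | untransfected).

    Events with mCherry >= threshold are the transfected subpopulation.
    Medians are midpoint medians, so the readout is invariant under any
    positive rescaling of the GFP channel.
    """
    for column in ("gfp", "mcherry"):
        if column not in events.columns:
            raise ValueError(f"event table lacks column {column!r}")
        if (events[column] < 0).any():
            raise ValueError(f"negative values in channel {column!r}")
    transfected = events["mcherry"] >= mcherry_threshold
    n_t = int(transfected.sum())
    n_u = int((~transfected).sum())
    if n_t == 0 or n_u == 0:
        raise GatingError(
            f"empty subpopulation after gating at {mcherry_threshold} "
            f"(transfected={n_t}, untransfected={n_u})"
        )
    med_t = float(np.median(events.loc[transfected, "gfp"]))
    med_u = float(np.median(events.loc[~transfected, "gfp"]))
    if med_u == 0:
        raise GatingError("untransfected GFP median is zero")
    return KnockdownResult(
        percentage=100.0 * med_t / med_u,
        n_transfected=n_t, n_untransfected=n_u,
        median_transfected=med_t, median_untransfected=med_u,
    )


def normalize_to_control(value: float, control_value: float) -> float:
    """Express a percentage relative to a non-relevant control: 100*v/c."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * value / control_value


def differential_call(
    signal_a: float,
    signal_b: float,
    ratio_threshold: float = 2.0,
    floor: float = 0.0,
    epsilon: float = 1e-12,
) -> str:
    """Call a signal pair ``positive_a`` / ``positive_b`` / ``negative``.

    ``positive_a`` requires signal_a >= floor and
    signal_a / max(signal_b, epsilon) >= ratio_threshold; symmetrically for
    b.  The rule is antisymmetric under swapping the two signals.
    """
    if signal_a < 0 or signal_b < 0:
        raise ValueError("signals must be non-negative")
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    if signal_a >= floor and signal_a / max(signal_b, epsilon) >= ratio_threshold:
        return "positive_a"
    if signal_b >= floor and signal_b / max(signal_a, epsilon) >= ratio_threshold:
        return "positive_b"
    return "negative"
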