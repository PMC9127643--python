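"""Published reference summary statistics for the two web-administered tests.

These are the group-level inputs (means, SDs, group sizes, and age
correlations by device type) reported for the norming study of the
web-administered switching and figure-matching tests.  They serve as worked
-example inputs to the effect-size routines: feeding them to
:func:`speedcog.stats.cohen_d` and :func:`speedcog.stats.cohen_q`
reproduces the published standardized mean differences and correlation
contrasts.

Note: the published nonswitch d (0.13) is not recoverable from the rounded
means/SDs given here; the rounded inputs imply 0.15.  All other rows
reproduce to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DeviceSummary:
    """Published per-device summary for one score."""

    score_name: str
    mean_keyboard: float
    sd_keyboard: float
    n_keyboard: int
    mean_touch: float
    sd_touch: float
    n_touch: int
    r_keyboard: float
    r_touch: float
    published_d: float
    published_q: float
    d_reproducible: bool = True


_SGST_N = (2820, 3309)
_FIGID_N = (3182, 3309)

#: One row per score, keyboard group first.  Scores are in seconds except
#: the figure count (0-60) and percent incorrect (0-100).
DEVICE_SUMMARIES: tuple[DeviceSummary, ...] = (
    DeviceSummary("sgst_normal", 1.04, 0.56, _SGST_N[0], 1.09, 0.80, _SGST_N[1],
                  0.38, 0.32, 0.07, 0.07),
    DeviceSummary("sgst_reverse", 1.10, 0.58, _SGST_N[0], 1.16, 0.59, _SGST_N[1],
                  0.35, 0.43, 0.10, -0.09),
    DeviceSummary("sgst_nonswitch", 0.92, 0.32, _SGST_N[0], 0.97, 0.34, _SGST_N[1],
                  0.48, 0.50, 0.13, -0.03, d_reproducible=False),
    DeviceSummary("sgst_switch", 1.50, 0.70, _SGST_N[0], 1.53, 0.63, _SGST_N[1],
                  0.35, 0.34, 0.05, 0.01),
    DeviceSummary("figid_score", 41.51, 8.43, _FIGID_N[0], 41.96, 8.36, _FIGID_N[1],
                  -0.61, -0.49, 0.05, -0.17),
    DeviceSummary("figid_pct_incorrect", 5.70, 4.97, _FIGID_N[0], 7.40, 5.70,
                  _FIGID_N[1], -0.044, -0.045, 0.32, 0.001),
    DeviceSummary("figid_median_rt", 4.76, 1.78, _FIGID_N[0], 4.53, 1.74, _FIGID_N[1],
                  0.56, 0.45, -0.13, 0.15),
)
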