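"""Depression outcome derivation from HADS-D scores.

The HADS depression subscale totals 0-21. Severity is read off validated
thresholds: scores below 5 indicate no depression, 5-7 mild, 8-10 moderate
and 11 or more severe. The three threshold binaries (>=5, >=8, >=11) are
nested by construction. Pre-pandemic mental-health status is a 0-2 count of
(diagnosis evidence, medication evidence); only a score of 2 counts as a
confirmed pre-pandemic case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")
# inclusive HADS-D bands per severity level
SEVERITY_BANDS = {"none": (0, 4), "mild": (5, 7), "moderate": (8, 10), "severe": (11, 21)}

__all__ = ["SEVERITY_LEVELS", "SEVERITY_BANDS", "threshold_outcomes",
           "prepandemic_score", "derive_outcomes"]


def threshold_outcomes(hads_d):
    """Map HADS-D score(s) to (mild, moderate, severe, severity4).

    Accepts a scalar or array; binaries are the >=5 / >=8 / >=11 indicators
    and ``severity4`` the four-band category with codes 0..3
    (none/mild/moderate/severe).
    """
    scalar = np.isscalar(hads_d)
    h = np.atleast_1d(np.asarray(hads_d))
    if not np.issubdtype(h.dtype, np.integer):
        hf = h.astype(float)
        if not np.all(hf == np.round(hf)):
            raise ValueError("HADS-D scores must be integers")
        h = hf.astype(int)
    if h.min() < 0 or h.max() > 21:
        raise ValueError("HADS-D scores must lie in [0, 21]")
    mild = (h >= 5).astype(np.int8)
    moderate = (h >= 8).astype(np.int8)
    severe = (h >= 11).astype(np.int8)
    severity4 = (mild + moderate + severe).astype(np.int8)
    if scalar:
        return int(mild[0]), int(moderate[0]), int(severe[0]), SEVERITY_LEVELS[severity4[0]]
    return mild, moderate, severe, severity4


def prepandemic_score(diagnosis, medication):
    """Pre-pandemic mental-health score: one point per evidence source.

    Returns ``(score, positive)`` where positive means score == 2 (both a
    diagnosis and sustained medication dispensation).
    """
    scalar = np.isscalar(diagnosis) and np.isscalar(medication)
    d = np.atleast_1d(np.asarray(diagnosis))
    m = np.atleast_1d(np.asarray(medication))
    for v in (d, m):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("flags must be binary 0/1")
    score = (d + m).astype(np.int8)
    positive = (score == 2).astype(np.int8)
    if scalar:
        return int(score[0]), bool(positive[0])
    return score, positive


def derive_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived outcome columns to a table with ``hads_d`` and the
    pre-pandemic ``diagnosis``/``medication`` flags (if present)."""
    out = df.copy()
    mild, moderate, severe, severity4 = threshold_outcomes(out["hads_d"].to_numpy())
    out["dep_mild"] = mild
    out["dep_moderate"] = moderate
    out["dep_severe"] = severe
    out["severity4"] = severity4
    if {"diagnosis", "medication"} <= set(out.columns):
        score, positive = prepandemic_score(out["diagnosis"].to_numpy(),
                                            out["medication"].to_numpy())
        out["prepandemic_score"] = score
        out["prepandemic_positive"] = positive
    return out
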