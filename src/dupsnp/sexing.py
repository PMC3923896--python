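"""Genetic sex inference from Y-specific probe intensities.

Males carry the salmonid male-specific sdY fragment, so Y-specific probes
hybridise strongly in males and only at background level in females.  The
per-sample mean probe intensity is therefore bimodal, and a deterministic
largest-gap split in one dimension recovers sex; a guard refuses to call
when the gap is not clearly larger than the within-cluster spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SexCall", "call_sex_from_y_probes", "concordance"]


@dataclass
class SexCall:
    sample_id: str
    mean_intensity: float
    call: str  # male | female | unknown


def call_sex_from_y_probes(
    y_intensities: pd.DataFrame,
    min_gap_sd: float = 3.0,
) -> pd.DataFrame:
    """Split samples into male/female by the largest gap in mean Y signal.

    ``y_intensities`` is a long frame (probe_id, sample_id, signal).
    Per-sample means are sorted; the split is placed at the largest
    consecutive gap, and the upper-intensity cluster is male (only males
    carry the sdY fragment).  If the gap is smaller than ``min_gap_sd``
    pooled within-cluster standard deviations — a relative criterion, so
    calls are invariant to rescaling all intensities — every call is
    "unknown".  A single sample is always "unknown".
    """
    means = y_intensities.groupby("sample_id")["signal"].mean().sort_values()
    n = len(means)
    if n < 2:
        return pd.DataFrame(
            {
                "sample_id": means.index,
                "mean_intensity": means.to_numpy(),
                "call": ["unknown"] * n,
            }
        )
    values = means.to_numpy()
    gaps = np.diff(values)
    split = int(np.argmax(gaps))
    gap = float(gaps[split])
    lower, upper = values[: split + 1], values[split + 1 :]

    def spread(cluster: np.ndarray) -> float:
        return float(cluster.std(ddof=0)) if len(cluster) > 1 else 0.0

    pooled_sd = max((spread(lower) + spread(upper)) / 2, 1e-12 * max(abs(values).max(), 1.0))
    confident = gap >= min_gap_sd * pooled_sd and gap > 0
    calls = {}
    for i, sid in enumerate(means.index):
        if not confident:
            calls[sid] = "unknown"
        else:
            calls[sid] = "female" if i <= split else "male"
    return pd.DataFrame(
        {
            "sample_id": means.index,
            "mean_intensity": values,
            "call": [calls[s] for s in means.index],
        }
    ).reset_index(drop=True)


def concordance(calls: pd.DataFrame, known_sex: pd.Series) -> float:
    """Fraction of known-sex samples whose call matches.

    ``known_sex`` maps sample id -> "male"/"female"; samples without a
    known label are ignored.  "unknown" calls count as discordant.
    """
    known = known_sex.dropna()
    known = known[known.isin(["male", "female"])]
    if len(known) == 0:
        raise ValueError("no known sex labels to compare against")
    call_map = dict(zip(calls["sample_id"], calls["call"]))
    matches = sum(1 for sid, sex in known.items() if call_map.get(sid) == sex)
    return matches / len(known)
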