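"""Plot-level phenotyping: 5-point field scores, senescence flags, outlier QC.

Field crews estimate the fraction of plants flowering in each plot and record
it on a 5-point percent scale (0, 25, 50, 75, 100).  Two quantization policies
are provided because the treatment of very low nonzero flowering is a real
scoring decision: under ``nearest`` a 2% plot rounds to 0, under ``detect``
(the default) any observed flowering scores at least 25, so that a recorded 0
certifies zero observed flowering — the condition the biennial category
demands.

Senescence of early annuals between the two timepoints shows up as a *decline*
in score from 60 to 100 DAS and is flagged, not silently corrected.  Rosner's
generalized extreme Studentized deviate (ESD) test screens score vectors for
multiple simultaneous outliers; results are advisory QC and nothing is
auto-deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SCORE_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)


def quantize_score(fraction: float, policy: str = "detect") -> float:
    """Quantize a flowering fraction in [0, 1] to the 5-point percent scale.

    policy="nearest": nearest multiple of 25, midpoint ties rounding away from
    zero (12.5% scores 25).  policy="detect": as nearest, except any strictly
    positive fraction scores at least 25.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if policy not in ("nearest", "detect"):
        raise ValueError(f"unknown policy {policy!r}")
    # ties away from zero: floor(x + 0.5) on the nonnegative quarter scale
    score = float(np.floor(fraction * 4.0 + 0.5) * 25.0)
    if policy == "detect" and fraction > 0.0 and score == 0.0:
        score = 25.0
    return score


def quantize_frame(
    records: pd.DataFrame, policy: str = "detect", columns=("frac60", "frac100")
) -> pd.DataFrame:
    """Score raw plot records: frac60/frac100 in [0,1] → pct60/pct100 on the 5-point scale."""
    out = records.copy()
    for frac_col, pct_col in zip(columns, ("pct60", "pct100")):
        out[pct_col] = [quantize_score(f, policy) for f in out[frac_col]]
    return out.drop(columns=list(columns))


@dataclass(frozen=True)
class SenescenceFlag:
    accession_id: str
    year: str
    block: str
    pct60: float
    pct100: float
    flagged: bool


def detect_senescence(observations: pd.DataFrame) -> pd.DataFrame:
    """Flag plots whose flowering score declined from 60 to 100 DAS.

    Returns the observation table plus a boolean ``senescence_flagged`` column;
    flagged plots indicate early annuals that senesced before end of season and
    would otherwise inflate the apparent biennial fraction.
    """
    out = observations.copy()
    out["senescence_flagged"] = out["pct100"] < out["pct60"]
    return out


def rosner_esd_test(values, max_outliers: int, alpha: float = 0.05) -> set[int]:
    """Rosner's generalized ESD test for up to ``max_outliers`` outliers.

    Iteratively computes R_i = max|x - mean| / sd on the remaining sample,
    removes the extreme point, and compares each R_i with the critical value

        lambda_i = (n - i) * t_{p, n-i-1} / sqrt((n - i - 1 + t^2) (n - i + 1)),

    where t is the Student-t quantile at p = 1 - alpha / (2 (n - i + 1)).  The
    declared outliers are the points removed up to the *largest* i with
    R_i > lambda_i; the empty set if none.

    Uses the sample standard deviation (ddof=1).  Raises on constant input or
    when n < max_outliers + 2.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    if n < max_outliers + 2:
        raise ValueError(f"need at least max_outliers + 2 = {max_outliers + 2} values, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant input: sd = 0, ESD statistic undefined")

    remaining = np.arange(n)
    removed: list[int] = []
    R = np.full(max_outliers, -np.inf)
    for i in range(max_outliers):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break  # remaining sample constant; no further testable outliers
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        R[i] = dev[j] / sd
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)

    n_out = 0
    for i in range(len(removed)):
        p = 1.0 - alpha / (2.0 * (n - i))
        df = n - i - 2
        t = stats.t.ppf(p, df)
        lam = (n - i - 1) * t / np.sqrt((df + t * t) * (n - i))
        if R[i] > lam:
            n_out = i + 1
    return set(removed[:n_out])


def qc_report(observations: pd.DataFrame, max_outliers: int = 5, alpha: float = 0.05) -> pd.DataFrame:
    """Per (year, timepoint) Rosner screen of plot scores; long-format flag table."""
    rows = []
    for year in observations["year"].unique():
        grp = observations[observations["year"] == year]
        for col in ("pct60", "pct100"):
            vals = grp[col].to_numpy(dtype=float)
            k = min(max_outliers, max(1, vals.size - 2))
            try:
                idx = rosner_esd_test(vals, max_outliers=k, alpha=alpha)
            except ValueError:
                idx = set()
            for i in sorted(idx):
                r = grp.iloc[i]
                rows.append(
                    {"year": year, "timepoint": col, "accession_id": r["accession_id"],
                     "block": r["block"], "value": vals[i]}
                )
    return pd.DataFrame(rows, columns=["year", "timepoint", "accession_id", "block", "value"])
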