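"""Agreement statistics over paired per-case metric series.

Bland–Altman limits of agreement (mean difference ± 1.96·SD), the paired
t-test, and descriptive mean/SD/95% CI summaries — the statistics used to
compare CBCT against CT segmentation quality case by case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementReport:
    n: int
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    fraction_outside: float
    t_statistic: float | None
    p_value: float | None


def bland_altman(x, y) -> AgreementReport:
    """Bland–Altman analysis of paired series ``x`` and ``y``.

    Differences d = x − y; limits of agreement are mean(d) ± 1.96·SD(d)
    with the n−1 SD.  The paired-t fields are filled when the differences
    are non-degenerate, else left as None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower = mean - LOA_MULTIPLIER * sd
    upper = mean + LOA_MULTIPLIER * sd
    outside = float(np.mean((d < lower) | (d > upper)))
    if sd > 0:
        t, p, _ = paired_t(x, y)
    else:
        t = p = None
    return AgreementReport(
        n=n, mean_diff=mean, sd_diff=sd, lower_limit=lower,
        upper_limit=upper, fraction_outside=outside, t_statistic=t, p_value=p,
    )


def paired_t(x, y) -> tuple[float, float, int]:
    """Two-sided paired t-test: t = mean(d)/(SD(d)/√n), df = n−1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate paired series (zero-variance differences)")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return t, p, n


def summarize(values) -> tuple[float, float, tuple[float, float]]:
    """Mean, SD (n−1), and the t-based 95% CI of the mean."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(sps.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n))
    return mean, sd, (mean - half, mean + half)
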