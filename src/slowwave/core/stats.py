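"""Group-level statistical tests used across the analysis stages.

All tests are two-sided.  The paired Wilcoxon drops zero differences and
reports the effective sample size; degenerate inputs (zero variance where a
variance is required, all-zero differences) raise instead of fabricating a
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "group_test", "DegenerateInputError", "SampleSizeError"]


class DegenerateInputError(ValueError):
    """Input carries no usable variation for the requested test."""


class SampleSizeError(ValueError):
    """Fewer observations than the test minimally requires."""


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": int(self.n),
        }


_METHODS = ("wilcoxon_paired", "mann_whitney", "bartlett", "one_sample_t")


def group_test(
    values,
    method: str,
    mu0: float | None = None,
    values_b=None,
) -> TestResult:
    """Run one of the supported two-sided tests.

    Parameters
    ----------
    values
        For ``wilcoxon_paired``: paired differences, or an (x, y) tuple.
        For ``mann_whitney`` / ``bartlett``: first sample (``values_b``
        holds the second).  For ``one_sample_t``: the sample.
    method
        One of ``wilcoxon_paired``, ``mann_whitney``, ``bartlett``,
        ``one_sample_t``.
    mu0
        Null value, required iff ``method == "one_sample_t"``.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")

    if method == "one_sample_t":
        if mu0 is None:
            raise ValueError("one_sample_t requires mu0")
        x = np.asarray(values, dtype=float)
        _require_n(x.size, 3)
        if np.ptp(x) == 0:
            raise DegenerateInputError("one_sample_t on constant sample")
        res = sps.ttest_1samp(x, popmean=mu0)
        return TestResult("one_sample_t", float(res.statistic), float(res.pvalue), x.size)

    if method == "wilcoxon_paired":
        if isinstance(values, tuple) and len(values) == 2 and values_b is None:
            x, y = (np.asarray(v, dtype=float) for v in values)
            d = x - y
        elif values_b is not None:
            d = np.asarray(values, dtype=float) - np.asarray(values_b, dtype=float)
        else:
            d = np.asarray(values, dtype=float)
        _require_n(d.size, 3)
        d_nz = d[d != 0]
        if d_nz.size == 0:
            raise DegenerateInputError("all paired differences are zero (effective n = 0)")
        if d_nz.size < 3:
            raise SampleSizeError(
                f"effective n after dropping zeros is {d_nz.size} (< 3)"
            )
        res = sps.wilcoxon(d_nz, zero_method="wilcox", method="auto")
        return TestResult("wilcoxon_paired", float(res.statistic), float(res.pvalue), d_nz.size)

    # two-sample methods below
    if values_b is None:
        raise ValueError(f"{method} requires two samples (values_b)")
    x = np.asarray(values, dtype=float)
    y = np.asarray(values_b, dtype=float)
    _require_n(min(x.size, y.size), 3)

    if method == "mann_whitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult("mann_whitney", float(res.statistic), float(res.pvalue), x.size + y.size)

    # bartlett
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("bartlett requires nonzero variance in both samples")
    res = sps.bartlett(x, y)
    return TestResult("bartlett", float(res.statistic), float(res.pvalue), x.size + y.size)


def _require_n(n: int, minimum: int) -> None:
    if n < minimum:
        raise SampleSizeError(f"need n >= {minimum}, got {n}")
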