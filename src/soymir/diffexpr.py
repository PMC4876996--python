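"""Normalization, log2 ratios, the exact count test, and qPCR verification.

The test compares a miRNA's count between two sequencing libraries of total
clean-read sizes N1 (baseline, non-GM) and N2 (test, GM).  Conditional on the
baseline count x, the test count K follows

    p(k | x) = (N2/N1)^k * (x+k)! / (x! k!) / (1 + N2/N1)^(x+k+1),

the classic exact statistic for digital expression counts (a negative
binomial with x+1 successes and success probability N1/(N1+N2)).  The
reported p-value is the smaller tail,

    p = min( sum_{k<=y} p(k|x),  sum_{k>=y} p(k|x) ),

clamped to (0, 1].  All accumulation is done in log space; when the upper
tail is the smaller one it is summed directly with a certified geometric
truncation bound rather than as a complement, so tiny tails keep full
relative precision.

Significance calls combine three gates: |log2 ratio| above a threshold,
p below a cutoff, and a minimum raw abundance.  Normalized values are
(count / total clean reads) x 1e7.  No multiple-testing correction is
applied, matching the published procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

NORM_SCALE = 1e7


@dataclass
class SignificanceParams:
    """Thresholds for calling a miRNA differentially expressed.

    ``min_raw_reads`` gates on the summed raw counts x + y of the two
    libraries (the abundance wording does not fix a per-library scope; the
    summed interpretation is the default and configurable here).
    ``rounded`` reproduces calls from values printed at two decimals, where
    the threshold becomes inclusive (|log2| >= min_abs_log2).
    """

    min_raw_reads: int = 100
    min_abs_log2: float = 1.0
    max_p: float = 0.001
    rounded: bool = False

    def __post_init__(self) -> None:
        if min(self.min_raw_reads, self.min_abs_log2, self.max_p) <= 0:
            raise ValueError("significance thresholds must be positive")


@dataclass
class CtRecord:
    """Quantification-cycle values for the ddCt method (reference: U6 snRNA)."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_test,
            self.ct_ref_test,
            self.ct_target_ctrl,
            self.ct_ref_ctrl,
        ):
            if v is None or not v > 0:
                raise ValueError("all Ct values must be present and positive")


def normalize(count: float, total: float, scale: float = NORM_SCALE) -> float:
    """Per-1e7 normalized expression: count / total * scale."""
    if total <= 0:
        raise ValueError("library total must be positive")
    return count / total * scale


def log2_ratio(
    count_test: float, count_base: float, n_test: float, n_base: float
) -> float:
    """log2(normalized test / normalized baseline); NaN if either side is 0."""
    if count_test < 0 or count_base < 0:
        raise ValueError("counts must be non-negative")
    norm_test = normalize(count_test, n_test)
    norm_base = normalize(count_base, n_base)
    if norm_test == 0 or norm_base == 0:
        return float("nan")
    return math.log2(norm_test / norm_base)


def _log_pointmass(ks: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * log_1pr
    )


def ac_pointmass(k, x: int, n1: float, n2: float):
    """Conditional point mass p(k | x) for library sizes n1, n2.

    Accepts scalar or array ``k``; evaluated in log space (overflow-safe).
    """
    if x < 0 or np.any(np.asarray(k) < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    ks = np.asarray(k, dtype=float)
    out = np.exp(_log_pointmass(ks, x, log_r, log_1pr))
    return float(out) if np.isscalar(k) else out


def _log_upper_tail(y: int, x: int, log_r: float, log_1pr: float) -> float:
    """log sum_{k>=y} p(k|x), summed directly with adaptive truncation.

    Terms decay with ratio t(k+1)/t(k) = r (x+k+1) / ((k+1)(1+r)) which is
    eventually < 1 and decreasing; once below 1 the remainder is bounded by a
    geometric series and summation stops when that bound is negligible
    relative to the running total.
    """
    r = math.exp(log_r)
    chunk = 512
    total_log = -math.inf
    k0 = y
    while True:
        ks = np.arange(k0, k0 + chunk, dtype=float)
        total_log = np.logaddexp(
            total_log, logsumexp(_log_pointmass(ks, x, log_r, log_1pr))
        )
        k_last = k0 + chunk - 1
        ratio = r * (x + k_last + 1) / ((k_last + 1) * (1 + r))
        if ratio < 1.0:
            last_log = _log_pointmass(np.array([k_last]), x, log_r, log_1pr)[0]
            rem_log = last_log + math.log(ratio) - math.log1p(-ratio)
            if rem_log < total_log + math.log(1e-18):
                break
        k0 += chunk
    return float(total_log)


def ac_log_p_value(x: int, y: int, n1: float, n2: float) -> float:
    """Natural log of the two-tailed exact p-value (never underflows)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x == y and n1 == n2:
        return math.log(0.5)
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    ks = np.arange(0, y + 1, dtype=float)
    log_lower = float(logsumexp(_log_pointmass(ks, x, log_r, log_1pr)))
    if log_lower < math.log(0.5):
        log_p = log_lower
    else:
        log_p = min(log_lower, _log_upper_tail(y, x, log_r, log_1pr))
    return min(log_p, 0.0)


def ac_p_value(x: int, y: int, n1: float, n2: float) -> float:
    """Two-tailed exact p-value for counts (x, y) in libraries (n1, n2).

    Returns min(lower tail through y, upper tail from y), in (0, 1].  For the
    exactly balanced configuration x == y with n1 == n2 the smaller tail is
    analytically 1/2 (the cumulative sum sum_{k<=x} C(x+k,k) 2^-(x+k+1)
    equals 1/2 by the negative-binomial/binomial tail duality), so 0.5 is
    returned exactly.
    """
    log_p = ac_log_p_value(x, y, n1, n2)  # also validates the arguments
    if x == y and n1 == n2:
        return 0.5
    return min(max(math.exp(log_p), 5e-324), 1.0)


def flag(
    log2: float,
    p_value: float,
    x: int,
    y: int,
    params: SignificanceParams | None = None,
) -> str:
    """'up', 'down' or 'none' for one comparison row.

    up/down require p < max_p and x + y > min_raw_reads and the log2 ratio
    beyond +-min_abs_log2 (strict by default; inclusive in rounded mode, which
    is how calls printed at two decimals are reproduced).
    """
    params = params or SignificanceParams()
    if math.isnan(log2):
        return "none"
    if p_value >= params.max_p or (x + y) <= params.min_raw_reads:
        return "none"
    t = params.min_abs_log2
    if params.rounded:
        log2 = round(log2, 2)
        if log2 >= t:
            return "up"
        if log2 <= -t:
            return "down"
        return "none"
    if log2 > t:
        return "up"
    if log2 < -t:
        return "down"
    return "none"


def threshold_calls(
    log2_values, min_abs_log2: float = 1.0, inclusive: bool = True
) -> list[str]:
    """Direction calls from log2 ratios alone (abundance and p gates already
    satisfied, as for rows of a published shortlist printed at two decimals).

    NaN yields 'none'.  With ``inclusive`` a printed |log2| exactly at the
    threshold is called (two-decimal rounding makes the strict rule
    unevaluable on printed values).
    """
    calls = []
    for v in np.asarray(log2_values, dtype=float):
        if math.isnan(v):
            calls.append("none")
        elif v >= min_abs_log2 if inclusive else v > min_abs_log2:
            calls.append("up")
        elif v <= -min_abs_log2 if inclusive else v < -min_abs_log2:
            calls.append("down")
        else:
            calls.append("none")
    return calls


def compare_libraries(
    count_table: pd.DataFrame,
    totals: Mapping[str, int],
    lib_test: str,
    lib_base: str,
    params: SignificanceParams | None = None,
) -> pd.DataFrame:
    """Full comparison table for one (test, baseline) library pair.

    ``lib_base`` plays the role of the first (non-GM) library: x, N1.  The
    log2 ratio is log2(normalized test / normalized baseline).  Columns: x, y,
    norm_base, norm_test, log2_ratio, p_value, flag.
    """
    params = params or SignificanceParams()
    n1, n2 = totals[lib_base], totals[lib_test]
    rows = []
    for seq, row in count_table.iterrows():
        x = int(row[lib_base])
        y = int(row[lib_test])
        norm1 = normalize(x, n1)
        norm2 = normalize(y, n2)
        l2 = log2_ratio(y, x, n2, n1)
        p = ac_p_value(x, y, n1, n2)
        rows.append(
            (
                seq,
                row["names"],
                x,
                y,
                norm1,
                norm2,
                l2,
                p,
                flag(l2, p, x, y, params),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "names",
            "x",
            "y",
            "norm_base",
            "norm_test",
            "log2_ratio",
            "p_value",
            "flag",
        ],
    ).set_index("sequence")


def null_type1_rate(
    seed: int,
    n_draws: int = 100_000,
    lam: float = 150.0,
    n1: float = 1.93e7,
    n2: float = 1.95e7,
    alpha: float = 0.001,
) -> float:
    """Empirical type-I rate of the exact test under a matched-rate null.

    Baseline counts x are drawn Poisson(lam); for each draw the probability
    that the second library's count (Poisson at the same normalized rate,
    lam * n2/n1) falls in the rejection region {y : p(x, y) < alpha} is
    added exactly (conditional Monte Carlo over the x draws — unbiased for
    the unconditional rejection rate, with far less variance than counting
    raw (x, y) hits).
    """
    from scipy.stats import poisson

    rng = np.random.default_rng(seed)
    xs = rng.poisson(lam, size=n_draws)
    lam2 = lam * n2 / n1
    region_prob: dict[int, float] = {}

    def conditional(x: int) -> float:
        mode = int(round(x * n2 / n1))
        # lower boundary: largest y below the mode with p < alpha
        y_lo, y = -1, 0
        while y <= mode and ac_p_value(x, y, n1, n2) < alpha:
            y_lo = y
            y += 1
        # upper boundary: smallest y at/above the mode with p < alpha
        y = max(mode, y_lo + 1)
        limit = mode + int(20 * math.sqrt(mode + 4)) + 200
        while y < limit and ac_p_value(x, y, n1, n2) >= alpha:
            y += 1
        lower = poisson.cdf(y_lo, lam2) if y_lo >= 0 else 0.0
        return float(lower + poisson.sf(y - 1, lam2))

    total = 0.0
    for x in xs.tolist():
        p = region_prob.get(x)
        if p is None:
            p = conditional(x)
            region_prob[x] = p
        total += p
    return total / n_draws


def ddct_fold_change(ct: CtRecord) -> float:
    """Relative expression by the comparative ddCt method: 2^-ddCt with
    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl)."""
    ddct = (ct.ct_target_test - ct.ct_ref_test) - (
        ct.ct_target_ctrl - ct.ct_ref_ctrl
    )
    return 2.0 ** (-ddct)
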