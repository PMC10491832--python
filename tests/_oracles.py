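"""Independent brute-force oracles for the separation statistic and the
randomization test.

Pure Python, written straight from the definitions (nearest-rank
percentiles, exhaustive scan of every grid point, exhaustive enumeration of
label assignments) and deliberately sharing no code with the package's
vectorized implementation.
"""

import itertools
import math


def oracle_percentile(values, p):
    """Nearest-rank percentile: min at p=0, else rank ceil(p*n/100)."""
    vs = sorted(values)
    if p == 0:
        return vs[0]
    return vs[math.ceil(p * len(vs) / 100) - 1]


def oracle_separation(values_m, values_f, lo=50, hi=100):
    """(s, s_m_gt_f, s_f_gt_m, selector_count) by exhaustive grid scan."""
    sat_f = [p for p in range(lo, hi + 1)
             if oracle_percentile(values_m, p) < oracle_percentile(values_f, 100 - p)]
    sat_m = [p for p in range(lo, hi + 1)
             if oracle_percentile(values_m, 100 - p) > oracle_percentile(values_f, p)]
    s_f_gt_m = max(sat_f) if sat_f else lo
    s_m_gt_f = max(sat_m) if sat_m else lo
    count = sum(
        oracle_percentile(values_m, p) < oracle_percentile(values_f, 100 - p)
        for p in range(0, 101)
    )
    return max(s_m_gt_f, s_f_gt_m), s_m_gt_f, s_f_gt_m, count


def oracle_direction(values_m, values_f):
    """'M>F' when the selector count is at most 50, else 'F>M'."""
    _, _, _, count = oracle_separation(values_m, values_f)
    return "M>F" if count <= 50 else "F>M"


def oracle_exact_p_value(values_m, values_f):
    """Exact randomization p-value (plain proportion) by full enumeration."""
    pooled = list(values_m) + list(values_f)
    n_m = len(values_m)
    s_obs = oracle_separation(values_m, values_f)[0]
    n_extreme = 0
    n_total = 0
    for members in itertools.combinations(range(len(pooled)), n_m):
        chosen = set(members)
        vm = [pooled[i] for i in range(len(pooled)) if i in chosen]
        vf = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if oracle_separation(vm, vf)[0] >= s_obs:
            n_extreme += 1
        n_total += 1
    return n_extreme / n_total
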