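"""Independent brute-force oracles used across the test suite.

Each function recomputes a statistic from first principles (explicit loops,
closed forms, hand-tabulated event tables) without touching the package's
implementation paths, so agreement is evidence of correctness rather than
self-consistency.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def snr_direct(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return (a.mean() - b.mean()) / (a.std(ddof=1) + b.std(ddof=1))


def bh_stepup(p_values) -> np.ndarray:
    """Textbook step-up: q_(i) = min over j>=i of p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_features_loop(values, labels, fdr_max):
    """Per-feature Welch t-test loop + BH + threshold; values samples x features."""
    values = np.asarray(values, float)
    sens = values[np.asarray(labels) == "sensitive"]
    res = values[np.asarray(labels) == "resistant"]
    ps = []
    for j in range(values.shape[1]):
        a = sens[:, j][~np.isnan(sens[:, j])]
        b = res[:, j][~np.isnan(res[:, j])]
        if len(a) < 2 or len(b) < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            ps.append(np.nan)
            continue
        ps.append(stats.ttest_ind(a, b, equal_var=False).pvalue)
    ps = np.asarray(ps)
    valid = ~np.isnan(ps)
    q = np.full_like(ps, np.nan)
    q[valid] = bh_stepup(ps[valid])
    return set(np.nonzero(valid & (q <= fdr_max))[0])


def select_genes_loop(values, labels, fold_change_cutoff, p_max):
    """Two-predicate loop on a genes x samples log2 matrix."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    sens = values[:, labels == "sensitive"]
    res = values[:, labels == "resistant"]
    out = set()
    for i in range(values.shape[0]):
        p = stats.ttest_ind(sens[i], res[i], equal_var=False).pvalue
        log2fc = res[i].mean() - sens[i].mean()
        if abs(log2fc) >= math.log2(fold_change_cutoff) and p < p_max:
            out.add(i)
    return out


def km_product_limit(times, events):
    """Hand product-limit: S(t) = prod over event times <= t of (1 - d/n)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times)):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        if d:
            s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    median = math.nan
    for t, sv in zip(out_t, out_s):
        if sv <= 0.5:
            median = t
            break
    return np.array(out_t), np.array(out_s), median


def logrank_oe(times_a, events_a, times_b, events_b):
    """Observed-minus-expected log-rank statistic with hypergeometric variance."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    all_times = sorted(set(np.concatenate([ta[ea], tb[eb]])))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        n = n_a + n_b
        d = int(np.sum((ta == t) & ea)) + int(np.sum((tb == t) & eb))
        d_a = int(np.sum((ta == t) & ea))
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def auc_pair_count(scores, is_positive):
    """AUC as the concordant fraction over all (positive, negative) pairs."""
    s = np.asarray(scores, float)
    pos = s[np.asarray(is_positive, bool)]
    neg = s[~np.asarray(is_positive, bool)]
    total = conc = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                conc += 1
            elif sp == sn:
                conc += 0.5
    return conc / total
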