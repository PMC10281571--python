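"""Independent brute-force oracles the implementation is checked against.

Each oracle recomputes a quantity by the most direct route available —
explicit enumeration, rational arithmetic, or resampling — sharing no
code with the implementation under test.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def agreement_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """2x2 metrics from an explicit per-patient agreement table.

    Materialises the predictions and labels patient by patient and
    counts marginal frequencies directly.
    """
    pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    lab = [1] * tp + [1] * fn + [0] * fp + [0] * tn
    n = len(pred)
    po = sum(p == l for p, l in zip(pred, lab)) / n
    pe = 0.0
    for cls in (0, 1):
        pe += (sum(p == cls for p in pred) / n) * (sum(l == cls for l in lab) / n)
    out = {
        "accuracy": po,
        "kappa": (po - pe) / (1 - pe) if pe < 1 else None,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (fp + tn) if fp + tn else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
    }
    s, c = out["sensitivity"], out["specificity"]
    out["roc_auc"] = (s + c) / 2 if s is not None and c is not None else None
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumeration of Fraction-valued
    hypergeometric probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(c1, r1) + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def fisher_margin_two_sided(r1: int, c1: int, n: int) -> dict:
    """fisher_two_sided for every table with the given margins."""
    r2 = n - r1
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(c1, r1) + 1)
    }
    return {a: sum(p for p in probs.values() if p <= pa) for a, pa in probs.items()}


def permutation_t_pvalue(x, y, n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the difference in means."""
    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        hits += abs(perm[: x.size].mean() - perm[x.size :].mean()) >= obs - 1e-12
    return (hits + 1) / (n_perm + 1)


def best_median_split(values):
    """Brute-force k=2 equal-frequency cut: over all positions that do
    not split ties, minimise occupancy imbalance (ties broken toward the
    earlier position); returns (cut_position, min_imbalance)."""
    s = sorted(values)
    n = len(s)
    best = None
    for j in range(1, n):
        if s[j - 1] == s[j]:
            continue
        imbalance = abs(j - (n - j))
        if best is None or imbalance < best[1]:
            best = (j, imbalance)
    return best


def enumerate_rules_scores(condition_sats, labels, max_conditions):
    """Brute-force rule enumeration for tiny instances.

    ``condition_sats`` maps a hashable condition id to a boolean
    satisfaction vector; scores every conjunction up to
    ``max_conditions`` for both orientations of the predicted class
    under the balanced-sensitivity/specificity fitness.  Returns a list
    of ((condition ids, positive_is_true_class), score).
    """
    labels = np.asarray(labels, bool)
    results = []
    ids = sorted(condition_sats)
    for size in range(1, max_conditions + 1):
        for combo in combinations(ids, size):
            sat = np.ones_like(labels)
            for cid in combo:
                sat = sat & condition_sats[cid]
            for positive in (labels, ~labels):
                tp = int((sat & positive).sum())
                fn = int((~sat & positive).sum())
                fp = int((sat & ~positive).sum())
                tn = int((~sat & ~positive).sum())
                if tp + fn == 0 or fp + tn == 0:
                    score = 0.0
                else:
                    score = (tp / (tp + fn) + tn / (fp + tn)) / 2
                results.append(((combo, positive is labels), score))
    return results
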