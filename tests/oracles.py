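"""Independent brute-force oracles, written directly from the published
segment-overlap definitions and kept free of any sspipe.metrics code."""

import itertools


def runs(s):
    """[(state, start, end)] maximal runs via groupby."""
    out, i = [], 0
    for state, grp in itertools.groupby(s):
        n = len(list(grp))
        out.append((state, i, i + n))
        i += n
    return out


def _minov_maxov(a, b):
    (_, s1, e1), (_, s2, e2) = a, b
    return min(e1, e2) - max(s1, s2), max(e1, e2) - min(s1, s2)


def sov99_oracle(truth, pred):
    """Literal 1999 definition: pooled N over classes, four-term delta."""
    num = 0.0
    N = 0
    for state in "HEC":
        obs = [r for r in runs(truth) if r[0] == state]
        prd = [r for r in runs(pred) if r[0] == state]
        for s1 in obs:
            partners = [s2 for s2 in prd if _minov_maxov(s1, s2)[0] > 0]
            len1 = s1[2] - s1[1]
            if not partners:
                N += len1
                continue
            for s2 in partners:
                minov, maxov = _minov_maxov(s1, s2)
                len2 = s2[2] - s2[1]
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                if delta < 0:
                    delta = 0
                num += (minov + delta) / maxov * len1
                N += len1
    return 100.0 * num / N if N else 100.0


def sov94_oracle(truth, pred):
    """Literal 1994 per-class definition (two-term delta, observed-residue
    normalizer), capped at 100, macro-averaged over classes in the truth."""
    per_class = []
    for state in "HEC":
        n_obs = sum(1 for c in truth if c == state)
        if n_obs == 0:
            continue
        num = 0.0
        for s1 in [r for r in runs(truth) if r[0] == state]:
            for s2 in [r for r in runs(pred) if r[0] == state]:
                minov, maxov = _minov_maxov(s1, s2)
                if minov <= 0:
                    continue
                len1 = s1[2] - s1[1]
                delta = min(maxov - minov, minov)
                num += (minov + delta) / maxov * len1
        per_class.append(min(100.0, 100.0 * num / n_obs))
    return sum(per_class) / len(per_class) if per_class else 100.0
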