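"""Independent brute-force reference implementations.

Deliberately naive (python loops, exhaustive scans) and written against the
stated rules only, so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np

A, B, H, N = 0, 1, 2, 3


def window_majority_oracle(positions, calls, length, window):
    """Exhaustive per-window tally: strict parent majority, HET-dominated or
    tied windows HET, empty windows MISSING."""
    n_win = max(1, -(-length // window))
    out = []
    for k in range(n_win):
        lo, hi = k * window + 1, (k + 1) * window
        a = b = h = 0
        for p, c in zip(positions, calls):
            if lo <= p <= hi:
                if c == A:
                    a += 1
                elif c == B:
                    b += 1
                elif c == H:
                    h += 1
        if a + b + h == 0:
            out.append(N)
        elif h > a + b:
            out.append(H)
        elif a > b:
            out.append(A)
        elif b > a:
            out.append(B)
        else:
            out.append(H)
    return out


def window_transition_oracle(states, mode="parental"):
    """Count COs on the compressed informative state string."""
    if mode == "parental":
        s = [x for x in states if x in (A, B)]
    else:
        s = ["HOM" if x in (A, B) else "HET" for x in states if x != N]
    return sum(1 for x, y in zip(s, s[1:]) if x != y)


def shift_count_oracle(calls):
    """Adjacent-difference count after dropping HET/MISSING."""
    s = [c for c in calls if c in (A, B)]
    return sum(1 for x, y in zip(s, s[1:]) if x != y)


def segmentation_oracle(positions, labels, min_run=3):
    """Enumerate runs of the determined label string, iteratively discard
    runs shorter than min_run, and emit internal runs as (donor, start_pos,
    end_pos, support); terminal runs as ('TERM', ...)."""
    pairs = [(p, l) for p, l in zip(positions, labels) if l in (A, B)]
    while True:
        runs = []
        for p, l in pairs:
            if runs and runs[-1][0] == l:
                runs[-1][1].append(p)
            else:
                runs.append([l, [p]])
        short = [r for r in runs if len(r[1]) < min_run]
        if not short:
            break
        drop = {id(r) for r in short}
        kept = [r for r in runs if id(r) not in drop]
        pairs = [(p, r[0]) for r in kept for p in r[1]]
    out = []
    for i, (l, ps) in enumerate(runs):
        tag = l if 0 < i < len(runs) - 1 else "TERM"
        out.append((tag, ps[0], ps[-1], len(ps)))
    return out


def sharing_census_oracle(events_by_line):
    """All-pairs overlap census: events as (chrom, start, end, donor)."""
    lines = list(events_by_line)
    result = {}
    for line in lines:
        for i, (c, s, e, d) in enumerate(events_by_line[line]):
            sharers = {line}
            for other in lines:
                if other == line:
                    continue
                for (c2, s2, e2, d2) in events_by_line[other]:
                    if c2 == c and d2 == d and s <= e2 and e >= s2:
                        sharers.add(other)
                        break
            result[(line, i)] = len(sharers)
    return result


def interval_validation_oracle(points, intervals, flank):
    """All-pairs check: point p validated iff [p-flank, p+flank] overlaps
    some interval [lo, hi]."""
    flags = []
    for p in points:
        flags.append(
            any(lo <= p + flank and hi >= p - flank for lo, hi in intervals)
        )
    return flags


def moving_average_oracle(counts, period):
    """Direct trailing mean."""
    out = [float("nan")] * len(counts)
    for i in range(period - 1, len(counts)):
        out[i] = sum(counts[i - period + 1 : i + 1]) / period
    return out


def correlation_dissimilarity_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if denom == 0:
        return 1.0
    return 1.0 - float((xm * ym).sum() / denom)


def average_linkage_oracle(matrix):
    """Naive UPGMA on the correlation dissimilarity matrix: returns the
    merge history as (clade frozenset, height) in merge order. Cluster
    distance is the unweighted mean of pairwise leaf dissimilarities."""
    matrix = np.asarray(matrix, float)
    n = len(matrix)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = correlation_dissimilarity_oracle(matrix[i], matrix[j])
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean(
                    [d[a, b] for a in clusters[i] for b in clusters[j]]
                )
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, i, j)
        dist, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, dist))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def welch_t_oracle(x, y):
    """Textbook Welch t statistic and two-tailed p from first principles."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def pearson_r_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
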