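"""Independent brute-force reference implementations used only by tests.

These transcribe the smoothing rules directly on explicit run lists, sharing
no code with the package, so they can serve as equivalence oracles.
"""

from collections import Counter


def rle(values):
    """Run-length encode a sequence into (value, start, length) triples."""
    runs = []
    i = 0
    n = len(values)
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        runs.append((values[i], i, j - i))
        i = j
    return runs


def _mode_largest(lengths):
    if not lengths:
        return None
    counts = Counter(lengths)
    top = max(counts.values())
    return max(length for length, c in counts.items() if c == top)


def oracle_smooth_binary(bits):
    """Reference mode-based cleaning of a binary repetition-start sequence."""
    bits = list(bits)
    runs = rle(bits)
    one_runs = [r for r in runs if r[0] == 1]
    if not one_runs:
        return bits
    M1 = _mode_largest([r[2] for r in one_runs])
    M0 = _mode_largest([r[2] for r in runs if r[0] == 0])
    confirmed = [r for r in one_runs if r[2] >= M1 / 2]
    candidates = [r for r in one_runs if r[2] < M1 / 2]
    if not confirmed:
        # degenerate: nothing reaches the threshold; keep the longest run
        # (leftmost on ties) as the single confirmed repetition
        best = max(one_runs, key=lambda r: (r[2], -r[1]))
        confirmed = [best]
        candidates = [r for r in one_runs if r is not best]
    if candidates and M0 is None:
        return bits
    for _value, start, length in candidates:
        near = any(abs(c[1] - start) <= M0 / 2 for c in confirmed)
        if near:
            for i in range(start, start + length):
                bits[i] = 0
    return bits


def oracle_count(bits):
    smoothed = oracle_smooth_binary(bits)
    return sum(1 for r in rle(smoothed) if r[0] == 1)


def oracle_smooth_labels(labels, t_min_steps, null_value):
    """Reference fixpoint smoothing of a label sequence.

    ``t_min_steps`` maps each non-null label value to its minimum duration in
    steps.  Repeatedly replaces the shortest (leftmost on ties) interior run
    that is flanked by one identical label on both sides and shorter than its
    minimum duration, until none remains.
    """
    labels = list(labels)
    while True:
        runs = rle(labels)
        applicable = []
        for r in range(1, len(runs) - 1):
            value, start, length = runs[r]
            if value == null_value:
                continue
            if runs[r - 1][0] != runs[r + 1][0] or runs[r - 1][0] == value:
                continue
            if length < t_min_steps[value]:
                applicable.append((length, start, runs[r - 1][0]))
        if not applicable:
            return labels
        length, start, replacement = min(applicable, key=lambda a: (a[0], a[1]))
        for i in range(start, start + length):
            labels[i] = replacement
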