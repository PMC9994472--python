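"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive: plain Python loops over sorted (distance, id) tuples,
applying the neighbor-selection case rules literally.  Kept free of any
import from the prediction code path it checks.
"""

import math


def oracle_cosine_distance(u, v):
    dot = sum(x * y for x, y in zip(u, v))
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(y * y for y in v))
    return 1.0 - dot / (nu * nv)


def oracle_select(query_freqs, rav_items, K, eps, zero_tol=1e-12):
    """rav_items: list of (genome_id, frequency_vector).

    Returns (entries, case) with entries sorted by (distance, genome_id).
    """
    dists = [
        (max(0.0, min(1.0, oracle_cosine_distance(query_freqs, freqs))), gid)
        for gid, freqs in rav_items
    ]
    zero = sorted((d, g) for d, g in dists if d <= zero_tol)
    if zero:
        return [(g, d) for d, g in zero], "ZERO_DISTANCE_OVERRIDE"
    within = sorted((d, g) for d, g in dists if d <= eps)
    if not within:
        return [], "EMPTY"
    if len(within) < K:
        return [(g, d) for d, g in within], "FEWER_THAN_K"
    if len(within) == K:
        return [(g, d) for d, g in within], "EXACTLY_K"
    return [(g, d) for d, g in within[:K]], "TRUNCATED_TO_K"


def assert_selection_equivalent(actual_entries, expected_entries, tol=1e-9):
    """Entry lists must agree rank-by-rank, except that members whose
    distances are mathematically tied may be reordered or swapped: the two
    distance computations (vectorized vs plain-Python sums) can differ by
    ~1e-16, which flips the order of exact ties."""
    actual = list(actual_entries)
    expected = list(expected_entries)
    assert len(actual) == len(expected)
    for (ga, da), (ge, de) in zip(actual, expected):
        assert abs(da - de) <= tol, f"rank distance mismatch: {da} vs {de}"
    act_d = dict(actual)
    exp_d = dict(expected)
    if expected:
        boundary = max(d for _, d in expected)
        for g in set(act_d) - set(exp_d):
            assert abs(act_d[g] - boundary) <= tol, f"{g} selected but not tied at boundary"
        for g in set(exp_d) - set(act_d):
            assert abs(exp_d[g] - boundary) <= tol, f"{g} dropped but not tied at boundary"


def oracle_rand_index(a, b):
    """All-pairs enumeration of partition agreement."""
    n = len(a)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    return agree / total
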