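"""Independent oracles used by the test suite.

These deliberately re-derive expected behaviour from first principles —
a second literal transcription of the printed band tables evaluated by
brute force, and binomial tail probabilities from ``math.comb`` — so
they share no code with the implementation under test.
"""

import math

# Second, independent transcription of the two printed band tables.
# Predicate forms: ("range", lo, hi) closed; ("lt", x); ("gt", x);
# ("ge", x); ("flag",); ("in", set).
MEOWS_TABLE = {
    "resp_rate": [(("range", 21, 25), 2), (("lt", 12), 3), (("gt", 25), 3)],
    "spo2": [(("range", 92, 95), 2), (("lt", 92), 3)],
    "o2_supplement": [(("flag",), 2)],
    "temperature": [(("range", 37.3, 37.7), 2), (("gt", 37.7), 3), (("lt", 36.0), 3)],
    "sbp": [
        (("range", 140, 150), 1),
        (("range", 150, 160), 2),
        (("gt", 160), 3),
        (("lt", 90), 3),
    ],
    "dbp": [(("range", 90, 100), 1), (("range", 100, 110), 2), (("gt", 110), 3)],
    "heart_rate": [
        (("range", 110, 120), 1),
        (("range", 120, 130), 2),
        (("range", 50, 60), 2),
        (("gt", 130), 3),
        (("lt", 50), 3),
    ],
    "avpu": [(("in", {"V", "P", "U"}), 3)],
    "vas_pain": [(("range", 4, 7), 2), (("ge", 7), 3)],
}

EWS_TABLE = {
    "heart_rate": [
        (("range", 41, 50), 1),
        (("range", 101, 110), 1),
        (("range", 111, 129), 2),
        (("lt", 40), 2),
        (("gt", 130), 3),
    ],
    "sbp": [
        (("range", 81, 100), 1),
        (("range", 71, 80), 2),
        (("gt", 200), 2),
        (("lt", 70), 3),
    ],
    "resp_rate": [
        (("range", 15, 20), 1),
        (("range", 21, 29), 2),
        (("lt", 8), 2),
        (("gt", 30), 3),
    ],
    "temperature": [
        (("range", 35.1, 36.5), 1),
        (("gt", 37.5), 1),
        (("lt", 35), 2),
    ],
    "avpu": [(("in", {"V"}), 1), (("in", {"P"}), 2), (("in", {"U"}), 3)],
}


def _predicate_matches(pred, value) -> bool:
    tag = pred[0]
    if tag == "range":
        return pred[1] <= value <= pred[2]
    if tag == "lt":
        return value < pred[1]
    if tag == "gt":
        return value > pred[1]
    if tag == "ge":
        return value >= pred[1]
    if tag == "flag":
        return bool(value)
    if tag == "in":
        return value in pred[1]
    raise AssertionError(pred)


def brute_force_score(table: dict, parameter: str, value) -> int:
    """Evaluate every band independently and take the max matching points."""
    if value is None:
        return 0
    best = 0
    for pred, points in table[parameter]:
        if _predicate_matches(pred, value):
            best = max(best, points)
    return best


def binom_cdf(k: int, n: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), from math.comb."""
    if p <= 0.0:
        return 1.0
    if p >= 1.0:
        return 0.0 if k < n else 1.0
    return sum(
        math.comb(n, i) * p**i * (1.0 - p) ** (n - i) for i in range(0, k + 1)
    )


def binom_sf_inclusive(k: int, n: int, p: float) -> float:
    """P(X >= k)."""
    return 1.0 - binom_cdf(k - 1, n, p)
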