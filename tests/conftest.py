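import pytest

from ptmnav import fixtures as fx


@pytest.fixture
def kgml_fixture():
    return fx.make_fixture_pathway(fx.SyntheticSpec(seed=3), "kgml")


@pytest.fixture
def gpml_fixture():
    return fx.make_fixture_pathway(fx.SyntheticSpec(seed=3), "gpml")


@pytest.fixture
def ks_table():
    return fx.make_kinase_substrate_table(seed=1)


def ecdf_score_oracle(items, member_keys):
    """Brute-force two-ECDF enrichment score, computed from the ECDF
    definitions by explicit enumeration (independent of the package's
    cumulative-sum implementation)."""
    order = sorted(range(len(items)), key=lambda i: -items[i][1])
    keys = [items[i][0] for i in order]
    n = len(keys)
    m = sum(k in member_keys for k in keys)
    if m == 0 or m == n:
        return float("nan")
    total = 0.0
    for i in range(1, n + 1):
        ecdf_sig = sum(1 for j in range(i) if keys[j] in member_keys) / m
        ecdf_rest = sum(1 for j in range(i) if keys[j] not in member_keys) / (n - m)
        total += ecdf_sig - ecdf_rest
    return total / n


def brute_force_hull(points):
    """Andrew monotone-chain convex hull; returns vertex set (as tuples)."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) <= 2:
        return set(pts)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return set(lower[:-1] + upper[:-1])
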