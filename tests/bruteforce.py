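"""Independent brute-force oracle: plain-Python nested-loop re-implementation
of cell counting, rule metrics, and the omega statistic.

Deliberately shares no code with the package; the expected-count model is
solved numerically from its defining equation rather than in closed form.
"""

import math


def brute_cells(reports, drug1, drug2, ae):
    """The eight 4x2 cells via nested filters over the report list."""
    cells = dict(n111=0, n110=0, n101=0, n100=0, n011=0, n010=0, n001=0, n000=0)
    for r in reports:
        has1 = drug1 in r.drugs
        has2 = drug2 in r.drugs
        target = ae in r.aes
        if has1 and has2:
            row = "11"
        elif has1:
            row = "10"
        elif has2:
            row = "01"
        else:
            row = "00"
        cells[f"n{row}{1 if target else 0}"] += 1
    return cells


def brute_pair_counts(reports):
    """Pair x AE co-report counts via a double loop (candidate oracle)."""
    counts = {}
    for r in reports:
        drugs = sorted(r.drugs)
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                for ae in r.aes:
                    key = (drugs[i], drugs[j], ae)
                    counts[key] = counts.get(key, 0) + 1
    return counts


def brute_metrics(cells):
    """support/confidence/lift/conviction straight from the formulas."""
    total = sum(cells.values())
    n111 = cells["n111"]
    n_pair = cells["n111"] + cells["n110"]
    n_ae = cells["n111"] + cells["n101"] + cells["n011"] + cells["n001"]
    support = n111 / total
    support_pair = n_pair / total
    support_ae = n_ae / total
    confidence = support / support_pair
    lift = confidence / support_ae
    if confidence < 1.0:
        conviction = (1.0 - support_ae) / (1.0 - confidence)
    else:
        conviction = math.inf if support_ae < 1.0 else 1.0
    return dict(support=support, confidence=confidence, lift=lift,
                conviction=conviction, support_ae=support_ae,
                support_pair=support_pair)


def brute_e111(cells, model="noren_excess"):
    """Expected count; the excess-risk equation is solved by bisection."""
    n11p = cells["n111"] + cells["n110"]
    n10p = cells["n101"] + cells["n100"]
    n01p = cells["n011"] + cells["n010"]
    n00p = cells["n001"] + cells["n000"]
    total = n11p + n10p + n01p + n00p
    n_ae = cells["n111"] + cells["n101"] + cells["n011"] + cells["n001"]
    independence = n11p * n_ae / total
    if model == "independence":
        return independence
    if n10p == 0 or n01p == 0 or n00p == 0:
        return independence
    f101, f011, f001 = cells["n101"] / n10p, cells["n011"] / n01p, cells["n001"] / n00p
    if f101 >= 1.0 or f011 >= 1.0:
        return float(n11p)
    if f001 >= 1.0:  # no finite solution to the excess equation
        return independence
    rhs = 1.0 / (1.0 - f101) + 1.0 / (1.0 - f011) - 1.0 / (1.0 - f001)
    if rhs < 1.0:  # no g in [0,1) satisfies 1/(1-g) = rhs; clamp at zero risk
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-15
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if 1.0 / (1.0 - mid) < rhs:
            lo = mid
        else:
            hi = mid
    return n11p * (lo + hi) / 2.0


def brute_omega(n111, e111):
    omega = math.log2((n111 + 0.5) / (e111 + 0.5))
    if n111 == 0:
        return omega, -math.inf
    lower = omega - 1.959964 / (math.log(2.0) * math.sqrt(n111))
    return omega, lower
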