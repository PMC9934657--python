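"""Independent naive-summation reference implementations for the scoring math.

Deliberately written with plain Python loops, ``math.fsum`` and explicit
set bookkeeping — no shared code with the package — so that agreement
with the engine is a genuine dual-route check.
"""

import math


def naive_pairs(lib_mz, exptl_mz, tol):
    """Greedy one-to-one pairing by ascending |delta m/z| (brute force)."""
    candidates = []
    for i, lm in enumerate(lib_mz):
        for j, em in enumerate(exptl_mz):
            d = abs(lm - em)
            if d <= tol:
                candidates.append((d, i, j))
    candidates.sort()
    used_i, used_j, pairs = set(), set(), []
    for _, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    return sorted(pairs)


def naive_cosine(lib, exptl, pairs, lib_norm="all"):
    lib_mz, lib_int = lib
    exptl_mz, exptl_int = exptl
    if not pairs:
        return 0.0
    num = math.fsum(lib_int[i] * exptl_int[j] for i, j in pairs)
    if lib_norm == "all":
        lib_sq = math.fsum(v * v for v in lib_int)
    else:
        lib_sq = math.fsum(lib_int[i] ** 2 for i, _ in pairs)
    exp_sq = math.fsum(exptl_int[j] ** 2 for _, j in pairs)
    if lib_sq == 0 or exp_sq == 0:
        return 0.0
    return min(num / math.sqrt(lib_sq * exp_sq), 1.0)


def naive_entropy(intensities):
    total = math.fsum(intensities)
    s = 0.0
    for v in intensities:
        if v > 0:
            p = v / total
            s -= p * math.log(p)
    return s


def naive_weight_transform(intensities):
    """Normalize; below entropy 3 raise to w = 0.25*(1+S) and re-normalize."""
    total = math.fsum(intensities)
    p = [v / total for v in intensities]
    s = naive_entropy(p)
    if s >= 3.0:
        return p
    w = 0.25 * (1.0 + s)
    q = [v**w if v > 0 else 0.0 for v in p]
    qt = math.fsum(q)
    return [v / qt for v in q]


def naive_entropy_similarity(lib, exptl, tol):
    lib_mz, lib_int = lib
    exptl_mz, exptl_int = exptl
    if not lib_mz or not exptl_mz:
        return 0.0
    a = naive_weight_transform(lib_int)
    b = naive_weight_transform(exptl_int)
    s_a = naive_entropy(a)
    s_b = naive_entropy(b)
    pairs = naive_pairs(lib_mz, exptl_mz, tol)
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    merged = [0.5 * a[i] + 0.5 * b[j] for i, j in pairs]
    merged += [0.5 * a[i] for i in range(len(a)) if i not in matched_a]
    merged += [0.5 * b[j] for j in range(len(b)) if j not in matched_b]
    s_m = naive_entropy(merged)
    sim = 1.0 - (2.0 * s_m - s_a - s_b) / math.log(4.0)
    return min(max(sim, 0.0), 1.0)


def naive_neme(lib_mz, exptl_mz, pairs):
    if not pairs:
        raise ValueError("undefined without pairs")
    return math.sqrt(
        math.fsum((lib_mz[i] - exptl_mz[j]) ** 2 for i, j in pairs) / len(pairs)
    )


def naive_score(lib, exptl, tol, lib_norm="all"):
    pairs = naive_pairs(lib[0], exptl[0], tol)
    cos = naive_cosine(lib, exptl, pairs, lib_norm=lib_norm)
    ent = naive_entropy_similarity(lib, exptl, tol)
    return cos * ent * ent
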