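"""Independent brute-force evaluators used to cross-check the package.

These deliberately re-derive the scoring rules with literal loops over
frozensets, with no code shared with the implementation under test.
"""

from __future__ import annotations


def minmax_predict(d, profiles, ys):
    """Literal enumeration of the min-max averaging rule over sets."""
    d = frozenset(d)
    profiles = [frozenset(p) for p in profiles]

    matches = [y for p, y in zip(profiles, ys) if p == d]
    if matches:
        return sum(matches) / len(matches)

    subset_idx = [i for i, p in enumerate(profiles) if p < d]
    if subset_idx:
        best = max(ys[i] for i in subset_idx)
        h = next(i for i in subset_idx if ys[i] == best)  # first-index tie-break
        vals = [ys[h]]
        for j, p in enumerate(profiles):
            if j != h and p < d and profiles[h] < p and ys[j] < ys[h]:
                vals.append(ys[j])
        y_min = sum(vals) / len(vals)
    else:
        y_min = 0.0  # virtual empty-profile drug

    superset_idx = [i for i, p in enumerate(profiles) if p > d]
    if superset_idx:
        worst = min(ys[i] for i in superset_idx)
        l = next(i for i in superset_idx if ys[i] == worst)
        vals = [ys[l]]
        for j, p in enumerate(profiles):
            if j != l and p > d and p < profiles[l] and ys[j] > ys[l]:
                vals.append(ys[j])
        y_max = sum(vals) / len(vals)
    else:
        y_max = 1.0  # virtual full-universe drug

    return (y_min + y_max) / 2.0


def sirna_synergy_loop(double_kd, singles):
    """Plain double loop for the mean multiplicative excess (x100)."""
    total, n = 0.0, 0
    for (i, j), y_ij in double_kd.items():
        total += y_ij - singles[i] * singles[j]
        n += 1
    return 100.0 * total / n
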