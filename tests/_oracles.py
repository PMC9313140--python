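"""Independent brute-force oracles shared by the test modules.

Pure-Python scalar loops — deliberately free of numpy vectorisation so they
cannot share a bug with the implementation they check.
"""

import math


def oracle_features(v):
    """The nine heuristic features, one scalar loop per definition."""

    def norm(a):
        return math.sqrt(sum(x * x for x in a))

    def sub(a, b):
        return [a[i] - b[i] for i in range(3)]

    def cross(a, b):
        return [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]

    def ang(a, b):
        na, nb = norm(a), norm(b)
        if na < 1e-12 or nb < 1e-12:
            return 0.0
        c = sum(a[i] * b[i] for i in range(3)) / (na * nb)
        return math.acos(max(-1.0, min(1.0, c)))

    v = [list(row) for row in v]
    n = len(v)
    d1 = [sub(v[i + 1], v[i]) for i in range(n - 1)]
    d2 = [sub(d1[i + 1], d1[i]) for i in range(n - 2)]
    p = [cross(v[i], v[i + 1]) for i in range(n - 1)]
    q = [cross(d1[i], d1[i + 1]) for i in range(n - 2)]
    r = [cross(d2[i], d2[i + 1]) for i in range(n - 3)]
    rows = []
    for i in range(n - 4):
        rows.append(
            [
                norm(v[i]), norm(d1[i]), norm(d2[i]),
                ang(v[i], v[i + 1]), ang(d1[i], d1[i + 1]), ang(d2[i], d2[i + 1]),
                ang(p[i], p[i + 1]), ang(q[i], q[i + 1]), ang(r[i], r[i + 1]),
            ]
        )
    return rows


def oracle_metrics(conf):
    """Accuracy, precision, recall, F1 straight from their definitions."""
    n = len(conf)
    total = sum(sum(row) for row in conf)
    correct = sum(conf[i][i] for i in range(n))
    out = {"accuracy": correct / total, "precision": [], "recall": [], "f1": []}
    for c in range(n):
        tp = conf[c][c]
        fp = sum(conf[r][c] for r in range(n)) - tp
        fn = sum(conf[c][r] for r in range(n)) - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        out["precision"].append(prec)
        out["recall"].append(rec)
        out["f1"].append(f1)
    return out
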