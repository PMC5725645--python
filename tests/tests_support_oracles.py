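"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive expected behavior from first principles
(case tables, explicit enumeration, set arithmetic) rather than calling
the package's own code paths.
"""

import io as sio
import math

import numpy as np
import pandas as pd


# -- decision tree ----------------------------------------------------------


def oracle_phase(b, g, c, tau=2.0):
    present = [x > 0 for x in (b, g, c)]
    if sum(present) == 0:
        return "error"
    if sum(present) == 1:
        return {0: "P1", 1: "P2", 2: "P3"}[present.index(True)]
    if c == 0:
        pass  # ratio non-computable: take the P1|P2 branch
    elif b + g == 0:
        return "P3"
    elif math.log((b + g) / c) <= tau:
        return "P3"
    if g == 0:
        return "P1"
    if b == 0:
        return "P2"
    return "P2" if math.log(b / g) <= tau else "P1"


def oracle_phase_cases(step=0.05):
    vals = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    degenerate = [
        (0.0, 0.0, 0.0), (0.5, 0.0, 0.0), (0.0, 0.5, 0.0), (0.0, 0.0, 0.5),
        (0.3, 0.3, 0.0), (0.3, 0.0, 0.3), (0.0, 0.3, 0.3),
    ]
    seen = []
    for b in vals:
        for g in vals:
            for c in vals:
                if b + g + c <= 1.0 + 1e-9:
                    seen.append((float(b), float(g), float(c)))
    for b, g, c in seen + degenerate:
        yield b, g, c, oracle_phase(b, g, c)


# -- weighted UniFrac -------------------------------------------------------


def random_newick(rng, n_leaves):
    nodes = [f"L{i}" for i in range(n_leaves)]
    trees = [f"{n}:{rng.uniform(0.1, 3):.3f}" for n in nodes]
    while len(trees) > 1:
        i, j = sorted(rng.choice(len(trees), 2, replace=False))
        merged = f"({trees[i]},{trees[j]}):{rng.uniform(0.1, 3):.3f}"
        trees = [t for k, t in enumerate(trees) if k not in (i, j)] + [merged]
    return trees[0].rsplit(":", 1)[0] + ";", nodes


def brute_force_unifrac(newick, taxa, a, b, normalized=False):
    from skbio import TreeNode

    tree = TreeNode.read(sio.StringIO(newick))
    pa = np.asarray(a, float) / np.sum(a)
    pb = np.asarray(b, float) / np.sum(b)
    frac = {t: (pa[i], pb[i]) for i, t in enumerate(taxa)}
    total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips(include_self=True)}
        fa = sum(frac[t][0] for t in leaves if t in frac)
        fb = sum(frac[t][1] for t in leaves if t in frac)
        total += (node.length or 0.0) * abs(fa - fb)
    if not normalized:
        return total
    denom = 0.0
    for tip in tree.tips():
        depth, node = 0.0, tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        fa, fb = frac[tip.name]
        denom += depth * (fa + fb)
    return total / denom if denom else 0.0


# -- stool transition -------------------------------------------------------

_VOCAB = ["meconium stool", "dark meconium", "yellow seedy", "soft stool", "loose stool"]


def random_records(rng, start="2020-01-02"):
    n = int(rng.integers(1, 15))
    texts = [_VOCAB[i] for i in rng.integers(0, len(_VOCAB), n)]
    records = pd.DataFrame(
        {
            "subject_id": "s",
            "timestamp": pd.date_range(start, periods=n, freq="D")
            + pd.Timedelta(hours=8),
            "text": texts,
        }
    )
    return records, texts


def oracle_stool_scan(texts, max_later=2):
    has_mec = ["meconium" in t.lower() for t in texts]
    for i in range(len(texts)):
        if not has_mec[i] and sum(has_mec[i + 1 :]) <= max_later:
            return i
    return None


# -- regression designs -----------------------------------------------------


def design_from_frame(df, cols, outcome="zscore", groups="subject_id"):
    from gutphase.models import RegressionDesign

    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for c in cols:
        X[c] = df[c]
    return RegressionDesign(
        y=df[outcome], X=X, groups=df[groups], terms={c: [c] for c in cols}
    )
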