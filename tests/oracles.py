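"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the vectorized code paths in the package: Gower is
recomputed cell-by-cell with explicit loops, chi-square/Cramér's V from the
textbook formulas, and the adjusted Rand index by enumerating element pairs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from morphodisp.gower import column_range, partial_dissimilarity
from morphodisp.matrix_io import MISSING, CharacterMatrix


def gower_bruteforce(m: CharacterMatrix) -> np.ndarray:
    """Pairwise Gower by looping partial_dissimilarity over characters."""
    n = m.n_taxa
    ranges = [column_range(m.column(j), s) for j, s in enumerate(m.specs)]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for k, spec in enumerate(m.specs):
                delta, w = partial_dissimilarity(
                    m.states[i][k], m.states[j][k], spec, ranges[k]
                )
                num += w * delta
                den += w
            d[i, j] = num / den if den > 0 else math.nan
    return d


def chi2_by_hand(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square from margins, cell by cell (zero margins dropped)."""
    from scipy.stats import chi2 as chi2_dist

    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    n = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df, float(chi2_dist.sf(stat, df))


def cramers_v_by_hand(table: np.ndarray) -> float:
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    stat, _, _ = chi2_by_hand(t)
    return math.sqrt(stat / (t.sum() * (min(t.shape) - 1)))


def ari_pair_counting(a: list, b: list) -> float:
    """Adjusted Rand index by explicit enumeration of all element pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


def random_mixed_matrix(rng: np.random.Generator, n_taxa: int = 10,
                        missing_rate: float = 0.15) -> CharacterMatrix:
    """A small random mixed-kind matrix for oracle comparisons."""
    from morphodisp.matrix_io import CharacterSpec

    specs = [
        CharacterSpec("num1", "numeric"),
        CharacterSpec("num2", "numeric"),
        CharacterSpec("ordn", "ordinal", ("a", "b", "c", "d")),
        CharacterSpec("nom", "nominal", ("x", "y", "z")),
        CharacterSpec("bin", "binary_symmetric"),
        CharacterSpec("asym", "binary_asymmetric"),
    ]
    rows = []
    for _ in range(n_taxa):
        row = [
            float(rng.integers(0, 12)),
            float(np.round(rng.normal(), 3)),
            ("a", "b", "c", "d")[rng.integers(0, 4)],
            ("x", "y", "z")[rng.integers(0, 3)],
            str(rng.integers(0, 2)),
            str(rng.integers(0, 2)),
        ]
        # num1 stays fully observed so every taxon pair is comparable
        for j in range(1, len(specs)):
            if rng.random() < missing_rate:
                row[j] = MISSING
        rows.append(row)
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], specs, rows)
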