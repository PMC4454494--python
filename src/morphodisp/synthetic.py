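"""Synthetic mixed-type character matrices with known group structure.

The generator emulates the statistical shape of discrete morphological
matrices: a handful of latent morphotype groups, characters of mixed kind
(numeric counts, ordinal, nominal, binary), and entries missing completely
at random — the typical signature of fossil character data.

The single ``separation`` knob controls effect size across kinds: numeric
group centers sit on an equally spaced grid with step ``separation`` (the
group-to-grid assignment permuted per character) while within-group noise
has unit variance, so adjacent groups differ by exactly ``separation``
within-group standard deviations per character; categorical characters give each
group a modal state with mixture weight (1 + separation) / (L + separation)
over L levels (the remaining mass spread uniformly), so ``separation = 0``
makes every kind uninformative about group membership.

All randomness flows from one seeded generator in a fixed draw order:
group assignment, then per-character parameters and values (characters in
matrix order), then the missingness mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .errors import MorphodispError
from .matrix_io import MISSING, CharacterMatrix, CharacterSpec, GroupScheme

_KIND_ORDER = ("numeric", "ordinal", "nominal", "binary_symmetric", "binary_asymmetric")
_DEFAULT_LEVELS = {
    "ordinal": ("0", "1", "2", "3", "4"),
    "nominal": ("A", "B", "C", "D"),
    "binary_symmetric": ("0", "1"),
    "binary_asymmetric": ("0", "1"),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic matrix draw."""

    n_taxa: int
    char_counts: Mapping[str, int]
    n_groups: int
    separation: float
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.n_taxa < self.n_groups:
            raise MorphodispError("need n_taxa >= n_groups >= 1")
        if not 0 <= self.missing_rate < 1:
            raise MorphodispError("missing_rate must be in [0, 1)")
        bad = set(self.char_counts) - set(_KIND_ORDER)
        if bad:
            raise MorphodispError(f"unknown character kinds: {sorted(bad)}")
        if any(c < 0 for c in self.char_counts.values()):
            raise MorphodispError("character counts must be >= 0")
        if sum(self.char_counts.values()) < 1:
            raise MorphodispError("need at least one character")


def _modal_mixture(levels: Sequence[str], modal: int, separation: float) -> np.ndarray:
    L = len(levels)
    p = np.full(L, (1.0 - (1 + separation) / (L + separation)) / (L - 1))
    p[modal] = (1 + separation) / (L + separation)
    return p


def generate_matrix(spec: SyntheticSpec) -> tuple[CharacterMatrix, GroupScheme]:
    """Draw a matrix and its ground-truth group scheme from a SyntheticSpec.

    Numeric characters are integer-rounded (count-like), keeping every
    generated matrix usable by the binned association stage, which requires
    discrete states.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_taxa, spec.n_groups
    taxa = [f"t{i + 1:03d}" for i in range(n)]

    # balanced-ish group assignment over a random permutation
    perm = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    for gi, chunk in enumerate(np.array_split(perm, g)):
        groups[chunk] = gi

    specs: list[CharacterSpec] = []
    columns: list[list] = []
    idx = 0
    for kind in _KIND_ORDER:
        for _ in range(spec.char_counts.get(kind, 0)):
            idx += 1
            name = f"{kind}_{idx}"
            if kind == "numeric":
                centers = spec.separation * rng.permutation(g).astype(float)
                vals = np.round(centers[groups] + rng.normal(0.0, 1.0, size=n))
                specs.append(CharacterSpec(name=name, kind="numeric"))
                columns.append([float(v) for v in vals])
            else:
                levels = _DEFAULT_LEVELS[kind]
                modal = rng.integers(0, len(levels), size=g)
                col = []
                for i in range(n):
                    p = _modal_mixture(levels, int(modal[groups[i]]), spec.separation)
                    col.append(levels[rng.choice(len(levels), p=p)])
                specs.append(CharacterSpec(name=name, kind=kind, levels=levels))
                columns.append(col)

    states = [[columns[j][i] for j in range(len(columns))] for i in range(n)]
    if spec.missing_rate > 0:
        mask = rng.random((n, len(columns))) < spec.missing_rate
        # keep at least one observation per column
        for j in range(len(columns)):
            if mask[:, j].all():
                mask[rng.integers(0, n), j] = False
        for i in range(n):
            for j in range(len(columns)):
                if mask[i, j]:
                    states[i][j] = MISSING
    matrix = CharacterMatrix(taxa=taxa, specs=specs, states=states)
    truth = GroupScheme(
        name="truth",
        assignment={t: f"g{groups[i] + 1}" for i, t in enumerate(taxa)},
    )
    return matrix, truth


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index between two partitions of the same element set.

    Partitions may be label sequences (aligned) or mappings element -> label.
    """
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        if not (isinstance(a, Mapping) and isinstance(b, Mapping)):
            raise MorphodispError("both partitions must be mappings, or neither")
        if set(a) != set(b):
            raise MorphodispError("partitions cover different element sets")
        keys = sorted(a)
        la = [a[k] for k in keys]
        lb = [b[k] for k in keys]
    else:
        la, lb = list(a), list(b)
        if len(la) != len(lb):
            raise MorphodispError("partitions cover different element sets")
    return float(adjusted_rand_score(la, lb))
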