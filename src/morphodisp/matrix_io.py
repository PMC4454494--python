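"""Reading, validation and serialization of taxon x character matrices.

The on-disk matrix dialect is strict: a UTF-8 TSV whose header row names the
characters (matching the character specification file) and whose first column
holds taxon identifiers.  Character specifications live in a YAML file, one
entry per character with ``name``, ``kind`` and (for ordinal/nominal/binary)
``levels``.  Missing data tokens default to ``{"NA", "?", ""}``.

Characters come in five kinds.  ``numeric`` states are real numbers;
``ordinal`` and ``nominal`` states are labels drawn from an explicit ordered
level list; ``binary_symmetric`` / ``binary_asymmetric`` are two-state
characters, the asymmetric flavour treating joint absence as non-informative
(its first level is the "absent" state).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .errors import (
    DuplicateTaxonError,
    EmptyColumnError,
    InvalidStateError,
    SpecMismatchError,
    UnknownTaxonError,
    ValidationError,
)

KINDS = ("numeric", "ordinal", "nominal", "binary_symmetric", "binary_asymmetric")
CATEGORICAL_KINDS = ("ordinal", "nominal", "binary_symmetric", "binary_asymmetric")
DEFAULT_MISSING_TOKENS = frozenset({"NA", "?", ""})

#: Reserved group label marking a taxon carried through the pipeline but
#: omitted from variance computations.
EXCLUDED = "EXCLUDED"


class _Missing:
    """Singleton sentinel for a missing character state."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = _Missing()


@dataclass(frozen=True)
class CharacterSpec:
    """Declaration of one character: its name, kind and admissible states."""

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    description: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(
                f"character {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {KINDS}"
            )
        levels = self.levels
        if self.kind in ("ordinal", "nominal"):
            if levels is None or len(levels) < 2:
                raise ValidationError(
                    f"character {self.name!r}: kind {self.kind!r} requires >=2 levels"
                )
        if self.kind in ("binary_symmetric", "binary_asymmetric"):
            if levels is None:
                object.__setattr__(self, "levels", ("0", "1"))
            elif len(levels) != 2:
                raise ValidationError(
                    f"character {self.name!r}: binary characters take exactly 2 levels"
                )
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(s) for s in self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise ValidationError(
                    f"character {self.name!r}: duplicate levels {self.levels}"
                )

    @property
    def is_categorical(self) -> bool:
        return self.kind in CATEGORICAL_KINDS

    def admissible(self, state: Any) -> bool:
        if state is MISSING:
            return True
        if self.kind == "numeric":
            return isinstance(state, (int, float)) and math.isfinite(float(state))
        return str(state) in self.levels  # type: ignore[operator]


@dataclass
class CharacterMatrix:
    """A validated taxa x characters grid of mixed-type states.

    ``states[i][j]`` is the state of taxon ``taxa[i]`` for character
    ``specs[j]``: a float for numeric characters, a level label for
    categorical ones, or the :data:`MISSING` sentinel.
    """

    taxa: list[str]
    specs: list[CharacterSpec]
    states: list[list[Any]]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            seen: set[str] = set()
            for t in self.taxa:
                if t in seen:
                    raise DuplicateTaxonError(f"duplicate taxon id {t!r}")
                seen.add(t)
        if len(self.states) != len(self.taxa):
            raise ValidationError(
                f"{len(self.states)} state rows for {len(self.taxa)} taxa"
            )
        ncol = len(self.specs)
        for t, row in zip(self.taxa, self.states):
            if len(row) != ncol:
                raise ValidationError(
                    f"taxon {t!r}: {len(row)} states for {ncol} characters"
                )
        for j, spec in enumerate(self.specs):
            observed = 0
            for i, t in enumerate(self.taxa):
                s = self.states[i][j]
                if s is MISSING:
                    continue
                observed += 1
                if not spec.admissible(s):
                    raise InvalidStateError(
                        f"taxon {t!r}, character {spec.name!r}: state {s!r} "
                        f"not admissible (levels: {spec.levels})"
                    )
            if observed == 0:
                raise EmptyColumnError(
                    f"character {spec.name!r} has no observed values"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.specs)

    def column(self, j: int) -> list[Any]:
        return [row[j] for row in self.states]

    def taxon_index(self, taxon: str) -> int:
        return self.taxa.index(taxon)


@dataclass
class GroupScheme:
    """A named assignment of taxa to group labels.

    Taxa mapped to :data:`EXCLUDED` are carried through the pipeline but
    omitted from variance computations (e.g. a problematic taxon attached to
    a cluster but left out of disparity).
    """

    name: str
    assignment: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        """Group label -> member taxa, excluding EXCLUDED."""
        out: dict[str, list[str]] = {}
        for taxon, label in self.assignment.items():
            if label == EXCLUDED:
                continue
            out.setdefault(label, []).append(taxon)
        return out

    def excluded(self) -> list[str]:
        return [t for t, g in self.assignment.items() if g == EXCLUDED]

    def validate_against(self, matrix: CharacterMatrix) -> None:
        known = set(matrix.taxa)
        for taxon in self.assignment:
            if taxon not in known:
                raise UnknownTaxonError(
                    f"group scheme {self.name!r}: unknown taxon {taxon!r}"
                )
        if not any(len(m) >= 2 for m in self.groups().values()):
            raise ValidationError(
                f"group scheme {self.name!r}: no group with >=2 members"
            )


# ---------------------------------------------------------------------------
# readers


def read_spec(spec_path: str | Path) -> list[CharacterSpec]:
    """Read a YAML character specification (list of name/kind/levels entries)."""
    with open(spec_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise SpecMismatchError(f"{spec_path}: expected a non-empty list of characters")
    specs = []
    for entry in raw:
        if not isinstance(entry, Mapping) or "name" not in entry or "kind" not in entry:
            raise SpecMismatchError(f"{spec_path}: each entry needs 'name' and 'kind'")
        levels = entry.get("levels")
        specs.append(
            CharacterSpec(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                levels=tuple(str(x) for x in levels) if levels is not None else None,
                description=str(entry.get("description", "")),
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SpecMismatchError(f"{spec_path}: duplicate character names")
    return specs


def _parse_cell(token: str, spec: CharacterSpec, missing_tokens: frozenset[str],
                taxon: str) -> Any:
    token = token.strip()
    if token in missing_tokens:
        return MISSING
    if spec.kind == "numeric":
        try:
            return float(token)
        except ValueError:
            raise InvalidStateError(
                f"taxon {taxon!r}, character {spec.name!r}: "
                f"non-numeric state {token!r}"
            ) from None
    if token not in spec.levels:  # type: ignore[operator]
        raise InvalidStateError(
            f"taxon {taxon!r}, character {spec.name!r}: state {token!r} "
            f"not in declared levels {spec.levels}"
        )
    return token


def read_matrix(
    matrix_path: str | Path,
    spec_path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> CharacterMatrix:
    """Read and validate a TSV character matrix against its YAML spec.

    The TSV header must name the characters in the spec's order; the first
    column holds taxon identifiers.
    """
    specs = read_spec(spec_path)
    missing_tokens = frozenset(missing_tokens)
    lines = Path(matrix_path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValidationError(f"{matrix_path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    expected = [s.name for s in specs]
    if header[1:] != expected:
        raise SpecMismatchError(
            f"{matrix_path}: header columns {header[1:]} do not match "
            f"spec characters {expected}"
        )
    taxa: list[str] = []
    states: list[list[Any]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(specs) + 1:
            raise ValidationError(
                f"{matrix_path}:{lineno}: {len(cells)} fields, "
                f"expected {len(specs) + 1}"
            )
        taxon = cells[0].strip()
        if taxon in taxa:
            raise DuplicateTaxonError(
                f"{matrix_path}:{lineno}: duplicate taxon id {taxon!r}"
            )
        taxa.append(taxon)
        states.append(
            [_parse_cell(c, s, missing_tokens, taxon) for c, s in zip(cells[1:], specs)]
        )
    return CharacterMatrix(taxa=taxa, specs=specs, states=states)


def read_groups(path: str | Path, matrix: CharacterMatrix,
                name: str | None = None) -> GroupScheme:
    """Read a two-column taxon -> group-label TSV as a GroupScheme.

    Taxa absent from the file are assigned :data:`EXCLUDED`; the label
    ``EXCLUDED`` itself is reserved and flags explicit exclusion.
    """
    assignment: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated fields")
        taxon, label = parts[0].strip(), parts[1].strip()
        if taxon in assignment:
            raise DuplicateTaxonError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
        assignment[taxon] = label
    scheme = GroupScheme(name=name or Path(path).stem, assignment=assignment)
    scheme.validate_against(matrix)
    # carry unlisted taxa as EXCLUDED so downstream sees the full taxon set
    for t in matrix.taxa:
        scheme.assignment.setdefault(t, EXCLUDED)
    return scheme


# ---------------------------------------------------------------------------
# writers


def write_matrix(matrix: CharacterMatrix, matrix_path: str | Path,
                 spec_path: str | Path | None = None,
                 missing_token: str = "?") -> None:
    """Write a CharacterMatrix back to the TSV dialect (and spec to YAML)."""
    lines = ["taxon\t" + "\t".join(s.name for s in matrix.specs)]
    for taxon, row in zip(matrix.taxa, matrix.states):
        cells = [taxon]
        for state, spec in zip(row, matrix.specs):
            if state is MISSING:
                cells.append(missing_token)
            elif spec.kind == "numeric":
                cells.append(repr(float(state)))
            else:
                cells.append(str(state))
        lines.append("\t".join(cells))
    Path(matrix_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if spec_path is not None:
        entries = []
        for s in matrix.specs:
            e: dict[str, Any] = {"name": s.name, "kind": s.kind}
            if s.levels is not None:
                e["levels"] = list(s.levels)
            if s.description:
                e["description"] = s.description
            entries.append(e)
        Path(spec_path).write_text(
            yaml.safe_dump(entries, sort_keys=False), encoding="utf-8"
        )


def write_groups(scheme: GroupScheme, path: str | Path) -> None:
    lines = [f"{t}\t{g}" for t, g in scheme.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _jsonify(obj: Any) -> Any:
    """Convert report dataclasses / numpy scalars to plain JSON types."""
    import numpy as np

    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        if math.isinf(obj):
            return "+INF" if obj > 0 else "-INF"
        return obj
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonify(obj.item())
    if isinstance(obj, np.ndarray):
        return [_jsonify(x) for x in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x) for x in obj]
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_report(obj: Any, path: str | Path) -> None:
    """Serialize a pipeline result dataclass to deterministic JSON.

    Numeric fields round-trip losslessly (floats emitted at full precision);
    infinities are encoded as the strings ``"+INF"`` / ``"-INF"``.
    """
    payload = json.dumps(_jsonify(obj), sort_keys=True, indent=1)
    Path(path).write_text(payload + "\n", encoding="utf-8")


def read_report(path: str | Path) -> Any:
    """Read a report written by :func:`write_report` back to plain dicts."""

    def _undo(x: Any) -> Any:
        if x == "+INF":
            return math.inf
        if x == "-INF":
            return -math.inf
        if isinstance(x, dict):
            return {k: _undo(v) for k, v in x.items()}
        if isinstance(x, list):
            return [_undo(v) for v in x]
        return x

    with open(path, "r", encoding="utf-8") as fh:
        return _undo(json.load(fh))
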