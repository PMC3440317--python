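"""Amino-acid alphabet, substitution matrices, tri-peptide indexing and
subsequence patterns.

The feature space of the predictor is the set of all 20**3 = 8000 ordered
tri-peptides over the canonical amino-acid alphabet.  Every module in the
package addresses that space through a :class:`TriPeptideIndex`, a bijection
between tri-peptides and attribute indices.  Similarity between residues is
scored with standard published substitution matrices (BLOSUM62 or PAM160),
bundled with the package as NCBI-format text tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Canonical 20-letter amino-acid alphabet, in the lexicographic order used
#: throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INT = {a: i for i, a in enumerate(AMINO_ACIDS)}

N_TRIPEPTIDES = 20 ** 3

_BUNDLED = {"blosum62": "BLOSUM62.txt", "pam160": "PAM160.txt"}


class NonStandardResidueError(ValueError):
    """A sequence contains a residue outside the 20-letter alphabet."""


def validate_sequence(seq: str, *, context: str = "sequence") -> None:
    """Raise :class:`NonStandardResidueError` naming the first offending
    position if *seq* contains anything outside the canonical alphabet.

    Ambiguity codes (B, Z, X), selenocysteine (U) and stops (*) are rejected:
    the tri-peptide attribute space has no slot for them, and coercing them
    silently would corrupt propensity estimates.
    """
    for pos, res in enumerate(seq):
        if res not in AA_TO_INT:
            raise NonStandardResidueError(
                f"non-standard residue {res!r} at position {pos + 1} in {context}"
            )


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode a validated residue string as an int array (0..19)."""
    try:
        return np.fromiter((AA_TO_INT[r] for r in seq), dtype=np.int64, count=len(seq))
    except KeyError:
        validate_sequence(seq)  # raises with a precise message
        raise  # pragma: no cover


def is_standard(seq: str) -> bool:
    return all(r in AA_TO_INT for r in seq)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer residue-pair score table.

    Attributes
    ----------
    name:
        Identifier of the matrix (``blosum62`` or ``pam160`` for the bundled
        tables).
    scores:
        ``(20, 20)`` integer array indexed by :data:`AMINO_ACIDS` order.
    """

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (20, 20):
            raise ValueError(f"expected a 20x20 score table, got {s.shape}")
        if not np.array_equal(s, s.T):
            raise ValueError(f"substitution matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "scores", s.astype(np.int64))

    def score(self, a: str, b: str) -> int:
        """Similarity score of the residue pair (a, b)."""
        return int(self.scores[AA_TO_INT[a], AA_TO_INT[b]])

    @classmethod
    def from_ncbi_text(cls, text: str, name: str) -> "SubstitutionMatrix":
        """Parse an NCBI-style matrix table (header row of residues, one row
        per residue).  Only the 20 canonical residues are retained."""
        rows: dict[str, dict[str, int]] = {}
        header: list[str] | None = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if header is None:
                header = fields
                continue
            rows[fields[0]] = {
                col: int(v) for col, v in zip(header, fields[1:], strict=True)
            }
        if header is None:
            raise ValueError(f"no header row found parsing matrix {name!r}")
        missing = [a for a in AMINO_ACIDS if a not in rows]
        if missing:
            raise ValueError(f"matrix {name!r} missing rows for {missing}")
        scores = np.array(
            [[rows[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=np.int64
        )
        return cls(name=name, scores=scores)

    def to_ncbi_text(self) -> str:
        lines = ["   " + "  ".join(AMINO_ACIDS)]
        for i, a in enumerate(AMINO_ACIDS):
            lines.append(
                a + " " + " ".join(f"{int(v):3d}" for v in self.scores[i])
            )
        return "\n".join(lines) + "\n"


def load_substitution_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled substitution matrix by name (``blosum62`` | ``pam160``)."""
    key = name.lower()
    if key not in _BUNDLED:
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: {sorted(_BUNDLED)}"
        )
    text = (resources.files("tripitope.data") / _BUNDLED[key]).read_text()
    return SubstitutionMatrix.from_ncbi_text(text, name=key)


@dataclass(frozen=True)
class SubsequencePattern:
    """Projection of a sliding window onto exactly three compared positions.

    The contiguous pattern ``AAA`` compares all three residues of a 3-residue
    window.  The gapped patterns span a 4-residue window and ignore one
    position (``A_AA`` ignores the second, ``AA_A`` the third), so the
    attribute space stays at 20**3 in every case.
    """

    name: str
    positions: tuple[int, int, int]
    window_width: int

    def project(self, window: str) -> str:
        p = self.positions
        return window[p[0]] + window[p[1]] + window[p[2]]


CONTIGUOUS = SubsequencePattern("AAA", (0, 1, 2), 3)
GAP_FIRST = SubsequencePattern("A_AA", (0, 2, 3), 4)
GAP_LAST = SubsequencePattern("AA_A", (0, 1, 3), 4)

PATTERNS = {p.name: p for p in (CONTIGUOUS, GAP_FIRST, GAP_LAST)}


def get_pattern(name: str | SubsequencePattern) -> SubsequencePattern:
    if isinstance(name, SubsequencePattern):
        return name
    try:
        return PATTERNS[name]
    except KeyError:
        raise ValueError(
            f"unknown subsequence pattern {name!r}; available: {sorted(PATTERNS)}"
        ) from None


@dataclass(frozen=True)
class TriPeptideIndex:
    """Bijection between the 8000 tri-peptides and attribute indices.

    The default ordering is lexicographic over :data:`AMINO_ACIDS`, which is
    stable across runs.  A custom permutation of the lexicographic order can
    be supplied (used e.g. to check that no hidden order dependence exists).
    """

    #: permutation such that attribute ``i`` is tri-peptide
    #: ``lex_tripeptide(permutation[i])``
    permutation: np.ndarray = field(
        default_factory=lambda: np.arange(N_TRIPEPTIDES)
    )

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=np.int64)
        if perm.shape != (N_TRIPEPTIDES,) or not np.array_equal(
            np.sort(perm), np.arange(N_TRIPEPTIDES)
        ):
            raise ValueError("permutation must be a permutation of 0..7999")
        object.__setattr__(self, "permutation", perm)

    @property
    def is_lexicographic(self) -> bool:
        return bool(np.array_equal(self.permutation, np.arange(N_TRIPEPTIDES)))

    def tripeptides(self) -> list[str]:
        """All 8000 tri-peptides in attribute order."""
        return [lex_tripeptide(int(k)) for k in self.permutation]

    def index_of(self, tripeptide: str) -> int:
        lex = lex_index(tripeptide)
        if self.is_lexicographic:
            return lex
        return int(np.argwhere(self.permutation == lex)[0, 0])

    def tripeptide_at(self, i: int) -> str:
        return lex_tripeptide(int(self.permutation[i]))

    def from_lexicographic(self, values: np.ndarray) -> np.ndarray:
        """Reorder a vector computed in lexicographic order into this index's
        attribute order (rows of a matrix are preserved)."""
        return np.asarray(values)[..., self.permutation]


DEFAULT_INDEX = TriPeptideIndex()


def lex_index(tripeptide: str) -> int:
    """Lexicographic attribute index of a tri-peptide."""
    if len(tripeptide) != 3:
        raise ValueError(f"expected a tri-peptide, got {tripeptide!r}")
    a, b, c = (AA_TO_INT[r] for r in tripeptide)
    return 400 * a + 20 * b + c


def lex_tripeptide(i: int) -> str:
    """Tri-peptide at lexicographic index *i*."""
    if not 0 <= i < N_TRIPEPTIDES:
        raise ValueError(f"index {i} outside [0, {N_TRIPEPTIDES})")
    return AMINO_ACIDS[i // 400] + AMINO_ACIDS[(i // 20) % 20] + AMINO_ACIDS[i % 20]
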