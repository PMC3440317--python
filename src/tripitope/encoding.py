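"""Tri-peptide attribute encoding.

A peptide of length ``L`` is represented by one real score per tri-peptide
attribute.  For attribute ``i`` with representative tri-peptide ``phi_i`` the
similarity component is

    T_i = sum over windows j of [ s(phi_i[0], w_j[0]) + s(phi_i[1], w_j[1])
                                  + s(phi_i[2], w_j[2]) ]

where ``w_j`` are the tri-peptides obtained by sliding a window over the
peptide (projected onto three compared positions for the gapped patterns) and
``s`` is a substitution-matrix score.  A 20-residue peptide therefore sums
over its 18 contiguous windows for every attribute.

The propensity component ``P_i`` is the smoothed ratio of attribute ``i``'s
frequency among known epitopes to its frequency in a background protein pool.
The full encoding modulates similarity by propensity elementwise:

    combined:        K_i = T_i * P_i
    similarity_only: K_i = T_i
    propensity_only: K_i = (occurrences of tri-peptide i in the peptide) * P_i

Because each position of the similarity sum depends only on the residue
occupying it, ``T`` factorises over positions: the implementation reduces the
naive 8000 x windows double loop to three 20-vector matrix products and a
broadcast sum.  A brute-force double loop is kept in the test suite as the
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .matrices import (
    AMINO_ACIDS,
    DEFAULT_INDEX,
    N_TRIPEPTIDES,
    SubsequencePattern,
    SubstitutionMatrix,
    TriPeptideIndex,
    CONTIGUOUS,
    get_pattern,
    lex_index,
    seq_to_ints,
    validate_sequence,
)

Mode = Literal["combined", "similarity_only", "propensity_only"]

MODES = ("combined", "similarity_only", "propensity_only")


def extract_subsequences(
    peptide: str, pattern: SubsequencePattern = CONTIGUOUS
) -> list[str]:
    """Ordered projected tri-peptides of every window of *peptide*.

    Returns ``len(peptide) - pattern.window_width + 1`` tri-peptides; for the
    gapped patterns the ignored position is dropped from each 4-residue
    window.
    """
    validate_sequence(peptide, context="peptide")
    w = pattern.window_width
    if len(peptide) < w:
        raise ValueError(
            f"peptide of length {len(peptide)} is shorter than the "
            f"{pattern.name} window width {w}"
        )
    return [pattern.project(peptide[j : j + w]) for j in range(len(peptide) - w + 1)]


def _position_counts(peptide: str, pattern: SubsequencePattern) -> np.ndarray:
    """(3, 20) counts of which residue occupies each compared position,
    accumulated over all windows."""
    ints = seq_to_ints(peptide)
    w = pattern.window_width
    n_win = len(peptide) - w + 1
    if n_win < 1:
        raise ValueError(
            f"peptide of length {len(peptide)} is shorter than the "
            f"{pattern.name} window width {w}"
        )
    counts = np.zeros((3, 20), dtype=np.int64)
    for k, p in enumerate(pattern.positions):
        np.add.at(counts[k], ints[p : p + n_win], 1)
    return counts


def similarity_vector(
    peptide: str,
    matrix: SubstitutionMatrix,
    pattern: SubsequencePattern = CONTIGUOUS,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> np.ndarray:
    """Similarity component ``T`` of the encoding: one score per attribute."""
    return similarity_matrix([peptide], matrix, pattern, index)[0]


def similarity_matrix(
    peptides: Sequence[str],
    matrix: SubstitutionMatrix,
    pattern: SubsequencePattern = CONTIGUOUS,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> np.ndarray:
    """Stack of similarity vectors, shape ``(n_peptides, 8000)``."""
    n = len(peptides)
    counts = np.empty((n, 3, 20), dtype=np.float64)
    for r, pep in enumerate(peptides):
        counts[r] = _position_counts(pep, pattern)
    m = matrix.scores.astype(np.float64)
    v = np.einsum("npa,ab->npb", counts, m)  # (n, 3, 20)
    t = (
        v[:, 0, :, None, None] + v[:, 1, None, :, None] + v[:, 2, None, None, :]
    ).reshape(n, N_TRIPEPTIDES)
    return index.from_lexicographic(t)


def tripeptide_count_vector(
    peptide: str,
    pattern: SubsequencePattern = CONTIGUOUS,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> np.ndarray:
    """Occurrence count of each of the 8000 tri-peptides among the peptide's
    projected windows."""
    out = np.zeros(N_TRIPEPTIDES, dtype=np.float64)
    lex = np.zeros(N_TRIPEPTIDES, dtype=np.float64)
    for w in extract_subsequences(peptide, pattern):
        lex[lex_index(w)] += 1
    out = index.from_lexicographic(lex)
    return out


@dataclass
class PropensityTable:
    """Per-tri-peptide epitope propensity.

    ``f`` is the frequency of each tri-peptide among positive (epitope)
    peptides, ``F`` its frequency in a background protein pool; both are
    normalised to sum to one.  The propensity is the pseudocount-smoothed
    ratio ``P = (f + eps) / (F + eps)``; smoothing keeps the ratio finite for
    tri-peptides absent from the background.
    """

    f: np.ndarray
    F: np.ndarray
    P: np.ndarray
    smoothing: float
    pattern: str = "AAA"
    index: TriPeptideIndex = field(default_factory=lambda: DEFAULT_INDEX, repr=False)

    def __post_init__(self) -> None:
        for name in ("f", "F", "P"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (N_TRIPEPTIDES,):
                raise ValueError(f"{name} must have shape ({N_TRIPEPTIDES},)")
            setattr(self, name, v)
        if np.any(self.P <= 0):
            raise ValueError("propensity values must be strictly positive")

    @classmethod
    def uniform(cls, index: TriPeptideIndex = DEFAULT_INDEX) -> "PropensityTable":
        """Unit propensity: combined encoding collapses to similarity-only."""
        u = np.full(N_TRIPEPTIDES, 1.0 / N_TRIPEPTIDES)
        return cls(f=u.copy(), F=u.copy(), P=np.ones(N_TRIPEPTIDES), smoothing=0.0,
                   index=index)

    def to_tsv(self, path: str | Path) -> None:
        """Serialise as tab-delimited text, round-trippable bit-exactly
        (floats written with 17 significant digits)."""
        trip = self.index.tripeptides()
        with open(path, "w") as fh:
            fh.write(f"# pattern={self.pattern}\tsmoothing={self.smoothing!r}\n")
            fh.write("tripeptide\tf\tF\tP\n")
            for i in range(N_TRIPEPTIDES):
                fh.write(
                    f"{trip[i]}\t{self.f[i]:.17g}\t{self.F[i]:.17g}\t{self.P[i]:.17g}\n"
                )

    @classmethod
    def from_tsv(
        cls, path: str | Path, index: TriPeptideIndex = DEFAULT_INDEX
    ) -> "PropensityTable":
        f = np.zeros(N_TRIPEPTIDES)
        F = np.zeros(N_TRIPEPTIDES)
        P = np.zeros(N_TRIPEPTIDES)
        pattern, smoothing = "AAA", 0.0
        with open(path) as fh:
            header = fh.readline().strip()
            if header.startswith("#"):
                meta = dict(
                    kv.split("=", 1) for kv in header.lstrip("# ").split("\t")
                )
                pattern = meta.get("pattern", "AAA")
                smoothing = float(meta.get("smoothing", "0"))
                fh.readline()  # column header
            for line in fh:
                trip, fv, Fv, Pv = line.rstrip("\n").split("\t")
                i = index.index_of(trip)
                f[i], F[i], P[i] = float(fv), float(Fv), float(Pv)
        return cls(f=f, F=F, P=P, smoothing=smoothing, pattern=pattern, index=index)


def _window_frequencies(
    peptides: Iterable[str],
    pattern: SubsequencePattern,
    index: TriPeptideIndex,
    what: str,
) -> tuple[np.ndarray, int]:
    counts = np.zeros(N_TRIPEPTIDES, dtype=np.float64)
    total = 0
    for pep in peptides:
        for w in extract_subsequences(pep, pattern):
            counts[lex_index(w)] += 1
            total += 1
    if total == 0:
        raise ValueError(f"no tri-peptide windows in the {what} collection")
    return index.from_lexicographic(counts / total), total


def compute_propensity(
    positives: Sequence[str],
    background: Sequence[str],
    pattern: SubsequencePattern | str = CONTIGUOUS,
    smoothing: float | None = None,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> PropensityTable:
    """Estimate the propensity table from epitope peptides and a background
    protein pool.

    Parameters
    ----------
    positives, background:
        Non-empty collections of residue strings.  The background should be
        large (it plays the role of a genome-scale protein sample).
    smoothing:
        Pseudocount added to both frequencies before taking the ratio.
        Defaults to ``1 / (total windows counted across both collections)``.
    """
    if not len(positives):
        raise ValueError("positive peptide collection is empty")
    if not len(background):
        raise ValueError("background peptide collection is empty")
    pattern = get_pattern(pattern)
    f, n_pos = _window_frequencies(positives, pattern, index, "positive")
    F, n_bg = _window_frequencies(background, pattern, index, "background")
    if smoothing is None:
        smoothing = 1.0 / (n_pos + n_bg)
    if smoothing < 0:
        raise ValueError("smoothing pseudocount must be non-negative")
    denom = F + smoothing
    if np.any(denom <= 0):
        raise ValueError(
            "background frequencies are not strictly positive after smoothing; "
            "increase the pseudocount or enlarge the background pool"
        )
    P = (f + smoothing) / denom
    return PropensityTable(
        f=f, F=F, P=P, smoothing=float(smoothing), pattern=pattern.name, index=index
    )


@dataclass
class EncodingConfig:
    """Full configuration needed to encode a peptide reproducibly."""

    matrix: SubstitutionMatrix
    pattern: SubsequencePattern = CONTIGUOUS
    mode: Mode = "combined"
    propensity: PropensityTable | None = None
    index: TriPeptideIndex = field(default_factory=lambda: DEFAULT_INDEX, repr=False)

    def __post_init__(self) -> None:
        self.pattern = get_pattern(self.pattern)
        if self.mode not in MODES:
            raise ValueError(f"unknown encoding mode {self.mode!r}; one of {MODES}")
        if self.mode != "similarity_only" and self.propensity is None:
            raise ValueError(f"mode {self.mode!r} requires a propensity table")

    def with_propensity(self, propensity: PropensityTable) -> "EncodingConfig":
        return EncodingConfig(
            matrix=self.matrix,
            pattern=self.pattern,
            mode=self.mode,
            propensity=propensity,
            index=self.index,
        )


def encode(peptide: str, config: EncodingConfig) -> np.ndarray:
    """Feature vector (length 8000) of one peptide under *config*."""
    return encode_many([peptide], config)[0]


def encode_many(peptides: Sequence[str], config: EncodingConfig) -> np.ndarray:
    """Feature matrix ``(n_peptides, 8000)`` under *config*."""
    if config.mode == "propensity_only":
        assert config.propensity is not None
        counts = np.stack(
            [
                tripeptide_count_vector(p, config.pattern, config.index)
                for p in peptides
            ]
        )
        return counts * config.propensity.P[None, :]
    t = similarity_matrix(peptides, config.matrix, config.pattern, config.index)
    if config.mode == "similarity_only":
        return t
    assert config.propensity is not None
    return t * config.propensity.P[None, :]
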