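"""Building fixed-length, non-redundant, labeled peptide datasets.

Starting from antigen sequences (FASTA) and epitope annotations (TSV), this
module normalises epitopes to a fixed length by symmetric trimming/extension,
removes redundant peptides by single-linkage identity clustering, samples an
equal number of negative windows from non-epitopic antigen regions, and
assigns similarity-aware cross-validation folds so that no two peptides in
different folds exceed a configured identity ceiling.

Coordinates are 0-based half-open internally and 1-based inclusive in all
files meant to be read by people (annotation TSV, dataset manifest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .matrices import AA_TO_INT, is_standard

logger = logging.getLogger(__name__)

#: Peptide lengths supported by the predictor.
SUPPORTED_LENGTHS = (10, 12, 14, 16, 18, 20)

#: Pairwise-identity ceiling used to deduplicate the dataset.
DATASET_IDENTITY_CEILING = 0.30
#: Pairwise-identity ceiling allowed between peptides of different CV folds.
CROSS_FOLD_IDENTITY_CEILING = 0.20


@dataclass(frozen=True)
class EpitopeRecord:
    """A validated epitope annotation on its source antigen."""

    epitope_id: str
    antigen_id: str
    antigen_seq: str
    epitope_seq: str
    start: int  # 0-based
    end: int  # half-open

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= len(self.antigen_seq)):
            raise ValueError(
                f"{self.epitope_id}: span [{self.start}, {self.end}) outside "
                f"antigen {self.antigen_id} of length {len(self.antigen_seq)}"
            )
        if self.antigen_seq[self.start : self.end] != self.epitope_seq:
            raise ValueError(
                f"{self.epitope_id}: epitope sequence does not match antigen "
                f"{self.antigen_id} at [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Peptide:
    """A fixed-length labeled peptide with provenance."""

    seq: str
    antigen_id: str
    start: int  # 0-based
    end: int  # half-open
    label: int  # 1 epitope, 0 non-epitope


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``id -> sequence`` mapping (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_epitope_table(
    table_path: str | Path, antigens: dict[str, str] | str | Path
) -> list[EpitopeRecord]:
    """Read and validate an epitope annotation TSV against its antigens.

    Expected columns: ``epitope_id  antigen_id  epitope_seq  start  end
    is_tcell_related`` with 1-based inclusive coordinates; ``start``/``end``
    may be empty, in which case the epitope is located by exact substring
    search (rejected if the match is absent or ambiguous).  Records flagged
    as T-cell related, records whose antigen is missing, whose span does not
    match, or which contain non-standard residues are rejected and logged.
    Identical epitope sequences are collapsed to the first occurrence.
    """
    if not isinstance(antigens, dict):
        antigens = read_fasta(antigens)
    records: list[EpitopeRecord] = []
    seen: set[str] = set()
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        required = {"epitope_id", "antigen_id", "epitope_seq"}
        if not required <= set(col):
            raise ValueError(
                f"epitope table missing required columns {sorted(required - set(col))}"
            )
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            eid = fields[col["epitope_id"]]
            aid = fields[col["antigen_id"]]
            seq = fields[col["epitope_seq"]].upper()

            def _reject(reason: str) -> None:
                logger.warning("rejecting %s (line %d): %s", eid, lineno, reason)

            if "is_tcell_related" in col:
                flag = fields[col["is_tcell_related"]].strip().lower()
                if flag in ("1", "true", "yes"):
                    _reject("flagged as T-cell related")
                    continue
            if aid not in antigens:
                _reject(f"antigen {aid!r} not found in FASTA")
                continue
            antigen = antigens[aid]
            if not is_standard(seq):
                _reject("epitope contains non-standard residues")
                continue
            raw_start = fields[col["start"]].strip() if "start" in col else ""
            if raw_start:
                start = int(raw_start) - 1  # 1-based inclusive -> 0-based
                end = int(fields[col["end"]])
                if not (0 <= start < end <= len(antigen)) or antigen[start:end] != seq:
                    _reject("stated span does not match the antigen")
                    continue
            else:
                first = antigen.find(seq)
                if first < 0:
                    _reject("epitope not found in antigen")
                    continue
                if antigen.find(seq, first + 1) >= 0:
                    _reject("epitope occurs more than once in antigen")
                    continue
                start, end = first, first + len(seq)
            if seq in seen:
                continue  # identical epitopes collapse to one record
            seen.add(seq)
            records.append(
                EpitopeRecord(
                    epitope_id=eid,
                    antigen_id=aid,
                    antigen_seq=antigen,
                    epitope_seq=seq,
                    start=start,
                    end=end,
                )
            )
    return records


def normalize_length(record: EpitopeRecord, L: int) -> Peptide | None:
    """Normalise an epitope to exactly *L* residues.

    Longer epitopes are trimmed symmetrically about their centre; shorter
    ones are extended symmetrically into the antigen.  An odd leftover
    residue is resolved toward the N-terminus (one less trimmed / one more
    added on the N side).  When the antigen cannot supply the residues on one
    side the window slides toward the other; returns ``None`` if the antigen
    is shorter than *L*.
    """
    m = record.end - record.start
    n = len(record.antigen_seq)
    if n < L:
        return None
    if m >= L:
        excess = m - L
        start = record.start + excess // 2  # odd excess: trim less at N side
    else:
        deficit = L - m
        left = (deficit + 1) // 2  # odd deficit: extend more at N side
        start = record.start - left
        start = max(0, min(start, n - L))  # slide window inside the antigen
    end = start + L
    return Peptide(
        seq=record.antigen_seq[start:end],
        antigen_id=record.antigen_id,
        start=start,
        end=end,
        label=1,
    )


def _as_int_matrix(peptides: Sequence[str]) -> np.ndarray:
    L = len(peptides[0])
    out = np.empty((len(peptides), L), dtype=np.int8)
    for i, p in enumerate(peptides):
        if len(p) != L:
            raise ValueError("all peptides must have equal length")
        out[i] = [AA_TO_INT[r] for r in p]
    return out


def pairwise_identity(peptides: Sequence[str]) -> np.ndarray:
    """Fraction of identical positions for every pair of equal-length
    peptides (ungapped, position-by-position)."""
    m = _as_int_matrix(peptides)
    n, L = m.shape
    ident = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        ident[i] = (m == m[i]).mean(axis=1)
    return ident


def _single_linkage_clusters(link: np.ndarray) -> list[list[int]]:
    """Connected components of a boolean linkage matrix (union-find)."""
    n = link.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in np.nonzero(link[i, i + 1 :])[0]:
            ri, rj = find(i), find(int(j) + i + 1)
            if ri != rj:
                parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [sorted(members) for members in clusters.values()]


def reduce_redundancy(
    peptides: Sequence[str], identity_ceiling: float = DATASET_IDENTITY_CEILING
) -> list[int]:
    """Indices of a non-redundant subset: single-linkage clusters of pairs
    with identity >= *identity_ceiling*, keeping the first member (input
    order) of each cluster.

    Transitively linked peptides collapse into one cluster even if their
    direct identity is below the ceiling (single-linkage caveat).
    """
    if not peptides:
        return []
    ident = pairwise_identity(peptides)
    clusters = _single_linkage_clusters(ident >= identity_ceiling)
    return sorted(c[0] for c in clusters)


def eligible_negative_windows(
    antigen_seq: str, spans: Sequence[tuple[int, int]], L: int
) -> list[int]:
    """Start positions of length-*L* windows that do not intersect any
    epitope span and contain only standard residues."""
    out = []
    for s in range(len(antigen_seq) - L + 1):
        e = s + L
        if any(s < b and a < e for a, b in spans):
            continue
        if not is_standard(antigen_seq[s:e]):
            continue
        out.append(s)
    return out


def sample_negatives(
    antigens: dict[str, tuple[str, list[tuple[int, int]]]],
    L: int,
    n: int,
    seed: int,
) -> list[Peptide]:
    """Sample *n* distinct negative peptides uniformly from non-epitopic
    windows.

    *antigens* maps antigen id to ``(sequence, epitope spans)`` with 0-based
    half-open spans.  Windows overlapping any span, or containing
    non-standard residues, are ineligible; duplicate sequences are excluded.
    """
    pool: list[tuple[str, int, str]] = []
    for aid in sorted(antigens):
        seq, spans = antigens[aid]
        for s in eligible_negative_windows(seq, spans, L):
            pool.append((aid, s, seq[s : s + L]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    chosen: list[Peptide] = []
    used: set[str] = set()
    for k in order:
        aid, s, pep = pool[k]
        if pep in used:
            continue
        used.add(pep)
        chosen.append(Peptide(seq=pep, antigen_id=aid, start=s, end=s + L, label=0))
        if len(chosen) == n:
            return chosen
    raise ValueError(
        f"only {len(chosen)} distinct eligible negative windows available, "
        f"but {n} were requested"
    )


def assign_folds(
    peptides: Sequence[str],
    k: int = 5,
    cross_fold_identity_ceiling: float = CROSS_FOLD_IDENTITY_CEILING,
    seed: int = 0,
) -> np.ndarray:
    """Similarity-aware fold assignment.

    Peptides linked (single linkage) by pairwise identity strictly above the
    ceiling are kept together in one fold; clusters are dealt to folds by
    greedy size balancing (largest cluster first, to the currently smallest
    fold; ties broken by a seeded shuffle of equal-sized clusters).  A
    verification pass asserts that no cross-fold pair exceeds the ceiling.
    """
    if k < 2:
        raise ValueError("fold count must be at least 2")
    n = len(peptides)
    ident = pairwise_identity(peptides)
    clusters = _single_linkage_clusters(ident > cross_fold_identity_ceiling)
    if any(len(c) > n / 2 for c in clusters):
        logger.warning(
            "a similarity cluster holds more than half the peptides; "
            "folds will be imbalanced"
        )
    rng = np.random.default_rng(seed)
    clusters = sorted(clusters, key=lambda c: c[0])
    rng.shuffle(clusters)
    clusters.sort(key=len, reverse=True)  # stable: shuffled order breaks ties
    folds = np.full(n, -1, dtype=np.int64)
    sizes = np.zeros(k, dtype=np.int64)
    for c in clusters:
        target = int(np.argmin(sizes))
        folds[c] = target
        sizes[target] += len(c)
    # verification: no cross-fold pair above the ceiling
    for i in range(n):
        bad = (ident[i] > cross_fold_identity_ceiling) & (folds != folds[i])
        if bad.any():  # pragma: no cover - guarded by construction
            raise AssertionError("cross-fold identity ceiling violated")
    return folds


@dataclass
class EpitopeDataset:
    """A balanced, fold-annotated, fixed-length peptide dataset."""

    length: int
    positives: list[Peptide]
    negatives: list[Peptide]
    folds_pos: np.ndarray
    folds_neg: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positives and negatives must be equal in count")
        for p in list(self.positives) + list(self.negatives):
            if len(p.seq) != self.length:
                raise ValueError("all peptides must have the dataset length")

    @property
    def n_folds(self) -> int:
        return int(max(self.folds_pos.max(), self.folds_neg.max())) + 1

    def all_peptides(self) -> list[Peptide]:
        return list(self.positives) + list(self.negatives)

    def sequences(self) -> list[str]:
        return [p.seq for p in self.all_peptides()]

    def labels(self) -> np.ndarray:
        return np.array(
            [1] * len(self.positives) + [0] * len(self.negatives), dtype=np.int64
        )

    def folds(self) -> np.ndarray:
        return np.concatenate([self.folds_pos, self.folds_neg])

    def to_manifest(self, path: str | Path) -> None:
        """Write the dataset as a TSV manifest (1-based inclusive spans)."""
        with open(path, "w") as fh:
            fh.write("peptide\tlabel\tfold\tantigen_id\tstart\tend\n")
            for pep, fold in zip(
                self.all_peptides(), self.folds(), strict=True
            ):
                fh.write(
                    f"{pep.seq}\t{pep.label}\t{int(fold)}\t{pep.antigen_id}"
                    f"\t{pep.start + 1}\t{pep.end}\n"
                )

    @classmethod
    def from_manifest(cls, path: str | Path) -> "EpitopeDataset":
        pos, neg, fp, fn = [], [], [], []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                seq, label, fold, aid, start, end = line.rstrip("\n").split("\t")
                pep = Peptide(
                    seq=seq,
                    antigen_id=aid,
                    start=int(start) - 1,
                    end=int(end),
                    label=int(label),
                )
                if pep.label == 1:
                    pos.append(pep)
                    fp.append(int(fold))
                else:
                    neg.append(pep)
                    fn.append(int(fold))
        return cls(
            length=len(pos[0].seq) if pos else len(neg[0].seq),
            positives=pos,
            negatives=neg,
            folds_pos=np.array(fp, dtype=np.int64),
            folds_neg=np.array(fn, dtype=np.int64),
        )


def build_dataset(
    records: Sequence[EpitopeRecord],
    L: int = 20,
    seed: int = 0,
    k_folds: int = 5,
    identity_ceiling: float = DATASET_IDENTITY_CEILING,
    cross_fold_identity_ceiling: float = CROSS_FOLD_IDENTITY_CEILING,
) -> EpitopeDataset:
    """End-to-end dataset construction from validated epitope records.

    Pipeline: length normalisation -> exact deduplication -> single-linkage
    redundancy reduction at *identity_ceiling* -> equal-count negative
    sampling from non-epitopic windows -> similarity-aware fold assignment
    for positives and negatives separately.
    """
    if L not in SUPPORTED_LENGTHS:
        raise ValueError(f"length {L} unsupported; one of {SUPPORTED_LENGTHS}")
    records = sorted(records, key=lambda r: r.epitope_id)
    positives: list[Peptide] = []
    seen: set[str] = set()
    for rec in records:
        pep = normalize_length(rec, L)
        if pep is None:
            logger.info("%s: antigen too short for L=%d", rec.epitope_id, L)
            continue
        if not is_standard(pep.seq) or pep.seq in seen:
            continue
        seen.add(pep.seq)
        positives.append(pep)
    if not positives:
        raise ValueError("no usable positive peptides after length normalisation")
    keep = reduce_redundancy([p.seq for p in positives], identity_ceiling)
    positives = [positives[i] for i in keep]

    antigens: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for rec in records:
        seq, spans = antigens.setdefault(rec.antigen_id, (rec.antigen_seq, []))
        spans.append((rec.start, rec.end))
    negatives = sample_negatives(antigens, L, len(positives), seed=seed)

    folds_pos = assign_folds(
        [p.seq for p in positives],
        k=k_folds,
        cross_fold_identity_ceiling=cross_fold_identity_ceiling,
        seed=seed,
    )
    folds_neg = assign_folds(
        [p.seq for p in negatives],
        k=k_folds,
        cross_fold_identity_ceiling=cross_fold_identity_ceiling,
        seed=seed + 1,
    )
    return EpitopeDataset(
        length=L,
        positives=positives,
        negatives=negatives,
        folds_pos=folds_pos,
        folds_neg=folds_neg,
    )
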