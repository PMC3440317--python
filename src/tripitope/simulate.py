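"""Synthetic antigen/epitope corpora with planted tri-peptide enrichment.

The generator emulates the inputs the pipeline consumes in the wild: antigen
proteins carrying annotated linear epitopes, plus background protein pools.
Antigens and background proteins are drawn residue-wise from a fixed
amino-acid composition (by default the average composition of known
proteins).  Planted epitopes are drawn from a tri-peptide-tilted
distribution: while a planted segment grows, each candidate residue is
accepted with probability ``multiplier(last window) / max multiplier``
(window-level rejection sampling), so a tri-peptide with multiplier ``m``
appears about ``m`` times more often than under the background composition
and the segment remains sequence-like rather than a motif concatenation.

Everything is driven by one seeded generator per call: the same spec and
seed produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from . import datasets
from .datasets import EpitopeDataset, EpitopeRecord, Peptide, write_fasta
from .matrices import AMINO_ACIDS, N_TRIPEPTIDES, lex_index

#: Average amino-acid composition of known proteins (fractions, ACDE... order).
STANDARD_AA_FREQS = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0664,
        0.0535, 0.0686, 0.0110, 0.0292,
    ]
)
STANDARD_AA_FREQS = STANDARD_AA_FREQS / STANDARD_AA_FREQS.sum()

def qp_tripeptides() -> list[str]:
    """All tri-peptides containing at least one glutamine or proline.

    Known linear-epitope propensity scales are dominated by tri-peptides
    built around Q and P, so this family is the generator's default planted
    signal: it covers enough of the tri-peptide space (mass ~0.24 under the
    standard composition) that a planted epitope carries several enriched
    windows, rather than one vanishingly rare motif that no classifier could
    recover.
    """
    from itertools import product as iproduct

    return [
        "".join(t)
        for t in iproduct(AMINO_ACIDS, repeat=3)
        if any(r in "QP" for r in t)
    ]


def default_enriched(multiplier: float = 10.0) -> dict[str, float]:
    """Default planted-motif map: the glutamine/proline tri-peptide family,
    each motif enriched by *multiplier* relative to the background
    composition."""
    return {t: multiplier for t in qp_tripeptides()}


#: Planted epitope motifs and their default enrichment multiplier.
DEFAULT_ENRICHED = default_enriched()


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic corpus."""

    n_antigens: int = 300
    antigen_length: tuple[int, int] = (150, 400)
    n_epitopes_per_antigen: int = 2
    epitope_length: tuple[int, int] = (12, 30)
    enriched_tripeptides: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHED)
    )
    background_composition: np.ndarray = field(
        default_factory=lambda: STANDARD_AA_FREQS.copy()
    )
    n_background: int = 200
    background_length: tuple[int, int] = (150, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, dtype=np.float64)
        if comp.shape != (20,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("background composition must be 20 frequencies summing to 1")
        object.__setattr__(self, "background_composition", comp)
        if any(m <= 0 for m in self.enriched_tripeptides.values()):
            raise ValueError("enrichment multipliers must be positive")
        if self.epitope_length[0] > self.antigen_length[0]:
            raise ValueError("epitopes cannot be longer than the shortest antigen")

    def multiplier_vector(self) -> np.ndarray:
        mult = np.ones(N_TRIPEPTIDES)
        for trip, m in self.enriched_tripeptides.items():
            mult[lex_index(trip)] = m
        return mult


class _ResidueSampler:
    """Buffered residue proposals from a fixed composition."""

    def __init__(self, comp: np.ndarray, rng: np.random.Generator) -> None:
        self.cum = np.cumsum(comp)
        self.cum[-1] = 1.0
        self.rng = rng
        self._buf = np.empty(0, dtype=np.int64)
        self._pos = 0

    def draw(self, n: int) -> np.ndarray:
        return np.searchsorted(self.cum, self.rng.random(n), side="right")

    def next(self) -> int:
        if self._pos >= len(self._buf):
            self._buf = self.draw(4096)
            self._pos = 0
        v = int(self._buf[self._pos])
        self._pos += 1
        return v


def _plain_sequence(length: int, sampler: _ResidueSampler) -> str:
    ints = sampler.draw(length)
    return "".join(AMINO_ACIDS[i] for i in ints)


def _tilted_sequence(
    length: int,
    sampler: _ResidueSampler,
    mult: np.ndarray,
    max_mult: float,
    rng: np.random.Generator,
) -> str:
    """Window-rejection sampling: residue c extending the window (a, b) is
    accepted with probability mult(abc)/max_mult, i.e. the realised next-
    residue law is proportional to composition(c) * mult(abc)."""
    if max_mult == 1.0:
        return _plain_sequence(length, sampler)
    out: list[int] = []
    while len(out) < length:
        c = sampler.next()
        if len(out) >= 2:
            m = mult[400 * out[-2] + 20 * out[-1] + c]
            if rng.random() > m / max_mult:
                continue
        out.append(c)
    return "".join(AMINO_ACIDS[i] for i in out)


@dataclass
class SyntheticCorpus:
    spec: GeneratorSpec
    antigens: dict[str, str]
    records: list[EpitopeRecord]
    background: dict[str, str]

    def write(
        self,
        antigen_fasta: str | Path,
        epitope_tsv: str | Path,
        background_fasta: str | Path,
    ) -> None:
        """Write the corpus in the formats the dataset builder consumes
        (epitope spans 1-based inclusive in the TSV)."""
        write_fasta(antigen_fasta, sorted(self.antigens.items()))
        write_fasta(background_fasta, sorted(self.background.items()))
        with open(epitope_tsv, "w") as fh:
            fh.write(f"# synthetic corpus\tseed={self.spec.seed}\n")
            fh.write(
                "epitope_id\tantigen_id\tepitope_seq\tstart\tend\tis_tcell_related\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.epitope_id}\t{r.antigen_id}\t{r.epitope_seq}"
                    f"\t{r.start + 1}\t{r.end}\t0\n"
                )


def read_epitope_tsv_records(
    epitope_tsv: str | Path, antigen_fasta: str | Path
) -> list[EpitopeRecord]:
    """Read back a corpus annotation file, skipping the seed comment line."""
    with open(epitope_tsv) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    tmp = Path(str(epitope_tsv) + ".clean")
    tmp.write_text("\n".join(lines) + "\n")
    try:
        return datasets.read_epitope_table(tmp, antigen_fasta)
    finally:
        tmp.unlink(missing_ok=True)


def generate_corpus(spec: GeneratorSpec) -> SyntheticCorpus:
    """Generate antigens with planted epitopes plus a background pool.

    Epitope spans are placed without overlap inside each antigen (with a
    one-residue gap so adjacent windows stay distinguishable); the exact
    spans are recorded in the annotation records.
    """
    rng = np.random.default_rng(spec.seed)
    sampler = _ResidueSampler(spec.background_composition, rng)
    mult = spec.multiplier_vector()
    max_mult = float(mult.max())
    antigens: dict[str, str] = {}
    records: list[EpitopeRecord] = []
    eid = 0
    for a in range(spec.n_antigens):
        aid = f"ANT{a:05d}"
        alen = int(rng.integers(spec.antigen_length[0], spec.antigen_length[1] + 1))
        seq = list(_plain_sequence(alen, sampler))
        spans: list[tuple[int, int]] = []
        for _ in range(spec.n_epitopes_per_antigen):
            elen = int(
                rng.integers(spec.epitope_length[0], spec.epitope_length[1] + 1)
            )
            if elen > alen:
                raise ValueError("epitope longer than its antigen")
            placed = None
            for _attempt in range(50):
                s = int(rng.integers(0, alen - elen + 1))
                e = s + elen
                if all(e + 1 <= b or s >= b2 + 1 for b, b2 in spans):
                    placed = (s, e)
                    break
            if placed is None:
                continue  # antigen too crowded; skip this epitope
            s, e = placed
            spans.append((s, e))
            epi = _tilted_sequence(elen, sampler, mult, max_mult, rng)
            seq[s:e] = epi
        antigen_seq = "".join(seq)
        antigens[aid] = antigen_seq
        for s, e in sorted(spans):
            records.append(
                EpitopeRecord(
                    epitope_id=f"EPI{eid:06d}",
                    antigen_id=aid,
                    antigen_seq=antigen_seq,
                    epitope_seq=antigen_seq[s:e],
                    start=s,
                    end=e,
                )
            )
            eid += 1
    background = {
        f"BG{b:05d}": _plain_sequence(
            int(rng.integers(spec.background_length[0],
                             spec.background_length[1] + 1)),
            sampler,
        )
        for b in range(spec.n_background)
    }
    return SyntheticCorpus(
        spec=spec, antigens=antigens, records=records, background=background
    )


def generate_contrast_pools(
    spec_a: GeneratorSpec,
    spec_b: GeneratorSpec,
    n: int,
    L: int = 20,
) -> tuple[list[str], list[str]]:
    """Two fixed-length peptide pools for the tendency screen.

    Pool A is drawn under *spec_a* (typically enriched in the positive-class
    tri-peptides, standing in for pathogen-derived peptides); pool B under
    *spec_b* (typically neutral, standing in for host peptides).  ``n = 0``
    yields empty pools.
    """
    pools = []
    for spec in (spec_a, spec_b):
        rng = np.random.default_rng(spec.seed)
        sampler = _ResidueSampler(spec.background_composition, rng)
        mult = spec.multiplier_vector()
        max_mult = float(mult.max())
        pools.append(
            [_tilted_sequence(L, sampler, mult, max_mult, rng) for _ in range(n)]
        )
    return pools[0], pools[1]


def permute_labels(dataset: EpitopeDataset, seed: int) -> EpitopeDataset:
    """Null-model variant of a dataset: labels randomly reassigned to
    peptides (class sizes and per-peptide fold assignments preserved)."""
    from dataclasses import replace as dc_replace

    peps = dataset.all_peptides()
    folds = dataset.folds()
    n = len(peps)
    labels = np.concatenate(
        [np.ones(len(dataset.positives), dtype=int),
         np.zeros(len(dataset.negatives), dtype=int)]
    )[np.random.default_rng(seed).permutation(n)]
    pos = [dc_replace(peps[i], label=1) for i in range(n) if labels[i] == 1]
    neg = [dc_replace(peps[i], label=0) for i in range(n) if labels[i] == 0]
    return EpitopeDataset(
        length=dataset.length,
        positives=pos,
        negatives=neg,
        folds_pos=np.array([folds[i] for i in range(n) if labels[i] == 1]),
        folds_neg=np.array([folds[i] for i in range(n) if labels[i] == 0]),
    )


def antigen_grouped_folds(
    peptides: list[Peptide], k: int = 5, seed: int = 0
) -> np.ndarray:
    """Fold assignment that keeps all peptides from one source antigen in a
    single fold (greedy size balancing over a seeded antigen order).

    Grouping by provenance removes the leak channel that matters for window
    peptides — overlapping windows of the same protein — without relying on a
    pairwise identity threshold, which for 20-mers is percolated by
    chance-level matches at benchmark scale (see docs/methods.md).
    """
    by_antigen: dict[str, list[int]] = {}
    for i, p in enumerate(peptides):
        by_antigen.setdefault(p.antigen_id, []).append(i)
    rng = np.random.default_rng(seed)
    groups = [by_antigen[a] for a in sorted(by_antigen)]
    rng.shuffle(groups)
    groups.sort(key=len, reverse=True)
    folds = np.full(len(peptides), -1, dtype=np.int64)
    sizes = np.zeros(k, dtype=np.int64)
    for g in groups:
        target = int(np.argmin(sizes))
        folds[g] = target
        sizes[target] += len(g)
    return folds


def benchmark_dataset(
    n_per_class: int = 2000,
    L: int = 20,
    seed: int = 0,
    enriched_tripeptides: dict[str, float] | None = None,
    k_folds: int = 5,
) -> tuple[EpitopeDataset, list[str], GeneratorSpec]:
    """The standard synthetic benchmark: a balanced dataset of *n_per_class*
    planted-epitope peptides and negatives at length *L*, plus the background
    pool used for propensity estimation.

    The corpus is oversampled, positives are exactly deduplicated and
    truncated to *n_per_class* in deterministic id order, negatives are drawn
    from non-epitopic windows of the same antigens, and CV folds are grouped
    by source antigen (positives and negatives of one antigen share a fold).
    """
    enriched = (
        dict(DEFAULT_ENRICHED) if enriched_tripeptides is None
        else dict(enriched_tripeptides)
    )
    n_epi = 4
    spec = GeneratorSpec(
        n_antigens=ceil(1.15 * n_per_class / n_epi),
        n_epitopes_per_antigen=n_epi,
        enriched_tripeptides=enriched,
        seed=seed,
    )
    corpus = generate_corpus(spec)
    records = sorted(corpus.records, key=lambda r: r.epitope_id)
    positives: list[Peptide] = []
    seen: set[str] = set()
    for rec in records:
        pep = datasets.normalize_length(rec, L)
        if pep is None or pep.seq in seen:
            continue
        seen.add(pep.seq)
        positives.append(pep)
    if len(positives) < n_per_class:
        raise ValueError(
            f"corpus yielded only {len(positives)} distinct positives; "
            f"{n_per_class} requested"
        )
    positives = positives[:n_per_class]
    spans: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for rec in records:
        seq, sp = spans.setdefault(rec.antigen_id, (rec.antigen_seq, []))
        sp.append((rec.start, rec.end))
    negatives = datasets.sample_negatives(spans, L, n_per_class, seed=seed)
    antigen_fold: dict[str, int] = {}
    folds_pos = antigen_grouped_folds(positives, k=k_folds, seed=seed)
    for p, f in zip(positives, folds_pos, strict=True):
        antigen_fold[p.antigen_id] = int(f)
    # negatives follow their antigen's fold; antigens without positives are
    # dealt to the smallest folds deterministically
    sizes = np.bincount(folds_pos, minlength=k_folds).astype(np.int64)
    folds_neg = np.empty(len(negatives), dtype=np.int64)
    for i, p in enumerate(negatives):
        if p.antigen_id not in antigen_fold:
            antigen_fold[p.antigen_id] = int(np.argmin(sizes))
        folds_neg[i] = antigen_fold[p.antigen_id]
        sizes[folds_neg[i]] += 1
    dataset = EpitopeDataset(
        length=L,
        positives=positives,
        negatives=negatives,
        folds_pos=folds_pos,
        folds_neg=folds_neg,
    )
    background = [corpus.background[k] for k in sorted(corpus.background)]
    return dataset, background, spec
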