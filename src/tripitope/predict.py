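"""Sliding-window epitope prediction on full-length proteins.

A trained model scores every length-L window of a protein; a positive
decision score marks the window as a putative linear epitope.  Overlapping
positive windows are reported as-is, with an optional merged-interval summary
(the union of positive spans), since the raw calls are the primary output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .datasets import read_fasta
from .matrices import is_standard
from .model import TrainedModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowPrediction:
    """One scored window; coordinates 0-based half-open."""

    protein_id: str
    start: int
    end: int
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def call(self) -> bool:
        return self.score > 0


def predict_protein(
    sequence: str,
    model: TrainedModel,
    L: int | None = None,
    step: int = 1,
    protein_id: str = "protein",
) -> list[WindowPrediction]:
    """Score every window of *sequence* at the given stride.

    Window length defaults to the model's training length.  Windows containing
    non-standard residues are skipped (and logged); a sequence shorter than
    one window is an error.
    """
    L = L or model.length
    if L != model.length:
        raise ValueError(
            f"window length {L} does not match the model's training length "
            f"{model.length}"
        )
    if step < 1:
        raise ValueError("stride must be >= 1")
    if len(sequence) < L:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than the window "
            f"length {L}"
        )
    sequence = sequence.upper()
    starts, windows = [], []
    for s in range(0, len(sequence) - L + 1, step):
        w = sequence[s : s + L]
        if not is_standard(w):
            logger.info(
                "%s: skipping window %d-%d (non-standard residue)",
                protein_id, s + 1, s + L,
            )
            continue
        starts.append(s)
        windows.append(w)
    if not windows:
        return []
    scores = model.score_peptides(windows)
    return [
        WindowPrediction(protein_id=protein_id, start=s, end=s + L, score=float(v))
        for s, v in zip(starts, scores, strict=True)
    ]


def predict_fasta(
    fasta_path: str | Path, model: TrainedModel, L: int | None = None, step: int = 1
) -> list[WindowPrediction]:
    out: list[WindowPrediction] = []
    for pid, seq in read_fasta(fasta_path).items():
        out.extend(predict_protein(seq, model, L=L, step=step, protein_id=pid))
    return out


def merge_positive_spans(
    predictions: Iterable[WindowPrediction],
) -> dict[str, list[tuple[int, int]]]:
    """Union of positive-call spans per protein (0-based half-open)."""
    by_protein: dict[str, list[tuple[int, int]]] = {}
    for p in predictions:
        if p.call:
            by_protein.setdefault(p.protein_id, []).append((p.start, p.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for pid, spans in by_protein.items():
        spans.sort()
        acc = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[pid] = [(s, e) for s, e in acc]
    return merged


def write_predictions_tsv(
    predictions: Sequence[WindowPrediction], path: str | Path
) -> None:
    """TSV report with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tscore\tcall\n")
        for p in predictions:
            fh.write(
                f"{p.protein_id}\t{p.start + 1}\t{p.end}\t{p.score:.6g}"
                f"\t{'positive' if p.call else 'negative'}\n"
            )


def write_predictions_bed(
    predictions: Sequence[WindowPrediction], path: str | Path,
    positive_only: bool = True,
) -> None:
    """BED (0-based half-open) output of window calls."""
    with open(path, "w") as fh:
        for p in predictions:
            if positive_only and not p.call:
                continue
            fh.write(
                f"{p.protein_id}\t{p.start}\t{p.end}\twindow\t{p.score:.6g}\t+\n"
            )
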