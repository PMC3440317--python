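"""Independent brute-force oracles used by the test suite.

These deliberately avoid the factorised computations used by the package:
the similarity oracle loops over every (attribute, window) pair, and the AUC
oracle counts concordant score pairs exhaustively.
"""

import numpy as np

from tripitope.encoding import extract_subsequences
from tripitope.matrices import AA_TO_INT, N_TRIPEPTIDES, lex_tripeptide


def brute_force_similarity(peptide, matrix, pattern):
    """Double loop over attributes and windows; per-position score sums."""
    windows = extract_subsequences(peptide, pattern)
    w1 = np.array([AA_TO_INT[w[0]] for w in windows])
    w2 = np.array([AA_TO_INT[w[1]] for w in windows])
    w3 = np.array([AA_TO_INT[w[2]] for w in windows])
    m = matrix.scores
    out = np.empty(N_TRIPEPTIDES)
    for i in range(N_TRIPEPTIDES):
        phi = lex_tripeptide(i)
        a1, a2, a3 = (AA_TO_INT[r] for r in phi)
        out[i] = m[a1, w1].sum() + m[a2, w2].sum() + m[a3, w3].sum()
    return out


def pair_counting_auc(scores, labels):
    """AUC as the exhaustive Mann-Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
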