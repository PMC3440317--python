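"""Encode a single peptide in the tri-peptide attribute space.

Builds the 8000-dimensional feature vector of a 20-residue peptide: the
similarity component sums substitution-matrix scores between each attribute
tri-peptide and all 18 windows of the peptide; the combined encoding
multiplies each attribute by its epitope propensity.
"""

import numpy as np

import tripitope as tp
from tripitope.encoding import EncodingConfig, compute_propensity
from tripitope.matrices import lex_index

matrix = tp.load_substitution_matrix("blosum62")
peptide = "QQPWKLMNQQPGHSTRQQPV"  # 20 residues, Q/P-rich

windows = tp.extract_subsequences(peptide)
print(f"{len(windows)} contiguous tri-peptide windows: {windows[:4]} ...")

sim = tp.similarity_vector(peptide, matrix)
print(f"similarity vector: {sim.shape[0]} attributes, "
      f"T(QQP) = {sim[lex_index('QQP')]:.0f}, T(WWW) = {sim[lex_index('WWW')]:.0f}")

# a toy propensity table: Q/P-rich epitopes against a random background
rng = np.random.default_rng(0)
background = ["".join(rng.choice(list(tp.AMINO_ACIDS), 200)) for _ in range(50)]
prop = compute_propensity([peptide, "PQQPQQPQQPQQPQQPQQPQ"], background)
combined = tp.encode(
    peptide, EncodingConfig(matrix=matrix, mode="combined", propensity=prop)
)
print(f"propensity P(QQP) = {prop.P[lex_index('QQP')]:.1f}  "
      f"-> combined K(QQP) = {combined[lex_index('QQP')]:.0f}")
print("High K values mark attributes that are both similar to the peptide's "
      "windows and enriched among epitopes.")
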