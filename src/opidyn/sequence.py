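"""Global pairwise sequence identity and similarity.

Identity counts identical aligned residue pairs over all aligned columns
excluding terminal gaps; similarity additionally counts substitutions with a
positive substitution-matrix score (BLOSUM62 by default).  Both are
percentages of the same denominator.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[float, float]:
    """Return (identity %, similarity %) from one optimal global alignment.

    Columns where either sequence is gapped do not count toward the
    denominator; terminal overhangs are excluded by construction because
    gapped columns are skipped.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        bad = set(s) - _STANDARD
        if bad:
            raise ValueError(f"non-standard amino acids: {sorted(bad)}")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    matrix = aligner.substitution_matrix
    alignment = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    n_cols = n_ident = n_sim = 0
    for ca, cb in zip(a_row, b_row):
        if ca == "-" or cb == "-":
            continue
        n_cols += 1
        if ca == cb:
            n_ident += 1
            n_sim += 1
        elif matrix[ca, cb] > 0:
            n_sim += 1
    if n_cols == 0:
        return 0.0, 0.0
    return 100.0 * n_ident / n_cols, 100.0 * n_sim / n_cols
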