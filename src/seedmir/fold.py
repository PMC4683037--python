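"""RNA secondary-structure folding.

MFE folding delegates to the ViennaRNA thermodynamic nearest-neighbor model at
37 degC. A Nussinov maximum base-pairing scorer (no energies) is provided as a
parameter-free oracle for structural lower bounds.
"""

from __future__ import annotations

import RNA

from .io import SecondaryStructure, to_rna

CANONICAL_PAIRS = {
    ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G"),
}


def can_pair(x: str, y: str) -> bool:
    """Watson-Crick or G:U wobble (DNA alphabet, T==U)."""
    return (x, y) in CANONICAL_PAIRS


def fold(sequence: str) -> SecondaryStructure:
    """Minimum-free-energy structure of a single strand.

    Refuses sequences with more than 10% ambiguous bases, where the energy
    model is meaningless.
    """
    if len(sequence) < 10:
        raise ValueError("sequence too short to fold (<10 nt)")
    if sequence.count("N") > 0.1 * len(sequence):
        raise ValueError("sequence has >10% N; refusing to fold")
    db, mfe = RNA.fold(to_rna(sequence.upper()))
    if db.count("(") == 0:
        mfe = 0.0
    return SecondaryStructure(dotbracket=db, mfe=round(float(mfe), 2))


def nussinov_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum number of nested canonical pairs (Nussinov recursion).

    Energy-free combinatorial upper bound used as an independent check on
    thermodynamic folds; O(n^3).
    """
    s = sequence.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return 0
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if can_pair(s[k], s[j]):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i][j] = best
    return dp[0][n - 1]
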