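"""Protein sequence identity: LCS dynamic program and Needleman-Wunsch.

Two identity measures are computed side by side:

* LCS identity — the length of the longest (not necessarily contiguous)
  common subsequence, from the classic prefix recursion
  ``c[i,j] = 0`` at a boundary, ``c[i-1,j-1] + 1`` on a match, else
  ``max(c[i,j-1], c[i-1,j])`` — divided by the longer sequence's length.
* NW identity — identical columns over the total length (gap columns
  included) of a global Needleman-Wunsch alignment under BLOSUM62 with
  affine gap penalties (defaults 10 / 0.5, the EMBOSS needle convention).

The quadratic DP table is explicit; protein lengths make that cheap.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

try:  # numba accelerates the LCS table fill; fall back to pure numpy loops
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "lcs_length",
    "lcs_identity",
    "nw_identity",
    "read_protein_fasta",
    "write_identity_table",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@njit(cache=True)
def _lcs_table_fill(x: np.ndarray, y: np.ndarray) -> int:  # pragma: no cover
    m, n = x.shape[0], y.shape[0]
    c = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if x[i - 1] == y[j - 1]:
                c[i, j] = c[i - 1, j - 1] + 1
            else:
                c[i, j] = max(c[i, j - 1], c[i - 1, j])
    return c[m, n]


def lcs_length(x: str, y: str) -> int:
    """Length of the longest common subsequence of two sequences."""
    if not x or not y:
        return 0
    xa = np.frombuffer(x.encode("ascii"), dtype=np.uint8)
    ya = np.frombuffer(y.encode("ascii"), dtype=np.uint8)
    return int(_lcs_table_fill(xa, ya))


def lcs_identity(x: str, y: str) -> float:
    """LCS length divided by the longer sequence's length, in [0, 1]."""
    if max(len(x), len(y)) == 0:
        raise ValueError("both sequences are empty")
    return lcs_length(x, y) / max(len(x), len(y))


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def nw_identity(
    x: str, y: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Global-alignment identity under BLOSUM62 with affine gaps.

    Identity is the fraction of alignment columns (gap columns included)
    whose residues are identical. Non-standard residues score via the
    BLOSUM62 'X' row. The first co-optimal alignment in Biopython's
    deterministic enumeration order is used.
    """
    if not x or not y:
        raise ValueError("sequences must be non-empty")
    alphabet = set(str(_BLOSUM62.alphabet))
    x = "".join(c if c in alphabet else "X" for c in x.upper())
    y = "".join(c if c in alphabet else "X" for c in y.upper())
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = next(iter(aligner.align(x, y)))
    counts = alignment.counts()
    return counts.identities / alignment.length


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (gene id), uppercased.

    When several records share an id prefix ``<gene>|...``, the longest
    sequence is kept as the gene's representative.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id.split("|")[0]
        seq = str(rec.seq).upper()
        if gene_id not in seqs or len(seq) > len(seqs[gene_id]):
            seqs[gene_id] = seq
    return seqs


def write_identity_table(
    rows: list[tuple[str, str, float, float]], path: str | Path
) -> None:
    """TSV 'gene_a gene_b lcs_identity nw_identity'."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlcs_identity\tnw_identity\n")
        for a, b, lcs, nw in rows:
            fh.write(f"{a}\t{b}\t{lcs:.6g}\t{nw:.6g}\n")
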