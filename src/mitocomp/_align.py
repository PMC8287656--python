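"""Protein-guided codon alignment shared by the distance and selection code."""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

_STOPS_T4 = {"TAA", "TAG"}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def align_proteins(a: str, b: str) -> tuple[str, str]:
    """Global affine-gap protein alignment; returns the two gapped strings.

    The first optimal alignment in Biopython's deterministic enumeration
    order is used, so results are reproducible.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein sequence")
    # BLOSUM62 has no '*' column; treat any stray stop as unknown residue
    a = a.replace("*", "X")
    b = b.replace("*", "X")
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def backthread_codons(nt: str, gapped_aa: str) -> str:
    """Expand a gapped protein string to a gapped nucleotide string.

    Each residue column becomes its source codon, each gap column '---'.
    Trailing nucleotides beyond 3*len(aa) (e.g. a stop codon) are dropped.
    """
    out = []
    pos = 0
    for ch in gapped_aa:
        if ch == "-":
            out.append("---")
        else:
            out.append(nt[pos : pos + 3])
            pos += 3
    return "".join(out)


def codon_gapped_pair(nt_a: str, nt_b: str, aa_a: str, aa_b: str) -> tuple[str, str]:
    """Protein-guided nucleotide alignment of two coding sequences.

    Returns gapped nucleotide strings of equal length whose columns respect
    codon boundaries.  Terminal stop codons must already be excluded from
    the protein strings (the nt strings may still carry them; extra 3' nt
    are ignored).
    """
    ga, gb = align_proteins(aa_a, aa_b)
    return backthread_codons(nt_a, ga), backthread_codons(nt_b, gb)
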