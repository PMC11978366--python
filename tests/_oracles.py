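"""Independent brute-force oracles used to validate the fast paths.

These deliberately re-derive results from first principles (plain
translation tables, full dynamic programming) and share no code with the
implementation they check.
"""

from __future__ import annotations

NEG = float("-inf")

_CODONS = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            _CODONS[_a + _b + _c] = _AMINO[16 * _i + 4 * _j + _k]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def oracle_translate(dna: str, offset: int = 0) -> str:
    out = []
    for i in range(offset, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append(_CODONS.get(codon, "X"))
    return "".join(out)


def oracle_revcomp(dna: str) -> str:
    return "".join(_COMP[b] for b in reversed(dna))


def oracle_six_frame(seq: str, min_len: int) -> set[tuple[str, int, int, str]]:
    """All maximal stop-free stretches as (strand, gstart, gend, protein)."""
    n = len(seq)
    out = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else oracle_revcomp(seq)
        for frame in range(3):
            prot = oracle_translate(s, frame)
            pos = 0
            for stretch in prot.split("*"):
                if len(stretch) >= min_len:
                    a = frame + 3 * pos
                    b = a + 3 * len(stretch)
                    if strand == "+":
                        out.add((strand, a, b, stretch))
                    else:
                        out.add((strand, n - b, n - a, stretch))
                pos += len(stretch) + 1
    return out


def oracle_peptide_placements(seq: str, peptide: str) -> set[tuple[str, int, int]]:
    """Every genomic placement of a peptide in any of the six frames."""
    n = len(seq)
    out = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else oracle_revcomp(seq)
        for frame in range(3):
            prot = oracle_translate(s, frame)
            p = prot.find(peptide)
            while p >= 0:
                a = frame + 3 * p
                b = a + 3 * len(peptide)
                # the stretch must be stop-free through the peptide (always
                # true: the peptide itself has no '*')
                if strand == "+":
                    out.add((strand, a, b))
                else:
                    out.add((strand, n - b, n - a))
                p = prot.find(peptide, p + 1)
    return out


def oracle_glocal_score(
    target: str,
    query: str,
    match: int = 2,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> float:
    """Affine-gap DP: query global, target local (free target overhangs).

    ``gap_open`` is the score of a gap of length 1; each additional gap
    position adds ``gap_extend``.
    """
    m, n = len(target), len(query)
    # M: t[i-1] aligned to q[j-1]; X: gap in query (target unaligned);
    # Y: gap in target (query unaligned)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0  # leading target overhang is free
        M[i][0] = 0.0  # equivalently: start the alignment after t[:i]
    for j in range(1, n + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        ti = target[i - 1]
        for j in range(1, n + 1):
            s = match if ti == query[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s if best_prev > NEG else NEG
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
    best = Y[0][n]
    for i in range(m + 1):
        best = max(best, M[i][n], Y[i][n])
    return best


def oracle_digest(protein: str) -> list[str]:
    """Fully cleaved tryptic products (cut after K/R unless P follows)."""
    peps = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P"):
            peps.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        peps.append(protein[start:])
    return peps
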