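"""Standard genetic code utilities for 4-fold degenerate (4D) site logic.

A third codon position is 4-fold degenerate when all four bases at that
position encode the same amino acid, i.e. degeneracy is a property of the
first two codon bases alone.  The set of such dinucleotide prefixes is
enumerated from the standard code at import time rather than hard-coded.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def _enumerate_fourfold_prefixes() -> frozenset[str]:
    prefixes = set()
    for b1 in BASES:
        for b2 in BASES:
            aas = {CODON_TO_AA[b1 + b2 + b3] for b3 in BASES}
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


#: Dinucleotide prefixes of the eight 4-fold degenerate codon families.
FOURFOLD_PREFIXES: frozenset[str] = _enumerate_fourfold_prefixes()

#: The 32 codons whose third position is a 4D site.
FOURFOLD_CODONS: frozenset[str] = frozenset(
    p + b for p in FOURFOLD_PREFIXES for b in BASES
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_fourfold(codon: str) -> bool:
    """True if the codon's third position is 4-fold degenerate.

    Codons containing characters outside ACGT (e.g. N) are never 4D.
    """
    return codon[:2] in FOURFOLD_PREFIXES and codon[2] in BASES


def transcript_codons(chrom_seq: str, cds_intervals, strand: str,
                      phase: int = 0):
    """Enumerate codons of one transcript with their genome coordinates.

    ``cds_intervals`` are 0-based half-open (start, end) pairs on the given
    chromosome.  For minus-strand transcripts the concatenated CDS is
    reverse-complemented, so codons read in translation order while the
    returned coordinate triples remain genome positions.  ``phase`` is the
    number of bases to skip before the first complete codon (the GFF3 phase
    of the first CDS segment in transcript orientation).  A trailing partial
    codon is dropped.

    Returns (codons, positions): a list of 3-mers and an int array of shape
    (n_codons, 3) of genome positions per codon position.
    """
    import numpy as np

    ivs = sorted((int(s), int(e)) for s, e in cds_intervals)
    seq = "".join(chrom_seq[s:e] for s, e in ivs)
    pos = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in ivs]) \
        if ivs else np.empty(0, dtype=np.int64)
    if strand == "-":
        seq = reverse_complement(seq)
        pos = pos[::-1]
    if phase:
        seq = seq[phase:]
        pos = pos[phase:]
    n_codons = len(seq) // 3
    seq = seq[: n_codons * 3]
    pos = pos[: n_codons * 3].reshape(n_codons, 3)
    codons = [seq[i:i + 3] for i in range(0, n_codons * 3, 3)]
    return codons, pos
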