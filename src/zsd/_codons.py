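"""Standard genetic code helpers shared by the simulator and diversity code.

The genetic code itself comes from Biopython's standard table; what this
module adds are the codon-level quantities needed for Nei-Gojobori style
counting: per-codon synonymous/nonsynonymous site fractions and
pathway-averaged difference counts for codon pairs.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))  # 61 codons

assert len(SENSE_CODONS) == 61


def translate(nt_seq: str) -> str:
    """Translate an ungapped nucleotide sequence; stop codons become '*'."""
    if len(nt_seq) % 3:
        raise ValueError(f"sequence length {len(nt_seq)} is not a codon multiple")
    out = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3].upper()
        out.append(CODON_TO_AA.get(codon, "*" if codon in STOP_CODONS else "X"))
    return "".join(out)


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a sense codon (0..3).

    Each position contributes the fraction of its three possible
    single-nucleotide changes that are synonymous; changes creating a stop
    codon count as nonsynonymous, so syn + nonsyn sites always total 3.
    """
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_TO_AA.get(mutant) == aa:
                syn += 1.0
    return syn / 3.0


@lru_cache(maxsize=None)
def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at d positions are connected by d! substitution
    pathways; each single-nucleotide step is synonymous iff it preserves the
    amino acid. Counts are averaged over the minimal pathways that avoid
    stop-codon intermediates; if every pathway passes through a stop codon,
    all pathways are used (the conventional fallback).
    """
    if codon1 not in CODON_TO_AA or codon2 not in CODON_TO_AA:
        raise ValueError("pathway_differences requires sense codons")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon1
        syn = nonsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon2:
                return None
            if CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return (syn, nonsyn)

    paths = [walk(order) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # all pathways blocked by stops: fall back to every pathway
        valid = []
        for order in permutations(diff_pos):
            cur = codon1
            syn = nonsyn = 0.0
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
                if CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt) and cur not in STOP_CODONS:
                    syn += 1.0
                else:
                    nonsyn += 1.0
                cur = nxt
            valid.append((syn, nonsyn))
    n = len(valid)
    return (sum(v[0] for v in valid) / n, sum(v[1] for v in valid) / n)
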