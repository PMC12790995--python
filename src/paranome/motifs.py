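"""Coding-VNTR repeat motifs and deterministic back-translation.

The exon-8-analog VNTR alternates between two reading frames of the same
underlying repeat: a SADD-frame unit of 19 (``SADDNLKTPSERQLTPLPP``) or
23 (``SADDNIKTPAERLRGPLPPSAPP``) residues, the two lengths alternating
within a run, and a 25-residue MIISR-frame unit
(``MIISRHLPSVSSLPFHPQLHPQQMI``).  A full repeat domain runs n1 SADD
units, then n2 MIISR units, then n3 SADD units.
"""

from __future__ import annotations

SADD_UNIT_19 = "SADDNLKTPSERQLTPLPP"
SADD_UNIT_23 = "SADDNIKTPAERLRGPLPPSAPP"
MIISR_UNIT = "MIISRHLPSVSSLPFHPQLHPQQMI"

# one fixed codon per amino acid: keeps planted repeats exact tandem arrays
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def backtranslate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def _sadd_run(n: int) -> str:
    return "".join(SADD_UNIT_19 if i % 2 == 0 else SADD_UNIT_23 for i in range(n))


def vntr_protein(n1: int, n2: int, n3: int) -> str:
    """Repeat domain with n1 SADD-frame, n2 MIISR-frame, n3 SADD-frame units."""
    if min(n1, n2, n3) < 0:
        raise ValueError("unit counts must be non-negative")
    return _sadd_run(n1) + MIISR_UNIT * n2 + _sadd_run(n3)


def vntr_dna(n1: int, n2: int, n3: int) -> str:
    return backtranslate(vntr_protein(n1, n2, n3))
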