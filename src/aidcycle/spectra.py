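"""Default substitution spectra, mutation-load distributions and a VH
reference for the somatic-hypermutation simulator.

The three spectra correspond to B-cell transductants expressing AID-mCherry
either untagged or fused to the CDT1 or geminin (GEM) cell-cycle degron.
Only a few summary statistics of the real spectra are published (the fraction
of point mutations at A or T: 17.9 %, 6.8 % and 8.4 %; the G-to-T transversion
fraction: 0 %, 3.4 % and 11.1 %; and >80 % of mutations at G or C in all
three).  The full 12-cell joint spectra below are therefore SYNTHETIC
reconstructions: transition-dominated G/C-focused spectra, as is
characteristic of AID-driven hypermutation in Ramos B cells, constrained to
reproduce those published marginals exactly.  The same applies to the
mutation-load distributions, which are synthetic but ordered so that the
CDT1-tagged construct carries the heaviest load.

Each spectrum maps (ref, alt) to the percentage of all point mutations; the
12 percentages of each spectrum sum to 100.
"""

from __future__ import annotations

__all__ = ["SUBSTITUTION_SPECTRA", "LOAD_DISTRIBUTIONS", "VH_REFERENCE", "INDEL_RATES"]

SUBSTITUTION_SPECTRA = {
    # A or T marginal 17.9 %, G->T 0 %, G/C marginal 82.1 %
    "AID-mCherry": {
        ("A", "G"): 5.4, ("A", "C"): 1.8, ("A", "T"): 1.8,
        ("T", "C"): 5.3, ("T", "G"): 1.8, ("T", "A"): 1.8,
        ("C", "T"): 30.0, ("C", "G"): 6.0, ("C", "A"): 5.0,
        ("G", "A"): 32.1, ("G", "C"): 9.0, ("G", "T"): 0.0,
    },
    # A or T marginal 6.8 %, G->T 3.4 %, G/C marginal 93.2 %
    "AID-mCherry-CDT1": {
        ("A", "G"): 2.0, ("A", "C"): 0.7, ("A", "T"): 0.7,
        ("T", "C"): 2.0, ("T", "G"): 0.7, ("T", "A"): 0.7,
        ("C", "T"): 34.6, ("C", "G"): 6.0, ("C", "A"): 6.0,
        ("G", "A"): 37.2, ("G", "C"): 6.0, ("G", "T"): 3.4,
    },
    # A or T marginal 8.4 %, G->T 11.1 %, G/C marginal 91.6 %
    "AID-mCherry-GEM": {
        ("A", "G"): 2.4, ("A", "C"): 0.9, ("A", "T"): 0.9,
        ("T", "C"): 2.4, ("T", "G"): 0.9, ("T", "A"): 0.9,
        ("C", "T"): 33.8, ("C", "G"): 6.0, ("C", "A"): 6.0,
        ("G", "A"): 28.7, ("G", "C"): 6.0, ("G", "T"): 11.1,
    },
}

#: Synthetic per-sequence mutation-load distributions over {0,1,2,3,4,>=5}.
#: The CDT1-tagged construct accumulates markedly more mutations per VH
#: region than the untagged or GEM-tagged constructs.
LOAD_DISTRIBUTIONS = {
    "AID-mCherry": {0: 0.80, 1: 0.10, 2: 0.05, 3: 0.03, 4: 0.01, 5: 0.01},
    "AID-mCherry-CDT1": {0: 0.45, 1: 0.15, 2: 0.12, 3: 0.10, 4: 0.08, 5: 0.10},
    "AID-mCherry-GEM": {0: 0.82, 1: 0.09, 2: 0.04, 3: 0.03, 4: 0.01, 5: 0.01},
}

#: Deletions and insertions are rare relative to point mutations
#: (a few percent of mutated sequences carry one).
INDEL_RATES = (0.04, 0.02)

#: Synthetic 360-nt stand-in for a rearranged VH region (in frame from the
#: first codon, slightly G/C-rich as Ig V segments are).  It is NOT a real
#: immunoglobulin sequence; it only needs the right alphabet, length and
#: base composition for alignment-based mutation calling to be exercised
#: realistically.
VH_REFERENCE = (
    "ATGGAGTGGTCCTGGGTGTTCCTGGTGGCCCTGCTGAAGGGCGTGCAGTGTGAGGTGCAG"
    "CTGGTGGAGAGCGGAGGCGGACTGGTGCAGCCTGGCGGATCCCTGAGACTGAGCTGCGCC"
    "GCTAGCGGCTTCACCTTCAGCAGCTACGCCATGAGCTGGGTCCGCCAGGCTCCAGGCAAG"
    "GGACTGGAGTGGGTGTCCGCCATCAGCGGCAGCGGCGGCAGCACATACTACGCCGACAGC"
    "GTGAAGGGCCGGTTCACCATCAGCCGGGACAACAGCAAGAACACCCTGTACCTGCAGATG"
    "AACAGCCTGAGGGCCGAGGACACCGCCGTGTACTACTGTGCCAAGGACCGGTTCGGCTAA"
)
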