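"""Published sequence constants of the MIG-seq protocol.

Tail and anchor sequences of the 1st-PCR primers, the published recommended
primer set (set-1), the 2nd-PCR common/indexed primer templates, the
adapter-read-through queries used by the preprocessing screen, and the read
geometry of the sequencing layout (80 nt read 1, 94 nt read 2, 6 nt index).
"""

# 1st-PCR primer architecture: 14 nt tail + 3 nt 2nd-PCR anchor + 12 nt SSR + 2 nt anchor
FORWARD_TAIL = "CGCTCTTCCGATCT"
REVERSE_TAIL = "TGCTCTTCCGATCT"
FORWARD_PCR2_ANCHOR = "CTG"
REVERSE_PCR2_ANCHOR = "GAC"
TAILED_PRIMER_LEN = 31
ANNEALING_LEN = 14

# admissible two-base anchors at the primer 3' end
ANCHORS = ("AC", "AG", "CC", "GG", "TC", "TG")

# recommended multiplex set (set-1): (core motif, repeat count, anchor)
SET1_DEFINITIONS = (
    ("ACT", 4, "TG"),
    ("CTA", 4, "TG"),
    ("TTG", 4, "AC"),
    ("GTT", 4, "CC"),
    ("GTT", 4, "TC"),
    ("GTG", 4, "AC"),
    ("GT", 6, "TC"),
    ("TG", 6, "AC"),
)

# 2nd-PCR primers; "xxxxxx" marks the six-base sample index placeholder
COMMON_FORWARD_PCR2 = (
    "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCTCTG"
)
INDEXED_REVERSE_PCR2_TEMPLATE = (
    "CAAGCAGAAGACGGCATACGAGATxxxxxxGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTGAC"
)

# read-through adapter queries: the read-2 sequencing-primer region searched in
# read 1, and the read-1 sequencing-primer region searched in trimmed read 2
ADAPTER_QUERY_READ1 = "GTCAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ADAPTER_QUERY_READ2 = "CAGAGATCGGAAGAGCGTCGTGTAGGGAAAGA"

# read geometry after DarkCycle skipping (17 bases of read 1, 3 of read 2)
READ1_LEN = 80
READ2_RAW_LEN = 94  # 14 nt primer region (12 SSR + 2 anchor) + 80 nt genomic
READ2_TRIM = 14
INDEX_LEN = 6

# library size selection window (final library, bp)
SIZE_SELECT_MIN = 300
SIZE_SELECT_MAX = 800
# non-genomic bases added per fragment end by the 1st PCR (14 tail + 3 anchor)
TAIL_BASES_PER_END = 17
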