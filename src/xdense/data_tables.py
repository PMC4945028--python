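"""Small published sequence tables used as worked-example inputs.

``EMSA_PROBES`` holds the electrophoretic-mobility-shift-assay probe
sequences from the CLAMP GA-repeat binding experiments: a 36-nt high-affinity
probe carrying the optimal 15-bp motif, a constant-flank control, and four
60-nt probes with centered GA-repeat tracts of 4, 8, 10 and 15 units.
"""

EMSA_PROBES: dict[str, str] = {
    "high_affinity_fwd": "CGGGCCAGCTGCTGTCTCGCTCGCACCCGCACCGCT",
    "high_affinity_rev": "AGCGGTGCGGGTGCGAGCGAGACAGCAGCTGGCCCG",
    "constant_flank_fwd": "CTACTATAGCAATGGGAGCGAGAAGTATCAGTCAGT",
    "constant_flank_rev": "ACTGACTGATACTTCTCGCTCCCATTGCTATAGTAG",
    "four_repeat_fwd": "GTATTGTTTATTTATGTAATTATAATGAGAGAGATATTGTTTATTTATTAATGTATAATT",
    "four_repeat_rev": "AATTATACATTAATAAATAAACAATATCTCTCTCATTATAATTACATAAATAAACAATAC",
    "eight_repeat_fwd": "TGTTTATTTATGTAATTATAATGAGAGAGAGAGAGAGATATTGTTTATTTATTAATGTAT",
    "eight_repeat_rev": "ATACATTAATAAATAAACAATATCTCTCTCTCTCTCTCATTATAATTACATAAATAAACA",
    "ten_repeat_fwd": "TTTATTTATGTAATTATAATGAGAGAGAGAGAGAGAGAGATATTGTTTATTTATTAATGT",
    "ten_repeat_rev": "ACATTAATAAATAAACAATATCTCTCTCTCTCTCTCTCTCATTATAATTACATAAATAAA",
    "fifteen_repeat_fwd": "TTATGTAATTATAATGAGAGAGAGAGAGAGAGAGAGAGAGAGAGATATTGTTTATTTATT",
    "fifteen_repeat_rev": "AATAAATAAACAATATCTCTCTCTCTCTCTCTCTCTCTCTCTCTCATTATAATTACATAA",
}

# planted GA-repeat unit counts of the repeat-series probes
EMSA_REPEAT_UNITS: dict[str, int] = {
    "four_repeat_fwd": 4,
    "eight_repeat_fwd": 8,
    "ten_repeat_fwd": 10,
    "fifteen_repeat_fwd": 15,
}
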