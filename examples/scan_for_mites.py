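"""Discover a MITE insertion from its terminal structure.

Plants a hAT-style element (8 bp TSD, 10 bp TIR) into a random host
sequence, then recovers it with the scanner: the insertion gap must be
shorter than 500 bp and show terminal inverted repeats plus a target site
duplication.
"""

import numpy as np

from hd1panel import CandidateStatus, classify_superfamily, scan_insertions
from hd1panel.simulate import plant_mite

rng = np.random.default_rng(8)
host = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))

query, planted = plant_mite(host, site=700, tsd_len=8, tir_len=10,
                            element_length=180, seed=15)
print(f"planted: 180 bp element at position 700, TSD 8 bp, TIR 10 bp\n")

for cand in scan_insertions(host, query):
    print(f"status    : {cand.status.value}")
    print(f"position  : {cand.reference_position}")
    print(f"gap length: {cand.length} bp (element + duplicated target site)")
    print(f"TSD       : {cand.tsd_sequence}")
    print(f"TIR       : {cand.tir_length} bp")
    if cand.status is CandidateStatus.MITE:
        sf = classify_superfamily(len(cand.tsd_sequence), cand.tir_length)
        print(f"superfamily: {sf.value}   (8 bp TSD with TIR > 5 bp -> hAT)")
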