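"""In-silico degenerate-primer PCR.

Plants one concrete expansion of a degenerate primer pair into a random
genomic template, then recovers the amplicon computationally.
"""

import numpy as np

from rlkscan import DegeneratePrimer, SeqRecord, insilico_pcr, orf_screen
from rlkscan.simulate import plant_primer_sites

fwd = DegeneratePrimer("kinF", "GGNGARACNTTY", "forward")
rev = DegeneratePrimer("kinR", "TCYTGNCKRAAN", "reverse")
print(f"forward primer {fwd.iupac} covers {fwd.degeneracy} concrete sequences")

rng = np.random.default_rng(0)
template_seq = "".join(rng.choice(list("ACGT"), size=700))
template_seq = plant_primer_sites(template_seq, fwd, rev, positions=(80, 560), seed=0)
template = SeqRecord(id="genomic", residues=template_seq, alphabet="nt")

amplicons = insilico_pcr(template, fwd, rev, max_mismatches=0,
                         min_len=400, max_len=600)
for a in amplicons:
    print(f"amplicon on {a.template_id}: positions {a.start + 1}-{a.end} "
          f"(1-based), length {len(a)} nt")
    product = a.trimmed(len(fwd.iupac), len(rev.iupac))
    print(f"primer-trimmed product: {len(product)} nt")
# One amplicon at the planted coordinates means the primer pair is specific
# for this template at zero mismatches.
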