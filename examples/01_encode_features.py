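"""Encode a short DNA sequence with several composition schemes.

The ANF encoding augments each position's chemical-property triple with
the accumulated frequency of that nucleotide in the prefix; EIIP maps each
base to its electron-ion interaction pseudopotential; k-mer gives the
sliding-window word frequencies.
"""

import numpy as np

from enhancerkit import SequenceRecord, encode_anf, encode_eiip, encode_kmer

record = SequenceRecord("demo", "TCGTTCATGG")

anf = encode_anf([record]).values[0].reshape(len(record), 4)
print("ANF 4-tuples (NCP triple + accumulated frequency), one per position:")
for pos, row in enumerate(anf, start=1):
    print(f"  pos {pos:2d} {record.seq[pos - 1]}: ({row[0]:.0f}, {row[1]:.0f}, {row[2]:.0f}, {row[3]:.2f})")

eiip = encode_eiip([record])
print("\nEIIP pseudopotentials:", np.round(eiip.values[0], 4).tolist())

kmer = encode_kmer([record], k=2)
nonzero = {n: round(float(v), 3) for n, v in zip(kmer.feature_names, kmer.values[0]) if v > 0}
print("\nnon-zero 2-mer frequencies (denominator = 9 windows):", nonzero)
print("\nEach ANF tuple encodes chemistry plus positional frequency; the")
print("2-mer row sums to 1 because it is a distribution over windows.")
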