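"""RPKM and CPM from read-recruitment counts.

X = reads recruited to a MAG in a sample, l = MAG length in kb, N =
total trimmed sample reads in millions: RPKM = X / (l * N); CPM rescales
each sample's RPKM column to sum to one million so samples are directly
comparable.
"""

import pandas as pd

from eukmag import ReadCountTable, cpm, rpkm

counts = pd.DataFrame(
    {"mag_id": ["m1", "m1", "m2", "m2", "m3", "m3"],
     "sample_id": ["s1", "s2"] * 3,
     "reads": [1000, 500, 4000, 100, 0, 2400]}
)
lengths = pd.DataFrame({"mag_id": ["m1", "m2", "m3"],
                        "length_bp": [2_500_000, 4_000_000, 1_200_000]})
totals = pd.DataFrame({"sample_id": ["s1", "s2"],
                       "total_reads": [2_000_000, 1_000_000]})

table = ReadCountTable.from_long_tables(counts, lengths, totals)
r = rpkm(table)
print("RPKM = X / (l_kb * N_millions); m1/s1 = 1000/(2500*2) = 0.2:")
print(r.values.round(4).to_string())

c = cpm(r)
print("\nCPM (each sample column sums to 1e6):")
print(c.values.round(1).to_string())
print("column sums:", c.values.sum(axis=0).round(6).to_dict())
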