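"""Score a capillary-electrophoresis peak table as binary characters.

Builds a toy peak table for three samples at one amplicon locus, aligns
fragment sizes with the ±0.5 nt tolerance, and scores presence/absence.
"""

import pandas as pd

from clonotyper import bin_peaks, lattice_round, score_presence_absence

peaks = pd.DataFrame(
    [
        ("7379", "tub1", 100.2),
        ("9242", "tub1", 100.6),
        ("9501", "tub1", 103.1),
        ("9501", "tub1", 100.4),
    ],
    columns=["sample_id", "locus_id", "size_nt"],
)

bins = bin_peaks(peaks, max_gap=0.5)
print("bins:", [(b.label, b.sizes) for b in bins.bins])
# sizes within 0.5 nt of each other land in one size class; 103.1 is alone

matrix = score_presence_absence(bins, ["7379", "9242", "9501"])
for sid in matrix.sample_ids:
    print(sid, "".join(matrix.row(sid)))
# each row is 1/0 per size class: 9501 carries both fragments

alleles = lattice_round([120.1, 122.0, 124.2], period=2)
print("lattice-rounded microsatellite alleles:", alleles)
# sub-nucleotide drift removed: alleles sit exactly 1 repeat unit apart
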