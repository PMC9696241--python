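"""p-distances with pairwise deletion and a single-linkage tree.

Four short SNP haplotypes, one with a heterozygous call: the ambiguous
site is excluded only from the pairs it touches, and the dendrogram is
exported as Newick.
"""

import numpy as np

from clonotyper import (
    CharacterMatrix,
    SampleRecord,
    distance_long_table,
    pairwise_p_distance,
    single_linkage,
    to_newick,
)

rows = {"7379": "acgtacgt", "9503": "acgtacgt", "9506": "acrtacgt", "9242": "ttgtacgt"}
samples = [SampleRecord(s) for s in rows]
matrix = CharacterMatrix(
    samples, [f"c{i}" for i in range(8)], np.array([list(v) for v in rows.values()])
)

dist = pairwise_p_distance(matrix)
print(dist.to_square_frame().round(3))
# 9506's heterozygous site 3 (r) is deleted pairwise: its distance to the
# identical clones stays 0 over 7 compared sites, never counted as a change

print("compared sites 7379 vs 9506:", dist.compared[0, 2])

tree = single_linkage(dist)
print(to_newick(tree))
# leaf-to-leaf path length equals the p-distance at which the pair merged

print(distance_long_table(dist).head(4))
# long form (sample_i, sample_j, p, mismatches, compared) feeds heat maps
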