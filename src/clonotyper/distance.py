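"""Uncorrected p-distances with pairwise deletion, and single-linkage trees.

For every sample pair only the sites where *both* members carry a
homozygous call are compared (pairwise deletion); the p-distance is the
fraction of those compared sites that mismatch.  No substitution-model
correction is applied — at intraspecific divergences (p well below 0.05)
multiple hits are negligible and an uncorrected proportion is the honest
statistic.

A pair with zero comparable sites has an *undefined* distance.  It is
flagged (NaN plus an explicit pair list), never coerced to zero, and
clustering refuses to run over it.

Single-linkage agglomeration is implemented here with a deterministic
lexicographic tie-break so that merge order is reproducible; cutting the
dendrogram at height ``h`` is equivalent to taking connected components
of the graph with an edge for every pair at ``p <= h`` — the duality the
genotype-resolution layer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, RecodeError, UndefinedDistanceError
from .matrix import CharacterMatrix, ambiguity_mask


@dataclass
class DistanceResult:
    """Pairwise p-distances with per-pair bookkeeping.

    ``p[i, j] = mismatches[i, j] / compared[i, j]`` wherever
    ``compared > 0``; undefined entries are NaN.
    """

    sample_ids: list[str]
    p: np.ndarray
    mismatches: np.ndarray
    compared: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.compared[i, j] == 0:
                    out.append((self.sample_ids[i], self.sample_ids[j]))
        return out

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.p[i, j])

    def subset(self, ids: list[str]) -> "DistanceResult":
        idx = [self.sample_ids.index(i) for i in ids]
        sel = np.ix_(idx, idx)
        return DistanceResult(
            list(ids), self.p[sel], self.mismatches[sel], self.compared[sel]
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.sample_ids, columns=self.sample_ids)


def pairwise_p_distance(matrix: CharacterMatrix) -> DistanceResult:
    """Compute uncorrected p-distances under pairwise deletion.

    Raw 0/1 FLP matrices must be harmonized to the nucleotide alphabet
    first (:func:`clonotyper.matrix.harmonize`).
    """
    if matrix.n_samples < 2:
        raise EmptyInputError("need at least 2 samples for distances")
    if matrix.is_raw_binary:
        raise RecodeError("harmonize (recode 0/1 -> c/a) before computing distances")
    ok = ~ambiguity_mask(matrix)
    states = matrix.states
    n = matrix.n_samples
    p = np.zeros((n, n))
    mism = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        diff = both & (states[i] != states[i + 1 :])
        comp_i = both.sum(axis=1)
        mism_i = diff.sum(axis=1)
        comp[i, i + 1 :] = comp[i + 1 :, i] = comp_i
        mism[i, i + 1 :] = mism[i + 1 :, i] = mism_i
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i, i + 1 :] = p[i + 1 :, i] = np.where(
                comp_i > 0, mism_i / np.maximum(comp_i, 1), np.nan
            )
    comp[np.diag_indices(n)] = matrix.n_characters
    return DistanceResult(matrix.sample_ids, p, mism, comp)


@dataclass
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass
class Dendrogram:
    """Leaves plus the ordered single-linkage merge list."""

    leaves: list[str]
    merges: list[Merge]

    def cut(self, height: float) -> list[frozenset]:
        """Partition the leaves at a threshold (merges with h <= height applied)."""
        parts = [set([leaf]) for leaf in self.leaves]

        def find(leaf):
            for part in parts:
                if leaf in part:
                    return part
            raise KeyError(leaf)

        for m in self.merges:
            if m.height <= height:
                a, b = find(m.left[0]), find(m.right[0])
                if a is not b:
                    a |= b
                    parts.remove(b)
        return [frozenset(p) for p in parts]


def single_linkage(dist: DistanceResult) -> Dendrogram:
    """Agglomerative single-linkage clustering of a distance result.

    Inter-cluster distance is the minimum over cross pairs.  Ties are
    broken deterministically: the candidate merge whose (sorted) pair of
    lexicographically-smallest members is smallest wins.
    """
    undef = dist.undefined_pairs
    if undef:
        raise UndefinedDistanceError(
            f"cannot cluster: undefined distances for pairs {undef}", pairs=undef
        )
    ids = dist.sample_ids
    clusters: list[tuple[str, ...]] = [(i,) for i in sorted(ids)]
    d = {
        frozenset((a, b)): dist.get(a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    }

    def linkdist(c1, c2):
        return min(d[frozenset((a, b))] for a in c1 for b in c2)

    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = linkdist(clusters[i], clusters[j])
                key = (h, *sorted((clusters[i][0], clusters[j][0])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, *_), i, j = best
        left, right = sorted((clusters[i], clusters[j]))
        merged = tuple(sorted(left + right))
        merges.append(Merge(left=left, right=right, height=float(h)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort()
    return Dendrogram(leaves=sorted(ids), merges=merges)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def to_newick(tree: Dendrogram) -> str:
    """Serialize an ultrametric dendrogram as Newick text.

    Node height is half the merge height, so the path length between two
    leaves equals the single-linkage distance at which they merged
    (cophenetic convention).  Branch length = parent node height minus
    child node height; leaves sit at height 0.
    """
    if not tree.merges:
        (leaf,) = tree.leaves
        return f"{leaf}:0;"
    node: dict[tuple[str, ...], tuple[str, float]] = {
        (leaf,): (leaf, 0.0) for leaf in tree.leaves
    }
    for m in tree.merges:
        h = m.height / 2.0
        ltext, lh = node[m.left]
        rtext, rh = node[m.right]
        text = f"({ltext}:{_fmt(h - lh)},{rtext}:{_fmt(h - rh)})"
        node[m.members] = (text, h)
    root_text, _ = node[tree.merges[-1].members]
    return root_text + ";"


def distance_long_table(dist: DistanceResult) -> pd.DataFrame:
    """Melt the distance matrices into long form for heat-map plotting.

    One row per ordered sample pair (n^2 rows, diagonal included) with
    p-distance, absolute mismatch count and compared-site count.
    """
    rows = []
    for i, a in enumerate(dist.sample_ids):
        for j, b in enumerate(dist.sample_ids):
            rows.append(
                {
                    "sample_i": a,
                    "sample_j": b,
                    "p": 0.0 if i == j else float(dist.p[i, j]),
                    "mismatches": int(dist.mismatches[i, j]),
                    "compared": int(dist.compared[i, j]),
                }
            )
    return pd.DataFrame(rows)
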