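"""Replicate-based genotyping error and genotype resolution.

Replicate runs of the same DNA extract should be identical; any mismatch
between a clone and its replicate measures the genotyping error of the
method.  The mean and the maximum replicate-pair p-distance set the
*borders of resolution*: two clones whose p-distance does not exceed the
chosen border cannot be told apart by the method, so they are assigned to
one operational genotype.

Indistinguishability is chained: clones are nodes, pairs at
``p <= threshold`` are edges, and genotypes are the connected components
(equivalently, the clusters obtained by cutting the single-linkage
dendrogram at the threshold).  Chaining matters — under pairwise deletion
the pair relation need not be transitive, and the component construction
resolves that deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .distance import DistanceResult, pairwise_p_distance
from .errors import MetadataError, UndefinedDistanceError
from .matrix import CharacterMatrix, SampleRecord, ambiguity_profile, harmonize


def pair_replicates(samples: list[SampleRecord]) -> list[tuple[str, str]]:
    """List (original, replicate) ID pairs from sample metadata.

    One pair per replicate sample; originals without replicates are
    simply not paired.  A replicate pointing at a sample absent from the
    panel raises :class:`MetadataError`.
    """
    ids = {s.sample_id for s in samples}
    pairs = []
    for s in samples:
        if s.replicate_of:
            if s.replicate_of not in ids:
                raise MetadataError(
                    f"replicate {s.sample_id!r} points at missing sample "
                    f"{s.replicate_of!r}"
                )
            pairs.append((s.replicate_of, s.sample_id))
    return pairs


@dataclass
class ReplicateErrorEstimate:
    """Per-replicate-pair mismatch rates with mean/max summaries.

    With zero pairs the estimate is *not determined* (``determined`` is
    False and the rates are None) — never silently zero.  ``pooled_rate``
    (total mismatches / total compared sites) is also reported; it equals
    ``mean_rate`` when all pairs compare the same number of sites.
    """

    per_pair: list[tuple[str, float]]  # (clone ID, p-distance to its replicate)
    n_pairs: int
    mean_rate: float | None
    max_rate: float | None
    pooled_rate: float | None

    @property
    def determined(self) -> bool:
        return self.n_pairs > 0

    @property
    def mean_pct(self) -> float | None:
        return None if self.mean_rate is None else self.mean_rate * 100.0

    @property
    def max_pct(self) -> float | None:
        return None if self.max_rate is None else self.max_rate * 100.0


def estimate_error(
    dist: DistanceResult, pairs: list[tuple[str, str]]
) -> ReplicateErrorEstimate:
    """Estimate the genotyping error rate from replicate pairs."""
    if not pairs:
        return ReplicateErrorEstimate([], 0, None, None, None)
    per_pair = []
    mism = comp = 0
    for orig, rep in pairs:
        p = dist.get(orig, rep)
        if math.isnan(p):
            raise UndefinedDistanceError(
                f"replicate pair ({orig}, {rep}) has no comparable sites",
                pairs=[(orig, rep)],
            )
        per_pair.append((orig, p))
        i, j = dist.sample_ids.index(orig), dist.sample_ids.index(rep)
        mism += int(dist.mismatches[i, j])
        comp += int(dist.compared[i, j])
    rates = [r for _, r in per_pair]
    return ReplicateErrorEstimate(
        per_pair=per_pair,
        n_pairs=len(per_pair),
        mean_rate=float(np.mean(rates)),
        max_rate=float(np.max(rates)),
        pooled_rate=mism / comp if comp else None,
    )


@dataclass
class GenotypeResolution:
    """Partition of clones into distinguishable genotypes at a threshold."""

    threshold: float
    clusters: list[frozenset]
    indistinguishable_pairs: list[tuple[str, str]]

    @property
    def n_genotypes(self) -> int:
        return len(self.clusters)

    def genotype_of(self) -> dict[str, int]:
        """Map each clone to a genotype index (clusters sorted by members)."""
        ordered = sorted(self.clusters, key=lambda c: sorted(c))
        return {sid: g for g, c in enumerate(ordered) for sid in c}


def resolve_genotypes(
    dist: DistanceResult,
    threshold: float,
    samples: list[SampleRecord] | None = None,
) -> GenotypeResolution:
    """Group clones into genotypes at an error-rate threshold.

    An edge joins every pair at ``p <= threshold`` (inclusive, so a zero
    threshold merges identical clones); genotypes are the connected
    components.  When ``samples`` metadata is given, replicate samples
    are excluded first — replicates estimate error, they are not extra
    clones.  Thresholds are proportions (0.26% error -> 0.0026).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    ids = list(dist.sample_ids)
    if samples is not None:
        reps = {s.sample_id for s in samples if s.replicate_of}
        ids = [i for i in ids if i not in reps]
    sub = dist.subset(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            p = sub.get(a, b)
            if math.isnan(p):
                raise UndefinedDistanceError(
                    f"distance between {a!r} and {b!r} is undefined "
                    "(no mutually unambiguous sites)",
                    pairs=[(a, b)],
                )
            if p <= threshold:
                edges.append(tuple(sorted((a, b))))
    g.add_edges_from(edges)
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: sorted(c),
    )
    return GenotypeResolution(
        threshold=float(threshold),
        clusters=list(clusters),
        indistinguishable_pairs=sorted(edges),
    )


@dataclass
class MethodSummary:
    """One row of the method-comparison report."""

    name: str
    marker_type: str
    n_samples: int
    n_characters: int
    percent_ambiguous: float
    mean_ambiguous_per_sample: float
    sd_ambiguous_per_sample: float
    error: ReplicateErrorEstimate
    resolutions: dict[str, GenotypeResolution] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "method": self.name,
            "marker_type": self.marker_type,
            "n_samples": self.n_samples,
            "n_characters": self.n_characters,
            "percent_ambiguous": self.percent_ambiguous,
            "percent_ambiguous_display": round(self.percent_ambiguous),
            "mean_ambiguous_per_sample": self.mean_ambiguous_per_sample,
            "sd_ambiguous_per_sample": self.sd_ambiguous_per_sample,
            "n_replicate_pairs": self.error.n_pairs,
            "error_mean_pct": self.error.mean_pct,
            "error_max_pct": self.error.max_pct,
            "error_display": (
                "n.d." if not self.error.determined else f"{self.error.mean_pct:.2f}"
            ),
        }
        for label, res in self.resolutions.items():
            row[f"n_genotypes_{label}"] = res.n_genotypes
            row[f"pairs_{label}"] = ";".join(
                f"{a}-{b}" for a, b in res.indistinguishable_pairs
            )
        return row


def resolution_report(
    matrix: CharacterMatrix, name: str = "panel"
) -> MethodSummary:
    """Run the full per-method summary: profile, error estimate, resolution.

    Genotype counts are reported at threshold 0 and, when replicates
    exist, at the mean and maximum replicate error rates.  Without
    replicates the error is "n.d." and only the zero threshold is used.
    """
    matrix = harmonize(matrix)
    prof = ambiguity_profile(matrix)
    dist = pairwise_p_distance(matrix)
    pairs = pair_replicates(matrix.samples)
    err = estimate_error(dist, pairs)
    thresholds = {"zero": 0.0}
    if err.determined:
        thresholds["mean_error"] = err.mean_rate
        thresholds["max_error"] = err.max_rate
    resolutions = {
        label: resolve_genotypes(dist, t, samples=matrix.samples)
        for label, t in thresholds.items()
    }
    return MethodSummary(
        name=name,
        marker_type=matrix.marker_type,
        n_samples=matrix.n_samples,
        n_characters=matrix.n_characters,
        percent_ambiguous=prof.percent,
        mean_ambiguous_per_sample=prof.mean,
        sd_ambiguous_per_sample=prof.sd,
        error=err,
        resolutions=resolutions,
    )


def summaries_to_frame(summaries: list[MethodSummary]) -> pd.DataFrame:
    """Stack method summaries into one comparison table."""
    return pd.DataFrame([s.to_row() for s in summaries])


def render_summary_text(summary: MethodSummary) -> str:
    """Human-readable one-method report."""
    lines = [
        f"method: {summary.name} ({summary.marker_type})",
        f"samples: {summary.n_samples}   characters: {summary.n_characters}",
        (
            f"ambiguous: {summary.percent_ambiguous:.1f}% "
            f"({summary.mean_ambiguous_per_sample:.1f} ± "
            f"{summary.sd_ambiguous_per_sample:.1f} per sample)"
        ),
    ]
    if summary.error.determined:
        lines.append(
            f"error rate: mean {summary.error.mean_pct:.2f}% / "
            f"max {summary.error.max_pct:.2f}% "
            f"({summary.error.n_pairs} replicate pairs)"
        )
    else:
        lines.append("error rate: n.d. (0 replicate pairs)")
    for label, res in summary.resolutions.items():
        pair_txt = (
            "; ".join(f"{a}~{b}" for a, b in res.indistinguishable_pairs) or "none"
        )
        lines.append(
            f"genotypes at {label} (p <= {res.threshold:.6g}): "
            f"{res.n_genotypes}   merged pairs: {pair_txt}"
        )
    return "\n".join(lines)
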