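"""Score capillary-electrophoresis peak tables as binary character matrices.

Fragment-length polymorphism (FLP) methods read out amplicon sizes from a
capillary sequencer.  Sizes for the same allele wobble by a fraction of a
nucleotide between runs, so before scoring they are aligned across
samples with a one-nucleotide (+/- 0.5 nt) tolerance:

* generic amplicons (e.g. beta-tubulin intron fragments) are *gap-binned*
  per locus: sizes are sorted and a new bin opens whenever the gap to the
  previous size exceeds ``max_gap`` (single-linkage gap binning);
* microsatellite alleles are *lattice-rounded*: all sizes at a locus are
  snapped onto the best-fitting lattice of points spaced by the repeat
  unit length, which removes sub-nucleotide drift while preserving the
  repeat-number differences that carry the signal.

Each resulting size class becomes one presence/absence character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, SampleMismatchError
from .matrix import CharacterMatrix, SampleRecord, _build_samples

PEAK_COLUMNS = ("sample_id", "locus_id", "size_nt")


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak CSV with columns sample_id, locus_id, size_nt.

    Duplicate identical rows (same sample, locus and size, e.g. from two
    dyes or re-runs) are collapsed to one.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "locus_id": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise EmptyInputError(f"peak table {path} lacks columns {missing}")
    return clean_peak_table(df)


def clean_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, list(PEAK_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["locus_id"] = df["locus_id"].astype(str)
    df["size_nt"] = df["size_nt"].astype(float)
    if df.empty:
        raise EmptyInputError("peak table is empty")
    if (df["size_nt"] <= 0).any():
        bad = df.loc[df["size_nt"] <= 0].iloc[0]
        raise ConfigError(
            f"non-positive fragment size {bad['size_nt']} for sample "
            f"{bad['sample_id']!r}, locus {bad['locus_id']!r}"
        )
    return df.drop_duplicates().reset_index(drop=True)


@dataclass
class Bin:
    """One size class at one locus."""

    locus_id: str
    sizes: list[float]  # distinct member sizes, ascending

    @property
    def min(self) -> float:
        return self.sizes[0]

    @property
    def max(self) -> float:
        return self.sizes[-1]

    @property
    def label(self) -> str:
        """Locus plus integer-rounded midpoint, e.g. ``tub1_161``."""
        mid = int(round((self.min + self.max) / 2.0))
        return f"{self.locus_id}_{mid}"


@dataclass
class BinSet:
    """Disjoint, ascending bins plus the peak-row -> bin assignment."""

    bins: list[Bin]
    assignment: dict[tuple[str, str, float], int]  # (sample, locus, size) -> bin idx
    peaks: pd.DataFrame


def bin_peaks(peaks: pd.DataFrame, max_gap: float = 0.5) -> BinSet:
    """Align fragment sizes across samples by gap binning per locus.

    Distinct sizes at a locus are sorted ascending; a new bin opens when
    the gap to the previous size exceeds ``max_gap`` nucleotides.  The
    result is independent of input row order.  Note the chaining caveat:
    a ladder of sizes each ``<= max_gap`` apart ends up in one bin even if
    its total span exceeds ``max_gap``.
    """
    peaks = clean_peak_table(peaks)
    if max_gap <= 0:
        raise ConfigError(f"max_gap must be positive, got {max_gap}")
    bins: list[Bin] = []
    for locus in sorted(peaks["locus_id"].unique()):
        sizes = np.sort(peaks.loc[peaks["locus_id"] == locus, "size_nt"].unique())
        current = [float(sizes[0])]
        for s in sizes[1:]:
            s = float(s)
            if s - current[-1] > max_gap:
                bins.append(Bin(locus, current))
                current = [s]
            else:
                current.append(s)
        bins.append(Bin(locus, current))
    assignment = {}
    by_locus: dict[str, list[tuple[int, Bin]]] = {}
    for i, b in enumerate(bins):
        by_locus.setdefault(b.locus_id, []).append((i, b))
    for row in peaks.itertuples(index=False):
        for i, b in by_locus[row.locus_id]:
            if b.min <= row.size_nt <= b.max:
                assignment[(row.sample_id, row.locus_id, row.size_nt)] = i
                break
    return BinSet(bins=bins, assignment=assignment, peaks=peaks)


def lattice_round(sizes, period: float) -> list[int]:
    """Snap fragment sizes onto the best repeat-unit lattice.

    Finds the offset ``phi`` in ``[0, period)`` (scanned on a 0.01-nt
    grid, smallest optimum wins) minimizing the total distance from each
    size to its nearest lattice point ``phi + k * period``, then returns
    each size snapped to its nearest point, as an integer after removing
    ``phi``'s fractional part.  This mirrors how microsatellite allele
    calls are cleaned before binary scoring.
    """
    sizes = [float(s) for s in sizes]
    if not sizes:
        raise EmptyInputError("no sizes to round")
    if period < 1:
        raise ConfigError(f"repeat period must be >= 1, got {period}")
    arr = np.asarray(sizes)
    phis = np.round(np.arange(0.0, period, 0.01), 2)
    # distance of x to lattice {phi + k*period}: fold into the period circle
    resid = arr[None, :] - phis[:, None]
    frac = resid - period * np.round(resid / period)
    # round away float noise so exact ties resolve to the smallest phi
    costs = np.round(np.abs(frac).sum(axis=1), 9)
    best = int(np.argmin(costs))  # argmin takes the first = smallest phi
    phi = float(phis[best])
    k = np.round((arr - phi) / period)
    snapped = phi + k * period
    return [int(round(s - (phi - int(phi)))) for s in snapped]


def lattice_round_table(peaks: pd.DataFrame, periods: dict[str, float]) -> pd.DataFrame:
    """Apply :func:`lattice_round` per locus to a peak table.

    ``periods`` maps locus_id -> repeat unit length; loci absent from the
    map are left untouched.
    """
    peaks = clean_peak_table(peaks)
    out = []
    for locus, grp in peaks.groupby("locus_id", sort=False):
        if locus in periods:
            grp = grp.copy()
            grp["size_nt"] = [
                float(v) for v in lattice_round(grp["size_nt"].tolist(), periods[locus])
            ]
        out.append(grp)
    return pd.concat(out, ignore_index=True).drop_duplicates().reset_index(drop=True)


def score_presence_absence(
    bins: BinSet, samples: list[SampleRecord] | list[str] | None = None
) -> CharacterMatrix:
    """Score one presence/absence character per bin.

    A cell is ``1`` if the sample has at least one peak in the bin, else
    ``0``.  The output is a raw FLP matrix (harmonize with
    :func:`clonotyper.matrix.recode_binary` before distances).
    """
    peaks = bins.peaks
    peak_ids = list(dict.fromkeys(peaks["sample_id"]))
    if samples is None:
        samples = _build_samples(peak_ids)
    elif samples and isinstance(samples[0], str):
        samples = _build_samples(list(samples))
    known = {s.sample_id for s in samples}
    unknown = [sid for sid in peak_ids if sid not in known]
    if unknown:
        raise SampleMismatchError(
            f"peaks reference samples absent from metadata: {sorted(set(unknown))}"
        )
    order = sorted(range(len(bins.bins)), key=lambda i: (bins.bins[i].locus_id, bins.bins[i].min))
    grid = np.full((len(samples), len(bins.bins)), "0", dtype="<U1")
    row_of = {s.sample_id: i for i, s in enumerate(samples)}
    for key, b in bins.assignment.items():
        grid[row_of[key[0]], b] = "1"
    characters = _dedup_labels([bins.bins[i].label for i in order])
    return CharacterMatrix(
        list(samples), characters, grid[:, order], marker_type="FLP"
    )


def _dedup_labels(labels: list[str]) -> list[str]:
    # adjacent bins can round to the same integer midpoint; keep labels unique
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}.{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return out
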