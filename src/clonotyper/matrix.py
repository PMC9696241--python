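"""Character matrices for clonal genotyping panels.

The common currency of the pipeline is a rectangular samples x characters
state table (:class:`CharacterMatrix`).  Two marker families feed it:

* fragment-length polymorphisms (FLP) scored as binary presence/absence of
  an amplicon size class, read from 0/1 tables and later recoded to the
  nucleotide alphabet (0 -> ``c``, 1 -> ``a``) so that every dataset can be
  handled by the same distance machinery;
* SNP characters read from aligned FASTA, with homozygous states
  ``a/c/g/t`` and ambiguous states (IUPAC heterozygous codes, ``n``, gap
  ``-``, missing ``?``).

Ambiguity is defined as "any non-homozygous call": heterozygous IUPAC
codes, unknowns and gaps alike.  Ambiguous cells are profiled here and
excluded pairwise by the distance layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from .errors import (
    AlphabetError,
    EmptyInputError,
    MetadataError,
    RaggedAlignmentError,
    RecodeError,
    SampleMismatchError,
    TableParseError,
)

#: Homozygous nucleotide states.
UNAMBIGUOUS = frozenset("acgt")
#: IUPAC multi-base (heterozygous) codes.
IUPAC_HET = frozenset("ryswkmbdhv")
#: Unknown / gap / missing states.
MISSING = frozenset("n-?")
#: Full nucleotide-coded alphabet accepted in a harmonized matrix.
ALPHABET = UNAMBIGUOUS | IUPAC_HET | MISSING
#: Raw binary coding used by presence/absence tables before harmonization.
RAW_BINARY = frozenset("01?")

CONTINENTS = frozenset({"Africa", "America", "Asia", "Australia", "Europe"})


@dataclass(frozen=True)
class SampleRecord:
    """One panel member: a clone, or a replicate run of a clone.

    Replicates carry the base clone's ID plus the suffix ``r`` (e.g.
    ``7379r`` replicates ``7379``) and point back via ``replicate_of``.
    """

    sample_id: str
    replicate_of: str = ""
    country: str = ""
    continent: str = ""

    def __post_init__(self):
        if not self.sample_id:
            raise MetadataError("sample_id must be non-empty")

    @property
    def is_replicate(self) -> bool:
        return bool(self.replicate_of)


@dataclass
class AmbiguityProfile:
    """Per-sample ambiguous-cell counts with panel-level summaries.

    ``percent`` is the mean count expressed as a percentage of the number
    of characters, matching how method-comparison tables report it.
    """

    per_sample_counts: dict[str, int]
    mean: float
    sd: float
    percent: float


@dataclass
class CharacterMatrix:
    """Rectangular samples x characters state grid.

    ``marker_type`` is ``"FLP"``, ``"SNP"`` or ``"mixed"``.  FLP matrices
    start life in raw 0/1 coding (``is_raw_binary``) and are harmonized to
    the nucleotide alphabet with :func:`recode_binary`.
    """

    samples: list[SampleRecord]
    characters: list[str]
    states: np.ndarray  # dtype '<U1', shape (n_samples, n_characters)
    marker_type: str = "SNP"

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.shape != (len(self.samples), len(self.characters)):
            raise ValueError(
                f"state grid shape {self.states.shape} does not match "
                f"{len(self.samples)} samples x {len(self.characters)} characters"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate sample IDs: {dup}")
        if len(set(self.characters)) != len(self.characters):
            seen, dup = set(), set()
            for c in self.characters:
                (dup if c in seen else seen).add(c)
            raise TableParseError(f"duplicate character labels: {sorted(dup)}")
        allowed = ALPHABET | RAW_BINARY
        bad = set(self.states.ravel()) - allowed
        if bad:
            raise AlphabetError(f"states outside alphabet: {sorted(bad)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def is_raw_binary(self) -> bool:
        """True if any cell still uses the raw 0/1 presence coding."""
        return bool(np.isin(self.states, ["0", "1"]).any())

    def row(self, sample_id: str) -> np.ndarray:
        return self.states[self.sample_ids.index(sample_id)]

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise MetadataError(f"unknown sample {sample_id!r}")

    # -- IO --------------------------------------------------------------

    def to_fasta(self, path) -> None:
        """Write the matrix as an aligned FASTA, one record per sample."""
        with open(path, "w") as fh:
            for rec, row in zip(self.samples, self.states):
                fh.write(f">{rec.sample_id}\n{''.join(row)}\n")

    def to_csv(self, path) -> None:
        """Write the grid as CSV: header = character labels, col 1 = IDs."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", *self.characters])
            for rec, row in zip(self.samples, self.states):
                w.writerow([rec.sample_id, *row])


def infer_replicates(sample_ids: list[str]) -> dict[str, str]:
    """Map replicate IDs (``<clone>r``) to their base clone where present."""
    ids = set(sample_ids)
    return {
        sid: sid[:-1]
        for sid in sample_ids
        if sid.endswith("r") and sid[:-1] in ids
    }


def _build_samples(sample_ids, metadata=None):
    """Attach metadata records, inferring replicate links from the `r` suffix."""
    meta = {m.sample_id: m for m in metadata} if metadata else {}
    rep = infer_replicates(sample_ids)
    out = []
    for sid in sample_ids:
        if sid in meta:
            out.append(meta[sid])
        else:
            out.append(SampleRecord(sample_id=sid, replicate_of=rep.get(sid, "")))
    for s in out:
        if s.replicate_of and s.replicate_of not in sample_ids:
            raise MetadataError(
                f"replicate {s.sample_id!r} points at missing sample "
                f"{s.replicate_of!r}"
            )
    return out


def read_metadata(path) -> list[SampleRecord]:
    """Read sample metadata CSV (sample_id, replicate_of, country, continent)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    replicate_of=(row.get("replicate_of") or "").strip(),
                    country=(row.get("country") or "").strip(),
                    continent=(row.get("continent") or "").strip(),
                )
            )
    return out


def read_snp_alignment(path, metadata=None) -> CharacterMatrix:
    """Read an aligned FASTA of SNP characters into a matrix.

    States are lowercased on read; any symbol outside the nucleotide
    alphabet (incl. IUPAC codes, ``n``, ``-``, ``?``) is rejected.
    Records of unequal length raise :class:`RaggedAlignmentError` naming
    the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    length = len(records[0].seq)
    rows, ids = [], []
    for rec in records:
        seq = str(rec.seq).lower()
        if len(seq) != length:
            raise RaggedAlignmentError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        bad = set(seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {rec.id!r} contains invalid symbols: {sorted(bad)}"
            )
        ids.append(rec.id)
        rows.append(list(seq))
    samples = _build_samples(ids, metadata)
    characters = [f"c{i + 1}" for i in range(length)]
    return CharacterMatrix(samples, characters, np.array(rows), marker_type="SNP")


def read_binary_table(path, sep=None, metadata=None) -> CharacterMatrix:
    """Read a presence/absence table (CSV/TSV) into a raw FLP matrix.

    Header row holds character labels, first column sample IDs; cells must
    be ``0``, ``1`` or ``?``.  Cells are kept in raw coding pending
    :func:`recode_binary`.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise EmptyInputError(f"no data rows in {path}")
    characters = [c.strip() for c in rows[0][1:]]
    ids, grid = [], []
    for r in rows[1:]:
        sid = r[0].strip()
        cells = [c.strip() for c in r[1:]]
        if len(cells) != len(characters):
            raise TableParseError(
                f"row {sid!r} has {len(cells)} cells, expected {len(characters)}",
                sample=sid,
            )
        for cell, label in zip(cells, characters):
            if cell not in RAW_BINARY:
                raise TableParseError(
                    f"non-binary cell {cell!r} at sample {sid!r}, "
                    f"character {label!r}",
                    sample=sid,
                    character=label,
                )
        ids.append(sid)
        grid.append(cells)
    samples = _build_samples(ids, metadata)
    return CharacterMatrix(samples, characters, np.array(grid), marker_type="FLP")


def recode_binary(matrix: CharacterMatrix) -> CharacterMatrix:
    """Harmonize a raw presence/absence matrix to the nucleotide alphabet.

    ``0 -> c``, ``1 -> a``, ``? -> ?``.  A matrix that is already
    nucleotide-coded raises :class:`RecodeError` rather than silently
    recoding twice.
    """
    cells = set(matrix.states.ravel())
    if not cells <= RAW_BINARY:
        raise RecodeError(
            f"matrix is not raw binary (found states {sorted(cells - RAW_BINARY)}); "
            "recoding is not idempotent"
        )
    mapped = matrix.states.copy()
    mapped[matrix.states == "0"] = "c"
    mapped[matrix.states == "1"] = "a"
    return replace(matrix, states=mapped)


def decode_binary(matrix: CharacterMatrix) -> CharacterMatrix:
    """Invert :func:`recode_binary` (``c -> 0``, ``a -> 1``)."""
    cells = set(matrix.states.ravel())
    if not cells <= {"a", "c", "?"}:
        raise RecodeError(
            f"matrix is not a recoded binary matrix (found {sorted(cells - {'a', 'c', '?'})})"
        )
    mapped = matrix.states.copy()
    mapped[matrix.states == "c"] = "0"
    mapped[matrix.states == "a"] = "1"
    return replace(matrix, states=mapped)


def harmonize(matrix: CharacterMatrix) -> CharacterMatrix:
    """Return a nucleotide-coded matrix, recoding raw FLP input if needed."""
    return recode_binary(matrix) if matrix.is_raw_binary else matrix


def merge_matrices(parts: list[CharacterMatrix]) -> CharacterMatrix:
    """Column-concatenate matrices over an identical sample set.

    Parts may order samples differently; rows are aligned to the first
    part's order.  Character labels must be disjoint.  Marker type becomes
    ``mixed`` when parts disagree.
    """
    parts = [p for p in parts if p.n_characters > 0]
    if not parts:
        raise EmptyInputError("nothing to merge")
    if len(parts) == 1:
        return parts[0]
    first = parts[0]
    ref_ids = first.sample_ids
    blocks, characters = [first.states], list(first.characters)
    for p in parts[1:]:
        missing = set(ref_ids) ^ set(p.sample_ids)
        if missing:
            raise SampleMismatchError(
                f"sample sets differ; unmatched samples: {sorted(missing)}"
            )
        overlap = set(characters) & set(p.characters)
        if overlap:
            raise TableParseError(
                f"duplicate character labels across parts: {sorted(overlap)}"
            )
        order = [p.sample_ids.index(sid) for sid in ref_ids]
        blocks.append(p.states[order])
        characters.extend(p.characters)
    marker_types = {p.marker_type for p in parts}
    marker = marker_types.pop() if len(marker_types) == 1 else "mixed"
    return CharacterMatrix(
        first.samples, characters, np.hstack(blocks), marker_type=marker
    )


def is_ambiguous(state: str) -> bool:
    """True for every non-homozygous state (IUPAC codes, ``n``, ``-``, ``?``).

    Raw binary ``0``/``1`` count as unambiguous presence/absence calls.
    """
    if state in UNAMBIGUOUS or state in {"0", "1"}:
        return False
    if state in ALPHABET:
        return True
    raise AlphabetError(f"symbol {state!r} outside alphabet")


def ambiguity_mask(matrix: CharacterMatrix) -> np.ndarray:
    """Boolean grid marking ambiguous cells."""
    return ~np.isin(matrix.states, ["a", "c", "g", "t", "0", "1"])


def ambiguity_profile(matrix: CharacterMatrix) -> AmbiguityProfile:
    """Count ambiguous cells per sample; summarize mean, sd and percent.

    ``sd`` is the sample (n-1) standard deviation; ``percent`` is
    ``mean / n_characters * 100``.
    """
    if matrix.n_samples == 0 or matrix.n_characters == 0:
        raise EmptyInputError("cannot profile an empty matrix")
    counts = ambiguity_mask(matrix).sum(axis=1)
    per_sample = {sid: int(c) for sid, c in zip(matrix.sample_ids, counts)}
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    return AmbiguityProfile(
        per_sample_counts=per_sample,
        mean=mean,
        sd=sd,
        percent=mean / matrix.n_characters * 100.0,
    )
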