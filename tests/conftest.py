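import numpy as np
import pytest
from hypothesis import settings

from clonotyper.matrix import CharacterMatrix, SampleRecord, _build_samples

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_matrix(rows: dict[str, str], marker_type: str = "SNP") -> CharacterMatrix:
    """Build a CharacterMatrix from {sample_id: state string}."""
    ids = list(rows)
    samples = _build_samples(ids)
    length = len(next(iter(rows.values())))
    characters = [f"c{i + 1}" for i in range(length)]
    grid = np.array([list(rows[i]) for i in ids])
    return CharacterMatrix(samples, characters, grid, marker_type=marker_type)


@pytest.fixture
def tiny_snp_matrix():
    return make_matrix({"A": "acca", "B": "acta", "C": "arca"})


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name="aln.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{k}\n{v}\n" for k, v in records.items()))
        return path

    return _write


@pytest.fixture
def write_csv(tmp_path):
    def _write(text: str, name="table.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


#: 23 four-digit clone codes of the reference panel.
PANEL = [
    "7379", "7498", "7551", "9242", "9256", "9290", "9316", "9333",
    "9351", "9501", "9502", "9503", "9504", "9506", "9508", "9509",
    "9510", "9511", "9512", "9513", "9514", "9560", "9622",
]


def matrix_with_edges(clone_ids, edge_spec, n_chars=1000, k_edge=2, k_far=20):
    """Build a matrix whose p-distances realize a requested edge structure.

    ``edge_spec`` maps hub clone -> list of leaf clones; each leaf differs
    from its hub at ``k_edge`` sites (a "near" pair), every other pair
    differs at >= ``k_far`` sites.  ``extra_near`` chains can be added by
    the caller by copying rows.
    """
    rows = {cid: ["a"] * n_chars for cid in clone_ids}
    block = 0
    anchored = set()
    for hub, leaves in edge_spec.items():
        anchored.add(hub)
        for leaf in leaves:
            anchored.add(leaf)
            for j in range(k_edge):
                rows[leaf][block * k_edge + j] = "c"
            block += 1
    far_start = n_chars // 2
    units = list(edge_spec) + [c for c in clone_ids if c not in anchored]
    for u, unit in enumerate(units):
        for cid in [unit, *edge_spec.get(unit, [])]:
            for j in range(k_far):
                rows[cid][far_start + u * k_far + j] = "g"
    return make_matrix({cid: "".join(r) for cid, r in rows.items()})


def random_nucleotide_matrix(rng, n_samples=6, n_chars=20, p_ambig=0.15):
    """Random small matrix mixing homozygous and ambiguous states."""
    states = rng.choice(list("acgt"), size=(n_samples, n_chars))
    amb = rng.random((n_samples, n_chars)) < p_ambig
    amb_states = rng.choice(list("ryswkmn-?"), size=(n_samples, n_chars))
    states = np.where(amb, amb_states, states)
    ids = [f"s{i}" for i in range(n_samples)]
    return make_matrix({i: "".join(r) for i, r in zip(ids, states)})
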