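"""Reference classification of the 42 basidiomycete chitin synthases.

The published study of chitin synthase (CHS) evolution in Basidiomycota
analyzed 42 complete CHS sequences from 11 species.  Four tree-based
methods all recovered three groups (A: classes B/C/E, B: class III,
C: classes IVa/IVb/Va/Vb) plus the more inclusive group AB, and the
network-community analysis of the BLAST percent-identity matrix recovered
the same structure as communities C3 (= A), C2 (= B), and C1 (= C).

This module ships that published classification (sequence ids, NCBI
accessions, species, CHS class, tree group, network community) as
structured data, for use as the reference partition in congruence
comparisons and in tests.

The percent-identity matrix itself is distributed only as journal
supplementary data and is not redistributed here; :func:`deposited_matrix`
loads it from ``data/chs42_similarity.tsv`` when the user has placed it
there.  :func:`synthetic_study_matrix` builds a SYNTHETIC stand-in with the
same 42 labels and the published group structure for end-to-end runs that
do not depend on the original scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .community import Partition
from .simio import SimilarityMatrix, read_square_matrix
from .synth import planted_matrix

__all__ = [
    "ChsRecord",
    "CHS_RECORDS",
    "labels",
    "community_partition",
    "tree_partition",
    "group_ab",
    "deposited_matrix",
    "DEPOSITED_MATRIX_PATH",
    "synthetic_study_matrix",
]

ALIGNMENT_LENGTH = 4944  # columns in the 42-sequence alignment, gaps included


@dataclass(frozen=True)
class ChsRecord:
    id: str  # zero-padded sequence number used as node label
    accession: str  # NCBI protein accession
    species: str
    chs_class: str  # B, C, E, III, IVa, IVb, Va, Vb
    tree_group: str  # A, B, C (shared by all four tree methods)
    community: str  # C1, C2, C3 (network communities; C3=A, C2=B, C1=C)


def _r(i: int, acc: str, sp: str, cls: str, grp: str, com: str) -> ChsRecord:
    return ChsRecord(f"{i:02d}", acc, sp, cls, grp, com)


CHS_RECORDS: tuple[ChsRecord, ...] = (
    _r(1, "XP_566840", "Cryptococcus neoformans var. neoformans JEC21", "Vb", "C", "C1"),
    _r(2, "AAB71697", "Cryptococcus neoformans var. grubii", "IVb", "C", "C1"),
    _r(3, "BAC78196", "Coprinopsis cinerea", "IVa", "C", "C1"),
    _r(4, "CAB96110", "Agaricus bisporus", "III", "B", "C2"),
    _r(5, "AAW43575", "Cryptococcus neoformans var. neoformans JEC21", "III", "B", "C2"),
    _r(6, "AAW44688", "Cryptococcus neoformans var. neoformans JEC22", "E", "A", "C3"),
    _r(7, "AAW42050", "Cryptococcus neoformans var. neoformans JEC21", "B", "A", "C3"),
    _r(8, "XP_003328148", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "IVa", "C", "C1"),
    _r(9, "XP_003328707", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "B", "A", "C3"),
    _r(10, "CBQ67873", "Sporisorium reilianum", "B", "A", "C3"),
    _r(11, "EFP91815", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "III", "B", "C2"),
    _r(12, "EFP89079", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "Va", "C", "C1"),
    _r(13, "EFP83544", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "IVb", "C", "C1"),
    _r(14, "EFP78527", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "Vb", "C", "C1"),
    _r(15, "EFP77369", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "C", "A", "C3"),
    _r(16, "EFP76086", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "III", "B", "C2"),
    _r(17, "BAJ08815", "Lentinula edodes", "E", "A", "C3"),
    _r(18, "XP_001830485", "Coprinopsis cinerea okayama7#130", "IVb", "C", "C1"),
    _r(19, "EAU80919", "Coprinopsis cinerea okayama7#130", "B", "A", "C3"),
    _r(20, "AAB84284", "Ustilago maydis", "IVa", "C", "C1"),
    _r(21, "AAB84285", "Ustilago maydis", "Vb", "C", "C1"),
    _r(22, "ABB70406", "Puccinia graminis f. sp. tritici", "IVb", "C", "C1"),
    _r(23, "ABB70409", "Puccinia graminis f. sp. tritici", "III", "B", "C2"),
    _r(24, "ABB70407", "Puccinia graminis f. sp. tritici", "B", "A", "C3"),
    _r(25, "ABB70408", "Puccinia graminis f. sp. tritici", "III", "B", "C2"),
    _r(26, "ABB70410", "Puccinia graminis", "Va", "C", "C1"),
    _r(27, "BAF41225", "Pleurotus ostreatus", "IVa", "C", "C1"),
    _r(28, "BAF37219", "Pleurotus ostreatus", "III", "B", "C2"),
    _r(29, "BAF76741", "Pleurotus ostreatus", "B", "A", "C3"),
    _r(30, "ABW09311", "Moniliophthora perniciosa", "III", "B", "C2"),
    _r(31, "BAD20778", "Malassezia pachydermatis", "B", "A", "C3"),
    _r(32, "BAF37218", "Lentinula edodes", "Vb", "C", "C1"),
    _r(33, "XP_570882", "Cryptococcus neoformans var. neoformans JEC21", "III", "B", "C2"),
    _r(34, "AAW45092", "Cryptococcus neoformans var. neoformans JEC21", "IVa", "C", "C1"),
    _r(35, "AAW44838", "Cryptococcus neoformans var. neoformans JEC21", "IVb", "C", "C1"),
    _r(36, "AAW47172", "Cryptococcus neoformans var. neoformans JEC21", "C", "A", "C3"),
    _r(37, "AAW44187", "Cryptococcus neoformans var. neoformans JEC21", "Va", "C", "C1"),
    _r(38, "CBQ67884", "Sporisorium reilianum", "C", "A", "C3"),
    _r(39, "XP_003327390", "Puccinia graminis f. sp. tritici CRL 75-36-700-3", "IVb", "C", "C1"),
    _r(40, "ADX07313", "Flammulina velutipes", "III", "B", "C2"),
    _r(41, "ADX07309", "Flammulina velutipes", "C", "A", "C3"),
    _r(42, "ADX07293", "Flammulina velutipes", "III", "B", "C2"),
)


def labels() -> tuple[str, ...]:
    """The 42 node labels, in id order."""
    return tuple(r.id for r in CHS_RECORDS)


def community_partition() -> Partition:
    """The published network communities C1 (18), C2 (11), C3 (13)."""
    return Partition.from_mapping({r.id: r.community for r in CHS_RECORDS})


def tree_partition() -> Partition:
    """The groups A (13), B (11), C (18) shared by all four tree methods."""
    return Partition.from_mapping({r.id: r.tree_group for r in CHS_RECORDS})


def group_ab() -> frozenset[str]:
    """The more inclusive group AB = A union B (= communities C3 + C2)."""
    return frozenset(r.id for r in CHS_RECORDS if r.tree_group in ("A", "B"))


DEPOSITED_MATRIX_PATH = Path("data") / "chs42_similarity.tsv"


def deposited_matrix(
    path: str | Path = DEPOSITED_MATRIX_PATH,
) -> SimilarityMatrix:
    """Load the published 42x42 CHS percent-identity matrix.

    The matrix is journal supplementary data and is not redistributed with
    this package; export it as labeled TSV (labels = the two-digit sequence
    ids) to ``data/chs42_similarity.tsv`` to enable the checks that depend
    on it.
    """
    path = Path(path)
    if not path.is_absolute() and not path.exists():
        # also look next to the package checkout, so tests work from any cwd
        candidate = Path(__file__).resolve().parents[2] / path
        if candidate.exists():
            path = candidate
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: the published 42x42 chitin synthase "
            "similarity matrix is supplementary data of the original study "
            "and is not redistributed with this package; place it there as "
            "a labeled TSV to enable matrix-dependent checks"
        )
    return read_square_matrix(path, dialect="labeled-tsv")


def synthetic_study_matrix(seed: int = 0, sd: float = 4.0) -> SimilarityMatrix:
    """A SYNTHETIC stand-in for the unavailable published matrix.

    Carries the 42 published sequence ids and plants the published group
    structure at score levels typical for CHS families: ~60% identity
    within a community, ~40% between the sister communities C2 and C3
    (whose union is the tree methods' group AB), and ~35% between the
    outgroup community C1 and the rest, with Gaussian noise of standard
    deviation *sd*.  Both inter-community score scales lie below the
    within-community scale, so at the critical threshold the three
    communities are internally dense and joined only by a handful of
    boundary edges (C2-C3 more strongly than C1), the qualitative
    structure reported for the original network.  Useful for end-to-end
    demonstrations and seeded pipeline runs; its absolute numbers
    (critical threshold, edge counts, index values) are properties of this
    construction, not of the original data.
    """
    order = {"C1": 0, "C2": 1, "C3": 2}
    block_of = [order[r.community] for r in CHS_RECORDS]
    mu = np.array(
        [
            [60.0, 35.0, 35.0],
            [35.0, 60.0, 40.0],
            [35.0, 40.0, 60.0],
        ]
    )
    return planted_matrix(labels(), block_of, mu, sd=sd, seed=seed)
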