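"""Synthetic similarity matrices with planted community structure.

Real percent-identity matrices over protein families are approximately
block-structured: members of one family score high against each other and
low against outsiders, with alignment noise on top.  The generators here
plant that structure directly at the score level — Gaussian scores around a
within-block mean and a between-block mean, clipped to [0, 100] — so every
pipeline stage (threshold scan, community detection, bootstrap) can be
exercised against a known ground truth without any sequence data.

An optional second hierarchy level (tighter sub-blocks inside each block)
creates two separation scales and therefore two peaks in the delta profile,
the situation where secondary peaks of the scan become informative.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .community import Partition
from .errors import SizeError
from .simio import SimilarityMatrix

__all__ = ["PlantedSpec", "planted_blocks", "planted_matrix"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-community similarity matrix.

    ``block_sizes`` are the community sizes; within-block pairs score
    around ``mu_in``, between-block pairs around ``mu_out`` (percent
    identity, so ``0 <= mu_out < mu_in <= 100``), with Gaussian noise of
    standard deviation ``sd``.  Optional ``sub_blocks`` (a nested size list
    per block) plant tighter groups at ``sub_mu_in > mu_in``.
    """

    block_sizes: tuple[int, ...]
    mu_in: float = 80.0
    mu_out: float = 30.0
    sd: float = 5.0
    seed: int = 0
    sub_blocks: tuple[tuple[int, ...], ...] | None = None
    sub_mu_in: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if self.sub_blocks is not None:
            object.__setattr__(
                self, "sub_blocks", tuple(tuple(b) for b in self.sub_blocks)
            )
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.block_sizes) < 3:
            raise SizeError("need at least 3 nodes in total")
        if not 0 <= self.mu_out < self.mu_in <= 100:
            raise ValueError("require 0 <= mu_out < mu_in <= 100")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if (self.sub_blocks is None) != (self.sub_mu_in is None):
            raise ValueError("sub_blocks and sub_mu_in go together")
        if self.sub_blocks is not None:
            if len(self.sub_blocks) != len(self.block_sizes):
                raise ValueError("one sub-block list per block required")
            for sizes, total in zip(self.sub_blocks, self.block_sizes):
                if sum(sizes) != total:
                    raise ValueError("sub-block sizes must sum to the block size")
            if not self.mu_in < self.sub_mu_in <= 100:
                raise ValueError("require mu_in < sub_mu_in <= 100")


def _block_labels(block_sizes: Sequence[int]) -> list[str]:
    if len(block_sizes) > len(string.ascii_lowercase):
        raise ValueError("at most 26 blocks supported")
    width = len(str(max(block_sizes)))
    return [
        f"{string.ascii_lowercase[b]}{i + 1:0{width}d}"
        for b, size in enumerate(block_sizes)
        for i in range(size)
    ]


def planted_matrix(
    labels: Sequence[str],
    block_of: Sequence[int],
    mu: np.ndarray,
    sd: float,
    seed: int,
) -> SimilarityMatrix:
    """General planted generator: pair (i, j) scores
    ``Normal(mu[block_of[i], block_of[j]], sd)`` clipped to [0, 100].

    ``mu`` is the k x k matrix of block-pair means (diagonal = within-block
    means).  Symmetric by construction, diagonal 100, deterministic per
    seed.
    """
    n = len(labels)
    if n < 3:
        raise SizeError("need at least 3 nodes in total")
    rng = np.random.default_rng(seed)
    block_of = np.asarray(block_of)
    means = np.asarray(mu, dtype=float)[np.ix_(block_of, block_of)]
    iu = np.triu_indices(n, k=1)
    scores = means[iu]
    if sd > 0:
        scores = scores + rng.normal(0.0, sd, size=scores.size)
    scores = np.clip(scores, 0.0, 100.0)
    vals = np.full((n, n), 100.0)
    vals[iu] = scores
    vals.T[iu] = scores
    return SimilarityMatrix(tuple(labels), vals, symmetrized=True)


def planted_blocks(spec: PlantedSpec) -> tuple[SimilarityMatrix, Partition]:
    """Generate a planted-community matrix and its ground-truth partition.

    Labels are block-coded (``a01, a02, ..., b01, ...``) so block membership
    is visible and label sort order groups blocks contiguously.
    """
    labels = _block_labels(spec.block_sizes)
    if spec.sub_blocks is None:
        k = len(spec.block_sizes)
        mu = np.full((k, k), spec.mu_out)
        np.fill_diagonal(mu, spec.mu_in)
        block_of = [
            b for b, size in enumerate(spec.block_sizes) for _ in range(size)
        ]
    else:
        # flatten sub-blocks into fine-grained blocks; mean depends on
        # whether two fine blocks share a coarse block
        fine_sizes: list[int] = []
        coarse_of_fine: list[int] = []
        for coarse, sizes in enumerate(spec.sub_blocks):
            for s in sizes:
                fine_sizes.append(s)
                coarse_of_fine.append(coarse)
        k = len(fine_sizes)
        mu = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                if a == b:
                    mu[a, b] = spec.sub_mu_in
                elif coarse_of_fine[a] == coarse_of_fine[b]:
                    mu[a, b] = spec.mu_in
                else:
                    mu[a, b] = spec.mu_out
        block_of = [b for b, size in enumerate(fine_sizes) for _ in range(size)]
    S = planted_matrix(labels, block_of, mu, spec.sd, spec.seed)
    truth: list[frozenset[str]] = []
    start = 0
    for size in spec.block_sizes:
        truth.append(frozenset(labels[start : start + size]))
        start += size
    return S, Partition(tuple(truth))
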