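"""Branch support by binomial resampling of the similarity matrix.

Tree methods attach bootstrap percentages to clades by resampling alignment
columns.  The network analogue implemented here resamples the similarity
matrix itself: each percent identity ``S_ij`` is read as a success
probability ``p = S_ij / 100``; a replicate draws
``k ~ Binomial(trials, p)`` and sets ``S'_ij = k * 100 / trials``, where
``trials`` is the alignment length including gaps (4,944 for the 42-sequence
chitin synthase study).  ``S'`` is unbiased for ``S`` with variance
``100^2 p (1 - p) / trials`` — largest near 50% identity and vanishing at
the spectrum's ends, mimicking how character resampling would perturb
similarity scores.

Each replicate matrix is thresholded at the *same* critical sigma_c as the
original and run through the same Newman-Girvan procedure; the support of a
reference branch is the percentage of replicates whose dendrogram contains
that exact node set as a branch (clade-presence scoring, exact-set match).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Dendrogram, newman_girvan
from .errors import StateError
from .netscan import build_network
from .simio import SimilarityMatrix

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "resample_matrix",
    "bootstrap_support",
    "variance_report",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for a bootstrap run.

    ``trials`` is dataset-specific: it must equal the alignment length
    (including gaps) that produced the similarity scores.  The default is
    the 42-sequence chitin synthase alignment length.
    """

    sigma_c: int
    replicates: int = 1000
    trials: int = 4944
    seed: int = 0
    partition_rule: str = "max-modularity"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not 0 <= self.sigma_c <= 100:
            raise ValueError("sigma_c must be in [0, 100]")


@dataclass(frozen=True)
class BootstrapResult:
    """Per-branch support percentages and per-entry resampling variance."""

    branch_support: dict[frozenset[str], float]
    per_entry_variance: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = ()
    replicate_count: int = 0
    seed: int = 0

    def support_table(self) -> pd.DataFrame:
        rows = [
            {
                "size": len(branch),
                "members": ",".join(sorted(branch)),
                "support": sup,
            }
            for branch, sup in self.branch_support.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["size", "members"], ascending=[False, True])
            .reset_index(drop=True)
        )


def resample_matrix(
    S: SimilarityMatrix, trials: int, rng: np.random.Generator
) -> SimilarityMatrix:
    """One bootstrap replicate of *S*.

    Each unordered pair is drawn once and mirrored, so the replicate is
    symmetric by construction; the diagonal stays at 100 (p = 1 is
    degenerate).  Entries are exact rationals k*100/trials stored as
    floats.
    """
    if not S.symmetrized:
        raise StateError("resampling requires a symmetrized matrix")
    n = S.n
    iu = np.triu_indices(n, k=1)
    p = S.values[iu] / 100.0
    k = rng.binomial(trials, p)
    vals = np.full((n, n), 100.0)
    vals[iu] = k * 100.0 / trials
    vals.T[iu] = vals[iu]
    np.fill_diagonal(vals, 100.0)
    return SimilarityMatrix(S.labels, vals, symmetrized=True)


def _replicate_branch_sets(
    S_rep: SimilarityMatrix, sigma_c: int
) -> set[frozenset[str]]:
    """All branch node sets of one replicate's dendrogram (root, initial
    components, every split product down to singletons)."""
    G = build_network(S_rep, sigma_c)
    d = newman_girvan(G)
    return d.branch_sets()


def bootstrap_support(
    S: SimilarityMatrix,
    reference: Dendrogram,
    cfg: BootstrapConfig,
) -> BootstrapResult:
    """Support percentages for every branch of *reference*.

    A branch counts as featured in a replicate iff its exact node set
    occurs among the replicate dendrogram's branches.  The root (full node
    set) is a branch of every dendrogram, so its support is always 100.
    Replicates are drawn sequentially from one seeded generator: the same
    seed gives a bit-identical result, and replicate order cannot change
    the supports (each is a plain count).
    """
    rng = np.random.default_rng(cfg.seed)
    ref_branches = sorted(
        reference.branch_sets(), key=lambda s: (-len(s), sorted(s))
    )
    counts = {b: 0 for b in ref_branches}
    n = S.n
    sum_ = np.zeros((n, n))
    sumsq = np.zeros((n, n))
    for _ in range(cfg.replicates):
        S_rep = resample_matrix(S, cfg.trials, rng)
        sum_ += S_rep.values
        sumsq += S_rep.values**2
        rep_sets = _replicate_branch_sets(S_rep, cfg.sigma_c)
        for b in ref_branches:
            if b in rep_sets:
                counts[b] += 1
    mean = sum_ / cfg.replicates
    if cfg.replicates > 1:
        var = (sumsq - cfg.replicates * mean**2) / (cfg.replicates - 1)
        var = np.clip(var, 0.0, None)
    else:
        var = np.zeros((n, n))
    support = {
        b: 100.0 * c / cfg.replicates for b, c in counts.items()
    }
    return BootstrapResult(
        branch_support=support,
        per_entry_variance=var,
        labels=S.labels,
        replicate_count=cfg.replicates,
        seed=cfg.seed,
    )


def variance_report(
    S: SimilarityMatrix, cfg: BootstrapConfig
) -> pd.DataFrame:
    """Empirical per-entry variance of S' across replicates.

    Returns one row per unordered pair (label_i, label_j, original score,
    variance), sorted by variance descending.  For large replicate counts
    the variance approaches the binomial closed form
    ``100^2 p (1-p) / trials``, peaking at scores near 50.
    """
    rng = np.random.default_rng(cfg.seed)
    n = S.n
    iu = np.triu_indices(n, k=1)
    p = S.values[iu] / 100.0
    draws = rng.binomial(
        cfg.trials, np.broadcast_to(p, (cfg.replicates, p.size))
    ) * (100.0 / cfg.trials)
    var = draws.var(axis=0, ddof=1) if cfg.replicates > 1 else np.zeros(p.size)
    rows = pd.DataFrame(
        {
            "label_i": [S.labels[i] for i in iu[0]],
            "label_j": [S.labels[j] for j in iu[1]],
            "original_S": S.values[iu],
            "variance": var,
        }
    )
    return rows.sort_values(
        "variance", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
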