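"""Integration of multiple call sets: rank-combination and intersection.

The rank-combination fuses K callers' rankings into one.  Every variant in
the union universe gets a per-tool rank (uncalled variants share the worst
rank), ranks are mapped to standard-normal scores, and the score columns
are decorrelated with the pseudo-inverse of their correlation matrix
before summing.  Down-weighting by the precision matrix means that a
clique of highly correlated callers counts roughly as one voice while an
independent caller keeps its full weight — adding an exact duplicate of a
tool provably leaves the combined ranking unchanged, and two exactly
reversed rankings cancel to a complete tie.  The method depends on the
input rankings only, never on the score scales.

The intersection baseline keeps the variants present in every tool's
FDR-restricted prefix; its recall can never exceed the weakest tool's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .calling import CallSet
from .evaluation import LabeledCallSet, fdr_prefix, prefix_keys

__all__ = ["RankMatrix", "build_rank_matrix", "rank_combine", "intersect_callsets"]

logger = logging.getLogger(__name__)


@dataclass
class RankMatrix:
    """Per-tool ranks of every variant in the union universe.

    ``ranks[i, k]`` is tool k's rank of universe variant i: called
    variants keep their relative order 1..n_k, uncalled variants share
    the single worst rank |U|.  ``scores`` maps ranks through the
    standard-normal quantile of 1 - rank/(|U|+1), so a better rank is a
    larger score and the scale is comparable across tools regardless of
    how many variants each called.
    """

    tools: list[str]
    variants: list  # universe Variant objects, coordinate-sorted
    ranks: np.ndarray  # (n_variants, n_tools) int
    scores: np.ndarray  # (n_variants, n_tools) float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("normal scores must be finite")


def build_rank_matrix(callsets: list[CallSet]) -> RankMatrix:
    if len(callsets) < 2:
        raise ValueError("rank combination needs at least two call sets")
    universe: dict = {}
    for cs in callsets:
        for rec in cs:
            universe.setdefault(rec.key, rec.variant)
    keys = sorted(universe, key=lambda k: (k[0], k[1], k[2]))
    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    ranks = np.full((n, len(callsets)), n, dtype=np.int64)
    for k, cs in enumerate(callsets):
        for rec in cs:
            ranks[index[rec.key], k] = rec.rank
    scores = norm.ppf(1.0 - ranks / (n + 1.0))
    return RankMatrix(
        tools=[cs.tool_id for cs in callsets],
        variants=[universe[k] for k in keys],
        ranks=ranks,
        scores=scores,
    )


def _decorrelation_weights(
    scores: np.ndarray, eig_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Column weights w such that combined = Z @ w with Z the standardized
    score columns and w = Sigma^+ 1 (precision-matrix row sums).

    Eigenvalues of the correlation matrix below ``eig_tol`` are treated as
    null directions; a zero-variance column contributes nothing.
    """
    z = scores - scores.mean(axis=0, keepdims=True)
    sd = z.std(axis=0)
    degenerate = sd <= 0
    if degenerate.any():
        logger.warning(
            "zero-variance score column(s) at index %s contribute a null direction",
            np.flatnonzero(degenerate).tolist(),
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    z = z / sd_safe
    z[:, degenerate] = 0.0
    sigma = (z.T @ z) / max(len(z), 1)
    sigma[np.diag_indices_from(sigma)] = np.where(degenerate, 1.0,
                                                  np.diag(sigma))
    vals, vecs = np.linalg.eigh(sigma)
    inv = np.where(vals > eig_tol, 1.0 / np.maximum(vals, eig_tol), 0.0)
    pinv = (vecs * inv) @ vecs.T
    return z, pinv.sum(axis=1)


def rank_combine(callsets: list[CallSet], tool_id: str = "rank-combination",
                 eig_tol: float = 1e-10) -> CallSet:
    """Fuse K >= 2 ranked call sets into one combined ranking.

    Steps: build the union rank matrix; map ranks to standard-normal
    scores; standardize the score columns; estimate their correlation
    matrix; weight the columns by the row sums of its pseudo-inverse
    (eigenvalues below ``eig_tol`` are null directions); rank by the
    weighted sum, ties broken by ascending coordinate.  Because only
    ranks enter, the result is invariant to any strictly monotone
    transformation of the tools' scores.
    """
    rm = build_rank_matrix(callsets)
    z, w = _decorrelation_weights(rm.scores, eig_tol=eig_tol)
    combined = z @ w
    scored = list(zip(rm.variants, combined.astype(float)))
    return CallSet.from_scores(tool_id, scored)


def intersect_callsets(
    callsets: list[CallSet],
    alpha: float | None = None,
    labeled: dict[str, LabeledCallSet] | None = None,
) -> set:
    """Variants present in every tool's call set (or FDR-restricted prefix).

    With ``alpha`` and per-tool labels, each tool is first restricted to
    its largest prefix with FDR <= alpha; otherwise full call sets are
    intersected.  Returns the set of (chrom, pos, alt) keys.
    """
    if len(callsets) < 2:
        raise ValueError("intersection needs at least two call sets")
    key_sets = []
    for cs in callsets:
        if alpha is not None:
            if labeled is None or cs.tool_id not in labeled:
                raise ValueError(
                    f"alpha given but no labels for tool {cs.tool_id!r}"
                )
            lab = labeled[cs.tool_id]
            key_sets.append(prefix_keys(lab, fdr_prefix(lab, alpha)))
        else:
            key_sets.append(cs.keys())
    return set.intersection(*key_sets)
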