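"""Domain model for clonal tumor simulations.

A tumor sample is modelled as a mixture of K diploid cancer clones plus
contaminating normal cells.  The clones are related by a rooted clonal
ancestry tree: a somatic variant is acquired at one node and inherited by
every descendant, while germline variants are present in the normal genome
and in all clones.  Clone proportions are drawn from a symmetric Dirichlet
distribution, and the expected variant allele frequency (VAF) of every
variant in the mixed sample follows from the clone weights, the per-clone
copy number of the variant (1 or 2 on a diploid background), and the
normal-contamination fraction kappa.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VariantClass",
    "Variant",
    "ClonalTree",
    "CloneWeights",
    "Origin",
    "TruthVariant",
    "MixtureSpec",
    "build_clonal_tree",
    "draw_clone_weights",
    "assign_variants",
    "compute_true_vaf",
]


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    MNV = "MNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class Origin(str, enum.Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"


@dataclass(frozen=True, order=True)
class Variant:
    """A sequence variant with a 1-based, VCF-style anchored position.

    Insertions and deletions use the left-anchored VCF representation
    (e.g. deletion ``ref="ACC", alt="A"``), so ``len(ref) != len(alt)``
    exactly when the variant changes sequence length.
    """

    chrom: str
    pos: int  # 1-based reference position of the first ref base
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == len(self.alt):
            return VariantClass.SNV if len(self.ref) == 1 else VariantClass.MNV
        return (
            VariantClass.INSERTION
            if len(self.alt) > len(self.ref)
            else VariantClass.DELETION
        )

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity for matching calls to truth: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval of reference bases consumed."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def is_snv(self) -> bool:
        return self.vclass is VariantClass.SNV


@dataclass(frozen=True)
class ClonalTree:
    """Rooted clone ancestry tree over nodes 1..n_clones.

    ``parent`` maps every non-root node to its parent; the root is absent
    from the mapping.
    """

    n_clones: int
    parent: dict[int, int]

    def __post_init__(self) -> None:
        nodes = set(range(1, self.n_clones + 1))
        roots = nodes - set(self.parent)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
        if set(self.parent) | roots != nodes:
            raise ValueError("parent mapping refers to unknown nodes")
        # reachability from root doubles as the acyclicity check
        children: dict[int, list[int]] = {n: [] for n in nodes}
        for child, par in self.parent.items():
            if par not in nodes:
                raise ValueError(f"unknown parent node {par}")
            children[par].append(child)
        seen: set[int] = set()
        stack = [next(iter(roots))]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ValueError("cycle detected in clonal tree")
            seen.add(node)
            stack.extend(children[node])
        if seen != nodes:
            raise ValueError("not all nodes reachable from the root")

    @property
    def root(self) -> int:
        return next(n for n in range(1, self.n_clones + 1) if n not in self.parent)

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def descendants(self, node: int) -> set[int]:
        """All nodes below ``node`` (excluding ``node`` itself)."""
        out: set[int] = set()
        stack = [node]
        while stack:
            for child in self.children(stack.pop()):
                out.add(child)
                stack.append(child)
        return out

    def subtree(self, node: int) -> set[int]:
        return {node} | self.descendants(node)


@dataclass(frozen=True)
class CloneWeights:
    """One Dirichlet draw of clone mixture proportions."""

    weights: dict[int, float]
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all clone weights must be positive")

    def weight_of(self, clones) -> float:
        return float(sum(self.weights[c] for c in clones))


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth variant with its clonal placement and true VAF.

    ``copies`` is the number of mutated alleles per carrier clone (1 =
    heterozygous, 2 = homozygous on a diploid background); all carriers of
    one variant share the same zygosity.  ``normal_copies`` is the copy
    number in the contaminating normal genome: 0 for somatic variants,
    1 or 2 for germline ones.
    """

    variant: Variant
    origin: Origin
    carriers: frozenset[int]
    copies: int
    normal_copies: int
    assigned_node: int | None = None
    true_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.copies not in (1, 2):
            raise ValueError("copies per carrier must be 1 or 2")
        if self.origin is Origin.SOMATIC:
            if self.normal_copies != 0:
                raise ValueError("somatic variants have normal_copies == 0")
            if self.assigned_node is None:
                raise ValueError("somatic variants need an assigned node")
        else:
            if self.normal_copies not in (1, 2):
                raise ValueError("germline variants have normal_copies in {1, 2}")


@dataclass(frozen=True)
class MixtureSpec:
    """Tumor-sample mixing parameters.

    kappa is the fraction of reads in the tumor sample that originate from
    the contaminating normal genome (purity = 1 - kappa); coverage_level is
    the target mean depth over the capture targets.
    """

    kappa: float
    coverage_level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.coverage_level <= 0:
            raise ValueError("coverage_level must be positive")


def build_clonal_tree(
    n_clones: int,
    parent_vector: dict[int, int] | None = None,
    seed: int = 0,
) -> ClonalTree:
    """Build a clone ancestry tree over nodes 1..n_clones.

    With an explicit ``parent_vector`` the topology is validated and used
    as-is.  Otherwise a random recursive tree is drawn: node 1 is the root
    and each node i > 1 attaches to a uniformly chosen node in 1..i-1,
    deterministically per seed.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    if parent_vector is not None:
        return ClonalTree(n_clones=n_clones, parent=dict(parent_vector))
    rng = np.random.default_rng(seed)
    parent = {i: int(rng.integers(1, i)) for i in range(2, n_clones + 1)}
    return ClonalTree(n_clones=n_clones, parent=parent)


def draw_clone_weights(tree: ClonalTree, alpha: float = 1 / 8, seed: int = 0) -> CloneWeights:
    """Draw clone proportions from a symmetric Dirichlet(alpha, ..., alpha).

    The default concentration 1/8 produces sparse mixtures in which a few
    clones dominate, mimicking strong clonal architecture.
    """
    if alpha <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet([alpha] * tree.n_clones)
    # guard against numerically zero components (weights must be > 0)
    w = np.clip(w, 1e-300, None)
    w = w / w.sum()
    weights = {node: float(w[node - 1]) for node in range(1, tree.n_clones + 1)}
    return CloneWeights(weights=weights, alpha=alpha, seed=seed)


def assign_variants(
    variants: list[tuple[Variant, Origin]],
    tree: ClonalTree,
    seed: int = 0,
) -> list[TruthVariant]:
    """Place variants on the clonal tree and fix their zygosity.

    Somatic variants are assigned to a uniformly random node and inherited
    by every descendant of that node; one zygosity draw per variant makes
    all carriers heterozygous or homozygous with probability 1/2 each.
    Germline variants are carried by the normal genome (1 or 2 copies,
    probability 1/2 each) and inherited by all clones at the same copy
    number.
    """
    rng = np.random.default_rng(seed)
    all_clones = frozenset(range(1, tree.n_clones + 1))
    out: list[TruthVariant] = []
    for variant, origin in variants:
        if origin is Origin.SOMATIC:
            node = int(rng.integers(1, tree.n_clones + 1))
            copies = int(rng.integers(1, 3))
            out.append(
                TruthVariant(
                    variant=variant,
                    origin=origin,
                    carriers=frozenset(tree.subtree(node)),
                    copies=copies,
                    normal_copies=0,
                    assigned_node=node,
                )
            )
        elif origin is Origin.GERMLINE:
            copies = int(rng.integers(1, 3))
            out.append(
                TruthVariant(
                    variant=variant,
                    origin=origin,
                    carriers=all_clones,
                    copies=copies,
                    normal_copies=copies,
                )
            )
        else:
            raise ValueError(f"unknown origin label: {origin!r}")
    return out


def compute_true_vaf(tv: TruthVariant, weights: CloneWeights, kappa: float) -> float:
    """Expected alt-allele fraction of a variant in the mixed tumor sample.

    On a diploid background the mutated-allele dosage contributed by clone
    c is w_c * copies / 2, scaled by the tumor fraction (1 - kappa); the
    contaminating normal contributes kappa * normal_copies / 2.  A
    homozygous germline variant therefore has VAF 1 at any contamination
    level, while a fully clonal heterozygous somatic variant has VAF
    (1 - kappa) / 2.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    carrier_weight = tv.copies * sum(weights.weights[c] for c in tv.carriers)
    vaf = ((1.0 - kappa) * carrier_weight + kappa * tv.normal_copies) / 2.0
    return float(min(vaf, 1.0))


def with_true_vaf(tv: TruthVariant, weights: CloneWeights, kappa: float) -> TruthVariant:
    """Return a copy of ``tv`` with ``true_vaf`` filled in for this mixture."""
    from dataclasses import replace

    return replace(tv, true_vaf=compute_true_vaf(tv, weights, kappa))
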