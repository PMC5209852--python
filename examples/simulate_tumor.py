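"""Simulate a heterogeneous tumor-normal exome experiment from a seed.

Draws a clonal ancestry tree, Dirichlet(1/8) clone proportions, and a
random truth variant set over a synthetic reference, then mixes clone
reads with 20% normal contamination into a tumor sample.
"""

from somabench.core import MixtureSpec, Origin
from somabench.pipeline import (
    PipelineConfig,
    build_genomes,
    simulate_sample,
    simulate_truth,
)

config = PipelineConfig(
    seed=1,
    genome_length=100_000,
    n_targets=20,
    n_somatic=200,
    n_germline=400,
    kappa=0.2,
    depth=50.0,
)
sim = simulate_truth(config)

print("clonal tree (child <- parent):")
for child, parent in sorted(sim.tree.parent.items()):
    print(f"  {child} <- {parent}")
print("\nclone weights (Dirichlet alpha = 1/8):")
for clone, w in sorted(sim.weights.weights.items()):
    print(f"  clone {clone}: {w:.4f}")

somatic = [tv for tv in sim.truth if tv.origin is Origin.SOMATIC]
germline = [tv for tv in sim.truth if tv.origin is Origin.GERMLINE]
vafs = sorted(tv.true_vaf for tv in somatic)
print(f"\n{len(somatic)} somatic and {len(germline)} germline truth variants")
print(
    "somatic true-VAF quartiles at kappa=0.2: "
    f"{vafs[len(vafs)//4]:.3f} / {vafs[len(vafs)//2]:.3f} / {vafs[3*len(vafs)//4]:.3f}"
)
# Low quartile VAFs come from subclonal variants carried by light clones;
# the theoretical ceiling is (1-kappa) = 0.8 for clonal heterozygous x2.

genomes = build_genomes(sim, seed=config.seed)
tumor, normal = simulate_sample(
    sim, genomes, MixtureSpec(kappa=0.2, coverage_level=50.0, seed=1), config
)
n_contam = int((tumor.clone == 0).sum())
print(f"\ntumor pool: {len(tumor)} reads, {n_contam} from the normal genome "
      f"({100 * n_contam / len(tumor):.1f}% ~ kappa)")
print(f"matched normal pool: {len(normal)} reads")
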