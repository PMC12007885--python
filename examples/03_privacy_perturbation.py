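"""Generate privacy-perturbed synthetic samples for one ancestry group.

The constrained randomized response flips a homozygous genotype (0 or 2)
to heterozygous with probability 2/(e^eps + 2) and a heterozygous one to
either homozygote with probability 1/(e^eps + 2) each; direct 0 <-> 2
flips never happen. At eps = 6 roughly 0.5% of homozygous calls change.
"""

import numpy as np

from genosynth import (
    FounderConfig,
    LDPParams,
    SynthesisConfig,
    apply_qc,
    fit_pca,
    group_geometry,
    simulate_founders,
    synthesize_group,
)
from genosynth.stratify import geometry_for

params = LDPParams(epsilon=6.0)
print(f"eps=6: q_extreme={params.q_extreme:.3e}, q_het={params.q_het:.3e}")
print("transition matrix:\n", params.transition_matrix().round(5))

founders = simulate_founders(
    FounderConfig(
        group_sizes={"African": 200, "European": 200},
        n_snps=500,
        fst=0.1,
        maf_range=(0.1, 0.5),
        seed=2,
    )
)
clean, _ = apply_qc(founders)
model = fit_pca(clean)
geoms = group_geometry(model, clean)

rng = np.random.default_rng(3)
synthetic = synthesize_group(
    clean.for_ancestry("African"),
    model,
    geometry_for(geoms, "African"),
    SynthesisConfig(per_group_target=1000),
    params,
    rng,
)
orig = clean.for_ancestry("African")
orig_maf = orig.genotypes.mean(axis=0) / 2
syn_maf = synthetic.genotypes.mean(axis=0) / 2
print(f"synthetic samples: {synthetic.n_samples}")
print(f"max |allele-frequency gap| original vs synthetic: {np.abs(orig_maf - syn_maf).max():.4f}")
# Small gap = the perturbation preserves allele-frequency structure while
# guaranteeing no synthetic sample is identical to its source.
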