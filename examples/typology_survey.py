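"""Measure predictive structure across a synthetic corpus of kinship systems.

Generates three small corpora whose languages plant predictive structure at
rho = 0 (none), 0.5 (partial) and 1 (maximal), scores every language's
symmetric conditional entropy against its own 1,000-shuffle baseline, and
prints the mean z-score and the share of languages classified significantly
low. Negative z means more predictive structure than chance; z < -1.96 marks
a significant degree of it.
"""

import numpy as np

from kinstruct import (
    GeneratorSpec,
    generate_system,
    load_inventory,
    permutation_baseline,
    symmetric_conditional_entropy,
)
from kinstruct.permutation import derive_seed

inventory = load_inventory("default")
statistic = lambda s: symmetric_conditional_entropy(s, inventory).h_sym

print("rho    mean z   % significantly low")
for rho in (0.0, 0.5, 1.0):
    spec = GeneratorSpec(n_languages=25, predictiveness=rho, seed=42)
    zs, n_low = [], 0
    for i in range(spec.n_languages):
        lang = f"rho{rho}_lang{i}"
        rng = np.random.default_rng(derive_seed(spec.seed, lang))
        system = generate_system(spec, inventory, rng, system_id=lang)
        result = permutation_baseline(
            system, inventory, statistic,
            n_permutations=1000, seed=derive_seed(spec.seed, "perm:" + lang),
        )
        zs.append(result.z)
        n_low += result.classification == "significantly_low"
    print(f"{rho:.1f}  {np.mean(zs):8.2f}   {100 * n_low / spec.n_languages:5.1f}%")

print()
print("Languages built with rho = 1 sit far below their baselines (strong")
print("predictive structure); rho = 0 languages are indistinguishable from chance.")
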