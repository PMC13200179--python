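"""Compute wACSF descriptors and classify test structures by similarity regime.

Generates a small training set of synthetic coordination complexes, then
measures how far new structures sit from it in descriptor space (nearest
neighbor distance, normalized by the training set's own mean nearest-neighbor
distance) and maps the distances onto the identical / familiar / unfamiliar /
strange regimes used to anticipate prediction reliability.
"""

import numpy as np

from awespec import (SyntheticConfig, classify_regime, compute_wacsf_atom,
                     generate_complex, generate_dataset, mean_nn_distance,
                     nearest_neighbor_distance)

from awespec.io_formats import Molecule

train = generate_dataset(SyntheticConfig(n_samples=300, seed=0))
train_x = np.stack([compute_wacsf_atom(m, m.absorber_index) for m, _ in train])
normalizer = mean_nn_distance(train_x)
print(f"training set: {len(train)} complexes, descriptor dim {train_x.shape[1]}")
print(f"mean nearest-neighbor distance (normalizer): {normalizer:.2f}\n")

base = train[3][0]
rng = np.random.default_rng(0)


def jitter(sd):
    return Molecule(base.elements,
                    base.coords + rng.normal(0, sd, base.coords.shape),
                    base.absorber_index)


probes = {
    "training copy": base,
    "jittered copy (0.003 Å)": jitter(3e-3),
    "jittered copy (0.05 Å)": jitter(5e-2),
    "fresh in-distribution": generate_complex(SyntheticConfig(seed=99), 0),
    "stretched bonds + P/Br ligands": generate_complex(
        SyntheticConfig(seed=99, first_shell_mean=3.2,
                        ligand_elements=("P", "Br")), 1),
}
for name, mol in probes.items():
    x = compute_wacsf_atom(mol, mol.absorber_index)
    d = nearest_neighbor_distance(x, train_x, normalizer)
    print(f"{name:32s} d = {d:8.4f}  ->  {classify_regime(d)}")
print("\nLarger d means the absorber's environment is less like anything in")
print("training; predictions in the 'strange' regime should not be trusted.")
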