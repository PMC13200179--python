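"""Reproducible desk-scale experiments on the synthetic benchmark.

Each function builds its inputs from the synthetic generator, runs the full
pipeline (descriptors -> encoder -> basis -> training -> evaluation) and
returns plain dictionaries of numbers.  These are the canonical study
conditions used by the examples and the acceptance checks:

* benchmark          - n=600 complexes (generator seed 0), 80/20 split,
                       AWE-wACSF, 300 epochs, batch 32, lr 2e-3 halved every
                       100 epochs.
* second shell       - 240 paired molecules whose first shells are identical
                       within a pair and whose second-shell composition (C vs
                       N at ~3.5 Å) carries the only class signal; absorber
                       descriptors use a 3.0 Å cutoff so the absorber-only
                       baseline is blind to it; basis lambda 1e-4 for a low
                       codec floor; 400 epochs; three seeds.
* regime curve       - the benchmark model evaluated on constructed
                       identical/familiar/unfamiliar/strange batches.
* bootstrap UQ       - M=8 ensemble on a 300-sample benchmark, evaluated on
                       a mixed-jitter test set spanning easy to hard.
"""

from __future__ import annotations

import numpy as np

from .awe_model import AoModel, AweModel
from .descriptors import WacsfConfig, WacsfProvider, compute_wacsf_atom
from .io_formats import Molecule
from .spectral_basis import BasisConfig, build_basis
from .synthetic_data import (GroundTruthParams, SyntheticConfig,
                             generate_dataset, generate_ood_split,
                             ground_truth_spectrum, second_shell_task)
from .train_eval_uq import (TrainConfig, bootstrap_train, evaluate_model,
                            pack_dataset, per_sample_losses, split_dataset,
                            train_model, uncertainty_report)

__all__ = ["run_benchmark", "run_second_shell_experiment",
           "run_regime_experiment", "run_uq_experiment"]


def run_benchmark(train_seed: int = 1, n_samples: int = 600,
                  data_seed: int = 0, epochs: int = 300):
    """Train AWE-wACSF on the standard synthetic benchmark.

    Returns (results dict, context dict); the context carries the trained
    model and the split for follow-up analyses.
    """
    basis = build_basis(GroundTruthParams().grid(), BasisConfig())
    provider = WacsfProvider()
    pairs = generate_dataset(SyntheticConfig(n_samples=n_samples, seed=data_seed))
    train, test = split_dataset(pairs, 0.2, seed=train_seed)
    train_data = pack_dataset(train, provider, basis)
    test_data = pack_dataset(test, provider, basis)
    model = AweModel(provider, basis, np.random.default_rng(train_seed))
    history = train_model(model, train_data,
                          TrainConfig(epochs=epochs, seed=train_seed))
    summary = evaluate_model(model, test_data)
    results = {
        "median_loss": summary.median, "q1": summary.q1, "q3": summary.q3,
        "whisker_low": summary.whisker_low, "whisker_high": summary.whisker_high,
        "final_train_loss": history[-1], "n_train": len(train), "n_test": len(test),
    }
    context = {"model": model, "train": train, "test": test, "basis": basis,
               "provider": provider, "history": history}
    return results, context


def run_second_shell_experiment(seeds=(0, 1, 2), n_samples: int = 240,
                                epochs: int = 400):
    """AWE vs AO on the second-shell sensitivity task.

    Both models see identical 3.0 Å-cutoff absorber-atom descriptor inputs;
    only the AWE model also aggregates the environment (7 Å shells), which is
    where the class signal lives.  Returns per-seed median test losses.
    """
    basis = build_basis(GroundTruthParams().grid(),
                        BasisConfig(ridge_lambda=1e-4))
    wacsf = WacsfConfig(cutoff_radius=3.0,
                        radial_centers=tuple(np.linspace(0.5, 3.0, 17)[1:]))
    provider = WacsfProvider(config=wacsf)
    triples = second_shell_task(SyntheticConfig(
        n_samples=n_samples, seed=0, first_shell_sd=0.05))
    pairs = [(m, s) for m, s, _ in triples]
    per_seed = []
    for seed in seeds:
        train, test = split_dataset(pairs, 0.2, seed=seed)
        train_data = pack_dataset(train, provider, basis)
        test_data = pack_dataset(test, provider, basis)
        awe = AweModel(provider, basis, np.random.default_rng(seed))
        train_model(awe, train_data, TrainConfig(epochs=epochs, seed=seed))
        ao = AoModel(provider.dimension, len(basis.grid),
                     np.random.default_rng(seed + 500))
        train_model(ao, train_data, TrainConfig(epochs=epochs, seed=seed + 500))
        per_seed.append({"seed": seed,
                         "awe_median": evaluate_model(awe, test_data).median,
                         "ao_median": evaluate_model(ao, test_data).median})
    wins = sum(r["awe_median"] < r["ao_median"] for r in per_seed)
    return {"per_seed": per_seed, "awe_wins": wins, "n_seeds": len(seeds)}


def run_regime_experiment(context: dict | None = None, n_per_regime: int = 60):
    """Median loss per constructed similarity regime for one trained model."""
    if context is None:
        _, context = run_benchmark()
    model, train = context["model"], context["train"]
    provider, basis = context["provider"], context["basis"]
    splits = generate_ood_split(SyntheticConfig(seed=0), train,
                                wacsf=provider.config,
                                n_per_regime=n_per_regime)
    medians = {}
    for label, batch in splits.items():
        data = pack_dataset(batch, provider, basis)
        medians[label] = evaluate_model(model, data).median
    order = ["identical", "familiar", "unfamiliar", "strange"]
    monotone = all(medians[a] <= medians[b] for a, b in zip(order, order[1:]))
    return {"medians": medians, "monotone": monotone}


def _mixed_jitter_test_set(train, rng, jitter_scales=(0.005, 0.05, 0.2, 0.5),
                           per_scale: int = 15):
    """Jittered training structures spanning easy to hard difficulty."""
    pairs = []
    for sd in jitter_scales:
        for i in rng.choice(len(train), per_scale, replace=False):
            base = train[i][0]
            coords = base.coords + rng.normal(0.0, sd, size=base.coords.shape)
            coords -= coords[base.absorber_index]
            mol = Molecule(base.elements, coords, base.absorber_index)
            pairs.append((mol, ground_truth_spectrum(mol)))
    return pairs


def run_uq_experiment(base_seed: int = 11, n_samples: int = 300,
                      n_members: int = 8, epochs: int = 120):
    """Bootstrap-ensemble uncertainty on a mixed-difficulty test set.

    Returns the spread/error Pearson correlation and the ensemble-mean versus
    median single-member error comparison.
    """
    basis = build_basis(GroundTruthParams().grid(), BasisConfig())
    provider = WacsfProvider()
    pairs = generate_dataset(SyntheticConfig(n_samples=n_samples, seed=0))
    train, _ = split_dataset(pairs, 0.2, seed=1)
    train_data = pack_dataset(train, provider, basis)
    test_pairs = _mixed_jitter_test_set(
        train, np.random.Generator(np.random.PCG64(
            np.random.SeedSequence((base_seed, 5)))))
    test_data = pack_dataset(test_pairs, provider, basis)

    def factory(rng):
        return AweModel(provider, basis, rng)

    ensemble = bootstrap_train(train_data, n_members, base_seed,
                               TrainConfig(epochs=epochs, seed=base_seed),
                               factory)
    report = uncertainty_report(ensemble, test_data)
    member_mean_errors = [float(np.mean(per_sample_losses(m, test_data)))
                          for m in ensemble.members]
    return {"pearson_r": report.pearson_r,
            "ensemble_mean_error": float(np.mean(report.losses)),
            "median_member_error": float(np.median(member_mean_errors)),
            "spreads": report.spreads, "losses": report.losses,
            "n_test": len(test_pairs), "n_members": n_members}
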