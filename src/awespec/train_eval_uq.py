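"""Training loop, held-out evaluation with box statistics, similarity-regime
curves, and bootstrap-ensemble uncertainty quantification.

Training minimizes the composite objective (MS-SSIM spectral loss plus
coefficient MSE) for environment-aware models, or the MS-SSIM loss on the
gridded output for the absorber-only baseline, with Adam on minibatches of 32
and a step-decayed learning rate lr0 * 0.5^floor(epoch / period).  For the
environment-aware models the MS-SSIM target is the ridge reconstruction
Phi c_ref of the reference spectrum, so both loss terms see the same
representation; evaluation always scores predictions against the raw
reference spectrum.

Uncertainty comes from bootstrap ensembles: M models trained on
with-replacement resamples of the training split (resampling never touches
the held-out set), whose pointwise prediction spread is summarized per sample
and correlated with the realized error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as st

from .autodiff import Tensor
from .awe_model import AweModel, pack_descriptor_sets
from .descriptors import (DescriptorProvider, classify_regime,
                          compute_descriptor_set, mean_nn_distance,
                          nearest_neighbor_distance)
from .exceptions import NumericalError
from .io_formats import Molecule, Spectrum
from .nn import Adam
from .similarity_loss import MsSsimConfig, ms_ssim_loss, ms_ssim_loss_tensor
from .spectral_basis import GaussianBasis

__all__ = ["TrainConfig", "EvalSummary", "EnsembleModel", "UncertaintyReport",
           "PackedDataset", "split_dataset", "pack_dataset", "train_model",
           "evaluate_model", "regime_curve", "bootstrap_train",
           "ensemble_predict", "uncertainty_error_correlation",
           "learning_rate_at"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 32
    lr0: float = 2e-3
    lr_halving_period: int = 100
    seed: int = 0
    test_fraction: float = 0.20

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.lr0 <= 0 \
                or self.lr_halving_period < 1:
            raise ValueError("training hyperparameters must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test fraction must lie in (0, 1)")


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Step-decayed learning rate: lr0 halved every ``lr_halving_period`` epochs."""
    return config.lr0 * 0.5 ** (epoch // config.lr_halving_period)


def split_dataset(pairs: list, fraction: float, seed: int) -> tuple[list, list]:
    """Disjoint, exhaustive, seed-reproducible train/test split."""
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least two samples to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n_test = min(max(round(fraction * n), 1), n - 1)
    order = np.random.Generator(np.random.PCG64(seed)).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [pairs[i] for i in range(n) if i not in test_idx]
    test = [pairs[i] for i in range(n) if i in test_idx]
    return train, test


@dataclass
class PackedDataset:
    """Descriptors, padded environment arrays and training targets."""

    batch: dict                 # x0 / xenv / renv / mask arrays, length n
    y_raw: np.ndarray           # (n, N_E) reference spectra
    y_target: np.ndarray        # (n, N_E) MS-SSIM target (basis reconstruction)
    c_ref: np.ndarray           # (n, K) reference coefficients
    molecules: list[Molecule]

    def __len__(self) -> int:
        return self.y_raw.shape[0]

    def subset(self, idx) -> dict:
        idx = np.asarray(idx)
        return {k: v[idx] for k, v in self.batch.items()}


def pack_dataset(pairs: list[tuple[Molecule, Spectrum]],
                 provider: DescriptorProvider, basis: GaussianBasis,
                 cutoff: float = 7.0) -> PackedDataset:
    """Precompute descriptors and coefficient targets once for a dataset."""
    dsets = [compute_descriptor_set(m, provider) for m, _ in pairs]
    batch = pack_descriptor_sets(dsets, cutoff)
    y_raw = np.stack([s.intensities for _, s in pairs])
    c_ref = y_raw @ basis.ridge_op.T
    y_target = c_ref @ basis.phi.T
    return PackedDataset(batch=batch, y_raw=y_raw, y_target=y_target,
                         c_ref=c_ref, molecules=[m for m, _ in pairs])


def _batch_loss(model, data: PackedDataset, idx: np.ndarray,
                ssim_config: MsSsimConfig, rng, training: bool) -> Tensor:
    if isinstance(model, AweModel):
        c, yhat = model.forward(data.subset(idx), rng=rng, training=training)
        ssim = ms_ssim_loss_tensor(yhat, data.y_target[idx], ssim_config)
        diff = c - data.c_ref[idx]
        return ssim + (diff * diff).mean()
    yhat = model.forward(data.batch["x0"][idx])
    return ms_ssim_loss_tensor(yhat, data.y_raw[idx], ssim_config)


def train_model(model, data: PackedDataset, config: TrainConfig,
                ssim_config: MsSsimConfig = MsSsimConfig()) -> list[float]:
    """Minibatch Adam optimization; returns the per-epoch mean loss history."""
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((config.seed, 1))))
    dropout_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((config.seed, 2))))
    if hasattr(model, "fit_input_scaling"):
        model.fit_input_scaling(data.batch)  # descriptor standardization, train split only
    optimizer = Adam(model.parameters(), lr=config.lr0)
    n = len(data)
    history: list[float] = []
    for epoch in range(config.epochs):
        optimizer.lr = learning_rate_at(epoch, config)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            optimizer.zero_grad()
            loss = _batch_loss(model, data, idx, ssim_config, dropout_rng,
                               training=True)
            value = loss.item()
            if not np.isfinite(value):
                raise NumericalError(
                    f"non-finite loss at epoch {epoch}, batch indices {idx.tolist()}")
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        history.append(float(np.mean(epoch_losses)))
    return history


# ------------------------------------------------------------------ evaluation
@dataclass(frozen=True)
class EvalSummary:
    """Per-sample MS-SSIM losses with box-plot statistics.

    Whiskers follow the Tukey convention: the most extreme samples within
    1.5 IQR of the quartiles ("non-outlier bounds").
    """

    losses: np.ndarray
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float

    @classmethod
    def from_losses(cls, losses: np.ndarray) -> "EvalSummary":
        losses = np.asarray(losses, dtype=float)
        if losses.size == 0:
            raise ValueError("cannot summarize an empty loss list")
        q1, med, q3 = np.quantile(losses, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        inside = losses[(losses >= q1 - 1.5 * iqr) & (losses <= q3 + 1.5 * iqr)]
        return cls(losses=losses, q1=float(q1), median=float(med), q3=float(q3),
                   whisker_low=float(inside.min()), whisker_high=float(inside.max()))


def predict_spectra(model, data: PackedDataset) -> np.ndarray:
    """Deterministic batched inference on a packed dataset."""
    if isinstance(model, AweModel):
        _, yhat = model.forward(data.batch, training=False)
    else:
        yhat = model.forward(data.batch["x0"])
    return yhat.data


def per_sample_losses(model, data: PackedDataset,
                      ssim_config: MsSsimConfig = MsSsimConfig()) -> np.ndarray:
    yhat = predict_spectra(model, data)
    return np.array([ms_ssim_loss(yhat[i], data.y_raw[i], ssim_config)
                     for i in range(len(data))])


def evaluate_model(model, data: PackedDataset,
                   ssim_config: MsSsimConfig = MsSsimConfig()) -> EvalSummary:
    """MS-SSIM loss of every held-out sample against its reference spectrum."""
    if len(data) == 0:
        raise ValueError("empty evaluation set")
    return EvalSummary.from_losses(per_sample_losses(model, data, ssim_config))


def regime_curve(model, test_data: PackedDataset, training_X: np.ndarray,
                 ssim_config: MsSsimConfig = MsSsimConfig(),
                 normalizer: float | None = None) -> dict[str, EvalSummary]:
    """Per-regime evaluation summaries keyed by regime label.

    Test samples are assigned via the nearest-neighbor descriptor distance of
    their absorber descriptor (row 0 of the packed features) to the training
    matrix; empty regimes are absent from the result, not reported as zero.
    """
    if normalizer is None:
        normalizer = mean_nn_distance(training_X)
    losses = per_sample_losses(model, test_data, ssim_config)
    regimes = [classify_regime(nearest_neighbor_distance(
        test_data.batch["x0"][i], training_X, normalizer))
        for i in range(len(test_data))]
    out: dict[str, EvalSummary] = {}
    for label in ("identical", "familiar", "unfamiliar", "strange"):
        sel = [i for i, r in enumerate(regimes) if r == label]
        if sel:
            out[label] = EvalSummary.from_losses(losses[sel])
    return out


# -------------------------------------------------------------------- ensembles
@dataclass
class EnsembleModel:
    """Bootstrap ensemble: member models plus their resample indices and seeds."""

    members: list
    resample_indices: list[np.ndarray]
    member_seeds: list[int]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least two members")


@dataclass(frozen=True)
class UncertaintyReport:
    mean_predictions: np.ndarray   # (n, N_E)
    spreads: np.ndarray            # (n,) grid-mean of the pointwise std
    losses: np.ndarray             # (n,) realized MS-SSIM loss of the mean prediction
    pearson_r: float               # nan if undefined (zero variance)


def bootstrap_train(train_data: PackedDataset, m_members: int, base_seed: int,
                    config: TrainConfig, model_factory,
                    ssim_config: MsSsimConfig = MsSsimConfig()) -> EnsembleModel:
    """Train M models on with-replacement resamples of the training split.

    ``model_factory(rng)`` builds a fresh, identically configured model.
    Resample size equals the training size; indices are recorded for audit.
    Reproducible: the same base seed yields the same ensemble.
    """
    if m_members < 2:
        raise ValueError("bootstrap requires at least two members")
    n = len(train_data)
    members, indices, seeds = [], [], []
    for m in range(m_members):
        seq = np.random.SeedSequence((base_seed, m))
        member_seed = int(seq.generate_state(1)[0] % (2 ** 31))
        rng = np.random.Generator(np.random.PCG64(seq))
        resample = rng.integers(0, n, size=n)
        sub = PackedDataset(batch=train_data.subset(resample),
                            y_raw=train_data.y_raw[resample],
                            y_target=train_data.y_target[resample],
                            c_ref=train_data.c_ref[resample],
                            molecules=[train_data.molecules[i] for i in resample])
        model = model_factory(np.random.Generator(np.random.PCG64(member_seed)))
        member_config = TrainConfig(epochs=config.epochs,
                                    batch_size=config.batch_size,
                                    lr0=config.lr0,
                                    lr_halving_period=config.lr_halving_period,
                                    seed=member_seed,
                                    test_fraction=config.test_fraction)
        train_model(model, sub, member_config, ssim_config)
        members.append(model)
        indices.append(resample)
        seeds.append(member_seed)
    return EnsembleModel(members=members, resample_indices=indices,
                         member_seeds=seeds)


def ensemble_predict_batch(ensemble: EnsembleModel, data: PackedDataset
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean spectra, pointwise std, per-sample spread scalar) over members."""
    preds = np.stack([predict_spectra(m, data) for m in ensemble.members])
    mean = preds.mean(axis=0)
    std = preds.std(axis=0)          # population std over members
    return mean, std, std.mean(axis=-1)


def ensemble_predict(ensemble: EnsembleModel, mol: Molecule
                     ) -> tuple[Spectrum, np.ndarray, float]:
    """Single-molecule ensemble prediction (mean spectrum, std, spread)."""
    model0 = ensemble.members[0]
    data = PackedDataset(batch=model0.pack_molecule(mol),
                         y_raw=np.zeros((1, model0.basis.grid.energies.size)),
                         y_target=np.zeros((1, model0.basis.grid.energies.size)),
                         c_ref=np.zeros((1, model0.basis.n_functions)),
                         molecules=[mol])
    mean, std, spread = ensemble_predict_batch(ensemble, data)
    return Spectrum(model0.basis.grid, mean[0]), std[0], float(spread[0])


def uncertainty_error_correlation(spreads: np.ndarray,
                                  losses: np.ndarray) -> float:
    """Pearson r between ensemble spread and realized loss; nan if undefined."""
    spreads = np.asarray(spreads, dtype=float)
    losses = np.asarray(losses, dtype=float)
    if spreads.size != losses.size or spreads.size < 3:
        raise ValueError("need at least three paired samples")
    if np.std(spreads) == 0 or np.std(losses) == 0:
        return float("nan")
    return float(st.pearsonr(spreads, losses).statistic)


def uncertainty_report(ensemble: EnsembleModel, test_data: PackedDataset,
                       ssim_config: MsSsimConfig = MsSsimConfig()
                       ) -> UncertaintyReport:
    mean, _, spread = ensemble_predict_batch(ensemble, test_data)
    losses = np.array([ms_ssim_loss(mean[i], test_data.y_raw[i], ssim_config)
                       for i in range(len(test_data))])
    return UncertaintyReport(mean_predictions=mean, spreads=spread,
                             losses=losses,
                             pearson_r=uncertainty_error_correlation(spread, losses))
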