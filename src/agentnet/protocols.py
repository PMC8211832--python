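"""Reference desk-scale studies: simulate, train, and measure end to end.

These functions bundle the package's standard validation experiments at
sizes a single CPU core handles in minutes (the methods note discusses
the choices):

* `ca_study` — train on 2,000 grid transitions, score held-out per-cell
  accuracy, and track how attention separates Moore neighbors from the
  rest of the grid over training.
* `vicsek_study` — train on one-step transitions of a 40-agent vision-
  sector flock (cone read as a 120-degree total field of view so the
  recovered width is commensurate with the configured angle), then
  recover the interaction sector from heading-aligned attention maps.
* `aoup_spacing_study` — integrate the confined active-particle system
  to a clustered steady state and estimate the hexagonal lattice
  constant from the pair-distance distribution.

Every study derives all of its randomness from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .model import AgentNet, ModelConfig
from .simulators import aoup as aoup_mod
from .simulators import ca as ca_mod
from .simulators import vicsek as vicsek_mod
from .simulators.datasets import generate_ca, generate_vicsek
from .training import TrainConfig, TrainingLog, ca_accuracy, train
from .utils import rng_from

CA_STUDY = dict(n_train=2000, n_test=100, epochs=26, lr=2e-3, batch_size=32,
                plateau_patience=8)
VICSEK_STUDY = dict(n_agents=40, n_train=1800, n_test=150, epochs=26,
                    lr=2e-3, batch_size=32, plateau_patience=8)
AOUP_STUDY = dict(n_particles=100, n_steps=50_000, T=0.02, D_a=0.2, k=0.1,
                  dt=0.05, snapshots=10)


@dataclass
class CAStudyResult:
    model: AgentNet
    accuracy: float                  # held-out per-cell accuracy in [0, 1]
    log: TrainingLog
    neighbor_alpha: np.ndarray       # per epoch: mean alpha of Moore pairs
    outside_alpha: np.ndarray        # per epoch: mean alpha of other pairs
    test_dataset: object


def ca_attention_profile(model: AgentNet, inputs: np.ndarray) -> np.ndarray:
    """Mean attention map alpha^c over frames, (n_cells, n_cells)."""
    alphas = []
    for start in range(0, inputs.shape[0], 32):
        res = model.forward(inputs[start:start + 32])
        alphas.append(res.alpha_full()[..., 0])
    return np.concatenate(alphas).mean(axis=0)


def ca_study(seed: int, n_train: int | None = None,
             epochs: int | None = None) -> CAStudyResult:
    p = dict(CA_STUDY)
    if n_train is not None:
        p["n_train"] = n_train
    if epochs is not None:
        p["epochs"] = epochs
    config = ca_mod.CAConfig()
    train_ds = generate_ca(config, p["n_train"], seed=int(rng_from(
        seed, "ca-train").integers(2**31)))
    test_ds = generate_ca(config, p["n_test"], seed=int(rng_from(
        seed, "ca-test").integers(2**31)))
    model = AgentNet(ModelConfig.for_system("ca", dtype="float32"),
                     seed=seed)
    neigh_mask = ca_mod.neighbor_mask(config)
    off = ~np.eye(neigh_mask.shape[0], dtype=bool)
    probe = test_ds.inputs[:20]
    neigh_curve, out_curve = [], []

    def track(epoch, m, entry):
        amap = ca_attention_profile(m, probe)
        neigh_curve.append(float(amap[neigh_mask].mean()))
        out_curve.append(float(amap[off & ~neigh_mask].mean()))

    log = train(model, train_ds, TrainConfig(
        epochs=p["epochs"], batch_size=p["batch_size"], lr=p["lr"],
        plateau_patience=p["plateau_patience"], seed=seed,
    ), epoch_callback=track)
    acc = ca_accuracy(model, test_ds)
    return CAStudyResult(model=model, accuracy=acc, log=log,
                         neighbor_alpha=np.asarray(neigh_curve),
                         outside_alpha=np.asarray(out_curve),
                         test_dataset=test_ds)


def ca_halfmax_neighbor_count(model: AgentNet, inputs: np.ndarray,
                              cell: int = 7 * 14 + 7) -> int:
    """Number of cells whose mean attention toward `cell` exceeds half of
    the map maximum (a bulk cell has eight Moore neighbors)."""
    amap = ca_attention_profile(model, inputs)[cell]
    return int((amap >= 0.5 * amap.max()).sum())


@dataclass
class VicsekStudyResult:
    model: AgentNet
    sector: analysis.SectorResult        # from the x-variable attention
    sector_y: analysis.SectorResult
    roc_auc: float
    log: TrainingLog
    test_dataset: object
    config: vicsek_mod.VicsekConfig


def vicsek_study(seed: int, epochs: int | None = None) -> VicsekStudyResult:
    p = dict(VICSEK_STUDY)
    if epochs is not None:
        p["epochs"] = epochs
    config = vicsek_mod.VicsekConfig(n_agents=p["n_agents"],
                                     sector_is_full_angle=True)
    train_ds = generate_vicsek(config, p["n_train"], seed=int(rng_from(
        seed, "vm-train").integers(2**31)))
    test_ds = generate_vicsek(config, p["n_test"], seed=int(rng_from(
        seed, "vm-test").integers(2**31)))
    model = AgentNet(ModelConfig.for_system("vicsek", dtype="float32"),
                     seed=seed)
    log = train(model, train_ds, TrainConfig(
        epochs=p["epochs"], batch_size=p["batch_size"], lr=p["lr"],
        plateau_patience=p["plateau_patience"], seed=seed,
    ))
    amap = analysis.attention_map(model, test_ds.inputs[:100])
    sector = analysis.sector_recovery(amap, var=0)
    sector_y = analysis.sector_recovery(amap, var=1)
    auc = vicsek_membership_auc(model, test_ds)
    return VicsekStudyResult(model=model, sector=sector, sector_y=sector_y,
                             roc_auc=auc, log=log, test_dataset=test_ds,
                             config=config)


def vicsek_membership_auc(model: AgentNet, dataset,
                          n_frames: int = 100) -> float:
    """ROC-AUC of attention against ground-truth sector membership."""
    from sklearn.metrics import roc_auc_score

    n = dataset.inputs.shape[1]
    off = ~np.eye(n, dtype=bool)
    alpha = []
    for start in range(0, min(n_frames, len(dataset)), 32):
        res = model.forward(dataset.inputs[start:start + 32])
        alpha.append(res.alpha_full()[..., 0])
    alpha = np.concatenate(alpha)
    m = alpha.shape[0]
    labels = dataset.membership[:m][:, off].ravel().astype(int)
    scores = alpha[:, off].ravel()
    return float(roc_auc_score(labels, scores))


def aoup_spacing_study(seed: int, R: float = 3.0,
                       n_steps: int | None = None) -> analysis.PeriodicityResult:
    p = dict(AOUP_STUDY)
    if n_steps is not None:
        p["n_steps"] = n_steps
    config = aoup_mod.AOUPConfig(
        n_particles=p["n_particles"], k=p["k"], T=p["T"], D_a=p["D_a"],
        dt=p["dt"], R=R,
    )
    rng = rng_from(seed, "aoup-spacing", int(R * 1000))
    store = max(p["n_steps"] // (2 * p["snapshots"]), 1)
    positions, _ = aoup_mod.simulate(config, p["n_steps"], rng,
                                     store_every=store)
    return analysis.hexagonal_periodicity(
        positions[-p["snapshots"]:], R, min_r=0.7 * R)
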