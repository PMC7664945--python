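"""Shipped hyperparameter presets for the three benchmark problem shapes.

Each preset carries the published per-dataset settings: two sparse
auto-encoder layers (hidden size, epoch cap, L2 coefficient, sparsity
coefficient, sparsity proportion), the PSO swarm settings for the
calibration stage, and the train/test protocol (50/50 for the epilepsy
shape, 70/30 for the other two, five repeats each).
"""

from __future__ import annotations

from .io import RunConfig
from .metrics import RepeatProtocol
from .pso import PSOConfig
from .sae import SparseAEConfig

__all__ = ["get_run_preset", "RUN_PRESETS"]


def _preset(
    ae1: tuple, ae2: tuple, pso: tuple, train_fraction: float
) -> RunConfig:
    hls1, men1, l2_1, sr1, sp1 = ae1
    hls2, men2, l2_2, sr2, sp2 = ae2
    particles, iters = pso
    return RunConfig(
        ae_configs=(
            SparseAEConfig(hls1, men1, l2_1, sr1, sp1, seed=0),
            SparseAEConfig(hls2, men2, l2_2, sr2, sp2, seed=1),
        ),
        pso=PSOConfig(
            n_particles=particles, max_iter=iters,
            cognitive=2.0, social=2.0,
            inertia_start=0.9, inertia_end=0.2,
        ),
        protocol=RepeatProtocol(n_repeats=5, train_fraction=train_fraction),
        # fine-tuning is capped below convergence on purpose: output
        # calibration corrects an imperfect network, so the presets stop
        # supervised training while residual training error remains
        finetune_epochs=100,
        finetune_lr=0.5,
        finetune_momentum=0.9,
    )


RUN_PRESETS: dict[str, RunConfig] = {
    # EEG epilepsy shape: 4096 -> 2007 -> 112, 50/50 split
    "epilepsy": _preset(
        ae1=(2007, 420, 0.004, 4.0, 0.14),
        ae2=(112, 110, 0.002, 2.0, 0.12),
        pso=(50, 30),
        train_fraction=0.5,
    ),
    # SPECTF heart shape: 44 -> 40 -> 35, 70/30 split
    "spectf": _preset(
        ae1=(40, 110, 0.003, 2.0, 0.1),
        ae2=(35, 60, 0.001, 1.0, 0.1),
        pso=(40, 40),
        train_fraction=0.7,
    ),
    # cardiac-arrhythmia shape: 279 -> 250 -> 200, 16 classes, 70/30 split
    "arrhythmia": _preset(
        ae1=(250, 130, 0.003, 3.0, 0.12),
        ae2=(200, 109, 0.001, 1.0, 0.1),
        pso=(60, 45),
        train_fraction=0.7,
    ),
}


def get_run_preset(name: str) -> RunConfig:
    """Named pipeline preset ('epilepsy', 'spectf' or 'arrhythmia')."""
    if name not in RUN_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(RUN_PRESETS)}"
        )
    return RUN_PRESETS[name]
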