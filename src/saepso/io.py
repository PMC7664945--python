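"""Delimited-text loading and run-configuration handling.

``load_tabular`` reads CSV / UCI ``.data``-style files (comma-delimited,
``?`` marking a missing value), median-imputes, min-max scales features to
[0, 1] and maps labels to 0..M-1 in first-appearance order.  ``RunConfig``
bundles every tunable of the pipeline and round-trips through YAML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, DataError
from .metrics import RepeatProtocol
from .preprocessing import MinMaxScaler, median_impute
from .pso import PSOConfig
from .sae import SparseAEConfig
from .stack import LabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_tabular",
    "load_config",
    "save_config",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the pipeline on one dataset."""

    ae_configs: tuple[SparseAEConfig, ...]
    pso: PSOConfig = PSOConfig()
    protocol: RepeatProtocol = RepeatProtocol()
    finetune_epochs: int = 400
    finetune_lr: float = 1.0
    finetune_momentum: float = 0.9
    feature_source: str = "deepest_encoding"
    linear_bounds: tuple[float, float] = (-5.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ae_configs:
            raise ConfigError("at least one auto-encoder layer is required")
        for prev, nxt in zip(self.ae_configs[:-1], self.ae_configs[1:]):
            if nxt.hidden_size >= prev.hidden_size:
                logger.warning(
                    "hidden sizes do not shrink: %d -> %d",
                    prev.hidden_size, nxt.hidden_size,
                )
        if self.feature_source not in ("original_input", "deepest_encoding"):
            raise ConfigError(
                f"unknown feature_source {self.feature_source!r}"
            )
        if self.finetune_epochs < 0 or self.finetune_lr < 0:
            raise ConfigError("finetune settings must be non-negative")
        if not 0.0 <= self.finetune_momentum < 1.0:
            raise ConfigError(
                f"finetune_momentum must lie in [0, 1), got {self.finetune_momentum}"
            )

    def pso_for_repeat(self, repeat_seed: int) -> PSOConfig:
        """The calibration-stage PSO config, reseeded per repeat and using
        the configured linear-parameter bounds."""
        return replace(
            self.pso,
            seed=(self.pso.seed + repeat_seed) % (2**31 - 1),
            bounds=tuple(self.linear_bounds),
        )


def load_tabular(
    path: str | Path,
    has_missing: bool = True,
    label_column: int = -1,
    scale: bool = True,
    train_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, LabelSet]:
    """Load a delimited numeric table with an integer label column.

    ``?`` cells are treated as missing and median-imputed (statistics from
    ``train_mask`` rows only, when a split is declared).  Features are
    min-max scaled to [0, 1] unless ``scale`` is False; labels are mapped to
    0..M-1 preserving first-appearance order.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, header=None,
            na_values=["?"] if has_missing else None,
            keep_default_na=False,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: ragged or malformed rows ({exc})") from exc
    if frame.shape[1] < 2:
        raise DataError(f"{path}: need at least one feature and a label column")

    label_pos = label_column % frame.shape[1]
    raw_labels = frame.iloc[:, label_pos]
    feats = frame.drop(columns=frame.columns[label_pos])
    try:
        x = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric feature value ({exc})") from exc

    if np.any(np.isnan(x)):
        x = median_impute(x, train_mask=train_mask)
    if scale:
        scaler = MinMaxScaler()
        ref = x if train_mask is None else x[train_mask]
        scaler.fit(ref)
        x = scaler.transform(x)

    # integer label columns keep their numeric order (so a generated dataset
    # round-trips exactly); anything else is coded in first-appearance order
    try:
        numeric = raw_labels.astype(float)
        is_integer = np.allclose(numeric, numeric.astype(int))
    except (TypeError, ValueError):
        is_integer = False
    if is_integer:
        values = numeric.astype(int).to_numpy()
        codes = {v: i for i, v in enumerate(sorted(set(values.tolist())))}
        mapped = np.array([codes[v] for v in values], dtype=int)
    else:
        codes = {}
        mapped = np.empty(len(raw_labels), dtype=int)
        for i, v in enumerate(raw_labels):
            if v not in codes:
                codes[v] = len(codes)
            mapped[i] = codes[v]
    return x, LabelSet(mapped, n_classes=max(len(codes), 2))


_AE_KEYS = {
    "hidden_size", "max_epochs", "l2_coeff", "sparsity_coeff",
    "sparsity_proportion", "seed",
}
_PSO_KEYS = {
    "n_particles", "max_iter", "cognitive", "social", "inertia_start",
    "inertia_end", "bounds", "vmax_fraction", "seed",
}
_PROTOCOL_KEYS = {"n_repeats", "train_fraction", "stratified", "seeds"}
_TOP_KEYS = {
    "ae_layers", "pso", "protocol", "finetune_epochs", "finetune_lr",
    "finetune_momentum", "feature_source", "linear_bounds", "seed",
}


def _filtered(mapping: dict, allowed: set, where: str) -> dict:
    unknown = set(mapping) - allowed
    if unknown:
        warnings.warn(f"ignoring unknown {where} key(s): {sorted(unknown)}")
    return {k: v for k, v in mapping.items() if k in allowed}


def config_from_dict(doc: dict) -> RunConfig:
    """Validated RunConfig from a plain mapping (YAML-shaped)."""
    if not isinstance(doc, dict) or "ae_layers" not in doc:
        raise ConfigError("configuration must be a mapping with 'ae_layers'")
    doc = _filtered(doc, _TOP_KEYS, "top-level")
    try:
        ae = tuple(
            SparseAEConfig(**_filtered(layer, _AE_KEYS, "auto-encoder"))
            for layer in doc["ae_layers"]
        )
        pso = PSOConfig(**{
            **_filtered(doc.get("pso", {}), _PSO_KEYS, "pso"),
        })
        if "bounds" in doc.get("pso", {}):
            pso = replace(pso, bounds=tuple(doc["pso"]["bounds"]))
        proto_doc = _filtered(doc.get("protocol", {}), _PROTOCOL_KEYS, "protocol")
        if proto_doc.get("seeds") is not None:
            proto_doc["seeds"] = tuple(proto_doc["seeds"])
        protocol = RepeatProtocol(**proto_doc)
        return RunConfig(
            ae_configs=ae,
            pso=pso,
            protocol=protocol,
            finetune_epochs=int(doc.get("finetune_epochs", 400)),
            finetune_lr=float(doc.get("finetune_lr", 1.0)),
            finetune_momentum=float(doc.get("finetune_momentum", 0.9)),
            feature_source=doc.get("feature_source", "deepest_encoding"),
            linear_bounds=tuple(doc.get("linear_bounds", (-5.0, 5.0))),
            seed=int(doc.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid configuration: {exc}") from exc


def config_to_dict(cfg: RunConfig) -> dict:
    doc = {
        "ae_layers": [asdict(c) for c in cfg.ae_configs],
        "pso": asdict(cfg.pso),
        "protocol": asdict(cfg.protocol),
        "finetune_epochs": cfg.finetune_epochs,
        "finetune_lr": cfg.finetune_lr,
        "finetune_momentum": cfg.finetune_momentum,
        "feature_source": cfg.feature_source,
        "linear_bounds": list(cfg.linear_bounds),
        "seed": cfg.seed,
    }
    doc["pso"]["bounds"] = list(np.ravel(doc["pso"]["bounds"]).tolist())
    if doc["protocol"]["seeds"] is not None:
        doc["protocol"]["seeds"] = list(doc["protocol"]["seeds"])
    return doc


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML ({exc})") from exc
    return config_from_dict(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def save_network(network, path: str | Path) -> None:
    """Serialize a stacked network (encoder halves + Softmax) to JSON."""
    import json

    doc = {
        "n_classes": network.n_classes,
        "encoders": [
            {
                "encoder_weights": e.encoder_weights.tolist(),
                "encoder_bias": e.encoder_bias.tolist(),
                "decoder_weights": e.decoder_weights.tolist(),
                "decoder_bias": e.decoder_bias.tolist(),
            }
            for e in network.encoders
        ],
        "softmax_weights": network.softmax_weights.tolist(),
        "softmax_bias": network.softmax_bias.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_network(path: str | Path):
    import json

    from .sae import AEWeights
    from .stack import StackedNetwork

    doc = json.loads(Path(path).read_text())
    encoders = [
        AEWeights(
            np.asarray(e["encoder_weights"]),
            np.asarray(e["encoder_bias"]),
            np.asarray(e["decoder_weights"]),
            np.asarray(e["decoder_bias"]),
        )
        for e in doc["encoders"]
    ]
    return StackedNetwork(
        encoders,
        np.asarray(doc["softmax_weights"]),
        np.asarray(doc["softmax_bias"]),
        doc["n_classes"],
    )
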