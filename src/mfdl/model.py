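"""The multimodal functional deep-learning model.

One functional neural subnet per omics modality maps its variant function to
a low-dimensional embedding Z_k^(D_k); the embeddings are concatenated
column-wise into the shared representation Z_wide, and a plain feedforward
head maps Z_wide to the phenotype (identity link, so scalar and vector
phenotypes are handled by the head's output width).

A modality that is a scalar or a low-dimensional matrix (e.g. expression of a
handful of genes) is not suitable for functional smoothing; its subnet
degenerates to plain dense layers — with every modality dense the whole model
is an ordinary deep neural network.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .basis import make_bspline_system, uniform_grid, DEFAULT_GRID_SIZE
from .functional import (
    CovariateBlock,
    DenseLayer,
    FunctionalFirstLayer,
    FunctionalHiddenLayer,
    FunctionalOutputLayer,
    OmicsVariantFunction,
    dirac_design,
)

__all__ = ["SubnetConfig", "HeadConfig", "MFDLModel", "build_model", "concat_shared"]


@dataclass
class SubnetConfig:
    """Architecture of one per-modality subnet.

    ``marker_basis``/``layer_basis`` are (order, n_basis) pairs; the marker
    basis expands the first-layer weight surface over the variant positions,
    the layer basis parameterizes every deeper functional layer.
    """

    modality_kind: str = "functional"          # "functional" | "dense"
    n_hidden_functional_layers: int = 1        # D_k - 2
    marker_basis: tuple[int, int] = (5, 7)
    layer_basis: tuple[int, int] = (5, 7)
    grid_size: int = DEFAULT_GRID_SIZE
    embedding_width: int = 8                   # width of Z_k^(D_k)
    dense_widths: tuple[int, ...] = (8,)       # hidden widths of the dense path
    n_features: int = 0                        # input width for the dense path
    activation: str = "tanh"
    n_covariates: int = 0

    def __post_init__(self):
        if self.embedding_width < 1:
            raise ValueError("embedding_width must be >= 1")
        if self.modality_kind not in ("functional", "dense"):
            raise ValueError(f"unknown modality_kind {self.modality_kind!r}")
        if self.modality_kind == "dense" and self.n_features < 1:
            raise ValueError("dense subnet needs n_features >= 1")


@dataclass
class HeadConfig:
    """Dense head on the shared representation: hidden layers + linear output."""

    hidden_widths: tuple[int, ...] = (16,)
    output_dim: int = 1
    activation: str = "tanh"
    link: str = "identity"

    def __post_init__(self):
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


class _FunctionalSubnet:
    def __init__(self, cfg: SubnetConfig, rng: np.random.Generator, name: str):
        self.cfg = cfg
        order, J = cfg.marker_basis
        self.marker_basis = make_bspline_system(order, J)
        order2, J2 = cfg.layer_basis
        layer_basis = make_bspline_system(order2, J2)
        self.grid = uniform_grid(cfg.grid_size)
        self.layers = [
            FunctionalFirstLayer(self.marker_basis, layer_basis, self.grid,
                                 activation=cfg.activation, n_covariates=cfg.n_covariates,
                                 rng=rng, name=f"{name}.L1")
        ]
        for d in range(cfg.n_hidden_functional_layers):
            self.layers.append(
                FunctionalHiddenLayer(layer_basis, layer_basis, self.grid,
                                      activation=cfg.activation, rng=rng,
                                      name=f"{name}.L{d + 2}"))
        self.layers.append(
            FunctionalOutputLayer(layer_basis, self.grid, cfg.embedding_width,
                                  rng=rng, name=f"{name}.out"))

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def _design(self, modality: OmicsVariantFunction) -> np.ndarray:
        # Phi depends only on the data; cache it across training epochs.
        # Identity is checked with `is` on arrays the cache keeps alive, so a
        # recycled object address can never alias a freed one.
        cached = getattr(self, "_phi_cache", None)
        if (cached is not None and cached[0] is modality.values
                and cached[1] is modality.positions01):
            return cached[2]
        Phi = dirac_design(modality, self.marker_basis)
        self._phi_cache = (modality.values, modality.positions01, Phi)
        return Phi

    def forward(self, modality: OmicsVariantFunction, X: np.ndarray | None) -> np.ndarray:
        Phi = self._design(modality)
        Z = self.layers[0].forward(Phi, X)
        for layer in self.layers[1:]:
            Z = layer.forward(Z)
        return Z

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers[1:]):
            dout = layer.backward(dout)
        self.layers[0].backward(dout)


class _DenseSubnet:
    def __init__(self, cfg: SubnetConfig, rng: np.random.Generator, name: str):
        self.cfg = cfg
        widths = [cfg.n_features, *cfg.dense_widths]
        self.layers = [
            DenseLayer(widths[i], widths[i + 1], activation=cfg.activation,
                       rng=rng, name=f"{name}.L{i + 1}")
            for i in range(len(widths) - 1)
        ]
        self.layers.append(DenseLayer(widths[-1], cfg.embedding_width,
                                      activation="identity", rng=rng, name=f"{name}.out"))

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, modality, X=None) -> np.ndarray:
        Z = np.asarray(modality.values if isinstance(modality, OmicsVariantFunction)
                       else modality, dtype=float)
        for layer in self.layers:
            Z = layer.forward(Z)
        return Z

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)


class MFDLModel:
    """Per-modality subnets + shared representation + dense head."""

    def __init__(self, subnet_configs, head_config: HeadConfig, seed: int = 0):
        self.subnet_configs = list(subnet_configs)
        self.head_config = head_config
        self.rng_seed = seed
        rng = np.random.default_rng(seed)
        self.subnets = []
        for k, cfg in enumerate(self.subnet_configs):
            cls = _FunctionalSubnet if cfg.modality_kind == "functional" else _DenseSubnet
            self.subnets.append(cls(cfg, rng, name=f"subnet{k}"))
        head_in = sum(cfg.embedding_width for cfg in self.subnet_configs)
        widths = [head_in, *head_config.hidden_widths]
        self.head = [
            DenseLayer(widths[i], widths[i + 1], activation=head_config.activation,
                       rng=rng, name=f"head.L{i + 1}")
            for i in range(len(widths) - 1)
        ]
        self.head.append(DenseLayer(widths[-1], head_config.output_dim,
                                    activation="identity", rng=rng, name="head.out"))
        self._emb_slices = None

    # -- parameters --------------------------------------------------------
    @property
    def params(self):
        ps = [p for net in self.subnets for p in net.params]
        ps += [p for layer in self.head for p in layer.params]
        return ps

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    # -- forward / backward ------------------------------------------------
    def forward(self, modalities, covariates: np.ndarray | None = None) -> np.ndarray:
        if len(modalities) != len(self.subnets):
            raise ValueError(
                f"model has {len(self.subnets)} modalities, got {len(modalities)}")
        ns = [m.values.shape[0] if isinstance(m, OmicsVariantFunction) else
              np.asarray(m).shape[0] for m in modalities]
        if len(set(ns)) > 1:
            raise ValueError(f"sample counts differ across modalities: {ns}")
        embeddings = [net.forward(m, covariates)
                      for net, m in zip(self.subnets, modalities)]
        Z = concat_shared(embeddings)
        widths = [e.shape[1] for e in embeddings]
        edges = np.cumsum([0, *widths])
        self._emb_slices = [slice(edges[i], edges[i + 1]) for i in range(len(widths))]
        for layer in self.head:
            Z = layer.forward(Z)
        return Z

    def backward(self, d_yhat: np.ndarray) -> None:
        """Accumulate parameter gradients for the most recent ``forward``."""
        d = d_yhat
        for layer in reversed(self.head):
            d = layer.backward(d)
        for net, sl in zip(self.subnets, self._emb_slices):
            net.backward(d[:, sl])

    def predict(self, modalities, covariates=None) -> np.ndarray:
        return self.forward(modalities, covariates)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "subnet_configs": [asdict(c) for c in self.subnet_configs],
            "head_config": asdict(self.head_config),
            "rng_seed": self.rng_seed,
            "params": {
                p.name: {
                    "shape": list(p.value.shape),
                    "data": base64.b64encode(np.ascontiguousarray(p.value).tobytes()).decode(),
                }
                for p in self.params
            },
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "MFDLModel":
        payload = json.loads(text)
        sub = [SubnetConfig(**{**c, "marker_basis": tuple(c["marker_basis"]),
                               "layer_basis": tuple(c["layer_basis"]),
                               "dense_widths": tuple(c["dense_widths"])})
               for c in payload["subnet_configs"]]
        hc = payload["head_config"]
        head = HeadConfig(hidden_widths=tuple(hc["hidden_widths"]),
                          output_dim=hc["output_dim"], activation=hc["activation"],
                          link=hc["link"])
        model = cls(sub, head, seed=payload["rng_seed"])
        for p in model.params:
            rec = payload["params"][p.name]
            p.value = np.frombuffer(
                base64.b64decode(rec["data"]), dtype=float).reshape(rec["shape"]).copy()
        return model

    @classmethod
    def load(cls, path) -> "MFDLModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_model(subnet_configs, head_config: HeadConfig, seed: int = 0) -> MFDLModel:
    """Seeded model construction; identical seed gives identical parameters."""
    return MFDLModel(subnet_configs, head_config, seed=seed)


def concat_shared(embeddings) -> np.ndarray:
    """Column-wise concatenation of per-modality embeddings (Z_wide)."""
    embeddings = [np.asarray(e, dtype=float) for e in embeddings]
    ns = {e.shape[0] for e in embeddings}
    if len(ns) > 1:
        raise ValueError(f"embeddings have differing sample counts: {sorted(ns)}")
    return np.concatenate(embeddings, axis=1)
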