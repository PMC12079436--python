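"""The six parametric classifier architectures and their exact weight audit.

Each builder returns an :class:`ArchitectureSpec` whose layer descriptors
carry every dimension needed to count trainable parameters in closed form:

    dense            in*out + out
    conv1d           kernel*in_channels*filters + filters
    simple recurrent in*u + u^2 + u
    LSTM             4*(in*u + u^2 + u)          (single bias per gate)
    BiLSTM           2x the LSTM count
    GRU              3*(in*u + u^2 + 2u)         (input + recurrent bias per gate)
    dropout / pooling / flatten   0

Geometry notes, with N the input width:

* The CNN consumes the descriptor as an N x 1 single-channel sequence; with
  kernel 9, valid padding and pool width 2 the step axis shrinks
  N -> N-8 -> (N-8)//2 -> (N-8)//2-8 -> ((N-8)//2-8)//2, so at N = 153 the
  flatten width is 32 * 464 = 14,848.
* The recurrent cells consume the whole descriptor as a single timestep of
  width N; this is the only reading under which the published LSTM and GRU
  layer totals (144,384 and 315,648 at N = 153) are arithmetically
  consistent, and it is what the closed-form counts above assume.

Two published per-layer totals are internally inconsistent with N = 153
under any standard convention — the simple-RNN cell (printed 35,840, which
implies an input width of 151) and the BiLSTM cell (printed 295,936,
implying 160). ``PUBLISHED_TOTALS`` keeps the printed values so the audit
flags the discrepancy instead of hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from bbbpep import nn

ARCHITECTURE_NAMES = ("FCN", "CNN", "RNN", "LSTM", "BiLSTM", "GRU")

#: Dropout rate applied wherever the architectures include a dropout layer.
DEFAULT_DROPOUT = 0.3

#: Published per-layer "Total weights" columns at input width 153, in the
#: same order as the corresponding spec's layers (audit reference).
PUBLISHED_TOTALS = {
    "FCN": [44352, 0, 578],
    "CNN": [4640, 0, 1938128, 0, 0, 1425504, 194],
    "RNN": [35840, 0, 8256, 0, 130],
    "LSTM": [144384, 0, 8256, 0, 130],
    "GRU": [315648, 0, 32896, 0, 258],
    "BiLSTM": [295936, 0, 16448, 0, 130],
}


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: kind plus the resolved dimensions."""

    kind: str
    label: str
    dims: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named architecture with fully resolved layer descriptors.

    ``input_kind`` mirrors :class:`bbbpep.nn.Network`: how the flat
    descriptor matrix is reshaped before the first layer.
    """

    name: str
    input_dim: int
    input_kind: str
    layers: tuple


def layer_param_count(layer: LayerSpec) -> int:
    """Closed-form trainable-parameter count of one layer descriptor."""
    k, d = layer.kind, layer.dims
    if k == "dense":
        return d["in"] * d["out"] + d["out"]
    if k == "conv1d":
        return d["kernel"] * d["in_channels"] * d["filters"] + d["filters"]
    if k == "simple_rnn":
        return d["in"] * d["units"] + d["units"] ** 2 + d["units"]
    if k == "lstm":
        return 4 * (d["in"] * d["units"] + d["units"] ** 2 + d["units"])
    if k == "bilstm":
        return 2 * 4 * (d["in"] * d["units"] + d["units"] ** 2 + d["units"])
    if k == "gru":
        return 3 * (d["in"] * d["units"] + d["units"] ** 2 + 2 * d["units"])
    if k in ("dropout", "maxpool1d", "flatten"):
        return 0
    raise ValueError(f"unknown layer kind {k!r}")


def count_trainable(spec: ArchitectureSpec) -> tuple:
    """Per-layer and total trainable parameter counts: ``(per_layer, total)``."""
    per_layer = [layer_param_count(layer) for layer in spec.layers]
    return per_layer, sum(per_layer)


def cnn_flatten_width(input_dim: int, kernel: int = 9, pool: int = 2, filters: int = 464) -> int:
    """Step-axis width after conv/pool/conv/pool, times the filter count."""
    length = input_dim - (kernel - 1)
    length //= pool
    length -= kernel - 1
    length //= pool
    if length < 1:
        raise ValueError(f"input width {input_dim} too small for the CNN geometry")
    return length * filters


def build_architecture(name: str, input_dim: int, dropout: float = DEFAULT_DROPOUT) -> ArchitectureSpec:
    """Resolve one of the six named architectures at the given input width."""
    if input_dim < 1:
        raise ValueError(f"input_dim must be >= 1, got {input_dim}")
    drop = LayerSpec("dropout", "Dropout", {"rate": dropout})

    if name == "FCN":
        layers = (
            LayerSpec("dense", "Hidden", {"in": input_dim, "out": 288, "activation": "relu"}),
            drop,
            LayerSpec("dense", "Output", {"in": 288, "out": 2}),
        )
        return ArchitectureSpec(name, input_dim, "flat", layers)

    if name == "CNN":
        flat = cnn_flatten_width(input_dim)
        layers = (
            LayerSpec("conv1d", "Conv1D", {"kernel": 9, "in_channels": 1, "filters": 464, "activation": "relu"}),
            LayerSpec("maxpool1d", "MaxPooling1D", {"width": 2}),
            LayerSpec("conv1d", "Conv1D_2", {"kernel": 9, "in_channels": 464, "filters": 464, "activation": "relu"}),
            LayerSpec("maxpool1d", "MaxPooling1D_2", {"width": 2}),
            LayerSpec("flatten", "Flatten", {"width": flat}),
            LayerSpec("dense", "Dense", {"in": flat, "out": 96, "activation": "relu"}),
            LayerSpec("dense", "Output", {"in": 96, "out": 2}),
        )
        return ArchitectureSpec(name, input_dim, "sequence_1ch", layers)

    if name == "RNN":
        layers = (
            LayerSpec("simple_rnn", "SimpleRNN", {"in": input_dim, "units": 128}),
            drop,
            LayerSpec("dense", "Dense", {"in": 128, "out": 64, "activation": "relu"}),
            drop,
            LayerSpec("dense", "Output", {"in": 64, "out": 2}),
        )
        return ArchitectureSpec(name, input_dim, "single_step", layers)

    if name == "LSTM":
        layers = (
            LayerSpec("lstm", "LSTM", {"in": input_dim, "units": 128}),
            drop,
            LayerSpec("dense", "Dense", {"in": 128, "out": 64, "activation": "relu"}),
            drop,
            LayerSpec("dense", "Output", {"in": 64, "out": 2}),
        )
        return ArchitectureSpec(name, input_dim, "single_step", layers)

    if name == "BiLSTM":
        layers = (
            LayerSpec("bilstm", "Bidirectional", {"in": input_dim, "units": 128}),
            drop,
            LayerSpec("dense", "Dense", {"in": 256, "out": 64, "activation": "relu"}),
            drop,
            LayerSpec("dense", "Output", {"in": 64, "out": 2}),
        )
        return ArchitectureSpec(name, input_dim, "single_step", layers)

    if name == "GRU":
        layers = (
            LayerSpec("gru", "GRU", {"in": input_dim, "units": 256}),
            drop,
            LayerSpec("dense", "Dense", {"in": 256, "out": 128, "activation": "relu"}),
            drop,
            LayerSpec("dense", "Output", {"in": 128, "out": 2}),
        )
        return ArchitectureSpec(name, input_dim, "single_step", layers)

    raise ValueError(f"unknown architecture {name!r}; choose from {ARCHITECTURE_NAMES}")


def instantiate(spec: ArchitectureSpec) -> nn.Network:
    """Materialize an architecture spec as an uninitialized numpy network."""
    layers: list = []
    for ls in spec.layers:
        d = ls.dims
        if ls.kind == "dense":
            layers.append(nn.Dense(d["in"], d["out"], d.get("activation")))
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(d["rate"]))
        elif ls.kind == "conv1d":
            layers.append(nn.Conv1D(d["in_channels"], d["filters"], d["kernel"], d.get("activation")))
        elif ls.kind == "maxpool1d":
            layers.append(nn.MaxPool1D(d["width"]))
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
        elif ls.kind == "simple_rnn":
            layers.append(nn.SimpleRNN(d["in"], d["units"]))
        elif ls.kind == "lstm":
            layers.append(nn.LSTM(d["in"], d["units"]))
        elif ls.kind == "bilstm":
            layers.append(nn.BiLSTM(d["in"], d["units"]))
        elif ls.kind == "gru":
            layers.append(nn.GRU(d["in"], d["units"]))
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    return nn.Network(layers, input_kind=spec.input_kind)


def audit(spec: ArchitectureSpec, expected: list | None = None) -> list:
    """Compare closed-form per-layer counts against expected reference totals.

    Returns a list of dicts (label, kind, computed, expected, match). With no
    reference the expected/match fields are None.
    """
    per_layer, _ = count_trainable(spec)
    rows = []
    for i, (layer, computed) in enumerate(zip(spec.layers, per_layer)):
        exp = expected[i] if expected is not None and i < len(expected) else None
        rows.append(
            {
                "label": layer.label,
                "kind": layer.kind,
                "computed": computed,
                "expected": exp,
                "match": None if exp is None else computed == exp,
            }
        )
    return rows
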