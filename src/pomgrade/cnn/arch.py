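"""Architecture description and parameter accounting for the grading CNN.

The network is a compact stack of six convolutional layers (with 3x3,
stride-2 max pooling after all but the third), two 256-unit full-connection
layers, and a 3-way softmax output. SAME padding keeps convolutions
size-preserving; each pooling stage halves the spatial extent with
floor rounding (n -> floor(n / 2)), so a 208x208x3 input reaches the first
full-connection layer as a 6x6x64 tensor flattened to 2,304 values.

The 1x1 convolution of the third layer mixes highly correlated features
across channels at a single spatial location, which is why no pooling
follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple


@dataclass(frozen=True)
class LayerSpec:
    name: str
    op: str  # "conv" | "fc" | "softmax"
    kernel: Optional[Tuple[int, int]] = None
    n_out: int = 0  # filters for conv, units for fc / softmax
    stride: int = 1
    pool_after: bool = False  # 3x3 stride-2 max pool, floor-halving
    pool_kernel: Tuple[int, int] = (3, 3)
    pool_stride: int = 2


@dataclass
class ArchitectureSpec:
    input_size: int = 208
    in_channels: int = 3
    n_classes: int = 3
    layers: List[LayerSpec] = field(default_factory=list)

    @property
    def conv_layers(self) -> List[LayerSpec]:
        return [l for l in self.layers if l.op == "conv"]

    @property
    def n_pools(self) -> int:
        return sum(l.pool_after for l in self.layers)

    def validate(self) -> None:
        if self.input_size // (2 ** self.n_pools) < 1:
            raise ValueError(
                f"input_size {self.input_size} too small for {self.n_pools} "
                "halving pool stages"
            )


def build_architecture(input_size: int = 208, n_classes: int = 3,
                       in_channels: int = 3) -> ArchitectureSpec:
    """The reference stack: filter counts (8, 16, 32, 64, 64, 64, 256, 256, K).

    ``input_size`` must survive five floor-halvings (>= 64 keeps at least a
    2x2 map in front of the flatten).
    """
    if input_size < 64:
        raise ValueError("input_size must be >= 64 for five pooling stages")
    layers = [
        LayerSpec("Conv1", "conv", (5, 5), 8, pool_after=True),
        LayerSpec("Conv2", "conv", (3, 3), 16, pool_after=True),
        LayerSpec("Conv3", "conv", (1, 1), 32, pool_after=False),
        LayerSpec("Conv4", "conv", (3, 3), 64, pool_after=True),
        LayerSpec("Conv5", "conv", (3, 3), 64, pool_after=True),
        LayerSpec("Conv6", "conv", (3, 3), 64, pool_after=True),
        LayerSpec("Fc1", "fc", None, 256),
        LayerSpec("Fc2", "fc", None, 256),
        LayerSpec("Output", "softmax", None, n_classes),
    ]
    arch = ArchitectureSpec(input_size=input_size, in_channels=in_channels,
                            n_classes=n_classes, layers=layers)
    arch.validate()
    return arch


def spatial_chain(arch: ArchitectureSpec) -> List[Tuple[int, int]]:
    """(H, W) after each pooling stage; convolutions are size-preserving.

    Each pool maps n -> floor(n / 2). For input 208 the chain is
    104, 52, 26, 13, 6.
    """
    arch.validate()
    sizes = []
    n = arch.input_size
    for layer in arch.layers:
        if layer.op == "conv" and layer.pool_after:
            n = n // 2
            sizes.append((n, n))
    return sizes


def flattened_dim(arch: ArchitectureSpec) -> int:
    """Length of the rasterized vector entering the first fc layer."""
    chain = spatial_chain(arch)
    h, w = chain[-1] if chain else (arch.input_size, arch.input_size)
    convs = arch.conv_layers
    channels = convs[-1].n_out if convs else arch.in_channels
    return h * w * channels


def count_parameters(arch: ArchitectureSpec) -> Dict[str, int]:
    """Trainable parameter count per layer plus 'total'.

    conv: kh * kw * C_in * C_out + C_out; fc: N_in * N_out + N_out. The
    softmax output layer is counted as the final full connection onto the
    class logits.
    """
    counts: Dict[str, int] = {}
    c_in = arch.in_channels
    n_in = None
    for layer in arch.layers:
        if layer.op == "conv":
            kh, kw = layer.kernel
            counts[layer.name] = kh * kw * c_in * layer.n_out + layer.n_out
            c_in = layer.n_out
        else:
            if n_in is None:
                n_in = flattened_dim(arch)
            counts[layer.name] = n_in * layer.n_out + layer.n_out
            n_in = layer.n_out
    counts["total"] = sum(counts.values())
    return counts
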