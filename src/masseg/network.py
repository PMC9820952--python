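"""Deep-supervised 4-stage residual-U-block (RSU) segmentation network.

The network is a two-level U-shape: the outer encoder–decoder halves /
doubles the spatial resolution between stages, while every stage is itself
a small U-shaped block (an RSU) whose nested encoder–decoder pools over
``depth`` internal scales and adds the result back onto a residual input
transform.  The deepest stage uses a dilated RSU (growing dilation instead
of pooling) so it can operate at spatial sizes too small to pool further.
One 3-class score head is attached to each decoder scale plus the
bottleneck (deep supervision); an optional fused head combines all side
outputs at full resolution and serves as the prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Node, Parameter, Tape


@dataclass
class NetworkConfig:
    num_stages: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 128)
    rsu_depths: tuple[int, ...] = (5, 4, 3, 2)
    mid_channels: tuple[int, ...] | None = None  # defaults to channels // 2
    num_classes: int = 3
    in_channels: int = 1
    dilated_bottleneck: bool = True
    include_fused_output: bool = True
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        self.channels = tuple(int(c) for c in self.channels)
        self.rsu_depths = tuple(int(d) for d in self.rsu_depths)
        if self.mid_channels is not None:
            self.mid_channels = tuple(int(c) for c in self.mid_channels)
        if self.num_stages < 2:
            raise ValueError("num_stages must be >= 2")
        if len(self.channels) != self.num_stages or len(self.rsu_depths) != self.num_stages:
            raise ValueError("channels and rsu_depths must have num_stages entries")
        if any(c <= 0 for c in self.channels):
            raise ValueError("channels must be strictly positive")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @property
    def mids(self) -> tuple[int, ...]:
        if self.mid_channels is not None:
            return self.mid_channels
        return tuple(max(1, c // 2) for c in self.channels)

    @property
    def divisor(self) -> int:
        """Input spatial sizes must be divisible by this (outer stage pooling)."""
        return 2 ** (self.num_stages - 1)


class _Registry:
    """Creates and holds named parameters with seeded He-style init."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: dict[str, Parameter] = {}

    def conv(self, name: str, cin: int, cout: int) -> tuple[Parameter, Parameter]:
        std = np.sqrt(2.0 / (27 * cin))
        w = Parameter(f"{name}.w", self.rng.normal(0.0, std, size=(3, 3, 3, cin, cout)))
        b = Parameter(f"{name}.b", np.zeros(cout))
        self.params[w.name] = w
        self.params[b.name] = b
        return w, b

    def linear(self, name: str, cin: int, cout: int) -> tuple[Parameter, Parameter]:
        std = np.sqrt(2.0 / cin)
        w = Parameter(f"{name}.w", self.rng.normal(0.0, std, size=(cin, cout)))
        b = Parameter(f"{name}.b", np.zeros(cout))
        self.params[w.name] = w
        self.params[b.name] = b
        return w, b

    def norm(self, name: str, c: int) -> tuple[Parameter, Parameter]:
        g = Parameter(f"{name}.g", np.ones(c))
        be = Parameter(f"{name}.be", np.zeros(c))
        self.params[g.name] = g
        self.params[be.name] = be
        return g, be


class ConvBlock:
    """conv3x3x3 -> instance norm -> LeakyReLU."""

    def __init__(self, reg: _Registry, name: str, cin: int, cout: int,
                 dilation: int = 1, slope: float = 0.01):
        self.w, self.b = reg.conv(name, cin, cout)
        self.g, self.be = reg.norm(name, cout)
        self.dilation = dilation
        self.slope = slope

    def __call__(self, tape: Tape | None, x: Node) -> Node:
        h = nn.conv3d(tape, x, self.w, self.b, dilation=self.dilation)
        h = nn.instance_norm(tape, h, self.g, self.be)
        return nn.leaky_relu(tape, h, self.slope)


class RSU:
    """Residual U-block: a nested encoder–decoder over ``depth`` scales.

    Non-dilated form pools 2x per level (requires spatial size >= 2**depth);
    the dilated form keeps full resolution and grows the dilation instead.
    """

    def __init__(self, reg: _Registry, name: str, depth: int, cin: int,
                 cmid: int, cout: int, dilated: bool = False, slope: float = 0.01):
        if depth < 1:
            raise ValueError("RSU depth must be >= 1")
        self.depth = depth
        self.dilated = dilated
        dil = (lambda l: 2 ** l) if dilated else (lambda l: 1)
        self.block_in = ConvBlock(reg, f"{name}.in", cin, cout, slope=slope)
        self.enc = [ConvBlock(reg, f"{name}.e0", cout, cmid, dilation=dil(0), slope=slope)]
        self.enc += [
            ConvBlock(reg, f"{name}.e{l}", cmid, cmid, dilation=dil(l), slope=slope)
            for l in range(1, depth + 1)
        ]
        bottom_dil = 2 ** (depth + 1) if dilated else 2
        self.bottom = ConvBlock(reg, f"{name}.bt", cmid, cmid, dilation=bottom_dil, slope=slope)
        self.dec = [
            ConvBlock(reg, f"{name}.d{l}", 2 * cmid, cmid, dilation=dil(l), slope=slope)
            for l in range(1, depth + 1)
        ]
        self.dec0 = ConvBlock(reg, f"{name}.d0", 2 * cmid, cout, dilation=dil(0), slope=slope)

    def __call__(self, tape: Tape | None, x: Node) -> Node:
        if not self.dilated:
            size = np.array(x.value.shape[1:4])
            if np.any(size < 2 ** self.depth):
                raise ValueError(
                    f"RSU depth {self.depth} needs spatial sizes >= {2 ** self.depth}, "
                    f"got {tuple(size)}"
                )
        x_in = self.block_in(tape, x)
        h = [self.enc[0](tape, x_in)]
        for l in range(1, self.depth + 1):
            prev = h[-1] if self.dilated else nn.max_pool2(tape, h[-1])
            h.append(self.enc[l](tape, prev))
        g = self.bottom(tape, h[-1])
        for l in range(self.depth, 0, -1):
            g = self.dec[l - 1](tape, nn.concat(tape, [g, h[l]]))
            if not self.dilated:
                g = nn.upsample2(tape, g)
        g = self.dec0(tape, nn.concat(tape, [g, h[0]]))
        return nn.add(tape, x_in, g)


class MasseterNet:
    """The full deep-supervised segmentation network.

    ``forward`` returns raw class scores as a list ordered fine-to-coarse
    (full resolution first, then each halving), with the fused full-
    resolution output appended last when enabled.
    """

    def __init__(self, cfg: NetworkConfig, seed: int):
        self.cfg = cfg
        self.seed = int(seed)
        reg = _Registry(np.random.default_rng(seed))
        ns, ch, mids, depths = cfg.num_stages, cfg.channels, cfg.mids, cfg.rsu_depths
        sl = cfg.negative_slope
        self.encoders = []
        cin = cfg.in_channels
        for s in range(ns):
            dilated = cfg.dilated_bottleneck and s == ns - 1
            self.encoders.append(
                RSU(reg, f"en{s + 1}", depths[s], cin, mids[s], ch[s], dilated=dilated, slope=sl)
            )
            cin = ch[s]
        self.decoders = []
        for s in range(ns - 2, -1, -1):
            self.decoders.append(
                RSU(reg, f"de{s + 1}", depths[s], ch[s] + ch[s + 1], mids[s], ch[s], slope=sl)
            )
        # side heads: decoder scales fine->coarse, then the bottleneck
        side_channels = list(ch[: ns - 1]) + [ch[ns - 1]]
        self.sides = [
            (reg.conv(f"side{s}", c, cfg.num_classes)) for s, c in enumerate(side_channels)
        ]
        if cfg.include_fused_output:
            self.fuse_w, self.fuse_b = reg.linear("fuse", ns * cfg.num_classes, cfg.num_classes)
        self.params = reg.params

    # -- forward ----------------------------------------------------------
    def forward_nodes(self, tape: Tape | None, x: np.ndarray) -> list[Node]:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, ..., None]
        elif x.ndim == 4:
            x = x[..., None]
        size = np.array(x.shape[1:4])
        div = self.cfg.divisor
        if np.any(size % div):
            raise ValueError(
                f"input spatial sizes {tuple(size)} must be divisible by {div}"
            )
        ns = self.cfg.num_stages
        node = Node(x)
        enc_out = []
        for s, enc in enumerate(self.encoders):
            node = enc(tape, node)
            enc_out.append(node)
            if s < ns - 1:
                node = nn.max_pool2(tape, node)
        dec_out = [enc_out[-1]]  # coarsest
        node = enc_out[-1]
        for i, dec in enumerate(self.decoders):
            skip = enc_out[ns - 2 - i]
            node = dec(tape, nn.concat(tape, [nn.upsample2(tape, node), skip]))
            dec_out.append(node)
        # dec_out is coarse->fine; sides indexed fine->coarse
        sides_ft = []
        for s in range(ns):
            w, b = self.sides[s]
            feat = dec_out[ns - 1 - s]
            sides_ft.append(nn.conv3d(tape, feat, w, b))
        outputs = list(sides_ft)
        if self.cfg.include_fused_output:
            ups = [sides_ft[0]] + [
                nn.upsample2_n(tape, sides_ft[s], s) for s in range(1, ns)
            ]
            fused = nn.channel_linear(tape, nn.concat(tape, ups), self.fuse_w, self.fuse_b)
            outputs.append(fused)
        return outputs

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Inference forward pass: raw score grids, fine-to-coarse (+ fused last)."""
        return [n.value for n in self.forward_nodes(None, x)]

    # -- parameters -------------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: p.value for k, p in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for k, p in self.params.items():
            if arrays[k].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.value = np.ascontiguousarray(arrays[k], dtype=np.float32)


def build_network(cfg: NetworkConfig, seed: int) -> MasseterNet:
    """Build a network with seeded, reproducible initialization."""
    return MasseterNet(cfg, seed)


def save_checkpoint(net: MasseterNet, path) -> None:
    meta = json.dumps({"config": asdict(net.cfg), "seed": net.seed})
    np.savez(path, __meta__=np.array(meta), **net.state_arrays())


def load_checkpoint(path) -> MasseterNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg_d = meta["config"]
        for key in ("channels", "rsu_depths"):
            cfg_d[key] = tuple(cfg_d[key])
        if cfg_d.get("mid_channels") is not None:
            cfg_d["mid_channels"] = tuple(cfg_d["mid_channels"])
        net = MasseterNet(NetworkConfig(**cfg_d), meta["seed"])
        net.load_state_arrays({k: z[k] for k in z.files if k != "__meta__"})
    return net
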