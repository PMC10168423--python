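"""Network builders: cycle generators, Wasserstein critics, refinement net.

Three 3D convolutional families, built from a declarative :class:`NetworkSpec`:

* **generator** (reconstruction GR / verification GV): encoder (early conv +
  two stride-2 down-convs; 32/64/128 filters) -> three residual transformer
  blocks at 128 filters -> symmetric decoder (two stride-2 deconvs + a
  sequential conv with 16 filters + final conv to 1 channel). Output passes
  through a Tanh rescaled to [0, 1] to match normalized intensities.
* **critic** (DR / DV): four stride-2 down-convs (64/128/256/512 filters) +
  one shape-preserving conv (512), then global average pooling -> linear ->
  a single unbounded scalar (Wasserstein critic, no output nonlinearity).
* **refiner**: nnU-Net-style residual encoder-decoder. Encoder = one residual
  conv block (RCB), five down-sampling RCBs and an anisotropic bottleneck RCB
  (stride 1x2x1); filters 32/64/128/256/320/320. Decoder mirrors with an
  up-sampling bottleneck deconv (k 3x2x3, s 1x2x1, p 1x0x1), five k2/s2
  deconv blocks, concatenating encoder skips at matching scales, and a final
  1x1x1 conv with Tanh.

``width_scale`` shrinks every filter count proportionally for desk-scale
runs; the refiner reduces its depth automatically (if allowed) when the input
shape does not support five halvings.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad

__all__ = [
    "NetworkSpec",
    "NetworkHandle",
    "build_generator",
    "build_critic",
    "build_refiner",
    "count_parameters",
    "GENERATOR_FILTERS",
    "CRITIC_FILTERS",
    "REFINER_FILTERS",
]

GENERATOR_FILTERS = (32, 64, 128)
GENERATOR_DECODER_FILTERS = (64, 32, 16, 1)
CRITIC_FILTERS = (64, 128, 256, 512, 512)
REFINER_FILTERS = (32, 64, 128, 256, 320, 320)


@dataclasses.dataclass
class NetworkSpec:
    """Declarative description of one network to build."""

    role: str  # generator | critic | refiner
    input_shape: tuple = (80, 128, 80)
    base_filters: tuple = None
    n_transformer_blocks: int = 3
    width_scale: float = 1.0
    use_skips: bool = True
    allow_depth_reduction: bool = True
    init_sigma: float = 0.02

    def __post_init__(self):
        if self.role not in ("generator", "critic", "refiner"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.base_filters is None:
            self.base_filters = {
                "generator": GENERATOR_FILTERS,
                "critic": CRITIC_FILTERS,
                "refiner": REFINER_FILTERS,
            }[self.role]
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        if any(int(round(f * self.width_scale)) < 1 for f in self.base_filters):
            raise ValueError("width_scale drives a filter count below 1")

    def _scaled(self, filters):
        return tuple(max(1, int(round(f * self.width_scale))) for f in filters)

    @property
    def filters(self) -> tuple:
        return self._scaled(self.base_filters)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Layer:
    def params(self) -> list:
        return [v for v in self.__dict__.values() if isinstance(v, ad.Tensor) and v.requires_grad]


class Conv3d(_Layer):
    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, rng=None, sigma=0.02):
        k = (k, k, k) if isinstance(k, int) else tuple(k)
        self.stride, self.pad = stride, pad
        self.weight = ad.parameter(rng.normal(0.0, sigma, size=(cout, cin) + k))
        self.bias = ad.parameter(np.zeros(cout)) if bias else None

    def __call__(self, x):
        y = ad.conv3d(x, self.weight, self.stride, self.pad)
        if self.bias is not None:
            y = ad.add(y, ad.reshape(self.bias, (1, -1, 1, 1, 1)))
        return y


class ConvTranspose3d(_Layer):
    """Transposed conv mapping cin -> cout; weight kept in conv orientation."""

    def __init__(self, cin, cout, k, stride=1, pad=0, output_padding=0, bias=True,
                 rng=None, sigma=0.02):
        k = (k, k, k) if isinstance(k, int) else tuple(k)
        self.k = k
        self.stride = (stride, stride, stride) if isinstance(stride, int) else tuple(stride)
        self.pad = (pad, pad, pad) if isinstance(pad, int) else tuple(pad)
        op = output_padding
        self.output_padding = (op, op, op) if isinstance(op, int) else tuple(op)
        self.weight = ad.parameter(rng.normal(0.0, sigma, size=(cin, cout) + k))
        self.bias = ad.parameter(np.zeros(cout)) if bias else None

    def __call__(self, x):
        out_spatial = tuple(
            (n - 1) * s - 2 * p + k + o
            for n, s, p, k, o in zip(
                x.shape[2:], self.stride, self.pad, self.k, self.output_padding
            )
        )
        y = ad.conv_transpose3d(x, self.weight, self.stride, self.pad, out_spatial)
        if self.bias is not None:
            y = ad.add(y, ad.reshape(self.bias, (1, -1, 1, 1, 1)))
        return y


class InstanceNorm3d(_Layer):
    """Affine instance norm; ``fused`` uses the fast first-order primitive.

    Critics keep ``fused=False`` so the gradient penalty can differentiate
    through the normalization twice.
    """

    def __init__(self, channels, eps=1e-5, affine=True, fused=True):
        self.eps = eps
        self.fused = fused and affine
        self.gamma = ad.parameter(np.ones((1, channels, 1, 1, 1))) if affine else None
        self.beta = ad.parameter(np.zeros((1, channels, 1, 1, 1))) if affine else None

    def __call__(self, x):
        if self.fused:
            return ad.instance_norm_affine(x, self.gamma, self.beta, self.eps)
        m = ad.mean(x, axis=(2, 3, 4), keepdims=True)
        c = ad.sub(x, m)
        v = ad.mean(ad.mul(c, c), axis=(2, 3, 4), keepdims=True)
        y = ad.mul(c, ad.power(ad.add(v, ad.constant(self.eps)), -0.5))
        if self.gamma is not None:
            y = ad.add(ad.mul(y, self.gamma), self.beta)
        return y


class Linear(_Layer):
    def __init__(self, cin, cout, rng=None, sigma=0.02):
        self.weight = ad.parameter(rng.normal(0.0, sigma, size=(cin, cout)))
        self.bias = ad.parameter(np.zeros(cout))

    def __call__(self, x):  # x: (N, cin)
        return ad.add(ad.matmul(x, self.weight), self.bias)


class ConvINReLU(_Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None, sigma=0.02, fused_norm=True):
        self.conv = Conv3d(cin, cout, k, stride, pad, rng=rng, sigma=sigma)
        self.norm = InstanceNorm3d(cout, fused=fused_norm)

    def __call__(self, x):
        return ad.relu(self.norm(self.conv(x)))

    def params(self):
        return self.conv.params() + self.norm.params()


class ResidualBlock(_Layer):
    """conv-IN-ReLU-conv-IN plus (projected) skip; final ReLU optional.

    The generator transformer uses stride 1, equal channels, no final ReLU
    (plain additive skip); the refiner's RCBs use a projection when channels
    or stride change and apply ReLU after the addition.
    """

    def __init__(self, cin, cout, stride=1, final_relu=False, rng=None, sigma=0.02):
        self.conv1 = Conv3d(cin, cout, 3, stride, 1, rng=rng, sigma=sigma)
        self.norm1 = InstanceNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, 1, 1, rng=rng, sigma=sigma)
        self.norm2 = InstanceNorm3d(cout)
        self.final_relu = final_relu
        stride_t = (stride, stride, stride) if isinstance(stride, int) else tuple(stride)
        if cin != cout or stride_t != (1, 1, 1):
            self.proj = Conv3d(cin, cout, 1, stride, 0, rng=rng, sigma=sigma)
        else:
            self.proj = None

    def _consume_parts(self, parts: list):
        """conv1(concat(parts)) and proj(concat(parts)) without materializing
        the concatenation: slice both weights along the input-channel axis,
        sum the partial convolutions, and release each input part as soon as
        both partials are computed (memory matters at full decoder
        resolution).
        """
        acc = skip_acc = None
        offset = 0
        for i in range(len(parts)):
            p = parts[i]
            c = p.shape[1]
            w1 = ad.slice_axis(self.conv1.weight, 1, offset, offset + c)
            wp = ad.slice_axis(self.proj.weight, 1, offset, offset + c)
            y1 = ad.conv3d(p, w1, self.conv1.stride, self.conv1.pad)
            yp = ad.conv3d(p, wp, self.proj.stride, self.proj.pad)
            acc = y1 if acc is None else ad.add(acc, y1)
            skip_acc = yp if skip_acc is None else ad.add(skip_acc, yp)
            parts[i] = None  # release the consumed part
            offset += c
        if self.conv1.bias is not None:
            acc = ad.add(acc, ad.reshape(self.conv1.bias, (1, -1, 1, 1, 1)))
        if self.proj.bias is not None:
            skip_acc = ad.add(skip_acc, ad.reshape(self.proj.bias, (1, -1, 1, 1, 1)))
        return acc, skip_acc

    def __call__(self, x):
        if isinstance(x, list):
            acc, skip = self._consume_parts(x)
            h = ad.relu(self.norm1(acc))
            h = self.norm2(self.conv2(h))
        else:
            h = ad.relu(self.norm1(self.conv1(x)))
            h = self.norm2(self.conv2(h))
            skip = x if self.proj is None else self.proj(x)
        out = ad.add(h, skip)
        return ad.relu(out) if self.final_relu else out

    def params(self):
        out = self.conv1.params() + self.norm1.params() + self.conv2.params() + self.norm2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


# ---------------------------------------------------------------------------
# network handles
# ---------------------------------------------------------------------------


class NetworkHandle:
    """A built, trainable volume->volume (or ->scalar) function."""

    def __init__(self, spec: NetworkSpec, forward, parameters: list):
        self.spec = spec
        self._forward = forward
        self.parameters = parameters

    def __call__(self, x, collect: list | None = None):
        if not isinstance(x, ad.Tensor):
            x = ad.as_tensor(x)
        return self._forward(x, collect)

    def probe_shapes(self, x_data: np.ndarray) -> list:
        """Forward a dummy input without recording gradients; return the
        per-stage (name, spatial shape) ledger."""
        collect: list = []
        with ad.no_grad():
            out = self(ad.constant(x_data), collect=collect)
        collect.append(("output", tuple(out.shape[1:]) if out.ndim >= 5 else tuple(out.shape)))
        return collect

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    def state(self) -> list:
        return [p.data.copy() for p in self.parameters]

    def load_state(self, state: list) -> None:
        if len(state) != len(self.parameters):
            raise ValueError("state does not match network parameters")
        for p, arr in zip(self.parameters, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch in state")
            p.data = arr.astype(np.float32).copy()


def count_parameters(handle: NetworkHandle) -> int:
    """Exact trainable parameter count of a built network."""
    return handle.n_parameters


def _note(collect, name, t):
    if collect is not None:
        collect.append((name, tuple(t.shape[1:])))  # (channels, D, H, W)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_generator(
    spec: NetworkSpec, seed: int = 0, output_bias: float | None = None
) -> NetworkHandle:
    """Encoder-transformer-decoder reconstruction/verification generator.

    ``output_bias`` initializes the final layer so the network's initial
    output equals that normalized intensity (typically the background/air
    level) instead of the Tanh midpoint 0.5 — without it most voxels start
    deep in the saturated tail of the output activation and the coarse
    stage trains an order of magnitude more slowly.
    """
    if spec.role != "generator":
        raise ValueError("spec.role must be 'generator'")
    rng = np.random.default_rng([int(seed), 1])
    f0, f1, f2 = spec.filters
    dec = spec._scaled(GENERATOR_DECODER_FILTERS[:3])  # (64, 32, 16) scaled
    sigma = spec.init_sigma

    early = ConvINReLU(1, f0, 3, 1, 1, rng=rng, sigma=sigma)
    down1 = ConvINReLU(f0, f1, 3, 2, 1, rng=rng, sigma=sigma)
    down2 = ConvINReLU(f1, f2, 3, 2, 1, rng=rng, sigma=sigma)
    blocks = [
        ResidualBlock(f2, f2, 1, final_relu=False, rng=rng, sigma=sigma)
        for _ in range(spec.n_transformer_blocks)
    ]
    up1 = ConvTranspose3d(f2, dec[0], 3, 2, 1, output_padding=1, rng=rng, sigma=sigma)
    up1n = InstanceNorm3d(dec[0])
    up2 = ConvTranspose3d(dec[0], dec[1], 3, 2, 1, output_padding=1, rng=rng, sigma=sigma)
    up2n = InstanceNorm3d(dec[1])
    seq = ConvINReLU(dec[1], dec[2], 3, 1, 1, rng=rng, sigma=sigma)
    final = Conv3d(dec[2], 1, 3, 1, 1, rng=rng, sigma=sigma)
    if output_bias is not None:
        # (tanh(z)+1)/2 == b  <=>  z == atanh(2b-1)
        b = float(np.clip(output_bias, 1e-3, 1 - 1e-3))
        final.bias.data = np.full_like(final.bias.data, np.arctanh(2 * b - 1))

    layers = [early, down1, down2, *blocks, up1, up1n, up2, up2n, seq, final]
    params = [p for layer in layers for p in layer.params()]

    def forward(x, collect=None):
        h = early(x)
        _note(collect, "early", h)
        h = down1(h)
        _note(collect, "down1", h)
        h = down2(h)
        _note(collect, "down2", h)
        for i, b in enumerate(blocks):
            h = b(h)
            _note(collect, f"transformer{i}", h)
        h = ad.relu(up1n(up1(h)))
        _note(collect, "up1", h)
        h = ad.relu(up2n(up2(h)))
        _note(collect, "up2", h)
        h = seq(h)
        _note(collect, "sequential", h)
        h = final(h)
        # Tanh rescaled to the normalized intensity range [0, 1]
        return ad.mul(ad.add(ad.tanh(h), ad.constant(1.0)), ad.constant(0.5))

    return NetworkHandle(spec, forward, params)


def build_critic(spec: NetworkSpec, seed: int = 0) -> NetworkHandle:
    """Wasserstein critic: volume -> unbounded scalar per sample."""
    if spec.role != "critic":
        raise ValueError("spec.role must be 'critic'")
    rng = np.random.default_rng([int(seed), 2])
    f = spec.filters
    sigma = spec.init_sigma
    downs = []
    cin = 1
    sizes = tuple(spec.input_shape)
    for c in f[:4]:
        if min(sizes) < 2:  # a further k4/s2 conv would collapse to size 0
            if not spec.allow_depth_reduction:
                raise ValueError(
                    f"input shape {spec.input_shape} too small for four "
                    "down-sampling critic layers"
                )
            break
        # fused_norm=False keeps the critic twice-differentiable for the GP
        downs.append(ConvINReLU(cin, c, 4, 2, 1, rng=rng, sigma=sigma, fused_norm=False))
        cin = c
        sizes = tuple((s + 2 - 4) // 2 + 1 for s in sizes)
    # final conv: kernel 4, stride 1, shape-preserving (asymmetric padding)
    last = ConvINReLU(
        cin, f[4], 4, 1, ((1, 2), (1, 2), (1, 2)), rng=rng, sigma=sigma, fused_norm=False
    )
    head = Linear(f[4], 1, rng=rng, sigma=sigma)
    layers = [*downs, last, head]
    params = [p for layer in layers for p in layer.params()]

    def forward(x, collect=None):
        h = x
        for i, d in enumerate(downs):
            h = d(h)
            _note(collect, f"down{i + 1}", h)
        h = last(h)
        _note(collect, "final_conv", h)
        pooled = ad.mean(h, axis=(2, 3, 4), keepdims=False)  # global average pool
        if collect is not None:
            collect.append(("global_pool", (1, 1, 1)))
        return head(pooled)  # (N, 1)

    return NetworkHandle(spec, forward, params)


def _refiner_depth(spec: NetworkSpec) -> int:
    def v2(n):
        k = 0
        while n % 2 == 0 and n > 1:
            n //= 2
            k += 1
        return k

    h, w, l = spec.input_shape
    depth = min(5, v2(h), v2(l), v2(w) - 1)  # bottleneck halves W once more
    if depth < 1:
        raise ValueError(f"input shape {spec.input_shape} supports no down-sampling")
    if depth < 5 and not spec.allow_depth_reduction:
        raise ValueError(
            f"input shape {spec.input_shape} needs depth {depth} but depth "
            "reduction is disabled (H,L must divide 32 and W divide 64)"
        )
    return depth


def build_refiner(spec: NetworkSpec, seed: int = 0) -> NetworkHandle:
    """Residual encoder-decoder refinement network (full resolution)."""
    if spec.role != "refiner":
        raise ValueError("spec.role must be 'refiner'")
    rng = np.random.default_rng([int(seed), 3])
    sigma = spec.init_sigma
    depth = _refiner_depth(spec)
    base = list(spec.base_filters)
    enc_f = spec._scaled(tuple(base[: depth + 1]))
    bott_f = spec._scaled((base[min(depth + 1, len(base) - 1)],))[0]

    # encoder: RCB + depth D-RCBs + B-RCB
    rcb0 = ResidualBlock(1, enc_f[0], 1, final_relu=True, rng=rng, sigma=sigma)
    drcbs = [
        ResidualBlock(enc_f[i], enc_f[i + 1], 2, final_relu=True, rng=rng, sigma=sigma)
        for i in range(depth)
    ]
    brcb = ResidualBlock(enc_f[-1], bott_f, (1, 2, 1), final_relu=True, rng=rng, sigma=sigma)

    use_skips = spec.use_skips

    def up_in(c_deconv, c_skip):
        return c_deconv + (c_skip if use_skips else 0)

    # decoder: UB-RCB + depth U-RCBs + final 1x1x1 conv
    ub_deconv = ConvTranspose3d(
        bott_f, bott_f, (3, 2, 3), (1, 2, 1), (1, 0, 1), rng=rng, sigma=sigma
    )
    ub_rcb = ResidualBlock(
        up_in(bott_f, enc_f[-1]), enc_f[-1], 1, final_relu=True, rng=rng, sigma=sigma
    )
    u_deconvs, u_rcbs = [], []
    cin = enc_f[-1]
    for i in range(depth - 1, -1, -1):
        u_deconvs.append(ConvTranspose3d(cin, cin, 2, 2, 0, rng=rng, sigma=sigma))
        u_rcbs.append(
            ResidualBlock(up_in(cin, enc_f[i]), enc_f[i], 1, final_relu=True, rng=rng, sigma=sigma)
        )
        cin = enc_f[i]
    final = Conv3d(enc_f[0], 1, 1, 1, 0, bias=False, rng=rng, sigma=sigma)

    layers = [rcb0, *drcbs, brcb, ub_deconv, ub_rcb, *u_deconvs, *u_rcbs, final]
    params = [p for layer in layers for p in layer.params()]

    def forward(x, collect=None):
        skips = []
        h = rcb0(x)
        _note(collect, "rcb", h)
        skips.append(h)
        for i, d in enumerate(drcbs):
            h = d(h)
            _note(collect, f"d-rcb{i + 1}", h)
            skips.append(h)
        h = brcb(h)
        _note(collect, "b-rcb", h)
        # skip fusion uses split convolutions over a consumable part list, so
        # neither the concatenated map nor stale deconv outputs stay alive
        h = ub_deconv(h)
        if use_skips:
            parts = [h, skips.pop()]
            h = None
            h = ub_rcb(parts)
        else:
            h = ub_rcb(h)
        _note(collect, "ub-rcb", h)
        for i, (dc, rc) in enumerate(zip(u_deconvs, u_rcbs)):
            h = dc(h)
            if use_skips:
                parts = [h, skips.pop()]
                h = None
                h = rc(parts)
            else:
                h = rc(h)
            _note(collect, f"u-rcb{i + 1}", h)
        h = final(h)
        _note(collect, "final_conv", h)
        return ad.tanh(h)

    return NetworkHandle(spec, forward, params)
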