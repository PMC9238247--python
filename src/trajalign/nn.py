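"""Minimal reverse-mode autodiff core and the two trainable networks.

The model has two parts. The gene activity module is a bias-free three-layer
MLP (regions -> 1024 -> 512 -> genes, leaky-ReLU slope 0.2) that learns a
nonlinear, data-specific gene activity function turning region accessibility
into pseudo gene expression. The projection module (genes -> 512 -> 128 ->
latent) embeds (pseudo) expression profiles into the shared latent space.
Batch normalization sits after each hidden linear layer, before the
activation; in the gene activity module the norm's shift term is disabled so
the whole map stays bias-free (zero input -> zero output at eval time).

The autodiff core is a small tape-based Tensor over NumPy arrays: enough ops
for the losses used here, checked against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tensor",
    "Linear",
    "BatchNorm",
    "GeneActivityNet",
    "ProjectionNet",
    "ModelState",
    "Adam",
    "init_model",
    "gene_activity_forward",
    "project",
    "effective_linear_map",
]

LEAKY_SLOPE = 0.2


# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad over the axes that broadcasting expanded to reach `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def _wrap(self, x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # plain numbers adopt this tensor's dtype so float32 graphs stay float32
        if np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0):
            return Tensor(np.asarray(x, dtype=self.data.dtype))
        return Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * np.power(self.data, p - 1),)
        return self._make(np.power(self.data, p), (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        def backward(g):
            return (g @ other.data.T, self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,),
                          lambda g: (g * 0.5 / out_data,))

    def abs(self):
        return self._make(np.abs(self.data), (self,),
                          lambda g: (g * np.sign(self.data),))

    def leaky_relu(self, slope: float = LEAKY_SLOPE):
        mask = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return self._make(self.data[idx], (self,), backward)

    # -- engine ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)
        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._prev, t._backward(t.grad)):
                if parent.requires_grad:
                    parent.grad = g if parent.grad is None else parent.grad + g

    def item(self) -> float:
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear:
    """Bias-free linear layer y = x @ W.T with Kaiming fan-in init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_out, n_in)).astype(dtype),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W.T

    def parameters(self):
        return [self.W]


class BatchNorm:
    """Batch normalization over the cell axis.

    Training mode normalizes by minibatch statistics and updates running
    statistics; eval mode uses the frozen running statistics. The shift
    (beta) can be disabled to keep a network bias-free.
    """

    def __init__(self, n: int, affine_shift: bool = True,
                 momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(n, dtype=dtype), requires_grad=True)
        self.beta = (Tensor(np.zeros(n, dtype=dtype), requires_grad=True)
                     if affine_shift else None)
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)
        self.update_running = True  # set False for batch-stat inference
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training:
            scale = (self.running_var + self.eps) ** -0.5
            xhat = (x - self.running_mean.astype(x.data.dtype)) \
                * scale.astype(x.data.dtype)
            out = xhat * self.gamma
            return out + self.beta if self.beta is not None else out
        # fused train-mode op with the closed-form batch-norm backward
        n = x.shape[0]
        mu = x.data.mean(axis=0)
        xc = x.data - mu
        var = (xc * xc).mean(axis=0)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv_std
        if self.update_running:
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * var * (n / max(n - 1, 1))).astype(
                self.running_var.dtype)

        gamma, beta = self.gamma, self.beta
        out_data = xhat * gamma.data + (beta.data if beta is not None else 0.0)

        def backward(g):
            dgamma = (g * xhat).sum(axis=0)
            gh = g * gamma.data  # grad wrt xhat
            dx = inv_std / n * (n * gh - gh.sum(axis=0)
                                - xhat * (gh * xhat).sum(axis=0))
            grads = (dx, dgamma)
            if beta is not None:
                grads += (g.sum(axis=0),)
            return grads

        out = Tensor(out_data)
        parents = (x, gamma) + ((beta,) if beta is not None else ())
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def parameters(self):
        return [self.gamma] + ([self.beta] if self.beta is not None else [])


class _MLP:
    """Stack of bias-free linear layers with batch norm + leaky ReLU between."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 slope: float, use_norm: bool, affine_shift: bool,
                 dtype=np.float64):
        self.slope = slope
        self.use_norm = use_norm
        self.linears = [Linear(dims[i], dims[i + 1], rng, dtype=dtype)
                        for i in range(len(dims) - 1)]
        self.norms = ([BatchNorm(dims[i + 1], affine_shift=affine_shift,
                                 dtype=dtype)
                       for i in range(len(dims) - 2)] if use_norm else [])

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.linears):
            x = lin(x)
            if i < len(self.linears) - 1:
                if self.use_norm:
                    x = self.norms[i](x)
                x = x.leaky_relu(self.slope)
        return x

    def train(self, mode: bool = True):
        for bn in self.norms:
            bn.training = mode

    def parameters(self):
        out = []
        for lin in self.linears:
            out += lin.parameters()
        for bn in self.norms:
            out += bn.parameters()
        return out


class GeneActivityNet(_MLP):
    """regions -> 1024 -> 512 -> genes, no bias anywhere (norm shift disabled)."""

    def __init__(self, n_regions: int, n_genes: int, rng,
                 hidden=(1024, 512), slope: float = LEAKY_SLOPE,
                 use_norm: bool = True, dtype=np.float64):
        super().__init__([n_regions, *hidden, n_genes], rng, slope,
                         use_norm, affine_shift=False, dtype=dtype)
        self.n_regions, self.n_genes = n_regions, n_genes


class ProjectionNet(_MLP):
    """genes -> 512 -> 128 -> latent."""

    def __init__(self, n_genes: int, n_latent: int, rng,
                 hidden=(512, 128), slope: float = LEAKY_SLOPE,
                 use_norm: bool = True, dtype=np.float64):
        super().__init__([n_genes, *hidden, n_latent], rng, slope,
                         use_norm, affine_shift=True, dtype=dtype)
        self.n_genes, self.n_latent = n_genes, n_latent


@dataclass
class ModelState:
    gact: GeneActivityNet
    proj: ProjectionNet
    rng_seed: int
    config: dict = field(default_factory=dict)

    def train(self, mode: bool = True):
        self.gact.train(mode)
        self.proj.train(mode)

    def inference_mode(self):
        """Deterministic full-batch inference: normalization layers use the
        statistics of the batch being embedded (the regime the alignment
        losses were trained under) without touching the running averages.

        Frozen running-average statistics (train(False)) reintroduce the
        cross-modality shift that train-mode normalization removed during
        optimization, which un-merges the batches; full-batch statistics at
        output time preserve the trained alignment and are deterministic for
        a fixed input matrix.
        """
        self.train(True)
        for bn in self.gact.norms + self.proj.norms:
            bn.update_running = False

    def parameters(self):
        return self.gact.parameters() + self.proj.parameters()

    def snapshot_gact(self) -> list[np.ndarray]:
        """Copies of all gene-activity-module arrays (weights + norm stats)."""
        arrs = [p.data.copy() for p in self.gact.parameters()]
        for bn in self.gact.norms:
            arrs += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrs

    def save(self, path) -> None:
        arrs = {}
        for name, net in (("gact", self.gact), ("proj", self.proj)):
            for i, p in enumerate(net.parameters()):
                arrs[f"{name}_p{i}"] = p.data
            for i, bn in enumerate(net.norms):
                arrs[f"{name}_bn{i}_mean"] = bn.running_mean
                arrs[f"{name}_bn{i}_var"] = bn.running_var
        np.savez(path, seed=self.rng_seed, **arrs)

    def load(self, path) -> None:
        """Restore weights and normalization statistics saved by save();
        the model must have been built with the same architecture."""
        with np.load(path) as arrs:
            for name, net in (("gact", self.gact), ("proj", self.proj)):
                for i, p in enumerate(net.parameters()):
                    saved = arrs[f"{name}_p{i}"]
                    if saved.shape != p.data.shape:
                        raise ValueError(
                            f"checkpoint {name} parameter {i} has shape "
                            f"{saved.shape}, expected {p.data.shape}")
                    p.data = saved.astype(p.data.dtype)
                for i, bn in enumerate(net.norms):
                    bn.running_mean = arrs[f"{name}_bn{i}_mean"]
                    bn.running_var = arrs[f"{name}_bn{i}_var"]


def init_model(n_regions: int, n_genes: int, n_latent: int, seed: int = 0,
               hidden_gact=(1024, 512), hidden_proj=(512, 128),
               use_norm: bool = True, gact_norm: bool | None = None,
               gam_init: np.ndarray | None = None,
               dtype=np.float64) -> ModelState:
    """Seeded model construction; identical seed gives identical parameters.

    gam_init (a binary regions x genes prior) warm-starts the gene activity
    module at the linear prior transfer; this disables that module's
    normalization layers by default so the warm output stays nonnegative.
    dtype=float32 roughly halves training cost; float64 is the default for
    exact agreement with the analytic test oracles.
    """
    for name, v in (("n_regions", n_regions), ("n_genes", n_genes),
                    ("n_latent", n_latent)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if gact_norm is None:
        gact_norm = use_norm and gam_init is None
    rng = np.random.default_rng(seed)
    gact = GeneActivityNet(n_regions, n_genes, rng, hidden=hidden_gact,
                           use_norm=gact_norm, dtype=dtype)
    proj = ProjectionNet(n_genes, n_latent, rng, hidden=hidden_proj,
                         use_norm=use_norm, dtype=dtype)
    if gam_init is not None:
        warm_start_gene_activity(gact, gam_init)
    return ModelState(gact, proj, seed,
                      {"hidden_gact": tuple(hidden_gact),
                       "hidden_proj": tuple(hidden_proj),
                       "latent_dim": n_latent, "use_norm": use_norm,
                       "gact_norm": gact_norm,
                       "warm_start": gam_init is not None,
                       "dtype": np.dtype(dtype).name})


def warm_start_gene_activity(gact: GeneActivityNet, A: np.ndarray,
                             eps: float = 0.01) -> None:
    """Initialize the gene activity module at the linear prior transfer.

    Sets the weights so the end-to-end map is approximately x -> x @ (A /
    colsum(A)) — each gene starts as the mean accessibility of its linked
    regions, the classical gene-activity-score transform — routed through an
    identity path in the hidden layers; the remaining hidden capacity gets
    eps-scaled random output weights so training can grow the nonlinear
    refinement. Starting at the prior transform anchors pseudo-expression in
    the expression data's region of gene space, which is what lets the
    shared projection merge the modalities with a consistent orientation.
    """
    W1, W2, W3 = (lin.W.data for lin in gact.linears)
    G = gact.n_genes
    h1, h2 = W1.shape[0], W2.shape[0]
    if G > min(h1, h2):
        raise ValueError(
            f"warm start needs hidden sizes >= n_genes ({G}); "
            f"got ({h1}, {h2})")
    A = np.asarray(A, dtype=W1.dtype)
    links = np.maximum(A.sum(axis=0), 1.0)
    W1[:G] = (A / links).T
    W2 *= eps
    W2[:G, :] = 0.0
    W2[:G, :G] = np.eye(G, dtype=W2.dtype)
    W3 *= eps
    W3[:, :G] = 0.0
    W3[:G, :G] = np.eye(G, dtype=W3.dtype)


def gene_activity_forward(gact: GeneActivityNet, X_atac) -> Tensor:
    """Pseudo gene-expression prediction for a cells x regions matrix."""
    X_atac = as_tensor(X_atac)
    if X_atac.shape[1] != gact.n_regions:
        raise ValueError(
            f"expected {gact.n_regions} regions, got {X_atac.shape[1]}"
        )
    return gact(X_atac)


def project(proj: ProjectionNet, X) -> Tensor:
    """Latent embedding of a cells x genes matrix."""
    X = as_tensor(X)
    if np.any(~np.isfinite(X.data)):
        raise ValueError("non-finite values in projection input")
    if X.shape[1] != proj.n_genes:
        raise ValueError(f"expected {proj.n_genes} genes, got {X.shape[1]}")
    return proj(X)


def effective_linear_map(gact: GeneActivityNet) -> Tensor:
    """End-to-end linear map of the gene activity module, regions x genes.

    The product of the layer weights (activations and normalization scales
    ignored) transposed to align with the regions x genes GAM; this is the
    object the sparsity prior penalizes.
    """
    M = None
    for lin in gact.linears:
        M = lin.W if M is None else lin.W @ M
    return M.T


class Adam:
    """Adam optimizer over a fixed list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
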