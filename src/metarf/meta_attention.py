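"""Meta-learned attention over tree outputs (the MetaRF head).

The head f_theta is a small feed-forward regressor (input M -> 40 -> 40 -> 1,
ReLU hidden activations, linear output) that maps the M-vector of per-tree
predictions x' to a single yield.  Its parameters are meta-trained with
MAML over reagent-defined tasks: for each sampled task, one inner gradient
step on the task's support pairs produces adapted parameters, and the outer
objective is the query loss at those adapted parameters,

    min_theta  sum_i  L_Ti( f_{theta - alpha * grad L_Ti(f_theta)} )

optimized with Adam.  At test time the meta-trained head is adapted to an
unseen reagent with exactly one gradient step on a handful of measured
support reactions (fine-tuning), then used for prediction.

Gradients are computed by analytic backpropagation in numpy.  The
second-order MAML term (the Hessian-vector product arising from
differentiating through the inner step) is computed by complex-step
differentiation of the gradient, which is exact to machine precision for
piecewise-linear networks: for support-loss gradient g_s,

    H_s(theta) v  =  Im[ g_s(theta + i*h*v) ] / h

with no subtractive cancellation, so h can be made arbitrarily small.

Two numerical choices make one-step adaptation at a small alpha workable:

* the head operates on standardized tree outputs and variance-scaled
  yields (statistics taken from the meta-training pool; all reported
  metrics stay on the percent scale via the inverse transform), keeping
  every activation at unit order so a single gradient step is stable;
* the initialization encodes *uniform attention* — f_theta0 equals the
  plain ensemble-mean prediction exactly — plus a pair of high-gain
  adaptation units whose contributions cancel at theta0 but give the
  inner gradient step a unit-order effect on a task's systematic offset
  (outgoing weights +-g with g = 0.8 / (2 sqrt(alpha))).  Without such a
  path, one step at alpha = 1e-4 barely moves the predictions and no
  realistic amount of outer-loop training can recover the lost gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_HIDDEN = 40
_CSTEP = 1e-60  # complex-step size; exact for any h small enough to linearize


# ---------------------------------------------------------------------------
# parameter pytree helpers

Params = dict[str, np.ndarray]

_PARAM_KEYS = ("W1", "b1", "W2", "b2", "w3", "b3")


def _zeros_like(p: Params) -> Params:
    return {k: np.zeros_like(v, dtype=float) for k, v in p.items()}


def _axpy(a: float, x: Params, y: Params) -> Params:
    """y + a * x, elementwise over the parameter tree."""
    return {k: y[k] + a * x[k] for k in y}


def _dot(x: Params, y: Params) -> float:
    return float(sum(np.vdot(x[k], y[k]).real for k in x))


@dataclass(frozen=True)
class AttentionHead:
    """Parameters theta of the tree-output regressor f_theta.

    ``attention_weights`` exposes the magnitude of each tree's first-layer
    weight column — the per-tree "attention" the meta-learner assigns.
    """

    params: Params
    input_dim: int

    @classmethod
    def initialize(cls, input_dim: int, seed: int, hidden: int = _HIDDEN) -> "AttentionHead":
        """Fan-in-scaled normal initialization (std = 1/sqrt(fan_in))."""
        rng = np.random.default_rng(seed)
        p = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(input_dim), (input_dim, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, hidden)),
            "b2": np.zeros(hidden),
            "w3": rng.normal(0.0, 1.0 / np.sqrt(hidden), hidden),
            "b3": np.zeros(()),
        }
        return cls(params=p, input_dim=input_dim)

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """f_theta applied row-wise; accepts (n, M) or a single M-vector."""
        x = np.asarray(x)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.input_dim:
            raise ValueError(f"input dim {x.shape[1]} != head input dim {self.input_dim}")
        out = _forward_cached(self.params, x)[0]
        return out[0] if single else out

    __call__ = forward

    def attention_weights(self) -> np.ndarray:
        """L2 norm of each input (tree) column of the first layer."""
        return np.linalg.norm(self.params["W1"], axis=1)


@dataclass(frozen=True)
class Scaler:
    """Input/target standardization, statistics from the meta-training pool.

    The head always sees standardized inputs and targets divided by their
    pooled standard deviation (and centered); predictions are mapped back
    to percent with :meth:`inverse_y`, so every reported metric stays on
    the percent-yield scale.
    """

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray) -> "Scaler":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sd = x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        ysd = y.std() or 1.0
        return cls(x_mean=x.mean(axis=0), x_sd=sd,
                   y_mean=float(y.mean()), y_sd=float(ysd))

    @classmethod
    def identity(cls, dim: int) -> "Scaler":
        return cls(x_mean=np.zeros(dim), x_sd=np.ones(dim), y_mean=0.0, y_sd=1.0)

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_y(self, pred: np.ndarray) -> np.ndarray:
        return np.asarray(pred) * self.y_sd + self.y_mean


def default_adaptation_gain(alpha: float) -> float:
    """Outgoing weight of the adaptation-unit pair, 0.8 / (2 sqrt(alpha)).

    Chosen so that one inner gradient step of size alpha moves the
    prediction by roughly the task's mean residual (gain^2 * 4 * alpha
    is of order one) while staying inside the one-step stability region
    of the unit-scale geometry.
    """
    if alpha <= 0:
        return 0.0
    return 0.8 / (2.0 * np.sqrt(alpha))


def default_attention_amplification(alpha: float, input_dim: int) -> float:
    """Gradient amplification of the per-tree attention column.

    The passthrough weights are divided by this factor and their
    downstream weight multiplied by it, leaving the initial function
    unchanged while scaling the inner-step update of the per-tree
    attention weights.  0.8 * sqrt(1 / (alpha * M)) puts the one-step
    update of the attention column at the edge of its stability region
    (the support Gram matrix of M standardized, correlated tree outputs
    has top eigenvalue of order M), so a single fine-tune step can
    re-weight trees, not just shift the output.
    """
    if alpha <= 0:
        return 1.0
    return max(1.0, 0.8 / np.sqrt(alpha * input_dim))


def initialize_uniform_attention(
    input_dim: int,
    seed: int,
    scaler: Scaler,
    alpha: float = 1e-4,
    hidden: int = _HIDDEN,
    eps: float = 0.01,
    gain: float | None = None,
) -> AttentionHead:
    """Head whose initial function is exactly the ensemble-mean prediction.

    Two passthrough units encode mean_m(x'_m) (uniform attention over
    trees, expressed in the scaler's standardized coordinates); a pair of
    high-gain units with cancelling outputs provides the fast-adaptation
    path; every remaining weight is small random (scale ``eps``) so
    meta-training can grow structure from a near-symmetric start.
    """
    if hidden < 4:
        raise ValueError("need at least 4 hidden units")
    rng = np.random.default_rng(seed)
    p = {
        "W1": rng.normal(0.0, eps / np.sqrt(input_dim), (input_dim, hidden)),
        "b1": np.zeros(hidden),
        "W2": rng.normal(0.0, eps / np.sqrt(hidden), (hidden, hidden)),
        "b2": np.zeros(hidden),
        # output weights of the spare units start at zero so the initial
        # function is exactly the ensemble mean; training revives them
        "w3": np.zeros(hidden),
        "b3": np.zeros(()),
    }
    # uniform attention: f(x_std) = [mean_m(x'_m) - y_mean] / y_sd, with the
    # attention column down-scaled by c and re-amplified downstream so the
    # inner step can re-weight trees
    c = default_attention_amplification(alpha, input_dim)
    bias = (scaler.x_mean.mean() - scaler.y_mean) / scaler.y_sd
    p["W1"][:, 0] = scaler.x_sd / (input_dim * scaler.y_sd * c)
    p["W1"][:, 1] = -p["W1"][:, 0]
    p["b1"][0], p["b1"][1] = bias / c, -bias / c
    p["W2"][:, 0] = 0.0
    p["W2"][:, 1] = 0.0
    p["W2"][0, 0] = c
    p["W2"][1, 1] = c
    p["w3"][0], p["w3"][1] = 1.0, -1.0
    # adaptation pair: constant unit-activations, cancelling +-gain outputs
    g = default_adaptation_gain(alpha) if gain is None else gain
    p["W2"][:, 2] = 0.0
    p["W2"][:, 3] = 0.0
    p["b2"][2], p["b2"][3] = 1.0, 1.0
    p["w3"][2], p["w3"][3] = g, -g
    return AttentionHead(params=p, input_dim=input_dim)


def initialize_adaptive(
    input_dim: int,
    seed: int,
    alpha: float = 1e-4,
    hidden: int = _HIDDEN,
    eps: float = 0.01,
    gain: float | None = None,
) -> AttentionHead:
    """Small random head plus the adaptation-unit pair (no forest prior).

    Used when the head regresses on raw reaction features (the
    forest-free ablation): there is no ensemble mean to start from, so
    the initial function is near zero (the pooled mean, in scaled
    coordinates) and only the fast-adaptation path is planted.
    """
    if hidden < 2:
        raise ValueError("need at least 2 hidden units")
    rng = np.random.default_rng(seed)
    p = {
        "W1": rng.normal(0.0, eps / np.sqrt(input_dim), (input_dim, hidden)),
        "b1": np.zeros(hidden),
        "W2": rng.normal(0.0, eps / np.sqrt(hidden), (hidden, hidden)),
        "b2": np.zeros(hidden),
        "w3": rng.normal(0.0, eps / np.sqrt(hidden), hidden),
        "b3": np.zeros(()),
    }
    g = default_adaptation_gain(alpha) if gain is None else gain
    p["W2"][:, 0] = 0.0
    p["W2"][:, 1] = 0.0
    p["b2"][0], p["b2"][1] = 1.0, 1.0
    p["w3"][0], p["w3"][1] = g, -g
    return AttentionHead(params=p, input_dim=input_dim)


def _relu(z: np.ndarray) -> np.ndarray:
    # mask on the real part keeps the complex-step tangent exact
    return np.where(z.real > 0, z, np.zeros((), dtype=z.dtype))


def _forward_cached(p: Params, x: np.ndarray):
    z1 = x @ p["W1"] + p["b1"]
    h1 = _relu(z1)
    z2 = h1 @ p["W2"] + p["b2"]
    h2 = _relu(z2)
    out = h2 @ p["w3"] + p["b3"]
    return out, (x, z1, h1, z2, h2)


def task_loss(head: AttentionHead, x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of f_theta over the given (x', y) pairs."""
    x = np.atleast_2d(np.asarray(x))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("task_loss requires at least one pair")
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y lengths differ")
    pred = head.forward(x)
    return float(np.mean((pred - y) ** 2))


def _loss_grad(p: Params, x: np.ndarray, y: np.ndarray) -> Params:
    """Backprop gradient of the mean-squared task loss; complex-safe."""
    n = x.shape[0]
    out, (x_, z1, h1, z2, h2) = _forward_cached(p, x)
    dout = 2.0 * (out - y) / n
    g = {}
    g["w3"] = h2.T @ dout
    g["b3"] = np.sum(dout)
    dh2 = np.outer(dout, p["w3"])
    dz2 = np.where(z2.real > 0, dh2, np.zeros((), dtype=dh2.dtype))
    g["W2"] = h1.T @ dz2
    g["b2"] = dz2.sum(axis=0)
    dh1 = dz2 @ p["W2"].T
    dz1 = np.where(z1.real > 0, dh1, np.zeros((), dtype=dh1.dtype))
    g["W1"] = x_.T @ dz1
    g["b1"] = dz1.sum(axis=0)
    return g


def loss_gradient(head: AttentionHead, x: np.ndarray, y: np.ndarray) -> Params:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    g = _loss_grad(head.params, x, y)
    if not all(np.all(np.isfinite(v)) for v in g.values()):
        raise FloatingPointError("non-finite gradient")
    return g


def _support_hvp(p: Params, x: np.ndarray, y: np.ndarray, v: Params) -> Params:
    """Hessian-vector product of the support loss via complex step."""
    norm = np.sqrt(_dot(v, v))
    if norm == 0.0:
        return _zeros_like(v)
    h = _CSTEP
    pc = {k: p[k].astype(complex) + 1j * h * (v[k] / norm) for k in p}
    gc = _loss_grad(pc, x.astype(complex), y.astype(complex))
    return {k: norm * gc[k].imag / h for k in gc}


def inner_update(
    head: AttentionHead, support_x: np.ndarray, support_y: np.ndarray, alpha: float
) -> AttentionHead:
    """One gradient-descent step on the support loss; the input is unmodified.

    theta' = theta - alpha * grad task_loss(theta, support).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    sx = np.atleast_2d(np.asarray(support_x, dtype=float))
    sy = np.atleast_1d(np.asarray(support_y, dtype=float))
    if sx.shape[0] == 0:
        raise ValueError("support set is empty")
    g = loss_gradient(head, sx, sy)
    return replace(head, params=_axpy(-alpha, g, head.params))


def fine_tune(
    head_meta: AttentionHead, support_x: np.ndarray, support_y: np.ndarray, alpha: float
) -> AttentionHead:
    """Adapt the meta-trained head to a new reagent: exactly one inner step."""
    return inner_update(head_meta, support_x, support_y, alpha)


# ---------------------------------------------------------------------------
# tasks and meta-training

@dataclass(frozen=True)
class Task:
    """Support/query split of the reactions sharing one group value."""

    group_value: str
    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray


@dataclass(frozen=True)
class MetaConfig:
    """Meta-training configuration.

    inner_lr is the single step size alpha used both for the inner update
    during meta-training and for test-time fine-tuning.  The outer optimizer
    is Adam.  second_order=True differentiates through the inner step
    (exact MAML); the first-order approximation drops the Hessian term.
    """

    inner_lr: float = 1e-4
    outer_lr: float = 1e-3
    meta_iterations: int = 80
    support_size: int = 40
    tasks_per_iteration: int = 1
    second_order: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.inner_lr < 0:
            raise ValueError("inner_lr must be >= 0")
        if self.support_size < 1:
            raise ValueError("support_size must be >= 1")
        if self.meta_iterations < 0:
            raise ValueError("meta_iterations must be >= 0")


TaskPool = dict[str, tuple[np.ndarray, np.ndarray]]


def sample_task(
    dataset_pool: TaskPool, k: int, seed: int | np.random.Generator
) -> Task:
    """Draw one task: a uniform group, K support pairs, the rest as query.

    Groups with at most K pairs are excluded from sampling; if every group
    is excluded, raises ValueError.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = [g for g, (x, y) in dataset_pool.items() if len(y) > k]
    if not eligible:
        raise ValueError(f"no group has more than K={k} pairs")
    group = eligible[rng.integers(len(eligible))]
    x, y = dataset_pool[group]
    idx = rng.permutation(len(y))
    s, q = idx[:k], idx[k:]
    return Task(
        group_value=group,
        support_x=np.asarray(x)[s],
        support_y=np.asarray(y)[s],
        query_x=np.asarray(x)[q],
        query_y=np.asarray(y)[q],
    )


def outer_gradient(head: AttentionHead, task: Task, config: MetaConfig) -> Params:
    """Gradient of the post-inner-update query loss with respect to theta.

    With theta' = theta - alpha * g_s(theta):
        d/dtheta L_q(theta') = (I - alpha * H_s(theta)) g_q(theta')
    The Hessian term is kept when config.second_order, dropped otherwise.
    """
    adapted = inner_update(head, task.support_x, task.support_y, config.inner_lr)
    gq = loss_gradient(adapted, task.query_x, task.query_y)
    if not config.second_order or config.inner_lr == 0.0:
        return gq
    hv = _support_hvp(
        head.params,
        np.atleast_2d(np.asarray(task.support_x, dtype=float)),
        np.atleast_1d(np.asarray(task.support_y, dtype=float)),
        gq,
    )
    return _axpy(-config.inner_lr, hv, gq)


@dataclass
class _AdamState:
    m: Params
    v: Params
    t: int = 0

    def step(self, params: Params, grad: Params, lr: float,
             b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> Params:
        self.t += 1
        new = {}
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grad[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grad[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            new[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
        return new


@dataclass
class MetaTrainResult:
    head: AttentionHead
    val_history: list[tuple[int, float]] = field(default_factory=list)


def meta_train(
    task_pool: TaskPool,
    input_dim: int,
    config: MetaConfig = MetaConfig(),
    init_head: AttentionHead | None = None,
    val_pool: TaskPool | None = None,
    early_stopping: bool = False,
    val_support_size: int | None = None,
    return_result: bool = False,
) -> AttentionHead | MetaTrainResult:
    """MAML meta-training of the attention head over reagent tasks.

    Each outer iteration samples ``tasks_per_iteration`` tasks, sums their
    post-inner-update query-loss gradients (the outer objective is the sum
    of adapted task losses) and takes one Adam step.  The full trajectory
    is deterministic for a fixed ``config.seed``.

    When ``val_pool`` is given, the post-fine-tune query loss on a
    validation task is logged every 10 iterations; with ``early_stopping``
    the head with the best logged validation loss is returned.
    """
    if not task_pool:
        raise ValueError("empty task pool")
    rng = np.random.default_rng(config.seed)
    init_seed = int(rng.integers(2**31))
    head = init_head if init_head is not None \
        else AttentionHead.initialize(input_dim, seed=init_seed)
    if head.input_dim != input_dim:
        raise ValueError("init_head input_dim mismatch")
    adam = _AdamState(m=_zeros_like(head.params), v=_zeros_like(head.params))
    history: list[tuple[int, float]] = []

    val_k = val_support_size if val_support_size else config.support_size

    def _val_loss(h: AttentionHead, n_draws: int = 5) -> float:
        """Post-fine-tune query loss on the validation group(s), averaged
        over several seeded support draws to tame single-draw noise.
        The support size mirrors deployment (val_support_size), not the
        meta-training K, so checkpoint selection tests what is used."""
        losses = []
        for g, (x, y) in val_pool.items():
            k = min(val_k, len(y) - 1)
            if k < 1:
                continue
            vrng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 17, len(y)]))
            for _ in range(n_draws):
                idx = vrng.permutation(len(y))
                s, q = idx[:k], idx[k:]
                adapted = inner_update(h, x[s], y[s], config.inner_lr)
                losses.append(task_loss(adapted, x[q], y[q]))
        return float(np.mean(losses)) if losses else np.inf

    if val_pool is not None:
        # iteration 0 = the initialization itself, so a meta-training run
        # that never improves the validation task cannot make things worse
        history.append((0, _val_loss(head)))
    best = (history[0][1] if history else np.inf, head)

    for it in range(config.meta_iterations):
        total = _zeros_like(head.params)
        for _ in range(config.tasks_per_iteration):
            task = sample_task(task_pool, config.support_size, rng)
            g = outer_gradient(head, task, config)
            total = _axpy(1.0, g, total)
        head = replace(head, params=adam.step(head.params, total, config.outer_lr))
        if val_pool is not None and (it + 1) % 10 == 0:
            vl = _val_loss(head)
            history.append((it + 1, vl))
            if vl < best[0]:
                best = (vl, head)

    if early_stopping and val_pool is not None and history:
        head = best[1]
    if return_result:
        return MetaTrainResult(head=head, val_history=history)
    return head


def predict(forest, head: AttentionHead, features: np.ndarray,
            scaler: Scaler | None = None, clip: bool = False) -> np.ndarray:
    """Compose the frozen forest with the head: f_theta(tree_transform(x)).

    ``scaler`` (when the head was trained in standardized coordinates)
    maps tree outputs in and predictions back to percent.  With ``clip``
    the outputs are clamped to the physical [0, 100] yield range.
    """
    from .forest_core import tree_transform

    xprime = tree_transform(forest, features).values
    if scaler is not None:
        pred = scaler.inverse_y(head.forward(scaler.transform_x(xprime)))
    else:
        pred = head.forward(xprime)
    if clip:
        pred = np.clip(pred, 0.0, 100.0)
    return pred
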