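"""Benchmark protocol, metrics, ablations, top-k selection and importance.

The central protocol is the leave-reagent-out few-shot benchmark: fit the
forest on the training groups, meta-train the attention head on
training-group tasks, and for every held-out test group select a handful of
support reactions (t-SNE + Kennard-Stone by default), adapt the head with
one gradient step, and score the predictions on the group's remaining
(query) reactions.  The random-forest baseline is given the same support
reactions appended to its training set — fairness demands every method see
the same data — and predicts with the plain ensemble mean.  Support
reactions are never scored as queries, for any method.

Metrics (R^2, RMSE, MAE) are on the percent-yield scale and are reported
pooled over the union of all test-group queries (per-group values are kept
as well).  Feature importance follows the permutation-and-retrain recipe:
the drop in pooled R^2 after shuffling a feature block across reactions and
retraining the entire pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fewshot_sampling import EmbeddingConfig, select_fewshot
from .forest_core import Forest, ForestConfig, fit_forest, tree_transform
from .meta_attention import (
    AttentionHead,
    MetaConfig,
    Scaler,
    _AdamState,
    _zeros_like,
    fine_tune,
    initialize_adaptive,
    task_loss,
    initialize_uniform_attention,
    loss_gradient,
    meta_train,
)
from .reaction_data import ReactionDataset, SplitSpec

logger = logging.getLogger(__name__)

_VARIANTS = (
    "metarf_random_sampling",
    "maml_on_raw_features",
    "transfer_head",
    "transfer_head_random_sampling",
)


# ---------------------------------------------------------------------------
# metrics

def r2(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    yt, yp = _check_pair(y_true, y_pred)
    ss_tot = np.sum((yt - yt.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("r2 undefined: y_true is constant")
    return float(1.0 - np.sum((yt - yp) ** 2) / ss_tot)


def rmse(y_true, y_pred) -> float:
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def mae(y_true, y_pred) -> float:
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(yt - yp)))


def _check_pair(y_true, y_pred):
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return yt, yp


@dataclass(frozen=True)
class TopKResult:
    mean: float
    sd: float
    indices: np.ndarray | None


def topk_selection(
    y_true, y_pred, k: int, mode: str = "predicted",
    n_draws: int = 1000, seed: int = 0,
) -> TopKResult:
    """True-yield statistics of the k reactions ranked best by ``mode``.

    "predicted" ranks by y_pred (ties to the lower index), "ideal" by
    y_true itself, and "random" averages mean and sd over ``n_draws``
    seeded uniform draws of k reactions.
    """
    yt, yp = _check_pair(y_true, y_pred)
    if k > yt.size:
        raise ValueError(f"k={k} exceeds number of reactions {yt.size}")
    if mode == "random":
        rng = np.random.default_rng(seed)
        means, sds = [], []
        for _ in range(n_draws):
            pick = rng.choice(yt.size, size=k, replace=False)
            means.append(yt[pick].mean())
            sds.append(yt[pick].std(ddof=0))
        return TopKResult(float(np.mean(means)), float(np.mean(sds)), None)
    score = yt if mode == "ideal" else yp
    order = np.argsort(-score, kind="stable")[:k]
    chosen = yt[order]
    return TopKResult(float(chosen.mean()), float(chosen.std(ddof=0)), order)


# ---------------------------------------------------------------------------
# benchmark results

@dataclass
class SeedResult:
    seed: int
    pooled: dict[str, float]
    per_group: dict[str, dict[str, float]]
    topk: TopKResult
    y_true: np.ndarray
    y_pred: np.ndarray


@dataclass
class BenchmarkResult:
    """Few-shot benchmark outcome for one method over a set of seeds."""

    method: str
    n_finetune: int
    seeds: tuple[int, ...]
    per_seed: list[SeedResult] = field(default_factory=list)

    def mean_metric(self, name: str) -> float:
        return float(np.mean([s.pooled[name] for s in self.per_seed]))

    def std_metric(self, name: str) -> float:
        return float(np.std([s.pooled[name] for s in self.per_seed]))

    def summary(self) -> dict[str, float]:
        return {
            "r2": self.mean_metric("r2"),
            "rmse": self.mean_metric("rmse"),
            "mae": self.mean_metric("mae"),
        }


# ---------------------------------------------------------------------------
# pipeline engine

def build_task_pool(
    dataset: ReactionDataset,
    indices: np.ndarray,
    transform,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group -> (inputs, yields) over the given record indices.

    ``transform`` maps an N x d feature matrix to the head's input space
    (per-tree outputs for MetaRF, identity for the forest-free ablation).
    """
    pool: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    groups = dataset.groups
    feats = dataset.features
    ys = dataset.yields
    for g in sorted(set(groups[indices])):
        gi = indices[groups[indices] == g]
        pool[g] = (transform(feats[gi]), ys[gi])
    return pool


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


def _pretrain_head(pool, input_dim, config: MetaConfig,
                   init: AttentionHead | None = None) -> AttentionHead:
    """Standard pretraining (no inner loop): Adam on pooled minibatches."""
    x_all = np.vstack([x for x, _ in pool.values()])
    y_all = np.concatenate([y for _, y in pool.values()])
    rng = np.random.default_rng(config.seed)
    head = init if init is not None \
        else AttentionHead.initialize(input_dim, seed=int(rng.integers(2**31)))
    adam = _AdamState(m=_zeros_like(head.params), v=_zeros_like(head.params))
    batch = min(config.support_size, len(y_all))
    for _ in range(config.meta_iterations):
        pick = rng.choice(len(y_all), size=batch, replace=False)
        g = loss_gradient(head, x_all[pick], y_all[pick])
        head = replace(head, params=adam.step(head.params, g, config.outer_lr))
    return head


@dataclass
class _RunSpec:
    use_forest: bool = True
    head_training: str = "maml"      # "maml" | "transfer"
    selection: str = "ks"            # "ks" | "random"
    selection_reps: int = 1


def _guarded_fine_tune(head, support_x, support_y, alpha, max_halvings: int = 6):
    """One fine-tune step with a backtracking stability guard.

    The high-gain adaptation paths are sized for a typical support batch;
    an unlucky draw (near-duplicate supports, extreme leverage) can put
    one full step outside its stability region.  If the step increases
    the support loss, the step size is halved and the step retaken —
    still exactly one gradient step, on the support data only.
    """
    before = task_loss(head, support_x, support_y)
    a = alpha
    for _ in range(max_halvings):
        adapted = fine_tune(head, support_x, support_y, a)
        if task_loss(adapted, support_x, support_y) <= before:
            return adapted
        a /= 2.0
    return head


def _select_support(dataset, group, n, selection, embed_config, rng):
    cand = dataset.indices_of_group(group)
    if selection == "random":
        return rng.choice(cand, size=n, replace=False)
    return select_fewshot(dataset, group, n, embed_config).order


def _run_one_seed(
    dataset: ReactionDataset,
    split: SplitSpec,
    spec: _RunSpec,
    n_finetune: int,
    seed: int,
    forest_config: ForestConfig,
    meta_config: MetaConfig,
    embed_config: EmbeddingConfig,
    topk: int,
    clip: bool,
) -> tuple[SeedResult, SeedResult | None]:
    """Run the adapted method and the enlarged-training-set RF baseline."""
    s_forest, s_meta, s_embed, s_sel = _subseeds(seed, 4)
    split = replace(split, subsample_seed=seed) \
        if split.train_fraction_within_groups < 1.0 else split
    train_idx = split.train_indices(dataset)
    feats, ys = dataset.features, dataset.yields

    forest = None
    if spec.use_forest:
        forest = fit_forest(feats[train_idx], ys[train_idx],
                            replace(forest_config, seed=s_forest))
        base_transform = lambda X: tree_transform(forest, X).values  # noqa: E731
        input_dim = forest.m_trees
    else:
        base_transform = lambda X: np.asarray(X, dtype=float)  # noqa: E731
        input_dim = dataset.feature_dim

    # head works in unit-scale coordinates; metrics stay on percent scale
    scaler = Scaler.fit(base_transform(feats[train_idx]), ys[train_idx])
    transform = lambda X: scaler.transform_x(base_transform(X))  # noqa: E731

    mc = replace(meta_config, seed=s_meta)
    pool = build_task_pool(dataset, train_idx, transform)
    pool = {g: (x, scaler.transform_y(y)) for g, (x, y) in pool.items()}
    largest = max(len(y) for _, y in pool.values())
    if largest <= mc.support_size:
        capped = max(1, largest - 1)
        logger.warning("support_size %d too large for the training groups; "
                       "capping at %d", mc.support_size, capped)
        mc = replace(mc, support_size=capped)

    val_idx = split.val_indices(dataset)
    val_pool = None
    if val_idx.size:
        val_pool = {g: (x, scaler.transform_y(y)) for g, (x, y) in
                    build_task_pool(dataset, val_idx, transform).items()}

    if spec.use_forest:
        init = initialize_uniform_attention(input_dim, s_meta, scaler,
                                            alpha=mc.inner_lr)
    else:
        init = initialize_adaptive(input_dim, s_meta, alpha=mc.inner_lr)

    if spec.head_training == "transfer":
        head = _pretrain_head(pool, input_dim, mc, init)
    else:
        # the reserved validation group arbitrates: keep the checkpoint
        # (including the initialization) with the best post-fine-tune loss
        head = meta_train(pool, input_dim, mc, init_head=init,
                          val_pool=val_pool, early_stopping=True,
                          val_support_size=max(n_finetune, 1))

    test_groups = sorted(split.test_groups)
    rng_sel = np.random.default_rng(s_sel)
    rep_metrics: list[dict] = []
    baseline_result = None
    ec = replace(embed_config, seed=s_embed)

    for rep in range(spec.selection_reps):
        group_preds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        group_pre: dict[str, np.ndarray] = {}
        support_union: list[np.ndarray] = []
        for g in test_groups:
            cand = dataset.indices_of_group(g)
            if cand.size < n_finetune + 1:
                logger.warning("test group %s has only %d reactions; skipped",
                               g, cand.size)
                continue
            if n_finetune == 0:
                support = np.array([], dtype=int)
            else:
                support = _select_support(dataset, g, n_finetune,
                                          spec.selection, ec, rng_sel)
            query = np.setdiff1d(cand, support)
            support_union.append(support)
            if support.size:
                adapted = _guarded_fine_tune(head, transform(feats[support]),
                                             scaler.transform_y(ys[support]),
                                             mc.inner_lr)
            else:
                adapted = head
            xq = transform(feats[query])
            pred = scaler.inverse_y(adapted.forward(xq))
            pre = scaler.inverse_y(head.forward(xq))
            if clip:
                pred = np.clip(pred, 0.0, 100.0)
                pre = np.clip(pre, 0.0, 100.0)
            group_preds[g] = (ys[query], pred)
            group_pre[g] = pre
        if not group_preds:
            raise ValueError("no test group large enough to evaluate")
        m = _collect(group_preds, topk)
        yt_all = np.concatenate([v[0] for v in group_preds.values()])
        pre_all = np.concatenate(list(group_pre.values()))
        m["pooled"]["rmse_pre_adapt"] = rmse(yt_all, pre_all)
        rep_metrics.append(m)

        if rep == 0:
            # RF baseline: same supports appended to the training set
            all_support = (np.concatenate(support_union)
                           if support_union and n_finetune else np.array([], int))
            enlarged = np.concatenate([train_idx, all_support]).astype(int)
            bforest = fit_forest(feats[enlarged], ys[enlarged],
                                 replace(forest_config, seed=s_forest))
            bl_preds = {}
            for g, (yt, _) in group_preds.items():
                cand = dataset.indices_of_group(g)
                support = np.intersect1d(cand, all_support)
                query = np.setdiff1d(cand, support)
                bl_preds[g] = (ys[query], bforest.predict_mean(feats[query]))
            bm = _collect(bl_preds, topk)
            baseline_result = SeedResult(seed=seed, **bm)

    first = rep_metrics[0]
    if spec.selection_reps > 1:
        pooled = {k: float(np.mean([m["pooled"][k] for m in rep_metrics]))
                  for k in first["pooled"]}
        first = {**first, "pooled": pooled}
    return SeedResult(seed=seed, **first), baseline_result


def _collect(group_preds: dict[str, tuple[np.ndarray, np.ndarray]], topk: int) -> dict:
    yt = np.concatenate([v[0] for v in group_preds.values()])
    yp = np.concatenate([v[1] for v in group_preds.values()])
    per_group = {}
    for g, (gt, gp) in group_preds.items():
        per_group[g] = {
            "r2": r2(gt, gp) if np.std(gt) > 0 else np.nan,
            "rmse": rmse(gt, gp),
            "mae": mae(gt, gp),
            "n": int(gt.size),
        }
    k = min(topk, yt.size)
    return {
        "pooled": {"r2": r2(yt, yp), "rmse": rmse(yt, yp), "mae": mae(yt, yp)},
        "per_group": per_group,
        "topk": topk_selection(yt, yp, k),
        "y_true": yt,
        "y_pred": yp,
    }


def run_fewshot_benchmark(
    dataset: ReactionDataset,
    split: SplitSpec,
    method: str = "metarf",
    n_finetune: int = 5,
    seeds: tuple[int, ...] = (0,),
    forest_config: ForestConfig = ForestConfig(),
    meta_config: MetaConfig = MetaConfig(),
    embed_config: EmbeddingConfig = EmbeddingConfig(),
    topk: int = 10,
    clip: bool = False,
) -> BenchmarkResult:
    """Leave-reagent-out few-shot benchmark for one method.

    method "metarf": forest + meta-trained head, Kennard-Stone supports,
    one-step adaptation per test group.  method "rf_baseline": the same
    forest refit with every support reaction added to its training set,
    predicting with the ensemble mean.  Both are scored on identical query
    sets.  Repeated per seed; deterministic given (seeds, configs).
    """
    if method not in ("metarf", "rf_baseline"):
        raise ValueError(f"unknown method {method!r}")
    if not split.test_groups:
        raise ValueError("split has no test groups")
    result = BenchmarkResult(method=method, n_finetune=n_finetune,
                             seeds=tuple(seeds))
    spec = _RunSpec()
    for s in seeds:
        meta_res, base_res = _run_one_seed(
            dataset, split, spec, n_finetune, s, forest_config, meta_config,
            embed_config, topk, clip,
        )
        result.per_seed.append(meta_res if method == "metarf" else base_res)
    return result


def run_method_comparison(
    dataset, split, n_finetune=5, seeds=(0,), **kw
) -> dict[str, BenchmarkResult]:
    """MetaRF and the enlarged-training RF baseline on shared supports."""
    metarf = BenchmarkResult("metarf", n_finetune, tuple(seeds))
    base = BenchmarkResult("rf_baseline", n_finetune, tuple(seeds))
    spec = _RunSpec()
    for s in seeds:
        m, b = _run_one_seed(dataset, split, spec, n_finetune, s,
                             kw.get("forest_config", ForestConfig()),
                             kw.get("meta_config", MetaConfig()),
                             kw.get("embed_config", EmbeddingConfig()),
                             kw.get("topk", 10), kw.get("clip", False))
        metarf.per_seed.append(m)
        base.per_seed.append(b)
    return {"metarf": metarf, "rf_baseline": base}


def run_ablation(
    dataset: ReactionDataset,
    split: SplitSpec,
    variant: str,
    n_finetune: int = 5,
    seeds: tuple[int, ...] = (0,),
    forest_config: ForestConfig = ForestConfig(),
    meta_config: MetaConfig = MetaConfig(),
    embed_config: EmbeddingConfig = EmbeddingConfig(),
    topk: int = 10,
    clip: bool = False,
) -> BenchmarkResult:
    """Ablation runners.

    metarf_random_sampling: Kennard-Stone supports replaced by uniform
    draws, metrics averaged over 10 repetitions per seed.
    maml_on_raw_features: the forest is removed; the head meta-learns
    directly on raw reaction features.
    transfer_head / transfer_head_random_sampling: the head is pretrained
    by ordinary pooled regression (no inner loop) and then fine-tuned with
    the same one-step rule.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {_VARIANTS}")
    spec = {
        "metarf_random_sampling": _RunSpec(selection="random", selection_reps=10),
        "maml_on_raw_features": _RunSpec(use_forest=False),
        "transfer_head": _RunSpec(head_training="transfer"),
        "transfer_head_random_sampling": _RunSpec(
            head_training="transfer", selection="random", selection_reps=10),
    }[variant]
    result = BenchmarkResult(method=variant, n_finetune=n_finetune,
                             seeds=tuple(seeds))
    for s in seeds:
        res, _ = _run_one_seed(dataset, split, spec, n_finetune, s,
                               forest_config, meta_config, embed_config,
                               topk, clip)
        result.per_seed.append(res)
    return result


# ---------------------------------------------------------------------------
# permutation-and-retrain importance

def feature_blocks_for(
    dataset: ReactionDataset, per_column_roles: tuple[str, ...] = ()
) -> dict[str, list[int]]:
    """Partition feature columns into named blocks.

    Roles in ``per_column_roles`` contribute one block per descriptor
    column ("role[dim]"); every other role is one whole block.
    """
    blocks: dict[str, list[int]] = {}
    slices = dataset.role_slices()
    for role in dataset.roles:
        sl = slices[role]
        if role in per_column_roles:
            for j, col in enumerate(range(sl.start, sl.stop)):
                blocks[f"{role}[{j}]"] = [col]
        else:
            blocks[role] = list(range(sl.start, sl.stop))
    return blocks


def _with_features(dataset: ReactionDataset, x: np.ndarray) -> ReactionDataset:
    records = [replace(r, features=x[i]) for i, r in enumerate(dataset.records)]
    return ReactionDataset(records=records, roles=dataset.roles,
                           group_role=dataset.group_role,
                           role_dims=dict(dataset.role_dims))


def permutation_importance(
    dataset: ReactionDataset,
    split: SplitSpec,
    feature_blocks: dict[str, list[int]],
    n_finetune: int = 5,
    repeats: int = 3,
    seed: int = 0,
    forest_config: ForestConfig = ForestConfig(),
    meta_config: MetaConfig = MetaConfig(),
    embed_config: EmbeddingConfig = EmbeddingConfig(),
    selection: str = "random",
) -> pd.DataFrame:
    """Shuffle-and-retrain feature importance.

    importance(block) = pooled R^2 of the intact pipeline minus the mean
    pooled R^2 over ``repeats`` retrainings with that block's values
    shuffled across reactions.  Blocks must partition the feature columns.
    Returns a DataFrame ranked by descending importance.

    Two variance-control measures, both needed because the retrained
    pooled R^2 carries substantial run-to-run noise from refitting the
    forest and re-adapting per group:

    * the retrained pipeline draws its fine-tune supports uniformly
      (averaged over 10 draws) rather than by Kennard-Stone — the maximin
      selection reacts discontinuously to feature perturbations, which
      swamps the importance signal with selection noise (pass
      selection="ks" to measure through the full selection procedure);
    * the design is paired: repeat r retrains the intact and every
      shuffled pipeline with the same sub-seed, and the importance is the
      mean over repeats of the paired R^2 difference, cancelling the
      seed-specific component of the noise.
    """
    cols = sorted(c for v in feature_blocks.values() for c in v)
    if cols != list(range(dataset.feature_dim)):
        raise ValueError("feature_blocks must partition the feature columns")

    def _score(ds, run_seed):
        if selection == "random":
            res = run_ablation(
                ds, split, "metarf_random_sampling", n_finetune,
                seeds=(run_seed,), forest_config=forest_config,
                meta_config=meta_config, embed_config=embed_config,
            )
        else:
            res = run_fewshot_benchmark(
                ds, split, "metarf", n_finetune, seeds=(run_seed,),
                forest_config=forest_config, meta_config=meta_config,
                embed_config=embed_config,
            )
        return res.per_seed[0].pooled["r2"]

    rep_seeds = [int(s) % 2**31 for s in
                 np.random.SeedSequence(seed).generate_state(repeats)]
    base_scores = [_score(dataset, rs) for rs in rep_seeds]
    drops: dict[str, list[float]] = {name: [] for name in feature_blocks}
    for r, rs in enumerate(rep_seeds):
        for name, block in feature_blocks.items():
            # permutation seeded by the block's columns, not its position,
            # so importances do not depend on block ordering
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, r, *sorted(block)]))
            x = dataset.features.copy()
            perm = rng.permutation(x.shape[0])
            x[:, block] = x[perm][:, block]
            drops[name].append(base_scores[r] - _score(_with_features(dataset, x), rs))
    rows = [
        {
            "block": name,
            "importance": float(np.mean(drops[name])),
            "importance_sd": float(np.std(drops[name])),
            "r2_intact": float(np.mean(base_scores)),
            "n_columns": len(feature_blocks[name]),
        }
        for name in feature_blocks
    ]
    df = pd.DataFrame(rows).sort_values("importance", ascending=False)
    return df.reset_index(drop=True)
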