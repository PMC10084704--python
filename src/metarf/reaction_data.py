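"""Reaction tables, descriptor tables and leave-reagent-out splits.

A reaction dataset couples a *reaction table* (one chemical component per
role, plus an observed yield in percent) with one *descriptor table* per
role (component id -> fixed-length numeric vector, e.g. precomputed DFT
descriptors).  Each reaction is encoded by concatenating the descriptor
vectors of its components in a fixed role order; that concatenation is the
feature vector every downstream model consumes.

Out-of-distribution evaluation uses *group-wise* splits: one role (the
"additive" in Buchwald-Hartwig screens) defines groups, and training,
validation and test sets are disjoint sets of group values, so test
reagents are never seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class ComponentDescriptor:
    """A fixed-length numeric descriptor for one component of one role."""

    component_id: str
    role: str
    values: np.ndarray
    value_names: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError(
                f"descriptor for {self.role}/{self.component_id} must be a "
                f"non-empty 1-D vector"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(
                f"descriptor for {self.role}/{self.component_id} has "
                f"non-finite entries"
            )
        object.__setattr__(self, "values", v)
        if self.value_names is not None and len(self.value_names) != v.size:
            raise ValueError("value_names length does not match descriptor length")


@dataclass(frozen=True)
class ReactionRecord:
    """One experiment: component ids per role, encoded features, yield in %."""

    reaction_id: str
    components: dict[str, str]
    features: np.ndarray
    yield_: float

    def __post_init__(self):
        if not 0.0 <= self.yield_ <= 100.0:
            raise ValueError(
                f"reaction {self.reaction_id}: yield {self.yield_} outside [0, 100]"
            )


@dataclass
class ReactionDataset:
    """An ordered collection of reactions sharing a role schema.

    ``roles`` fixes the concatenation order of the per-role descriptor
    blocks; ``group_role`` names the role whose values define tasks for
    leave-reagent-out evaluation.  Record order is the load order and is
    what selection plans and split files index into (0-based).
    """

    records: list[ReactionRecord]
    roles: tuple[str, ...]
    group_role: str
    role_dims: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.group_role not in self.roles:
            raise ValueError(f"group_role {self.group_role!r} not in roles {self.roles}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def feature_dim(self) -> int:
        return sum(self.role_dims.values())

    @property
    def features(self) -> np.ndarray:
        """N x d matrix of concatenated descriptors, in record order."""
        return np.vstack([r.features for r in self.records])

    @property
    def yields(self) -> np.ndarray:
        return np.array([r.yield_ for r in self.records], dtype=float)

    @property
    def groups(self) -> np.ndarray:
        """Group value (component id of group_role) per record."""
        return np.array([r.components[self.group_role] for r in self.records])

    def group_values(self) -> list[str]:
        """Distinct group values in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.components[self.group_role], None)
        return list(seen)

    def indices_of_group(self, group_value: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group_value)

    def role_slices(self) -> dict[str, slice]:
        """Column slice of each role's block inside the feature vector."""
        out, start = {}, 0
        for role in self.roles:
            d = self.role_dims[role]
            out[role] = slice(start, start + d)
            start += d
        return out


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/val/test group sets plus within-group subsampling.

    ``train_fraction_within_groups`` < 1 supports the "tiny training set"
    regimes: the training records are uniformly subsampled (without
    replacement, seeded) while the group structure itself is untouched.
    """

    train_groups: frozenset[str]
    val_groups: frozenset[str]
    test_groups: frozenset[str]
    train_fraction_within_groups: float = 1.0
    subsample_seed: int = 0

    def __post_init__(self):
        sets = (self.train_groups, self.val_groups, self.test_groups)
        total = sum(len(s) for s in sets)
        if len(self.train_groups | self.val_groups | self.test_groups) != total:
            raise ValueError("train/val/test group sets overlap")
        if not 0.0 < self.train_fraction_within_groups <= 1.0:
            raise ValueError("train_fraction_within_groups must be in (0, 1]")

    def train_indices(self, dataset: ReactionDataset) -> np.ndarray:
        """Record indices of the (possibly subsampled) training set."""
        idx = np.flatnonzero(np.isin(dataset.groups, sorted(self.train_groups)))
        f = self.train_fraction_within_groups
        if f < 1.0:
            rng = np.random.default_rng(self.subsample_seed)
            k = max(1, int(round(f * idx.size)))
            idx = np.sort(rng.choice(idx, size=k, replace=False))
        return idx

    def val_indices(self, dataset: ReactionDataset) -> np.ndarray:
        return np.flatnonzero(np.isin(dataset.groups, sorted(self.val_groups)))

    def test_indices(self, dataset: ReactionDataset) -> np.ndarray:
        return np.flatnonzero(np.isin(dataset.groups, sorted(self.test_groups)))


def encode_reaction(
    components: dict[str, ComponentDescriptor | np.ndarray],
    role_order: tuple[str, ...] | list[str],
) -> np.ndarray:
    """Concatenate per-role descriptor vectors in ``role_order``.

    Permuting ``role_order`` permutes whole blocks, never elements within
    a block.  Raises ``KeyError`` naming the role if one is missing.
    """
    parts = []
    for role in role_order:
        if role not in components:
            raise KeyError(f"no descriptor supplied for role {role!r}")
        d = components[role]
        vec = d.values if isinstance(d, ComponentDescriptor) else np.asarray(d, float)
        if vec.ndim != 1 or vec.size == 0:
            raise ValueError(f"descriptor for role {role!r} must be a non-empty vector")
        parts.append(vec)
    return np.concatenate(parts)


def load_descriptor_table(path, role: str) -> dict[str, ComponentDescriptor]:
    """Read one role's descriptor CSV: column ``component_id`` then numbers."""
    df = pd.read_csv(path, dtype={"component_id": str})
    if "component_id" not in df.columns:
        raise ValueError(f"{path}: descriptor table needs a component_id column")
    value_cols = [c for c in df.columns if c != "component_id"]
    if not value_cols:
        raise ValueError(f"{path}: descriptor table has no value columns")
    out: dict[str, ComponentDescriptor] = {}
    for _, row in df.iterrows():
        cid = row["component_id"]
        if cid in out:
            raise ValueError(f"{path}: duplicate component_id {cid!r}")
        out[cid] = ComponentDescriptor(
            component_id=cid,
            role=role,
            values=row[value_cols].to_numpy(dtype=float),
            value_names=tuple(value_cols),
        )
    return out


def load_dataset(
    reaction_table,
    descriptor_tables: dict[str, object],
    group_role: str,
    role_order: tuple[str, ...] | list[str] | None = None,
) -> ReactionDataset:
    """Assemble a :class:`ReactionDataset` from CSV paths.

    ``reaction_table`` columns: ``reaction_id``, one column per role holding
    the component id, and ``yield``.  ``descriptor_tables`` maps role name to
    CSV path.  Record order equals reaction-table row order.
    """
    roles = tuple(role_order) if role_order is not None else tuple(descriptor_tables)
    descriptors = {r: load_descriptor_table(p, r) for r, p in descriptor_tables.items()}
    role_dims = {}
    for role in roles:
        lengths = {d.values.size for d in descriptors[role].values()}
        if len(lengths) != 1:
            raise ValueError(f"role {role!r}: descriptors have mixed lengths {lengths}")
        role_dims[role] = lengths.pop()

    df = pd.read_csv(reaction_table, dtype=str)
    required = {"reaction_id", "yield", *roles}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reaction table missing columns: {sorted(missing)}")
    if df["reaction_id"].duplicated().any():
        dup = df.loc[df["reaction_id"].duplicated(), "reaction_id"].iloc[0]
        raise ValueError(f"duplicate reaction_id {dup!r}")

    records = []
    for row_num, rowd in enumerate(df.to_dict("records")):
        y = float(rowd["yield"])
        if not 0.0 <= y <= 100.0:
            raise ValueError(f"row {row_num}: yield {y} outside [0, 100]")
        comps = {}
        for role in roles:
            cid = rowd[role]
            if cid not in descriptors[role]:
                raise KeyError(
                    f"row {row_num}: component {cid!r} not in role {role!r} "
                    f"descriptor table"
                )
            comps[role] = cid
        features = encode_reaction(
            {role: descriptors[role][comps[role]] for role in roles}, roles
        )
        records.append(
            ReactionRecord(
                reaction_id=rowd["reaction_id"],
                components=comps,
                features=features,
                yield_=y,
            )
        )
    return ReactionDataset(records=records, roles=roles, group_role=group_role,
                           role_dims=role_dims)


def load_dataset_from_config(config_path) -> ReactionDataset:
    """Load via a YAML/JSON config: role order, group_role, file paths."""
    from pathlib import Path

    cfg_path = Path(config_path)
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    base = cfg_path.parent
    tables = {r: base / p for r, p in cfg["descriptor_tables"].items()}
    return load_dataset(
        base / cfg["reaction_table"],
        tables,
        group_role=cfg["group_role"],
        role_order=tuple(cfg["roles"]),
    )


def split_by_group(
    dataset: ReactionDataset,
    n_train: int,
    n_val: int,
    seed: int,
    train_fraction_within_groups: float = 1.0,
) -> SplitSpec:
    """Draw a leave-reagent-out split: n_train/n_val groups, rest is test.

    Groups are drawn without replacement with ``seed``; deterministic for a
    fixed seed.  Errors if no test group would remain.
    """
    groups = dataset.group_values()
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    if n_train + n_val >= len(groups):
        raise ValueError(
            f"n_train + n_val = {n_train + n_val} >= {len(groups)} groups: "
            f"no test group would remain"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    train = frozenset(groups[i] for i in order[:n_train])
    val = frozenset(groups[i] for i in order[n_train : n_train + n_val])
    test = frozenset(groups[i] for i in order[n_train + n_val :])
    return SplitSpec(
        train_groups=train,
        val_groups=val,
        test_groups=test,
        train_fraction_within_groups=train_fraction_within_groups,
        subsample_seed=seed,
    )
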