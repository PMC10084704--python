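"""Synthetic high-throughput-experimentation (HTE) reaction datasets.

Emulates the structure of a combinatorial yield screen — a full cross of a
few components per role (aryl halide x ligand x base x additive at the
Buchwald-Hartwig scale by default) — with known ground truth, so every
model component can be tested without external downloads.

Yield model, on the percent scale:

    y = clip( base
              + sum over non-group roles of a per-component main effect
              + an interaction between the first two roles
              + a group shift tied to the group component's descriptors
              + Gaussian noise,  0, 100 )

Descriptors are standard normal per dimension; designated *informative*
dimensions additionally carry a per-component latent value, and every
planted effect is a linear map of those informative dimensions.  The group
shift being a smooth function of the group role's descriptors mirrors the
premise that DFT features generalize: few-shot adaptation to a new group is
learnable from descriptors plus a handful of support yields.

An optional mixture structure over one role's descriptors plants latent
clusters inside each group, which is what representative-sampling coverage
tests exercise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reaction_data import (
    ComponentDescriptor,
    ReactionDataset,
    ReactionRecord,
    encode_reaction,
)


@dataclass(frozen=True)
class RoleSpec:
    name: str
    n_components: int
    descriptor_dim: int

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError(f"role {self.name}: n_components must be >= 1")
        if self.descriptor_dim < 1:
            raise ValueError(f"role {self.name}: descriptor_dim must be >= 1")


# Buchwald-Hartwig HTE shape: 15 aryl halides x 4 ligands x 3 bases x 22 additives
_DEFAULT_ROLES = (
    RoleSpec("aryl_halide", 15, 20),
    RoleSpec("ligand", 4, 20),
    RoleSpec("base", 3, 20),
    RoleSpec("additive", 22, 20),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; all effect scales are in percent yield.

    informative_dims maps role name to the descriptor dimensions carrying
    signal (default: dimension 0 of every role).  cluster_k > 1 plants that
    many descriptor-space clusters over the components of ``cluster_role``
    (default: the first role), giving each group's candidate reactions a
    latent cluster label.
    """

    roles: tuple[RoleSpec, ...] = _DEFAULT_ROLES
    group_role: str = "additive"
    base_yield: float = 50.0
    effect_scale: float = 15.0
    main_effect_scale: float = 8.0
    interaction_scale: float = 10.0
    noise_sd: float = 5.0
    informative_dims: dict[str, tuple[int, ...]] | None = None
    latent_scale: float = 2.0
    cluster_k: int = 1
    cluster_role: str | None = None
    cluster_sep: float = 4.0
    seed: int = 0

    def __post_init__(self):
        names = [r.name for r in self.roles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate role names")
        if self.group_role not in names:
            raise ValueError(f"group_role {self.group_role!r} not among roles")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")

    def informative(self, role: str) -> tuple[int, ...]:
        if self.informative_dims and role in self.informative_dims:
            return tuple(self.informative_dims[role])
        return (0,)

    def role_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.roles)

    def space_size(self) -> int:
        """Number of combinations in the full cross."""
        return int(np.prod([r.n_components for r in self.roles], dtype=object))


@dataclass
class GroundTruth:
    """Every latent quantity the generator planted, for recovery tests."""

    base_yield: float
    noise_sd: float
    main_effects: dict[str, dict[str, float]]
    group_shifts: dict[str, float]
    interaction_roles: tuple[str, str] | None
    interaction_z: dict[str, dict[str, float]]
    interaction_scale: float
    component_clusters: dict[str, dict[str, int]] = field(default_factory=dict)

    def signal(self, record: ReactionRecord) -> float:
        """Noise-free (pre-clip) yield of one reaction."""
        total = self.base_yield
        for role, effects in self.main_effects.items():
            total += effects[record.components[role]]
        total += self.group_shifts[_group_component(record, self.group_shifts)]
        if self.interaction_roles is not None:
            r1, r2 = self.interaction_roles
            z1 = self.interaction_z[r1][record.components[r1]]
            z2 = self.interaction_z[r2][record.components[r2]]
            total += self.interaction_scale * z1 * z2
        return total

    def reaction_cluster(self, record: ReactionRecord) -> int:
        """Latent cluster label of a reaction (via its clustered component)."""
        if not self.component_clusters:
            return 0
        role, mapping = next(iter(self.component_clusters.items()))
        return mapping[record.components[role]]


def _group_component(record: ReactionRecord, shifts: dict[str, float]) -> str:
    for cid in record.components.values():
        if cid in shifts:
            return cid
    raise KeyError("record has no component with a planted group shift")


def _zscore(u: np.ndarray) -> np.ndarray:
    if u.size < 2 or np.std(u) == 0:
        return np.zeros_like(u)
    return (u - u.mean()) / u.std()


def gen_components(config: SynthConfig) -> dict[str, list[ComponentDescriptor]]:
    """Draw descriptor tables for every role; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    cluster_role = config.cluster_role or config.roles[0].name
    out: dict[str, list[ComponentDescriptor]] = {}
    for spec in config.roles:
        values = rng.normal(size=(spec.n_components, spec.descriptor_dim))
        inf = list(config.informative(spec.name))
        if max(inf) >= spec.descriptor_dim:
            raise ValueError(f"informative dim out of range for role {spec.name}")
        latent = rng.normal(0.0, config.latent_scale, size=(spec.n_components, len(inf)))
        values[:, inf] += latent
        if config.cluster_k > 1 and spec.name == cluster_role:
            labels = np.arange(spec.n_components) % config.cluster_k
            centers = rng.normal(0.0, config.cluster_sep,
                                 size=(config.cluster_k, spec.descriptor_dim))
            values += centers[labels]
        names = tuple(f"{spec.name}_d{j:02d}" for j in range(spec.descriptor_dim))
        out[spec.name] = [
            ComponentDescriptor(
                component_id=f"{spec.name}_{c:03d}",
                role=spec.name,
                values=values[c],
                value_names=names,
            )
            for c in range(spec.n_components)
        ]
    return out


def gen_dataset(
    config: SynthConfig = SynthConfig(),
    coverage: float | str = "full",
) -> tuple[ReactionDataset, GroundTruth]:
    """Generate reactions over the combinatorial space with known truth.

    ``coverage="full"`` enumerates the complete cross (dense HTE-style
    coverage); a fraction in (0, 1] samples that share of the combinations
    uniformly without replacement (sparse ELN-style coverage).
    """
    if coverage != "full":
        coverage = float(coverage)
        if not 0.0 < coverage <= 1.0:
            raise ValueError("coverage must be 'full' or a fraction in (0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    components = gen_components(config)
    role_names = config.role_names()
    cluster_role = config.cluster_role or config.roles[0].name

    # planted effects from informative descriptor dims, z-scored per role
    main_effects: dict[str, dict[str, float]] = {}
    group_shifts: dict[str, float] = {}
    interaction_z: dict[str, dict[str, float]] = {}
    z_by_role: dict[str, np.ndarray] = {}
    for spec in config.roles:
        descs = components[spec.name]
        inf = list(config.informative(spec.name))
        w = rng.normal(size=len(inf))
        w /= np.linalg.norm(w)
        u = np.array([d.values[inf] @ w for d in descs])
        z_by_role[spec.name] = _zscore(u)

    for spec in config.roles:
        descs = components[spec.name]
        z = z_by_role[spec.name]
        if spec.name == config.group_role:
            group_shifts = {
                d.component_id: config.effect_scale * z[i] for i, d in enumerate(descs)
            }
        else:
            main_effects[spec.name] = {
                d.component_id: config.main_effect_scale * z[i]
                for i, d in enumerate(descs)
            }

    # the interaction couples the group role with the first other role:
    # a reagent's effect depends on the substrate it is paired with, which
    # is what makes unseen-reagent prediction genuinely hard
    non_group = [r.name for r in config.roles if r.name != config.group_role]
    interaction_roles = (non_group[0], config.group_role) if non_group else None
    if interaction_roles:
        for r in interaction_roles:
            interaction_z[r] = {
                d.component_id: z_by_role[r][i] for i, d in enumerate(components[r])
            }

    clusters: dict[str, dict[str, int]] = {}
    if config.cluster_k > 1:
        clusters[cluster_role] = {
            d.component_id: i % config.cluster_k
            for i, d in enumerate(components[cluster_role])
        }

    truth = GroundTruth(
        base_yield=config.base_yield,
        noise_sd=config.noise_sd,
        main_effects=main_effects,
        group_shifts=group_shifts,
        interaction_roles=interaction_roles,
        interaction_z=interaction_z,
        interaction_scale=config.interaction_scale,
        component_clusters=clusters,
    )

    combos = list(itertools.product(*(components[r] for r in role_names)))
    if coverage != "full":
        k = max(1, int(round(coverage * len(combos))))
        keep = np.sort(rng.choice(len(combos), size=k, replace=False))
        combos = [combos[i] for i in keep]

    by_id = {r: {d.component_id: d for d in components[r]} for r in role_names}
    records = []
    noise = rng.normal(0.0, config.noise_sd, size=len(combos))
    for i, combo in enumerate(combos):
        comps = {r: d.component_id for r, d in zip(role_names, combo)}
        features = encode_reaction({r: by_id[r][comps[r]] for r in role_names},
                                   role_names)
        stub = ReactionRecord(f"rxn_{i:05d}", comps, features, 0.0)
        y = float(np.clip(truth.signal(stub) + noise[i], 0.0, 100.0))
        records.append(ReactionRecord(f"rxn_{i:05d}", comps, features, y))

    dataset = ReactionDataset(
        records=records,
        roles=role_names,
        group_role=config.group_role,
        role_dims={r.name: r.descriptor_dim for r in config.roles},
    )
    return dataset, truth


def eln_preset() -> SynthConfig:
    """Sparse electronic-lab-notebook-style space (use fractional coverage)."""
    return SynthConfig(
        roles=(
            RoleSpec("aryl_halide", 12, 10),
            RoleSpec("amine", 10, 10),
            RoleSpec("ligand", 6, 10),
            RoleSpec("base", 5, 10),
            RoleSpec("solvent", 5, 10),
        ),
        group_role="ligand",
    )


def write_dataset_csvs(dataset: ReactionDataset, outdir) -> Path:
    """Write the CSV interchange files: reaction table, one descriptor CSV
    per role, and a dataset config YAML; returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in dataset.records:
        row = {"reaction_id": r.reaction_id, **r.components, "yield": r.yield_}
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "reactions.csv", index=False)

    slices = dataset.role_slices()
    tables: dict[str, str] = {}
    for role in dataset.roles:
        sl = slices[role]
        seen: dict[str, np.ndarray] = {}
        for r in dataset.records:
            seen.setdefault(r.components[role], r.features[sl])
        df = pd.DataFrame(
            [{"component_id": cid,
              **{f"{role}_d{j:02d}": v for j, v in enumerate(vec)}}
             for cid, vec in seen.items()]
        )
        fname = f"descriptors_{role}.csv"
        df.to_csv(outdir / fname, index=False)
        tables[role] = fname

    cfg = {
        "roles": list(dataset.roles),
        "group_role": dataset.group_role,
        "reaction_table": "reactions.csv",
        "descriptor_tables": tables,
    }
    cfg_path = outdir / "dataset.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return cfg_path
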