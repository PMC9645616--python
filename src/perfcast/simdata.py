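"""Synthetic gene-expression dataset generator.

Emulates log2-scale microarray expression with two balanced sample groups.
Each *part* of a configuration contributes a block of features sharing one
parameter setting; parts are concatenated column-wise into one dataset, so
heterogeneous feature populations (strong discriminators, weak discriminators,
pure noise) can coexist in a single simulated experiment.

The generative model per part:

* per-subject biological signal ``b ~ MVN(0, sdB^2 * R)`` where ``R`` is a
  block-diagonal exchangeable correlation matrix (block sizes drawn uniformly
  in ``[bs_min, 3*bs_min]``, within-block correlation drawn uniformly in
  ``[rho_min, rho_max]``),
* the delivered value is ``b`` plus the mean of ``n_rep`` technical replicate
  errors, iid ``N(0, sdW^2)`` — marginal variance ``sdB^2 + sdW^2/n_rep``,
* discriminating parts add a group effect ``z * log2(delta)`` to group-2
  samples, where the fold change ``delta`` is drawn from a normal
  distribution with mean ``fold_min`` and standard deviation ``sigma``
  truncated below at ``fold_min`` (a shifted half-normal) and the sign ``z``
  is uniform on {-1, +1} (up-/down-regulation). ``fold_min`` is a
  fold-change ratio: ``fold_min = 2`` shifts group means by one log2 unit.

The reference configuration (three parts, 100 samples, 90 features) and the
registry of its nine standard variations ``S1``...``S9`` live in
:func:`reference_config` and :func:`simulation_registry`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PartConfig",
    "SimulationConfig",
    "LabeledDataset",
    "sample_delta",
    "build_block_correlation",
    "simulate_part",
    "simulate_dataset",
    "generate_collection",
    "generate_study_collection",
    "reference_config",
    "simulation_registry",
    "read_part_table",
    "write_part_table",
]

# default within-block correlation bounds when a configuration leaves them open
DEFAULT_RHO_MIN = 0.2
DEFAULT_RHO_MAX = 0.8


@dataclass(frozen=True)
class PartConfig:
    """One homogeneous block of simulated features.

    Parameters mirror the configuration table of the generator: sample counts
    are shared across parts of one simulation, the rest may differ per part.
    """

    num_datasets: int
    n_train: int                 # samples per dataset (n_TR)
    n_group1: int                # samples in group 1 (nGr1); group 2 = rest
    n_features: int              # features contributed by this part (nBiom)
    n_rep: int = 3               # technical replicates averaged per value
    sd_tech: float = 3.0         # technical sd on log2 scale (sdW)
    sd_biol: float = 3.0         # biological sd on log2 scale (sdB)
    bs_min: int = 3              # minimum correlation block size
    sigma: float = 0.1           # sd of the fold-change distribution
    diff_expr: bool = True       # whether this part's features discriminate
    fold_min: float = 2.0        # minimum fold change (ratio scale)
    order_features: bool = True  # sort dataset columns by decreasing |t|
    rho_min: float = DEFAULT_RHO_MIN
    rho_max: float = DEFAULT_RHO_MAX

    def __post_init__(self) -> None:
        if not (0 < self.n_group1 < self.n_train):
            raise ValueError("need 0 < n_group1 < n_train")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if min(self.sd_tech, self.sd_biol, self.sigma) < 0:
            raise ValueError("sd_tech, sd_biol and sigma must be >= 0")
        if self.bs_min < 1:
            raise ValueError("bs_min must be >= 1")
        if self.fold_min <= 0:
            raise ValueError("fold_min is a fold-change ratio and must be > 0")
        if not (-1.0 <= self.rho_min <= self.rho_max < 1.0):
            raise ValueError("need -1 <= rho_min <= rho_max < 1")
        if self.num_datasets < 1:
            raise ValueError("num_datasets must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """A named simulation: an ordered list of parts plus a seed."""

    name: str
    parts: tuple[PartConfig, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("at least one part required")
        head = self.parts[0]
        for p in self.parts[1:]:
            if (p.num_datasets, p.n_train, p.n_group1) != (
                head.num_datasets,
                head.n_train,
                head.n_group1,
            ):
                raise ValueError(
                    "all parts must share num_datasets, n_train and n_group1"
                )
        object.__setattr__(self, "parts", tuple(self.parts))

    @property
    def num_datasets(self) -> int:
        return self.parts[0].num_datasets

    @property
    def n_train(self) -> int:
        return self.parts[0].n_train

    @property
    def n_features(self) -> int:
        return sum(p.n_features for p in self.parts)


@dataclass
class LabeledDataset:
    """A samples x features log2 expression matrix with binary labels.

    ``is_discriminator`` and ``delta`` carry the simulation ground truth
    (``delta`` is the signed log2-scale group effect, 0 for
    non-discriminators); for real data they are all-False / all-zero.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    is_discriminator: np.ndarray | None = None
    delta: np.ndarray | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, d = self.X.shape
        if len(self.y) != n:
            raise ValueError("label length does not match sample count")
        if np.isnan(self.X).any():
            raise ValueError("missing values are not allowed")
        if len(np.unique(self.y)) != 2:
            raise ValueError("both classes must be present")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match matrix")
        if self.is_discriminator is None:
            self.is_discriminator = np.zeros(d, dtype=bool)
        if self.delta is None:
            self.delta = np.zeros(d, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["class"] = self.y
        return df

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            pd.DataFrame(
                {
                    "feature": self.feature_names,
                    "is_discriminator": self.is_discriminator.astype(int),
                    "delta": self.delta,
                }
            ).to_csv(sidecar, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        if "class" not in df.columns:
            raise ValueError("expected a 'class' column")
        y = df.pop("class").to_numpy()
        return cls(
            X=df.to_numpy(dtype=float),
            y=y,
            feature_names=list(df.columns),
            name=name or str(path),
        )


def sample_delta(
    fold_min: float,
    sigma: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw fold changes from N(fold_min, sigma^2) truncated below at fold_min.

    Truncating a normal at its own mean leaves a shifted half-normal, so the
    draw is ``fold_min + |N(0, sigma^2)|`` with mean
    ``fold_min + sigma * sqrt(2/pi)``. The draw is on the fold-change
    (ratio) scale; the simulator applies ``log2`` of it as the additive
    group effect on the log2 expression scale.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return fold_min + np.abs(rng.normal(0.0, sigma, size=size))


def build_block_correlation(
    n_features: int,
    bs_min: int,
    rho_min: float,
    rho_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Block-diagonal exchangeable correlation matrix.

    Consecutive blocks of size uniform on ``[bs_min, 3*bs_min]`` (the last
    block truncated to fit); each block gets a single within-block correlation
    drawn uniformly in ``[rho_min, rho_max]``.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if rho_min > rho_max:
        raise ValueError("rho_min must be <= rho_max")
    R = np.eye(n_features)
    start = 0
    while start < n_features:
        size = int(rng.integers(bs_min, 3 * bs_min + 1))
        size = min(size, n_features - start)
        rho = float(rng.uniform(rho_min, rho_max))
        if size > 1 and rho < -1.0 / (size - 1):
            raise ValueError(
                f"rho={rho:.3f} is not positive semi-definite for an "
                f"exchangeable block of size {size}"
            )
        block = slice(start, start + size)
        R[block, block] = rho
        np.fill_diagonal(R[block, block], 1.0)
        start += size
    return R


def simulate_part(
    part: PartConfig, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one part's feature block for a given label vector.

    Returns ``(X_part, is_discriminator, delta)`` where ``delta`` is the
    signed group-2 shift per feature (0 when ``diff_expr`` is off).
    """
    y = np.asarray(y)
    if (y == 1).sum() != part.n_group1 or len(y) != part.n_train:
        raise ValueError("label vector inconsistent with n_train / n_group1")
    n, d = part.n_train, part.n_features

    R = build_block_correlation(d, part.bs_min, part.rho_min, part.rho_max, rng)
    # rho_max < 1 keeps R positive definite; tiny jitter guards rounding
    L = np.linalg.cholesky(R + 1e-12 * np.eye(d))
    biological = part.sd_biol * (rng.standard_normal((n, d)) @ L.T)
    technical = rng.normal(0.0, part.sd_tech, size=(n, d, part.n_rep)).mean(axis=2)
    X = biological + technical

    delta = np.zeros(d)
    is_disc = np.zeros(d, dtype=bool)
    if part.diff_expr:
        fold = sample_delta(part.fold_min, part.sigma, rng, size=d)
        z = rng.choice([-1.0, 1.0], size=d)
        delta = z * np.log2(fold)   # fold-change ratio -> log2-scale shift
        is_disc[:] = True
        X[y == 0] += delta  # group-2 shift; symmetric under relabeling
    return X, is_disc, delta


def _two_sample_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistic per column (group1 - group2)."""
    g1, g2 = X[y == 1], X[y == 0]
    n1, n2 = len(g1), len(g2)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (g1.mean(axis=0) - g2.mean(axis=0)) / denom
    return np.where(denom > 0, t, 0.0)


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    name: str = "dataset",
) -> LabeledDataset:
    """Concatenate all parts of a configuration into one labeled dataset."""
    n = config.n_train
    y = np.zeros(n, dtype=int)
    y[: config.parts[0].n_group1] = 1

    blocks, disc, delta, names = [], [], [], []
    for pi, part in enumerate(config.parts, start=1):
        Xp, dp, deltap = simulate_part(part, y, rng)
        blocks.append(Xp)
        disc.append(dp)
        delta.append(deltap)
        names.extend(f"P{pi}_f{j + 1:03d}" for j in range(part.n_features))
    X = np.hstack(blocks)
    is_disc = np.concatenate(disc)
    delta_all = np.concatenate(delta)
    feature_names = np.array(names)

    if any(p.order_features for p in config.parts):
        order = np.argsort(-np.abs(_two_sample_t(X, y)), kind="stable")
        X = X[:, order]
        is_disc = is_disc[order]
        delta_all = delta_all[order]
        feature_names = feature_names[order]

    return LabeledDataset(
        X=X,
        y=y,
        feature_names=list(feature_names),
        is_discriminator=is_disc,
        delta=delta_all,
        name=name,
    )


def generate_collection(
    config: SimulationConfig, num_datasets: int | None = None
) -> list[LabeledDataset]:
    """Generate the configured number of independent datasets.

    Reproducible: dataset ``i`` uses the stream seeded by
    ``(config.seed, i)``, so the collection is a pure function of the
    configuration and independent of generation order.
    """
    total = config.num_datasets if num_datasets is None else num_datasets
    out = []
    for i in range(total):
        rng = np.random.default_rng([config.seed, i])
        out.append(simulate_dataset(config, rng, name=f"{config.name}_{i + 1:04d}"))
    return out


def generate_study_collection(
    config: SimulationConfig, num_datasets_per_part: int | None = None
) -> list[LabeledDataset]:
    """Generate the heterogeneous study collection: one sub-collection per part.

    Each configuration part spawns its own ``num_datasets`` single-part
    datasets (e.g. the reference configuration yields 300 datasets with 50
    strongly discriminating features, 300 with 20, and 300 pure-noise
    datasets, 900 in total). This across-part heterogeneity in difficulty is
    what gives the classification errors enough spread for meta-regression
    to predict; a collection of part-combined datasets (see
    :func:`generate_collection`) is far more homogeneous.

    Dataset ``i`` of part ``pi`` uses the stream seeded by
    ``(config.seed, pi, i)``; reproducible and order-independent.
    """
    out = []
    for pi, part in enumerate(config.parts, start=1):
        sub = SimulationConfig(
            name=f"{config.name}_P{pi}", parts=(part,), seed=config.seed
        )
        total = part.num_datasets if num_datasets_per_part is None else num_datasets_per_part
        for i in range(total):
            rng = np.random.default_rng([config.seed, pi, i])
            out.append(
                simulate_dataset(sub, rng, name=f"{config.name}_P{pi}_{i + 1:04d}")
            )
    return out


# ---------------------------------------------------------------------------
# reference configuration and the S1-S9 registry


def reference_config(
    num_datasets: int = 300, seed: int = 0, name: str = "S1"
) -> SimulationConfig:
    """The three-part reference configuration.

    100 samples split 50/50; parts contribute 50 + 20 + 20 features; parts 1-2
    discriminate with minimum fold change 2, part 3 is noise (sdW = sdB = 1).
    """
    common = dict(num_datasets=num_datasets, n_train=100, n_group1=50)
    p1 = PartConfig(**common, n_features=50, sd_tech=3, sd_biol=3, diff_expr=True, fold_min=2)
    p2 = PartConfig(**common, n_features=20, sd_tech=3, sd_biol=3, diff_expr=True, fold_min=2)
    p3 = PartConfig(**common, n_features=20, sd_tech=1, sd_biol=1, diff_expr=False, fold_min=1)
    return SimulationConfig(name=name, parts=(p1, p2, p3), seed=seed)


def simulation_registry(
    num_datasets: int = 300, seed: int = 0
) -> dict[str, SimulationConfig]:
    """The nine standard simulations as variations of the reference.

    S1 reference; S2 half the samples; S3 half the datasets; S4 fold changes
    (2, 1.5, 1); S5 fold changes (1.5, 1, 0.5); S6 half the discriminators
    (25, 10, 10); S7 fixed high correlation (rho = 0.8); S8 higher biological
    variation sdB = (4, 4, 2); S9 = S8's variation plus S5's fold changes.
    """

    def variant(name: str, **per_part) -> SimulationConfig:
        base = reference_config(num_datasets=num_datasets, seed=seed, name=name)
        parts = []
        for i, p in enumerate(base.parts):
            override = {k: v[i] if isinstance(v, (tuple, list)) else v
                        for k, v in per_part.items()}
            parts.append(replace(p, **override))
        return SimulationConfig(name=name, parts=tuple(parts), seed=seed)

    reg = {
        "S1": reference_config(num_datasets=num_datasets, seed=seed, name="S1"),
        "S2": variant("S2", n_train=50, n_group1=25),
        "S3": variant("S3", num_datasets=max(1, num_datasets // 2)),
        "S4": variant("S4", fold_min=(2.0, 1.5, 1.0)),
        "S5": variant("S5", fold_min=(1.5, 1.0, 0.5)),
        "S6": variant("S6", n_features=(25, 10, 10)),
        "S7": variant("S7", rho_min=0.8, rho_max=0.8),
        "S8": variant("S8", sd_biol=(4.0, 4.0, 2.0)),
        "S9": variant("S9", sd_biol=(4.0, 4.0, 2.0), fold_min=(1.5, 1.0, 0.5)),
    }
    return reg


# ---------------------------------------------------------------------------
# configuration table I/O (parameters as rows, parts as columns)

_ROW_TO_FIELD = {
    "num.datasets": "num_datasets",
    "nTrain": "n_train",
    "nGr1": "n_group1",
    "nBiom": "n_features",
    "nRep": "n_rep",
    "sdW": "sd_tech",
    "sdB": "sd_biol",
    "bsMin": "bs_min",
    "sigma": "sigma",
    "diffExpr": "diff_expr",
    "foldMin": "fold_min",
    "orderBiom": "order_features",
    "rhoMin": "rho_min",
    "rhoMax": "rho_max",
}
_INT_FIELDS = {"num_datasets", "n_train", "n_group1", "n_features", "n_rep", "bs_min"}
_BOOL_FIELDS = {"diff_expr", "order_features"}


def read_part_table(path_or_buffer, name: str = "custom", seed: int = 0) -> SimulationConfig:
    """Parse a configuration table (parameter rows x part columns) into a config."""
    df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
    unknown = set(df.index) - set(_ROW_TO_FIELD)
    if unknown:
        raise ValueError(f"unknown configuration rows: {sorted(unknown)}")
    parts = []
    for col in df.columns:
        kwargs = {}
        for row, value in df[col].items():
            fieldname = _ROW_TO_FIELD[row]
            if fieldname in _INT_FIELDS:
                kwargs[fieldname] = int(round(float(value)))
            elif fieldname in _BOOL_FIELDS:
                kwargs[fieldname] = bool(round(float(value)))
            else:
                kwargs[fieldname] = float(value)
        parts.append(PartConfig(**kwargs))
    return SimulationConfig(name=name, parts=tuple(parts), seed=seed)


def write_part_table(config: SimulationConfig, path) -> None:
    """Write a configuration in the parameter-rows x part-columns layout."""
    field_to_row = {v: k for k, v in _ROW_TO_FIELD.items()}
    rows = {}
    for rowname in _ROW_TO_FIELD:
        fieldname = _ROW_TO_FIELD[rowname]
        rows[rowname] = [
            float(getattr(p, fieldname)) if not isinstance(getattr(p, fieldname), bool)
            else float(getattr(p, fieldname))
            for p in config.parts
        ]
    df = pd.DataFrame(rows, index=[f"P{i + 1}" for i in range(len(config.parts))]).T
    df.to_csv(path, sep="\t")
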