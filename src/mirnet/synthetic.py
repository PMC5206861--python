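"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator emulates a mouse miRNome RT-qPCR array screen: a 528-miRNA
panel plus one housekeeping small-RNA feature, profiled across three study
groups (saline control, cisplatin injury, cisplatin + MSC treatment) with a
few replicates each.  Differential regulation is planted on the Ct scale —
an `f`-fold upregulation of a miRNA in the numerator group of a comparison
lowers its mean Ct there by log2(f) cycles — so the expected fold change
recovered downstream equals the planted fold exactly.  Per-well technical
noise is Gaussian on the Ct scale (log-normal on abundance), the standard
qPCR error model.

Alongside the Ct matrix the generator emits miRNA->gene target-prediction
tables for several mock databases with a controlled cross-database consensus
fraction, and a gene-set (GMT) annotation collection optionally enriched for
one miRNA's true targets.  Every output is a deterministic function of the
seed, and the planted truth is returned so recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .network import TargetEdgeTable
from .qpcr import CtTable, DEFAULT_DETECTION_LIMIT

__all__ = [
    "SynthConfig",
    "PlantedEffect",
    "PlantedTruth",
    "generate_ct_table",
    "generate_prediction_tables",
    "generate_annotation",
    "injury_screen_config",
    "DEFAULT_GROUPS",
    "DEFAULT_COMPARISONS",
]

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("saline", 3),
    ("cisplatin", 3),
    ("cisplatin_MSC", 3),
)

DEFAULT_COMPARISONS: dict[str, tuple[str, str]] = {
    "Cis_vs_Saline": ("cisplatin", "saline"),
    "CisMSC_vs_Cis": ("cisplatin_MSC", "cisplatin"),
}

DEFAULT_DATABASES = ("TargetScan", "miRanda", "miRDB")


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential: ``mirna`` moves ``direction`` by
    ``fold`` in ``comparison`` (numerator relative to denominator)."""

    mirna: str
    comparison: str
    direction: str  # "up" | "down"
    fold: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(
                f"direction must be up/down, got {self.direction!r}")
        if not self.fold >= 1.0:
            raise ConfigurationError(
                f"fold-change magnitude must be >= 1, got {self.fold}")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic miRNome screen.

    Ct-scale parameters are in cycles.  ``named_features`` assigns real
    miRNA names to the first panel slots (the rest get synthetic ids
    ``mmu-miR-S0001`` ...), so worked examples can plant published names.
    """

    seed: int = 0
    panel_size: int = 528
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    comparisons: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_COMPARISONS))
    baseline_ct_mean: float = 26.0
    baseline_ct_sd: float = 1.5
    noise_sd: float = 0.1
    reference_ct: float = 20.0
    reference_noise_sd: float = 0.0
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    reference_name: str = "SNOR-ref"
    planted_effects: tuple[PlantedEffect, ...] = ()
    named_features: tuple[str, ...] = ()
    n_genes: int = 2000
    n_databases: int = 3
    per_db_targets_per_mirna: int = 10
    consensus_fraction: float = 1.0
    n_gene_sets: int = 20
    gene_set_size_range: tuple[int, int] = (10, 50)
    enriched_set_mirna: str | None = None

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ConfigurationError("panel_size must be positive")
        if any(n < 2 for _, n in self.groups):
            raise ConfigurationError("every group needs >= 2 replicates")
        if not 0.0 <= self.consensus_fraction <= 1.0:
            raise ConfigurationError(
                f"consensus_fraction must be in [0, 1], "
                f"got {self.consensus_fraction}")
        if len(self.named_features) > self.panel_size:
            raise ConfigurationError("more named features than panel slots")
        lo, hi = self.gene_set_size_range
        if hi > self.n_genes:
            raise ConfigurationError("gene-set size exceeds gene universe")
        planted = {e.mirna for e in self.planted_effects}
        if len(planted) > self.panel_size:
            raise ConfigurationError("more planted miRNAs than panel slots")
        group_names = {g for g, _ in self.groups}
        for e in self.planted_effects:
            if e.comparison not in self.comparisons:
                raise ConfigurationError(
                    f"planted effect for {e.mirna!r} references unknown "
                    f"comparison {e.comparison!r}")
        for cid, (num, den) in self.comparisons.items():
            if num not in group_names or den not in group_names:
                raise ConfigurationError(
                    f"comparison {cid!r} references unknown group")

    def feature_names(self) -> list[str]:
        names = list(self.named_features)
        names += [f"mmu-miR-S{i + 1:04d}"
                  for i in range(len(names), self.panel_size)]
        return names

    def gene_universe(self) -> list[str]:
        return [f"Gene{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic dataset.

    ``regulation`` maps comparison id -> {"up": set, "down": set} of miRNA
    ids; ``targets`` maps planted miRNA id -> its true target gene set;
    ``db_tables`` is filled by :func:`generate_prediction_tables`.
    """

    regulation: dict[str, dict[str, set[str]]]
    targets: dict[str, set[str]]
    db_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def up(self, comparison: str) -> set[str]:
        return set(self.regulation[comparison]["up"])

    def down(self, comparison: str) -> set[str]:
        return set(self.regulation[comparison]["down"])


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per output kind (crc32 is stable
    # across processes, unlike built-in str hashing)
    return np.random.default_rng(
        [config.seed, zlib.crc32(stream.encode()) % (2**31)])


def generate_ct_table(config: SynthConfig) -> tuple[CtTable, PlantedTruth]:
    """Simulate the Ct matrix and return it with the planted truth.

    Each feature draws a latent baseline Ct shared by all samples; planted
    effects shift group means by -+log2(fold) relative to the comparison's
    denominator group (so the realized noise-free contrast equals the
    planted fold exactly, even when one miRNA is planted in a chain of
    comparisons); Gaussian per-well noise is added; wells beyond the
    detection limit become NaN (undetected).  The reference feature sits at
    ``reference_ct`` in every sample and is noise-free by default.
    """
    features = config.feature_names()
    feature_set = set(features)
    for e in config.planted_effects:
        if e.mirna not in feature_set:
            raise ConfigurationError(
                f"planted miRNA {e.mirna!r} is not on the panel")

    regulation: dict[str, dict[str, set[str]]] = {
        cid: {"up": set(), "down": set()} for cid in config.comparisons
    }
    for e in config.planted_effects:
        bucket = regulation[e.comparison][e.direction]
        other = "down" if e.direction == "up" else "up"
        if e.mirna in regulation[e.comparison][other]:
            raise ConfigurationError(
                f"{e.mirna!r} planted both up and down in {e.comparison!r}")
        bucket.add(e.mirna)

    # per-(feature, group) Ct offsets, applied relative to the denominator
    # group's current offset so each comparison realizes its planted fold
    group_names = [g for g, _ in config.groups]
    shift = {f: {g: 0.0 for g in group_names} for f in features}
    for e in config.planted_effects:
        num, den = config.comparisons[e.comparison]
        delta = -np.log2(e.fold) if e.direction == "up" else np.log2(e.fold)
        shift[e.mirna][num] = shift[e.mirna][den] + delta

    rng = _rng(config, "ct")
    baseline = rng.normal(config.baseline_ct_mean, config.baseline_ct_sd,
                          size=len(features))
    samples: list[str] = []
    sample_groups: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for group, n_rep in config.groups:
        offsets = np.array([shift[f][group] for f in features])
        for rep in range(n_rep):
            name = f"{group}_{rep + 1}"
            samples.append(name)
            sample_groups[name] = group
            noise = rng.normal(0.0, config.noise_sd, size=len(features)) \
                if config.noise_sd > 0 else 0.0
            columns.append(baseline + offsets + noise)

    values = pd.DataFrame(np.column_stack(columns), index=features,
                          columns=samples)
    values = values.where(values <= config.detection_limit)  # NaN = undetected

    ref_noise = (
        rng.normal(0.0, config.reference_noise_sd, size=len(samples))
        if config.reference_noise_sd > 0 else np.zeros(len(samples))
    )
    values.loc[config.reference_name] = config.reference_ct + ref_noise

    ct = CtTable(values=values, groups=sample_groups,
                 reference=config.reference_name,
                 detection_limit=config.detection_limit)

    # true target sets for every planted miRNA
    target_rng = _rng(config, "targets")
    universe = np.array(config.gene_universe())
    planted = sorted({e.mirna for e in config.planted_effects})
    targets = {
        m: set(target_rng.choice(universe, size=config.per_db_targets_per_mirna,
                                 replace=False))
        for m in planted
    }
    return ct, PlantedTruth(regulation=regulation, targets=targets)


def generate_prediction_tables(
    config: SynthConfig,
    truth: PlantedTruth,
    databases: Sequence[str] | None = None,
) -> list[TargetEdgeTable]:
    """Emit one target-prediction edge table per mock database.

    For every miRNA with a true target set, a ``consensus_fraction`` share
    of its targets (rounded) appears in all databases; remaining slots are
    filled with database-unique decoy genes drawn outside the miRNA's true
    set, so decoys never collide across databases.
    """
    if databases is None:
        databases = [DEFAULT_DATABASES[i] if i < len(DEFAULT_DATABASES)
                     else f"db{i + 1}" for i in range(config.n_databases)]
    rng = _rng(config, "predictions")
    universe = config.gene_universe()
    tables: list[TargetEdgeTable] = []
    rows_per_db: dict[str, list[tuple[str, str]]] = {db: [] for db in databases}
    for mirna in sorted(truth.targets):
        true = sorted(truth.targets[mirna])
        n_consensus = int(round(config.consensus_fraction * len(true)))
        consensus = list(rng.choice(true, size=n_consensus, replace=False))
        n_decoy = max(config.per_db_targets_per_mirna - n_consensus, 0)
        pool = [g for g in universe if g not in truth.targets[mirna]]
        decoys = rng.choice(pool, size=n_decoy * len(databases),
                            replace=False)
        for i, db in enumerate(databases):
            own = list(decoys[i * n_decoy:(i + 1) * n_decoy])
            for gene in consensus + own:
                rows_per_db[db].append((mirna, gene))
    for db in databases:
        df = pd.DataFrame(rows_per_db[db], columns=["mirna", "gene"])
        df["db"] = db
        tables.append(TargetEdgeTable(df))
        truth.db_tables[db] = df
    return tables


def generate_annotation(
    config: SynthConfig,
    truth: PlantedTruth,
) -> GeneSetCollection:
    """Draw ``n_gene_sets`` random gene sets from the universe.

    When ``enriched_set_mirna`` is set, an extra set named
    ``enriched_<mirna>`` contains all of that miRNA's true targets padded
    with random genes up to the minimum set size, guaranteeing strong
    over-representation of the miRNA's targets downstream.
    """
    rng = _rng(config, "annotation")
    universe = np.array(config.gene_universe())
    lo, hi = config.gene_set_size_range
    sets: dict[str, set[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"set{i + 1:03d}"] = set(rng.choice(universe, size=size,
                                                 replace=False))
    if config.enriched_set_mirna is not None:
        m = config.enriched_set_mirna
        if m not in truth.targets:
            raise ConfigurationError(
                f"enriched_set_mirna {m!r} has no true target set")
        members = set(truth.targets[m])
        pad_pool = [g for g in universe if g not in members]
        while len(members) < lo:
            members.add(str(rng.choice(pad_pool)))
            pad_pool = [g for g in pad_pool if g not in members]
        sets[f"enriched_{m}"] = members
    return GeneSetCollection(
        sets=sets,
        descriptions={name: "synthetic gene set" for name in sets},
        universe=set(universe),
    )


def injury_screen_config(
    seed: int,
    n_up: int = 39,
    n_down: int = 37,
    fold_range: tuple[float, float] = (5.0, 10.0),
    noise_sd: float = 0.1,
    **overrides,
) -> SynthConfig:
    """Config replicating the injury-screen conditions of the reference
    mouse cisplatin-AKI study: 39 upregulated and 37 downregulated miRNAs
    on a 528-feature panel, effect magnitudes of at least fivefold, mild
    per-well Ct noise and 3 replicates per group.

    Planted panel slots and fold magnitudes are drawn deterministically
    from ``seed``.
    """
    rng = np.random.default_rng([int(seed), 911])
    base = SynthConfig(seed=int(seed), noise_sd=noise_sd, **overrides)
    names = base.feature_names()
    slots = rng.choice(len(names), size=n_up + n_down, replace=False)
    folds = rng.uniform(*fold_range, size=n_up + n_down)
    effects = tuple(
        PlantedEffect(mirna=names[slot], comparison="Cis_vs_Saline",
                      direction="up" if i < n_up else "down",
                      fold=float(folds[i]))
        for i, slot in enumerate(slots)
    )
    return SynthConfig(seed=int(seed), noise_sd=noise_sd,
                       planted_effects=effects, **overrides)
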