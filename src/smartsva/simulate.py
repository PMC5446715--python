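"""Cell-mixture methylation simulator.

Generates bulk methylation data with known ground truth so that
cell-mixture adjustment methods can be evaluated end-to-end: a
haematopoietic lineage tree of q = 8 leukocyte subtypes (two progenitors
x four subtypes each) derived from a common reference profile, Dirichlet
per-sample cell proportions optionally confounded with a phenotype,
planted differentially methylated positions (DMPs), individual-specific
variation, batch shifts and measurement error.

All methylation variability is generated on the M-value scale; subtype
profiles are mixed on the beta scale (mixing cell populations averages
methylated fractions, not log-odds); the bulk signal then returns to the
M scale where batch shifts and noise are added.

Every operation consumes an explicit :class:`numpy.random.Generator`;
identical seeds give bit-identical datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .matrix import MethylationMatrix, beta_to_m, m_to_beta

__all__ = [
    "MixtureParams",
    "LineageParams",
    "IndividualParams",
    "SignalParams",
    "ProportionParams",
    "ConfoundingParams",
    "BatchParams",
    "NoiseParams",
    "SimulationConfig",
    "CellPanel",
    "PlantedSignal",
    "SimulationTruth",
    "SimulatedDataset",
    "sample_reference_profile",
    "differentiate",
    "build_cell_panel",
    "sample_cell_proportions",
    "plant_phenotype_effects",
    "assemble_dataset",
]

# Default lineage: root -> 2 progenitors -> 4 subtypes each, mimicking
# the myeloid / lymphoid split of blood leukocytes.
DEFAULT_TREE = {
    "myeloid": ["neutrophil", "monocyte", "eosinophil", "basophil"],
    "lymphoid": ["cd4t", "cd8t", "bcell", "nk"],
}


@dataclass
class MixtureParams:
    """Three-component normal mixture for the reference M-value profile
    (hypo-, hemi- and hyper-methylated CpGs)."""

    means: tuple = (-4.0, 0.0, 4.0)
    sds: tuple = (0.6, 0.6, 0.6)
    probs: tuple = (0.45, 0.10, 0.45)


@dataclass
class LineageParams:
    """Per differentiation step: fraction of CpGs shifted and the shift sd."""

    frac: float = 0.15  # pi^C
    sd: float = 1.0  # sigma_C


@dataclass
class IndividualParams:
    """Individual-specific methylation differences, per sample x subtype."""

    frac: float = 0.05  # pi^I
    sd: float = 0.5  # sigma_I


@dataclass
class SignalParams:
    """Phenotype-associated DMPs: fraction of CpGs and effect sd (M scale)."""

    frac: float = 0.01  # pi^G
    sd: float = 1.0  # sigma_G
    shared_across_subtypes: bool = True


@dataclass
class ProportionParams:
    """Dirichlet cell proportions: mean simplex point and overdispersion."""

    mean: tuple = (0.35, 0.10, 0.10, 0.05, 0.15, 0.10, 0.10, 0.05)  # pi^P
    overdispersion: float = 25.0  # phi


@dataclass
class ConfoundingParams:
    """Phenotype-linked shift of mean proportions: per-subtype log2 fold
    changes drawn N(0, sd^2). sd = 0 means no confounding."""

    sd: float = 0.3  # sigma_F


@dataclass
class BatchParams:
    n_batches: int = 5
    sd: float = 0.3  # sigma_B
    fraction: float = 1.0  # fraction of probes a batch shift touches


@dataclass
class NoiseParams:
    sd: float = 0.3  # sigma_E, measurement error on the M scale


@dataclass
class SimulationConfig:
    """Full generative configuration; defaults give a moderately noisy,
    moderately confounded case-control study of 10,000 CpGs and 100
    samples (50/50 groups) with 1% DMPs."""

    p: int = 10_000
    n: int = 100
    q: int = 8
    mixture: MixtureParams = field(default_factory=MixtureParams)
    lineage: LineageParams = field(default_factory=LineageParams)
    individual: IndividualParams = field(default_factory=IndividualParams)
    signal: SignalParams = field(default_factory=SignalParams)
    proportions: ProportionParams = field(default_factory=ProportionParams)
    confounding: ConfoundingParams = field(default_factory=ConfoundingParams)
    batch: BatchParams = field(default_factory=BatchParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    phenotype: str = "binary"
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.mixture.probs, float)
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("mixture probabilities must sum to 1")
        mean = np.asarray(self.proportions.mean, float)
        if len(mean) != self.q:
            raise ValueError("proportions.mean length must equal q")
        if abs(mean.sum() - 1.0) > 1e-12:
            raise ValueError("mean proportions must sum to 1")
        if np.any(mean < 0):
            raise ValueError("mean proportions must be nonnegative")
        for name, frac in (
            ("lineage.frac", self.lineage.frac),
            ("individual.frac", self.individual.frac),
            ("signal.frac", self.signal.frac),
            ("batch.fraction", self.batch.fraction),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, sd in (
            ("lineage.sd", self.lineage.sd),
            ("individual.sd", self.individual.sd),
            ("signal.sd", self.signal.sd),
            ("confounding.sd", self.confounding.sd),
            ("batch.sd", self.batch.sd),
            ("noise.sd", self.noise.sd),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phenotype not in ("binary", "continuous"):
            raise ValueError("phenotype must be 'binary' or 'continuous'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        nested = {
            "mixture": MixtureParams,
            "lineage": LineageParams,
            "individual": IndividualParams,
            "signal": SignalParams,
            "proportions": ProportionParams,
            "confounding": ConfoundingParams,
            "batch": BatchParams,
            "noise": NoiseParams,
        }
        for key, typ in nested.items():
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellPanel:
    """Per-cell-type mean M-value profiles (p x q) and the lineage tree.

    Column order is fixed: the four subtypes of the first progenitor,
    then the four of the second, in tree order.
    """

    A: np.ndarray
    tree: dict
    column_names: list

    @property
    def q(self) -> int:
        return self.A.shape[1]


@dataclass
class PlantedSignal:
    """DMP locations and per-subtype effect sizes (n_dmp x q, M scale)."""

    dmp_index: np.ndarray
    effects: np.ndarray  # length n_dmp, the shared effect (or mean across subtypes)
    per_subtype: np.ndarray  # n_dmp x q


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analyst would not."""

    B: np.ndarray  # n x q proportions
    dmp_index: np.ndarray
    effect: np.ndarray
    batch_label: np.ndarray  # length n, values in 0..n_batches-1
    phenotype: np.ndarray
    fold_changes: np.ndarray  # length q


@dataclass
class SimulatedDataset:
    Y: MethylationMatrix  # M scale
    truth: SimulationTruth
    config: SimulationConfig
    panel: Optional[CellPanel] = None

    @property
    def beta_view(self) -> MethylationMatrix:
        return self.Y.to_beta()


def sample_reference_profile(config: SimulationConfig, rng: np.random.Generator):
    """Reference (stem-cell) M-value profile from the 3-component mixture.

    Returns (values, component labels).
    """
    mix = config.mixture
    labels = rng.choice(3, size=config.p, p=np.asarray(mix.probs, float))
    means = np.asarray(mix.means, float)[labels]
    sds = np.asarray(mix.sds, float)[labels]
    return means + sds * rng.standard_normal(config.p), labels


def differentiate(
    parent: np.ndarray, frac: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One differentiation step: shift a random round(frac * p) subset of
    probes by N(0, sd^2); all other probes stay identical to the parent."""
    if not (0.0 <= frac <= 1.0):
        raise ValueError("frac must lie in [0, 1]")
    p = parent.shape[0]
    child = parent.copy()
    n_change = int(round(frac * p))
    if n_change > 0:
        idx = rng.choice(p, size=n_change, replace=False)
        child[idx] += sd * rng.standard_normal(n_change)
    return child


def build_cell_panel(config: SimulationConfig, rng: np.random.Generator) -> CellPanel:
    """Reference -> 2 progenitors -> 4 subtypes each, via differentiation."""
    tree = DEFAULT_TREE
    n_leaves = sum(len(v) for v in tree.values())
    if config.q != n_leaves:
        raise ValueError(
            f"q = {config.q} does not match the lineage tree ({n_leaves} subtypes)"
        )
    reference, _ = sample_reference_profile(config, rng)
    columns = []
    names = []
    for progenitor, subtypes in tree.items():
        prog_profile = differentiate(reference, config.lineage.frac, config.lineage.sd, rng)
        for subtype in subtypes:
            columns.append(
                differentiate(prog_profile, config.lineage.frac, config.lineage.sd, rng)
            )
            names.append(subtype)
    return CellPanel(A=np.column_stack(columns), tree=tree, column_names=names)


def sample_cell_proportions(
    config: SimulationConfig, phenotype: np.ndarray, rng: np.random.Generator
):
    """Dirichlet cell proportions, optionally confounded with the phenotype.

    Per-subtype log2 fold changes f_k ~ N(0, confounding.sd^2) are drawn
    once; for a binary phenotype, group-1 samples use mean proportions
    pi^P and group-2 samples pi^P * 2^f renormalized; for a continuous
    phenotype x_i the fold change scales linearly, pi^P * 2^(f * x_i).
    Each sample is then drawn Dirichlet(mean_i * phi).

    Returns (B, fold_changes) with every row of B on the simplex.
    """
    phi = config.proportions.overdispersion
    if phi <= 0:
        raise ValueError("overdispersion must be > 0")
    mean = np.asarray(config.proportions.mean, float)
    n, q = config.n, config.q
    f = config.confounding.sd * rng.standard_normal(q)

    x = np.asarray(phenotype, float)
    means = mean[None, :] * np.exp2(f[None, :] * x[:, None])
    means /= means.sum(axis=1, keepdims=True)

    gams = rng.standard_gamma(means * phi, size=(n, q))
    # guard against an (astronomically unlikely) all-zero gamma row
    gams = np.maximum(gams, np.finfo(float).tiny)
    B = gams / gams.sum(axis=1, keepdims=True)
    return B, f


def plant_phenotype_effects(
    panel: CellPanel, config: SimulationConfig, rng: np.random.Generator
) -> PlantedSignal:
    """Designate round(signal.frac * p) DMPs and draw their M-scale effects.

    Effects delta_j ~ N(0, signal.sd^2) are shared across subtypes by
    default; with sharing off each subtype gets its own independent draw
    (the realized bulk effect is then the proportion-weighted average).
    """
    p, q = panel.A.shape
    n_dmp = int(round(config.signal.frac * p))
    if n_dmp == 0:
        return PlantedSignal(
            dmp_index=np.empty(0, dtype=int),
            effects=np.empty(0),
            per_subtype=np.empty((0, q)),
        )
    dmp_index = np.sort(rng.choice(p, size=n_dmp, replace=False))
    if config.signal.shared_across_subtypes:
        delta = config.signal.sd * rng.standard_normal(n_dmp)
        per_subtype = np.repeat(delta[:, None], q, axis=1)
    else:
        per_subtype = config.signal.sd * rng.standard_normal((n_dmp, q))
        delta = per_subtype.mean(axis=1)
    return PlantedSignal(dmp_index=dmp_index, effects=delta, per_subtype=per_subtype)


def _make_phenotype(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.phenotype == "binary":
        half = config.n // 2
        return np.concatenate([np.zeros(half), np.ones(config.n - half)])
    return rng.standard_normal(config.n)


def assemble_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative pipeline and return data plus ground truth.

    Order of operations (one fixed random stream): phenotype -> cell
    panel -> confounded proportions -> DMP effects -> per-(sample,
    subtype) individual effects and beta-scale mixing -> batch labels and
    per-(batch, probe) shifts on the M scale -> measurement error.
    """
    rng = np.random.default_rng(config.seed)
    p, n, q = config.p, config.n, config.q

    phenotype = _make_phenotype(config, rng)
    panel = build_cell_panel(config, rng)
    B, fold_changes = sample_cell_proportions(config, phenotype, rng)
    signal = plant_phenotype_effects(panel, config, rng)

    n_ind = int(round(config.individual.frac * p))
    bulk_beta = np.empty((p, n))
    for i in range(n):
        M_i = panel.A.copy()
        if n_ind > 0:
            for k in range(q):
                idx = rng.choice(p, size=n_ind, replace=False)
                M_i[idx, k] += config.individual.sd * rng.standard_normal(n_ind)
        if signal.dmp_index.size:
            dose = phenotype[i] if config.phenotype == "continuous" else float(phenotype[i] == 1)
            if dose != 0.0:
                M_i[signal.dmp_index, :] += dose * signal.per_subtype
        bulk_beta[:, i] = m_to_beta(M_i) @ B[i]

    Ym = beta_to_m(bulk_beta)

    # round-robin randomization of samples into batches
    n_b = config.batch.n_batches
    batch_label = np.empty(n, dtype=int)
    batch_label[rng.permutation(n)] = np.arange(n) % n_b
    shifts = config.batch.sd * rng.standard_normal((p, n_b))
    if config.batch.fraction < 1.0:
        n_hit = int(round(config.batch.fraction * p))
        mask = np.zeros((p, n_b))
        for b in range(n_b):
            mask[rng.choice(p, size=n_hit, replace=False), b] = 1.0
        shifts *= mask
    Ym += shifts[:, batch_label]

    Ym += config.noise.sd * rng.standard_normal((p, n))

    Y = MethylationMatrix(
        values=Ym,
        probe_ids=[f"cg{j:06d}" for j in range(p)],
        sample_ids=[f"s{i:04d}" for i in range(n)],
        scale="M",
    )
    truth = SimulationTruth(
        B=B,
        dmp_index=signal.dmp_index,
        effect=signal.effects,
        batch_label=batch_label,
        phenotype=phenotype,
        fold_changes=fold_changes,
    )
    return SimulatedDataset(Y=Y, truth=truth, config=config, panel=panel)
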