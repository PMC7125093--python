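"""Chromosome encoding, four-objective candidate evaluation and Pareto utilities.

A candidate solution is a binary chromosome of ``n_channels + 8`` genes
(64 for the full 56-channel montage): the leading genes are the channel
mask, the next four encode the one-class SVM ``nu`` and the last four its
``gamma``, each 4-bit field read most-significant-bit first as an index into
a 16-entry lookup table of admissible values.

A candidate is scored on four objectives: the number of selected channels
(minimized) and the identification accuracy, TAR and TRR (maximized).
Internally all four are expressed in a minimization image
``(n_channels, 1 - accuracy, 1 - TAR, 1 - TRR)``; reports re-invert them.
The infeasible all-zero channel mask is penalized with a sentinel worst
image ``(n_channels_max + 1, 1, 1, 1)`` rather than repaired, keeping
evaluation total without injecting channels the search never chose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler

from .classify import crossval_identification, evaluate_authentication, train_one_class
from .dataset import FeatureCache, SubjectSplit

__all__ = [
    "PARAMETER_TABLE",
    "ParameterTable",
    "Chromosome",
    "ObjectiveVector",
    "FrontMember",
    "ParetoFront",
    "EvaluationConfig",
    "GAConfig",
    "decode_chromosome",
    "evaluate_candidate",
    "make_evaluator",
    "dominates",
    "pareto_filter",
    "random_subject_splits",
]

#: Admissible nu/gamma values, indexed by the decoded 4-bit field.
PARAMETER_TABLE: tuple[float, ...] = (
    0.000001, 0.0001, 0.0005, 0.001, 0.005, 0.01, 0.1, 0.2,
    0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


@dataclass(frozen=True)
class ParameterTable:
    """16-entry lookup shared by the nu and gamma fields."""

    values: tuple[float, ...] = PARAMETER_TABLE

    def __post_init__(self) -> None:
        if len(self.values) != 16:
            raise ValueError("parameter table must have exactly 16 entries")
        if any(v <= 0 for v in self.values):
            raise ValueError("parameter table values must be strictly positive")

    def __getitem__(self, i: int) -> float:
        return self.values[i]


@dataclass(frozen=True)
class Chromosome:
    """Binary genes: channel mask followed by 4-bit nu and gamma fields."""

    genes: tuple[int, ...]
    n_channels: int = 56

    def __post_init__(self) -> None:
        if len(self.genes) != self.n_channels + 8:
            raise ValueError(
                f"expected {self.n_channels + 8} genes, got {len(self.genes)}"
            )
        if any(g not in (0, 1) for g in self.genes):
            raise ValueError("genes must be binary")

    @property
    def channel_genes(self) -> tuple[int, ...]:
        return self.genes[: self.n_channels]

    @property
    def nu_field(self) -> tuple[int, ...]:
        return self.genes[self.n_channels: self.n_channels + 4]

    @property
    def gamma_field(self) -> tuple[int, ...]:
        return self.genes[self.n_channels + 4:]


def _bits_to_index(bits: Sequence[int]) -> int:
    """4-bit binary field to table position, most-significant bit first."""
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


def decode_chromosome(chromosome: Chromosome,
                      table: ParameterTable = ParameterTable()
                      ) -> tuple[frozenset[int], float, float]:
    """Channel index set plus the nu and gamma values looked up from the table."""
    mask = frozenset(i for i, g in enumerate(chromosome.channel_genes) if g)
    nu = table[_bits_to_index(chromosome.nu_field)]
    gamma = table[_bits_to_index(chromosome.gamma_field)]
    return mask, nu, gamma


@dataclass(frozen=True)
class ObjectiveVector:
    """The four objective values of one candidate, in report orientation.

    ``feasible`` is False only for the penalized empty channel mask, whose
    minimization image is the sentinel ``(n_channels_max + 1, 1, 1, 1)``.
    """

    n_channels: int
    accuracy: float
    tar: float
    trr: float
    accuracy_std: float = 0.0
    feasible: bool = True

    def minimization(self) -> tuple[float, float, float, float]:
        return (float(self.n_channels), 1.0 - self.accuracy,
                1.0 - self.tar, 1.0 - self.trr)

    @classmethod
    def sentinel(cls, n_channels_max: int = 56) -> "ObjectiveVector":
        return cls(n_channels=n_channels_max + 1, accuracy=0.0, tar=0.0,
                   trr=0.0, feasible=False)


@dataclass(frozen=True)
class FrontMember:
    """One Pareto-front entry: the chromosome with its decoded parameters."""

    chromosome: Chromosome
    objectives: ObjectiveVector
    nu: float
    gamma: float
    channel_indices: frozenset[int]


@dataclass
class ParetoFront:
    """Mutually non-dominated candidates plus run diagnostics."""

    members: list[FrontMember]
    n_evaluations: int = 0
    generations_run: int = 0
    generation_log: list[dict] = field(default_factory=list)
    evaluation_log: list[tuple[int, tuple[int, ...], ObjectiveVector]] = \
        field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def objectives_array(self) -> np.ndarray:
        return np.array([m.objectives.minimization() for m in self.members])


# ---------------------------------------------------------------------------
# Domination and filtering
# ---------------------------------------------------------------------------

def dominates(u: Sequence[float], v: Sequence[float]) -> bool:
    """Weak Pareto domination in the minimization image: u <= v, u != v."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    return bool(np.all(u <= v) and np.any(u < v))


def pareto_filter(candidates: Sequence[ObjectiveVector]) -> list[ObjectiveVector]:
    """Keep exactly the non-dominated candidates (minimization image).

    Duplicate objective vectors collapse to one representative.  Brute-force
    pairwise check; intended for reports and as an oracle, not inner loops.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    images = [c.minimization() for c in candidates]
    kept: list[ObjectiveVector] = []
    kept_images: list[tuple] = []
    for i, (cand, img) in enumerate(zip(candidates, images)):
        if img in kept_images:
            continue
        if any(dominates(other, img) for j, other in enumerate(images) if j != i):
            continue
        kept.append(cand)
        kept_images.append(img)
    return kept


def non_dominated_indices(images: np.ndarray) -> np.ndarray:
    """Indices of rows of ``images`` not dominated by any other row."""
    n = len(images)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        le = np.all(images <= images[i], axis=1)
        lt = np.any(images < images[i], axis=1)
        dominators = le & lt
        dominators[i] = False
        if dominators.any():
            keep[i] = False
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationConfig:
    """Protocol settings for scoring one candidate.

    The one-class model is trained on non-intruder instances of
    ``train_session``; TAR is measured on non-intruder instances and TRR on
    intruder instances of ``test_session`` (the enrol-on-session-one,
    verify-on-session-two protocol).  Identification accuracy is k-fold
    cross-validation over the non-intruder training-session instances with
    one fixed fold seed per run, so objective differences across candidates
    reflect channels and parameters rather than fold shuffling.
    """

    train_session: str = "1"
    test_session: str = "2"
    cv_folds: int = 10
    cv_seed: int = 0
    svm_C: float = 1.0
    standardize: bool = False


def evaluate_candidate(chromosome: Chromosome, cache: FeatureCache,
                       split: SubjectSplit,
                       cfg: EvaluationConfig = EvaluationConfig(),
                       table: ParameterTable = ParameterTable()) -> ObjectiveVector:
    """Score one chromosome on the four objectives.

    An all-zero channel mask returns the sentinel worst objective vector
    (feasibility penalization) instead of raising, so the optimizer's
    evaluation stays total.
    """
    mask, nu, gamma = decode_chromosome(chromosome, table)
    if not mask:
        return ObjectiveVector.sentinel(chromosome.n_channels)

    non_intruders = sorted(split.non_intruders)
    intruders = sorted(split.intruders)

    train_blocks = [cache.instance_matrix(s, cfg.train_session, mask)
                    for s in non_intruders]
    x_train = np.vstack(train_blocks)
    y_train = np.concatenate([
        np.full(len(block), subj) for subj, block in zip(non_intruders, train_blocks)
    ])
    genuine = np.vstack([cache.instance_matrix(s, cfg.test_session, mask)
                         for s in non_intruders])
    intruder = np.vstack([cache.instance_matrix(s, cfg.test_session, mask)
                          for s in intruders])
    if cfg.standardize:
        scaler = StandardScaler().fit(x_train)
        x_train = scaler.transform(x_train)
        genuine = scaler.transform(genuine)
        intruder = scaler.transform(intruder)

    model = train_one_class(x_train, nu=nu, gamma=gamma,
                            metadata={"subjects": non_intruders,
                                      "session": cfg.train_session,
                                      "mask": sorted(mask)})
    auth = evaluate_authentication(model, genuine, intruder)
    accuracy, accuracy_std = crossval_identification(
        x_train, y_train, k=cfg.cv_folds, seed=cfg.cv_seed, C=cfg.svm_C
    )
    return ObjectiveVector(n_channels=len(mask), accuracy=accuracy,
                           tar=auth.tar, trr=auth.trr, accuracy_std=accuracy_std)


def make_evaluator(cache: FeatureCache, split: SubjectSplit,
                   cfg: EvaluationConfig = EvaluationConfig(),
                   table: ParameterTable = ParameterTable(),
                   n_channels: int | None = None
                   ) -> Callable[[tuple[int, ...]], ObjectiveVector]:
    """Bind dataset and protocol into a genes -> objectives callable."""
    n_ch = len(cache.montage) if n_channels is None else n_channels

    def evaluator(genes: tuple[int, ...]) -> ObjectiveVector:
        return evaluate_candidate(Chromosome(genes=tuple(genes), n_channels=n_ch),
                                  cache, split, cfg, table)

    return evaluator


# ---------------------------------------------------------------------------
# Subject splits
# ---------------------------------------------------------------------------

def random_subject_splits(subjects: Sequence[str], n_splits: int = 10,
                          seed: int = 0) -> list[SubjectSplit]:
    """Random disjoint 50/50 non-intruder / intruder partitions.

    Odd subject counts put the extra subject on the non-intruder side.
    Reproducible for a fixed seed.
    """
    subjects = [str(s) for s in subjects]
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    n_non = (len(subjects) + 1) // 2
    splits = []
    for _ in range(n_splits):
        perm = list(rng.permutation(subjects))
        splits.append(SubjectSplit(non_intruders=perm[:n_non],
                                   intruders=perm[n_non:]))
    return splits


# ---------------------------------------------------------------------------
# GA configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """NSGA driver settings.

    Defaults follow the study protocol: population 30, at most 500
    generations, objective-space tolerance 1e-4 checked every 10th
    generation.  Genetic operators are standard binary-GA defaults:
    two-point crossover (p=0.9), per-gene bit-flip mutation (p=1/n_genes),
    binary tournament mating selection.  ``ref_divisions`` controls the
    systematic reference-point lattice of NSGA-III (4 divisions on 4
    objectives gives 35 points).
    """

    variant: str = "nsga2"
    population_size: int = 30
    max_generations: int = 500
    tolerance: float = 1e-4
    tolerance_check_period: int = 10
    crossover_prob: float = 0.9
    mutation_prob: float | None = None
    ref_divisions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("nsga2", "nsga3"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    def with_seed(self, seed: int) -> "GAConfig":
        return replace(self, seed=seed)
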