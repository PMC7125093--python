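"""Staged experiment orchestration: simulate, extract features, optimize, evaluate.

The workflow mirrors the cache-and-reuse design of the method: features are
extracted once per dataset over *all* channels and stored; the optimizer then
serves every candidate channel mask from that cache.  Each stage is an
importable function taking a :class:`RunConfig`; the command-line interface
in :mod:`eegselect.cli` is a thin wrapper over these.

Every run writes a machine-readable copy of its resolved configuration into
the output directory, and all randomness fans out deterministically from the
single top-level seed (generator, cross-validation folds, genetic search).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    EpochSet,
    FeatureCache,
    SubjectSplit,
    load_epochset,
    save_epochset,
    write_pareto_report,
)
from .errors import CacheError
from .features import FeatureConfig, compute_feature_cache
from .optimize import (
    Chromosome,
    EvaluationConfig,
    GAConfig,
    ObjectiveVector,
    ParameterTable,
    ParetoFront,
    decode_chromosome,
    evaluate_candidate,
    make_evaluator,
    random_subject_splits,
)
from .nsga import run_nsga
from .preprocessing import CARConfig, apply_car
from .synthetic import SyntheticSpec, generate_epochset

logger = logging.getLogger("eegselect")

CACHE_FILENAME = "feature_cache.tsv"


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run.

    Exactly one data source must be set: ``dataset_path`` (a directory in the
    package's on-disk epoch format) or ``synthetic`` (a generator spec).
    ``split`` is either explicit non-intruder/intruder lists or the string
    ``"random"`` combined with ``n_splits`` (random 50/50 subdivisions).
    """

    seed: int = 0
    output_dir: str = "runs/out"
    dataset_path: str | None = None
    synthetic: SyntheticSpec | None = None
    apply_car: bool = True
    features: FeatureConfig = field(default_factory=FeatureConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    split: SubjectSplit | str = "random"
    n_splits: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.dataset_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of dataset_path / synthetic must be set")

    # -- seed fan-out -----------------------------------------------------
    def derived_seeds(self) -> dict[str, int]:
        rng = np.random.default_rng(self.seed)
        gen, ga, cv = (int(v) for v in rng.integers(0, 2 ** 31, size=3))
        return {"generator": gen, "ga": ga, "cv": cv}

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "apply_car": self.apply_car,
            "features": dataclasses.asdict(self.features),
            "evaluation": dataclasses.asdict(self.evaluation),
            "ga": dataclasses.asdict(self.ga),
            "n_splits": self.n_splits,
            "log_level": self.log_level,
        }
        if self.dataset_path is not None:
            out["dataset_path"] = self.dataset_path
        if self.synthetic is not None:
            out["synthetic"] = dataclasses.asdict(self.synthetic)
        if isinstance(self.split, SubjectSplit):
            out["split"] = {"non_intruders": sorted(self.split.non_intruders),
                            "intruders": sorted(self.split.intruders)}
        else:
            out["split"] = self.split
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key in ("informative_channels", "carrier_freq_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = SyntheticSpec(**syn)
        if "features" in kwargs:
            kwargs["features"] = FeatureConfig(**{
                k: v for k, v in kwargs["features"].items() if k != "feature_order"
            })
        if "evaluation" in kwargs:
            kwargs["evaluation"] = EvaluationConfig(**kwargs["evaluation"])
        if "ga" in kwargs:
            kwargs["ga"] = GAConfig(**kwargs["ga"])
        split = kwargs.get("split", "random")
        if isinstance(split, dict):
            kwargs["split"] = SubjectSplit(non_intruders=split["non_intruders"],
                                           intruders=split["intruders"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    def write_resolved(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_or_generate(config: RunConfig) -> EpochSet:
    if config.dataset_path is not None:
        return load_epochset(config.dataset_path)
    seeds = config.derived_seeds()
    spec = dataclasses.replace(config.synthetic, seed=seeds["generator"])
    return generate_epochset(spec)


def cmd_simulate(config: RunConfig) -> Path:
    """Generate the configured synthetic dataset and write it to disk."""
    if config.synthetic is None:
        raise ValueError("simulate requires a synthetic spec in the config")
    epochset = _load_or_generate(config)
    out = Path(config.output_dir) / "dataset"
    save_epochset(epochset, out)
    config.write_resolved()
    logger.info("wrote synthetic dataset (%d subjects, %d channels) to %s",
                len(epochset.subjects), epochset.n_channels, out)
    return out


def cmd_extract_features(config: RunConfig) -> FeatureCache:
    """Build (or reuse) the complete per-channel feature cache.

    Re-running with an unchanged configuration is a no-op: the stored cache
    is returned as soon as its provenance matches the requested settings.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache_path = out / CACHE_FILENAME
    expected = {**config.features.provenance(), "car": config.apply_car}
    if cache_path.exists():
        cache = FeatureCache.load(cache_path)
        if cache.provenance == expected:
            logger.info("feature cache up to date at %s", cache_path)
            return cache
    epochset = _load_or_generate(config)
    if config.apply_car:
        epochset = apply_car(epochset, CARConfig(apply=True))
    cache = compute_feature_cache(epochset, config.features)
    cache.provenance = expected
    cache.save(cache_path)
    config.write_resolved()
    logger.info("extracted features for %d (subject, session) blocks -> %s",
                len(cache.blocks), cache_path)
    return cache


def _resolve_splits(config: RunConfig, subjects: list[str]) -> list[SubjectSplit]:
    if isinstance(config.split, SubjectSplit):
        return [config.split]
    if config.split == "random":
        return random_subject_splits(subjects, n_splits=config.n_splits,
                                     seed=config.seed)
    raise ValueError(f"unrecognized split specification {config.split!r}")


def summarize_fronts(fronts: list[ParetoFront]) -> pd.DataFrame:
    """Mean and std of accuracy/TAR/TRR per channel count across split fronts.

    For each split and channel count the best member (largest worst-case
    authentication rate, ties by accuracy) represents that count; counts are
    then aggregated over splits.
    """
    rows = []
    for i, front in enumerate(fronts):
        per_count: dict[int, ObjectiveVector] = {}
        for m in front.members:
            o = m.objectives
            cur = per_count.get(o.n_channels)
            key = (min(o.tar, o.trr), o.accuracy)
            if cur is None or key > (min(cur.tar, cur.trr), cur.accuracy):
                per_count[o.n_channels] = o
        for n_ch, o in per_count.items():
            rows.append({"split": i, "n_channels": n_ch, "accuracy": o.accuracy,
                         "TAR": o.tar, "TRR": o.trr})
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("n_channels").agg(
        n_splits=("split", "nunique"),
        accuracy_mean=("accuracy", "mean"), accuracy_std=("accuracy", "std"),
        TAR_mean=("TAR", "mean"), TAR_std=("TAR", "std"),
        TRR_mean=("TRR", "mean"), TRR_std=("TRR", "std"),
    ).fillna(0.0).reset_index()
    return grouped


def cmd_optimize(config: RunConfig) -> list[ParetoFront]:
    """Run the four-objective channel-selection search for every split.

    Writes, per split, a Pareto report and a per-generation log; in random-
    splits mode also a summary of mean +/- std per channel count across
    splits.  Requires the feature cache from :func:`cmd_extract_features`.
    """
    out = Path(config.output_dir)
    cache_path = out / CACHE_FILENAME
    if not cache_path.exists():
        raise CacheError(
            f"no feature cache at {cache_path}; run extract-features first"
        )
    cache = FeatureCache.load(cache_path)
    subjects = sorted({s for s, _ in cache.blocks})
    splits = _resolve_splits(config, subjects)
    seeds = config.derived_seeds()
    eval_cfg = dataclasses.replace(config.evaluation, cv_seed=seeds["cv"])
    fronts: list[ParetoFront] = []
    for i, split in enumerate(splits):
        ga_cfg = config.ga.with_seed(seeds["ga"] + i)
        evaluator = make_evaluator(cache, split, eval_cfg)
        front = run_nsga(ga_cfg, evaluator, n_channels=len(cache.montage))
        fronts.append(front)
        write_pareto_report(front, out / f"pareto_split{i}.tsv", cache.montage)
        log_path = out / f"generations_split{i}.log"
        with open(log_path, "w") as fh:
            for rec in front.generation_log:
                fh.write(json.dumps(rec) + "\n")
        logger.info("split %d: %d generations, %d evaluations, front size %d",
                    i, front.generations_run, front.n_evaluations, len(front))
    if len(fronts) > 1:
        summary = summarize_fronts(fronts)
        summary.to_csv(out / "summary_by_channel_count.tsv", sep="\t", index=False)
    config.write_resolved()
    return fronts


def cmd_evaluate(config: RunConfig, chromosome: Chromosome | None = None,
                 channels: list[str] | None = None, nu: float | None = None,
                 gamma: float | None = None) -> pd.DataFrame:
    """Score one explicit configuration (chromosome, or channel labels + nu/gamma).

    Returns a one-row table with the four objectives and the decoded
    parameters, and writes it to the output directory.
    """
    out = Path(config.output_dir)
    cache_path = out / CACHE_FILENAME
    if not cache_path.exists():
        raise CacheError(
            f"no feature cache at {cache_path}; run extract-features first"
        )
    cache = FeatureCache.load(cache_path)
    table = ParameterTable()
    n_ch = len(cache.montage)
    if chromosome is None:
        if channels is None or nu is None or gamma is None:
            raise ValueError("need a chromosome, or channels plus nu and gamma")
        lookup = {lab: i for i, lab in enumerate(cache.montage)}
        unknown = [c for c in channels if c not in lookup]
        if unknown:
            raise ValueError(f"unknown channel labels: {unknown}")
        genes = [0] * (n_ch + 8)
        for lab in channels:
            genes[lookup[lab]] = 1
        nu_idx = min(range(16), key=lambda i: abs(table[i] - nu))
        gamma_idx = min(range(16), key=lambda i: abs(table[i] - gamma))
        genes[n_ch: n_ch + 4] = [int(b) for b in f"{nu_idx:04b}"]
        genes[n_ch + 4:] = [int(b) for b in f"{gamma_idx:04b}"]
        chromosome = Chromosome(genes=tuple(genes), n_channels=n_ch)
    subjects = sorted({s for s, _ in cache.blocks})
    splits = _resolve_splits(config, subjects)
    seeds = config.derived_seeds()
    eval_cfg = dataclasses.replace(config.evaluation, cv_seed=seeds["cv"])
    obj = evaluate_candidate(chromosome, cache, splits[0], eval_cfg, table)
    mask, dec_nu, dec_gamma = decode_chromosome(chromosome, table)
    row = pd.DataFrame([{
        "n_channels": obj.n_channels, "accuracy": obj.accuracy,
        "TAR": obj.tar, "TRR": obj.trr, "nu": dec_nu, "gamma": dec_gamma,
        "channels": " ".join(cache.montage[i] for i in sorted(mask)),
    }])
    out.mkdir(parents=True, exist_ok=True)
    row.to_csv(out / "evaluation.tsv", sep="\t", index=False)
    config.write_resolved()
    return row
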