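"""Configuration dataclasses for every pipeline stage.

One master seed spawns per-stage child seeds deterministically (keyed by the
stage name), so a stage can be rerun in isolation and still reproduce the
values it produced inside a full pipeline run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

VALID_MODELS = ("ga_kpls", "lasso", "ridge", "svm", "rf", "logit")


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed.

    The stage name is hashed with CRC32 so the child stream depends only on
    (seed, stage), never on the order stages happen to run in.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(stage.encode())])
    )


@dataclass
class KernelConfig:
    """Gaussian-kernel KPLS settings.

    sigma : bandwidth of K(xi, xj) = exp(-||xi - xj||^2 / (2 sigma^2)).
        ``None`` means "to be tuned" (by the GA or a grid).
    n_components : latent components extracted; must stay below n_train.
    threshold : decision cut on the continuous predicted response under
        {0, 1} coding of the outcome (poor = 1).
    """

    sigma: Optional[float] = None
    n_components: int = 3
    threshold: float = 0.5

    def validate(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for bandwidth tuning.

    Chromosomes are real-valued log10 multipliers of the median pairwise
    Euclidean distance of the training data (the median heuristic), so
    ``sigma_log10_range`` is scale-free.
    """

    population_size: int = 20
    n_generations: int = 50
    sigma_log10_range: tuple[float, float] = (-2.0, 3.0)
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sd: float = 0.25
    tournament_size: int = 2
    elitism: int = 1
    cv_folds: int = 5
    fitness_metric: str = "mcc"
    patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be < population_size")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.fitness_metric not in ("mcc", "accuracy", "auc"):
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")


@dataclass
class BaselineConfig:
    """Tuning contract for the five comparison classifiers."""

    lambda_grid_size: int = 100
    cv_folds: int = 10
    rf_n_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_grid_size < 2:
            raise ValueError("lambda_grid_size must be >= 2")


@dataclass
class SynthConfig:
    """Synthetic cohort: the study conditions the generator emulates.

    Defaults mirror the motivating cohort: 149 patients with 28.19%
    poor-outcome prevalence, 116 differentially expressed genes split
    70 up : 46 down in the poor group.
    """

    n_samples: int = 149
    n_genes: int = 2000
    prevalence_poor: float = 0.2819
    n_de_genes: int = 116
    up_fraction: float = 70 / 116
    effect_size: float = 1.0
    signal: str = "linear"  # or "nonlinear"
    n_latent: int = 20
    latent_shift: float = 0.3
    latent_spread: float = 0.2
    noise_sd: float = 1.0
    censor_rate: float = 0.2
    surv_scale_good: float = 6.0
    surv_scale_poor: float = 1.5
    raw_intensities: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be <= n_genes")
        if not (0 < self.prevalence_poor < 1):
            raise ValueError("prevalence_poor must be in (0,1)")
        if self.surv_scale_poor >= self.surv_scale_good:
            raise ValueError("surv_scale_poor must be < surv_scale_good")
        if self.signal not in ("linear", "nonlinear"):
            raise ValueError(f"unknown signal kind {self.signal!r}")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0,1)")


@dataclass
class ScreenConfig:
    """Sure independence screening settings.

    d defaults to floor(2n / log10(n)), the screening dimension rule; the
    utility is the absolute two-sample t statistic (equivalent to absolute
    marginal correlation on standardized expression with a binary response).
    """

    log_base: float = 10.0
    d_override: Optional[int] = None
    utility: str = "abs_t"

    def validate(self) -> None:
        if self.log_base not in (10.0, np.e):
            raise ValueError("log_base must be 10 or e")
        if self.utility not in ("abs_t", "abs_cor"):
            raise ValueError(f"unknown utility {self.utility!r}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline protocol constants.

    n_repeats=1000 and train_fraction=0.8 are the repeated-holdout protocol;
    q_threshold=0.05 is the differential-expression call threshold.
    """

    seed: int = 0
    n_repeats: int = 1000
    train_fraction: float = 0.8
    models: Sequence[str] = VALID_MODELS
    q_threshold: float = 0.05
    n_permutations: int = 1000
    stratify: bool = True
    screen_within_split: bool = False
    ga: GAConfig = field(default_factory=GAConfig)
    baselines: BaselineConfig = field(default_factory=BaselineConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    synth: Optional[SynthConfig] = field(default_factory=SynthConfig)
    expression_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    raw_input: Optional[bool] = None  # None: infer (synth: from raw_intensities; files: False)
    out_dir: str = "results"

    def validate(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0,1)")
        for m in self.models:
            if m not in VALID_MODELS:
                raise ValueError(f"unknown model name {m!r}; valid: {VALID_MODELS}")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0,1)")
        self.ga.validate()
        self.baselines.validate()
        self.kernel.validate()
        self.screen.validate()
        if self.synth is not None:
            self.synth.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sub = {}
        for key, sub_cls in (
            ("ga", GAConfig), ("baselines", BaselineConfig),
            ("kernel", KernelConfig), ("screen", ScreenConfig),
        ):
            if key in raw:
                sub[key] = sub_cls(**raw.pop(key))
        if "synth" in raw:
            val = raw.pop("synth")
            sub["synth"] = None if val is None else SynthConfig(**val)
        cfg = cls(**raw, **sub)
        cfg.validate()
        return cfg
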