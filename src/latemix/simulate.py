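"""Synthetic multi-omics cohort generator.

Emulates the statistical structure that the downstream analysis relies on: a
population of adults with three blood-derived omic blocks of very different
widths (transcriptomic intensities, metabolomic concentrations, methylation
beta values in (0,1)), five approximately Gaussian cardiovascular targets
(systolic/diastolic blood pressure, E/e' ratio, E/A ratio, LAVI) driven by a
small set of shared latent factors plus age/sex/BMI effects, and an external
cohort that is older, hypertension-enriched and batch-shifted relative to the
base population.

The generative model is latent-factor linear-Gaussian: latent factors are iid
standard normal per sample; a sparse subset of features per block loads on
them ("signal" features, recorded as ground truth); targets combine latent
factors, covariates and Gaussian noise. Methylation values are an
inverse-logit squash of a Gaussian score, which keeps them strictly inside
(0,1). Twin-pair dependence, missing data and medication adjustments are not
modelled; samples are independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "OMIC_NAMES", "TARGET_NAMES", "COVARIATE_NAMES",
    "SimConfig", "ExternalShift", "MultiOmicsCohort",
    "simulate_cohort", "simulate_external_cohort", "write_cohort", "read_cohort",
]

OMIC_NAMES = ("transcriptomic", "metabolomic", "epigenetic")
TARGET_NAMES = ("sbp", "dbp", "e_over_eprime", "e_over_a", "lavi")
COVARIATE_NAMES = ("age", "sex", "bmi")

# Population anchors for a cohort of ~40-year-old Finnish adults: target means,
# residual noise sds (target units), and additive covariate effects per
# (age-year, female sex, BMI-unit).
_TARGET_MEANS = np.array([119.0, 75.2, 4.8, 1.5, 22.5])
_TARGET_NOISE_SD = np.array([8.0, 6.0, 0.55, 0.22, 3.6])
_COVARIATE_EFFECTS = np.array([
    [0.45, -4.0, 0.5],     # sbp: mmHg per year / female / BMI unit
    [0.35, -2.5, 0.45],    # dbp
    [0.04, 0.10, 0.03],    # E/e'
    [-0.015, 0.02, -0.008],  # E/A
    [0.10, 1.0, 0.15],     # LAVI: mL/m^2
])
# Target loadings on the 6 default latent factors, in target units per
# latent sd. Blood pressure and the LVDD biomarkers share some factors
# (factors 2 and 4) so that omic blocks informative for one target carry
# signal for the others too.
_TARGET_LOADINGS = np.array([
    [7.0, 5.0, 0.0, 3.0, 0.0, 0.0],
    [5.0, 4.0, 0.0, 2.0, 0.0, 0.0],
    [0.0, 0.30, 0.45, 0.0, 0.25, 0.0],
    [0.0, 0.0, 0.18, 0.12, 0.0, 0.10],
    [0.0, 0.0, 2.5, 0.0, 3.0, 2.5],
])


@dataclass
class SimConfig:
    """Generation parameters for a base cohort.

    Defaults mirror the study conditions the pipeline is designed around:
    1,249 participants (~80% for model fitting), block widths 2000/200/75
    (a desk-scale echo of 5,842 transcript probes / 228 metabolites / 75 CpG
    sites), mean age ~42 years, and Gaussian targets whose ±1-sd classes
    split roughly 15/70/15.
    """

    n_samples: int = 1249
    n_latent: int = 6
    block_sizes: tuple[int, int, int] = (2000, 200, 75)
    signal_density: tuple[float, float, float] = (0.06, 0.35, 0.4)
    target_loadings: np.ndarray | None = None   # 5 x n_latent, target units
    covariate_effects: np.ndarray | None = None  # 5 x 3 (age, sex, bmi)
    block_noise_sd: tuple[float, float, float] = (1.0, 1.0, 1.0)
    target_noise_sd: np.ndarray | None = None   # length 5, target units
    train_fraction: float = 0.8
    validation_fraction: float = 0.2  # of the training partition
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block_sizes must all be >= 1")
        for d in np.atleast_1d(self.signal_density):
            if not 0.0 < d <= 1.0:
                raise ValueError("signal_density must lie in (0, 1]")
        if any(s < 0 for s in self.block_noise_sd):
            raise ValueError("block_noise_sd must be >= 0")
        if self.target_loadings is None:
            if self.n_latent == 6:
                self.target_loadings = _TARGET_LOADINGS.copy()
            else:
                # spread the default pattern over however many factors exist
                rng = np.random.default_rng(12345)
                self.target_loadings = rng.normal(
                    0.0, 1.0, size=(5, self.n_latent)) * _TARGET_NOISE_SD[:, None]
        self.target_loadings = np.asarray(self.target_loadings, dtype=float)
        if self.target_loadings.shape != (5, self.n_latent):
            raise ValueError("target_loadings must have shape (5, n_latent)")
        if self.covariate_effects is None:
            self.covariate_effects = _COVARIATE_EFFECTS.copy()
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.covariate_effects.shape != (5, 3):
            raise ValueError("covariate_effects must have shape (5, 3)")
        if self.target_noise_sd is None:
            self.target_noise_sd = _TARGET_NOISE_SD.copy()
        self.target_noise_sd = np.asarray(self.target_noise_sd, dtype=float)
        if np.any(self.target_noise_sd < 0):
            raise ValueError("target_noise_sd must be >= 0")


@dataclass
class ExternalShift:
    """Distribution shift defining the external (older, hypertensive) cohort."""

    age_offset: float = 20.0           # years
    sbp_offset: float = 25.0           # mmHg
    dbp_offset: float = 8.0            # mmHg
    batch_location: float = 0.3        # sd of per-feature additive shift
    batch_scale: float = 0.1           # sd of per-feature log-multiplier
    hypertension_enrichment: float = 2.0  # oversampling weight for high-BP samples

    def __post_init__(self):
        if self.hypertension_enrichment < 1:
            raise ValueError("hypertension_enrichment must be >= 1")
        if self.batch_scale < 0 or self.batch_location < 0:
            raise ValueError("batch effect sds must be >= 0")


@dataclass
class MultiOmicsCohort:
    """Aligned omic blocks, covariates, target panel and split labels."""

    blocks: dict[str, pd.DataFrame]
    covariates: pd.DataFrame
    targets: pd.DataFrame
    split: pd.Series
    ground_truth: dict | None = None
    config: SimConfig | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.covariates.index

    @property
    def n_samples(self) -> int:
        return len(self.covariates)

    def split_mask(self, *names: str) -> np.ndarray:
        """Boolean mask over samples for the given split labels.

        ``split_mask("train", "validation")`` is the full model-fitting
        partition; ``split_mask("test")`` the held-out samples.
        """
        return self.split.isin(names).to_numpy()

    def validate(self) -> None:
        ids = self.covariates.index
        for name, block in self.blocks.items():
            if not block.index.equals(ids):
                raise ValueError(f"block {name!r} sample ids misaligned")
            if block.isna().any().any():
                raise ValueError(f"block {name!r} contains missing values")
        if not self.targets.index.equals(ids) or not self.split.index.equals(ids):
            raise ValueError("targets/split sample ids misaligned")
        epi = self.blocks.get("epigenetic")
        if epi is not None:
            vals = epi.to_numpy()
            if vals.min() <= 0.0 or vals.max() >= 1.0:
                raise ValueError("epigenetic beta values must lie strictly in (0,1)")


def _structure(config: SimConfig) -> dict:
    """Structural parameters (loadings, masks, offsets) shared by the base and
    external cohorts; drawn from the config seed only, never from sample noise."""
    rng = np.random.default_rng([config.seed, 0])
    out = {}
    for b, (name, size, density) in enumerate(
            zip(OMIC_NAMES, config.block_sizes, np.broadcast_to(
                config.signal_density, (3,)))):
        n_signal = max(1, int(round(density * size)))
        mask = np.zeros(size, dtype=bool)
        mask[rng.choice(size, n_signal, replace=False)] = True
        loadings = np.zeros((config.n_latent, size))
        for j in np.flatnonzero(mask):
            k = rng.integers(1, min(3, config.n_latent) + 1)
            factors = rng.choice(config.n_latent, k, replace=False)
            loadings[factors, j] = rng.uniform(0.4, 1.0, k) * rng.choice([-1, 1], k)
        offsets = rng.normal(0.0, 1.5, size) if name == "epigenetic" else np.zeros(size)
        out[name] = {"mask": mask, "loadings": loadings, "offsets": offsets}
    return out


def _draw_covariates(n: int, rng: np.random.Generator,
                     age_mean: float = 41.6) -> pd.DataFrame:
    age = rng.normal(age_mean, 5.1, n)
    sex = (rng.random(n) < 0.538).astype(float)  # 1 = female
    bmi = rng.normal(26.4, 4.7, n)
    return pd.DataFrame({"age": age, "sex": sex, "bmi": bmi})


def _draw_blocks(latents: np.ndarray, structure: dict, config: SimConfig,
                 rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    prefixes = {"transcriptomic": "tx", "metabolomic": "met", "epigenetic": "cg"}
    blocks = {}
    for b, name in enumerate(OMIC_NAMES):
        s = structure[name]
        score = latents @ s["loadings"]
        noise = rng.normal(0.0, config.block_noise_sd[b], score.shape)
        if name == "epigenetic":
            # squash to (0,1): beta-value support
            values = expit(s["offsets"] + 0.7 * (score + noise))
        else:
            values = score + noise
        cols = [f"{prefixes[name]}{j:05d}" for j in range(values.shape[1])]
        blocks[name] = pd.DataFrame(values, columns=cols)
    return blocks


def _draw_targets(latents: np.ndarray, covariates: pd.DataFrame,
                  config: SimConfig, rng: np.random.Generator,
                  age_center: float = 41.6) -> pd.DataFrame:
    cov_centered = covariates.to_numpy() - np.array([age_center, 0.0, 26.4])
    signal = latents @ config.target_loadings.T + cov_centered @ config.covariate_effects.T
    noise = rng.normal(0.0, config.target_noise_sd, size=(len(covariates), 5))
    return pd.DataFrame(_TARGET_MEANS + signal + noise, columns=list(TARGET_NAMES))


def _assign_split(n: int, config: SimConfig, rng: np.random.Generator) -> pd.Series:
    order = rng.permutation(n)
    n_fit = int(round(config.train_fraction * n))
    n_val = int(round(config.validation_fraction * n_fit))
    labels = np.full(n, "test", dtype=object)
    labels[order[:n_fit - n_val]] = "train"
    labels[order[n_fit - n_val:n_fit]] = "validation"
    return pd.Series(labels, name="split")


def simulate_cohort(config: SimConfig | None = None) -> MultiOmicsCohort:
    """Generate a base cohort under the latent-factor model.

    Same config (including seed) yields a bit-identical cohort. Ground truth
    (per-block signal masks and generating loadings) is recorded so that
    importance-recovery and filtering behaviour can be checked downstream.
    """
    config = config or SimConfig()
    structure = _structure(config)
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    latents = rng.standard_normal((n, config.n_latent))
    covariates = _draw_covariates(n, rng)
    blocks = _draw_blocks(latents, structure, config, rng)
    targets = _draw_targets(latents, covariates, config, rng)
    split = _assign_split(n, config, rng)

    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    for frame in (*blocks.values(), covariates, targets):
        frame.index = ids
    split.index = ids
    ground_truth = {
        name: {"signal_mask": structure[name]["mask"],
               "loadings": structure[name]["loadings"]}
        for name in OMIC_NAMES
    }
    cohort = MultiOmicsCohort(blocks, covariates, targets, split,
                              ground_truth=ground_truth, config=config)
    cohort.validate()
    return cohort


def simulate_external_cohort(base: SimConfig, shift: ExternalShift, n: int,
                             seed_offset: int = 1) -> MultiOmicsCohort:
    """Generate the distribution-shifted external cohort.

    Shares the structural loadings of ``base`` (so transfer of learned
    encoders is meaningful) but draws new samples with an older age
    distribution, offset blood pressures, per-feature batch effects
    (additive location + strictly positive multiplicative scale), and
    oversampling of hypertensive individuals. Only blood-pressure targets
    are populated; no LVDD panel exists in the external setting.
    """
    if n < 2:
        raise ValueError("external cohort needs n >= 2")
    structure = _structure(base)
    rng = np.random.default_rng([base.seed, 2, seed_offset])
    pool = max(n, int(np.ceil(n * shift.hypertension_enrichment)) + n)
    latents = rng.standard_normal((pool, base.n_latent))
    covariates = _draw_covariates(pool, rng, age_mean=41.6 + shift.age_offset)
    blocks = _draw_blocks(latents, structure, base, rng)
    # age is centred at the external cohort's own mean, so the blood-pressure
    # shifts are controlled by the explicit offsets alone
    targets = _draw_targets(latents, covariates, base, rng,
                            age_center=41.6 + shift.age_offset)
    targets["sbp"] += shift.sbp_offset
    targets["dbp"] += shift.dbp_offset

    # weighted subsample: hypertensive candidates get enrichment-fold weight
    hyper = (targets["sbp"] > 140) | (targets["dbp"] > 90)
    weights = np.where(hyper, shift.hypertension_enrichment, 1.0)
    keep = rng.choice(pool, size=n, replace=False, p=weights / weights.sum())
    keep.sort()

    # per-feature batch effects on the continuous blocks; methylation betas
    # stay on their (0,1) scale and receive the location shift on the logit
    out_blocks = {}
    for name in OMIC_NAMES:
        values = blocks[name].iloc[keep].to_numpy()
        scale = np.exp(rng.normal(0.0, shift.batch_scale, values.shape[1]))
        loc = rng.normal(0.0, shift.batch_location, values.shape[1])
        if name == "epigenetic":
            from scipy.special import logit
            values = expit(logit(values) * scale + loc)
        else:
            values = values * scale + loc
        out_blocks[name] = pd.DataFrame(values, columns=blocks[name].columns)

    ids = pd.Index([f"E{i:05d}" for i in range(n)], name="sample_id")
    covariates = covariates.iloc[keep].set_index(ids)
    targets = targets.iloc[keep][["sbp", "dbp"]].set_index(ids)
    for frame in out_blocks.values():
        frame.index = ids
    split = pd.Series("test", index=ids, name="split")
    cohort = MultiOmicsCohort(out_blocks, covariates, targets, split,
                              ground_truth=None, config=base)
    for name, block in cohort.blocks.items():
        if block.isna().any().any():
            raise ValueError(f"block {name!r} contains missing values")
    return cohort


_FILES = {
    "transcriptomic": "transcriptomic.tsv", "metabolomic": "metabolomic.tsv",
    "epigenetic": "epigenetic.tsv", "covariates": "covariates.tsv",
    "targets": "targets.tsv", "split": "split.tsv",
}


def write_cohort(cohort: MultiOmicsCohort, directory: str | Path) -> None:
    """Write a cohort as TSVs (one per component) plus a JSON sidecar.

    Numeric values are written at full repr precision so that
    ``read_cohort(write_cohort(c))`` round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, block in cohort.blocks.items():
        block.to_csv(directory / _FILES[name], sep="\t")
    cohort.covariates.to_csv(directory / _FILES["covariates"], sep="\t")
    cohort.targets.to_csv(directory / _FILES["targets"], sep="\t")
    cohort.split.to_frame().to_csv(directory / _FILES["split"], sep="\t")
    sidecar = {}
    if cohort.config is not None:
        cfg = cohort.config
        sidecar["config"] = {
            "n_samples": cfg.n_samples, "n_latent": cfg.n_latent,
            "block_sizes": list(cfg.block_sizes),
            "signal_density": list(np.atleast_1d(cfg.signal_density).astype(float)),
            "target_loadings": cfg.target_loadings.tolist(),
            "covariate_effects": cfg.covariate_effects.tolist(),
            "block_noise_sd": list(cfg.block_noise_sd),
            "target_noise_sd": cfg.target_noise_sd.tolist(),
            "train_fraction": cfg.train_fraction,
            "validation_fraction": cfg.validation_fraction,
            "seed": cfg.seed,
        }
    if cohort.ground_truth is not None:
        sidecar["ground_truth"] = {
            name: {"signal_mask": gt["signal_mask"].tolist(),
                   "loadings": gt["loadings"].tolist()}
            for name, gt in cohort.ground_truth.items()
        }
    (directory / "cohort.json").write_text(json.dumps(sidecar))


def read_cohort(directory: str | Path) -> MultiOmicsCohort:
    """Read a cohort written by :func:`write_cohort`; checks sample alignment."""
    directory = Path(directory)
    frames = {}
    for key, fname in _FILES.items():
        path = directory / fname
        if key in OMIC_NAMES and not path.exists():
            continue  # external cohorts may omit a block in principle
        if not path.exists():
            raise FileNotFoundError(f"missing cohort component: {fname}")
        frames[key] = pd.read_csv(path, sep="\t", index_col=0)
    if not any(k in frames for k in OMIC_NAMES):
        raise FileNotFoundError("no omic block files found")
    ids = frames["covariates"].index
    for key, frame in frames.items():
        if not frame.index.equals(ids):
            raise ValueError(f"sample ids in {_FILES[key]} misaligned with covariates")
    sidecar_path = directory / "cohort.json"
    config = ground_truth = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if "config" in sidecar:
            c = dict(sidecar["config"])
            for k in ("block_sizes", "signal_density", "block_noise_sd"):
                c[k] = tuple(c[k])
            for k in ("target_loadings", "covariate_effects", "target_noise_sd"):
                c[k] = np.asarray(c[k])
            config = SimConfig(**c)
        if "ground_truth" in sidecar:
            ground_truth = {
                name: {"signal_mask": np.asarray(gt["signal_mask"], dtype=bool),
                       "loadings": np.asarray(gt["loadings"], dtype=float)}
                for name, gt in sidecar["ground_truth"].items()
            }
    blocks = {k: frames[k] for k in OMIC_NAMES if k in frames}
    split = frames["split"].iloc[:, 0]
    split.name = "split"
    return MultiOmicsCohort(blocks, frames["covariates"], frames["targets"],
                            split, ground_truth=ground_truth, config=config)
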