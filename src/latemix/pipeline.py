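"""End-to-end orchestration: simulate/load a cohort, preprocess, train the
autoencoders (semi-supervised + matched unsupervised control), rank variable
importance, run the classifier bank per omic, fuse with VCDNs, and evaluate.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name, so a run is reproducible end to end. The
no-leakage contract is asserted on every run: all preprocessing statistics
must have been fitted on exactly the samples labelled ``train``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autoencoder import (SSAEArchitecture, TrainConfig, train_ssae,
                          train_usae_matched)
from .classifiers import (CLASSIFIER_FAMILIES, assemble_features, fit_bank_cv,
                          predict_bank)
from .fusion import build_codt_matrix, predict_vcdn, train_vcdn
from .importance import connection_weights
from .metrics import f1_scores, prob_regression_r2
from .preprocess import (assign_sd_classes, apply_scaler, filter_transcripts,
                         fit_scaler, residualize_targets,
                         select_features_by_list, verify_provenance)
from .simulate import (OMIC_NAMES, TARGET_NAMES, MultiOmicsCohort, SimConfig,
                       read_cohort, simulate_cohort)

__all__ = ["RunConfig", "stage_seed", "run_full"]

_AE_DEFAULTS = {
    # (p, l, corruption_sd, min_epochs, stop_window, scaling)
    "transcriptomic": {"p": 150, "l": 50, "corruption_sd": 0.01,
                       "min_epochs": 10, "stop_window": 10, "scaling": "minmax"},
    "metabolomic": {"p": 55, "l": 6, "corruption_sd": 0.1,
                    "min_epochs": 6, "stop_window": 6, "scaling": "zscore"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) + global_seed) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a full run; serialises to/from YAML losslessly."""

    sim: SimConfig = field(default_factory=SimConfig)
    cohort_dir: str | None = None
    targets: tuple = TARGET_NAMES
    families: tuple = tuple(CLASSIFIER_FAMILIES)
    alpha: float = 0.9
    dropout_rate: float = 0.5
    ae: dict = field(default_factory=lambda: {k: dict(v)
                                              for k, v in _AE_DEFAULTS.items()})
    max_epochs: int = 60
    vcdn_epochs: int = 300
    cpg_list: tuple | None = None
    run_usae: bool = True
    seed: int = 0
    output_dir: str | None = None

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        sim = self.sim
        return {
            "sim": {
                "n_samples": sim.n_samples, "n_latent": sim.n_latent,
                "block_sizes": list(sim.block_sizes),
                "signal_density": [float(x) for x in
                                   np.atleast_1d(sim.signal_density)],
                "target_loadings": sim.target_loadings.tolist(),
                "covariate_effects": sim.covariate_effects.tolist(),
                "block_noise_sd": list(sim.block_noise_sd),
                "target_noise_sd": sim.target_noise_sd.tolist(),
                "train_fraction": sim.train_fraction,
                "validation_fraction": sim.validation_fraction,
                "seed": sim.seed,
            },
            "cohort_dir": self.cohort_dir,
            "targets": list(self.targets),
            "families": list(self.families),
            "alpha": self.alpha,
            "dropout_rate": self.dropout_rate,
            "ae": {k: dict(v) for k, v in self.ae.items()},
            "max_epochs": self.max_epochs,
            "vcdn_epochs": self.vcdn_epochs,
            "cpg_list": list(self.cpg_list) if self.cpg_list is not None else None,
            "run_usae": self.run_usae,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim"))
        for k in ("block_sizes", "signal_density", "block_noise_sd"):
            sim[k] = tuple(sim[k])
        for k in ("target_loadings", "covariate_effects", "target_noise_sd"):
            sim[k] = np.asarray(sim[k], dtype=float)
        d["sim"] = SimConfig(**sim)
        d["targets"] = tuple(d["targets"])
        d["families"] = tuple(d["families"])
        if d.get("cpg_list") is not None:
            d["cpg_list"] = tuple(d["cpg_list"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.to_dict() == other.to_dict()

    def config_hash(self) -> str:
        return format(zlib.crc32(json.dumps(self.to_dict(),
                                            sort_keys=True).encode()), "08x")


def _encode_omic(config: RunConfig, omic: str, scaled: pd.DataFrame,
                 adjusted_values: pd.DataFrame, fit_mask: np.ndarray,
                 val_mask: np.ndarray) -> dict:
    """Train the SSAE (and matched USAE) for one omic; return both encoders."""
    cfg = config.ae[omic]
    # widths cannot exceed the (possibly filtered) block width
    p = min(cfg["p"], scaled.shape[1])
    l = min(cfg["l"], p)
    arch = SSAEArchitecture(scaled.shape[1], p, l,
                            t=adjusted_values.shape[1], r=config.dropout_rate,
                            alpha=config.alpha)
    tc = TrainConfig(corruption_sd=cfg["corruption_sd"],
                     min_epochs=cfg["min_epochs"],
                     stop_window=cfg["stop_window"],
                     max_epochs=config.max_epochs,
                     seed=stage_seed(config.seed, f"ssae:{omic}"))
    X_fit = scaled.loc[fit_mask].to_numpy()
    Y_fit = adjusted_values.loc[fit_mask].to_numpy()
    val_within = val_mask[fit_mask]
    ssae = train_ssae(arch, X_fit, Y_fit, tc, validation_mask=val_within)
    out = {"ssae": ssae, "arch": arch}
    if config.run_usae:
        # same seed as the SSAE: paired init, batching and corruption noise,
        # so the matched-MSE stopping target is reliably reachable
        tc_u = TrainConfig(corruption_sd=cfg["corruption_sd"],
                           min_epochs=cfg["min_epochs"],
                           stop_window=cfg["stop_window"],
                           max_epochs=config.max_epochs * 3,
                           seed=stage_seed(config.seed, f"ssae:{omic}"))
        out["usae"] = train_usae_matched(arch, X_fit, ssae.val_recon_mse_,
                                         tc_u, validation_mask=val_within)
    return out


def run_full(config: RunConfig) -> dict:
    """Execute the full study pipeline; returns the report bundle.

    Bundle keys: ``eval`` (per target/omic/classifier F1 table), ``fused``
    (test-sample fused probabilities per target x family), ``importance``
    (per-omic connection-weights matrices), ``ssae_vs_usae`` (paired macro-F1
    table and the fraction of cases where semi-supervision is at least as
    good), ``r2_ladder`` (variance explained by fused blood-pressure
    probabilities), ``manifest`` (config hash, stage seeds, stage list).
    """
    manifest = {"config_hash": config.config_hash(), "stages": []}

    def stage(name):
        manifest["stages"].append({"name": name,
                                   "seed": stage_seed(config.seed, name)})

    # --- cohort -----------------------------------------------------------
    stage("cohort")
    cohort = (read_cohort(config.cohort_dir) if config.cohort_dir
              else simulate_cohort(config.sim))
    split = cohort.split
    train_stat = (split == "train").to_numpy()   # statistics-fitting samples
    fit_mask = split.isin(["train", "validation"]).to_numpy()
    val_mask = (split == "validation").to_numpy()
    test_mask = (split == "test").to_numpy()

    # --- preprocessing ----------------------------------------------------
    stage("prep")
    adjusted = residualize_targets(cohort.targets, cohort.covariates, train_stat)
    classes = assign_sd_classes(cohort.targets, train_stat)

    tx_mask = filter_transcripts(cohort.blocks["transcriptomic"], adjusted,
                                 train_stat)
    tx_block = tx_mask.apply(cohort.blocks["transcriptomic"])
    tx_stats = fit_scaler(tx_block, train_stat, "minmax")
    met_block = cohort.blocks["metabolomic"]
    met_stats = fit_scaler(met_block, train_stat, "zscore")
    scaled = {"transcriptomic": apply_scaler(tx_block, tx_stats),
              "metabolomic": apply_scaler(met_block, met_stats)}
    if config.cpg_list is not None:
        epi_mask = select_features_by_list(cohort.blocks["epigenetic"],
                                           config.cpg_list)
        epi_block = epi_mask.apply(cohort.blocks["epigenetic"])
    else:
        epi_block = cohort.blocks["epigenetic"]   # beta values pass unscaled

    # leakage audit: every preprocessing statistic fitted on train only
    ids = cohort.sample_ids
    for artifact in (adjusted, classes, tx_mask, tx_stats, met_stats):
        verify_provenance(artifact, ids, train_stat)

    # --- autoencoders -----------------------------------------------------
    stage("autoencoders")
    encoders = {omic: _encode_omic(config, omic, scaled[omic], adjusted.values,
                                   fit_mask, val_mask)
                for omic in ("transcriptomic", "metabolomic")}
    subspaces = {}
    for omic, entry in encoders.items():
        subspaces[(omic, "ssae")] = entry["ssae"].transform(scaled[omic])
        if config.run_usae:
            subspaces[(omic, "usae")] = entry["usae"].transform(scaled[omic])
    subspaces[("epigenetic", "feature_select")] = epi_block

    # --- variable importance ---------------------------------------------
    stage("importance")
    importance = {
        omic: connection_weights(entry["ssae"],
                                 feature_ids=scaled[omic].columns,
                                 target_names=list(adjusted.values.columns))
        for omic, entry in encoders.items()
    }

    # --- classification, fusion, evaluation -------------------------------
    stage("classify")
    eval_rows, fused = [], {}
    r2_rows = {}
    for target in config.targets:
        labels = classes.labels[target].to_numpy()
        per_omic = {}
        for (omic, enc), sub in subspaces.items():
            feats = assemble_features(sub, cohort.covariates, train_stat)
            bank = fit_bank_cv(feats.loc[fit_mask], labels[fit_mask],
                               families=config.families,
                               seed=stage_seed(config.seed,
                                               f"bank:{target}:{omic}:{enc}"))
            test_probs = predict_bank(bank, feats.loc[test_mask])
            per_omic[(omic, enc)] = (bank, test_probs)
            for family, pm in test_probs.items():
                scores = f1_scores(labels[test_mask], pm.hard())
                eval_rows.append({"target": target, "omics": omic,
                                  "encoder": enc, "classifier": family,
                                  "f1_low": scores[-1], "f1_mid": scores[0],
                                  "f1_high": scores[1],
                                  "macro_f1": scores["macro"]})
        # multi-omics fusion over the SSAE subspaces + selected CpGs
        stage_name = f"vcdn:{target}"
        view_keys = [("transcriptomic", "ssae"), ("metabolomic", "ssae"),
                     ("epigenetic", "feature_select")]
        for family in config.families:
            train_views = [per_omic[k][0][family]["oof"] for k in view_keys]
            test_views = [per_omic[k][1][family] for k in view_keys]
            codt_train = build_codt_matrix(train_views)
            codt_test = build_codt_matrix(test_views)
            vcdn = train_vcdn(codt_train, labels[fit_mask],
                              seed=stage_seed(config.seed,
                                              f"{stage_name}:{family}"),
                              n_epochs=config.vcdn_epochs)
            pm = predict_vcdn(vcdn, codt_test, index=ids[test_mask])
            fused[(target, family)] = pm
            scores = f1_scores(labels[test_mask], pm.hard())
            eval_rows.append({"target": target, "omics": "multi-omics",
                              "encoder": "vcdn", "classifier": family,
                              "f1_low": scores[-1], "f1_mid": scores[0],
                              "f1_high": scores[1],
                              "macro_f1": scores["macro"]})
        if target in ("sbp", "dbp"):
            # variance explained by fused probabilities, best fused family
            fam = max(config.families,
                      key=lambda f: [r for r in eval_rows
                                     if r["target"] == target
                                     and r["omics"] == "multi-omics"
                                     and r["classifier"] == f][0]["macro_f1"])
            probs = fused[(target, fam)].probs
            y_test = cohort.targets[target].to_numpy()[test_mask]
            cov_test = cohort.covariates[["age", "sex", "bmi"]].to_numpy()[test_mask]
            ladder = prob_regression_r2(y_test, {
                "p_high": probs[[1]].to_numpy(),
                "p_high+p_low": probs[[1, -1]].to_numpy(),
                "p_high+p_low+covariates": np.column_stack(
                    [probs[[1, -1]].to_numpy(), cov_test]),
            })
            r2_rows[target] = ladder

    eval_table = pd.DataFrame(eval_rows)

    # --- SSAE vs USAE summary --------------------------------------------
    comparison = None
    if config.run_usae:
        s = eval_table[eval_table.encoder == "ssae"].set_index(
            ["target", "omics", "classifier"])["macro_f1"]
        u = eval_table[eval_table.encoder == "usae"].set_index(
            ["target", "omics", "classifier"])["macro_f1"]
        paired = pd.DataFrame({"ssae": s, "usae": u}).dropna()
        comparison = {
            "paired": paired,
            "fraction_ssae_at_least": float((paired.ssae >= paired.usae).mean()),
            "fraction_ssae_strictly_better": float(
                (paired.ssae > paired.usae).mean()),
        }

    bundle = {"cohort": cohort, "eval": eval_table, "fused": fused,
              "importance": importance, "ssae_vs_usae": comparison,
              "r2_ladder": r2_rows, "encoders": encoders,
              "manifest": manifest}

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        eval_table.to_csv(out / "eval_report.tsv", sep="\t", index=False)
        for omic, imp in importance.items():
            table = pd.concat({"RI": imp.raw, "zRI": imp.zscored,
                               "percentile": imp.percentile}, axis=1)
            table.to_csv(out / f"importance_{omic}.tsv", sep="\t")
        if comparison is not None:
            comparison["paired"].to_csv(out / "ssae_vs_usae.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
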