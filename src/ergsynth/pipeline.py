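"""End-to-end experiment orchestration.

One configuration object drives the whole study: simulate (or load) a
waveform dataset, split it into train and test subsets stratified by sex,
train a conditional GAN per stimulus on the training records, augment the
minority class with low-pass-smoothed synthetic waveforms, extract
time-domain features, and evaluate the original / oversampled / synthesized
training conditions with a grid-searched random forest on the untouched,
unbalanced real test rows.  A root seed fans out into named per-stage child
seeds so every stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ergio
from .classify import ConditionReport, CvSpec, run_conditions
from .features import DEFAULT_A_WINDOW, DEFAULT_B_WINDOW, feature_table
from .gan import AugmentationPolicy, GanConfig, train_cgan
from .postprocess import LowpassSpec
from .simulate import (FLICKER30, LA3, ErgWaveform, FlickerParams, La3Params,
                       SexEffect, SubjectVariability, child_seed,
                       default_sex_effect, make_study_fixture)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "split_dataset",
    "run_experiment",
    "embed_features",
]

logger = logging.getLogger("ergsynth")


@dataclass
class ExperimentConfig:
    """Full pipeline configuration.

    Either ``dataset_path`` (a dataset CSV) or the simulator parameters are
    used as the data source.  ``identity_sex_effect`` switches the simulated
    fixture to a null (no class difference) configuration.
    """

    dataset_path: str | None = None
    la3_params: La3Params = field(default_factory=La3Params)
    flicker_params: FlickerParams = field(default_factory=FlickerParams)
    sex_effect: SexEffect | None = None
    identity_sex_effect: bool = False
    variability: SubjectVariability = field(default_factory=SubjectVariability)
    test_fraction: float = 0.20
    split_unit: str = "subject"
    gan: GanConfig = field(default_factory=GanConfig)
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    lowpass: LowpassSpec = field(default_factory=LowpassSpec)
    a_window: tuple[float, float] = DEFAULT_A_WINDOW
    b_window: tuple[float, float] = DEFAULT_B_WINDOW
    cv: CvSpec = field(default_factory=CvSpec)
    stimuli: tuple[str, ...] = (LA3, FLICKER30)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.split_unit not in ("subject", "record"):
            raise ValueError("split_unit must be 'subject' or 'record'")
        for s in self.stimuli:
            if s not in (LA3, FLICKER30):
                raise ValueError(f"unknown stimulus {s!r}")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sex_effect"] = dataclasses.asdict(self.sex_effect) if self.sex_effect else None
        return d

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("la3_params") is not None and not isinstance(d["la3_params"], La3Params):
            d["la3_params"] = La3Params(**d["la3_params"])
        if d.get("flicker_params") is not None and not isinstance(d["flicker_params"], FlickerParams):
            d["flicker_params"] = FlickerParams(**d["flicker_params"])
        if d.get("sex_effect") is not None and not isinstance(d["sex_effect"], SexEffect):
            d["sex_effect"] = SexEffect(**d["sex_effect"])
        if d.get("variability") is not None and not isinstance(d["variability"], SubjectVariability):
            d["variability"] = SubjectVariability(**d["variability"])
        if d.get("gan") is not None and not isinstance(d["gan"], GanConfig):
            g = dict(d["gan"])
            for k in ("generator_hidden", "discriminator_hidden"):
                if k in g:
                    g[k] = tuple(g[k])
            d["gan"] = GanConfig(**g)
        if d.get("policy") is not None and not isinstance(d["policy"], AugmentationPolicy):
            d["policy"] = AugmentationPolicy(**d["policy"])
        if d.get("lowpass") is not None and not isinstance(d["lowpass"], LowpassSpec):
            d["lowpass"] = LowpassSpec(**d["lowpass"])
        if d.get("cv") is not None and not isinstance(d["cv"], CvSpec):
            c = dict(d["cv"])
            for k in ("inner_split", "n_estimators", "max_depth", "max_features"):
                if k in c:
                    c[k] = tuple(c[k])
            d["cv"] = CvSpec(**c)
        for k in ("a_window", "b_window", "stimuli"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def split_dataset(
    dataset: Sequence[ErgWaveform],
    test_fraction: float = 0.20,
    stratify_by: str = "sex",
    unit: str = "subject",
    seed: int = 0,
) -> tuple[list[ErgWaveform], list[ErgWaveform]]:
    """Stratified disjoint train/test partition.

    With ``unit='subject'`` all records of a subject land on one side (no
    replicate leakage); with ``unit='record'`` each waveform is assigned
    independently.  Within each stratum the held-out count is
    ``round(test_fraction × n_units)``.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if unit not in ("subject", "record"):
        raise ValueError("unit must be 'subject' or 'record'")
    sexes = {w.sex for w in dataset}
    if len(sexes) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    test_units: set = set()
    if unit == "subject":
        strata: dict[str, list[str]] = {}
        for w in dataset:
            strata.setdefault(getattr(w, stratify_by), [])
            if w.subject_id not in strata[w.sex]:
                strata[w.sex].append(w.subject_id)
        for sex in sorted(strata):
            units = strata[sex]
            k = int(round(test_fraction * len(units)))
            if k == 0 or k == len(units):
                raise ValueError(f"test fraction leaves an empty side for class {sex!r}")
            chosen = rng.permutation(len(units))[:k]
            test_units.update(units[i] for i in chosen)
        train = [w for w in dataset if w.subject_id not in test_units]
        test = [w for w in dataset if w.subject_id in test_units]
    else:
        idx_by_sex: dict[str, list[int]] = {}
        for i, w in enumerate(dataset):
            idx_by_sex.setdefault(getattr(w, stratify_by), []).append(i)
        test_idx: set[int] = set()
        for sex in sorted(idx_by_sex):
            ids = idx_by_sex[sex]
            k = int(round(test_fraction * len(ids)))
            if k == 0 or k == len(ids):
                raise ValueError(f"test fraction leaves an empty side for class {sex!r}")
            chosen = rng.permutation(len(ids))[:k]
            test_idx.update(ids[i] for i in chosen)
        train = [w for i, w in enumerate(dataset) if i not in test_idx]
        test = [w for i, w in enumerate(dataset) if i in test_idx]
    return train, test


def embed_features(
    feature_rows: pd.DataFrame,
    perplexity: float = 12.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding of the feature rows (visualization only).

    Returns one (x, y) pair per row; grouping labels stay in the input frame.
    """
    from sklearn.manifold import TSNE

    if len(feature_rows) < 5:
        raise ValueError("need at least 5 rows to embed")
    cols = [c for c in ("ta_s", "la_uv", "tb_s", "lb_uv") if feature_rows[c].notna().all()]
    X = feature_rows[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate constant features cannot be embedded")
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    tsne = TSNE(
        n_components=2, perplexity=min(perplexity, (len(feature_rows) - 1) / 3),
        random_state=seed, init="pca",
    )
    return tsne.fit_transform(Xz)


@dataclass
class ExperimentResult:
    """Per-stimulus condition reports plus run metadata and artifact paths."""

    reports: dict[str, ConditionReport]
    config: ExperimentConfig
    seeds: dict[str, int]
    counts: dict[str, dict[str, int]]
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "reports": {s: json.loads(r.to_json()) for s, r in self.reports.items()},
            "seeds": self.seeds,
            "counts": self.counts,
            "config": json.loads(json.dumps(self.config.to_dict())),
        }, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = ["Augmentation experiment", "=" * 52]
        for stim, rep in self.reports.items():
            lines.append(f"\n{stim}  (test n={rep.n_test}, hash {rep.test_hash[:12]}…)")
            lines.append(f"{'condition':<14}{'BA':>8}{'P':>8}{'R':>8}{'F1':>8}")
            for cond, m in rep.metrics.items():
                lines.append(
                    f"{cond:<14}{m.balanced_accuracy:>8.3f}{m.precision:>8.3f}"
                    f"{m.recall:>8.3f}{m.f1:>8.3f}"
                )
        return "\n".join(lines)


def _load_or_simulate(config: ExperimentConfig) -> list[ErgWaveform]:
    if config.dataset_path:
        logger.info("loading dataset from %s", config.dataset_path)
        return ergio.read_dataset(config.dataset_path)
    if config.identity_sex_effect:
        la3_eff = SexEffect.identity()
        fl_eff = SexEffect.identity()
    else:
        la3_eff = config.sex_effect or default_sex_effect(LA3)
        fl_eff = None  # fixture default: matching flicker effect
    return make_study_fixture(
        la3_params=config.la3_params,
        flicker_params=config.flicker_params,
        sex_effect=la3_eff,
        flicker_sex_effect=fl_eff,
        seed=child_seed(config.seed, "fixture"),
        variability=config.variability,
    )


def run_experiment(config: ExperimentConfig, plot: bool = False) -> ExperimentResult:
    """Execute the full pipeline and (optionally) write artifacts to disk.

    Stages: simulate/load → split → per-stimulus GAN training →
    augmentation + smoothing → feature extraction → three-condition
    evaluation.  Every stage draws from a named child seed of
    ``config.seed``.
    """
    seeds = {name: child_seed(config.seed, name)
             for name in ("fixture", "split", "gan", "sample", "oversample", "classifier",
                          "embedding")}
    dataset = _load_or_simulate(config)
    initial_sizes = {s: sum(w.stimulus == s for w in dataset) for s in config.stimuli}
    train, test = split_dataset(
        dataset, config.test_fraction, unit=config.split_unit, seed=seeds["split"],
    )
    logger.info("split: %d train / %d test records", len(train), len(test))

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    reports: dict[str, ConditionReport] = {}
    artifacts: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for stim in config.stimuli:
        tr = [w for w in train if w.stimulus == stim]
        te = [w for w in test if w.stimulus == stim]
        if not tr or not te:
            raise ValueError(f"stimulus {stim}: empty train or test side")
        counts[stim] = {
            "train": len(tr), "test": len(te),
            "train_male": sum(w.sex == "male" for w in tr),
            "train_female": sum(w.sex == "female" for w in tr),
        }
        gan_cfg = dataclasses.replace(config.gan, seed=child_seed(seeds["gan"], stim))
        logger.info("%s: training CGAN on %d waveforms (%d epochs)",
                    stim, len(tr), gan_cfg.epochs)
        results = train_cgan(tr, gan_cfg)
        cv = dataclasses.replace(config.cv, seed=seeds["classifier"])
        report = run_conditions(
            tr, te, results, policy=config.policy, cv=cv, lowpass=config.lowpass,
            seed=child_seed(seeds["sample"], stim), initial_size=initial_sizes[stim],
        )
        reports[stim] = report
        logger.info("%s: BA original=%.3f oversampled=%.3f synthesized=%.3f", stim,
                    report.metrics["original"].balanced_accuracy,
                    report.metrics["oversampled"].balanced_accuracy,
                    report.metrics["synthesized"].balanced_accuracy)
        if out_dir:
            ckpt = out_dir / f"generator_{stim.lower()}.npz"
            results.save(ckpt.with_suffix(""))
            artifacts[f"checkpoint_{stim}"] = str(ckpt)
            rep_csv = out_dir / f"report_{stim.lower()}.csv"
            report.to_frame().to_csv(rep_csv, index=False)
            artifacts[f"report_{stim}"] = str(rep_csv)
            ft = feature_table(tr)
            ft_csv = out_dir / f"features_train_{stim.lower()}.csv"
            ft.table.to_csv(ft_csv, index=False)
            artifacts[f"features_{stim}"] = str(ft_csv)
            if plot:
                artifacts[f"tsne_{stim}"] = _tsne_plot(
                    ft.table, results, out_dir / f"tsne_{stim.lower()}.png",
                    seeds["embedding"],
                )

    result = ExperimentResult(reports=reports, config=config, seeds=seeds,
                              counts=counts, artifacts=artifacts)
    if out_dir:
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            fh.write(result.to_json())
        artifacts["report_json"] = str(out_dir / "report.json")
    return result


def _tsne_plot(train_table: pd.DataFrame, results, path: Path, seed: int) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .features import feature_table as ftab

    synth = results.sample("male", n=max(10, len(train_table) // 5), seed=seed)
    synth_table = ftab(synth).table
    all_rows = pd.concat([train_table, synth_table], ignore_index=True)
    coords = embed_features(all_rows, seed=seed)
    groups = all_rows.apply(
        lambda r: f"{r['provenance']}-{r['sex']}", axis=1)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted(groups.unique()):
        mask = (groups == g).to_numpy()
        ax.scatter(coords[mask, 0], coords[mask, 1], s=12, label=g, alpha=0.7)
    ax.legend(fontsize=7)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
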