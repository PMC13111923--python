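"""End-to-end pipeline: synthesize -> preprocess -> train -> explain ->
cluster -> views -> ICA -> (optional) consistency -> report.

Each stage persists its outputs in the working directory together with the
configuration hash, so any artifact traces to exactly one configuration and
a rerun with the same config reproduces the tabular outputs bit-identically
(all stochastic stages are seeded from the config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .clustering import cluster_concepts
from .consistency import consistency_report
from .crp import Composite, Condition, crp
from .ica import GroundTruthLabeler, fit_ica, label_components, project_relevance
from .nn.model import LAST_CONV_LAYER, forward_activations
from .nn.train import train_loo
from .preprocessing import preprocess_epochs
from .relmax import concepts_for_model
from .synthetic import (generate_cohort, ground_truth,
                        lateralized_cohort_config, two_concept_cohort_config)
from .vil import BandScheme
from .views import (DEFAULT_REGIONS, cluster_mean_freq_relevance,
                    cluster_samples, functional_grouping, psd_relevance_curves)

__all__ = ["PipelineConfig", "Pipeline", "PipelineStageError", "run_pipeline",
           "export_report"]

logger = logging.getLogger(__name__)

_PRESETS = {"lateralized": lateralized_cohort_config,
            "two_concept": two_concept_cohort_config}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort_preset: str = "lateralized"
    cohort_overrides: dict = field(default_factory=dict)
    train_epochs: int = 200
    batch_size: int = 128
    lr: float = 1e-3
    seed_mode: str = "unique"
    layer: str = LAST_CONV_LAYER
    classes: tuple[int, ...] = (0, 1)
    mass_fraction: float = 0.2
    cap: int = 10
    cluster_eps: float = 0.4
    cluster_min_samples: int = 15
    bands: str | tuple = "default"
    regions: str = "default"
    consistency_enabled: bool = False
    consistency_reps: int = 3
    consistency_epochs: int = 60

    def validate(self) -> None:
        if self.cohort_preset not in _PRESETS:
            raise ValueError(f"unknown cohort preset {self.cohort_preset!r}")
        if self.seed_mode not in ("unique", "same"):
            raise ValueError("seed_mode must be 'unique' or 'same'")
        if not 0 < self.mass_fraction <= 1:
            raise ValueError("mass_fraction must lie in (0, 1]")
        self.band_scheme()  # raises on unknown band spec

    def band_scheme(self) -> BandScheme:
        if self.bands == "default":
            return BandScheme()
        if isinstance(self.bands, (list, tuple)):
            return BandScheme(tuple((str(n), float(lo), float(hi))
                                    for n, lo, hi in self.bands))
        raise ValueError(f"unknown band scheme {self.bands!r}")

    def region_map(self):
        if self.regions == "default":
            return DEFAULT_REGIONS
        raise ValueError(f"unknown region map {self.regions!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "classes" in raw:
            raw["classes"] = tuple(raw["classes"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = list(d["classes"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class Pipeline:
    """Stage-wise pipeline over a working directory."""

    def __init__(self, config: PipelineConfig, outdir):
        config.validate()
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        with open(self.outdir / "config.yaml", "w") as f:
            yaml.safe_dump(self.cfg.to_dict(), f)
        (self.outdir / "config.hash").write_text(self.cfg.config_hash + "\n")
        self._runs = None
        self._concepts = None

    # -- helpers ----------------------------------------------------------
    def _cohort_config(self):
        return _PRESETS[self.cfg.cohort_preset](
            seed=self.cfg.seed, **self.cfg.cohort_overrides)

    def _stage(self, name):
        logger.info("pipeline stage: %s (config %s)", name,
                    self.cfg.config_hash)

    # -- stages -----------------------------------------------------------
    def synth(self):
        self._stage("synth")
        try:
            epochs = generate_cohort(self._cohort_config())
            eio.save_epochs(self.outdir / "cohort.h5", epochs)
            return epochs
        except Exception as exc:
            raise PipelineStageError("synth", exc) from exc

    def preprocess(self):
        self._stage("preprocess")
        try:
            epochs = eio.load_epochs(self.outdir / "cohort.h5")
            pre = preprocess_epochs(epochs, batch_size=self.cfg.batch_size)
            eio.save_epochs(self.outdir / "epochs_pre.h5", pre)
            return pre
        except Exception as exc:
            raise PipelineStageError("preprocess", exc) from exc

    def train(self):
        self._stage("train")
        try:
            pre = eio.load_epochs(self.outdir / "epochs_pre.h5")
            runs = train_loo(pre, seed_mode=self.cfg.seed_mode, n_reps=1,
                             epochs=self.cfg.train_epochs,
                             batch_size=self.cfg.batch_size, lr=self.cfg.lr,
                             base_seed=self.cfg.seed)
            mdir = self.outdir / "models"
            mdir.mkdir(exist_ok=True)
            rows = []
            for run in runs:
                eio.save_model(mdir / f"rep{run.rep:02d}_subj{run.subject:02d}.h5",
                               run.model)
                rows.append({"rep": run.rep, "subject": run.subject,
                             "seed": run.seed, "accuracy": run.accuracy})
            pd.DataFrame(rows).to_csv(self.outdir / "runs.csv", index=False)
            self._runs = runs
            return runs
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("train", exc) from exc

    def explain(self):
        """Concepts per fold model, computed on the held-out subject."""
        self._stage("explain")
        try:
            pre = eio.load_epochs(self.outdir / "epochs_pre.h5")
            runs = self._runs
            if runs is None:
                raise RuntimeError("run the train stage first")
            from .crp import canonicalize

            concepts = []
            for run in runs:
                test = pre.select(pre.subjects == run.subject)
                canon = canonicalize(run.model)
                concepts.extend(concepts_for_model(
                    canon, test, layer_id=self.cfg.layer,
                    classes=self.cfg.classes,
                    mass_fraction=self.cfg.mass_fraction, cap=self.cfg.cap,
                    model_id=f"subj{run.subject:02d}"))
            rows = [{"model": c.model_id, "filter": c.filter_id,
                     "class": c.class_y, "k": c.k,
                     "sample_ids": " ".join(map(str, c.sample_ids)),
                     "relevance_mass": float(c.sample_relevance.sum())}
                    for c in concepts]
            pd.DataFrame(rows).to_csv(self.outdir / "concepts.csv", index=False)
            self._concepts = concepts
            return concepts
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("explain", exc) from exc

    def cluster(self):
        self._stage("cluster")
        try:
            concepts = self._concepts
            if concepts is None:
                raise RuntimeError("run the explain stage first")
            tables = {}
            frames = []
            for class_y in self.cfg.classes:
                ct = cluster_concepts(concepts, class_y, seed=self.cfg.seed,
                                      eps=self.cfg.cluster_eps,
                                      min_samples=self.cfg.cluster_min_samples)
                tables[class_y] = ct
                frames.append(ct.table)
                ct.composition.to_csv(
                    self.outdir / f"composition_class{class_y}.csv")
            pd.concat(frames).to_csv(self.outdir / "clusters.csv", index=False)
            self._clusters = tables
            return tables
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("cluster", exc) from exc

    def _cluster_members(self, class_y, label):
        ct = self._clusters[class_y]
        sel = ct.table[ct.table["label"] == label]
        keys = set(zip(sel["model"], sel["filter"]))
        return [c for c in self._concepts if c.class_y == class_y
                and (c.model_id, c.filter_id) in keys]

    def views(self):
        self._stage("views")
        try:
            pre = eio.load_epochs(self.outdir / "epochs_pre.h5")
            vdir = self.outdir / "views"
            vdir.mkdir(exist_ok=True)
            bands = self.cfg.band_scheme()
            regions = self.cfg.region_map()
            for class_y in self.cfg.classes:
                ct = self._clusters[class_y]
                for label in sorted(set(ct.table["label"])):
                    if label < 0:
                        continue
                    members = self._cluster_members(class_y, label)
                    tag = f"class{class_y}_cluster{label}"
                    psd_relevance_curves(members, pre).to_csv(
                        vdir / f"psd_{tag}.csv", index=False)
                    fr = cluster_mean_freq_relevance(members)
                    functional_grouping(fr, pre.channels, regions,
                                        bands).to_csv(
                        vdir / f"grouping_{tag}.csv")
            return vdir
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("views", exc) from exc

    def ica(self):
        self._stage("ica")
        try:
            pre = eio.load_epochs(self.outdir / "epochs_pre.h5")
            truth = ground_truth(self._cohort_config())
            labeler = GroundTruthLabeler(truth)
            idir = self.outdir / "ica"
            idir.mkdir(exist_ok=True)
            runs_by_subject = {f"subj{r.subject:02d}": r for r in self._runs}
            for class_y in self.cfg.classes:
                ct = self._clusters[class_y]
                for label in sorted(set(ct.table["label"])):
                    if label < 0:
                        continue
                    members = self._cluster_members(class_y, label)
                    X = cluster_samples(members, pre)
                    ica = fit_ica(X, seed=self.cfg.seed)
                    # cluster relevance: concatenated member heatmaps
                    from .crp import canonicalize

                    heatmaps = []
                    for c in members:
                        run = runs_by_subject[c.model_id]
                        canon = canonicalize(run.model)
                        cond = Condition(layer_id=c.layer_id,
                                         filters=(c.filter_id,),
                                         class_y=class_y)
                        rt = crp(canon, pre.data[c.sample_ids], cond)
                        heatmaps.append(rt.values)
                    R = np.concatenate(heatmaps, axis=0)
                    rel = project_relevance(ica, R)
                    labels = label_components(ica, labeler)
                    pd.DataFrame({
                        "component": np.arange(ica.n_components),
                        "label": [l for l, _ in labels],
                        "confidence": [c for _, c in labels],
                        "relevance": rel,
                    }).sort_values("relevance", ascending=False).to_csv(
                        idir / f"ica_class{class_y}_cluster{label}.csv",
                        index=False)
            return idir
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("ica", exc) from exc

    def consistency(self):
        self._stage("consistency")
        try:
            pre = eio.load_epochs(self.outdir / "epochs_pre.h5")
            runs_by_condition = {}
            for cond_name in ("unique", "same"):
                reps = []
                for rep in range(self.cfg.consistency_reps):
                    runs = train_loo(pre, seed_mode=cond_name, n_reps=1,
                                     epochs=self.cfg.consistency_epochs,
                                     batch_size=self.cfg.batch_size,
                                     base_seed=self.cfg.seed + rep)
                    by_class = {}
                    for class_y in self.cfg.classes:
                        maps = []
                        for run in runs:
                            test = pre.select(pre.subjects == run.subject)
                            mask = test.labels == class_y
                            acts = forward_activations(
                                run.model, test.data[mask], self.cfg.layer)
                            maps.append(acts.mean(axis=0))
                        by_class[class_y] = maps
                    reps.append(by_class)
                runs_by_condition[cond_name] = reps
            report = consistency_report(runs_by_condition)
            report.table.to_csv(self.outdir / "consistency.csv", index=False)
            report.summary.to_json(self.outdir / "consistency.json",
                                   orient="records", indent=2)
            return report
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("consistency", exc) from exc

    def report(self) -> Path:
        return export_report(self.outdir)

    def run(self) -> Path:
        self.synth()
        self.preprocess()
        self.train()
        self.explain()
        self.cluster()
        self.views()
        self.ica()
        if self.cfg.consistency_enabled:
            self.consistency()
        self.report()
        return self.outdir


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage; outputs land in ``outdir``."""
    return Pipeline(config, outdir).run()


def export_report(outdir) -> Path:
    """Assemble a human-readable markdown summary from persisted artifacts."""
    outdir = Path(outdir)
    lines = ["# Concept-relevance pipeline report", ""]
    h = outdir / "config.hash"
    if h.exists():
        lines += [f"Configuration hash: `{h.read_text().strip()}`", ""]
    runs = outdir / "runs.csv"
    lines.append("## Leave-one-out accuracy")
    if runs.exists():
        df = pd.read_csv(runs)
        lines.append("")
        lines.append(df.to_string(index=False))
        lines.append("")
        lines.append(f"Mean held-out accuracy: {df['accuracy'].mean():.3f}")
    else:
        lines.append("_absent_")
    lines += ["", "## Concepts"]
    cfile = outdir / "concepts.csv"
    if cfile.exists():
        df = pd.read_csv(cfile)
        lines.append(f"{len(df)} concepts "
                     f"({df['model'].nunique()} models, "
                     f"k in [{df['k'].min()}, {df['k'].max()}]).")
    else:
        lines.append("_absent_")
    lines += ["", "## Cluster composition (filters per model and cluster)"]
    comps = sorted(outdir.glob("composition_class*.csv"))
    if comps:
        for p in comps:
            df = pd.read_csv(p, index_col=0)
            n_models = len(df)
            coverage = (df > 0).sum(axis=0) / max(n_models, 1)
            lines += [f"### {p.stem}", "", df.to_string(), "",
                      "Model coverage per cluster: "
                      + ", ".join(f"{c}: {v:.2f}"
                                  for c, v in coverage.items()), ""]
    else:
        lines.append("_absent_")
    lines += ["", "## ICA component relevance"]
    icas = sorted(outdir.glob("ica/ica_*.csv"))
    if icas:
        for p in icas:
            df = pd.read_csv(p).head(5)
            lines += [f"### {p.stem}", "", df.to_string(index=False), ""]
    else:
        lines.append("_absent_")
    lines += ["", "## Consistency"]
    cons = outdir / "consistency.json"
    if cons.exists():
        lines.append(cons.read_text())
    else:
        lines.append("_absent_")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
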