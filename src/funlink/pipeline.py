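"""End-to-end workflow wiring: simulate -> features -> select -> train ->
predict -> assemble -> estimate-size -> gsla -> evaluate.

Stages communicate through files under one output directory, are
individually resumable (a stage is skipped when all its outputs are newer
than all its inputs), and a final ``summary.json`` aggregates the counts
of the whole run.  Configuration is a plain YAML mapping; unknown keys
are rejected before any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import __version__
from .classifier import (
    LabeledPairSet,
    TrainingConfig,
    filter_gold_positives,
    read_gold_table,
    sample_negatives,
    train,
)
from .errors import ConfigError
from .evidence import (
    FeatureMatrix,
    compute_features,
    default_registry,
    feature_aucs,
    select_features,
)
from .gba import AnnotationCorpus, pr_eval, read_annotation_table
from .gsla import GeneSet, GslaConfig, gsla_run, read_gmt
from .interactome import (
    EXPERIMENTAL,
    Interactome,
    read_edge_list_with_isolated,
    write_edge_list,
)
from .simulate import FixtureConfig, generate, load_bundle, write_bundle
from .sizeest import (
    SizeEstimateInputs,
    all_pairs_count,
    assemble_interactome,
    estimate_interactome_size,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "features", "select", "train", "predict",
    "assemble", "estimate-size", "gsla", "evaluate",
)

_TOP_KEYS = {"out_dir", "seed", "log_level", "stages", "fixture", "training", "gsla"}


def _build(cls, data: dict, what: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {what} config keys: {sorted(unknown)}")
    if cls is FixtureConfig and "module_size_range" in data:
        data = dict(data, module_size_range=tuple(data["module_size_range"]))
    if cls is TrainingConfig:
        data = dict(data)
        for k in ("sigma_grid", "c_grid"):
            if k in data:
                data[k] = tuple(data[k])
    return cls(**data)


# the pipeline's coarse default grid keeps a full run interactive;
# TrainingConfig itself defaults to the wide 9x9 search grid
_PIPELINE_GRID = {"sigma_grid": (0.25, 1.0, 4.0), "c_grid": (1.0, 8.0, 64.0)}


@dataclasses.dataclass
class RunConfig:
    """Validated full-run configuration."""

    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = STAGES
    fixture: FixtureConfig = None  # type: ignore[assignment]
    training: TrainingConfig = None  # type: ignore[assignment]
    gsla: GslaConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad} (choose from {STAGES})")
        if self.fixture is None:
            self.fixture = FixtureConfig(seed=self.seed)
        if self.training is None:
            self.training = _build(TrainingConfig, dict(_PIPELINE_GRID, seed=self.seed),
                                   "training")
        if self.gsla is None:
            self.gsla = GslaConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must be a YAML mapping")
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        seed = int(data.get("seed", 0))
        fixture = _build(FixtureConfig, dict(data.get("fixture", {}) or {}, seed=seed),
                         "fixture")
        training_raw = dict(_PIPELINE_GRID)
        training_raw.update(data.get("training", {}) or {})
        training_raw["seed"] = seed
        gsla_raw = dict(data.get("gsla", {}) or {}, seed=seed)
        return cls(
            out_dir=Path(data.get("out_dir", "funlink_run")),
            seed=seed,
            log_level=str(data.get("log_level", "INFO")),
            stages=tuple(data.get("stages", STAGES)),
            fixture=fixture,
            training=_build(TrainingConfig, training_raw, "training"),
            gsla=_build(GslaConfig, gsla_raw, "gsla"),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "fixture": dataclasses.asdict(self.fixture),
                "training": dataclasses.asdict(self.training),
                "gsla": dataclasses.asdict(self.gsla),
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------

def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    """True when every output exists and none is older than any input."""
    if not all(p.exists() for p in outputs):
        return False
    if not inputs:
        return True
    newest_in = max(p.stat().st_mtime for p in inputs)
    oldest_out = min(p.stat().st_mtime for p in outputs)
    return oldest_out >= newest_in


def _labeled_set_from_table(path: Path) -> LabeledPairSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    feature_names = [c for c in df.columns if c not in ("geneA", "geneB", "label")]
    fm = FeatureMatrix(
        [tuple(sorted((a, b))) for a, b in zip(df.geneA, df.geneB)],
        df[feature_names].to_numpy(dtype=float),
        feature_names,
    )
    return LabeledPairSet(fm, df["label"].to_numpy(dtype=int))


class Pipeline:
    """Executes the configured stages against one output directory."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = cfg.out_dir
        self.bundle_dir = self.out / "bundle"
        self.summary: dict = {}

    # -- individual stages --------------------------------------------

    def stage_simulate(self) -> None:
        outs = [self.bundle_dir / "manifest.json", self.out / "query.txt"]
        if _fresh(outs, []):
            logger.info("simulate: up to date, skipped")
            return
        bundle = generate(self.cfg.fixture)
        write_bundle(bundle, self.bundle_dir)
        first = bundle.sets[sorted(bundle.sets.sets)[0]]
        (self.out / "query.txt").write_text(
            "\n".join(sorted(first.members)) + "\n"
        )
        logger.info("simulate: %d genes, %d truth edges",
                    bundle.truth.n_genes, bundle.truth.n_edges)

    def stage_features(self) -> None:
        ins = [self.bundle_dir / "manifest.json"]
        out = self.out / "labeled_pairs.tsv"
        if _fresh([out], ins):
            logger.info("features: up to date, skipped")
            return
        bundle = load_bundle(self.bundle_dir)
        positives = [gi.pair for gi in filter_gold_positives(bundle.gold)]
        negatives = sample_negatives(
            bundle.truth.genes, positives, self.cfg.training.neg_ratio, self.cfg.seed
        )
        pairs = positives + sorted(negatives)
        labels = np.array([1] * len(positives) + [0] * len(negatives))
        fm = compute_features(pairs, bundle.evidence, default_registry())
        df = fm.to_frame()
        df.insert(2, "label", labels)
        df.to_csv(out, sep="\t", index=False, float_format="%.6g")
        logger.info("features: %d positives, %d negatives, %d features",
                    len(positives), len(negatives), len(fm.feature_names))

    def stage_select(self) -> None:
        ins = [self.out / "labeled_pairs.tsv"]
        out = self.out / "selected_features.json"
        if _fresh([out], ins):
            logger.info("select: up to date, skipped")
            return
        data = _labeled_set_from_table(ins[0])
        aucs = feature_aucs(data.features, data.labels)
        selected = select_features(aucs, threshold=0.6)
        out.write_text(json.dumps({"aucs": aucs, "selected": selected},
                                  indent=2, sort_keys=True) + "\n")
        logger.info("select: %d of %d features pass the 0.6 AUC gate",
                    len(selected), len(aucs))

    def stage_train(self) -> None:
        ins = [self.out / "labeled_pairs.tsv", self.out / "selected_features.json"]
        outs = [self.out / "model.joblib", self.out / "model_meta.json"]
        if _fresh(outs, ins):
            logger.info("train: up to date, skipped")
            return
        data = _labeled_set_from_table(ins[0])
        selected = json.loads(ins[1].read_text())["selected"]
        sub = LabeledPairSet(data.features.subset(selected), data.labels)
        res = train(sub, self.cfg.training)
        joblib.dump(res, outs[0])
        outs[1].write_text(json.dumps({
            "sigma": res.sigma, "C": res.c,
            "selected_features": res.selected_features,
            "cv_sensitivity": res.cv_sensitivity,
            "cv_specificity": res.cv_specificity,
            "cv_harmonic_mean": res.cv_harmonic_mean,
            "apparent_sensitivity": res.apparent_sensitivity,
            "apparent_specificity": res.apparent_specificity,
        }, indent=2, sort_keys=True) + "\n")
        logger.info("train: sigma=%g C=%g cv harmonic mean=%.3f",
                    res.sigma, res.c, res.cv_harmonic_mean)

    def stage_predict(self) -> None:
        ins = [self.out / "model.joblib", self.bundle_dir / "manifest.json"]
        out = self.out / "predicted_edges.tsv"
        if _fresh([out], ins):
            logger.info("predict: up to date, skipped")
            return
        res = joblib.load(ins[0])
        bundle = load_bundle(self.bundle_dir)
        genes = sorted(bundle.truth.genes)
        pairs = [(genes[i], genes[j]) for i in range(len(genes))
                 for j in range(i + 1, len(genes))]
        fm = compute_features(pairs, bundle.evidence, default_registry())
        calls = res.predict(fm.subset(res.selected_features))
        net = Interactome(genes=genes)
        for (a, b), hit, conf in calls:
            if hit:
                net.add_edge(a, b, score=round(conf, 6))
        write_edge_list(net, out)
        logger.info("predict: %d of %d pairs called positive", net.n_edges, len(pairs))

    def stage_assemble(self) -> None:
        ins = [self.out / "predicted_edges.tsv", self.bundle_dir / "gold_standard.tsv"]
        outs = [self.out / "assembled_edges.tsv", self.out / "assemble_report.json"]
        if _fresh(outs, ins):
            logger.info("assemble: up to date, skipped")
            return
        predicted = read_edge_list_with_isolated(ins[0])
        gold = filter_gold_positives(read_gold_table(ins[1]))
        experimental = Interactome()
        for gi in gold:
            experimental.add_edge(*gi.pair, score=1.0, source=EXPERIMENTAL)
        merged, report = assemble_interactome(predicted, experimental)
        write_edge_list(merged, outs[0])
        outs[1].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        logger.info("assemble: %s", report)

    def stage_estimate_size(self) -> None:
        ins = [self.out / "assemble_report.json", self.out / "model_meta.json",
               self.bundle_dir / "manifest.json"]
        out = self.out / "size_estimate.json"
        if _fresh([out], ins):
            logger.info("estimate-size: up to date, skipped")
            return
        report = json.loads(ins[0].read_text())
        meta = json.loads(ins[1].read_text())
        manifest = json.loads(ins[2].read_text())
        n_genes = manifest["config"]["n_genes"]
        sens = min(meta["cv_sensitivity"], meta["apparent_sensitivity"])
        spec = min(meta["cv_specificity"], meta["apparent_specificity"])
        payload = {
            "n_predict": report["n_predicted"],
            "n_all_pairs": all_pairs_count(n_genes),
            "sensitivity": sens,
            "specificity": spec,
        }
        try:
            est = estimate_interactome_size(SizeEstimateInputs(**payload))
            payload.update(
                n_interactome=est.n_interactome,
                pairs_per_interaction=est.pairs_per_interaction,
                expected_covered=est.expected_covered,
                expected_precision=est.expected_precision,
                feasible=est.feasible,
            )
        except Exception as exc:  # ill-posed inputs are a reportable outcome
            payload.update(feasible=False, error=str(exc))
        out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        logger.info("estimate-size: %s", payload)

    def stage_gsla(self) -> None:
        ins = [self.out / "assembled_edges.tsv", self.out / "query.txt",
               self.bundle_dir / "gene_sets.gmt"]
        out = self.out / "gsla_report.tsv"
        if _fresh([out], ins):
            logger.info("gsla: up to date, skipped")
            return
        net = read_edge_list_with_isolated(ins[0])
        query_ids = [l for l in ins[1].read_text().splitlines() if l.strip()]
        query = GeneSet("query", "pipeline query set", frozenset(query_ids))
        refs = read_gmt(ins[2])
        results = gsla_run(net, query, refs, self.cfg.gsla)
        results.to_tsv(out)
        self.summary["gsla_sets_passed"] = len(results.significant())
        logger.info("gsla: %d/%d reference sets pass Q1 and Q2",
                    len(results.significant()), len(results))

    def stage_evaluate(self) -> None:
        ins = [self.out / "assembled_edges.tsv",
               self.bundle_dir / "annotations_old.tsv",
               self.bundle_dir / "annotations_new.tsv"]
        outs = [self.out / "pr_curve.tsv", self.out / "gba_auc.json"]
        if _fresh(outs, ins):
            logger.info("evaluate: up to date, skipped")
            return
        net = read_edge_list_with_isolated(ins[0])
        corpus = AnnotationCorpus(
            old=read_annotation_table(ins[1]),
            new=read_annotation_table(ins[2]),
        )
        cutoffs = [1e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.5]
        curve = pr_eval(net, corpus, cutoffs)
        curve.to_frame().to_csv(outs[0], sep="\t", index=False, float_format="%.6g")
        outs[1].write_text(json.dumps(
            {"pr_auc": curve.auc,
             "note": "precision counts old+new annotations as hits; optimistic "
                     "when shared annotation fed the network"},
            indent=2, sort_keys=True) + "\n")
        logger.info("evaluate: PR-AUC %.3f", curve.auc)

    # -- driver --------------------------------------------------------

    def run(self, stages: tuple[str, ...] | None = None) -> dict:
        cfg = self.cfg
        self.out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
        logger.info("funlink %s, config hash %s, seed %d",
                    __version__, cfg.config_hash(), cfg.seed)
        fns = {
            "simulate": self.stage_simulate,
            "features": self.stage_features,
            "select": self.stage_select,
            "train": self.stage_train,
            "predict": self.stage_predict,
            "assemble": self.stage_assemble,
            "estimate-size": self.stage_estimate_size,
            "gsla": self.stage_gsla,
            "evaluate": self.stage_evaluate,
        }
        for stage in stages or cfg.stages:
            try:
                fns[stage]()
            except Exception:
                logger.error("stage %r failed", stage)
                raise
        return self.write_summary()

    def write_summary(self) -> dict:
        s = {"version": __version__, "seed": self.cfg.seed,
             "config_hash": self.cfg.config_hash()}
        sel = self.out / "selected_features.json"
        if sel.exists():
            payload = json.loads(sel.read_text())
            s["n_features_computed"] = len(payload["aucs"])
            s["n_features_selected"] = len(payload["selected"])
        rep = self.out / "assemble_report.json"
        if rep.exists():
            s["interactome_counts"] = json.loads(rep.read_text())
        pred = self.out / "predicted_edges.tsv"
        if pred.exists():
            s["n_pairs_predicted"] = read_edge_list_with_isolated(pred).n_edges
        if "gsla_sets_passed" in self.summary:
            s["gsla_sets_passed"] = self.summary["gsla_sets_passed"]
        elif (self.out / "gsla_report.tsv").exists():
            with (self.out / "gsla_report.tsv").open() as fh:
                rows = [l for l in fh if not l.startswith("#")][1:]
            s["gsla_sets_passed"] = sum(
                1 for r in rows if r.split("\t")[6] == "True" and r.split("\t")[7] == "True"
            )
        auc = self.out / "gba_auc.json"
        if auc.exists():
            s["pr_auc"] = json.loads(auc.read_text())["pr_auc"]
        (self.out / "summary.json").write_text(
            json.dumps(s, indent=2, sort_keys=True) + "\n"
        )
        return s


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the configured stages; returns the summary dict."""
    return Pipeline(cfg).run(stages)
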