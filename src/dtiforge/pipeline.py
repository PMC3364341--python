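"""One-shot run configuration and the featurize->train->evaluate->screen pipeline.

A :class:`RunConfig` (YAML-loadable) is validated before any computation. The
pipeline writes every artifact under one run directory together with a
resolved copy of the configuration and a JSON-lines run log; rerunning the
same configuration reproduces the metrics report byte-identically.

All randomness derives from one root seed, fanned out per stage as
``sha256(root_seed:stage_label) mod 2^31`` so stages are decoupled but fully
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import DescriptorMatrix, InteractionCatalog, read_positives_tsv
from .evaluation import cross_validate, evaluate_classifier
from .exceptions import ConfigError
from .model import DTIModel, RFConfig, SVMConfig
from .pairs import SplitSpec, build_pair_dataset, make_split, scale_features, split_report
from .screening import ScoreTable, comprehensive_screen, network_topology, top_n_network, write_network

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{root_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Inputs are either a synthetic preset (``preset: ci``) or paths to the
    canonical TSV formats (drug/target descriptor matrices + positives).
    """

    seed: int = 17
    outdir: str = "run"
    preset: str | None = "ci"
    drugs_tsv: str | None = None
    targets_tsv: str | None = None
    positives_tsv: str | None = None
    scenario: str = "I"
    test_fraction: float = 0.2
    method: str = "rf"
    ntree: int = 500
    mtry: int | None = None
    cv_folds: int = 5
    scale_mode: str = "train"
    threshold: float = 0.5
    top_n: int = 50

    def __post_init__(self):
        if self.method not in ("rf", "svm"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.scale_mode not in ("train", "joint"):
            raise ConfigError(f"unknown scale_mode {self.scale_mode!r}")
        SplitSpec(self.scenario, self.test_fraction, self.seed)  # validates
        if self.preset is None:
            missing = [
                name for name in ("drugs_tsv", "targets_tsv", "positives_tsv")
                if getattr(self, name) is None
            ]
            if missing:
                raise ConfigError(f"no preset and missing input paths: {missing}")
            for name in ("drugs_tsv", "targets_tsv", "positives_tsv"):
                p = Path(getattr(self, name))
                if not p.exists():
                    raise ConfigError(f"{name} does not exist: {p}")
        elif self.preset != "ci":
            raise ConfigError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("run config YAML must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        logger.info("%s: %s", stage, fields)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _load_catalog(cfg: RunConfig) -> InteractionCatalog:
    if cfg.preset == "ci":
        from .synthetic import ci_preset

        _, catalog = ci_preset(seed=cfg.seed)
        return catalog
    drugs = DescriptorMatrix.from_tsv(cfg.drugs_tsv)
    targets = DescriptorMatrix.from_tsv(cfg.targets_tsv)
    positives = read_positives_tsv(cfg.positives_tsv)
    return InteractionCatalog(drugs=drugs, targets=targets, positives=positives)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the staged pipeline; returns the metrics report dictionary.

    Stages: load/generate catalog -> assemble balanced pair dataset -> split ->
    scale -> train -> internal CV + external test evaluation -> comprehensive
    screen + top-N network. A stage failure aborts with the stage named.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    stage = "catalog"
    try:
        t0 = time.time()
        catalog = _load_catalog(cfg)
        log.event(stage, n_drugs=catalog.n_drugs, n_targets=catalog.n_targets,
                  positives=len(catalog.positives), secs=round(time.time() - t0, 2))

        stage = "dataset"
        dataset = build_pair_dataset(catalog, seed=derive_seed(cfg.seed, "negatives"))
        dataset.to_frame().to_csv(outdir / "dataset.tsv", sep="\t", index=False)
        log.event(stage, n_pairs=len(dataset))

        stage = "split"
        spec = SplitSpec(cfg.scenario, cfg.test_fraction, derive_seed(cfg.seed, "split"))
        train, test = make_split(dataset, spec)
        report["split"] = split_report(train, test)
        log.event(stage, **report["split"])

        stage = "scale"
        train, (test,), _ = scale_features(train, [test], mode=cfg.scale_mode)

        stage = "train"
        if cfg.method == "rf":
            config = RFConfig(ntree=cfg.ntree, mtry=cfg.mtry,
                              seed=derive_seed(cfg.seed, "rf"))
        else:
            config = SVMConfig(cv_folds=cfg.cv_folds, seed=derive_seed(cfg.seed, "svm"))
        results = DTIModel(train, method=cfg.method, config=config).fit()
        results.save(outdir / "model.joblib")
        log.event(stage, method=cfg.method)

        stage = "evaluate"
        cv = cross_validate(train, k=cfg.cv_folds, method=cfg.method, config=config,
                            seed=derive_seed(cfg.seed, "cv"), threshold=cfg.threshold)
        ext = evaluate_classifier(results, test, threshold=cfg.threshold)
        report["internal_cv_mean"] = cv["mean"].to_dict()
        report["external_test"] = ext.to_dict()
        log.event(stage, test_auc=ext.AUC)

        stage = "screen"
        table = comprehensive_screen(results, catalog.drugs, catalog.targets, catalog)
        table.to_tsv(outdir / "scores.tsv")
        n = min(cfg.top_n, len(table))
        net = top_n_network(table, n)
        write_network(net, edge_tsv=outdir / "network_edges.tsv",
                      graphml=outdir / "network.graphml")
        topo = network_topology(net)
        report["network"] = {
            "top_n": n,
            "centralization": topo["centralization"],
            "heterogeneity": topo["heterogeneity"],
        }
        log.event(stage, top_n=n)
    except Exception as e:
        log.event("error", failed_stage=stage, error=str(e))
        raise type(e)(f"pipeline stage {stage!r} failed: {e}") from e

    report = _clean_json(_round_floats(report))
    report_json = json.dumps(report, sort_keys=True, indent=2)
    (outdir / "metrics.json").write_text(report_json + "\n")
    log.event("done")
    return report


def _clean_json(obj):
    """NaN -> None and numpy scalars -> Python scalars, recursively."""
    if isinstance(obj, dict):
        return {str(k): _clean_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_json(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj
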