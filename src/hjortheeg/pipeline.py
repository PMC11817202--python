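"""Config-driven orchestration: simulate/load → preprocess → features →
experiment grid (band subset × Hjorth-parameter subset × classifiers) →
reports, channel statistics and LIME channel maps.

A single master seed is fanned out deterministically: the simulation
uses the master seed itself, stochastic learners use ``seed + 1``, and
the LIME explainer of instance *i* uses ``seed + 2 + i``. Re-running a
stage with unchanged inputs rewrites identical outputs.
"""

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .bands import Band, CANONICAL_BANDS, band_by_name, sort_band_names
from .errors import ConfigurationError
from .evaluate import ClassifierSpec, EvaluationReport, loso_folds, run_loso
from .explain import (
    Explanation,
    LimeConfig,
    aggregate_channel_importance,
    channel_stats_frame,
    lime_explain,
    wilcoxon_map,
)
from .features import cohort_feature_table, extract_features
from .io import (
    canonical_feature_columns,
    feature_columns_of,
    read_edf,
    read_epochs,
    read_feature_table,
    write_epochs,
    write_feature_table,
)
from .montage import MONTAGE_19
from .mrmr import SelectionConfig, mrmr
from .preprocess import preprocess_recording
from .synthetic import EffectSpec, SimulationConfig, generate_cohort

from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class Experiment:
    name: str
    bands: Tuple[str, ...]
    parameters: Tuple[str, ...] = ("activity", "mobility", "complexity")
    classifiers: Tuple[str, ...] = ("linear_svm", "rf", "lda", "knn")
    selection: SelectionConfig = field(default_factory=SelectionConfig)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("hjortheeg_out")
    simulate: Optional[SimulationConfig] = None
    load_paths: Tuple[str, ...] = ()
    target_fs: float = 250.0
    broadband: Tuple[float, float] = (0.5, 45.0)
    epoch_length: float = 4.0
    bands: Tuple[Band, ...] = CANONICAL_BANDS
    grid: Tuple[Experiment, ...] = ()
    lime: LimeConfig = field(default_factory=LimeConfig)
    stats_unit: str = "subject_mean"

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        band_names = {b.name for b in self.bands}
        for exp in self.grid:
            missing = set(exp.bands) - band_names
            if missing:
                raise ConfigurationError(
                    f"experiment {exp.name!r} references undefined bands {sorted(missing)}"
                )
        if self.simulate is None and not self.load_paths:
            self.simulate = SimulationConfig(seed=self.seed)


def _band_from_entry(entry) -> Band:
    if isinstance(entry, str):
        return band_by_name(entry)
    name, low, high = entry
    return Band(name, float(low), float(high))


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    seed = int(raw.get("seed", 0))
    bands = tuple(_band_from_entry(b) for b in raw.get("bands", [])) or CANONICAL_BANDS
    sim = None
    load_paths: Tuple[str, ...] = ()
    inp = raw.get("input", {})
    if "load" in inp:
        load_paths = tuple(inp["load"])
    else:
        s = dict(inp.get("simulate", {}))
        if "effect" in s:
            s["effect"] = EffectSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in s["effect"].items()
            })
        if "montage" in s:
            s["montage"] = tuple(s["montage"])
        s.setdefault("seed", seed)
        s["bands"] = bands
        sim = SimulationConfig(**s)
    pre = raw.get("preprocessing", {})
    grid = []
    for g in raw.get("grid", []):
        sel = SelectionConfig(**g.get("selection", {}))
        grid.append(
            Experiment(
                name=g["name"],
                bands=tuple(g["bands"]),
                parameters=tuple(g.get("parameters", ("activity", "mobility", "complexity"))),
                classifiers=tuple(g.get("classifiers", ("linear_svm", "rf", "lda", "knn"))),
                selection=sel,
            )
        )
    lime_raw = dict(raw.get("lime", {}))
    lime_raw.setdefault("seed", seed + 2)
    return RunConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "hjortheeg_out")),
        simulate=sim,
        load_paths=load_paths,
        target_fs=float(pre.get("target_fs", 250.0)),
        broadband=tuple(pre.get("broadband", (0.5, 45.0))),
        epoch_length=float(pre.get("epoch_length", 4.0)),
        bands=bands,
        grid=tuple(grid),
        lime=LimeConfig(**lime_raw),
        stats_unit=raw.get("stats", {}).get("unit", "subject_mean"),
    )


def _log(stage: str, output_dir: Path, t0: float, **info) -> None:
    entry = {"stage": stage, "wall_s": round(time.time() - t0, 3), **info}
    output_dir.mkdir(parents=True, exist_ok=True)
    with open(output_dir / "run.log", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> List[Path]:
    """Simulate or load recordings, preprocess, and cache per-band epochs."""
    t0 = time.time()
    if cfg.load_paths:
        cohort = [read_edf(p) for p in cfg.load_paths]
    else:
        cohort = generate_cohort(cfg.simulate)
    epoch_dir = cfg.output_dir / "epochs"
    epoch_dir.mkdir(parents=True, exist_ok=True)
    paths, manifest = [], []
    for rec in cohort:
        per_band = preprocess_recording(
            rec,
            cfg.bands,
            target_fs=cfg.target_fs,
            broadband=cfg.broadband,
            epoch_length=cfg.epoch_length,
        )
        for band_name, es in per_band.items():
            p = epoch_dir / f"{rec.subject_id}_{band_name}.epk"
            write_epochs(es, p)
            paths.append(p)
            manifest.append(
                {
                    "path": p.name,
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "band": band_name,
                    "n_epochs": es.n_epochs,
                }
            )
    with open(cfg.output_dir / "manifest.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config_digest": _digest(cfg), "epochs": manifest}, fh, indent=1)
    _log("simulate", cfg.output_dir, t0, n_subjects=len(cohort), config_digest=_digest(cfg))
    return paths


def stage_features(cfg: RunConfig) -> pd.DataFrame:
    """Assemble the cohort feature table from cached epoch containers."""
    t0 = time.time()
    manifest_path = cfg.output_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigurationError(
            f"missing {manifest_path}; run the simulate stage first"
        )
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    by_subject: Dict[str, Dict[str, Path]] = {}
    for e in manifest["epochs"]:
        by_subject.setdefault(e["subject_id"], {})[e["band"]] = (
            cfg.output_dir / "epochs" / e["path"]
        )
    tables = []
    for sid in by_subject:
        per_band = {band: read_epochs(p) for band, p in by_subject[sid].items()}
        tables.append(extract_features(per_band))
    table = cohort_feature_table(tables)
    write_feature_table(table, cfg.output_dir / "features.csv")
    _log("features", cfg.output_dir, t0, n_rows=len(table),
         n_features=len(feature_columns_of(table)))
    return table


def _experiment_columns(exp: Experiment, table: pd.DataFrame) -> List[str]:
    wanted = set(
        canonical_feature_columns(exp.bands, exp.parameters)
    ) & set(feature_columns_of(table))
    return [c for c in canonical_feature_columns(exp.bands, exp.parameters) if c in wanted]


def _subset_table(table: pd.DataFrame, exp: Experiment) -> pd.DataFrame:
    cols = _experiment_columns(exp, table)
    if not cols:
        raise ConfigurationError(f"experiment {exp.name!r} selects no feature columns")
    return table[["subject_id", "group", "epoch"] + cols]


def stage_evaluate(cfg: RunConfig, table: Optional[pd.DataFrame] = None) -> Dict:
    """Run every (experiment, classifier) cell of the grid."""
    t0 = time.time()
    if table is None:
        fpath = cfg.output_dir / "features.csv"
        if not fpath.exists():
            raise ConfigurationError(f"missing {fpath}; run the features stage first")
        table = read_feature_table(fpath)
    reports: Dict[str, Dict[str, EvaluationReport]] = {}
    report_dir = cfg.output_dir / "reports"
    report_dir.mkdir(parents=True, exist_ok=True)
    for exp in cfg.grid:
        sub = _subset_table(table, exp)
        sel = exp.selection
        if sel.k > len(feature_columns_of(sub)):
            sel = SelectionConfig(
                k=len(feature_columns_of(sub)), scheme=sel.scheme,
                n_bins=sel.n_bins, class_prior=sel.class_prior,
            )
        reports[exp.name] = {}
        for clf_name in exp.classifiers:
            spec = ClassifierSpec(name=clf_name, seed=cfg.seed + 1)
            rep = run_loso(sub, spec, sel, mode="per_fold")
            reports[exp.name][clf_name] = rep
            with open(report_dir / f"{exp.name}_{clf_name}.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=1)
    _log("evaluate", cfg.output_dir, t0, n_experiments=len(cfg.grid))
    return reports


def lime_over_loso(
    table: pd.DataFrame,
    clf: ClassifierSpec,
    sel: Optional[SelectionConfig],
    lime_cfg: LimeConfig,
    max_instances_per_fold: Optional[int] = None,
) -> List[Explanation]:
    """Refit each LOSO fold and explain its held-out epochs with LIME."""
    features = feature_columns_of(table)
    y = (table["group"].to_numpy() == "patient")
    explanations = []
    for train, test in loso_folds(table["subject_id"]):
        if sel is not None:
            selection = mrmr(table.iloc[train], table["group"].iloc[train], sel).ordered
        else:
            selection = features
        X = table[selection].to_numpy(dtype=np.float64)
        scaler = StandardScaler().fit(X[train])
        est = clf.build()
        est.fit(scaler.transform(X[train]), y[train])

        def predict_fn(Z, est=est, scaler=scaler):
            Zs = scaler.transform(Z)
            if hasattr(est, "decision_function"):
                return est.decision_function(Zs)
            pos = list(est.classes_).index(True)
            return est.predict_proba(Zs)[:, pos]

        mean, sd = X[train].mean(axis=0), X[train].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        rows = test if max_instances_per_fold is None else test[:max_instances_per_fold]
        for row in rows:
            icfg = LimeConfig(
                n_samples=lime_cfg.n_samples,
                kernel_width=lime_cfg.kernel_width,
                top_k=lime_cfg.top_k,
                ridge_alpha=lime_cfg.ridge_alpha,
                seed=lime_cfg.seed + int(row),
            )
            explanations.append(
                lime_explain(
                    predict_fn, X[row], mean, sd, selection, icfg,
                    instance_id=f"{table['subject_id'].iloc[row]}:{table['epoch'].iloc[row]}",
                )
            )
    return explanations


def stage_explain(
    cfg: RunConfig, table: Optional[pd.DataFrame] = None,
    classifier: str = "linear_svm",
    max_instances_per_fold: Optional[int] = None,
) -> Dict:
    """LIME channel maps and Wilcoxon channel statistics per experiment."""
    t0 = time.time()
    if table is None:
        fpath = cfg.output_dir / "features.csv"
        if not fpath.exists():
            raise ConfigurationError(f"missing {fpath}; run the features stage first")
        table = read_feature_table(fpath)
    out = {}
    xdir = cfg.output_dir / "explain"
    xdir.mkdir(parents=True, exist_ok=True)
    for exp in cfg.grid:
        sub = _subset_table(table, exp)
        sel = exp.selection
        n_feats = len(feature_columns_of(sub))
        if sel.k > n_feats:
            sel = SelectionConfig(k=n_feats, scheme=sel.scheme,
                                  n_bins=sel.n_bins, class_prior=sel.class_prior)
        clf = ClassifierSpec(name=classifier, seed=cfg.seed + 1)
        explanations = lime_over_loso(sub, clf, sel, cfg.lime, max_instances_per_fold)
        maps = {}
        for band in sort_band_names(exp.bands):
            imp = aggregate_channel_importance(explanations, band)
            maps[band] = imp
            pd.DataFrame(
                {
                    "channel": list(imp),
                    "importance": list(imp.values()),
                    "x": [MONTAGE_19.position(c)[0] for c in imp],
                    "y": [MONTAGE_19.position(c)[1] for c in imp],
                }
            ).to_csv(xdir / f"lime_{exp.name}_{band}.csv", index=False)
        stats = {}
        for band in sort_band_names(exp.bands):
            for param in exp.parameters:
                cs = wilcoxon_map(sub, param, band, unit=cfg.stats_unit)
                stats[(band, param)] = cs
                channel_stats_frame(cs).to_csv(
                    xdir / f"stats_{exp.name}_{band}_{param}.csv", index=False
                )
        out[exp.name] = {"lime": maps, "stats": stats, "explanations": explanations}
    _log("explain", cfg.output_dir, t0, n_experiments=len(cfg.grid))
    return out


def stage_report(cfg: RunConfig, reports: Optional[Dict] = None) -> pd.DataFrame:
    """Grid summary shaped like a band-combination results table.

    Rows = experiments; columns = AC/SN/SP/AUC per classifier (percent,
    AUC on [0, 1]). Written as CSV and as an aligned text table.
    """
    t0 = time.time()
    report_dir = cfg.output_dir / "reports"
    rows = []
    for exp in cfg.grid:
        row = {"experiment": exp.name}
        for clf_name in exp.classifiers:
            if reports is not None:
                rep = reports[exp.name][clf_name].to_dict()
            else:
                p = report_dir / f"{exp.name}_{clf_name}.json"
                if not p.exists():
                    raise ConfigurationError(f"missing {p}; run the evaluate stage first")
                with open(p) as fh:
                    rep = json.load(fh)
            row[f"{clf_name}_AC"] = round(rep["accuracy"], 2)
            row[f"{clf_name}_SN"] = round(rep["sensitivity"], 2)
            row[f"{clf_name}_SP"] = round(rep["specificity"], 2)
            row[f"{clf_name}_AUC"] = round(rep["auc"], 4)
        rows.append(row)
    summary = pd.DataFrame(rows)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(cfg.output_dir / "grid_summary.csv", index=False)
    with open(cfg.output_dir / "grid_summary.txt", "w") as fh:
        fh.write(summary.to_string(index=False) + "\n")
    _log("report", cfg.output_dir, t0, n_rows=len(summary))
    return summary


def run(cfg: RunConfig, explain_classifier: str = "linear_svm",
        max_lime_instances_per_fold: Optional[int] = None) -> Dict:
    """Execute the full pipeline; returns the in-memory artifacts."""
    stage_simulate(cfg)
    table = stage_features(cfg)
    reports = stage_evaluate(cfg, table)
    explained = (
        stage_explain(cfg, table, classifier=explain_classifier,
                      max_instances_per_fold=max_lime_instances_per_fold)
        if cfg.grid
        else {}
    )
    summary = stage_report(cfg, reports) if cfg.grid else pd.DataFrame()
    return {
        "table": table,
        "reports": reports,
        "explain": explained,
        "summary": summary,
    }
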