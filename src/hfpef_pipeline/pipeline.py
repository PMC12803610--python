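"""End-to-end run orchestration.

Chains generate -> phenotype -> split -> train/evaluate -> cluster ->
deconfound -> enrich over a run directory, with per-stage parameter blocks
from one structured YAML config, a global seed fanned out per stage by
stage-name hashing, and a JSON manifest recording each stage's inputs,
parameters, seed and wall time.  Deterministic stages reproduce bit-identical
outputs under an identical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconfound as dc
from . import enrichment as en
from . import harness as hn
from . import phenotyping as ph
from . import snf as sn
from . import synthcohort as sc

log = logging.getLogger("hfpef_pipeline")

STAGES = ("generate", "phenotype", "split", "train", "cluster",
          "deconfound", "enrich")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    generate: dict = field(default_factory=dict)      # CohortConfig overrides
    phenotype: dict = field(default_factory=dict)     # PhenotypingParams overrides
    split: dict = field(default_factory=lambda: {"fraction": 0.8})
    train: dict = field(default_factory=dict)         # CvConfig overrides
    cluster: dict = field(default_factory=dict)       # SnfParams overrides
    deconfound: dict = field(default_factory=dict)    # DeconfoundParams overrides
    enrich: dict = field(default_factory=dict)        # SsgseaParams + gmt path
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (stage-name hashing avoids
    cross-stage stream collisions)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the run directory.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained alongside the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    state: dict = {}

    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        t0 = time.time()
        log.info("stage %s starting", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        entry = {
            "stage": stage,
            "seed": stage_seed(config.seed, stage),
            "params": getattr(config, stage, {}),
            "outputs": {p.name: _hash_file(p) for p in outputs},
            "wall_time_s": round(time.time() - t0, 3),
        }
        manifest.append(entry)
        log.info("stage %s done in %.1fs", stage, entry["wall_time_s"])
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: list[dict]) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


# --------------------------------------------------------------------------
# Stage implementations
# --------------------------------------------------------------------------

def _stage_generate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    kw = dict(config.generate)
    kw.setdefault("seed", stage_seed(config.seed, "generate"))
    cc = sc.CohortConfig(**kw)
    records, truth = sc.generate_cohort(cc)
    cohort_dir = out / "cohort"
    files = sc.write_cohort(records, cohort_dir)
    files.append(sc.write_truth(truth, cohort_dir))
    state.update(records=records, truth=truth, cohort_config=cc)
    return files


def _load_cohort(config: RunConfig, out: Path, state: dict):
    if "records" not in state:
        state["records"] = sc.read_cohort(out / "cohort")
    return state["records"]


def _stage_phenotype(config: RunConfig, out: Path, state: dict) -> list[Path]:
    records = _load_cohort(config, out, state)
    params = ph.PhenotypingParams(**config.phenotype)
    labels, counts = ph.label_cohort(records, params)
    frame = ph.labels_frame(labels)
    p1 = out / "labels.tsv"
    frame.to_csv(p1, sep="\t")
    p2 = out / "phenotype_branch_counts.tsv"
    pd.Series(counts, name="count").rename_axis("rule").to_csv(p2, sep="\t")
    state["labels"] = labels
    return [p1, p2]


def _stage_split(config: RunConfig, out: Path, state: dict) -> list[Path]:
    labels = state["labels"]
    key = {l.id: l.group.value for l in labels}
    train, val = ph.stratified_split(key, config.split.get("fraction", 0.8),
                                     seed=stage_seed(config.seed, "split"))
    p = out / "split.tsv"
    frame = pd.DataFrame({"id": train + val,
                          "subset": ["train"] * len(train) + ["val"] * len(val)})
    frame.to_csv(p, sep="\t", index=False)
    state.update(train_ids=train, val_ids=val)
    return [p]


def _feature_table(records, config: sc.CohortConfig | None = None) -> pd.DataFrame:
    blocks = [sc.omics_matrix(records, m) for m in sc.MODALITIES]
    return pd.concat(blocks, axis=1)


def _stage_train(config: RunConfig, out: Path, state: dict) -> list[Path]:
    records = _load_cohort(config, out, state)
    labels = state["labels"]
    case = pd.Series({l.id: l.group is ph.Group.HFPEF for l in labels})
    X = _feature_table(records)
    kw = dict(config.train)
    kw.setdefault("seed", stage_seed(config.seed, "train"))
    kw.setdefault("outer_folds", 5)
    kw.setdefault("inner_folds", 3)
    kw.setdefault("grid", (hn.DEFAULT_GRID[0],))   # desk-scale default
    cv = hn.CvConfig(**kw)
    report = hn.nested_cv(X, case.loc[X.index], cv)
    p1 = out / "cv_metrics.tsv"
    report.fold_metrics.to_csv(p1, sep="\t", index=False)
    p2 = out / "oof_scores.tsv"
    report.oof_scores.rename("score").to_csv(p2, sep="\t")
    state["cv_report"] = report
    return [p1, p2]


def _stage_cluster(config: RunConfig, out: Path, state: dict) -> list[Path]:
    records = _load_cohort(config, out, state)
    labels = state["labels"]
    hfpef_ids = {l.id for l in labels if l.group is ph.Group.HFPEF}
    subset = [r for r in records if r.id in hfpef_ids]
    blocks = {m: sc.omics_matrix(subset, m) for m in sc.MODALITIES}
    keep = sn.complete_samples(blocks)
    blocks = {m: b.loc[keep] for m, b in blocks.items()}
    kw = dict(config.cluster)
    k_clusters = kw.pop("k_clusters", "auto")
    n = len(keep)
    params = sn.SnfParams(**kw) if kw else sn.SnfParams()
    if params.K >= n:
        params = sn.SnfParams(K=max(1, n // 3), mu=params.mu, t=params.t)
    affinities = {m: sn.build_affinity(b, params) for m, b in blocks.items()}
    fused = sn.fuse(list(affinities.values()), params)
    assignment = sn.spectral_cluster(fused, k_clusters, params,
                                     seed=stage_seed(config.seed, "cluster"))
    p1 = out / "clusters.tsv"
    pd.Series(assignment.labels, name="cluster").rename_axis("id") \
        .to_csv(p1, sep="\t")
    dom = sn.modality_dominance(affinities, assignment)
    p2 = out / "modality_dominance.tsv"
    dom.to_csv(p2, sep="\t")
    followup = {r.id: (r.followup_years, r.death) for r in subset}
    km = sn.km_by_cluster(assignment, followup)
    rows = [{"cluster": c, "n": v["n"], "deaths": v["deaths"],
             "mortality_fraction": v["mortality_fraction"]} for c, v in km.items()]
    p3 = out / "km_by_cluster.tsv"
    pd.DataFrame(rows).to_csv(p3, sep="\t", index=False)
    state["assignment"] = assignment
    return [p1, p2, p3]


def _stage_deconfound(config: RunConfig, out: Path, state: dict) -> list[Path]:
    records = _load_cohort(config, out, state)
    labels = state["labels"]
    group_of = {l.id: l.group for l in labels}
    case_ids = [r.id for r in records if group_of[r.id] is ph.Group.HFPEF]
    ctrl_ids = [r.id for r in records if group_of[r.id] is ph.Group.NON_HF_CONTROL]
    subset = [r for r in records if r.id in set(case_ids) | set(ctrl_ids)]
    X = _feature_table(subset)
    contrast = pd.Series({r.id: group_of[r.id] is ph.Group.HFPEF for r in subset})
    meds = sorted({m for r in subset for m in r.medications})
    covariates = pd.DataFrame(
        {m: [float(m in r.medications) for r in subset] for m in meds},
        index=[r.id for r in subset])
    params = dc.DeconfoundParams(**config.deconfound)
    recs = dc.deconfound(X, contrast, covariates, params, "hfpef_vs_non_hf")
    p = out / "associations.tsv"
    dc.associations_frame(recs).to_csv(p, sep="\t", index=False)
    state["associations"] = recs
    return [p]


def _stage_enrich(config: RunConfig, out: Path, state: dict) -> list[Path]:
    recs = state.get("associations")
    if recs is None:
        raise ValueError("enrich requires the deconfound stage")
    kw = dict(config.enrich)
    gmt_path = kw.pop("gmt", None)
    if gmt_path is None:
        raise ValueError("enrich stage needs a 'gmt' path in config")
    kw.setdefault("seed", stage_seed(config.seed, "enrich"))
    params = en.SsgseaParams(**kw)
    collection = en.read_gmt(gmt_path)
    effect = pd.Series({r.feature: r.effect for r in recs
                        if r.feature.startswith("pro_")})
    results = en.normalize_and_fdr({"hfpef": effect}, collection, params)
    frame = pd.DataFrame([{"pathway": r.pathway, "group": r.group, "es": r.es,
                           "nes": r.nes, "q": r.q,
                           "leading_edge": ";".join(r.leading_edge)}
                          for r in results])
    p = out / "enrichment.tsv"
    frame.to_csv(p, sep="\t", index=False)
    return [p]


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "phenotype": _stage_phenotype,
    "split": _stage_split,
    "train": _stage_train,
    "cluster": _stage_cluster,
    "deconfound": _stage_deconfound,
    "enrich": _stage_enrich,
}
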