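"""End-to-end orchestration: simulate -> features -> cluster -> risk -> evaluate.

A :class:`RunConfig` fixes every stage's parameters and seed; the
pipeline writes versioned artifacts plus a manifest with content
hashes, so re-running an identical config reproduces identical
artifacts.  Stages can be toggled off, in which case downstream stages
consume the artifacts already present in the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import PAPER_K, assign_clusters, fit_phenotype_model, patient_cluster_matrix
from .features import NeighborhoodSpec, extract_all, feature_catalog
from .risk import PenaltyConfig, compute_osrs, evaluate_survival, fit_risk_model, stratify
from .synthetic import DegenerateConfigError, SimConfig, gen_cell_map, gen_survival

STAGES = ("simulate", "features", "cluster", "risk", "evaluate")


@dataclasses.dataclass
class RunConfig:
    """Normalized configuration of one pipeline run."""

    out_dir: str = "phenotil_run"
    n_patients: int = 50
    tiles_per_patient: int = 3
    tile_size: int = 512
    n_til_hotspots: int = 3
    offspring_mean: float = 20.0
    lambda_nontil: float = 1000.0
    hotspot_dispersion: float = 60.0
    censor_rate: float = 0.3
    dL: int = 20
    radius_multipliers: tuple[int, ...] = (10, 20, 30)
    K: int = PAPER_K
    paper_mode: bool = True
    l1_ratio: float = 0.5
    alphas: tuple[float, ...] = (0.01, 0.1, 1.0)
    stages: tuple[str, ...] = STAGES
    seeds: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radius_multipliers"] = list(self.radius_multipliers)
        d["alphas"] = list(self.alphas)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("radius_multipliers", "alphas", "stages"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def validate_config(config: dict | RunConfig) -> tuple[RunConfig, list[str]]:
    """Normalize a config, defaulting missing seeds; raise on hard errors.

    Returns the normalized config and a list of warnings emitted.
    """
    cfg = RunConfig.from_dict(config) if isinstance(config, dict) else config
    notes: list[str] = []
    errors: list[str] = []
    if cfg.dL <= 0 or any(m <= 0 for m in cfg.radius_multipliers):
        errors.append("neighborhood radii must be positive")
    if any(b <= a for a, b in zip(cfg.radius_multipliers, cfg.radius_multipliers[1:])):
        errors.append("radius multipliers must be strictly increasing")
    if cfg.paper_mode and cfg.K != PAPER_K:
        errors.append(
            f"paper mode fixes K={PAPER_K} niches; got K={cfg.K} "
            "(disable paper_mode to explore other K)"
        )
    if cfg.n_patients < 1 or cfg.tiles_per_patient < 1:
        errors.append("n_patients and tiles_per_patient must be >= 1")
    if errors:
        raise ValueError("; ".join(errors))
    for stage in cfg.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if stage not in cfg.seeds:
            cfg.seeds[stage] = 0
            msg = f"seed for stage {stage!r} missing; defaulted to 0"
            notes.append(msg)
            warnings.warn(msg)
    return cfg, notes


def _content_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def run_pipeline(config: dict | RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg, notes = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = NeighborhoodSpec(dL=cfg.dL, multipliers=cfg.radius_multipliers)
    artifacts: dict[str, str] = {}

    def register(name: str, path: Path) -> None:
        artifacts[name] = _content_hash(path)

    if "simulate" in cfg.stages:
        seed = cfg.seeds["simulate"]
        rng = np.random.default_rng(seed)
        all_cells = []
        true_counts = np.zeros((cfg.n_patients, cfg.K))
        for p in range(cfg.n_patients):
            probs = rng.dirichlet(np.full(cfg.K, 0.5))
            for t in range(cfg.tiles_per_patient):
                sc = SimConfig(
                    tile_size=cfg.tile_size,
                    n_til_hotspots=cfg.n_til_hotspots,
                    offspring_mean=cfg.offspring_mean,
                    lambda_nontil=cfg.lambda_nontil,
                    hotspot_dispersion=cfg.hotspot_dispersion,
                    n_phenotypes=cfg.K,
                    phenotype_probs=probs,
                    censor_rate=cfg.censor_rate,
                )
                # a rare parent-point draw can overpack the tile; the
                # generator then raises by contract and the tile is redrawn
                for attempt in range(10):
                    tile_seed = int(rng.integers(0, 2**31 - 1))
                    try:
                        cm, truth = gen_cell_map(sc, seed=tile_seed)
                        break
                    except DegenerateConfigError:
                        if attempt == 9:
                            raise
                cells = cm.cells.copy()
                cells.insert(0, "patient_id", f"P{p:04d}")
                cells.insert(1, "tile_id", f"P{p:04d}_T{t}")
                cells["true_phenotype"] = truth.true_phenotype
                all_cells.append(cells)
                for ph in truth.true_phenotype[truth.true_phenotype > 0]:
                    true_counts[p, ph - 1] += 1
        cells_df = pd.concat(all_cells, ignore_index=True)
        _write_df(cells_df, out / "cells.csv")
        register("cells.csv", out / "cells.csv")
        sc0 = SimConfig()  # default beta_star carries the planted hazard weights
        surv = gen_survival(true_counts, sc0.beta_star, cfg.censor_rate,
                            seed=cfg.seeds["simulate"])
        _write_df(surv, out / "survival.csv")
        register("survival.csv", out / "survival.csv")

    if "features" in cfg.stages:
        cells_df = pd.read_csv(out / "cells.csv")
        tables = []
        from .cellmap import CellMap

        for tile_id, grp in cells_df.groupby("tile_id", sort=True):
            cm = CellMap(grp.drop(columns=["patient_id", "tile_id", "true_phenotype"],
                                  errors="ignore"),
                         tile_id=str(tile_id),
                         shape=(cfg.tile_size, cfg.tile_size))
            ft = extract_all(cm, spec=spec)
            ft = ft.reset_index()
            ft.insert(0, "tile_id", tile_id)
            ft.insert(0, "patient_id", grp["patient_id"].iloc[0])
            tables.append(ft)
        feats = pd.concat(tables, ignore_index=True)
        feats.to_parquet(out / "features.parquet", index=False)
        # hash the stable CSV rendering (parquet bytes can vary by writer)
        artifacts["features.parquet"] = hashlib.sha256(
            feats.to_csv(index=False).encode()
        ).hexdigest()

    if "cluster" in cfg.stages:
        feats = pd.read_parquet(out / "features.parquet")
        F = feats[feature_catalog(spec)]
        model = fit_phenotype_model(F, K=cfg.K, seed=cfg.seeds["cluster"])
        model.to_json(out / "phenotype_model.json")
        register("phenotype_model.json", out / "phenotype_model.json")
        labels = assign_clusters(model, F)
        lab_df = feats[["patient_id", "tile_id", "til_id"]].copy()
        lab_df["cluster"] = labels
        _write_df(lab_df, out / "labels.csv")
        register("labels.csv", out / "labels.csv")
        mat = patient_cluster_matrix(labels, feats["patient_id"].to_numpy(), K=cfg.K)
        _write_df(mat.sort_index(), out / "cluster_matrix.csv", index=True)
        register("cluster_matrix.csv", out / "cluster_matrix.csv")

    if "risk" in cfg.stages:
        mat = pd.read_csv(out / "cluster_matrix.csv", index_col=0)
        surv = pd.read_csv(out / "survival.csv")
        surv = surv.set_index("patient_id").loc[mat.index].reset_index()
        rm = fit_risk_model(
            mat, surv,
            penalty=PenaltyConfig(l1_ratio=cfg.l1_ratio, alphas=cfg.alphas),
            seed=cfg.seeds["risk"],
        )
        rm.to_json(out / "risk_model.json")
        register("risk_model.json", out / "risk_model.json")

    if "evaluate" in cfg.stages:
        from .risk import RiskModel

        mat = pd.read_csv(out / "cluster_matrix.csv", index_col=0)
        surv = pd.read_csv(out / "survival.csv")
        surv = surv.set_index("patient_id").loc[mat.index].reset_index()
        rm = RiskModel.from_json(out / "risk_model.json")
        scores = rm.scores(mat)
        groups = stratify(scores, rm.cutoff)
        report = evaluate_survival(surv, scores=scores, groups=groups)
        report.to_json(out / "evaluation.json")
        register("evaluation.json", out / "evaluation.json")
        for g, df in report.km.items():
            _write_df(df, out / f"km_{g}.csv")
            register(f"km_{g}.csv", out / f"km_{g}.csv")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "seeds": cfg.seeds,
        "warnings": notes,
        "artifacts": artifacts,
        "library_versions": _library_versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _library_versions() -> dict[str, str]:
    import lifelines
    import scipy
    import skimage
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-image": skimage.__version__,
        "lifelines": lifelines.__version__,
    }
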