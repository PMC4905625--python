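"""Run orchestration: generation -> classification -> clustering -> stats.

A :class:`RunConfig` fixes every tunable (all defaults are the study's
published values); :func:`run_pipeline` executes the stages, writes one
CSV/JSON artifact per stage plus a manifest, and is bitwise-reproducible
for non-image outputs given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DYSMORPHIC_CUTOFF,
    GIANT_CELL_CUTOFF,
    TuberFeatures,
    classify_tuber,
    is_perituberal,
)
from .cluster import (
    DEFAULT_CLUSTER_FEATURES,
    LOG_EPSILON,
    FeatureMatrix,
    anova_feature_discrimination,
    auto_cluster_count,
    log_skew_transform,
    ward_cluster,
)
from .errors import TuberhistError
from .stats import chi_square, kendall_tau, kruskal_wallis, pairwise_posthoc
from .synthdata import (
    CohortSpec,
    cohort_to_dataframe,
    sample_cohort,
    write_cohort_csv,
)


class StageError(TuberhistError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tuberhist-run"
    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {
            "A": 7, "B": 13, "C": 8, "perituberal": 7, "control": 10
        }
    )
    gc_cutoff: float = GIANT_CELL_CUTOFF
    dn_cutoff: float = DYSMORPHIC_CUTOFF
    cluster_features: Sequence[str] = DEFAULT_CLUSTER_FEATURES
    k: int = 3
    log_eps: float = LOG_EPSILON
    bootstrap_B: int = 1000
    bootstrap_level: float = 0.95
    make_plots: bool = False

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "n_per_group": dict(self.n_per_group),
            "gc_cutoff": self.gc_cutoff,
            "dn_cutoff": self.dn_cutoff,
            "cluster_features": list(self.cluster_features),
            "k": self.k,
            "log_eps": self.log_eps,
            "bootstrap_B": self.bootstrap_B,
            "bootstrap_level": self.bootstrap_level,
            "make_plots": self.make_plots,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: raw[k] for k in cls().to_dict() if k in raw}
        return cls(**known)


def classify_frame(
    df: pd.DataFrame,
    gc_cutoff: float = GIANT_CELL_CUTOFF,
    dn_cutoff: float = DYSMORPHIC_CUTOFF,
) -> pd.DataFrame:
    """Append ``tuber_type`` and ``perituberal`` columns to a feature table.

    ``vimentin_density`` maps to the giant-cell density and
    ``smi32_density`` to the dysmorphic-neuron density.
    """
    out = df.copy()
    types, peri = [], []
    for _, row in df.iterrows():
        f = TuberFeatures(
            giant_cell_density=float(row["vimentin_density"]),
            dysmorphic_density=float(row["smi32_density"]),
            calcification_present=bool(row["calcification_present"]),
        )
        types.append(classify_tuber(f, gc_cutoff, dn_cutoff).label)
        peri.append(is_perituberal(f))
    out["tuber_type"] = types
    out["perituberal"] = peri
    return out


def _round_p(res) -> dict:
    d = {
        "method": res.method,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p,
        "p_3dec": None if np.isnan(res.p) else round(res.p, 3),
        "n": res.n,
    }
    if res.extra:
        d["extra"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in res.extra.items()
        }
    return d


def run_pipeline(config: Optional[RunConfig] = None) -> dict:
    """Execute the simulate->classify->cluster->stats pipeline.

    Returns the run report (also written to ``report.json``); every output
    file is listed in ``manifest.json`` together with the config hash.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    report: dict = {"stages": {}}

    # --- simulate ----------------------------------------------------------
    try:
        cohort = sample_cohort(
            CohortSpec(n_per_group=dict(config.n_per_group), seed=config.seed)
        )
        write_cohort_csv(cohort, out / "cohort.csv")
        outputs.append("cohort.csv")
        df = cohort_to_dataframe(cohort)
        report["stages"]["simulate"] = {"n_samples": len(df)}
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise StageError("simulate", e) from e

    if len(df) == 0:
        report["empty"] = True
        _finalize(config, out, outputs, report)
        return report

    # --- classify ----------------------------------------------------------
    try:
        classified = classify_frame(df, config.gc_cutoff, config.dn_cutoff)
        classified.to_csv(out / "classified.csv", index=False)
        outputs.append("classified.csv")
        tubers = classified[classified["true_group"].isin(["A", "B", "C"])]
        acc = (
            float((tubers["tuber_type"] == tubers["true_group"]).mean())
            if len(tubers)
            else None
        )
        report["stages"]["classify"] = {
            "n_tubers": int(len(tubers)),
            "accuracy_vs_truth": acc,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e

    # --- cluster ------------------------------------------------------------
    try:
        feats = list(config.cluster_features)
        tub = classified[classified["true_group"].isin(["A", "B", "C"])]
        stage: dict = {"features": feats}
        if len(tub) >= max(2, config.k):
            fm = FeatureMatrix(tub.reset_index(drop=True)[feats].copy())
            fm = log_skew_transform(fm, feats, eps=config.log_eps)
            labels, tree = ward_cluster(fm, k=config.k, columns=feats)
            pd.DataFrame(
                {"sample_id": tub["sample_id"].to_numpy(), "cluster": labels}
            ).to_csv(out / "clusters.csv", index=False)
            outputs.append("clusters.csv")
            pd.DataFrame(
                tree.merges, columns=["left", "right", "height", "size"]
            ).to_csv(out / "linkage.csv", index=False)
            outputs.append("linkage.csv")
            stage["k"] = config.k
            stage["auto_k"] = auto_cluster_count(tree)
            anova = anova_feature_discrimination(fm, labels, columns=feats)
            stage["anova"] = {c: _round_p(r) for c, r in anova.items()}
            if config.make_plots:
                _write_dendrogram(tree, out / "dendrogram.png")
                outputs.append("dendrogram.png")
        else:
            stage["skipped"] = "too few tuber samples"
        report["stages"]["cluster"] = stage
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e) from e

    # --- stats --------------------------------------------------------------
    try:
        stage = {}
        by_type = classified.groupby("tuber_type")
        type_order = sorted(by_type.groups)
        for feat in config.cluster_features:
            groups = [g[feat].to_numpy(float) for _, g in by_type]
            if len(groups) >= 2 and all(len(g) for g in groups):
                stage[f"kruskal_{feat}"] = _round_p(kruskal_wallis(groups))
                if all(len(g) >= 2 for g in groups):
                    stage[f"dunn_{feat}"] = [
                        _round_p(r)
                        for r in pairwise_posthoc(groups, names=type_order)
                    ]
        table = pd.crosstab(classified["fcd_like"], classified["tuber_type"])
        if table.shape[0] > 1 and (table.to_numpy().sum(axis=1) > 0).all():
            try:
                stage["chi2_fcd_by_type"] = _round_p(
                    chi_square(table.to_numpy())
                )
            except TuberhistError:
                pass
        type_rank = classified["tuber_type"].map({"A": 0, "B": 1, "C": 2})
        if type_rank.nunique() > 1 and len(classified) >= 3:
            stage["kendall_age_vs_type"] = _round_p(
                kendall_tau(classified["age_at_surgery_y"], type_rank)
            )
        report["stages"]["stats"] = stage
        (out / "stats.json").write_text(json.dumps(stage, indent=2,
                                                   sort_keys=True))
        outputs.append("stats.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", e) from e

    _finalize(config, out, outputs, report)
    return report


def _write_dendrogram(tree, path):  # pragma: no cover - plotting is optional
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import scipy.cluster.hierarchy as sch

    fig, ax = plt.subplots(figsize=(6, 4))
    sch.dendrogram(tree.merges, ax=ax, color_threshold=None)
    ax.set_ylabel("Ward height")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _finalize(config: RunConfig, out: Path, outputs: list, report: dict):
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    outputs.append("report.json")
    cfg = config.to_dict()
    # hash identifies the analysis, not where it was written
    hashable = {k: v for k, v in cfg.items() if k != "out_dir"}
    cfg_hash = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "package_version": __version__,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
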