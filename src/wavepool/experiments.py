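"""Factorial experiment grid: enumeration, execution, and summary reports.

The default grid is the study design: 6 pooling configurations x 2 depths
x 3 batch sizes x 3 speckle levels = 108 configurations, each repeated
with 5 random seeds.  ``run_grid`` trains on built-in phantoms and writes
one results row per (configuration, seed); ``summarize`` turns a results
CSV into per-noise-level tables plus Friedman/Kendall-W, selected Wilcoxon
pairs with rank-biserial effect sizes, BCa confidence intervals per cell,
and a critical-difference diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import MetricsReport
from .model import ModelConfig, build_model
from .phantom import PhantomSpec, dataset_arrays, generate_dataset
from .pooling import STUDY_CONFIGS, PoolingConfig
from .stats import (ScoreMatrix, bca_ci, friedman, nemenyi_cd, nemenyi_cliques,
                    truncate_p, wilcoxon_signed_rank_exact)
from .training import TrainConfig, evaluate, train_model

RESULT_COLUMNS = ["pooling", "preprocess", "order", "blocks", "batch", "noise",
                  "seed", "accuracy", "precision", "recall", "specificity",
                  "f1", "auc", "brier", "ece", "epochs"]


@dataclass(frozen=True)
class GridSpec:
    poolings: Tuple[PoolingConfig, ...] = STUDY_CONFIGS
    depths: Tuple[int, ...] = (3, 4)
    batch_sizes: Tuple[int, ...] = (8, 16, 32)
    noise_levels: Tuple[float, ...] = (0.0, 0.1, 0.2)
    seeds: Tuple[int, ...] = (0, 1, 2, 3, 4)
    # desk-scale data/training knobs
    n_phantoms: int = 240
    image_size: int = 32
    max_epochs: int = 100

    def __post_init__(self) -> None:
        for name in ("poolings", "depths", "batch_sizes", "noise_levels", "seeds"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid factor {name!r} is empty")


def config_key(pool: PoolingConfig, blocks: int, batch: int, noise: float) -> str:
    return f"{pool.name}|B{blocks}|bs{batch}|noise{noise:g}"


def enumerate_grid(spec: GridSpec) -> List[Dict]:
    """All pooling x depth x batch x noise configurations (seeds are repeats)."""
    configs = []
    for pool in spec.poolings:
        for blocks in spec.depths:
            for batch in spec.batch_sizes:
                for noise in spec.noise_levels:
                    configs.append({
                        "key": config_key(pool, blocks, batch, noise),
                        "pooling": pool, "blocks": blocks,
                        "batch": batch, "noise": noise,
                    })
    keys = {c["key"] for c in configs}
    assert len(keys) == len(configs), "grid keys must be unique"
    return configs


def _run_one(cfg: Dict, seed: int, data) -> Dict:
    samples, manifest = data
    x_tr, y_tr = dataset_arrays(samples, manifest, "train")
    x_va, y_va = dataset_arrays(samples, manifest, "val")
    x_te, y_te = dataset_arrays(samples, manifest, "test")
    pool: PoolingConfig = cfg["pooling"]
    model = build_model(ModelConfig(blocks=cfg["blocks"], pooling=pool,
                                    input_size=x_tr.shape[-1]), seed=seed)
    tcfg = TrainConfig(batch_size=cfg["batch"], seed=seed,
                       noise_level=cfg["noise"], preprocess=pool.preprocess,
                       max_epochs=cfg.get("max_epochs", 100))
    history = train_model(model, x_tr, y_tr, x_va, y_va, tcfg)
    report = evaluate(model, x_te, y_te, [cfg["noise"]],
                      preprocess=pool.preprocess, seed=seed + 10_000)[0]
    return {
        "key": cfg["key"], "pooling": pool.name, "preprocess": pool.preprocess,
        "order": pool.order if pool.order else "", "blocks": cfg["blocks"],
        "batch": cfg["batch"], "noise": cfg["noise"], "seed": seed,
        "accuracy": report.accuracy, "precision": report.precision,
        "recall": report.recall, "specificity": report.specificity,
        "f1": report.f1, "auc": report.auc, "brier": report.brier,
        "ece": report.ece, "epochs": len(history["train_loss"]),
    }


def run_grid(spec: GridSpec, out_csv: str | Path, resume: bool = True,
             phantom_spec: Optional[PhantomSpec] = None,
             data_seed: int = 1234) -> pd.DataFrame:
    """Execute the grid on built-in phantoms, one row per (config, seed).

    With ``resume`` the function skips (config, seed) pairs already present
    in the output CSV, so an interrupted sweep can be continued.
    """
    out_csv = Path(out_csv)
    if phantom_spec is None:
        phantom_spec = PhantomSpec(size=spec.image_size)
    data = generate_dataset(spec.n_phantoms, 0.5, phantom_spec, data_seed)
    done: set = set()
    rows: List[Dict] = []
    if resume and out_csv.exists():
        prev = pd.read_csv(out_csv)
        rows = prev.to_dict("records")
        done = {(r["key"], r["seed"]) for r in rows}
    for cfg in enumerate_grid(spec):
        cfg = {**cfg, "max_epochs": spec.max_epochs}
        for seed in spec.seeds:
            if (cfg["key"], seed) in done:
                continue
            rows.append(_run_one(cfg, seed, data))
            pd.DataFrame(rows).to_csv(out_csv, index=False)
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df


def summarize(results_csv: str | Path, out_dir: Optional[str | Path] = None,
              metric: str = "accuracy", bootstrap_B: int = 2000,
              rng_seed: int = 0) -> Dict:
    """Build the report: per-noise tables, omnibus/pairwise stats, CD data.

    Pure function of the CSV contents (bootstrap seeds are fixed), so
    regenerating the report from the same file is deterministic.
    """
    df = pd.read_csv(results_csv)
    report: Dict = {"metric": metric, "tables": {}, "stats": {}}

    for noise, sub in df.groupby("noise"):
        table = (sub.groupby("pooling")[metric]
                 .agg(["mean", "std", "count"]).reset_index())
        cells = []
        rng = np.random.default_rng(rng_seed)
        for _, row in table.iterrows():
            vals = sub.loc[sub["pooling"] == row["pooling"], metric].to_numpy()
            if len(vals) >= 2 and np.ptp(vals) > 0:
                lo, hi = bca_ci(vals, np.mean, B=bootstrap_B, rng=rng)
            else:
                lo = hi = float(vals.mean())
            cells.append({"pooling": row["pooling"], "mean": row["mean"],
                          "std": 0.0 if np.isnan(row["std"]) else row["std"],
                          "n": int(row["count"]), "ci_low": lo, "ci_high": hi})
        report["tables"][f"noise_{noise:g}"] = cells

    methods = sorted(df["pooling"].unique())
    if len(methods) < 2:
        report["stats"]["notice"] = "fewer than 2 methods; statistics skipped"
        return report

    pivot = df.pivot_table(index=["blocks", "batch", "noise", "seed"],
                           columns="pooling", values=metric)
    pivot = pivot.dropna()
    if len(pivot) >= 2:
        sm = ScoreMatrix(pivot.to_numpy(), list(pivot.columns))
        fr = friedman(sm)
        cd = nemenyi_cd(len(pivot.columns), len(pivot))
        report["stats"]["friedman"] = {
            "chi2": fr.statistic, "p": truncate_p(fr.p_value),
            "kendalls_w": fr.effect_size,
            "mean_ranks": dict(zip(pivot.columns, fr.extra["mean_ranks"])),
            "nemenyi_cd": cd,
            "cliques": [list(c) for c in
                        nemenyi_cliques(fr.extra["mean_ranks"], cd)],
        }
        pairs = []
        cols = list(pivot.columns)
        best = pivot.mean().idxmax()
        for other in cols:
            if other == best:
                continue
            x, y = pivot[best].to_numpy(), pivot[other].to_numpy()
            try:
                res = wilcoxon_signed_rank_exact(x[:20], y[:20], "greater")
                pairs.append({"better": best, "worse": other,
                              "p": truncate_p(res.p_value),
                              "rank_biserial": res.effect_size})
            except ValueError as exc:
                pairs.append({"better": best, "worse": other,
                              "note": f"no difference ({exc})"})
        report["stats"]["wilcoxon_vs_best"] = pairs

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        if "friedman" in report["stats"]:
            ranks = report["stats"]["friedman"]["mean_ranks"]
            pd.DataFrame([{"pooling": k, "mean_rank": v} for k, v in ranks.items()]
                         ).to_csv(out_dir / "mean_ranks.csv", index=False)
            _cd_diagram(ranks, report["stats"]["friedman"]["nemenyi_cd"],
                        out_dir / "cd_diagram.png")
    return report


def _cd_diagram(mean_ranks: Dict[str, float], cd: float, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = sorted(mean_ranks.items(), key=lambda kv: kv[1])
    fig, ax = plt.subplots(figsize=(7, 2 + 0.3 * len(items)))
    for i, (name, rank) in enumerate(items):
        ax.plot([rank], [i], "ko")
        ax.annotate(f" {name} ({rank:.2f})", (rank, i), va="center")
    lo = min(r for _, r in items)
    ax.plot([lo, lo + cd], [-0.8, -0.8], "k-", lw=3)
    ax.annotate(f"CD = {cd:.3f}", (lo, -0.6))
    ax.set_ylim(-1.2, len(items))
    ax.set_xlabel("mean rank (lower is better)")
    ax.get_yaxis().set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
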