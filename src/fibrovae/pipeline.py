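"""End-to-end orchestration: simulate -> fuse -> train -> score -> analyze.

A single :class:`PipelineConfig` drives every stage; each stochastic stage
receives a recorded seed derived from the global seed, and the run manifest
(seeds, config hash, output checksums) is sufficient to re-run bit-identically
in serial mode.  Severity labels never reach the trainer: the model is built
from the clinical table (core columns only) and embeddings, and the
constructor refuses severity columns outright.

Figures are deterministic renderings of the CSV outputs, so tests assert on
the CSVs: the loss curve, the anomaly-score histogram with the 85th-percentile
line, and severity-stratified boxplots of the scores.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, stats
from .features import encode_binaries
from .simulate import CORE_CONTINUOUS, CohortSimConfig, generate_cohort
from .vae import MultimodalVAE, VAEConfig

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("fibrovae")

_DEFAULT_MARKERS = ["dlco_pct", "fev1_pct", "spo2_rest", "six_mwt_m", "vo2max", "mmrc"]


@dataclass
class PipelineConfig:
    """Configuration of a full anomaly-detection run."""

    sim: CohortSimConfig = field(default_factory=CohortSimConfig)
    vae: VAEConfig = field(default_factory=VAEConfig)
    percentile: float = 85.0
    markers: list[str] = field(default_factory=lambda: list(_DEFAULT_MARKERS))
    include_imaging: bool = True
    seed: int = 0
    outdir: str = "fibrovae_run"

    def __post_init__(self) -> None:
        # Stage seeds derived from the global seed, recorded in the manifest.
        ss = np.random.SeedSequence(self.seed)
        sim_seed, vae_seed = (int(s) % (2**31) for s in ss.generate_state(2))
        self.sim = dataclasses.replace(self.sim, seed=sim_seed)
        self.vae = dataclasses.replace(self.vae, seed=vae_seed)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "vae": self.vae.to_dict(),
            "percentile": self.percentile,
            "markers": list(self.markers),
            "include_imaging": self.include_imaging,
            "seed": self.seed,
            "outdir": str(self.outdir),
        }


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seeds: dict
    outputs: dict[str, str]  # relative path -> sha256
    stages: list[dict]
    error: dict | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded)."""
    d = config.to_dict()
    d.pop("outdir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _write_figures(outdir: Path, loss_curve, scores: pd.DataFrame, threshold: float) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(loss_curve) + 1), loss_curve)
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean ELBO loss")
    ax.set_title("VAE training curve")
    fig.tight_layout()
    fig.savefig(outdir / "loss_curve.png", dpi=100)
    plt.close(fig)
    written.append("loss_curve.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(scores["score"], bins=15, edgecolor="black")
    ax.axvline(threshold, linestyle="--", color="tab:red", label=f"85th pct = {threshold:.2f}")
    ax.set_xlabel("anomaly score")
    ax.set_ylabel("patients")
    ax.set_title("Multimodal anomaly scores")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "score_hist.png", dpi=100)
    plt.close(fig)
    written.append("score_hist.png")

    if "severity" in scores.columns:
        order = [g for g in ("mild", "moderate", "severe") if g in set(scores["severity"])]
        data = [scores.loc[scores["severity"] == g, "score"] for g in order]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot(data, tick_labels=order)
        for i, g in enumerate(order, start=1):
            vals = scores.loc[scores["severity"] == g, "score"]
            ax.plot(np.full(len(vals), i), vals, "o", alpha=0.5, markersize=4)
        ax.axhline(threshold, linestyle="--", color="tab:red")
        ax.set_ylabel("anomaly score")
        ax.set_title("Anomaly scores by disease severity")
        fig.tight_layout()
        fig.savefig(outdir / "severity_box.png", dpi=100)
        plt.close(fig)
        written.append("severity_box.png")
    return written


def run_pipeline(config: PipelineConfig | None = None) -> RunManifest:
    """Run the full anomaly-detection analysis under one config.

    Writes the simulated cohort, the per-patient scores with flags, summary
    and correlation tables, severity statistics, figures and a manifest to
    ``config.outdir``.  On stage failure, the manifest records the stage and
    error and partial outputs are retained.
    """
    if config is None:
        config = PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    outputs: dict[str, str] = {}
    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=_config_hash(config),
        seeds={"global": config.seed, "sim": config.sim.seed, "vae": config.vae.seed},
        outputs=outputs,
        stages=stages,
    )

    def record(name: str, t0: float) -> None:
        stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})
        log.info("stage %-10s done in %.2fs", name, time.time() - t0)

    current = "init"
    try:
        current, t0 = "simulate", time.time()
        clinical, embeddings, truth = generate_cohort(config.sim)
        clinical.to_csv(outdir / "clinical.csv")
        embeddings.round(6).to_csv(outdir / "embeddings.csv")
        truth.to_csv(outdir / "ground_truth.csv")
        record("simulate", t0)

        current, t0 = "fuse", time.time()
        model = MultimodalVAE.from_dataframes(
            clinical,
            embeddings if config.include_imaging else None,
            config=config.vae,
        )
        record("fuse", t0)

        current, t0 = "train", time.time()
        results = model.fit()
        pd.DataFrame(
            {"epoch": np.arange(1, len(results.loss_curve) + 1), "elbo": results.loss_curve}
        ).to_csv(outdir / "loss_curve.csv", index=False)
        record("train", t0)

        current, t0 = "score", time.time()
        severity = truth.loc[model.matrix.patient_ids, "severity"].tolist()
        scores = results.anomaly_scores(severity=severity)
        flags = analysis.flag_high_anomaly(
            scores["score"].to_numpy(), severity, percentile=config.percentile
        )
        scores["flagged"] = flags.flags
        scores["discordant_truth"] = truth.loc[model.matrix.patient_ids, "discordant"].to_numpy()
        scores.round(6).to_csv(outdir / "scores.csv")
        record("score", t0)

        current, t0 = "analyze", time.time()
        s = analysis.summarize_scores(scores["score"].to_numpy())
        pd.DataFrame(
            [
                {
                    "n": s.n,
                    "median": s.median,
                    "q25": s.q25,
                    "q75": s.q75,
                    "min": s.min,
                    "max": s.max,
                    "skewness": s.skewness,
                    "threshold": flags.threshold,
                    "flagged": flags.flagged_count,
                    "percentile": config.percentile,
                    "interpolation": "linear order-statistic",
                }
            ]
        ).round(6).to_csv(outdir / "score_summary.csv", index=False)
        analysis.stratify_by_severity(scores["score"].to_numpy(), severity).round(6).to_csv(
            outdir / "severity_summaries.csv"
        )
        analysis.correlate_with_markers(
            scores["score"].to_numpy(),
            encode_binaries(clinical).loc[model.matrix.patient_ids],
            config.markers,
        ).round(6).to_csv(outdir / "score_correlations.csv")

        # Severity-group statistics battery on the core continuous variables.
        kw_rows, dunn_tables, cliff_rows = [], [], []
        groups_of = lambda var: {
            g: clinical.loc[truth["severity"] == g, var].to_numpy()
            for g in ("mild", "moderate", "severe")
        }
        for var in CORE_CONTINUOUS:
            grp = groups_of(var)
            kw = stats.kruskal_wallis(grp)
            kw_rows.append({"variable": var, "H": kw.H, "p": kw.p, "df": kw.df, "status": kw.status})
            dt = stats.dunn_posthoc_holm(grp)
            dt.insert(0, "variable", var)
            dunn_tables.append(dt)
            for g1, g2 in (("mild", "moderate"), ("mild", "severe"), ("moderate", "severe")):
                delta, band = stats.cliffs_delta(grp[g1], grp[g2])
                cliff_rows.append(
                    {"variable": var, "group1": g1, "group2": g2, "delta": delta, "band": band}
                )
        pd.DataFrame(kw_rows).round(6).to_csv(outdir / "kruskal_wallis.csv", index=False)
        pd.concat(dunn_tables, ignore_index=True).round(6).to_csv(
            outdir / "dunn_holm.csv", index=False
        )
        pd.DataFrame(cliff_rows).round(6).to_csv(outdir / "cliffs_delta.csv", index=False)

        # Exploratory PCA of the standardized core continuous block.
        Xc = clinical[CORE_CONTINUOUS].to_numpy(dtype=float)
        Xs = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0, ddof=1)
        pca = stats.pca_explore(Xs, columns=CORE_CONTINUOUS)
        pd.DataFrame(
            {
                "component": np.arange(1, len(pca.explained_fractions) + 1),
                "explained_fraction": pca.explained_fractions,
            }
        ).round(6).to_csv(outdir / "pca_scree.csv", index=False)
        pd.DataFrame(
            pca.loadings[:, :2], index=CORE_CONTINUOUS, columns=["PC1", "PC2"]
        ).round(6).to_csv(outdir / "pca_loadings.csv")
        record("analyze", t0)

        current, t0 = "figures", time.time()
        figures = _write_figures(outdir, results.loss_curve, scores, flags.threshold)
        record("figures", t0)

        for p in sorted(outdir.glob("*.csv")):
            outputs[p.name] = _sha256(p)
        for name in figures:
            outputs[name] = _sha256(outdir / name)
    except Exception as exc:
        manifest.error = {
            "stage": current,
            "message": f"{type(exc).__name__}: {exc}",
        }
        for p in sorted(outdir.glob("*.csv")):
            outputs[p.name] = _sha256(p)
        manifest.save(outdir / "manifest.json")
        raise

    manifest.save(outdir / "manifest.json")
    return manifest
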