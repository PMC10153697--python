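"""End-to-end orchestration: fixture/raw inputs -> detection, diel calls,
comparisons and environmental fits, under one declarative seeded config.
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
import yaml

from . import detect as _detect
from . import diel as _diel
from . import enviro as _enviro
from .containers import ERCCSet, ExpressionMatrix
from .design import SampleDesign, subset_timepoints
from .normalize import median_polish_summarize, quantile_normalize

log = logging.getLogger("dielarray")

__all__ = ["RunConfig", "run", "load_fixture"]


@dataclass
class RunConfig:
    """Declarative run description; round-trips losslessly through YAML."""

    fixture_dir: str
    out_dir: str
    seed: int = 0
    snr_threshold: float = 5.0
    ercc_min_samples: int = 3
    fdr_threshold: float = 0.25
    n_background: int = 1000
    cluster_boot: int = 1000
    identity_threshold: float = 95.0
    pathway_fraction: float = 1 / 3
    n_perm: int = 999
    timepoint_subset: list[str] | None = None   # phase labels for a rerun
    run_enviro: bool = True
    run_cluster: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.snr_threshold <= 0 or self.ercc_min_samples < 0:
            raise ValueError("thresholds out of range")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded, so the
        same analysis is recognizable wherever it is run)."""
        d = dataclasses.asdict(self)
        d.pop("fixture_dir"), d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_fixture(fixture_dir) -> dict:
    """Read a fixture directory written by :func:`dielarray.synth.write_fixture`."""
    d = Path(fixture_dir)
    probes = pd.read_csv(d / "probe_intensities.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(d / "platform_annotation.tsv", sep="\t", index_col=0)
    design_df = pd.read_csv(d / "design.tsv", sep="\t")
    design = [SampleDesign(**row) for row in design_df.to_dict("records")]
    ercc_df = pd.read_csv(d / "ercc.tsv", sep="\t", index_col=0)
    ercc = ERCCSet(ercc_df["concentration"], ercc_df.drop(columns="concentration"))
    ctd = pd.read_csv(d / "ctd.csv", index_col=0)
    truth_path = d / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t", index_col=0) if truth_path.exists() else None
    return {"probes": probes, "annotation": annotation, "design": design,
            "ercc": ercc, "ctd": ctd, "truth": truth}


def _stage(name: str):
    log.info("stage %s", name)
    return time.monotonic()


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns a summary dict and writes the bundle.

    Stages: normalize (quantile + median polish) -> detect (SNR + ERCC)
    -> diel (Fourier/AR1 FDR, peaks, clusters) -> enviro (MLD skipped
    here; NMDS + envfit + gene-environment correlations on the fixture
    CTD).  All outputs carry the config digest; identical config + seed
    gives identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_fixture(config.fixture_dir)
    design = inputs["design"]
    if config.timepoint_subset:
        design = subset_timepoints(design, config.timepoint_subset)
        keep = [d.sample_id for d in design]
        inputs["probes"] = inputs["probes"][keep]
        inputs["ercc"] = ERCCSet(inputs["ercc"].concentration,
                                 inputs["ercc"].log2_intensity[keep])
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds]

    t0 = _stage("normalize")
    qn = quantile_normalize(inputs["probes"])
    expr = median_polish_summarize(qn, inputs["annotation"]["gene_id"], design)
    log.info("normalized %d genes in %.1fs", expr.data.shape[0], time.monotonic() - t0)

    t0 = _stage("detect")
    det = _detect.detect_genes(expr, inputs["ercc"],
                               snr_threshold=config.snr_threshold,
                               min_samples=config.ercc_min_samples)
    detected = det.detected
    log.info("detected %d of %d genes", len(detected), expr.data.shape[0])

    t0 = _stage("diel")
    model = _diel.FourierDielModel(expr.sel_genes(detected),
                                   fdr_threshold=config.fdr_threshold)
    res = model.fit(n_background=config.n_background, seed=stage_seed[0],
                    cluster=config.run_cluster, n_boot=config.cluster_boot)
    log.info("diel: %d of %d detected genes in %.1fs",
             res.n_diel, len(detected), time.monotonic() - t0)

    ann = inputs["annotation"].drop_duplicates("gene_id").set_index("gene_id")
    sub = ann["sublineage"].reindex(expr.genes)
    summary = {
        "config_digest": config.digest(),
        "n_genes": int(expr.data.shape[0]),
        "n_detected": int(len(detected)),
        "n_diel": int(res.n_diel),
        "detected_by_sublineage": det.per_gene.groupby(sub)["detected"].sum()
                                      .astype(int).to_dict(),
        "diel_by_sublineage": res.table["is_diel"].groupby(sub.loc[res.table.index])
                                  .sum().astype(int).to_dict(),
        "peak_histogram": res.table.loc[res.diel_genes, "peak"]
                              .value_counts().to_dict(),
        "stress": None,
    }

    enviro_tables = {}
    if config.run_enviro:
        t0 = _stage("enviro")
        avg, hours, reps = _diel.replicate_average(expr.sel_genes(detected))
        ctd = inputs["ctd"]
        env_vars = [c for c in ctd.columns
                    if c not in ("phase_label", "clock_hour", "hours_since_start")
                    and ctd[c].std() > 0]
        ord_ = _enviro.nmds(avg, seed=stage_seed[1])
        # per-gene environmental summaries: correlation with each variable
        per_gene, _ = _enviro.env_gene_correlations(avg, ctd[env_vars])
        fit = _enviro.envfit(ord_, per_gene.fillna(0.0), n_perm=config.n_perm,
                             seed=stage_seed[2])
        enviro_tables = {"ordination": ord_.frame(), "envfit": fit,
                         "correlations": per_gene}
        summary["stress"] = ord_.stress
        summary["envfit_significant"] = fit.index[fit["significant"]].tolist()

    digest = config.digest()
    header = f"# config={digest}\n"

    def write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t")

    write(expr.data, "expression.tsv")
    write(det.to_frame(), "detection.tsv")
    write(res.results_frame(), "diel.tsv")
    for name, df in enviro_tables.items():
        write(df, f"enviro_{name}.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    config.to_yaml(out / "config.yaml")
    return {"summary": summary, "expr": expr, "detection": det, "diel": res,
            "enviro": enviro_tables}
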