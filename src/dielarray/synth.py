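"""Synthetic probe-level microarray fixtures with known ground truth.

Emulates a targeted diel metatranscriptome experiment: 8-10 time points at
3 h intervals over ~27 h with duplicate samples, genes carried by 4-6
probes each, a diel subpopulation following a 24 h sinusoid with assigned
peak phases, AR1-correlated noise, a low-intensity noise floor, an ERCC
spike-in ladder whose least concentrated member bounds detection, and
diel environmental covariates.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .containers import ERCCSet, ExpressionMatrix
from .design import SampleDesign, make_design

__all__ = [
    "GeneTruth",
    "make_truths",
    "simulate_expression",
    "expand_to_probes",
    "spike_ercc",
    "simulate_ctd",
    "simulate_density_profile",
    "make_probe_sequences",
    "make_references",
    "write_fixture",
    "DEFAULT_ERCC_LADDER",
]

SUBLINEAGES = ("A1", "A2", "A3")

#: Two-fold ladder spanning ~3 decades; the least concentrated member
#: plays the role of the detection-bounding spike.
DEFAULT_ERCC_LADDER = [(f"ERCC-{i:05d}", 4.7 * 2.0 ** (i - 1)) for i in range(1, 13)]


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth generating parameters for one gene."""

    gene_id: str
    sublineage: str               # A1 | A2 | A3
    pathway: str
    is_diel: bool
    peak_phase: float | None      # clock hour of peak, [0, 24); diel only
    amplitude: float              # log2 units, > 0 iff diel
    baseline: float               # log2 units
    ar1_phi: float                # lag-1 autocorrelation, |phi| < 1
    detectable: bool = True

    def __post_init__(self) -> None:
        if self.is_diel and not self.amplitude > 0:
            raise ValueError("diel genes need positive amplitude")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")


def make_truths(n_genes: int, frac_diel: float = 0.2, amplitude: float = 1.5,
                baseline: float = 8.0, baseline_sd: float = 1.0,
                ar1_phi: float = 0.3, frac_undetectable: float = 0.15,
                undetectable_baseline: float = 1.0, seed: int = 0,
                pathways: tuple[str, ...] = (
                    "photosynthesis", "nitrogen_fixation", "ribosome",
                    "amino_acid_metabolism", "porphyrin_metabolism",
                    "oxidative_phosphorylation"),
                ) -> list[GeneTruth]:
    """Draw a gene population with diel and low-intensity subsets.

    Peak phases of diel genes are assigned uniformly over the 24 h clock.
    ``frac_undetectable`` genes sit at ``undetectable_baseline``, far
    below the bulk: they emulate the low-intensity noise floor of a real
    array (targets absent from the sample), populate the dimmest decile
    that the detection stage uses as its noise estimate, and exercise the
    ERCC detection bound.  Keep this fraction above the detection decile
    (default 0.10) so the noise floor is estimated from floor-level genes.
    """
    rng = np.random.default_rng(seed)
    truths = []
    for g in range(n_genes):
        diel = rng.random() < frac_diel
        faint = (not diel) and rng.random() < frac_undetectable / (1 - frac_diel)
        base = undetectable_baseline if faint else baseline + baseline_sd * rng.standard_normal()
        truths.append(GeneTruth(
            gene_id=f"gene{g:05d}",
            sublineage=SUBLINEAGES[g % 3],
            pathway=pathways[g % len(pathways)],
            is_diel=diel,
            peak_phase=float(rng.uniform(0, 24)) if diel else None,
            amplitude=amplitude if diel else 0.0,
            baseline=float(base),
            ar1_phi=ar1_phi,
            detectable=not faint,
        ))
    return truths


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """AR1 series started from its stationary distribution (no burn-in)."""
    x = np.empty(n)
    if sd == 0:
        x[:] = 0.0
        return x
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi ** 2))
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_expression(design: list[SampleDesign], truths: list[GeneTruth],
                        noise_sd: float, seed: int) -> ExpressionMatrix:
    """Gene x sample log2 levels: sinusoid (diel genes) plus AR1 noise.

    A diel gene follows ``baseline + amplitude * cos(2*pi*(t - peak)/24)``
    at clock hour ``t``, so its noiseless maximum falls at the sampled
    clock hour nearest ``peak_phase``.  Each replicate runs its own AR1
    noise series over the time grid (innovation sd ``noise_sd``, stationary
    start).
    """
    if not design:
        raise ValueError("design is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    reps = sorted({d.replicate for d in design})
    by_rep = {r: [d for d in design if d.replicate == r] for r in reps}
    cols = [d.sample_id for d in design]
    out = pd.DataFrame(0.0, index=[t.gene_id for t in truths], columns=cols)
    for tr in truths:
        for r in reps:
            ds = by_rep[r]
            noise = _ar1(rng, len(ds), tr.ar1_phi, noise_sd)
            for d, z in zip(ds, noise):
                level = tr.baseline + z
                if tr.is_diel:
                    level += tr.amplitude * np.cos(
                        2 * np.pi * (d.clock_hour - tr.peak_phase) / 24.0)
                out.at[tr.gene_id, d.sample_id] = level
    return ExpressionMatrix(out, design)


def expand_to_probes(expr: ExpressionMatrix, truths: list[GeneTruth],
                     probes_per_gene: int | tuple[int, int] = (4, 6),
                     affinity_sd: float = 0.3, probe_noise_sd: float = 0.0,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Explode gene levels into linear-scale probe intensities.

    Each probe gets one affinity offset ~ N(0, affinity_sd^2), drawn once
    and held constant across samples — the additive probe effect that
    median polish assumes — plus optional per-cell noise.  Intensity is
    ``2 ** (gene log2 level + affinity + noise)``.

    Returns ``(probe intensity table, annotation)`` where the annotation
    maps probe_id -> (gene_id, sublineage, pathway).
    """
    if isinstance(probes_per_gene, int):
        lo = hi = probes_per_gene
    else:
        lo, hi = probes_per_gene
    if not 1 <= lo <= hi <= 10:
        raise ValueError("probes_per_gene must lie within [1, 10]")
    rng = np.random.default_rng(seed)
    meta = {t.gene_id: t for t in truths}
    rows, ann = [], []
    for gene in expr.genes:
        n_probes = int(rng.integers(lo, hi + 1))
        offsets = rng.normal(0.0, affinity_sd, size=n_probes) if affinity_sd > 0 \
            else np.zeros(n_probes)
        for j in range(n_probes):
            pid = f"{gene}_p{j + 1}"
            noise = rng.normal(0.0, probe_noise_sd, size=expr.data.shape[1]) \
                if probe_noise_sd > 0 else 0.0
            rows.append(pd.Series(
                2.0 ** (expr.data.loc[gene].values + offsets[j] + noise),
                index=expr.data.columns, name=pid))
            t = meta[gene]
            ann.append((pid, gene, t.sublineage, t.pathway))
    probes = pd.DataFrame(rows)
    annotation = pd.DataFrame(
        ann, columns=["probe_id", "gene_id", "sublineage", "pathway"]
    ).set_index("probe_id")
    return probes, annotation


def spike_ercc(design: list[SampleDesign],
               ladder: list[tuple[str, float]] = DEFAULT_ERCC_LADDER,
               slope: float = 1.0, intercept: float = 2.0,
               noise_sd: float = 0.0, seed: int = 0) -> ERCCSet:
    """Simulate the spike-in ladder on the concentration-response line.

    log2 intensity = intercept + slope * log2(concentration) + N(0, sd^2),
    independently per sample.  The least concentrated member is flagged by
    the returned :class:`ERCCSet` as the detection floor.
    """
    ids = [e for e, _ in ladder]
    conc = np.array([c for _, c in ladder], float)
    if (conc <= 0).any() or len(set(conc)) != len(conc):
        raise ValueError("concentrations must be positive and distinct")
    rng = np.random.default_rng(seed)
    base = intercept + slope * np.log2(conc)
    cols = [d.sample_id for d in design]
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(len(ids), len(cols))) \
        if noise_sd > 0 else np.tile(base[:, None], (1, len(cols)))
    return ERCCSet(pd.Series(conc, index=ids, name="concentration"),
                   pd.DataFrame(vals, index=ids, columns=cols))


def simulate_ctd(design: list[SampleDesign],
                 params: dict[str, tuple[float, float, float]] | None = None,
                 ) -> pd.DataFrame:
    """One CTD record per time point: 24 h sinusoidal covariates.

    ``params`` maps variable -> (mean, diel amplitude, peak clock hour).
    Defaults loosely mimic sub-mixed-layer open-ocean conditions.
    """
    if params is None:
        params = {
            "temperature": (24.5, 0.15, 15.0),
            "salinity": (35.2, 0.0, 0.0),
            "oxygen": (205.0, 2.0, 17.0),
            "chlorophyll": (0.12, 0.03, 14.0),
            "par": (60.0, 60.0, 12.0),
        }
    tps = sorted({(d.hours_since_start, d.clock_hour, d.phase_label)
                  for d in design})
    rows = []
    for k, (h, clock, label) in enumerate(tps):
        row = {"cast_id": f"cast{k + 1:02d}", "phase_label": label,
               "clock_hour": clock, "hours_since_start": h}
        for var, (mean, amp, peak) in params.items():
            val = mean + amp * np.cos(2 * np.pi * (clock - peak) / 24.0)
            if var == "par":
                val = max(val, 0.0)   # no negative irradiance at night
            row[var] = val
        rows.append(row)
    return pd.DataFrame(rows).set_index("cast_id")


def simulate_density_profile(surface_sigma: float = 23.5,
                             gradient: float = 0.01, mld_true: float = 28.0,
                             max_pressure: float = 200.0,
                             step: float = 2.0) -> pd.DataFrame:
    """Piecewise-linear potential-density profile with a known mixed layer.

    sigma_theta is constant at ``surface_sigma`` down to a knee placed so
    that the profile crosses ``sigma_theta(10 dbar) + 0.03`` exactly at
    ``mld_true``, then increases linearly at ``gradient`` kg/m^3 per dbar.
    Sampled every ``step`` dbar, so interpolation recovers ``mld_true``
    exactly.
    """
    knee = mld_true - 0.03 / gradient
    if knee <= 10.0:
        raise ValueError("mld_true too shallow for this gradient")
    p = np.arange(0.0, max_pressure + step, step)
    sigma = surface_sigma + np.where(p > knee, (p - knee) * gradient, 0.0)
    return pd.DataFrame({"pressure": p, "sigma_theta": sigma})


# ---------------------------------------------------------------------------
# probe / reference sequences (for cross-hybridization screening tests)

_BASES = np.array(list("ACGT"))


def make_probe_sequences(annotation: pd.DataFrame, length: int = 60,
                         seed: int = 0) -> dict[str, str]:
    """Random independent probe sequences (60-mers), one per probe id."""
    rng = np.random.default_rng(seed)
    return {pid: "".join(rng.choice(_BASES, size=length))
            for pid in annotation.index}


def make_references(probe_seqs: dict[str, str], annotation: pd.DataFrame,
                    spacer: int = 20, seed: int = 0,
                    ) -> list[tuple[str, str, str]]:
    """Per-sublineage reference sequences embedding that lineage's probes.

    Probes are concatenated with random spacers, so each probe has an
    exact (100% identity) match in its own sublineage's reference and,
    generically, no match elsewhere.  Returns (ref_id, sublineage, seq).
    """
    rng = np.random.default_rng(seed)
    refs = []
    for sub in sorted(annotation["sublineage"].unique()):
        pids = annotation.index[annotation["sublineage"] == sub]
        parts = []
        for pid in pids:
            parts.append("".join(rng.choice(_BASES, size=spacer)))
            parts.append(probe_seqs[pid])
        parts.append("".join(rng.choice(_BASES, size=spacer)))
        refs.append((f"ref_{sub}", sub, "".join(parts)))
    return refs


# ---------------------------------------------------------------------------
# fixture directory

def write_fixture(outdir, design: list[SampleDesign], truths: list[GeneTruth],
                  probes: pd.DataFrame, annotation: pd.DataFrame,
                  ercc: ERCCSet, ctd: pd.DataFrame,
                  probe_seqs: dict[str, str] | None = None,
                  references: list[tuple[str, str, str]] | None = None,
                  manifest: dict | None = None) -> None:
    """Write a complete fixture directory (TSV/CSV/FASTA + YAML manifest)."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    probes.rename_axis("probe_id").to_csv(out / "probe_intensities.tsv", sep="\t")
    annotation.to_csv(out / "platform_annotation.tsv", sep="\t")
    pd.DataFrame([dataclasses.asdict(d) for d in design]).to_csv(
        out / "design.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(
        out / "truth.tsv", sep="\t", index=False)
    ladder = ercc.concentration.rename_axis("ercc_id").reset_index()
    pd.merge(ladder, ercc.log2_intensity.rename_axis("ercc_id").reset_index(),
             on="ercc_id").to_csv(out / "ercc.tsv", sep="\t", index=False)
    ctd.to_csv(out / "ctd.csv")
    if probe_seqs is not None:
        with open(out / "probes.fasta", "w") as fh:
            for pid, seq in probe_seqs.items():
                fh.write(f">{pid}\n{seq}\n")
    if references is not None:
        with open(out / "references.fasta", "w") as fh:
            for rid, sub, seq in references:
                fh.write(f">{rid} sublineage={sub}\n{seq}\n")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest or {}, fh, sort_keys=True)
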