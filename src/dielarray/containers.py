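"""Shared in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import SampleDesign

__all__ = ["ExpressionMatrix", "ERCCSet"]


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 transcript levels with the sample design attached.

    ``data`` rows are genes, columns are ``sample_id``s in design order.
    ``probe_counts`` records how many probes were summarized per gene
    (provenance from the probe-set roll-up; absent for simulated truth
    matrices).
    """

    data: pd.DataFrame
    design: list[SampleDesign]
    probe_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        ids = [d.sample_id for d in self.design]
        if list(self.data.columns) != ids:
            raise ValueError("expression columns must match design sample ids")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def sel_genes(self, genes) -> "ExpressionMatrix":
        pc = self.probe_counts.loc[genes] if self.probe_counts is not None else None
        return ExpressionMatrix(self.data.loc[genes], self.design, pc)


@dataclass
class ERCCSet:
    """ERCC spike-in ladder: concentrations (aM) plus per-sample intensities.

    ``log2_intensity`` rows are spike ids, columns sample ids.  The least
    concentrated member (``floor_id``) bounds gene detection.
    """

    concentration: pd.Series          # aM, indexed by ercc_id
    log2_intensity: pd.DataFrame      # ercc_id x sample_id
    floor_id: str = field(init=False)

    def __post_init__(self) -> None:
        conc = self.concentration
        if (conc <= 0).any():
            raise ValueError("ERCC concentrations must be positive")
        if conc.duplicated().any() and conc.min() in conc[conc.duplicated()].values:
            raise ValueError("minimum ERCC concentration must be unique")
        self.floor_id = conc.idxmin()
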