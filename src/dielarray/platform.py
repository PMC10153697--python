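"""Array platform model: probe annotation, cross-hybridization screening,
ambiguity clustering and probe-set coverage.

Probes (typically 60 nt) target genes from one of three UCYN-A sublineages
(A1/A2/A3).  A probe is a cross-hybridization risk when it aligns to a
reference sequence from a *different* sublineage at >=95% nucleotide
identity over >=95% of the probe; probes that cluster with probes from
other sublineages or genes are rejected unless their gene symbol is
whitelisted (highly conserved genes such as *nifH*).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

__all__ = [
    "Probe",
    "PlatformDesign",
    "CrossHybHit",
    "parse_platform",
    "cross_hybridization_screen",
    "cluster_probes",
    "flag_ambiguous",
    "probe_set_summary",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"^[ACGTN]*$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Probe:
    probe_id: str
    gene_id: str
    sublineage: str
    sequence: str

    def __post_init__(self) -> None:
        if not _VALID.match(self.sequence):
            raise ValueError(f"{self.probe_id}: sequence must be over ACGTN")


@dataclass
class PlatformDesign:
    """The array design: probes plus the gene annotation they map to."""

    probes: list[Probe]
    annotation: pd.DataFrame        # gene_id -> sublineage, pathway, symbol
    ercc_controls: list[str] = field(default_factory=list)
    replicate_spot_count: int = 4   # each probe printed at this many coordinates

    def __post_init__(self) -> None:
        if self.replicate_spot_count < 1:
            raise ValueError("replicate spot count must be >= 1")
        missing = {p.gene_id for p in self.probes} - set(self.annotation.index)
        if missing:
            raise ValueError(f"probes reference unannotated genes: {sorted(missing)[:5]}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_features(self) -> int:
        """Experimental features on the array: probes x replicate spots."""
        return self.n_probes * self.replicate_spot_count

    def sublineage_counts(self) -> pd.Series:
        return pd.Series([p.sublineage for p in self.probes]).value_counts().sort_index()


@dataclass(frozen=True)
class CrossHybHit:
    probe_id: str
    target_id: str
    target_sublineage: str
    strand: str                     # '+' or '-'
    percent_identity: float
    aligned_fraction: float         # of the probe length, percent


def parse_platform(annotation_path, fasta_path=None, *,
                   ercc_prefix: str = "ERCC-",
                   replicate_spot_count: int = 4) -> PlatformDesign:
    """Load a platform from an annotation TSV and optional probe FASTA.

    The annotation must carry columns probe_id (or index), gene_id,
    sublineage and optionally pathway / symbol.  Probe ids present in the
    FASTA but absent from the annotation are an error (listed).
    """
    ann = pd.read_csv(annotation_path, sep="\t")
    if "probe_id" in ann.columns:
        ann = ann.set_index("probe_id")
    if ann.empty:
        raise ValueError("empty platform annotation")
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
        orphans = sorted(set(seqs) - set(ann.index))
        if orphans:
            raise ValueError(f"probes in FASTA missing from annotation: {orphans}")
    probes = [Probe(pid, row["gene_id"], row["sublineage"], seqs.get(pid, ""))
              for pid, row in ann.iterrows()
              if not str(pid).startswith(ercc_prefix)]
    gene_cols = [c for c in ("sublineage", "pathway", "symbol") if c in ann.columns]
    gene_ann = ann.reset_index().groupby("gene_id")[gene_cols].first()
    ercc = [str(p) for p in ann.index if str(p).startswith(ercc_prefix)]
    return PlatformDesign(probes, gene_ann, ercc, replicate_spot_count)


def _alignment_stats(query: str, target: str) -> tuple[float, float] | None:
    """Best infix alignment of query into target.

    Returns (percent identity over the alignment span, percent of the
    query aligned) or None when no alignment exists.  Gaps count as
    mismatches; N matches nothing.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    matches = span = qlen = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        span += n
        if op == "=":
            matches += n
            qlen += n
        elif op == "X":
            qlen += n
        elif op == "I":        # insertion relative to target: query bases
            qlen += n
    identity = 100.0 * matches / span if span else 0.0
    frac = 100.0 * qlen / len(query)
    return identity, frac


def cross_hybridization_screen(probes: list[Probe],
                               references: list[tuple[str, str, str]],
                               identity_threshold: float = 95.0,
                               length_threshold: float = 95.0,
                               inclusive: bool = True,
                               same_sublineage: bool = False,
                               ) -> list[CrossHybHit]:
    """Screen probes against reference sequences of other sublineages.

    ``references`` are (id, sublineage, sequence) tuples; both strands
    are searched (reverse complement of each reference).  A hit is
    emitted when the probe aligns at >= identity_threshold percent
    identity over >= length_threshold percent of the probe to a reference
    from a different sublineage (set ``same_sublineage`` to screen all).
    With ``inclusive=False`` the thresholds are strict (>).
    """
    if not references:
        raise ValueError("references must be non-empty")
    ok = (lambda v, thr: v >= thr) if inclusive else (lambda v, thr: v > thr)
    hits: list[CrossHybHit] = []
    for probe in probes:
        if not probe.sequence:
            continue
        # allow enough edits to reach the identity threshold, plus margin
        for rid, sub, seq in references:
            if sub == probe.sublineage and not same_sublineage:
                continue
            for strand, target in (("+", seq.upper()), ("-", reverse_complement(seq.upper()))):
                stats = _alignment_stats(probe.sequence, target)
                if stats is None:
                    continue
                ident, frac = stats
                if ok(ident, identity_threshold) and ok(frac, length_threshold):
                    hits.append(CrossHybHit(probe.probe_id, rid, sub, strand,
                                            round(ident, 4), round(frac, 4)))
    return hits


def cluster_probes(probes: list[Probe],
                   identity_threshold: float = 95.0) -> list[list[Probe]]:
    """Greedy length-sorted single-pass clustering of probe sequences.

    Probes are visited longest first (ties by id); each joins the first
    cluster whose representative (founder) it matches at >= threshold
    identity over the full probe, else founds a new cluster.  Matches on
    either strand count.
    """
    orderered = sorted(probes, key=lambda p: (-len(p.sequence), p.probe_id))
    clusters: list[list[Probe]] = []
    for probe in orderered:
        placed = False
        for cl in clusters:
            rep = cl[0].sequence
            best = 0.0
            for target in (rep, reverse_complement(rep)):
                stats = _alignment_stats(probe.sequence, target)
                if stats is not None:
                    ident, frac = stats
                    # identity over the full probe: unaligned tail = mismatch
                    best = max(best, ident * min(frac, 100.0) / 100.0)
            if best >= identity_threshold:
                cl.append(probe)
                placed = True
                break
        if not placed:
            clusters.append([probe])
    return clusters


def flag_ambiguous(clusters: list[list[Probe]],
                   whitelist: set[str] | None = None,
                   symbols: dict[str, str] | None = None) -> list[str]:
    """Probe ids to reject: members of multi-sublineage or multi-gene clusters.

    ``symbols`` maps gene_id -> gene symbol; probes whose symbol is in
    ``whitelist`` (conserved genes, e.g. nifH) are exempt.
    """
    whitelist = whitelist or set()
    symbols = symbols or {}
    rejected = []
    for cl in clusters:
        subs = {p.sublineage for p in cl}
        genes = {p.gene_id for p in cl}
        if len(subs) > 1 or len(genes) > 1:
            for p in cl:
                if symbols.get(p.gene_id, p.gene_id) not in whitelist:
                    rejected.append(p.probe_id)
    return rejected


def probe_set_summary(design: PlatformDesign, k: int = 3
                      ) -> tuple[pd.Series, float]:
    """Probe count per gene and the fraction of genes with >= k probes."""
    if not design.probes:
        return pd.Series(dtype=int, name="n_probes"), float("nan")
    counts = (pd.Series([p.gene_id for p in design.probes])
              .value_counts().sort_index().rename("n_probes"))
    return counts, float((counts >= k).mean())
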