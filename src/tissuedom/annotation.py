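"""Gene models, strand-aware TSS windows, and CpG-to-region assignment.

Internal coordinates are 0-based half-open everywhere; the GTF reader
converts from the 1-based closed convention at the I/O boundary.  Each
transcript is one analysis unit; transcripts sharing a (chrom, strand, TSS)
triple can be merged into a single unit whose expression is the sum (or max)
of its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: promoter length upstream of the TSS (bp); the lower bound of the
#: methylation/expression scan range, configurable per call.
DEFAULT_PROMOTER_BP = 1500

REGION_NAMES = (
    "promoter",
    "first_exon",
    "first_intron",
    "other_exons",
    "other_introns",
    "gene_body",
)


@dataclass
class GeneModel:
    """One transcript unit with strand-aware TSS and derived regions.

    ``exons`` are genomic half-open intervals sorted 5'->3' in strand order
    (i.e. descending genomic coordinates on the minus strand).  ``regions``
    maps region name -> list of genomic half-open intervals.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.member_ids:
            self.member_ids = [self.transcript_id]
        if not self.regions:
            self.regions = _compute_regions(self)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


def _compute_regions(m: GeneModel, promoter_bp: int = DEFAULT_PROMOTER_BP) -> dict:
    """Promoter / first exon / first intron / other exons / other introns /
    gene body, strand-aware, all half-open genomic intervals."""
    exons = list(m.exons)
    # genomic-sorted copy for intron derivation
    gsort = sorted(exons)
    introns = [
        (gsort[i][1], gsort[i + 1][0])
        for i in range(len(gsort) - 1)
        if gsort[i + 1][0] > gsort[i][1]
    ]
    if m.strand == "+":
        promoter = (max(0, m.tss - promoter_bp), m.tss)
        first_exon = exons[0]
        first_intron = [introns[0]] if introns else []
        other_introns = introns[1:]
    else:
        promoter = (m.tss + 1, m.tss + 1 + promoter_bp)
        first_exon = exons[0]  # strand order: highest-coordinate exon first
        first_intron = [introns[-1]] if introns else []
        other_introns = introns[:-1]
    other_exons = [e for e in gsort if e != first_exon]
    return {
        "promoter": [promoter],
        "first_exon": [first_exon],
        "first_intron": first_intron,
        "other_exons": other_exons,
        "other_introns": other_introns,
        "gene_body": [(m.start, m.end)],
    }


def _finalize(transcript_id, gene_id, chrom, strand, exons) -> GeneModel:
    gsort = sorted(exons)
    if strand == "+":
        tss = gsort[0][0]
        ordered = gsort
    else:
        tss = gsort[-1][1] - 1
        ordered = gsort[::-1]
    return GeneModel(transcript_id, gene_id, chrom, strand, tss, ordered)


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def read_gene_models(path: str) -> list[GeneModel]:
    """Read transcript models from GTF (Ensembl dialect) or BED12.

    Format is chosen by extension (.bed -> BED12, otherwise GTF).  GTF
    1-based closed coordinates are converted to 0-based half-open.
    """
    if str(path).endswith(".bed") or str(path).endswith(".bed12"):
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path: str) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF record")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            if strand not in "+-":
                import warnings

                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}; record rejected")
                continue
            try:
                s, e = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from err
            if e <= s:
                raise ValueError(f"{path}:{lineno}: empty or inverted exon")
            tid = _gtf_attr(attrs, "transcript_id")
            gid = _gtf_attr(attrs, "gene_id") or tid
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            rec = exons.setdefault(tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append((s, e))
    return [
        _finalize(tid, rec["gene_id"], rec["chrom"], rec["strand"], rec["exons"])
        for tid, rec in exons.items()
    ]


def _read_bed12(path: str) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, _end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in "+-":
                import warnings

                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}; record rejected")
                continue
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            models.append(_finalize(name, name, chrom, strand, exons))
    return models


def merge_same_tss(models: list[GeneModel]) -> list[GeneModel]:
    """Collapse transcripts with identical (chrom, strand, tss) into one unit.

    The merged unit keeps the first member's exon structure and carries all
    member transcript IDs; idempotent.  Merge member expression with
    :func:`aggregate_member_expression`.
    """
    groups: dict[tuple, list[GeneModel]] = {}
    for m in models:
        groups.setdefault((m.chrom, m.strand, m.tss), []).append(m)
    merged = []
    for members in groups.values():
        lead = members[0]
        if len(members) == 1:
            merged.append(lead)
            continue
        ids = [i for m in members for i in m.member_ids]
        merged.append(
            GeneModel(
                transcript_id=lead.transcript_id,
                gene_id=lead.gene_id,
                chrom=lead.chrom,
                strand=lead.strand,
                tss=lead.tss,
                exons=lead.exons,
                member_ids=ids,
            )
        )
    return merged


def aggregate_member_expression(
    models: list[GeneModel], table: pd.DataFrame, how: str = "sum"
) -> pd.DataFrame:
    """Per-unit expression from a per-transcript table (index = transcript id).

    ``how``: "sum" (default; preserves total signal) or "max".
    """
    if how not in ("sum", "max"):
        raise ValueError("how must be 'sum' or 'max'")
    rows = []
    for m in models:
        present = [i for i in m.member_ids if i in table.index]
        if not present:
            continue
        sub = table.loc[present]
        rows.append(sub.sum(axis=0) if how == "sum" else sub.max(axis=0))
    return pd.DataFrame(rows, index=[m.transcript_id for m in models if any(i in table.index for i in m.member_ids)])


@dataclass(frozen=True)
class TssWindow:
    """Half-open genomic interval [start, end) spanning ``upstream`` bp 5' of
    the TSS through ``downstream`` bp 3' of it (strand-aware)."""

    gene: GeneModel
    upstream: int
    downstream: int
    start: int
    end: int
    clipped: bool = False


def tss_window(model: GeneModel, upstream: int = 200, downstream: int = 400) -> TssWindow:
    """Strand-aware TSS window; on the minus strand "upstream" extends to
    larger genomic coordinates.  Clipped at chromosome start and flagged."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be >= 0")
    if model.strand == "+":
        start, end = model.tss - upstream, model.tss + downstream
    else:
        start, end = model.tss + 1 - downstream, model.tss + 1 + upstream
    clipped = start < 0
    return TssWindow(model, upstream, downstream, max(0, start), end, clipped)


def strand_offset(model: GeneModel, pos: int) -> int:
    """Signed strand-aware offset of genomic position ``pos`` from the TSS
    (negative = upstream).  The TSS base itself is offset 0."""
    return pos - model.tss if model.strand == "+" else model.tss - pos


def assign_cpgs_to_regions(
    cpgs: pd.DataFrame,
    models: list[GeneModel],
    window_upstream: int = 200,
    window_downstream: int = 400,
) -> pd.DataFrame:
    """Map CpG sites to (gene, region) pairs by interval intersection.

    ``cpgs`` needs columns chrom, pos (0-based).  A site may map to several
    genes and several regions of one gene; one output row per mapping.
    Region names are the GeneModel regions plus ``tss_window``.
    """
    model_chroms = {m.chrom for m in models}
    cpg_chroms = set(cpgs["chrom"].unique())
    if model_chroms and cpg_chroms and not (model_chroms & cpg_chroms):
        raise ValueError(
            f"no shared chromosome names between CpGs ({sorted(cpg_chroms)[:3]}...) "
            f"and gene models ({sorted(model_chroms)[:3]}...)"
        )
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for name, ivals in m.regions.items():
            for s, e in ivals:
                if e > s:
                    tree.addi(s, e, (m.transcript_id, name))
        w = tss_window(m, window_upstream, window_downstream)
        if w.end > w.start:
            tree.addi(w.start, w.end, (m.transcript_id, "tss_window"))
    out = []
    for chrom, pos in zip(cpgs["chrom"].to_numpy(), cpgs["pos"].to_numpy()):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(int(pos)):
            gene, region = iv.data
            out.append((chrom, int(pos), gene, region))
    return pd.DataFrame(out, columns=["chrom", "pos", "gene_id", "region"])
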