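"""Gene annotations, canonical per-chromosome ordering, and coordinate arithmetic.

Genes are stored in the 0-based half-open convention (``[left, right)``), the
same convention BED uses; GTF/GFF3 records (1-based, inclusive) are shifted on
read.  Per chromosome, genes are totally ordered by ``(left, right, id)`` and
indexed ``1..n``; every downstream structure (vicinity sets, cover solutions)
refers to genes through that 1-based index.

Strand enters only through the transcription start/end landmarks (TSS/TES).
Distances used for vicinity membership and tie-breaking are strand-agnostic
"facing gaps" (bp between the nearest ends of two genes, zero when they
overlap); the strand-dependent TSS/TES distance is provided separately as a
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Gene",
    "GeneIndex",
    "AnnotationError",
    "read_annotation",
    "landmarks",
    "facing_gap",
    "orientation_distance",
    "write_bed",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Gene:
    """One annotated gene: half-open interval ``[left, right)`` plus strand."""

    id: str
    chromosome: str
    left: int
    right: int
    strand: str

    def __post_init__(self) -> None:
        if self.left < 0:
            raise AnnotationError(f"gene {self.id}: negative coordinate {self.left}")
        if not self.left < self.right:
            raise AnnotationError(
                f"gene {self.id}: empty or inverted interval [{self.left}, {self.right})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.right - self.left

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left + self.right)


def landmarks(g: Gene) -> tuple[int, int]:
    """Return ``(TSS, TES)`` for a gene.

    On the + strand the transcription start site is the leftmost base and the
    end site the rightmost base; on the - strand the roles swap.  Both are
    base positions (0-based), so the rightmost base of ``[left, right)`` is
    ``right - 1``.
    """
    if g.strand == "+":
        return g.left, g.right - 1
    return g.right - 1, g.left


def facing_gap(a: Gene, b: Gene) -> int:
    """Strand-agnostic genomic gap between two genes' nearest ends, in bp.

    Zero when the genes overlap or one is nested in the other.  Symmetric.
    """
    if a.chromosome != b.chromosome:
        raise AnnotationError(
            f"facing_gap across chromosomes: {a.chromosome} vs {b.chromosome}"
        )
    earlier, later = (a, b) if a.left <= b.left else (b, a)
    return max(0, later.left - earlier.right)


def orientation_distance(a: Gene, b: Gene) -> int:
    """Strand-aware distance: |TSS-TSS| on the same strand, |TSS-TES| otherwise.

    Diagnostic companion to :func:`facing_gap`; not used by the solver.
    """
    if a.chromosome != b.chromosome:
        raise AnnotationError(
            f"orientation_distance across chromosomes: {a.chromosome} vs {b.chromosome}"
        )
    tss_a, _ = landmarks(a)
    tss_b, tes_b = landmarks(b)
    if a.strand == b.strand:
        return abs(tss_a - tss_b)
    return abs(tss_a - tes_b)


@dataclass
class GeneIndex:
    """Position-ordered genes of one chromosome, indexed ``1..n``.

    The ordering key is ``(left, right, id)``: total and deterministic, so
    shuffled input never changes an index.  1-based indices are the public
    currency; internal numpy arrays are 0-based.
    """

    chromosome: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise AnnotationError(f"chromosome {self.chromosome}: no genes")
        self.genes = sorted(self.genes, key=lambda g: (g.left, g.right, g.id))
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene ids on {self.chromosome}: {dup}")
        for g in self.genes:
            if g.chromosome != self.chromosome:
                raise AnnotationError(
                    f"gene {g.id} on {g.chromosome} placed in index for {self.chromosome}"
                )
        self._lefts = np.array([g.left for g in self.genes], dtype=np.int64)
        self._rights = np.array([g.right for g in self.genes], dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def lefts(self) -> np.ndarray:
        return self._lefts

    @property
    def rights(self) -> np.ndarray:
        return self._rights

    def gene(self, i: int) -> Gene:
        """Gene at 1-based index ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"gene index {i} out of range 1..{self.n}")
        return self.genes[i - 1]

    def index_of(self, gene_id: str) -> int:
        """1-based index of a gene id."""
        try:
            return self._id_to_index[gene_id]
        except AttributeError:
            self._id_to_index = {g.id: k + 1 for k, g in enumerate(self.genes)}
            return self._id_to_index[gene_id]

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def pair_gap(self, i: int, j: int) -> int:
        """facing_gap between genes at 1-based indices i and j (fast path)."""
        if i == j:
            return 0
        lo, hi = (i, j) if i < j else (j, i)
        return max(0, int(self._lefts[hi - 1] - self._rights[lo - 1]))


# ---------------------------------------------------------------------------
# readers / writers


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".bed",):
        return "bed"
    if suffix in (".gtf",):
        return "gtf"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    raise AnnotationError(f"cannot infer annotation format from {path.name}; pass format=")


def _read_bed(path: Path) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path.name}:{lineno}: BED record needs >=6 fields "
                    f"(chrom start end name score strand), got {len(fields)}"
                )
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5]
            try:
                left, right = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                warnings.warn(
                    f"{path.name}:{lineno}: record {name!r} has no strand; skipped",
                    stacklevel=3,
                )
                continue
            genes.append(Gene(id=name, chromosome=chrom, left=left, right=right, strand=strand))
    return genes


def _read_gff(path: Path, dialect: str, feature_filter: str, protein_coding_only: bool) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[Gene] = []
    for feat in db.features_of_type(feature_filter):
        if protein_coding_only:
            biotype = (
                feat.attributes.get("gene_biotype")
                or feat.attributes.get("gene_type")
                or feat.attributes.get("biotype")
            )
            if biotype is not None and biotype[0] != "protein_coding":
                continue
        name = (
            (feat.attributes.get("gene_id") or [None])[0]
            or (feat.attributes.get("ID") or [None])[0]
            or feat.id
        )
        if feat.strand not in ("+", "-"):
            warnings.warn(f"{path.name}: feature {name!r} has no strand; skipped", stacklevel=3)
            continue
        # GTF/GFF3 are 1-based inclusive; shift to 0-based half-open.
        genes.append(
            Gene(
                id=name,
                chromosome=feat.seqid,
                left=feat.start - 1,
                right=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def read_annotation(
    path: str | Path,
    format: Optional[str] = None,
    feature_filter: str = "gene",
    protein_coding_only: bool = False,
) -> list[GeneIndex]:
    """Read a GTF/GFF3/BED annotation into one :class:`GeneIndex` per chromosome.

    Parameters
    ----------
    path
        Annotation file.  BED must carry >=6 columns (strand required).
    format
        ``"gtf"``, ``"gff3"`` or ``"bed"``; inferred from the extension when
        omitted.
    feature_filter
        Feature type to retain from GTF/GFF3 (default ``"gene"``); ignored for
        BED.
    protein_coding_only
        Restrict to records whose biotype attribute is ``protein_coding``,
        when the attribute is present.

    Returns
    -------
    list of GeneIndex, sorted by chromosome name.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "bed":
        genes = _read_bed(path)
    elif fmt in ("gtf", "gff3"):
        genes = _read_gff(path, fmt, feature_filter, protein_coding_only)
    else:
        raise AnnotationError(f"unknown annotation format {fmt!r}")
    if not genes:
        raise AnnotationError(f"no genes parsed from {path}")
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    return [GeneIndex(chromosome=c, genes=gs) for c, gs in sorted(by_chrom.items())]


def write_bed(
    genes: Iterable[Gene],
    path: str | Path,
    scores: Optional[Sequence[float]] = None,
) -> None:
    """Write genes as BED6; ``scores`` (e.g. per-set average estimation
    distance, bp) are rounded to integers, defaulting to 0."""
    genes = list(genes)
    if scores is not None and len(scores) != len(genes):
        raise ValueError("scores length must match number of genes")
    with open(path, "w") as fh:
        for k, g in enumerate(genes):
            score = int(round(scores[k])) if scores is not None else 0
            fh.write(f"{g.chromosome}\t{g.left}\t{g.right}\t{g.id}\t{score}\t{g.strand}\n")
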