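"""Nonredundant gene-catalog construction.

Implements the redundancy-removal step of a metagenomic gene catalog: greedy
incremental clustering of predicted genes at nucleotide identity/coverage
thresholds (the conventional cutoff is 95% identity over 90% of the shorter
sequence), and merging of independently derived gene sets with overlap
statistics.

Identity and coverage follow the short-sequence convention: identity is the
number of identical aligned positions divided by the length of the shorter
sequence, and coverage is the fraction of the shorter sequence inside the
mutually aligned span.  Genes are compared in the given orientation only
(coding strand, as produced by gene prediction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

logger = logging.getLogger(__name__)

__all__ = ["GeneRecord", "GeneCatalog", "align_identity", "cluster_genes", "merge_gene_sets"]

MIN_GENE_LENGTH = 150
_VALID_BASES = frozenset("ACGT")

# Fixed alignment scoring; the thresholds, not the scores, are the contract.
_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


@dataclass(frozen=True)
class GeneRecord:
    """One catalog entry: a predicted gene with optional annotation metadata.

    ``lineage`` is an ordered rank tuple (domain -> genus), possibly partial;
    ``ko_ids`` the KEGG Orthology annotations; ``source`` tags whether the gene
    came from reference mapping or de novo assembly.
    """

    gene_id: str
    sequence: str
    lineage: tuple[str, ...] = ()
    ko_ids: frozenset[str] = frozenset()
    source: str = "assembled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineage", tuple(self.lineage))
        object.__setattr__(self, "ko_ids", frozenset(self.ko_ids))
        if len(self.sequence) < MIN_GENE_LENGTH:
            raise ValueError(
                f"gene {self.gene_id!r}: length {len(self.sequence)} < {MIN_GENE_LENGTH} bp"
            )
        if self.source not in ("mapped", "assembled"):
            raise ValueError(f"gene {self.gene_id!r}: unknown source {self.source!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCatalog:
    """A clustered gene set: all records plus representative -> members map.

    Representatives (the nonredundant set) are members of their own cluster;
    clusters partition the records.
    """

    records: list[GeneRecord]
    clusters: dict[str, list[str]] = field(default_factory=dict)

    @property
    def representatives(self) -> list[GeneRecord]:
        by_id = {r.gene_id: r for r in self.records}
        return [by_id[rep] for rep in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


def _check_dna(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{label}: non-ACGT characters {sorted(bad)}")


def align_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity and coverage of two DNA sequences.

    Returns ``(identity, coverage)`` where identity = identical aligned
    positions / length of the shorter sequence and coverage = shorter-sequence
    positions inside the mutually aligned span / shorter length.  Symmetric in
    its arguments.
    """
    _check_dna(a, "a")
    _check_dna(b, "b")
    # Canonical order makes the optimal-path tie-break independent of argument
    # order, so the function is exactly symmetric.
    s, l = sorted((a, b), key=lambda x: (len(x), x))
    aln = _aligner.align(l, s)[0]
    row_l, row_s = aln[0], aln[1]
    identical = sum(1 for x, y in zip(row_l, row_s) if x == y and x != "-")
    both = [i for i, (x, y) in enumerate(zip(row_l, row_s)) if x != "-" and y != "-"]
    if both:
        lo, hi = both[0], both[-1]
        covered = sum(1 for c in row_s[lo : hi + 1] if c != "-")
    else:
        covered = 0
    n = len(s)
    return identical / n, covered / n


def _matches(query: str, rep: str, id_thresh: float, cov_thresh: float) -> bool:
    ident, cov = align_identity(query, rep)
    return ident >= id_thresh and cov >= cov_thresh


def _check_thresholds(id_thresh: float, cov_thresh: float) -> None:
    for name, t in (("id_thresh", id_thresh), ("cov_thresh", cov_thresh)):
        if not (0.0 < t <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {t}")


def cluster_genes(
    records: list[GeneRecord], id_thresh: float = 0.95, cov_thresh: float = 0.90
) -> GeneCatalog:
    """Greedy incremental clustering into a nonredundant catalog.

    Records are processed longest-first (ties by gene id); each joins the
    first existing representative it matches at ``identity >= id_thresh`` and
    ``coverage >= cov_thresh``, else founds a new cluster.  Cluster scan order
    is founding order, so the first matching representative wins even if a
    later one matches better.
    """
    _check_thresholds(id_thresh, cov_thresh)
    ordered = sorted(records, key=lambda r: (-r.length, r.gene_id))
    reps: list[GeneRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        for rep in reps:
            if _matches(rec.sequence, rep.sequence, id_thresh, cov_thresh):
                clusters[rep.gene_id].append(rec.gene_id)
                break
        else:
            reps.append(rec)
            clusters[rec.gene_id] = [rec.gene_id]
    return GeneCatalog(records=list(ordered), clusters=clusters)


def merge_gene_sets(
    set_a: GeneCatalog,
    set_b: GeneCatalog,
    id_thresh: float = 0.95,
    cov_thresh: float = 0.90,
) -> tuple[GeneCatalog, dict[str, float]]:
    """Merge two internally nonredundant gene sets and report their overlap.

    A representative of B is *shared* when it matches any representative of A
    at the thresholds (first match wins).  The merged catalog keeps all of A's
    representatives, records shared B genes as members of the matching A
    cluster, and appends B's non-matching representatives as new clusters.
    Overlap statistics mirror a gene-set Venn: ``shared_count`` plus the
    shared fraction of each input.
    """
    _check_thresholds(id_thresh, cov_thresh)
    a_reps = set_a.representatives
    b_reps = set_b.representatives
    clusters = {rep: list(members) for rep, members in set_a.clusters.items()}
    records = list(set_a.records)
    shared = 0
    for rec in b_reps:
        records.append(rec)
        for rep in a_reps:
            if _matches(rec.sequence, rep.sequence, id_thresh, cov_thresh):
                clusters[rep.gene_id].append(rec.gene_id)
                shared += 1
                break
        else:
            clusters[rec.gene_id] = [rec.gene_id]
    overlap = {
        "shared_count": shared,
        "frac_of_a": shared / len(a_reps) if a_reps else 0.0,
        "frac_of_b": shared / len(b_reps) if b_reps else 0.0,
    }
    logger.info(
        "merged gene sets: |A|=%d |B|=%d shared=%d merged=%d",
        len(a_reps), len(b_reps), shared, len(clusters),
    )
    return GeneCatalog(records=records, clusters=clusters), overlap
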