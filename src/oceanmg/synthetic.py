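"""Synthetic multi-strain communities for exercising the analysis stages.

The generator emulates the statistical structure the downstream math assumes:
a strain pangenome with core and private accessory genes, uniform-random gene
sequences (with a substitution-only mutator for making near-duplicates at a
controlled divergence), per-sample unique-mapped read counts drawn
multinomially with gene probability proportional to gene length times the
summed abundance of the strains carrying the gene, and an environment table in
which temperature is a strictly monotone transform of one taxon's abundance
while the remaining variables are independent noise within oceanographically
plausible ranges.

No read sequences are simulated: the mapping step is out of scope and the
downstream computations consume counts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneRecord, MIN_GENE_LENGTH
from .strains import StrainPangenome

__all__ = [
    "CommunitySpec",
    "ENV_COLUMNS",
    "generate_pangenomes",
    "community_spec",
    "mutate_sequence",
    "simulate_counts",
    "expected_gene_profile",
    "generate_env_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

ENV_COLUMNS = (
    "temperature",      # degC
    "salinity",         # PSU
    "pH",
    "phosphate",        # uM
    "silicate",         # uM
    "ammonium",         # uM
    "nitrite",          # uM
    "nitrate",          # uM
    "chlorophyll_a",    # ug/L
)

# Plausible oligotrophic surface-water ranges for the noise covariates.
_ENV_RANGES = {
    "salinity": (33.0, 37.5),
    "pH": (7.8, 8.3),
    "phosphate": (0.0, 0.5),
    "silicate": (0.0, 5.0),
    "ammonium": (0.0, 0.5),
    "nitrite": (0.0, 0.3),
    "nitrate": (0.0, 2.0),
    "chlorophyll_a": (0.0, 0.5),
}


@dataclass
class CommunitySpec:
    """Ground truth of a synthetic community.

    ``true_abundance`` holds per-strain relative abundances (sum to 1);
    ``pangenomes`` maps strain id -> gene id set; ``gene_lengths`` covers every
    referenced gene (>= 150 bp, the minimum predicted-gene length);
    ``annotations`` maps gene id -> (lineage tuple, KO id set).
    """

    strains: list[str]
    true_abundance: dict[str, float]
    pangenomes: dict[str, frozenset[str]]
    gene_lengths: dict[str, int]
    annotations: dict[str, tuple[tuple[str, ...], frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.strains) != set(self.true_abundance) or set(self.strains) != set(self.pangenomes):
            raise ValueError("strains, true_abundance and pangenomes must cover the same ids")
        ab = np.array([self.true_abundance[s] for s in self.strains], dtype=float)
        if (ab < 0).any():
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {ab.sum():.12f})")
        for strain, genes in self.pangenomes.items():
            missing = set(genes) - set(self.gene_lengths)
            if missing:
                raise ValueError(f"strain {strain!r}: genes without length {sorted(missing)[:5]}")
        short = {g: L for g, L in self.gene_lengths.items() if L < MIN_GENE_LENGTH}
        if short:
            raise ValueError(f"gene lengths below {MIN_GENE_LENGTH} bp: {short}")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(set().union(*self.pangenomes.values()) if self.pangenomes else set())


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_pangenomes(
    n_strains: int,
    core_size: int,
    accessory_size: int,
    gene_len_range: tuple[int, int] = (150, 1500),
    seed: int = 0,
    genus: str = "Prochlorococcus",
    ko_pool_size: int = 50,
    id_prefix: str = "",
) -> tuple[list[StrainPangenome], list[GeneRecord]]:
    """Build a synthetic strain pangenome set.

    Every strain carries all ``core_size`` core genes plus ``accessory_size``
    private accessory genes.  Sequences are uniform-random over ACGT with
    lengths uniform in ``gene_len_range``; each gene receives one KO drawn
    from a pool of ``ko_pool_size`` and a cyanobacterial lineage ending at
    ``genus``.  Deterministic for a fixed seed.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if core_size < 0 or accessory_size < 0:
        raise ValueError("core_size and accessory_size must be >= 0")
    lo, hi = gene_len_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid gene length range {gene_len_range}")
    if lo < MIN_GENE_LENGTH:
        raise ValueError(f"minimum gene length is {MIN_GENE_LENGTH} bp, got range {gene_len_range}")

    rng = np.random.default_rng(seed)
    lineage = ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales", genus + "aceae", genus)

    def make_gene(gene_id: str) -> GeneRecord:
        length = int(rng.integers(lo, hi + 1))
        ko = f"K{int(rng.integers(1, ko_pool_size + 1)):05d}"
        return GeneRecord(gene_id, _random_seq(rng, length), lineage=lineage, ko_ids={ko})

    records = [make_gene(f"{id_prefix}core{i:05d}") for i in range(core_size)]
    core_ids = frozenset(r.gene_id for r in records)
    pangenomes = []
    for k in range(n_strains):
        strain = f"{id_prefix}strain{k:02d}"
        acc = [make_gene(f"{strain}_acc{i:04d}") for i in range(accessory_size)]
        records.extend(acc)
        pangenomes.append(
            StrainPangenome(strain, core_ids | {r.gene_id for r in acc})
        )
    return pangenomes, records


def community_spec(
    pangenomes: Sequence[StrainPangenome],
    records: Sequence[GeneRecord],
    abundances: Sequence[float],
) -> CommunitySpec:
    """Assemble a :class:`CommunitySpec` from generated pangenomes and records."""
    if len(abundances) != len(pangenomes):
        raise ValueError("one abundance per strain required")
    return CommunitySpec(
        strains=[p.strain_id for p in pangenomes],
        true_abundance={p.strain_id: float(a) for p, a in zip(pangenomes, abundances)},
        pangenomes={p.strain_id: frozenset(p.gene_ids) for p in pangenomes},
        gene_lengths={r.gene_id: r.length for r in records},
        annotations={r.gene_id: (r.lineage, r.ko_ids) for r in records},
    )


def mutate_sequence(seq: str, divergence: float, seed: int = 0) -> str:
    """Substitute each position independently with probability ``divergence``
    to a uniformly chosen *different* base, so expected identity to the parent
    is exactly ``1 - divergence``.  No indels."""
    if not (0.0 <= divergence <= 1.0):
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if not np.isin(arr, _BASES).all():
        raise ValueError("sequence contains non-ACGT characters")
    rng = np.random.default_rng(seed)
    hit = rng.random(arr.size) < divergence
    out = arr.copy()
    if hit.any():
        idx = {b: i for i, b in enumerate(_BASES)}
        cur = np.array([idx[b] for b in arr[hit]])
        # shift by 1..3 modulo 4 guarantees a different base, uniform over the other three
        out[hit] = _BASES[(cur + rng.integers(1, 4, size=cur.size)) % 4]
    return out.tobytes().decode()


def simulate_counts(
    spec: CommunitySpec,
    n_reads_per_sample: int,
    n_samples: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a unique-mapped read-count table (genes x samples).

    Per sample, counts are multinomial with gene probability proportional to
    gene length times the summed relative abundance of the strains carrying
    the gene (uniform read starts over shared genes).  Column sums equal
    ``n_reads_per_sample`` exactly.
    """
    if n_reads_per_sample < 0:
        raise ValueError("n_reads_per_sample must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    genes = spec.gene_ids
    if not genes:
        raise ValueError("empty community: no genes to sample reads from")
    carrier_weight = {g: 0.0 for g in genes}
    for strain in spec.strains:
        a = spec.true_abundance[strain]
        for g in spec.pangenomes[strain]:
            carrier_weight[g] += a
    w = np.array([carrier_weight[g] * spec.gene_lengths[g] for g in genes], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all gene sampling weights are zero")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads_per_sample, p, size=n_samples).T
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    return pd.DataFrame(counts, index=genes, columns=samples)


def expected_gene_profile(spec: CommunitySpec) -> pd.Series:
    """Length-normalized expected relative abundance of each gene (the truth
    the profiler should recover from simulated counts)."""
    genes = spec.gene_ids
    carrier = pd.Series(0.0, index=genes)
    for strain in spec.strains:
        for g in spec.pangenomes[strain]:
            carrier[g] += spec.true_abundance[strain]
    return carrier / carrier.sum()


def generate_env_table(
    n_samples: int,
    linked_taxon_abundance: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Environment covariate table for ``n_samples`` stations.

    Temperature is a strictly increasing affine transform of the linked
    taxon's abundance (rank correlation exactly +1 for distinct abundances);
    the other covariates are independent uniform noise within plausible
    oligotrophic surface-water ranges.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for downstream correlation tests")
    a = np.asarray(linked_taxon_abundance, dtype=float)
    if a.size != n_samples:
        raise ValueError("linked_taxon_abundance length must equal n_samples")
    rng = np.random.default_rng(seed)
    span = a.max() - a.min()
    scaled = (a - a.min()) / span if span > 0 else np.zeros_like(a)
    data = {"temperature": 18.0 + 14.0 * scaled}
    for col in ENV_COLUMNS[1:]:
        lo, hi = _ENV_RANGES[col]
        data[col] = rng.uniform(lo, hi, size=n_samples)
    index = [f"S{j + 1:02d}" for j in range(n_samples)]
    return pd.DataFrame(data, index=index)[list(ENV_COLUMNS)]
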