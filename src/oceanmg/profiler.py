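"""Length-normalized relative-abundance profiles at gene, KO and taxon level.

Gene relative abundance follows the unique-mapped-read convention: counts are
first divided by gene length, then renormalized per sample to sum to one.
Functional (KO) and taxonomic profiles aggregate gene-level abundances by
annotation; taxa unclassified at the requested rank are pooled under
``"unassigned"`` so taxon profiles also conserve mass.

Tables are plain pandas DataFrames with features as rows and samples as
columns.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RANKS", "UNASSIGNED", "gene_abundance", "ko_profile", "taxon_profile", "core_fraction"]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"


def gene_abundance(counts: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Gene-level relative abundance: ``(count / length)`` renormalized to sum
    to one per sample.  A sample with no reads yields an all-zero column (with
    a logged warning)."""
    missing = [g for g in counts.index if g not in lengths]
    if missing:
        raise KeyError(f"no length for counted gene(s), e.g. {missing[:5]}")
    L = pd.Series({g: lengths[g] for g in counts.index}, dtype=float)
    if (L <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    norm = counts.div(L, axis=0)
    totals = norm.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("all-zero sample(s) %s: returning zero profiles", zero)
        totals = totals.replace(0, np.nan)
    return norm.div(totals, axis=1).fillna(0.0)


def ko_profile(profile: pd.DataFrame, ko_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Aggregate a gene-level profile to KO level.

    KO abundance is the sum of member-gene relative abundances.  A gene with k
    KO annotations contributes its full abundance to each of the k (so the KO
    column totals may exceed one); genes with no KO contribute to none.
    """
    pairs = [
        (ko, gene)
        for gene in profile.index
        for ko in ko_map.get(gene, ())
    ]
    if not pairs:
        return pd.DataFrame(columns=profile.columns, dtype=float)
    idx = pd.DataFrame(pairs, columns=["ko", "gene"])
    mat = profile.loc[idx["gene"]].to_numpy()
    out = pd.DataFrame(mat, columns=profile.columns)
    out["ko"] = idx["ko"].to_numpy()
    return out.groupby("ko").sum().sort_index()


def taxon_profile(
    profile: pd.DataFrame,
    lineage_map: Mapping[str, Sequence[str]],
    rank: str = "genus",
) -> pd.DataFrame:
    """Aggregate a gene-level profile at a taxonomic rank.

    The lineage of each gene is an ordered rank tuple (domain -> genus),
    possibly partial; genes unclassified at ``rank`` are pooled under
    ``"unassigned"`` so the taxon profile sums to one whenever the gene
    profile does.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)

    def taxon_of(gene: str) -> str:
        lineage = lineage_map.get(gene, ())
        if len(lineage) > depth and lineage[depth]:
            return lineage[depth]
        return UNASSIGNED

    groups = pd.Series({g: taxon_of(g) for g in profile.index})
    return profile.groupby(groups).sum().sort_index()


def core_fraction(profile: pd.DataFrame) -> float:
    """Fraction of observed features present (abundance > 0) in every sample,
    among features present in at least one sample."""
    if profile.shape[1] < 2:
        raise ValueError("core fraction needs at least 2 samples")
    present = profile > 0
    observed = present.any(axis=1)
    n_observed = int(observed.sum())
    if n_observed == 0:
        raise ValueError("no feature observed in any sample")
    return float(present.all(axis=1).sum() / n_observed)
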