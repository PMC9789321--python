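"""ASV-table curation and replicated rarefaction.

The preprocessing chain applied to every dataset before diversity analysis:
remove taxa unassigned at the domain level and any eukaryotic taxa, drop
samples left with fewer than 1000 reads, collapse the table to the family
rank, and rarefy to 1110 reads per sample with 10 independent replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LINEAGE_RANKS, CountTable

__all__ = ["CurationLog", "RarefactionResult", "curate_table", "collapse_to_rank", "rarefy"]

_KEPT_DOMAINS = {"bacteria", "archaea"}
_REMOVED_DOMAINS = {"eukaryota", "eukarya", "eukaryote", "eukaryotes"}


@dataclass
class CurationLog:
    removed_taxa: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    min_reads: int = 1000


def curate_table(table: CountTable, min_reads: int = 1000) -> tuple[CountTable, CurationLog]:
    """Drop unassigned-domain and eukaryotic taxa, then low-depth samples.

    Order matters and is fixed: the taxon filter runs first, and samples
    whose remaining total is below ``min_reads`` are removed afterwards.
    """
    taxonomy = table.taxonomy or {}

    def keep_taxon(t: str) -> bool:
        lin = taxonomy.get(t, ())
        domain = lin[0] if len(lin) > 0 else None
        if domain is None or str(domain).strip() == "" or str(domain).lower() == "unassigned":
            return False
        if str(domain).lower() in _REMOVED_DOMAINS:
            return False
        return True

    kept = [t for t in table.taxon_ids if keep_taxon(t)]
    log = CurationLog(min_reads=min_reads)
    log.removed_taxa = [t for t in table.taxon_ids if t not in set(kept)]
    counts = table.counts[kept]
    totals = counts.sum(axis=1)
    keep_samples = totals >= min_reads
    log.removed_samples = list(counts.index[~keep_samples])
    counts = counts.loc[keep_samples]
    if len(counts) == 0:
        raise ValueError("curation removed every sample (all totals below min_reads)")
    new_tax = {t: taxonomy[t] for t in kept if t in taxonomy} or None
    return CountTable(counts=counts.copy(), taxonomy=new_tax), log


def collapse_to_rank(table: CountTable, rank: str = "family") -> CountTable:
    """Sum counts over taxa sharing the lineage prefix down to ``rank``.

    Taxa unassigned at ``rank`` land in an ``unclassified`` bucket scoped to
    their deepest assigned parent lineage, so unassigned members of
    different parents are never merged.  Idempotent at a fixed rank.
    """
    if table.taxonomy is None:
        raise ValueError("collapse requires taxonomy")
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
    depth = LINEAGE_RANKS.index(rank)

    def key_and_lineage(t: str) -> tuple[str, tuple]:
        lin = tuple(table.taxonomy.get(t, ()))
        prefix = list(lin[: depth + 1]) + [None] * max(0, depth + 1 - len(lin))
        if prefix[depth] is None or str(prefix[depth]).strip() == "":
            assigned = [str(r) for r in prefix[:depth] if r is not None and str(r).strip() != ""]
            key = ";".join(assigned + ["unclassified"]) if assigned else "unclassified"
            prefix[depth] = None
        else:
            assigned = [str(r) if r is not None else "" for r in prefix]
            key = ";".join(str(r) for r in prefix)
        return key, tuple(prefix)

    groups: dict[str, list[str]] = {}
    lineages: dict[str, tuple] = {}
    for t in table.taxon_ids:
        key, prefix = key_and_lineage(t)
        groups.setdefault(key, []).append(t)
        lineages[key] = prefix
    data = {key: table.counts[members].sum(axis=1) for key, members in groups.items()}
    collapsed = pd.DataFrame(data, index=table.counts.index)
    return CountTable(counts=collapsed, taxonomy=lineages)


@dataclass
class RarefactionResult:
    depth: int
    replicates: list[CountTable]
    dropped_samples: list[str]
    seed: int


def rarefy(
    table: CountTable, depth: int = 1110, replicates: int = 10, seed: int = 0
) -> RarefactionResult:
    """Subsample each sample to ``depth`` reads without replacement.

    Each replicate draws a multivariate hypergeometric sample per row
    (QIIME-style rarefaction); samples below ``depth`` are dropped and
    listed.  Replicate ``r`` uses seed ``seed + r`` so any replicate can be
    regenerated on its own.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"rarefaction depth {depth} exceeds every sample total (max {int(totals.max())})")
    dropped = list(totals.index[~keep])
    counts = table.counts.loc[keep]
    reps: list[CountTable] = []
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        mat = np.empty_like(counts.to_numpy())
        for i in range(len(counts)):
            mat[i] = rng.multivariate_hypergeometric(counts.iloc[i].to_numpy(), depth)
        reps.append(
            CountTable(
                counts=pd.DataFrame(mat, index=counts.index, columns=counts.columns),
                taxonomy=table.taxonomy,
            )
        )
    return RarefactionResult(depth=depth, replicates=reps, dropped_samples=dropped, seed=seed)
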