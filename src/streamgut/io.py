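"""Tabular input/output and metadata summaries.

The pipeline's on-disk lingua franca is plain TSV (UTF-8, tab-delimited,
``#`` comment lines ignored, first column an identifier) plus a minimal
BIOM-style JSON for count tables.  In memory, sample metadata is a
:class:`pandas.DataFrame` with the fixed column set
``sample_id, order, family, genus, site, ffg``; counts live in
:class:`CountTable`; pairwise dissimilarities in :class:`DistanceMatrix`.

A transcription of the study's 41-sample NEON metadata table ships with the
package and is returned by :func:`load_neon_metadata`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FFG_VOCABULARY",
    "METADATA_COLUMNS",
    "CountTable",
    "DistanceMatrix",
    "MetadataSummary",
    "load_neon_metadata",
    "read_metadata",
    "write_metadata",
    "read_count_table",
    "write_count_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "summarize_metadata",
]

#: Controlled vocabulary of functional feeding groups (normalized form).
FFG_VOCABULARY = frozenset(
    {
        "filtering collectors",
        "gathering collectors",
        "scrapers",
        "predators",
        "shredder/detritivore",
    }
)

#: Synonyms folded into the controlled vocabulary after case/whitespace
#: normalization.  Extensible per call via ``ffg_synonyms``.
_FFG_BUILTIN_SYNONYMS = {
    "shredders/detritivores": "shredder/detritivore",
    "shredder/detritivores": "shredder/detritivore",
    "shredders/detritivore": "shredder/detritivore",
    "filtering collector": "filtering collectors",
    "gathering collector": "gathering collectors",
    "scraper": "scrapers",
    "predator": "predators",
}

METADATA_COLUMNS = ("sample_id", "order", "family", "genus", "site", "ffg")

#: Ranks of a full taxonomy lineage, domain through genus.
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def _normalize_ffg(value: str, synonyms: dict[str, str] | None = None) -> str:
    s = " ".join(str(value).strip().lower().split())
    if synonyms and s in synonyms:
        s = synonyms[s]
    if s in _FFG_BUILTIN_SYNONYMS:
        s = _FFG_BUILTIN_SYNONYMS[s]
    return s


def missing_genus_placeholder(family: str) -> str:
    """Family-scoped stand-in level for records without a genus name."""
    return f"{family}:unknown"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Samples x taxa non-negative integer count matrix with lineages.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and taxon ids as columns.
    taxonomy
        Optional map taxon id -> lineage tuple (domain..species, entries may
        be ``None`` for unassigned ranks).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if c.columns.has_duplicates:
            raise ValueError("duplicate taxon ids in count table")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count at sample {c.index[bad[0]]!r}, "
                    f"taxon {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[bad[0]]!r}, "
                f"taxon {c.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal, entries in [0, 1]."""

    ids: list[str]
    data: np.ndarray
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if np.abs(d - d.T).max(initial=0.0) > self._tol:
            raise ValueError("distance matrix is not symmetric")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        if d.size and (d.min() < -self._tol or d.max() > 1.0 + self._tol):
            raise ValueError("distance entries must lie in [0, 1]")
        self.data = np.clip(d, 0.0, 1.0)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def filter(self, keep_ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in keep_ids]
        return DistanceMatrix(list(keep_ids), self.data[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def _validate_metadata(df: pd.DataFrame, ffg_synonyms: dict[str, str] | None = None) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    df = df[list(METADATA_COLUMNS)].copy()
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")
    for col in ("order", "family", "site"):
        empty = df[col].isna() | (df[col].astype(str).str.strip() == "")
        if empty.any():
            raise ValueError(f"empty {col!r} for samples {list(df.loc[empty, 'sample_id'])}")
    syn = {(_normalize_ffg(k)): _normalize_ffg(v) for k, v in (ffg_synonyms or {}).items()}
    df["ffg"] = [_normalize_ffg(v, syn) for v in df["ffg"]]
    unknown = ~df["ffg"].isin(FFG_VOCABULARY)
    if unknown.any():
        rows = df.loc[unknown, ["sample_id", "ffg"]].to_records(index=False).tolist()
        raise ValueError(f"unknown functional feeding group labels: {rows}")
    genus = df["genus"].astype(object)
    genus = genus.where(~genus.isin(["NA", "na", "N/A", ""]), other=np.nan)
    df["genus"] = genus.where(pd.notna(genus), None)
    return df.reset_index(drop=True)


def read_metadata(path, ffg_synonyms: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Functional feeding group labels are normalized (case, whitespace,
    built-in and user-supplied synonyms); a literal ``NA`` genus becomes
    missing.  Rejects duplicate sample ids and out-of-vocabulary FFGs.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return _validate_metadata(df, ffg_synonyms)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out["genus"] = [g if g is not None and pd.notna(g) else "NA" for g in out["genus"]]
    out.to_csv(path, sep="\t", index=False)


def load_neon_metadata() -> pd.DataFrame:
    """The packaged 41-sample NEON stream macroinvertebrate metadata table."""
    ref = resources.files("streamgut").joinpath("data/neon_table1a.tsv")
    with resources.as_file(ref) as p:
        return read_metadata(p)


@dataclass
class MetadataSummary:
    """Per-variable level counts over a metadata table."""

    n_samples: int
    counts: dict[str, dict[str, int]]  # variable -> level -> n samples
    distinct: dict[str, int]  # variable -> number of distinct levels
    n_missing_genus: int


def summarize_metadata(metadata: pd.DataFrame) -> MetadataSummary:
    """Count samples per level of site, order, family, genus and FFG.

    Missing genera are tallied under their family-scoped placeholder
    (``<family>:unknown``) so that each family's unnamed genus counts as one
    distinct level; the number of missing-genus records is also reported.
    """
    if len(metadata) == 0:
        raise ValueError("metadata is empty")
    counts: dict[str, dict[str, int]] = {}
    for var in ("site", "order", "family", "ffg"):
        counts[var] = dict(Counter(metadata[var]))
    genus_levels = [
        g if g is not None and pd.notna(g) else missing_genus_placeholder(f)
        for g, f in zip(metadata["genus"], metadata["family"])
    ]
    counts["genus"] = dict(Counter(genus_levels))
    n_missing = int(sum(1 for g in metadata["genus"] if g is None or pd.isna(g)))
    distinct = {var: len(levels) for var, levels in counts.items()}
    return MetadataSummary(
        n_samples=len(metadata),
        counts=counts,
        distinct=distinct,
        n_missing_genus=n_missing,
    )


# ---------------------------------------------------------------------------
# Count tables (TSV and BIOM-style JSON)
# ---------------------------------------------------------------------------


def write_count_table(table: CountTable, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        out = table.counts.T  # taxa as rows, samples as columns
        out.index.name = "taxon_id"
        if table.taxonomy:
            lineage = [
                ";".join("" if r is None else str(r) for r in table.taxonomy.get(t, ()))
                for t in out.index
            ]
            out = out.assign(lineage=lineage)
        out.to_csv(path, sep="\t")
    elif fmt == "biom-json":
        c = table.counts.to_numpy()
        rows_ids = table.taxon_ids
        col_ids = table.sample_ids
        triples = [
            [int(i), int(j), int(c[j, i])]
            for i in range(c.shape[1])
            for j in range(c.shape[0])
            if c[j, i] != 0
        ]
        obs_meta = None
        if table.taxonomy:
            obs_meta = [
                {"taxonomy": [None if r is None else str(r) for r in table.taxonomy.get(t, ())]}
                for t in rows_ids
            ]
        doc = {
            "format": "Biological Observation Matrix 1.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "shape": [len(rows_ids), len(col_ids)],
            "rows": [
                {"id": t, "metadata": obs_meta[i] if obs_meta else None}
                for i, t in enumerate(rows_ids)
            ],
            "columns": [{"id": s, "metadata": None} for s in col_ids],
            "data": triples,
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown count-table format {fmt!r}")


def _parse_lineage(s: str) -> tuple:
    parts = [p.strip() for p in str(s).split(";")]
    return tuple(None if p in ("", "NA", "None") else p for p in parts)


def read_count_table(path, fmt: str = "tsv") -> CountTable:
    """Read a count table in TSV (taxa as rows) or BIOM-style JSON format.

    Raises on negative or non-integer cells, naming the offending
    coordinates; malformed input never yields a partial table.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        taxonomy = None
        if "lineage" in df.columns:
            taxonomy = {t: _parse_lineage(v) for t, v in df["lineage"].items()}
            df = df.drop(columns=["lineage"])
        return CountTable(counts=df.T, taxonomy=taxonomy)
    if fmt == "biom-json":
        doc = json.loads(path.read_text())
        for key in ("shape", "rows", "columns", "data", "matrix_type"):
            if key not in doc:
                raise ValueError(f"BIOM document missing field {key!r}")
        n_taxa, n_samples = doc["shape"]
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        if len(taxon_ids) != n_taxa or len(sample_ids) != n_samples:
            raise ValueError("BIOM shape does not match row/column lists")
        mat = np.zeros((n_samples, n_taxa), dtype=np.int64)
        if doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                if v != int(v) or v < 0:
                    raise ValueError(f"invalid count {v} at taxon {taxon_ids[i]!r}, sample {sample_ids[j]!r}")
                mat[j, i] = int(v)
        elif doc["matrix_type"] == "dense":
            arr = np.asarray(doc["data"])
            if arr.shape != (n_taxa, n_samples):
                raise ValueError("dense BIOM data shape mismatch")
            mat = arr.T.astype(np.int64)
        else:
            raise ValueError(f"unsupported matrix_type {doc['matrix_type']!r}")
        taxonomy = None
        metas = [r.get("metadata") for r in doc["rows"]]
        if any(m and "taxonomy" in m for m in metas):
            taxonomy = {
                t: tuple(m["taxonomy"]) if m and "taxonomy" in m else ()
                for t, m in zip(taxon_ids, metas)
            }
        return CountTable(counts=pd.DataFrame(mat, index=sample_ids, columns=taxon_ids), taxonomy=taxonomy)
    raise ValueError(f"unknown count-table format {fmt!r}")


def write_taxonomy(taxonomy: dict[str, tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tlineage\n")
        for t, lin in taxonomy.items():
            fh.write(f"{t}\t" + ";".join("" if r is None else str(r) for r in lin) + "\n")


def read_taxonomy(path) -> dict[str, tuple]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return {t: _parse_lineage(v) for t, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column labels differ")
    d = df.to_numpy(dtype=float)
    if np.abs(d - d.T).max(initial=0.0) > 1e-9:
        raise ValueError("asymmetric distance matrix on read")
    return DistanceMatrix(list(df.index), d)
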