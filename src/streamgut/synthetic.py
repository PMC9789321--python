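"""Synthetic data with known ground truth.

Three generators back the test suite and the acceptance checks:

* :func:`generate_metadata` — a study-design table (sites, insect orders,
  families, genera, functional feeding groups) shaped like the NEON field
  survey this package analyses: 10 stream sites, ~41 samples, 7 orders,
  26 families, 5 FFGs, with a configurable fraction of genus labels missing.
* :func:`generate_counts` — an ASV count table in which community
  composition responds to site, FFG, family and genus through a
  compositional log-linear model (softmax of additive per-taxon effects)
  and library sizes follow a clipped lognormal spanning roughly
  1.2k–100k reads.
* :func:`generate_pair_observations` — dissimilarity observations drawn
  directly from the hierarchical Beta regression (logit-linear mean,
  precision ``phi``) so the sampler can be validated against known
  variance components.

Each generator consumes an independent, documented RNG stream derived from
``config.seed`` so the three can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import FFG_VOCABULARY, CountTable, missing_genus_placeholder

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_metadata", "generate_counts", "generate_pair_observations"]

FACTORS = ("family", "genus", "ffg", "site")

# Stream-id offsets for the per-operation RNG derivation
# default_rng([seed, offset]): metadata=1, counts=2, pairs=3.
_STREAM_METADATA, _STREAM_COUNTS, _STREAM_PAIRS = 1, 2, 3

_ORDER_POOL = [
    "Ephemeroptera", "Diptera", "Plecoptera", "Trichoptera", "Coleoptera",
    "Odonata", "Megaloptera", "Hemiptera", "Lepidoptera", "Neuroptera",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters for all synthetic generators.

    The logit-scale standard deviations (``sigma_*``), grand mean ``alpha``
    and precision ``phi`` parameterize the Beta model when observations are
    drawn from it directly; for count generation the same ``sigma_*`` act as
    log-abundance effect scales.  Defaults mirror the study conditions: a
    dominant FFG effect (0.8), intermediate site effect (0.5), weaker
    family/genus effects (0.3 each), grand mean 0.85 on the logit scale and
    precision 20, with library sizes spanning the observed 1235–98479 reads.
    """

    n_sites: int = 10
    samples_per_site: int | Sequence[int] = 4
    n_asvs: int = 300
    n_orders: int = 7
    n_families: int = 26
    n_genera_per_family: int = 2
    n_ffgs: int = 5
    genus_missing_frac: float = 0.2
    sigma_site: float = 0.5
    sigma_ffg: float = 0.8
    sigma_family: float = 0.3
    sigma_genus: float = 0.3
    alpha: float = 0.85
    phi: float = 20.0
    baseline_log_sd: float = 1.5
    n_microbial_families: int = 40
    depth_log_mean: float = 9.4  # exp(9.4) ~ 12k reads
    depth_log_sd: float = 0.8
    depth_min: int = 1235
    depth_max: int = 98479
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_site", "sigma_ffg", "sigma_family", "sigma_genus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        for name in ("n_sites", "n_asvs", "n_orders", "n_families", "n_ffgs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")
        if not 0 <= self.genus_missing_frac <= 1:
            raise ValueError("genus_missing_frac must be in [0, 1]")
        if self.n_families < self.n_orders:
            raise ValueError("need at least one family per requested order")
        if self.n_ffgs > len(FFG_VOCABULARY):
            raise ValueError(f"at most {len(FFG_VOCABULARY)} functional feeding groups available")

    @property
    def sigmas(self) -> dict[str, float]:
        return {
            "family": self.sigma_family,
            "genus": self.sigma_genus,
            "ffg": self.sigma_ffg,
            "site": self.sigma_site,
        }

    @classmethod
    def paper_like(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Study-scale configuration: 10 sites, 41 samples total."""
        per_site = [5, 4, 4, 4, 4, 4, 4, 4, 4, 4]  # sums to 41
        cfg = cls(n_sites=10, samples_per_site=per_site, seed=seed)
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Miniature configuration for fast end-to-end runs."""
        cfg = cls(
            n_sites=4,
            samples_per_site=3,
            n_asvs=50,
            n_orders=3,
            n_families=6,
            n_microbial_families=12,
            depth_log_mean=8.0,
            depth_log_sd=0.3,
            depth_min=1500,
            depth_max=6000,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SyntheticTruth:
    """Realized effects and mappings behind one generated dataset."""

    config: GeneratorConfig
    effects: dict  # factor -> {level: effect}; counts: factor -> {level: vector}
    extra: dict = field(default_factory=dict)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _site_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for i in range(n):
        a, b = divmod(i, 26)
        out.append("S" + letters[a % 26] + letters[b] + letters[(i * 7) % 26])
    return out


def generate_metadata(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a sample metadata table by seeded draws from level pools.

    ``family -> order`` and ``genus -> family`` are functions (no genus in
    two families); each genus carries a fixed FFG, inherited by its samples.
    A ``genus_missing_frac`` fraction of rows has the genus label blanked
    (the record keeps its family, mirroring field tables where a specimen
    is identified only to family).
    """
    rng = _rng(config, _STREAM_METADATA)
    sites = _site_codes(config.n_sites)
    orders = _ORDER_POOL[: config.n_orders] + [
        f"Order{i:02d}" for i in range(len(_ORDER_POOL), config.n_orders)
    ]
    families = [f"Fam{i:02d}" for i in range(config.n_families)]
    # Every order gets at least one family; remainder assigned at random.
    fam_order = {}
    for i, fam in enumerate(families):
        if i < len(orders):
            fam_order[fam] = orders[i]
        else:
            fam_order[fam] = orders[rng.integers(len(orders))]
    genera = []
    genus_family = {}
    genus_ffg = {}
    ffgs = sorted(FFG_VOCABULARY)[: config.n_ffgs]
    for fam in families:
        for g in range(config.n_genera_per_family):
            name = f"{fam}g{g}"
            genera.append(name)
            genus_family[name] = fam
            genus_ffg[name] = ffgs[rng.integers(len(ffgs))]

    if isinstance(config.samples_per_site, int):
        per_site = [config.samples_per_site] * config.n_sites
    else:
        per_site = list(config.samples_per_site)
        if len(per_site) != config.n_sites:
            raise ValueError("samples_per_site list length must equal n_sites")

    rows = []
    for site, n_here in zip(sites, per_site):
        for k in range(n_here):
            genus = genera[rng.integers(len(genera))]
            fam = genus_family[genus]
            hide = rng.random() < config.genus_missing_frac
            rows.append(
                {
                    "sample_id": f"{site}-{k:02d}",
                    "order": fam_order[fam],
                    "family": fam,
                    "genus": None if hide else genus,
                    "site": site,
                    "ffg": genus_ffg[genus],
                    "_true_genus": genus,
                }
            )
    df = pd.DataFrame(rows)
    return df


def _effective_genus(metadata: pd.DataFrame) -> list[str]:
    return [
        g if g is not None and pd.notna(g) else missing_genus_placeholder(f)
        for g, f in zip(metadata["genus"], metadata["family"])
    ]


def generate_counts(
    metadata: pd.DataFrame, config: GeneratorConfig
) -> tuple[CountTable, SyntheticTruth]:
    """Draw an ASV count table from a compositional log-linear model.

    Per-ASV baseline log-abundances are drawn once; each sample's expected
    composition is ``softmax(baseline + site + ffg + family + genus)`` with
    per-level effect vectors drawn ``Normal(0, sigma_factor)`` per ASV.
    Library sizes are lognormal, clipped to ``[depth_min, depth_max]``;
    counts are multinomial.  A bacterial taxonomy lineage is attached to
    every ASV (a fraction is left unassigned at the family rank to exercise
    downstream collapse rules).
    """
    if len(metadata) < 1:
        raise ValueError("metadata must have at least one row")
    if config.n_asvs < 1:
        raise ValueError("n_asvs must be >= 1")
    rng = _rng(config, _STREAM_COUNTS)
    n_asvs = config.n_asvs
    baseline = rng.normal(0.0, config.baseline_log_sd, size=n_asvs)

    # True genus drives selection even when the label is hidden in metadata.
    genus_col = (
        metadata["_true_genus"]
        if "_true_genus" in metadata.columns
        else pd.Series(_effective_genus(metadata), index=metadata.index)
    )
    factor_values = {
        "site": metadata["site"],
        "ffg": metadata["ffg"],
        "family": metadata["family"],
        "genus": genus_col,
    }
    effects: dict[str, dict[str, np.ndarray]] = {}
    for factor in ("site", "ffg", "family", "genus"):
        sigma = config.sigmas[factor]
        effects[factor] = {
            level: rng.normal(0.0, sigma, size=n_asvs)
            for level in sorted(set(factor_values[factor]))
        }

    depths_raw = rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=len(metadata))
    depths = np.clip(np.round(depths_raw), config.depth_min, config.depth_max).astype(np.int64)

    mat = np.zeros((len(metadata), n_asvs), dtype=np.int64)
    for i in range(len(metadata)):
        eta = baseline.copy()
        for factor in ("site", "ffg", "family", "genus"):
            eta = eta + effects[factor][factor_values[factor].iloc[i]]
        eta -= eta.max()
        p = np.exp(eta)
        p /= p.sum()
        mat[i] = rng.multinomial(depths[i], p)

    taxon_ids = [f"ASV{i:04d}" for i in range(n_asvs)]
    taxonomy = {}
    n_mf = config.n_microbial_families
    for i, t in enumerate(taxon_ids):
        mf = int(rng.integers(n_mf))
        unassigned_family = rng.random() < 0.1
        lineage = (
            "Bacteria",
            f"Phylum{mf % 6:02d}",
            f"Class{mf % 12:02d}",
            f"Ord{mf % 20:02d}",
            None if unassigned_family else f"mbFam{mf:03d}",
            None if unassigned_family or rng.random() < 0.3 else f"mbGen{mf:03d}_{i % 3}",
            None,
        )
        taxonomy[t] = lineage

    table = CountTable(
        counts=pd.DataFrame(mat, index=list(metadata["sample_id"]), columns=taxon_ids),
        taxonomy=taxonomy,
    )
    truth = SyntheticTruth(
        config=config,
        effects=effects,
        extra={"baseline": baseline, "depths": dict(zip(metadata["sample_id"], depths.tolist()))},
    )
    return table, truth


def generate_pair_observations(
    levels: dict[str, Sequence[str]],
    config: GeneratorConfig,
    n_obs: int = 1500,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw dissimilarity observations directly from the Beta model.

    Group effects are drawn ``Normal(0, sigma_factor)`` per level; each of
    the ``n_obs`` observations picks one level per factor uniformly at
    random, the mean is the inverse logit of
    ``alpha + a_family + a_genus + a_ffg + a_site``, and the response is
    ``Beta(mu * phi, (1 - mu) * phi)``.

    Returns a DataFrame with columns ``y, family, genus, ffg, site`` plus
    the realized truth.
    """
    if config.phi <= 0:
        raise ValueError("phi must be positive")
    unknown = set(levels) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors: {sorted(unknown)}")
    rng = _rng(config, _STREAM_PAIRS)
    effects: dict[str, dict[str, float]] = {}
    for factor in FACTORS:
        sigma = config.sigmas[factor]
        effects[factor] = {
            str(lv): float(rng.normal(0.0, sigma)) for lv in levels.get(factor, [])
        }

    cols: dict[str, np.ndarray] = {}
    eta = np.full(n_obs, config.alpha, dtype=float)
    for factor in FACTORS:
        lvs = [str(lv) for lv in levels.get(factor, [])]
        if lvs:
            idx = rng.integers(len(lvs), size=n_obs)
            cols[factor] = np.array(lvs, dtype=object)[idx]
            eta += np.array([effects[factor][lv] for lv in lvs])[idx]
        else:
            cols[factor] = np.full(n_obs, "all", dtype=object)
    mu = expit(eta)
    a = mu * config.phi
    b = (1.0 - mu) * config.phi
    y = rng.beta(a, b)
    df = pd.DataFrame({"y": y, **{f: cols[f] for f in FACTORS}})
    truth = SyntheticTruth(config=config, effects=effects, extra={"mu": mu})
    return df, truth
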