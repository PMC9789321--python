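"""Bayesian hierarchical Beta regression for Bray-Curtis beta diversity.

The observation unit is one unordered sample pair with Bray-Curtis value
``y`` in (0, 1).  The model is

    y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)
    logit(mu_i) = alpha + a_family[i] + a_genus[i] + a_ffg[i] + a_site[i]

with varying (partially pooled) intercepts per level of insect family,
genus (qualified within family), functional feeding group, and stream site,
and priors

    alpha ~ Normal(0, 1)
    a_f[l] ~ Normal(0, sigma_f)        sigma_f ~ Exponential(rate 0.5)
    phi ~ Gamma(shape 0.01, rate 0.01)

Because each pair involves two samples, a factor's level for a pair is the
shared label when both samples agree and the sentinel level ``"mixed"``
otherwise; ``"mixed"`` is estimated like any other level.  Model comparison
fits four variants, each promoting one factor to a fixed effect (one
Normal(0, 1) coefficient per level, no pooling) with the rest varying, and
ranks them by WAIC.

Sampling is an adaptive Metropolis-within-Gibbs on the transformed space
(log sigma, log phi, non-centered effects ``a = sigma * z``): levels of a
factor are conditionally independent given everything else, so each
factor's ``z`` vector is updated in one vectorized batch with per-level
accept/reject.  Proposal scales adapt toward ~30% acceptance during warmup
and are frozen afterwards.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp

from .io import DistanceMatrix, missing_genus_placeholder

__all__ = [
    "FACTORS",
    "MIXED",
    "ModelSpec",
    "ParameterVector",
    "PosteriorDraws",
    "build_pair_observations",
    "beta_loglik",
    "log_posterior",
    "sample_posterior",
    "diagnostics",
    "prior_predictive",
    "waic",
    "compare_models",
    "bayes_r2",
    "variance_partition",
    "predict_levels",
    "fit_summary",
]

FACTORS = ("family", "genus", "ffg", "site")
MIXED = "mixed"

# Prior constants (sampler conventions: Exponential by rate, Gamma by
# shape and rate).
_SIGMA_RATE = 0.5
_PHI_SHAPE = 0.01
_PHI_RATE = 0.01


# ---------------------------------------------------------------------------
# Observation construction
# ---------------------------------------------------------------------------


def squeeze_unit_interval(y: np.ndarray, n: int) -> np.ndarray:
    """Smithson-Verkuilen squeeze ``(y (N - 1) + 0.5) / N`` off the boundaries."""
    return (np.asarray(y, dtype=float) * (n - 1) + 0.5) / n


def build_pair_observations(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    boundary_n: int | None = None,
    require_shared: str | None = None,
) -> pd.DataFrame:
    """One observation per unordered sample pair of a distance matrix.

    For each factor the pair's level is the shared label when the two
    samples agree and ``"mixed"`` otherwise.  Genus labels are qualified by
    family (``family/genus``; a missing genus becomes the family-scoped
    placeholder) so identical genus names in different families never
    merge.  Values are squeezed off 0/1 with ``N`` = number of pairs
    (override via ``boundary_n``).

    ``require_shared`` keeps only pairs whose two samples agree on that one
    factor — the alternative construction for fitting per-factor models on
    same-level pairs only.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in dm.ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[dm.ids]
    genus_q = [
        f"{f}/{g}" if g is not None and pd.notna(g) else missing_genus_placeholder(f)
        for f, g in zip(meta["family"], meta["genus"])
    ]
    labels = {
        "family": list(meta["family"]),
        "genus": genus_q,
        "ffg": list(meta["ffg"]),
        "site": list(meta["site"]),
    }
    rows = []
    ids = dm.ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        row = {"sample_a": ids[i], "sample_b": ids[j], "y": dm.data[i, j]}
        for f in FACTORS:
            a, b = labels[f][i], labels[f][j]
            row[f] = a if a == b else MIXED
        rows.append(row)
    df = pd.DataFrame(rows)
    if require_shared is not None:
        if require_shared not in FACTORS:
            raise ValueError(f"unknown factor {require_shared!r}")
        df = df[df[require_shared] != MIXED].reset_index(drop=True)
    n = boundary_n if boundary_n is not None else len(df)
    df["y"] = squeeze_unit_interval(df["y"].to_numpy(), n)
    return df


# ---------------------------------------------------------------------------
# Model specification and data preparation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which factor (if any) is fixed; the rest enter as varying intercepts.

    ``varying_factors`` defaults to the remaining factors of the canonical
    four.  The intercept-only (all-varying) model is
    ``ModelSpec(fixed_factor=None)``.
    """

    fixed_factor: str | None = None
    varying_factors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fixed_factor is not None and self.fixed_factor not in FACTORS:
            raise ValueError(f"unknown factor {self.fixed_factor!r}")
        if self.varying_factors is None:
            object.__setattr__(
                self,
                "varying_factors",
                tuple(f for f in FACTORS if f != self.fixed_factor),
            )
        else:
            vf = tuple(self.varying_factors)
            if self.fixed_factor in vf:
                raise ValueError("fixed factor cannot also vary")
            unknown = set(vf) - set(FACTORS)
            if unknown:
                raise ValueError(f"unknown factors: {sorted(unknown)}")
            object.__setattr__(self, "varying_factors", vf)

    def label(self) -> str:
        return self.fixed_factor if self.fixed_factor else "none"


class _ModelData:
    """Pre-encoded observations: squeezed y, per-factor level codes."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        y = np.asarray(data["y"], dtype=float)
        if len(y) == 0:
            raise ValueError("no observations")
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError("responses must lie strictly in (0, 1); squeeze first")
        self.y = y
        self.log_y = np.log(y)
        self.log_1my = np.log1p(-y)
        self.n = len(y)
        self.levels: dict[str, list[str]] = {}
        self.codes: dict[str, np.ndarray] = {}
        used = list(spec.varying_factors) + ([spec.fixed_factor] if spec.fixed_factor else [])
        for f in used:
            if f not in data.columns:
                raise ValueError(f"observation table lacks factor column {f!r}")
            vals = data[f].astype(str).to_numpy()
            lv = sorted(set(vals))
            code = {l: i for i, l in enumerate(lv)}
            self.levels[f] = lv
            self.codes[f] = np.array([code[v] for v in vals], dtype=np.int64)

    def loglik(self, eta: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta)
        a = mu * phi
        b = phi - a
        return (
            (a - 1.0) * self.log_y
            + (b - 1.0) * self.log_1my
            - (gammaln(a) + gammaln(b) - gammaln(phi))
        )


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def beta_loglik(y, mu, phi) -> np.ndarray | float:
    """Log density of Beta with mean-precision shapes ``(mu phi, (1-mu) phi)``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        raise ValueError("phi must be positive")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly in (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly in (0, 1)")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (a - 1) * np.log(y) + (b - 1) * np.log1p(-y) - (gammaln(a) + gammaln(b) - gammaln(phi))
    return float(out) if out.ndim == 0 else out


@dataclass
class ParameterVector:
    """Natural-scale parameters of one model configuration."""

    alpha: float
    effects: dict[str, np.ndarray]  # varying factor -> per-level effects
    sigma: dict[str, float]  # varying factor -> scale
    phi: float
    fixed_coefs: np.ndarray | None = None  # per-level, if spec has a fixed factor

    def linear_predictor(self, data: _ModelData, spec: ModelSpec) -> np.ndarray:
        eta = np.full(data.n, self.alpha)
        for f in spec.varying_factors:
            eta = eta + np.asarray(self.effects[f])[data.codes[f]]
        if spec.fixed_factor:
            eta = eta + np.asarray(self.fixed_coefs)[data.codes[spec.fixed_factor]]
        return eta


def _norm_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def log_posterior(params: ParameterVector, data, spec: ModelSpec) -> float:
    """Unnormalized log posterior on the natural scale.

    Non-positive ``sigma`` or ``phi`` yield ``-inf`` (rejected) rather than
    an exception, so proposal mechanisms can call this safely.
    """
    if not isinstance(data, _ModelData):
        data = _ModelData(data, spec)
    if params.phi <= 0 or any(params.sigma[f] <= 0 for f in spec.varying_factors):
        return -np.inf
    eta = params.linear_predictor(data, spec)
    lp = float(data.loglik(eta, params.phi).sum())
    lp += float(_norm_logpdf(params.alpha, 1.0))
    for f in spec.varying_factors:
        s = params.sigma[f]
        lp += float(_norm_logpdf(np.asarray(params.effects[f]), s).sum())
        lp += np.log(_SIGMA_RATE) - _SIGMA_RATE * s  # Exponential(rate) prior
    if spec.fixed_factor:
        lp += float(_norm_logpdf(np.asarray(params.fixed_coefs), 1.0).sum())
    a, b = _PHI_SHAPE, _PHI_RATE
    lp += a * np.log(b) - gammaln(a) + (a - 1) * np.log(params.phi) - b * params.phi
    return lp


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Post-warmup draws, ``chains x iterations x parameters``, with names."""

    draws: np.ndarray
    names: list[str]
    seed: int
    spec: ModelSpec
    levels: dict[str, list[str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate parameter names")
        self._idx = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def param(self, name: str) -> np.ndarray:
        return self.draws[:, :, self._idx[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.param(name).reshape(-1)


def _adapt_step(t: int) -> float:
    return min(0.25, 2.0 / np.sqrt(t + 10))


def sample_posterior(
    data: pd.DataFrame,
    spec: ModelSpec,
    chains: int = 4,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
) -> PosteriorDraws:
    """Adaptive Metropolis-within-Gibbs sampler for the Beta regression.

    ``iterations`` counts total sweeps per chain; the first ``warmup`` are
    used for proposal-scale adaptation and discarded.  Group effects use
    the non-centered parameterization ``a = sigma * z`` with ``z`` updated
    per factor in a vectorized batch; ``sigma`` and ``phi`` are sampled on
    the log scale with the Jacobian folded into the target.
    """
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    md = _ModelData(data, spec)
    kept = iterations - warmup
    vf = list(spec.varying_factors)
    ff = spec.fixed_factor

    names = ["alpha"]
    for f in vf:
        names += [f"a_{f}[{l}]" for l in md.levels[f]]
        names.append(f"sigma_{f}")
    if ff:
        names += [f"b_{ff}[{l}]" for l in md.levels[ff]]
    names.append("phi")
    out = np.empty((chains, kept, len(names)))
    accept_info: dict[str, float] = {}

    mean_y = float(md.y.mean())
    var_y = float(md.y.var()) or 1e-4
    phi_init = max(mean_y * (1 - mean_y) / var_y - 1.0, 2.0)

    for chain in range(chains):
        rng = np.random.default_rng([int(seed), 17, chain])
        # --- initialization with jittered restarts -----------------------
        for attempt in range(100):
            alpha = float(logit(mean_y)) + 0.2 * rng.normal()
            z = {f: 0.1 * rng.normal(size=len(md.levels[f])) for f in vf}
            log_sigma = {f: np.log(0.3) + 0.3 * rng.normal() for f in vf}
            beta = 0.1 * rng.normal(size=len(md.levels[ff])) if ff else None
            log_phi = float(np.log(phi_init) + 0.2 * rng.normal())
            sigma = {f: float(np.exp(log_sigma[f])) for f in vf}
            phi = float(np.exp(log_phi))
            eta = np.full(md.n, alpha)
            for f in vf:
                eta = eta + sigma[f] * z[f][md.codes[f]]
            if ff:
                eta = eta + beta[md.codes[ff]]
            ll = md.loglik(eta, phi)
            if np.all(np.isfinite(ll)):
                break
        else:
            raise RuntimeError("could not find a finite starting point in 100 attempts")

        # proposal scales
        s_alpha, s_phi = 0.1, 0.2
        s_z = {f: np.full(len(md.levels[f]), 0.3) for f in vf}
        s_sigma = {f: 0.3 for f in vf}
        s_shift = {f: 0.2 for f in vf}
        s_scale = {f: 0.2 for f in vf}
        s_beta = np.full(len(md.levels[ff]), 0.3) if ff else None
        n_acc = {"alpha": 0.0, "phi": 0.0}

        for t in range(iterations):
            g = _adapt_step(t) if t < warmup else 0.0

            # alpha ------------------------------------------------------
            da = s_alpha * rng.normal()
            eta2 = eta + da
            ll2 = md.loglik(eta2, phi)
            dlp = (ll2.sum() - ll.sum()) - 0.5 * ((alpha + da) ** 2 - alpha**2)
            acc = np.log(rng.random()) < dlp
            if acc:
                alpha, eta, ll = alpha + da, eta2, ll2
            if g:
                s_alpha *= np.exp(g * (float(acc) - 0.3))
            n_acc["alpha"] += float(acc)

            # varying effects (batched per factor) -----------------------
            for f in vf:
                codes = md.codes[f]
                dz = s_z[f] * rng.normal(size=len(s_z[f]))
                eta2 = eta + sigma[f] * dz[codes]
                ll2 = md.loglik(eta2, phi)
                dl = np.bincount(codes, weights=ll2 - ll, minlength=len(dz))
                dl += -0.5 * ((z[f] + dz) ** 2 - z[f] ** 2)
                acc_v = np.log(rng.random(size=len(dz))) < dl
                if acc_v.any():
                    z[f] = np.where(acc_v, z[f] + dz, z[f])
                    m = acc_v[codes]
                    eta[m] = eta2[m]
                    ll[m] = ll2[m]
                if g:
                    s_z[f] *= np.exp(g * (acc_v.astype(float) - 0.3))

            # likelihood-invariant moves ---------------------------------
            # (a) translation: alpha' = alpha + d, z_f' = z_f - d/sigma_f
            #     leaves eta untouched (each obs has one level per factor),
            #     so only the priors enter; samples the soft direction
            #     between the grand mean and a factor's level means.
            # (b) interweave: sigma_f' = sigma_f e^t, z_f' = z_f e^-t keeps
            #     the effects fixed; Jacobian e^{-Lt} on the z block.
            for f in vf:
                d = s_shift[f] * rng.normal()
                z2 = z[f] - d / sigma[f]
                dlp = (
                    -0.5 * ((alpha + d) ** 2 - alpha**2)
                    - 0.5 * (np.sum(z2**2) - np.sum(z[f] ** 2))
                )
                acc = np.log(rng.random()) < dlp
                if acc:
                    alpha += d
                    z[f] = z2
                if g:
                    s_shift[f] *= np.exp(g * (float(acc) - 0.3))

                tmove = s_scale[f] * rng.normal()
                sig2 = float(np.exp(log_sigma[f] + tmove))
                z2 = z[f] * np.exp(-tmove)
                lf = len(z2)
                dlp = (
                    -0.5 * (np.sum(z2**2) - np.sum(z[f] ** 2))
                    - _SIGMA_RATE * (sig2 - sigma[f])
                    + tmove
                    - lf * tmove
                )
                acc = np.log(rng.random()) < dlp
                if acc:
                    log_sigma[f] += tmove
                    sigma[f] = sig2
                    z[f] = z2
                if g:
                    s_scale[f] *= np.exp(g * (float(acc) - 0.3))

            # sigma (log scale) ------------------------------------------
            for f in vf:
                dls = s_sigma[f] * rng.normal()
                sig2 = float(np.exp(log_sigma[f] + dls))
                eta2 = eta + (sig2 - sigma[f]) * z[f][md.codes[f]]
                ll2 = md.loglik(eta2, phi)
                # Exponential(rate) prior + log-scale Jacobian
                dlp = (ll2.sum() - ll.sum()) - _SIGMA_RATE * (sig2 - sigma[f]) + dls
                acc = np.log(rng.random()) < dlp
                if acc:
                    log_sigma[f] += dls
                    sigma[f] = sig2
                    eta, ll = eta2, ll2
                if g:
                    s_sigma[f] *= np.exp(g * (float(acc) - 0.3))

            # fixed coefficients (batched) -------------------------------
            if ff:
                codes = md.codes[ff]
                db = s_beta * rng.normal(size=len(s_beta))
                eta2 = eta + db[codes]
                ll2 = md.loglik(eta2, phi)
                dl = np.bincount(codes, weights=ll2 - ll, minlength=len(db))
                dl += -0.5 * ((beta + db) ** 2 - beta**2)
                acc_v = np.log(rng.random(size=len(db))) < dl
                if acc_v.any():
                    beta = np.where(acc_v, beta + db, beta)
                    m = acc_v[codes]
                    eta[m] = eta2[m]
                    ll[m] = ll2[m]
                if g:
                    s_beta *= np.exp(g * (acc_v.astype(float) - 0.3))

            # phi (log scale) --------------------------------------------
            dlp_step = s_phi * rng.normal()
            phi2 = float(np.exp(log_phi + dlp_step))
            ll2 = md.loglik(eta, phi2)
            dlp = (ll2.sum() - ll.sum()) + _PHI_SHAPE * dlp_step - _PHI_RATE * (phi2 - phi)
            acc = np.log(rng.random()) < dlp
            if acc:
                log_phi += dlp_step
                phi = phi2
                ll = ll2
            if g:
                s_phi *= np.exp(g * (float(acc) - 0.3))
            n_acc["phi"] += float(acc)

            # record -----------------------------------------------------
            if t >= warmup:
                rowvals = [alpha]
                for f in vf:
                    rowvals.extend(sigma[f] * z[f])
                    rowvals.append(sigma[f])
                if ff:
                    rowvals.extend(beta)
                rowvals.append(phi)
                out[chain, t - warmup] = rowvals

        accept_info[f"chain{chain}_alpha"] = n_acc["alpha"] / iterations
        accept_info[f"chain{chain}_phi"] = n_acc["phi"] / iterations

    return PosteriorDraws(
        draws=out,
        names=names,
        seed=seed,
        spec=spec,
        levels={f: md.levels[f] for f in md.levels},
        meta={
            "acceptance": accept_info,
            "chains": chains,
            "iterations": iterations,
            "warmup": warmup,
            "n_obs": md.n,
        },
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain R-hat (no rank normalization) for one parameter, chains x draws."""
    c, s = x.shape
    half = s // 2
    if half < 2:
        raise ValueError("need at least 4 post-warmup draws for split R-hat")
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        return np.nan
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via chain-averaged autocorrelation with Geyer
    initial-monotone truncation."""
    c, s = x.shape
    if s < 4:
        return float("nan")
    acov = np.zeros(s)
    for ch in range(c):
        v = x[ch] - x[ch].mean()
        f = np.fft.rfft(v, n=2 * s)
        ac = np.fft.irfft(f * np.conj(f))[:s] / s
        acov += ac
    acov /= c
    if acov[0] == 0:
        return float("nan")
    rho = acov / acov[0]
    # Geyer: sum consecutive pairs while positive and non-increasing
    tau = 1.0
    prev = np.inf
    for t in range(1, s - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += 2 * pair
        prev = pair
    return float(c * s / tau)


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter split R-hat and effective sample size.

    Parameters constant across all draws are flagged (``constant=True``)
    with R-hat reported as NaN.
    """
    if draws.n_chains < 2:
        raise ValueError("diagnostics need at least two chains")
    if draws.n_draws < 4:
        raise ValueError("diagnostics need at least 4 post-warmup draws")
    rows = []
    for name in draws.names:
        x = draws.param(name)
        const = bool(np.all(x == x.reshape(-1)[0]))
        rows.append(
            {
                "parameter": name,
                "rhat": np.nan if const else _split_rhat(x),
                "ess": np.nan if const else _ess(x),
                "constant": const,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Prior predictive
# ---------------------------------------------------------------------------


def prior_predictive(
    spec: ModelSpec,
    levels: dict[str, list[str]],
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Simulate responses from the prior: parameters from their priors,
    then one y per draw from the Beta likelihood at uniformly chosen levels."""
    rng = np.random.default_rng([int(seed), 29])
    alpha = rng.normal(0.0, 1.0, size=n_draws)
    eta = alpha.copy()
    sigmas = {}
    for f in spec.varying_factors:
        lv = levels.get(f, [])
        s = rng.exponential(1.0 / _SIGMA_RATE, size=n_draws)
        sigmas[f] = s
        if lv:
            effects = rng.normal(0.0, s[:, None], size=(n_draws, len(lv)))
            pick = rng.integers(len(lv), size=n_draws)
            eta += effects[np.arange(n_draws), pick]
    if spec.fixed_factor:
        lv = levels.get(spec.fixed_factor, [])
        if lv:
            coefs = rng.normal(0.0, 1.0, size=(n_draws, len(lv)))
            pick = rng.integers(len(lv), size=n_draws)
            eta += coefs[np.arange(n_draws), pick]
    phi = rng.gamma(_PHI_SHAPE, 1.0 / _PHI_RATE, size=n_draws)
    phi = np.maximum(phi, 1e-300)
    mu = expit(eta)
    y = rng.beta(np.maximum(mu * phi, 1e-300), np.maximum((1 - mu) * phi, 1e-300))
    # the diffuse phi prior yields draws that round to exactly 0/1 in double
    # precision; nudge those to the nearest representable interior value so
    # the (0, 1) support contract holds numerically
    y = np.clip(y, 1e-12, 1 - 1e-12)
    return {"y": y, "alpha": alpha, "sigma": sigmas, "phi": phi, "mu": mu}


# ---------------------------------------------------------------------------
# Pointwise log-likelihood, WAIC, R2
# ---------------------------------------------------------------------------


def _pointwise_loglik(draws: PosteriorDraws, data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Matrix of log p(y_i | draw_s), shape (total draws, n observations)."""
    md = _ModelData(data, spec)
    c, s, _ = draws.draws.shape
    total = c * s
    flat = draws.draws.reshape(total, -1)
    idx = {n: i for i, n in enumerate(draws.names)}
    eta = np.tile(flat[:, idx["alpha"]][:, None], (1, md.n))
    for f in spec.varying_factors:
        a = flat[:, [idx[f"a_{f}[{l}]"] for l in draws.levels[f]]]
        eta += a[:, md.codes[f]]
    if spec.fixed_factor:
        b = flat[:, [idx[f"b_{spec.fixed_factor}[{l}]"] for l in draws.levels[spec.fixed_factor]]]
        eta += b[:, md.codes[spec.fixed_factor]]
    phi = flat[:, idx["phi"]][:, None]
    mu = expit(eta)
    a_ = mu * phi
    b_ = phi - a_
    ll = (
        (a_ - 1) * md.log_y[None, :]
        + (b_ - 1) * md.log_1my[None, :]
        - (gammaln(a_) + gammaln(b_) - gammaln(phi))
    )
    if not np.all(np.isfinite(ll)):
        bad = int(np.argwhere(~np.isfinite(ll))[0][1])
        raise ValueError(f"non-finite pointwise log-likelihood at observation {bad}")
    return ll


def waic(draws: PosteriorDraws, data: pd.DataFrame, spec: ModelSpec):
    """WAIC on the deviance scale with pointwise contributions.

    ``lppd_i = log mean_s exp(loglik_is)`` (log-sum-exp stabilized),
    ``p_i = var_s loglik_is``; ``WAIC = -2 (lppd - p_waic)``.
    """
    ll = _pointwise_loglik(draws, data, spec)
    s = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(ll.shape[1])
    waic_i = -2.0 * (lppd_i - p_i)
    return (
        float(waic_i.sum()),
        float(lppd_i.sum()),
        float(p_i.sum()),
        pd.DataFrame({"lppd": lppd_i, "p_waic": p_i, "waic": waic_i}),
    )


def bayes_r2(draws: PosteriorDraws, data: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """Posterior mean and SD of the Bayesian R-squared.

    Per draw, ``R2 = var_i(mu_i) / (var_i(mu_i) + mean_i(mu_i (1-mu_i) / (1+phi)))``.
    """
    md = _ModelData(data, spec)
    c, s, _ = draws.draws.shape
    flat = draws.draws.reshape(c * s, -1)
    idx = {n: i for i, n in enumerate(draws.names)}
    eta = np.tile(flat[:, idx["alpha"]][:, None], (1, md.n))
    for f in spec.varying_factors:
        a = flat[:, [idx[f"a_{f}[{l}]"] for l in draws.levels[f]]]
        eta += a[:, md.codes[f]]
    if spec.fixed_factor:
        b = flat[:, [idx[f"b_{spec.fixed_factor}[{l}]"] for l in draws.levels[spec.fixed_factor]]]
        eta += b[:, md.codes[spec.fixed_factor]]
    phi = flat[:, idx["phi"]]
    mu = expit(eta)
    var_mu = mu.var(axis=1, ddof=1)
    resid = (mu * (1 - mu) / (1 + phi[:, None])).mean(axis=1)
    r2 = np.where(var_mu + resid > 0, var_mu / (var_mu + resid), 0.0)
    return float(r2.mean()), float(r2.std(ddof=1)) if len(r2) > 1 else 0.0


def compare_models(fits: list[tuple[ModelSpec, PosteriorDraws]], data: pd.DataFrame) -> pd.DataFrame:
    """Rank fitted models by WAIC with pairwise-difference standard errors.

    ``SE(delta) = sqrt(n * var_i(waic_i_model - waic_i_best))``; the best
    model's delta and SE are 0.  All fits must share the observation set.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    pointwise = []
    n_obs = None
    for spec, draws in fits:
        fit_n = draws.meta.get("n_obs")
        if fit_n is not None and fit_n != len(data):
            raise ValueError(
                f"fit with fixed={spec.label()!r} was sampled on {fit_n} observations, "
                f"comparison data has {len(data)}"
            )
        w, lppd, p, pw = waic(draws, data, spec)
        if n_obs is None:
            n_obs = len(pw)
        elif len(pw) != n_obs:
            raise ValueError("fits computed on different observation sets")
        r2_mean, r2_sd = bayes_r2(draws, data, spec)
        rows.append(
            {
                "fixed": spec.label(),
                "random": ",".join(spec.varying_factors),
                "waic": w,
                "lppd": lppd,
                "p_waic": p,
                "r2": r2_mean,
                "se_r2": r2_sd,
            }
        )
        pointwise.append(pw["waic"].to_numpy())
    df = pd.DataFrame(rows)
    best = int(df["waic"].idxmin())
    deltas, ses = [], []
    for i in range(len(df)):
        diff = pointwise[i] - pointwise[best]
        deltas.append(df.loc[i, "waic"] - df.loc[best, "waic"])
        ses.append(0.0 if i == best else float(np.sqrt(n_obs * diff.var(ddof=1))))
    df["waic_delta"] = deltas
    df["se_waic_delta"] = ses
    return df.sort_values("waic", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Variance partitioning and predictions
# ---------------------------------------------------------------------------


def variance_partition(draws: PosteriorDraws) -> dict:
    """Posterior summaries of the four group-level SDs with ranking probabilities.

    Requires a fit of the intercept-only (all-varying) model.
    """
    missing = [f for f in FACTORS if f"sigma_{f}" not in draws.names]
    if missing:
        raise ValueError(f"draws lack sigma parameters for: {missing}")
    sig = {f: draws.flat(f"sigma_{f}") for f in FACTORS}
    summary = {
        f: {
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)),
            "q2.5": float(np.quantile(s, 0.025)),
            "q50": float(np.quantile(s, 0.5)),
            "q97.5": float(np.quantile(s, 0.975)),
        }
        for f, s in sig.items()
    }
    pr_greater = {
        f"{a}>{b}": float((sig[a] > sig[b]).mean())
        for a in FACTORS
        for b in FACTORS
        if a != b
    }
    stack = np.stack([sig[f] for f in FACTORS])
    arg = stack.argmax(axis=0)
    pr_largest = {f: float((arg == i).mean()) for i, f in enumerate(FACTORS)}
    return {"summary": summary, "pr_greater": pr_greater, "pr_largest": pr_largest}


def predict_levels(
    draws: PosteriorDraws,
    spec: ModelSpec,
    factor: str,
    level: str | None = None,
    seed: int = 0,
) -> dict:
    """Posterior (predictive) mean Bray-Curtis for one level of a factor.

    For an observed level the summary is of ``invlogit(alpha + a[level])``;
    for ``level=None`` (a new, unobserved level) the effect is drawn
    ``Normal(0, sigma_factor)`` per posterior draw, widening the interval
    by the between-level variance.
    """
    if factor not in spec.varying_factors:
        raise ValueError(f"{factor!r} is not a varying factor of this model")
    alpha = draws.flat("alpha")
    if level is not None:
        name = f"a_{factor}[{level}]"
        if name not in draws.names:
            raise ValueError(f"unknown level {level!r} for factor {factor!r}")
        eta = alpha + draws.flat(name)
    else:
        rng = np.random.default_rng([int(seed), 31])
        sig = draws.flat(f"sigma_{factor}")
        eta = alpha + rng.normal(0.0, sig)
    mu = expit(eta)
    return {
        "mean": float(mu.mean()),
        "median": float(np.quantile(mu, 0.5)),
        "q2.5": float(np.quantile(mu, 0.025)),
        "q97.5": float(np.quantile(mu, 0.975)),
    }


def fit_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean/SD/2.5%/50%/97.5% plus split R-hat and ESS per parameter."""
    diag = diagnostics(draws)
    rows = []
    for name in draws.names:
        x = draws.flat(name)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q50": float(np.quantile(x, 0.5)),
                "q97.5": float(np.quantile(x, 0.975)),
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    return df.join(diag)
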