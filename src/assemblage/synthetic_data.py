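"""Seeded community generators with known assembly process and planted guilds.

Two generative processes are provided and can be mixed per dataset:

* a neutral process — Moran-type birth/death dynamics in a local community of
  ``N`` individuals receiving immigrants from a fixed metacommunity with
  probability ``m`` per death — whose stationary behaviour matches the
  occurrence-frequency model fitted by :mod:`assemblage.ncm`;
* a niche process — per-taxon Gaussian responses to a scalar environmental
  value per sample, so narrow-tolerance taxa concentrate in few samples and
  wide-tolerance taxa spread evenly.

Mixing happens on expected per-sample weights (convex combination with weight
``lam``), after which reads are drawn multinomially at the configured depth;
the multinomial noise model is therefore identical across the process mix.
Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from assemblage.io_tables import CommunityTable, register_result


@dataclass(frozen=True)
class Metacommunity:
    """Regional relative abundances ``p`` over S taxa (descending, sum 1)."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("p must be a 1-D vector with at least 2 taxa")
        if (p <= 0).any():
            raise ValueError("metacommunity abundances must be positive")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("metacommunity abundances must sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def n_taxa(self) -> int:
        return self.p.size


@dataclass(frozen=True)
class NeutralSimConfig:
    S: int
    N: int = 1000
    m: float = 0.1
    burn_in_steps: int | None = None  # default 10 * N
    n_samples: int = 18
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must lie in [0, 1], got {self.m}")
        if self.N < 10:
            raise ValueError(f"N must be >= 10, got {self.N}")
        if self.depth < 100:
            raise ValueError(f"depth must be >= 100, got {self.depth}")

    @property
    def effective_burn_in(self) -> int:
        return 10 * self.N if self.burn_in_steps is None else self.burn_in_steps


@dataclass(frozen=True)
class NicheSimConfig:
    """Gaussian environmental-response sampling configuration.

    ``env`` holds one scalar environmental value per sample; ``optima`` and
    ``tolerances`` one value per taxon (``tolerances`` strictly positive, use
    ``np.inf`` for a flat response).
    """

    env: np.ndarray
    optima: np.ndarray
    tolerances: np.ndarray
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self):
        env = np.asarray(self.env, dtype=float)
        opt = np.asarray(self.optima, dtype=float)
        tol = np.asarray(self.tolerances, dtype=float)
        if not np.isfinite(env).all():
            raise ValueError("environmental values must be finite")
        if (tol <= 0).any():
            raise ValueError("niche tolerances must be strictly positive")
        if opt.shape != tol.shape:
            raise ValueError("optima and tolerances must have equal shape")
        object.__setattr__(self, "env", env)
        object.__setattr__(self, "optima", opt)
        object.__setattr__(self, "tolerances", tol)


@register_result
@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic dataset."""

    guild: tuple[str, ...]  # per-taxon: generalist / specialist / intermediate
    lam: float
    m: float
    N: int

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        bad = set(self.guild) - {"generalist", "specialist", "intermediate"}
        if bad:
            raise ValueError(f"unknown guild labels: {sorted(bad)}")
        object.__setattr__(self, "guild", tuple(self.guild))


@dataclass(frozen=True)
class GuildPlan:
    """Counts of planted wide-niche (generalist) and narrow-niche
    (specialist) taxa; remaining taxa get intermediate background niches."""

    n_wide: int = 0
    n_narrow: int = 0


def simulate_metacommunity(
    S: int, mu_log: float = 0.0, sigma_log: float = 1.0, seed: int = 0
) -> Metacommunity:
    """Lognormal rank-abundance metacommunity, sorted descending.

    ``sigma_log == 0`` degenerates to the uniform metacommunity 1/S.
    """
    if S < 2:
        raise ValueError(f"S must be >= 2, got {S}")
    if sigma_log < 0:
        raise ValueError(f"sigma_log must be >= 0, got {sigma_log}")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=mu_log, sigma=sigma_log, size=S)
    p = np.sort(draws)[::-1]
    return Metacommunity(p=p / p.sum())


def _moran_community(
    p: np.ndarray, N: int, m: float, burn_in: int, rng: np.random.Generator
) -> np.ndarray:
    """Run Moran birth/death dynamics, returning local counts per taxon.

    One step: a uniformly chosen individual dies and is replaced either by an
    immigrant drawn from ``p`` (probability ``m``) or by a copy of a random
    surviving local individual.
    """
    S = p.size
    community = rng.choice(S, size=N, p=p)  # multinomial initialization
    if burn_in == 0:
        return np.bincount(community, minlength=S)
    deaths = rng.integers(0, N, size=burn_in)
    immigrate = rng.random(burn_in) < m
    cum_p = np.cumsum(p)
    immigrants = np.searchsorted(cum_p, rng.random(burn_in))
    copies = rng.integers(0, N - 1, size=burn_in)
    com = community  # local alias; tight loop below dominates runtime
    for t in range(burn_in):
        i = deaths[t]
        if immigrate[t]:
            com[i] = immigrants[t]
        else:
            j = copies[t]
            if j >= i:
                j += 1
            com[i] = com[j]
    return np.bincount(com, minlength=S)


def simulate_neutral_sample(meta: Metacommunity, cfg: NeutralSimConfig) -> np.ndarray:
    """One sequenced sample from a neutral local community.

    Returns a count vector summing exactly to ``cfg.depth``: multinomial reads
    drawn from the local community's relative abundances after burn-in.
    """
    if cfg.S != meta.n_taxa:
        raise ValueError(f"cfg.S={cfg.S} does not match metacommunity size {meta.n_taxa}")
    rng = np.random.default_rng(cfg.seed)
    local = _moran_community(meta.p, cfg.N, cfg.m, cfg.effective_burn_in, rng)
    return rng.multinomial(cfg.depth, local / local.sum())


def niche_weights(
    p: np.ndarray, env: np.ndarray, optima: np.ndarray, tolerances: np.ndarray
) -> np.ndarray:
    """Expected per-sample weights ``w[k, j] ∝ p_k·exp(−(env_j−opt_k)²/2σ_k²)``,
    normalized within each sample."""
    with np.errstate(under="ignore"):
        resp = np.exp(
            -((env[None, :] - optima[:, None]) ** 2) / (2.0 * tolerances[:, None] ** 2)
        )
    w = p[:, None] * resp
    totals = w.sum(axis=0)
    if (totals == 0).any():
        bad = np.nonzero(totals == 0)[0].tolist()
        raise ValueError(
            f"all niche weights vanish in samples {bad}; optima/tolerances are "
            "pathological for the given environments"
        )
    return w / totals


def simulate_niche_sample(
    meta: Metacommunity, cfg: NicheSimConfig, sample_index: int
) -> np.ndarray:
    """One sequenced sample under pure Gaussian environmental filtering."""
    w = niche_weights(meta.p, cfg.env, cfg.optima, cfg.tolerances)
    rng = np.random.default_rng((cfg.seed, sample_index))
    return rng.multinomial(cfg.depth, w[:, sample_index])


def simulate_dataset(
    S: int,
    groups: dict[str, int],
    lam: float,
    guild_plan: GuildPlan | None = None,
    depth: int = 10_000,
    seed: int = 0,
    *,
    mu_log: float = 0.0,
    sigma_log: float = 1.0,
    m: float = 0.1,
    N: int = 1000,
    burn_in_steps: int | None = None,
    env_range: tuple[float, float] = (-2.0, 2.0),
    background_sigma: float = 0.6,
    narrow_sigma: float = 0.05,
    planted_floor: float = 3.0,
    lam_per_taxon: np.ndarray | None = None,
) -> tuple[CommunityTable, SyntheticTruth]:
    """Generate a multi-group dataset mixing neutral and niche assembly.

    Per-sample expected weights are the convex combination
    ``(1−lam)·neutral + lam·niche``; reads are drawn multinomially at
    ``depth``. The neutral component is the drifted local community of an
    independent Moran run per sample; the niche component uses Gaussian
    responses to a per-group environmental gradient spanning ``env_range``.

    ``lam_per_taxon`` optionally overrides the scalar mix with one weight per
    taxon, letting different guilds follow different assembly processes
    (e.g. neutral generalists alongside filtered specialists); the reported
    truth ``lam`` stays the scalar argument.

    ``guild_plan`` plants ``n_wide`` flat-response taxa (labelled generalist)
    and ``n_narrow`` taxa with tolerance ``narrow_sigma`` whose optima sit
    exactly on sample environments (labelled specialist). Planted taxa are
    raised to at least ``planted_floor`` times the median metacommunity
    abundance so they stay observable at the configured depth.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    if lam_per_taxon is not None:
        lam_per_taxon = np.asarray(lam_per_taxon, dtype=float)
        if lam_per_taxon.shape != (S,):
            raise ValueError(f"lam_per_taxon must have shape ({S},)")
        if ((lam_per_taxon < 0) | (lam_per_taxon > 1)).any():
            raise ValueError("lam_per_taxon entries must lie in [0, 1]")
    guild_plan = guild_plan or GuildPlan()
    n_planted = guild_plan.n_wide + guild_plan.n_narrow
    if n_planted > S:
        raise ValueError(
            f"guild plan ({n_planted} planted taxa) exceeds S={S}"
        )
    rng = np.random.default_rng(seed)

    draws = rng.lognormal(mean=mu_log, sigma=sigma_log, size=S)
    p = draws / draws.sum()
    if n_planted and planted_floor > 0:
        floor = planted_floor * np.median(p)
        p[:n_planted] = np.maximum(p[:n_planted], floor)
        p = p / p.sum()

    wide_idx = np.arange(guild_plan.n_wide)
    narrow_idx = np.arange(guild_plan.n_wide, n_planted)
    bg_idx = np.arange(n_planted, S)
    guild = np.array(["intermediate"] * S, dtype=object)
    guild[wide_idx] = "generalist"
    guild[narrow_idx] = "specialist"

    env_lo, env_hi = env_range
    optima = np.empty(S)
    tolerances = np.empty(S)
    tolerances[wide_idx] = np.inf
    optima[wide_idx] = 0.0
    tolerances[narrow_idx] = narrow_sigma
    tolerances[bg_idx] = background_sigma
    optima[bg_idx] = rng.normal(0.0, 0.75 * (env_hi - env_lo) / 2.0, size=bg_idx.size)

    burn = 10 * N if burn_in_steps is None else burn_in_steps
    counts_cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    group_map: dict[str, str] = {}
    for g_name in groups:
        n_g = groups[g_name]
        env_g = np.linspace(env_lo, env_hi, n_g) if n_g > 1 else np.array([0.0])
        # narrow taxa lock onto actual sample environments (cycled)
        optima[narrow_idx] = env_g[np.arange(narrow_idx.size) % n_g]
        w_niche = niche_weights(p, env_g, optima, tolerances)
        lam_vec = np.full(S, lam) if lam_per_taxon is None else lam_per_taxon
        for j in range(n_g):
            if (lam_vec < 1.0).any():
                local = _moran_community(p, N, m, burn, rng)
                w_neutral = local / local.sum()
            else:
                w_neutral = 0.0  # pure niche: neutral weight unused
            w = (1.0 - lam_vec) * w_neutral + lam_vec * w_niche[:, j]
            w = w / w.sum()
            counts_cols.append(rng.multinomial(depth, w))
            sid = f"{g_name}_s{j + 1}"
            sample_ids.append(sid)
            group_map[sid] = g_name

    table = CommunityTable(
        counts=np.stack(counts_cols, axis=1),
        otu_ids=tuple(f"OTU_{k + 1:04d}" for k in range(S)),
        sample_ids=tuple(sample_ids),
        groups=group_map,
    )
    truth = SyntheticTruth(guild=tuple(guild), lam=lam, m=m, N=N)
    return table, truth


def inject_correlated_pair(
    table: CommunityTable,
    otu_a: str,
    otu_b: str,
    sign: str = "+",
    strength: float = 0.9,
    seed: int = 0,
) -> CommunityTable:
    """Resample two rows through a Gaussian copula with correlation
    ``±strength``, preserving each row's original count multiset (marginal
    abundance distributions, hence diversity statistics, are unchanged)."""
    if not 0.0 < strength <= 1.0:
        raise ValueError(f"strength must lie in (0, 1], got {strength}")
    if sign not in ("+", "-"):
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    for otu in (otu_a, otu_b):
        if otu not in table.otu_ids:
            raise KeyError(f"unknown OTU id {otu!r}")
    rng = np.random.default_rng(seed)
    rho = strength if sign == "+" else -strength
    n = table.n_samples
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)  # svd handles |rho| = 1
    ia = table.otu_ids.index(otu_a)
    ib = table.otu_ids.index(otu_b)
    counts = table.counts.copy()
    for row_idx, latent in ((ia, z[:, 0]), (ib, z[:, 1])):
        sorted_vals = np.sort(counts[row_idx])
        ranks = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
        counts[row_idx] = sorted_vals[ranks]
    return CommunityTable(
        counts=counts,
        otu_ids=table.otu_ids,
        sample_ids=table.sample_ids,
        groups=table.groups,
    )
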