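"""Levins niche breadth and generalist/specialist classification.

Breadth of taxon *i* over *r* sites is ``B_i = 1 / sum_j P_ij**2`` where
``P_i.`` is the taxon's proportional abundance across sites (non-negative,
summing to 1); B ranges from 1 (single site) to r (perfectly even).

Classification compares each taxon's observed breadth — computed on
per-sample relative abundances, then normalized within the taxon — to the
2.5%/97.5% quantiles of a permutation null. Observed breadth strictly above
the band is a generalist, strictly below a specialist, anything else
(including a degenerate band) non-significant.

Null schemes
------------
``taxon_shuffle`` (default)
    Permutes the assignment of abundance profiles to taxon identities and
    shuffles each profile across samples. Under the null, niche breadth is
    exchangeable across taxa, so each taxon is compared against the breadth
    a community-typical profile would show; this detects taxa both more even
    and more concentrated than the community background, and is exactly
    degenerate (hence silent) on tables with identical columns.
``row_shuffle``
    Independently permutes each taxon's counts across samples. Preserves
    every taxon's abundance multiset; breadth varies only through the
    induced column-total noise, so this scheme has essentially no power and
    is retained for sensitivity analysis.
``column_label_permute``
    Permutes sample labels jointly. Breadth is invariant under relabelling,
    so the null is fully degenerate; retained as a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from assemblage.io_tables import CommunityTable, register_result

NULL_SCHEMES = ("taxon_shuffle", "row_shuffle", "column_label_permute")

GENERALIST = "generalist"
SPECIALIST = "specialist"
NON_SIGNIFICANT = "non_significant"


@register_result
@dataclass(frozen=True)
class GuildClassification:
    """Per-OTU observed breadth, null band and guild label."""

    otu_ids: tuple[str, ...]
    b_obs: tuple[float, ...]
    low_ci: tuple[float, ...]
    upp_ci: tuple[float, ...]
    guild: tuple[str, ...]
    n_perm: int
    r: int  # number of sites used
    scheme: str = "taxon_shuffle"
    seed: int | None = None

    def __post_init__(self):
        for name in ("otu_ids", "b_obs", "low_ci", "upp_ci", "guild"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        n = len(self.otu_ids)
        if any(len(getattr(self, f)) != n for f in ("b_obs", "low_ci", "upp_ci", "guild")):
            raise ValueError("per-OTU fields must have equal length")

    def members(self, guild: str) -> tuple[str, ...]:
        return tuple(o for o, g in zip(self.otu_ids, self.guild) if g == guild)

    def label_of(self, otu_id: str) -> str:
        return self.guild[self.otu_ids.index(otu_id)]

    def counts(self) -> dict[str, int]:
        out = {GENERALIST: 0, SPECIALIST: 0, NON_SIGNIFICANT: 0}
        for g in self.guild:
            out[g] += 1
        return out


def levins_breadth(row_proportions: np.ndarray) -> float:
    """``B = 1 / sum(P**2)`` for one taxon's site proportions (sum 1)."""
    p = np.asarray(row_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("breadth undefined for an all-zero vector")
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {total}")
    return float(1.0 / np.square(p).sum())


def _breadths_from_counts(counts: np.ndarray) -> np.ndarray:
    """Breadths for every row of a count matrix.

    Counts are first normalized per sample (columns with zero total yield
    zero contributions), then each row is normalized to proportions. Rows
    with zero total get NaN.
    """
    col_totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        relab = np.where(col_totals > 0, counts / col_totals, 0.0)
        row_totals = relab.sum(axis=1, keepdims=True)
        props = np.where(row_totals > 0, relab / row_totals, np.nan)
        return 1.0 / np.square(props).sum(axis=1)


def observed_breadths(table: CommunityTable) -> np.ndarray:
    """Observed Levins breadth per OTU (NaN for all-zero rows)."""
    return _breadths_from_counts(table.counts.astype(float))


def _permuted_breadths(
    counts: np.ndarray, scheme: str, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_otus) matrix of null breadths."""
    S, n = counts.shape
    out = np.empty((n_perm, S))
    for t in range(n_perm):
        if scheme == "column_label_permute":
            shuffled = counts[:, rng.permutation(n)]
        else:
            shuffled = counts[rng.permutation(S)] if scheme == "taxon_shuffle" else counts
            order = np.argsort(rng.random((S, n)), axis=1)
            shuffled = np.take_along_axis(shuffled, order, axis=1)
        out[t] = _breadths_from_counts(shuffled)
    return out


def null_breadth_distribution(
    table: CommunityTable,
    n_perm: int = 1000,
    scheme: str = "taxon_shuffle",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-OTU (2.5%, 97.5%) empirical quantiles of the null breadths.

    Quantiles use linear interpolation between order statistics. Deterministic
    under ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 for stable quantiles, got {n_perm}")
    if scheme not in NULL_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {NULL_SCHEMES}")
    rng = np.random.default_rng(seed)
    null = _permuted_breadths(table.counts.astype(float), scheme, n_perm, rng)
    with np.errstate(invalid="ignore"):
        low = np.nanquantile(null, 0.025, axis=0)
        upp = np.nanquantile(null, 0.975, axis=0)
    return low, upp


def classify_guilds(
    table: CommunityTable,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "taxon_shuffle",
) -> GuildClassification:
    """Classify every OTU as generalist, specialist or non-significant.

    Strict inequalities: a guild call requires the observed breadth to lie
    strictly outside the null band, so degenerate bands (null equals
    observed) are non-significant by construction; values within 1e-9
    relative of the band count as ties (permutations recompute sums in a
    different order, so exact equality is not representable in floats).
    OTUs absent from every sample have undefined breadth and are
    non-significant.
    """
    if table.n_samples < 4:
        raise ValueError(
            f"niche breadth needs >= 4 samples, got {table.n_samples}"
        )
    b_obs = observed_breadths(table)
    low, upp = null_breadth_distribution(table, n_perm=n_perm, scheme=scheme, seed=seed)
    guild = np.full(table.n_otus, NON_SIGNIFICANT, dtype=object)
    with np.errstate(invalid="ignore"):
        tol = 1e-9 * np.maximum(1.0, np.abs(b_obs))
        guild[b_obs > upp + tol] = GENERALIST
        guild[b_obs < low - tol] = SPECIALIST
    return GuildClassification(
        otu_ids=table.otu_ids,
        b_obs=tuple(float(b) for b in b_obs),
        low_ci=tuple(float(v) for v in low),
        upp_ci=tuple(float(v) for v in upp),
        guild=tuple(guild),
        n_perm=n_perm,
        r=table.n_samples,
        scheme=scheme,
        seed=seed,
    )
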