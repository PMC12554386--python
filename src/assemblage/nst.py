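"""Normalized stochasticity ratio: observed vs. null-expected dissimilarity.

For each within-group sample pair the observed dissimilarity ``d_obs`` is
compared to the mean dissimilarity ``e_null`` of the pair under a
richness-preserving randomization. The per-pair ratio is symmetric:

    nst_ij = d_obs / e_null              if d_obs <= e_null
           = (1 - d_obs) / (1 - e_null)  otherwise

so observed-equals-null maps to 1 and deterministic extremes (d_obs of 0 or
1 against an interior null) map to 0. The group value is the unweighted pair
mean; values above 0.5 are read as stochastic-process dominance.

Dissimilarities are taxonomic (abundance-based Ruzicka by default); no
phylogenetic information is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from assemblage.io_tables import CommunityTable, register_result
from assemblage.niche import GENERALIST, SPECIALIST, GuildClassification

METRICS = ("ruzicka", "bray_curtis", "jaccard_binary")
NULL_ALGORITHMS = ("proportional_fix", "occurrence_fix")


@register_result
@dataclass(frozen=True)
class NSTResult:
    """Per-pair observed/null dissimilarities and the group-level ratio."""

    group: str
    metric: str
    null_algorithm: str
    n_reps: int
    sample_i: tuple[str, ...]
    sample_j: tuple[str, ...]
    d_obs: tuple[float, ...]
    e_null: tuple[float, ...]
    nst_ij: tuple[float, ...]
    nst_group: float
    seed: int | None = None

    def __post_init__(self):
        for name in ("sample_i", "sample_j", "d_obs", "e_null", "nst_ij"):
            object.__setattr__(self, name, tuple(getattr(self, name)))


def _relative(matrix: np.ndarray) -> np.ndarray:
    totals = matrix.sum(axis=0, keepdims=True).astype(float)
    if (totals == 0).any():
        raise ValueError("sample with zero total abundance")
    return matrix / totals


def _dissimilarity_matrix(matrix: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise dissimilarity between sample columns, in [0, 1]."""
    if metric == "jaccard_binary":
        x = (matrix > 0).astype(float)
    else:
        x = _relative(matrix)
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        xi = x[:, i, None]
        rest = x[:, i + 1:]
        if metric == "bray_curtis":
            num = np.abs(xi - rest).sum(axis=0)
            den = (xi + rest).sum(axis=0)
            vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        else:  # ruzicka; jaccard_binary shares the min/max form on 0/1 data
            mins = np.minimum(xi, rest).sum(axis=0)
            maxs = np.maximum(xi, rest).sum(axis=0)
            vals = 1.0 - np.divide(
                mins, maxs, out=np.zeros_like(mins), where=maxs > 0
            )
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return d


def pairwise_dissimilarity(table: CommunityTable, metric: str = "ruzicka") -> np.ndarray:
    """Symmetric sample-by-sample dissimilarity matrix for one metric.

    ``ruzicka``/``bray_curtis`` act on per-sample relative abundances;
    ``jaccard_binary`` on presence/absence.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    return _dissimilarity_matrix(table.counts.astype(float), metric)


def _randomize_counts(
    counts: np.ndarray, algorithm: str, rng: np.random.Generator
) -> np.ndarray:
    """One richness- and abundance-multiset-preserving randomization.

    Per sample the number of occupied taxa is kept; occupying taxa are drawn
    without replacement from the regional pool — with probability
    proportional to regional occurrence frequency (``proportional_fix``) or
    uniformly (``occurrence_fix``) — and the sample's original nonzero count
    multiset is permuted onto them.
    """
    S, n = counts.shape
    occupied = counts > 0
    pool = np.nonzero(occupied.any(axis=1))[0]
    freq = occupied[pool].sum(axis=1).astype(float)
    probs = freq / freq.sum() if algorithm == "proportional_fix" else None
    out = np.zeros_like(counts)
    for j in range(n):
        richness = int(occupied[:, j].sum())
        if richness == 0:
            raise ValueError(f"sample column {j} has zero richness")
        taxa = rng.choice(pool, size=richness, replace=False, p=probs)
        values = rng.permutation(counts[occupied[:, j], j])
        out[taxa, j] = values
    return out


def randomize_community(
    table: CommunityTable, algorithm: str = "proportional_fix", seed: int | None = None
) -> CommunityTable:
    """Randomized copy of a group table (see :func:`_randomize_counts`)."""
    if algorithm not in NULL_ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {NULL_ALGORITHMS}"
        )
    rng = np.random.default_rng(seed)
    return CommunityTable(
        counts=_randomize_counts(table.counts, algorithm, rng),
        otu_ids=table.otu_ids,
        sample_ids=table.sample_ids,
        groups=table.groups,
    )


def _pair_ratio(d_obs: float, e_null: float) -> float:
    if e_null in (0.0, 1.0):
        return 1.0 if d_obs == e_null else 0.0
    if d_obs <= e_null:
        return d_obs / e_null
    return (1.0 - d_obs) / (1.0 - e_null)


def compute_nst(
    table: CommunityTable,
    metric: str = "ruzicka",
    algorithm: str = "proportional_fix",
    n_reps: int = 1000,
    seed: int | None = None,
    group: str | None = None,
) -> NSTResult:
    """Normalized stochasticity ratio for one (group-restricted) table."""
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    if table.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {table.n_samples}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if algorithm not in NULL_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    d_obs = pairwise_dissimilarity(table, metric)
    rng = np.random.default_rng(seed)
    counts = table.counts
    null_sum = np.zeros_like(d_obs)
    for _ in range(n_reps):
        rand = _randomize_counts(counts, algorithm, rng)
        null_sum += _dissimilarity_matrix(rand.astype(float), metric)
    e_null = null_sum / n_reps

    n = table.n_samples
    si, sj, dv, ev, rv = [], [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            si.append(table.sample_ids[i])
            sj.append(table.sample_ids[j])
            dv.append(float(d_obs[i, j]))
            ev.append(float(e_null[i, j]))
            rv.append(_pair_ratio(d_obs[i, j], e_null[i, j]))
    label = group
    if label is None:
        labels = set(table.groups.values())
        label = labels.pop() if len(labels) == 1 else "all"
    return NSTResult(
        group=label,
        metric=metric,
        null_algorithm=algorithm,
        n_reps=n_reps,
        sample_i=tuple(si),
        sample_j=tuple(sj),
        d_obs=tuple(dv),
        e_null=tuple(ev),
        nst_ij=tuple(rv),
        nst_group=float(np.mean(rv)),
        seed=seed,
    )


def compute_nst_by_group(
    table: CommunityTable,
    metric: str = "ruzicka",
    algorithm: str = "proportional_fix",
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[dict[str, NSTResult], dict[str, str]]:
    """One NSTResult per group; under-sized groups reported as skipped."""
    results: dict[str, NSTResult] = {}
    skipped: dict[str, str] = {}
    for k, group in enumerate(table.group_labels):
        sub = table.group_table(group)
        sub_seed = None if seed is None else seed + 7919 * k
        try:
            results[group] = compute_nst(
                sub, metric=metric, algorithm=algorithm, n_reps=n_reps,
                seed=sub_seed, group=group,
            )
        except ValueError as exc:
            skipped[group] = str(exc)
    return results, skipped


def compute_nst_by_guild_and_group(
    table: CommunityTable,
    guilds: GuildClassification,
    metric: str = "ruzicka",
    algorithm: str = "proportional_fix",
    n_reps: int = 1000,
    seed: int | None = None,
    min_samples: int = 3,
    min_taxa: int = 5,
) -> tuple[dict[tuple[str, str], NSTResult], dict[tuple[str, str], str]]:
    """Guild-stratified NST per group.

    The table is restricted to the guild's OTUs and the group's samples
    (abundances re-normalized inside the metric); strata with fewer than
    ``min_samples`` samples or ``min_taxa`` OTUs are skipped with a reason.
    """
    results: dict[tuple[str, str], NSTResult] = {}
    skipped: dict[tuple[str, str], str] = {}
    for k, group in enumerate(table.group_labels):
        samples = table.samples_in_group(group)
        for g_i, guild_name in enumerate((GENERALIST, SPECIALIST)):
            key = (group, guild_name)
            otus = [o for o in guilds.members(guild_name) if o in set(table.otu_ids)]
            if len(otus) < min_taxa:
                skipped[key] = f"only {len(otus)} {guild_name} taxa (< {min_taxa})"
                continue
            if len(samples) < min_samples:
                skipped[key] = f"only {len(samples)} samples (< {min_samples})"
                continue
            sub = table.subset(otus=otus, samples=samples, drop_empty_samples=True)
            if sub.n_samples < min_samples:
                skipped[key] = (
                    f"only {sub.n_samples} non-empty samples after restriction"
                )
                continue
            sub_seed = None if seed is None else seed + 7919 * k + 104729 * g_i
            try:
                results[key] = compute_nst(
                    sub, metric=metric, algorithm=algorithm, n_reps=n_reps,
                    seed=sub_seed, group=group,
                )
            except ValueError as exc:
                skipped[key] = str(exc)
    return results, skipped
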