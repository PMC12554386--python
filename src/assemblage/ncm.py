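"""Neutral community model: occurrence frequency vs. regional abundance.

Under neutral drift with immigration, the probability that a taxon with
regional relative abundance ``p`` is detected (above detection limit ``d``)
in a local community follows

    f_pred(p) = 1 - I_d(Nm * p, Nm * (1 - p))

with ``I`` the regularized incomplete beta function and ``Nm`` the product of
local community size and immigration rate. ``Nm`` is fitted by least squares
of observed occurrence frequencies against ``f_pred``; fit quality is the
ordinary coefficient of determination (not clamped; it may be negative).

Defaults the data do not determine: detection limit ``d`` is one read in an
average library (1 / mean library size); the community size ``N`` used to
convert ``Nm`` into a migration rate ``m = Nm / N`` is the mean library
size. Both are overridable.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from assemblage.io_tables import CommunityTable, TableValidationError, register_result
from assemblage.niche import GENERALIST, SPECIALIST, GuildClassification

NM_MAX = 1e7


class NCMFitError(RuntimeError):
    """The model cannot be fitted on the given table (with diagnostic)."""


@register_result
@dataclass(frozen=True)
class NCMFit:
    """Fitted neutral-model parameters and per-taxon records.

    ``partition`` marks each taxon as ``above``/``within``/``below`` the
    Wilson 95% band around its predicted frequency.
    """

    nm: float
    n_community: float  # assumed N used to derive m
    m: float
    r_squared: float
    d: float  # detection limit (relative abundance)
    otu_ids: tuple[str, ...]
    p: tuple[float, ...]  # mean per-sample relative abundance
    f_obs: tuple[float, ...]
    f_pred: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    partition: tuple[str, ...]
    n_samples: int = 0

    def __post_init__(self):
        for name in ("otu_ids", "p", "f_obs", "f_pred", "ci_low", "ci_high", "partition"):
            object.__setattr__(self, name, tuple(getattr(self, name)))


def occurrence_frequency(table: CommunityTable) -> np.ndarray:
    """Fraction of samples in which each taxon has a positive count."""
    if table.n_samples < 2:
        raise ValueError("occurrence frequency needs >= 2 samples")
    return (table.counts > 0).mean(axis=1)


def predicted_frequency(p, nm: float, d: float):
    """Neutral expectation of occurrence frequency (vectorized over ``p``)."""
    p_arr = np.asarray(p, dtype=float)
    if nm <= 0:
        raise ValueError(f"Nm must be positive, got {nm}")
    if not 0.0 < d < 1.0:
        raise ValueError(f"detection limit must lie in (0, 1), got {d}")
    if ((p_arr <= 0) | (p_arr >= 1)).any():
        raise ValueError("relative abundances must lie strictly in (0, 1)")
    out = 1.0 - special.betainc(nm * p_arr, nm * (1.0 - p_arr), d)
    return float(out) if np.isscalar(p) else out


def _sse(nm: float, p: np.ndarray, f_obs: np.ndarray, d: float) -> float:
    return float(np.sum((f_obs - predicted_frequency(p, nm, d)) ** 2))


def fit_nm_curve(p, f_obs, d: float) -> tuple[float, float]:
    """Least-squares ``Nm`` for occurrence frequencies vs. abundances.

    Returns ``(nm, r_squared)``. The objective is seeded on a log-spaced grid
    and refined by bounded scalar search (relative tolerance ~1e-10); R^2 is
    the ordinary coefficient of determination and is not clamped.
    """
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    f_obs = np.asarray(f_obs, dtype=float)
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    if sst == 0.0:
        raise NCMFitError(
            "all observed occurrence frequencies identical (SST = 0); "
            "R^2 undefined, fit refused"
        )
    grid = np.logspace(-2, np.log10(NM_MAX), 80)
    sse_grid = np.array([_sse(nm, p, f_obs, d) for nm in grid])
    k = int(np.argmin(sse_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda ln_nm: _sse(np.exp(ln_nm), p, f_obs, d),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    nm = float(np.exp(res.x))
    sse = _sse(nm, p, f_obs, d)
    return nm, 1.0 - sse / sst


def fit_ncm(
    table: CommunityTable,
    d: float | None = None,
    n_community: float | None = None,
) -> NCMFit:
    """Fit ``Nm`` by bounded least squares over a log-spaced grid seed.

    Taxa observed in zero samples are excluded. ``p`` is the mean of
    per-sample relative abundances (robust to depth variation).
    """
    f_all = occurrence_frequency(table)
    lib = table.library_sizes.astype(float)
    mean_lib = float(lib.mean())
    if d is None:
        d = 1.0 / mean_lib
    if n_community is None:
        n_community = mean_lib

    relab = table.counts / lib
    p_all = relab.mean(axis=1)
    keep = (f_all > 0) & (p_all > 0)
    p = np.clip(p_all[keep], 1e-12, 1 - 1e-12)
    f_obs = f_all[keep]
    otu_ids = tuple(o for o, k in zip(table.otu_ids, keep) if k)

    informative = int(((f_obs > 0) & (f_obs < 1)).sum())
    if informative < 5 and len(np.unique(f_obs)) < 2:
        raise NCMFitError(
            f"need >= 5 taxa with intermediate occurrence or mixed frequencies; "
            f"got {informative} intermediate over {f_obs.size} taxa"
        )
    nm, r_squared = fit_nm_curve(p, f_obs, d)
    f_pred = predicted_frequency(p, nm, d)

    n_samples = table.n_samples
    ci_low, ci_high = proportion_confint(
        f_pred * n_samples, n_samples, alpha=0.05, method="wilson"
    )
    partition = np.where(
        f_obs > ci_high, "above", np.where(f_obs < ci_low, "below", "within")
    )
    return NCMFit(
        nm=nm,
        n_community=float(n_community),
        m=nm / float(n_community),
        r_squared=r_squared,
        d=float(d),
        otu_ids=otu_ids,
        p=tuple(map(float, p)),
        f_obs=tuple(map(float, f_obs)),
        f_pred=tuple(map(float, f_pred)),
        ci_low=tuple(map(float, ci_low)),
        ci_high=tuple(map(float, ci_high)),
        partition=tuple(partition),
        n_samples=n_samples,
    )


def fit_ncm_by_guild_and_group(
    table: CommunityTable,
    guilds: GuildClassification,
    d: float | None = None,
    n_community: float | None = None,
    min_taxa: int = 5,
    min_samples: int = 4,
) -> tuple[dict[tuple[str, str], NCMFit], dict[tuple[str, str], str]]:
    """Fit the model separately per (group, guild) stratum.

    Returns ``(fits, skipped)``; strata failing preconditions are reported in
    ``skipped`` with a named reason rather than raising.
    """
    fits: dict[tuple[str, str], NCMFit] = {}
    skipped: dict[tuple[str, str], str] = {}
    guild_otus = {
        g: guilds.members(g) for g in (GENERALIST, SPECIALIST)
    }
    if not any(guild_otus.values()):
        for group in table.group_labels:
            for g in guild_otus:
                skipped[(group, g)] = "empty guild set"
        return fits, skipped

    for group in table.group_labels:
        samples = table.samples_in_group(group)
        for guild_name, otus in guild_otus.items():
            key = (group, guild_name)
            if not otus:
                skipped[key] = "empty guild set"
                continue
            if len(samples) < min_samples:
                skipped[key] = f"only {len(samples)} samples (< {min_samples})"
                continue
            otus_present = [o for o in otus if o in set(table.otu_ids)]
            if len(otus_present) < min_taxa:
                skipped[key] = f"only {len(otus_present)} taxa (< {min_taxa})"
                continue
            sub = table.subset(otus=otus_present, samples=samples, drop_empty_samples=True)
            if sub.n_samples < min_samples:
                skipped[key] = (
                    f"only {sub.n_samples} non-empty samples after restriction"
                )
                continue
            try:
                fits[key] = fit_ncm(sub, d=d, n_community=n_community)
            except (NCMFitError, ValueError, TableValidationError) as exc:
                skipped[key] = str(exc)
    return fits, skipped
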