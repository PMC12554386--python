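"""End-to-end orchestration: guilds, diversity, NCM, NST and networks.

A single :class:`PipelineConfig` drives every stage in dependency order
(guild classification first; the remaining stages are independent of each
other). Stage failures are recorded in the report and downstream dependents
are skipped while independent stages still run. One global seed derives a
deterministic substream per stage (stage-name hashing), so adding a stage
never perturbs another stage's randomness; two runs with the same config and
seed produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import assemblage
from assemblage import diversity as div
from assemblage import ncm as ncm_mod
from assemblage import nst as nst_mod
from assemblage import network as net_mod
from assemblage.io_tables import (
    CommunityTable,
    TableValidationError,
    read_community_table,
    register_result,
    result_to_dict,
    write_community_table,
    write_results,
)
from assemblage.niche import GENERALIST, SPECIALIST, classify_guilds
from assemblage.synthetic_data import GuildPlan, simulate_dataset

logger = logging.getLogger("assemblage.pipeline")


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Either ``table_path``+``metadata_path`` or a ``simulate`` block must be
    given. ``seed`` is mandatory.
    """

    seed: int
    output_dir: str
    table_path: str | None = None
    metadata_path: str | None = None
    simulate: dict | None = None
    niche: dict = field(default_factory=lambda: {"n_perm": 1000, "scheme": "taxon_shuffle"})
    ncm: dict = field(default_factory=dict)  # keys: d, n_community
    nst: dict = field(
        default_factory=lambda: {
            "metric": "ruzicka", "null_algorithm": "proportional_fix", "n_reps": 1000,
        }
    )
    network: dict = field(
        default_factory=lambda: {
            "n_top": 300, "method": "spearman", "r_threshold": 0.6,
            "p_threshold": 0.05, "min_prevalence": 0.2, "scope_n": 100,
        }
    )
    diversity: dict = field(default_factory=lambda: {"n_perm": 999})

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        problems = []
        if unknown:
            problems.append(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            problems.append("seed is mandatory")
        if "output_dir" not in data:
            problems.append("output_dir is mandatory")
        has_files = data.get("table_path") and data.get("metadata_path")
        if not has_files and not data.get("simulate"):
            problems.append(
                "either table_path+metadata_path or a simulate block is required"
            )
        if has_files:
            for key in ("table_path", "metadata_path"):
                if not Path(data[key]).exists():
                    problems.append(f"{key} does not exist: {data[key]}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded so identical analyses hash identically wherever written)."""
        data = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        canon = json.dumps(data, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stage-name hashing)."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


@register_result
@dataclass(frozen=True)
class StudyReport:
    """Machine-readable summary of every pipeline stage.

    Map keys use ``group|guild`` strings (JSON-safe); ``stages`` records
    complete/skipped/failed status for each configured stage and skips are
    first-class entries with reasons.
    """

    seed: int
    stages: dict
    guild_summary: dict
    shannon: dict  # key -> mean Shannon (nats)
    anosim: dict | None
    ncm: dict  # key -> {nm, m, r_squared, d, n_taxa}
    nst: dict  # key -> {nst_group, n_pairs}
    networks: dict  # group -> topology + edge-type metrics
    skipped: dict
    provenance: dict


def _key(group: str, guild: str | None = None) -> str:
    return group if guild is None else f"{group}|{guild}"


def _load_table(config: PipelineConfig, outdir: Path) -> CommunityTable:
    if config.simulate is not None:
        sim = dict(config.simulate)
        plan = sim.pop("guild_plan", None)
        if isinstance(plan, dict):
            plan = GuildPlan(**plan)
        sim.setdefault("seed", stage_seed(config.seed, "simulate"))
        table, truth = simulate_dataset(guild_plan=plan, **sim)
        write_community_table(table, outdir / "table.tsv", outdir / "metadata.tsv")
        write_results(truth, outdir / "truth.json", format="JSON")
        return table
    return read_community_table(config.table_path, config.metadata_path)


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute all stages; see module docstring for failure semantics."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    skipped: dict[str, str] = {}
    t0 = time.time()

    table = _load_table(config, outdir)
    logger.info(
        "loaded table: %d OTUs x %d samples, groups=%s",
        table.n_otus, table.n_samples, table.group_labels,
    )

    # -- guild classification (everything guild-stratified depends on it) ----
    guilds = None
    guild_summary: dict = {}
    try:
        guilds = classify_guilds(
            table,
            n_perm=int(config.niche.get("n_perm", 1000)),
            scheme=config.niche.get("scheme", "taxon_shuffle"),
            seed=stage_seed(config.seed, "niche"),
        )
        guild_summary = guilds.counts()
        write_results(guilds, outdir / "guilds.tsv", format="TSV")
        write_results(guilds, outdir / "guilds.json", format="JSON")
        stages["guilds"] = "complete"
    except Exception as exc:
        stages["guilds"] = f"failed: {exc}"
        logger.exception("guild classification failed")

    # -- diversity -----------------------------------------------------------
    shannon_map: dict[str, float] = {}
    anosim_out = None
    try:
        per_sample = div.shannon_per_sample(table)
        pd.DataFrame(
            {"sample_id": list(per_sample), "shannon": list(per_sample.values())}
        ).to_csv(outdir / "shannon.tsv", sep="\t", index=False, float_format="%.12g")
        for group in table.group_labels:
            vals = [per_sample[s] for s in table.samples_in_group(group)]
            shannon_map[_key(group, "all")] = float(np.mean(vals))
        if guilds is not None:
            for guild_name in (GENERALIST, SPECIALIST):
                otus = [o for o in guilds.members(guild_name)]
                if len(otus) < 2:
                    skipped[f"shannon:{guild_name}"] = (
                        f"only {len(otus)} {guild_name} taxa"
                    )
                    continue
                for group in table.group_labels:
                    try:
                        sub = table.subset(
                            otus=otus,
                            samples=table.samples_in_group(group),
                            drop_empty_samples=True,
                        )
                        vals = list(div.shannon_per_sample(sub).values())
                    except (ValueError, TableValidationError) as exc:
                        skipped[f"shannon:{_key(group, guild_name)}"] = str(exc)
                        continue
                    shannon_map[_key(group, guild_name)] = float(np.mean(vals))
        ord_res = div.pcoa_table(table)
        coords = ord_res.coords
        pd.DataFrame(
            coords,
            index=list(table.sample_ids),
            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
        ).to_csv(outdir / "pcoa.tsv", sep="\t", float_format="%.12g")
        labels = [table.groups[s] for s in table.sample_ids]
        if len(set(labels)) >= 2 and min(
            labels.count(g) for g in set(labels)
        ) >= 2:
            res = div.anosim(
                div.bray_curtis(table),
                labels,
                n_perm=int(config.diversity.get("n_perm", 999)),
                seed=stage_seed(config.seed, "anosim"),
            )
            write_results(res, outdir / "anosim.json", format="JSON")
            anosim_out = {"R": res.R, "p": res.p, "n_perm": res.n_perm}
        else:
            skipped["anosim"] = "fewer than 2 groups with >= 2 samples"
        stages["diversity"] = "complete"
    except Exception as exc:
        stages["diversity"] = f"failed: {exc}"
        logger.exception("diversity stage failed")

    # -- NCM -----------------------------------------------------------------
    ncm_map: dict[str, dict] = {}
    try:
        d_opt = config.ncm.get("d")
        n_opt = config.ncm.get("n_community")
        fit = ncm_mod.fit_ncm(table, d=d_opt, n_community=n_opt)
        write_results(fit, outdir / "ncm_all.json", format="JSON")
        ncm_map["all"] = _ncm_summary(fit)
        if guilds is not None:
            fits, ncm_skips = ncm_mod.fit_ncm_by_guild_and_group(
                table, guilds, d=d_opt, n_community=n_opt
            )
            for (group, guild_name), f in fits.items():
                ncm_map[_key(group, guild_name)] = _ncm_summary(f)
                write_results(
                    f, outdir / f"ncm_{group}_{guild_name}.json", format="JSON"
                )
            for (group, guild_name), reason in ncm_skips.items():
                skipped[f"ncm:{_key(group, guild_name)}"] = reason
        else:
            skipped["ncm:guild_strata"] = "guild classification unavailable"
        stages["ncm"] = "complete"
    except Exception as exc:
        stages["ncm"] = f"failed: {exc}"
        logger.exception("NCM stage failed")

    # -- NST -----------------------------------------------------------------
    nst_map: dict[str, dict] = {}
    try:
        nst_cfg = config.nst
        results, nst_skips = nst_mod.compute_nst_by_group(
            table,
            metric=nst_cfg.get("metric", "ruzicka"),
            algorithm=nst_cfg.get("null_algorithm", "proportional_fix"),
            n_reps=int(nst_cfg.get("n_reps", 1000)),
            seed=stage_seed(config.seed, "nst"),
        )
        for group, res in results.items():
            nst_map[_key(group, "all")] = {
                "nst_group": res.nst_group, "n_pairs": len(res.nst_ij),
            }
            write_results(res, outdir / f"nst_{group}.json", format="JSON")
        for group, reason in nst_skips.items():
            skipped[f"nst:{group}"] = reason
        if guilds is not None:
            g_results, g_skips = nst_mod.compute_nst_by_guild_and_group(
                table,
                guilds,
                metric=nst_cfg.get("metric", "ruzicka"),
                algorithm=nst_cfg.get("null_algorithm", "proportional_fix"),
                n_reps=int(nst_cfg.get("n_reps", 1000)),
                seed=stage_seed(config.seed, "nst_guild"),
            )
            for (group, guild_name), res in g_results.items():
                nst_map[_key(group, guild_name)] = {
                    "nst_group": res.nst_group, "n_pairs": len(res.nst_ij),
                }
            for (group, guild_name), reason in g_skips.items():
                skipped[f"nst:{_key(group, guild_name)}"] = reason
        else:
            skipped["nst:guild_strata"] = "guild classification unavailable"
        stages["nst"] = "complete"
    except Exception as exc:
        stages["nst"] = f"failed: {exc}"
        logger.exception("NST stage failed")

    # -- networks ------------------------------------------------------------
    net_map: dict[str, dict] = {}
    try:
        net_cfg = config.network
        for group in table.group_labels:
            sub = table.group_table(group)
            try:
                net = net_mod.build_network(
                    sub,
                    n_top=int(net_cfg.get("n_top", 300)),
                    method=net_cfg.get("method", "spearman"),
                    r_threshold=float(net_cfg.get("r_threshold", 0.6)),
                    p_threshold=float(net_cfg.get("p_threshold", 0.05)),
                    min_prevalence=float(net_cfg.get("min_prevalence", 0.2)),
                    guilds=guilds,
                )
            except ValueError as exc:
                skipped[f"network:{group}"] = str(exc)
                continue
            net_mod.write_graphml(net, outdir / f"network_{group}.graphml")
            entry: dict = {}
            try:
                topo = net_mod.topology(net)
                entry.update(result_to_dict(topo))
            except ValueError as exc:
                skipped[f"network_topology:{group}"] = str(exc)
            if guilds is not None:
                try:
                    etp = net_mod.edge_type_proportions(
                        net, guilds, scope_n=int(net_cfg.get("scope_n", 100))
                    )
                    entry["edge_types"] = {
                        "gg": etp.gg, "gs": etp.gs, "ss": etp.ss,
                        "n_edges_classified": etp.n_edges_classified,
                    }
                except ValueError as exc:
                    skipped[f"network_edge_types:{group}"] = str(exc)
            net_map[group] = entry
        stages["network"] = "complete"
    except Exception as exc:
        stages["network"] = f"failed: {exc}"
        logger.exception("network stage failed")

    report = StudyReport(
        seed=config.seed,
        stages=stages,
        guild_summary=guild_summary,
        shannon=shannon_map,
        anosim=anosim_out,
        ncm=ncm_map,
        nst=nst_map,
        networks=net_map,
        skipped=skipped,
        provenance={
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": assemblage.__version__,
        },
    )
    write_results(report, outdir / "report.json", format="JSON")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return report


def _ncm_summary(fit) -> dict:
    return {
        "nm": fit.nm,
        "m": fit.m,
        "r_squared": fit.r_squared,
        "d": fit.d,
        "n_taxa": len(fit.otu_ids),
    }


def compare_groups(report: StudyReport) -> pd.DataFrame:
    """Tidy long table of per-group metric values with rank ordering.

    One row per (metric, guild-scope, group); ``rank`` is 1 for the largest
    value. No hypothesis tests beyond the ANOSIM already in the report.
    """
    groups = sorted(
        {k.split("|")[0] for k in report.nst} | set(report.networks)
        | {k.split("|")[0] for k in report.shannon}
    )
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups to compare, got {groups}")

    rows: list[dict] = []

    def add(metric: str, guild: str, group: str, value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return
        rows.append({"metric": metric, "guild": guild, "group": group, "value": value})

    for key, value in report.shannon.items():
        group, guild = key.split("|")
        add("shannon_mean", guild, group, value)
    for key, entry in report.ncm.items():
        if key == "all" or "|" not in key:
            continue
        group, guild = key.split("|")
        add("ncm_m", guild, group, entry["m"])
        add("ncm_r_squared", guild, group, entry["r_squared"])
    for key, entry in report.nst.items():
        group, guild = key.split("|")
        add("nst", guild, group, entry["nst_group"])
    for group, entry in report.networks.items():
        for metric in ("avg_k", "density", "gd", "modularity", "pct_positive"):
            if metric in entry:
                add(metric, "all", group, entry[metric])
        if "edge_types" in entry:
            add("ss_fraction", "all", group, entry["edge_types"]["ss"])

    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("report holds no comparable metrics")
    df["rank"] = (
        df.groupby(["metric", "guild"])["value"]
        .rank(ascending=False, method="min")
        .astype(int)
    )
    return df.sort_values(["metric", "guild", "group"]).reset_index(drop=True)
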