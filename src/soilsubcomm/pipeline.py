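"""End-to-end orchestration: rarefy -> classify -> distance decay / ANOSIM
-> spatial selection -> variation partitioning -> neutral-model fit, over
one or more domains (e.g. bacteria / fungi / protists).

A :class:`PipelineConfig` either points at OTU-table + metadata TSVs per
domain or asks for a synthetic dataset; ``run_pipeline`` executes every
stage in a fixed order with per-stage seeds derived deterministically from
one master seed, writes stage outputs as TSVs, and returns a JSON-ready
report.  Identical config and seeds give byte-identical reports (the
provenance block carries a config hash and the package version, not wall
time, so reports are reproducible artifacts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .distdecay import anosim, bray_curtis, distance_decay_fit, environmental_distance
from .io import (
    ENV_VARIABLES,
    OtuTable,
    SampleMetadata,
    align,
    read_metadata,
    read_otu_table,
    write_metadata,
    write_otu_table,
)
from .ncm import fit_ncm
from .rarefy import rarefy_table
from .spatial import forward_select, pcnm
from .subcomm import (
    GROUPINGS,
    ClassificationThresholds,
    classify_taxa,
    partition_summary,
    subset_by_category,
)
from .vpa import hellinger, variation_partition

logger = logging.getLogger(__name__)


@dataclass
class DomainConfig:
    """One domain: either file inputs or a synthetic generator spec."""

    name: str
    otu_table: str | None = None
    metadata: str | None = None
    orientation: str = "samples_as_rows"
    synthetic: dict | None = None  # kwargs for synth.simulate_niche / simulate_neutral


@dataclass
class PipelineConfig:
    domains: list
    output_dir: str = "pipeline_out"
    rarefaction_depth: int | None = None
    rare_cutoff: float = 1e-4
    abundant_cutoff: float = 1e-2
    grouping: str = "merged"
    n_permutations: int = 999
    mantel_method: str = "spearman"
    alpha: float = 0.05
    distance_mode: str = "great_circle"
    ncm_min_otus: int = 50
    seed: int = 0

    def __post_init__(self):
        self.domains = [
            d if isinstance(d, DomainConfig) else DomainConfig(**d)
            for d in self.domains
        ]
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)

    def analysis_params(self) -> dict:
        """Config without the output location — what the numbers depend on."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.analysis_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_domain(dom: DomainConfig, seed: int) -> tuple[OtuTable, SampleMetadata]:
    if dom.synthetic is not None:
        from . import synth

        spec = dict(dom.synthetic)
        model = spec.pop("model", "neutral")
        spec.setdefault("seed", seed)
        if model == "neutral":
            table = synth.simulate_neutral(synth.NeutralSimConfig(**spec))
            meta = synth.simulate_metadata(table.n_samples, seed=spec["seed"] + 1)
        elif model == "niche":
            table, meta = synth.simulate_niche(synth.NicheSimConfig(**spec))
        else:
            raise ValueError(f"unknown synthetic model {model!r}")
        return table, meta
    if dom.otu_table is None or dom.metadata is None:
        raise ValueError(f"domain {dom.name!r}: need otu_table+metadata or synthetic")
    table = read_otu_table(dom.otu_table, dom.orientation)
    meta = read_metadata(dom.metadata)
    return align(table, meta)


def _stage_seeds(master: int, n_domains: int) -> list:
    ss = np.random.SeedSequence(master)
    return [s.generate_state(8).tolist() for s in ss.spawn(n_domains)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every configured domain; return the report dict.

    Stage outputs (rarefied tables, per-OTU categories, summaries) are
    written under ``config.output_dir/<domain>/``; the report itself is
    written as ``report.json``.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    thresholds = ClassificationThresholds(config.rare_cutoff, config.abundant_cutoff)
    groups = GROUPINGS[config.grouping]
    report = {
        "provenance": {
            "package": "soilsubcomm",
            "version": __version__,
            "config_hash": config.hash(),
            "master_seed": config.seed,
        },
        "config": config.analysis_params(),
        "domains": {},
    }
    seeds_per_domain = _stage_seeds(config.seed, len(config.domains))
    for dom, seeds in zip(config.domains, seeds_per_domain):
        t0 = time.perf_counter()
        dom_dir = out_root / dom.name
        dom_dir.mkdir(exist_ok=True)
        table, meta = _load_domain(dom, seeds[0])
        table, meta = align(table, meta)
        logger.info(
            "domain=%s stage=load n_samples=%d n_otus=%d",
            dom.name, table.n_samples, table.n_otus,
        )
        table = rarefy_table(table, config.rarefaction_depth, seed=seeds[1])
        table, meta = align(table, meta)
        write_otu_table(table, dom_dir / "rarefied.tsv")
        write_metadata(meta, dom_dir / "metadata.tsv")

        partition = classify_taxa(table, thresholds, grouping=config.grouping)
        partition.to_series().to_csv(dom_dir / "categories.tsv", sep="\t")
        summary = partition_summary(partition, table)
        summary.to_csv(dom_dir / "subcommunity_summary.tsv", sep="\t")

        env_dist = environmental_distance(meta)
        basis = pcnm(meta, config.distance_mode)
        pcnm_df = basis.to_dataframe()
        env_df = meta.env.copy()

        dom_report = {
            "n_samples": table.n_samples,
            "n_otus": table.n_otus,
            "depth": int(table.sample_totals()[0]),
            "subcommunity_summary": summary.round(6).to_dict(orient="index"),
            "pcnm": {
                "n_eigenvectors": int(basis.eigenvectors.shape[1]),
                "truncation_threshold": float(basis.truncation_threshold),
            },
            "subcommunities": {},
        }

        for gi, (gname, cats) in enumerate(sorted(groups.items())):
            entry: dict = {"categories": list(cats)}
            try:
                sub = subset_by_category(table, partition, cats)
            except ValueError as exc:
                entry["status"] = f"empty: {exc}"
                dom_report["subcommunities"][gname] = entry
                continue
            entry["n_otus"] = sub.n_otus
            sub_seed = int(seeds[2]) + gi
            if np.any(sub.sample_totals() == 0):
                entry["status"] = "skipped: zero-read samples in subset"
                dom_report["subcommunities"][gname] = entry
                continue
            bc = bray_curtis(sub)
            mt = distance_decay_fit(
                bc, env_dist, method=config.mantel_method,
                n_permutations=config.n_permutations, seed=sub_seed,
            )
            entry["distance_decay"] = {
                "mantel_r": round(mt.mantel.r, 10),
                "mantel_p": mt.mantel.p_value,
                "slope": round(mt.slope, 10),
                "intercept": round(mt.intercept, 10),
            }
            an = anosim(
                bc, meta.land_use, n_permutations=config.n_permutations,
                seed=sub_seed + 1, grouping_name="land_use",
            )
            entry["anosim"] = {"R": round(an.R, 10), "p": an.p_value}

            Y = hellinger(sub)
            sel_env = forward_select(
                Y, env_df, alpha=config.alpha,
                n_permutations=config.n_permutations, seed=sub_seed + 2,
            )
            sel_spat = forward_select(
                Y, pcnm_df, alpha=config.alpha,
                n_permutations=config.n_permutations, seed=sub_seed + 3,
            )
            entry["selected_env"] = sel_env.selected
            entry["selected_pcnm"] = sel_spat.selected
            # fall back to the full block when selection is empty so the
            # partition is still defined (recorded via the selected_* lists)
            Xe = env_df[sel_env.selected] if sel_env.selected else env_df
            Xs = pcnm_df[sel_spat.selected] if sel_spat.selected else pcnm_df
            vp = variation_partition(
                Y, Xe, Xs, n_permutations=config.n_permutations, seed=sub_seed + 4
            )
            entry["vpa"] = {
                "a_env": round(vp.a, 10),
                "b_shared": round(vp.b, 10),
                "c_space": round(vp.c, 10),
                "d_residual": round(vp.d, 10),
                "p_env": vp.p_env,
                "p_space": vp.p_spat,
                "display_pct": vp.display_fractions(),
            }
            try:
                # p and the detection limit refer to the full community's
                # even depth; only the subcommunity's OTUs are fitted
                fit = fit_ncm(table, min_otus=config.ncm_min_otus, otu_ids=sub.otu_ids)
                entry["ncm"] = {
                    "m": round(fit.m, 10),
                    "Nm": round(fit.Nm, 6),
                    "R2": round(fit.r_squared, 10),
                    "N": fit.N,
                    "n_otus_used": fit.n_otus_used,
                }
                fit.stats.to_csv(dom_dir / f"ncm_{gname}.tsv", sep="\t")
            except ValueError as exc:
                entry["ncm"] = {"status": f"not fitted: {exc}"}
            entry["status"] = "ok"
            dom_report["subcommunities"][gname] = entry
        logger.info(
            "domain=%s done elapsed=%.1fs", dom.name, time.perf_counter() - t0
        )
        report["domains"][dom.name] = dom_report
    report_path = out_root / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", report_path)
    return report
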