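"""End-to-end orchestration: filter -> network -> PIE -> screen.

A single YAML-configurable run executes the four analysis stages in
order, writes every intermediate artifact in the package's TSV/JSON
formats, and emits a machine-readable report with a provenance block
(config hash, master seed, library versions). A master seed drives all
randomness; per-stage seeds are derived at fixed offsets so each stage
is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .filtering import FilterConfig, filter_candidates
from .interactome import (
    ValidationError,
    read_edge_list,
    read_hit_table,
    read_node_list,
    read_phenotype_table,
    write_phenotype_table,
)
from .netbuild import build_seed_graph, expand_parsimony, write_node_roles
from .pie import DegreeMatchPolicy, PieCohesion
from .rnai import DEFAULT_ALPHA_TIERS, PhenotypeScreen

logger = logging.getLogger(__name__)

_PIE_SEED_OFFSET = 101  # per-stage seed = (master + offset) % 2**31


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    reference_path: str
    bait_paths: list
    out_dir: str
    reference_nodes_path: str | None = None
    control_paths: list = field(default_factory=list)
    blocklist_paths: dict = field(default_factory=dict)
    seeds_path: str | None = None
    phenotype_path: str | None = None
    min_replicates: int = 2
    min_links: int = 2
    n_rand: int = 10_000
    rng_seed: int = 0
    alpha_tiers: tuple = DEFAULT_ALPHA_TIERS
    degree_match_mode: str = "exact"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        paths = [self.reference_path, *self.bait_paths, *self.control_paths,
                 *self.blocklist_paths.values()]
        for opt in (self.reference_nodes_path, self.seeds_path, self.phenotype_path):
            if opt is not None:
                paths.append(opt)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input path(s): {missing}")
        if self.n_rand < 1:
            raise ValidationError("n_rand must be >= 1")

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location is not part of the analysis identity
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("filter")
def _run_filter(config: PipelineConfig, out: Path):
    bait_runs = [read_hit_table(p) for p in config.bait_paths]
    control_runs = [read_hit_table(p) for p in config.control_paths]
    blocklists = {name: frozenset(read_node_list(p))
                  for name, p in config.blocklist_paths.items()}
    fc = FilterConfig(min_replicates=config.min_replicates, blocklists=blocklists)
    candidates = filter_candidates(bait_runs, control_runs, fc)
    with open(out / "candidates.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein\taudit\tmax_unique_peptides\n")
        for p in sorted(candidates.audit):
            pep = candidates.peptide_support.get(p, "")
            fh.write(f"{p}\t{candidates.audit[p]}\t{pep}\n")
    return candidates


@_stage("network")
def _run_network(config: PipelineConfig, seeds, reference, out: Path):
    seed_graph = build_seed_graph(seeds, reference)
    extended = expand_parsimony(seed_graph, reference, min_links=config.min_links)
    with open(out / "network_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("# a\tb\tevidence\n")
        for e in sorted(extended.edges, key=lambda e: (e.a, e.b)):
            fh.write(f"{e.a}\t{e.b}\t{e.evidence}\n")
    write_node_roles(extended, out / "network_nodes.tsv")
    return extended


@_stage("pie")
def _run_pie(config: PipelineConfig, reference, node_set, out: Path):
    policy = DegreeMatchPolicy(mode=config.degree_match_mode)
    seed = (config.rng_seed + _PIE_SEED_OFFSET) % 2**31
    res = PieCohesion(reference, node_set, policy=policy).fit(
        n_rand=config.n_rand, seed=seed
    )
    with open(out / "pie.json", "w", encoding="utf-8") as fh:
        json.dump(res.to_dict(), fh, indent=2)
    res.write_null_histogram(out / "pie_null_histogram.tsv")
    return res


@_stage("screen")
def _run_screen(config: PipelineConfig, interactor_ids, out: Path):
    records = read_phenotype_table(config.phenotype_path)
    write_phenotype_table(records, out / "screen_counts.tsv")
    screen = PhenotypeScreen(records, interactor_ids=interactor_ids)
    res = screen.fit(alpha_tiers=config.alpha_tiers)
    res.to_frame().to_csv(out / "screen_results.tsv", sep="\t", index=False)
    return res


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run report.

    Any stage failure aborts with the stage name; artifacts written by
    completed stages are retained in ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference = read_edge_list(
        config.reference_path, nodes_path=config.reference_nodes_path
    )
    candidates = _run_filter(config, out)
    seeds = (
        read_node_list(config.seeds_path)
        if config.seeds_path is not None
        else set(candidates.proteins)
    )
    extended = _run_network(config, seeds, reference, out)
    pie_res = _run_pie(config, reference, extended.nodes, out)

    from . import __version__  # deferred: package __init__ imports this module

    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.content_hash(),
            "rng_seed": config.rng_seed,
            "versions": _library_versions(),
        },
        "filter": {
            "n_input_proteins": len(candidates.audit),
            "n_retained": len(candidates.proteins),
            "removed_by_rule": _rule_tally(candidates.audit),
        },
        "network": {
            "n_seed_nodes": len(extended.seed_nodes),
            "n_added_nodes": len(extended.added_nodes),
            "n_edges": extended.n_edges,
            "edge_tally": extended.edge_tally(),
            "dropped_seeds": sorted(extended.dropped_seeds),
        },
        "pie": pie_res.to_dict(),
    }
    if config.phenotype_path is not None:
        screen_res = _run_screen(config, seeds, out)
        report["screen"] = {
            "n_tested": len(screen_res.results),
            "n_unscored": len(screen_res.unscored),
            "n_significant": screen_res.n_significant,
            "n_significant_other": screen_res.n_significant_other,
            "total_screened": screen_res.total_screened,
        }

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _rule_tally(audit: dict) -> dict:
    tally: dict[str, int] = {}
    for rule in audit.values():
        if rule != "retained":
            tally[rule] = tally.get(rule, 0) + 1
    return tally


def _library_versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
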