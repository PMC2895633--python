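"""End-to-end orchestration: network → subnets → usage → clustering →
motifs → FFL null models → sRNA enrichment.

A single :class:`RunConfig` (usually loaded from YAML) drives the run; every
output file carries a header with the tool version, a hash of the resolved
configuration and the seed, and the machine-readable summary is written as
JSON.  Static and time-course data differ only in how the usage matrix is
built; all later stages are shared.  Mode ``meta`` treats a collection of
experiments as one wide matrix and drops the principal singular value,
removing global chip-wide variation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterAssignment, hier_cluster, label_clusters
from .expression import ExpressionMatrix, read_expression_tsv
from .motifs import FFL_ID, cluster_induced_subgraph, ffl_null_models, motif_zscores
from .network import (
    DEFAULT_DIMER_MAP,
    build_network,
    network_summary,
    read_dimer_map,
    read_gene_list,
    read_interaction_table,
    write_edge_list,
)
from .srna import cluster_enrichment_fraction, map_targets, subnet_target_enrichment
from .subnets import enumerate_subnets, write_subnet_file
from .usage_static import build_static_usage
from .usage_timecourse import build_timecourse_usage

__all__ = ["RunConfig", "ValidationError", "StageError", "run_full", "load_config"]

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """The configuration is incomplete or inconsistent for the chosen mode."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    edges: str = ""
    dimers: str | None = None
    phantoms: str | None = None
    subnet_min_size: int = 5
    mode: str = "static"  # static | timecourse | meta
    expression: str | None = None  # static: one genes × samples TSV
    design: str | None = None  # static: sample TAB comparison TAB group TSV
    expression_dir: str | None = None  # timecourse/meta: directory of TSVs
    q: float = 0.05
    alpha: float = 0.05
    n_perm: int = 1000
    n_pseudo: int = 1000
    null_fraction: float | None = 0.25
    cutoff: float | None = None
    k_clusters: int = 3
    n_random: int = 1000
    n_samples: int = 100
    n_swap_multiplier: int = 100
    srna_targets: str | None = None
    seed: int = 0
    out_dir: str = "subnetusage_out"

    def validate(self) -> None:
        if not self.edges:
            raise ValidationError("an edge file is required")
        if self.mode not in ("static", "timecourse", "meta"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "static" and not (self.expression and self.design):
            raise ValidationError("static mode requires 'expression' and 'design'")
        if self.mode in ("timecourse", "meta") and not self.expression_dir:
            raise ValidationError(f"{self.mode} mode requires 'expression_dir'")
        if self.cutoff is None and self.null_fraction is None:
            raise ValidationError("either 'cutoff' or 'null_fraction' is required")

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # output location does not affect results
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML config; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _header(cfg: RunConfig) -> str:
    return f"subnetusage {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}"


def _static_comparisons(cfg: RunConfig):
    expr = read_expression_tsv(cfg.expression)
    design = pd.read_csv(cfg.design, sep="\t", comment="#", dtype=str)
    if not {"sample", "comparison", "group"}.issubset(design.columns):
        raise ValidationError("design file needs columns sample, comparison, group")
    comparisons, ids = [], []
    for cid, grp in design.groupby("comparison", sort=True):
        samples = list(grp["sample"])
        missing = [s for s in samples if s not in expr.values.columns]
        if missing:
            raise ValidationError(f"comparison {cid}: samples absent from matrix: {missing}")
        sub = ExpressionMatrix(values=expr.values[samples].copy())
        comparisons.append((sub, list(grp["group"])))
        ids.append(str(cid))
    return comparisons, ids


def _load_experiments(cfg: RunConfig):
    paths = sorted(Path(cfg.expression_dir).glob("*.tsv"))
    if not paths:
        raise ValidationError(f"no .tsv experiments under {cfg.expression_dir}")
    experiments = [read_expression_tsv(p) for p in paths]
    ids = [p.stem for p in paths]
    return experiments, ids


def run_full(config: RunConfig) -> dict:
    """Execute the full workflow and return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
    }

    def stage(name: str):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                log.info("stage %s finished in %.2fs", name, dt)
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("network"):
        records = read_interaction_table(config.edges)
        dimer_map = read_dimer_map(config.dimers) if config.dimers else DEFAULT_DIMER_MAP
        phantoms = read_gene_list(config.phantoms) if config.phantoms else ()
        net = build_network(records, dimer_map=dimer_map, phantom_genes=phantoms)
        write_edge_list(net, out / "network_edges.tsv", header=header)
        report["network"] = network_summary(net)

    with stage("subnets"):
        subnets = enumerate_subnets(net, min_size=config.subnet_min_size)
        write_subnet_file(subnets, out / "subnets.txt")
        report["n_subnets"] = len(subnets)

    with stage("usage"):
        if config.mode == "static":
            comparisons, ids = _static_comparisons(config)
            res = build_static_usage(
                comparisons, subnets, net.nodes, q=config.q, alpha=config.alpha,
                n_perm=config.n_perm, seed=config.seed, comparison_ids=ids,
            )
            usage = res.usage
            report["skipped_comparisons"] = res.skipped
        else:
            experiments, ids = _load_experiments(config)
            if config.mode == "meta":
                wide = pd.concat([e.values for e in experiments], axis=1, join="inner")
                wide.columns = [f"s{i}" for i in range(wide.shape[1])]
                experiments, ids = [ExpressionMatrix(values=wide)], ["meta"]
            tc = build_timecourse_usage(
                experiments, subnets, n_pseudo=config.n_pseudo, seed=config.seed,
                cutoff=config.cutoff, target_null_fraction=config.null_fraction,
                drop_principal=(config.mode == "meta"), experiment_ids=ids,
            )
            usage = tc.usage
            report["z_cutoff"] = tc.cutoff
            with (out / "z_matrix.tsv").open("w") as fh:
                fh.write(f"# {header}\n")
                tc.z_matrix.to_csv(fh, sep="\t", index_label="root")
        with (out / "usage_matrix.tsv").open("w") as fh:
            fh.write(f"# {header}\n")
            usage.to_csv(fh, sep="\t", index_label="root")
        report["usage_columns"] = int(usage.shape[1])

    with stage("clustering"):
        if usage.shape[1] == 0 or usage.shape[0] < config.k_clusters:
            raise ValidationError("usage matrix too small to cluster")
        partition = hier_cluster(usage, k=config.k_clusters)
        assignment = label_clusters(partition, usage)
        with (out / "cluster_assignment.tsv").open("w") as fh:
            fh.write(f"# {header}\nroot\tlabel\n")
            for root in sorted(assignment.labels):
                fh.write(f"{root}\t{assignment.labels[root]}\n")
        report["cluster_sizes"] = {
            l: len(assignment.roots_with_label(l)) for l in assignment.mean_usage
        }
        report["mean_usage"] = {l: round(v, 6) for l, v in assignment.mean_usage.items()}

    with stage("motifs"):
        sub_by_root = {s.root: s for s in subnets}
        ffl_z: dict[str, float] = {}
        trn_sig = motif_zscores(
            net, n_random=config.n_random,
            n_swap_multiplier=config.n_swap_multiplier, seed=config.seed,
        )
        ffl_z["TRN"] = trn_sig.z.get(FFL_ID, math.nan)
        cluster_nets = {}
        for label in assignment.mean_usage:
            members = [sub_by_root[r] for r in assignment.roots_with_label(label)]
            cnet = cluster_induced_subgraph(net, members)
            cluster_nets[label] = (cnet, members)
            sig = motif_zscores(
                cnet, n_random=config.n_random,
                n_swap_multiplier=config.n_swap_multiplier, seed=config.seed + 1,
            )
            ffl_z[label] = sig.z.get(FFL_ID, math.nan)
        report["ffl_z"] = {k: (None if not math.isfinite(v) else round(v, 4)) for k, v in ffl_z.items()}

    with stage("ffl_null_models"):
        null_label = "null" if "null" in cluster_nets else min(
            assignment.mean_usage, key=lambda l: assignment.mean_usage[l]
        )
        cnet, members = cluster_nets[null_label]
        if members:
            nm = ffl_null_models(
                net, subnets, n_nodes=cnet.n_nodes,
                subnet_size_profile=[s.size for s in members],
                n_samples=config.n_samples, n_random=config.n_random,
                n_swap_multiplier=config.n_swap_multiplier, seed=config.seed,
            )
            report["ffl_null_models"] = {
                "cluster": null_label,
                "random_nodes_mean": round(nm.mean_nodes, 4),
                "random_nodes_p95": round(nm.percentile_nodes(95), 4),
                "random_subnets_mean": round(nm.mean_subnets, 4),
                "random_subnets_p95": round(nm.percentile_subnets(95), 4),
            }

    if config.srna_targets:
        with stage("srna"):
            names = read_gene_list(config.srna_targets)
            targets = map_targets(names, net)
            enriched, results = subnet_target_enrichment(
                subnets, targets, net.nodes, alpha=config.alpha
            )
            fractions = cluster_enrichment_fraction(assignment, enriched, subnets)
            with (out / "srna_enrichment.tsv").open("w") as fh:
                fh.write(f"# {header}\nroot\tp\tp_adj\tsignificant\n")
                for r in results:
                    fh.write(f"{r.root}\t{r.p_value:.6g}\t{r.p_adjusted:.6g}\t{int(r.significant)}\n")
            report["srna"] = {
                "n_mapped": len(targets.mapped),
                "n_unmapped": len(targets.unmapped),
                "enriched_roots": sorted(enriched),
                "fractions": {k: round(v, 4) for k, v in fractions.items()},
            }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
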