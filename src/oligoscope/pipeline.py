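"""End-to-end orchestration: simulate → oligotype → screen → ordinate → network.

A :class:`RunConfig` (YAML-serialisable) drives the stages; one global seed
deterministically derives per-stage seeds so a whole run is reproducible
bit for bit.  Each stage writes standard-format outputs into the run
directory and the final manifest records parameters, versions and the
read-count accounting (reads in = reads retained in oligotypes + reads set
aside as incomplete + reads in skipped OTUs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oligoscope import io as oio
from oligoscope import __version__
from oligoscope.oligotyping import (
    AlignedReadSet,
    OligotypeTable,
    OligotypingParams,
    OTUTooSmallError,
    canonical_site_order,
    decompose,
    drop_incomplete,
    remove_singletons,
    tabulate,
)
from oligoscope.ordination import (
    DEFAULT_CANDIDATES,
    RDA,
    forward_select,
    hellinger,
    select_models,
    zscore,
)
from oligoscope.network import (
    MCLParams,
    build_graph,
    cluster_summary,
    ia_null,
    mcl,
    network_stats,
)
from oligoscope.screening import screen_by_quartile, screening_report
from oligoscope.simulate import CommunityDesign, generate_community, generate_env_table

log = logging.getLogger("oligoscope")


@dataclass
class RunConfig:
    """Complete, serialisable configuration of a pipeline run.

    Defaults reproduce the analysis conditions: OTUs with more than 100
    reads, rounds at ≥ 21 sequences and entropy > 0.6 bits, upper-quartile
    C/T screening, RDA reported above 50% constrained variation at
    BH-adjusted P < 0.05, IA edges above 85 with 200 permutations, and MCL
    at inflation 2.5.
    """

    out_dir: str = "oligoscope_run"
    alignments_dir: str | None = None  # simulate when None
    env_table: str | None = None
    taxonomy_table: str | None = None  # optional per-OTU lineage TSV
    seed: int = 0

    # simulation
    n_otus: int = 20
    n_sites: int = 13
    reads_per_otu: tuple[int, int] = (100, 3000)
    variant_positions_per_otu: tuple[int, int] = (1, 5)
    error_rate: float = 0.001
    missing_tail_fraction: float = 0.02

    # oligotyping
    min_otu_reads: int = 100
    min_reads_for_round: int = 21
    min_entropy: float = 0.6
    incomplete_policy: str = "retain_complete"

    # ordination
    rda_candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    rda_alpha: float = 0.05
    rda_min_constrained: float = 0.50
    rda_permutations: int = 999

    # network
    ia_min: float = 85.0
    ia_alpha: float = 0.05
    ia_permutations: int = 200
    mcl_inflation: float = 2.5
    min_abundance: int = 2

    stages: tuple[str, ...] = ("simulate", "oligotype", "screen", "rda", "network")
    make_plots: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for f_ in (
            "reads_per_otu",
            "variant_positions_per_otu",
            "rda_candidates",
            "stages",
        ):
            if f_ in d and isinstance(d[f_], list):
                d[f_] = tuple(d[f_])
        return cls(**d)


def stage_seeds(seed: int, stages=("simulate", "oligotype", "screen", "rda", "network")):
    """Derive one deterministic sub-seed (< 2^31) per stage from one seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(stages))
    return {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(stages, children)
    }


@dataclass
class RunManifest:
    """Accounting record of one pipeline run."""

    seed: int
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "parameters": self.parameters,
                "stages_completed": self.stages_completed,
                "counts": self.counts,
            },
            indent=1,
            sort_keys=True,
        ))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write all outputs.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(seed=config.seed)
    d = asdict(config)
    # paths are run locations, not computation parameters; keep them out of
    # the echo so identical analyses produce identical manifests
    manifest.parameters = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in d.items()
        if k not in ("out_dir", "alignments_dir", "env_table")
    }

    # ---- stage: inputs ----------------------------------------------------
    if "simulate" in config.stages and config.alignments_dir is None:
        env = generate_env_table(config.n_sites, seed=seeds["simulate"])
        design = CommunityDesign(
            n_otus=config.n_otus,
            n_sites=config.n_sites,
            reads_per_otu=config.reads_per_otu,
            variant_positions_per_otu=config.variant_positions_per_otu,
            error_rate=config.error_rate,
            missing_tail_fraction=config.missing_tail_fraction,
            seed=seeds["simulate"],
        )
        read_sets, truth = generate_community(design, env)
        oio.write_env_table(env, out / "env_table.tsv")
        oio.write_alignments(read_sets, out / "alignments")
        oio.write_ground_truth(truth, out / "ground_truth.json")
        manifest.stages_completed.append("simulate")
    else:
        if config.alignments_dir is None or config.env_table is None:
            raise FileNotFoundError(
                "alignments_dir and env_table are required when not simulating"
            )
        read_sets = oio.read_alignments(config.alignments_dir)
        env = oio.read_env_table(config.env_table)
        if config.taxonomy_table:
            tax = pd.read_csv(config.taxonomy_table, sep="\t", index_col=0)
            for rs in read_sets:
                if rs.otu_id in tax.index:
                    rs.taxonomy = tax.loc[rs.otu_id].to_dict()
    manifest.counts["n_otus_in"] = len(read_sets)
    manifest.counts["n_reads_in"] = int(sum(rs.n_reads for rs in read_sets))

    # ---- stage: oligotype -------------------------------------------------
    params = OligotypingParams(
        min_reads_for_round=config.min_reads_for_round,
        min_entropy=config.min_entropy,
        min_otu_reads=config.min_otu_reads,
    )
    site_order = canonical_site_order(env.index)
    tables_by_otu: dict[str, OligotypeTable] = {}
    meta_by_otu: dict[str, dict] = {}
    logs = {}
    n_skipped = n_reads_skipped = n_incomplete = 0
    if "oligotype" in config.stages:
        for rs in read_sets:
            try:
                oligos, dlog = decompose(rs, params)
            except OTUTooSmallError:
                n_skipped += 1
                n_reads_skipped += rs.n_reads
                continue
            oligos, fill = drop_incomplete(
                oligos, rs.site_of_read, policy=config.incomplete_policy
            )
            n_incomplete += dlog.n_reads_in - sum(o.n_reads for o in oligos)
            tables_by_otu[rs.otu_id] = tabulate(oligos, site_order)
            meta_by_otu[rs.otu_id] = rs.taxonomy or {}
            logs[rs.otu_id] = {
                "rounds": dlog.rounds,
                "n_reads_in": dlog.n_reads_in,
                "n_reads_retained": int(sum(o.n_reads for o in oligos)),
                "fill": None if fill is None else
                {k: round(float(v), 4) for k, v in fill.items()},
            }
        table = OligotypeTable.concat(list(tables_by_otu.values()))
        n_before = table.n_oligotypes
        table, n_singletons = remove_singletons(table)
        tables_by_otu = {
            otu: table.for_otu(otu)
            for otu in table.meta["otu_id"].unique()
        }
        tables_by_otu = {o: t for o, t in tables_by_otu.items() if t.n_oligotypes}
        oio.write_oligotype_table(table, out / "oligotype_table.tsv")
        (out / "decomposition_log.json").write_text(
            json.dumps(logs, indent=1, sort_keys=True)
        )
        manifest.counts.update(
            {
                "n_otus_oligotyped": len(logs),
                "n_otus_skipped_small": n_skipped,
                "n_reads_in_skipped_otus": n_reads_skipped,
                "n_oligotypes_raw": int(n_before),
                "n_singletons_removed": int(n_singletons),
                "n_oligotypes": int(table.n_oligotypes),
                "n_reads_retained": int(table.counts.to_numpy().sum()),
                "n_reads_set_aside": int(n_incomplete),
            }
        )
        manifest.stages_completed.append("oligotype")
    else:
        table = None

    # ---- stage: screen ----------------------------------------------------
    if "screen" in config.stages and tables_by_otu:
        report = screening_report(tables_by_otu, meta_by_otu)
        if report.shape[0] >= 4:
            selected, q3c, q3t = screen_by_quartile(report)
        else:
            selected, q3c, q3t = [], float("nan"), float("nan")
        report["selected"] = report.index.isin(selected)
        report.to_csv(out / "screening.tsv", sep="\t")
        manifest.counts.update(
            {
                "n_otus_screened": int(report.shape[0]),
                "n_otus_selected_ct": len(selected),
                "q3_c": None if np.isnan(q3c) else round(q3c, 2),
                "q3_t": None if np.isnan(q3t) else round(q3t, 2),
            }
        )
        if config.make_plots and selected:
            from oligoscope import plots

            (out / "heatmaps").mkdir(exist_ok=True)
            for otu in selected:
                plots.heatmap(
                    tables_by_otu[otu], out / "heatmaps" / f"{otu}.png", title=otu
                )
        manifest.stages_completed.append("screen")

    # ---- stage: rda -------------------------------------------------------
    if "rda" in config.stages and tables_by_otu:
        candidates = [c for c in config.rda_candidates if c in env.columns]
        X = zscore(env[candidates])
        rng = np.random.default_rng(seeds["rda"])
        results = {}
        n_trivial = 0
        for otu in sorted(tables_by_otu):
            tab = tables_by_otu[otu]
            Y = pd.DataFrame(
                hellinger(tab.counts.to_numpy(float).T),
                index=tab.counts.columns,
                columns=tab.counts.index,
            ).loc[X.index]
            sel = forward_select(
                Y,
                X,
                alpha=config.rda_alpha,
                n_perm=config.rda_permutations,
                seed=int(rng.integers(2**31)),
            )
            if not sel:
                n_trivial += 1
                continue
            model = RDA(Y, X[sel])
            res = model.fit()
            res.selected_variables = sel
            res.permutation_test(
                n_perm=config.rda_permutations, seed=int(rng.integers(2**31))
            )
            results[otu] = res
        models = select_models(
            results,
            min_constrained=config.rda_min_constrained,
            alpha=config.rda_alpha,
            meta_by_otu=meta_by_otu,
        )
        models.to_csv(out / "rda_models.tsv", sep="\t")
        all_rows = [
            {
                "otu_id": o,
                "model": r.formula(),
                "constrained_pct": round(100 * r.constrained_fraction, 1),
                "p": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for o, r in sorted(results.items())
        ]
        pd.DataFrame(
            all_rows,
            columns=["otu_id", "model", "constrained_pct", "p", "p_adjusted"],
        ).to_csv(out / "rda_all_models.tsv", sep="\t", index=False)
        if len(models.index):
            (out / "triplot_scores").mkdir(exist_ok=True)
            for otu in models.index:
                r = results[otu]
                scores = pd.concat(
                    {
                        "site": r.site_scores,
                        "oligotype": r.oligotype_scores,
                        "constraint": r.biplot_scores,
                    },
                    names=["score_type", "name"],
                )
                scores.to_csv(out / "triplot_scores" / f"{otu}.tsv", sep="\t")
        if config.make_plots:
            from oligoscope import plots

            (out / "triplots").mkdir(exist_ok=True)
            for otu in models.index:
                plots.triplot(
                    results[otu], out / "triplots" / f"{otu}.svg", title=otu
                )
        manifest.counts.update(
            {
                "n_models_nontrivial": len(results),
                "n_models_trivial": int(n_trivial),
                "n_models_selected": int(models.shape[0]),
            }
        )
        manifest.stages_completed.append("rda")

    # ---- stage: network ---------------------------------------------------
    if "network" in config.stages and table is not None and table.n_oligotypes >= 2:
        counts = table.counts
        keep = counts.sum(axis=1) >= config.min_abundance
        counts = counts.loc[keep]
        meta = table.meta.loc[keep]
        if counts.shape[0] >= 2:
            ia, p, padj = ia_null(
                counts.to_numpy(float),
                n_perm=config.ia_permutations,
                seed=seeds["network"],
            )
            g = build_graph(
                counts,
                ia,
                padj,
                ia_min=config.ia_min,
                alpha=config.ia_alpha,
                min_abundance=config.min_abundance,
                node_meta=meta,
            )
            stats = network_stats(g)
            params_mcl = MCLParams(inflation=config.mcl_inflation)
            clusters = mcl(g, params_mcl)
            node_meta = pd.DataFrame(
                {
                    "abundance": counts.sum(axis=1),
                    "phylum": meta.get("phylum", pd.Series("-", index=meta.index)),
                    "class": meta.get("class", pd.Series("-", index=meta.index)),
                }
            )
            summary = cluster_summary(clusters, node_meta)
            oio.write_edge_list(g, out / "network_edges.tsv")
            oio.write_graphml(g, out / "network.graphml")
            oio.write_sif(g, out / "network.sif")
            (out / "network_stats.json").write_text(
                json.dumps(stats.to_dict(), indent=1, sort_keys=True)
            )
            membership = pd.DataFrame(
                [
                    {"oligotype": node, "cluster": ci + 1}
                    for ci, cl in enumerate(clusters)
                    for node in sorted(cl)
                ]
            )
            membership.to_csv(out / "mcl_clusters.tsv", sep="\t", index=False)
            summary.to_csv(out / "mcl_summary.tsv", sep="\t")
            manifest.counts.update(
                {
                    "network_nodes": stats.n_nodes,
                    "network_edges": stats.n_edges,
                    "network_components": stats.n_components,
                    "n_mcl_clusters": len(clusters),
                }
            )
            manifest.stages_completed.append("network")

    config.to_yaml(out / "config.yaml")
    manifest.write(out / "manifest.json")
    return manifest
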