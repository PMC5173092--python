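"""End-to-end orchestration of the ceRNA inference stages.

Stage order: simulate (optional) -> interactions -> pairs -> coexpr ->
network -> modules -> survival -> associate.  Every stage writes TSV
outputs into the run directory and registers them, with parameter values,
record counts and content checksums, in ``manifest.json``.  A single
global seed fans out into fixed per-purpose derived seeds so rerunning or
toggling one stage never shifts another stage's randomness; reruns with an
unchanged config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, bicliques, coexpression, interactions, network, pairs, simulate, survival

logger = logging.getLogger(__name__)

STAGES = ("simulate", "interactions", "pairs", "coexpr", "network", "modules", "survival", "associate")

# fixed offsets deriving per-purpose seeds from the global seed
_SEED_SPLIT = 1
_SEED_EXTERNAL = 104729  # keeps derived seeds well below 2**31 for small inputs


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    outdir: str = "cernet_run"
    seed: int = 0
    # inputs; None -> produced by the simulate stage
    interactions_path: str | None = None
    lnc_expression_path: str | None = None
    mrna_expression_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    simulate_external: bool = True
    # thresholds (defaults: pair FDR < 0.01, co-expression FDR < 0.01,
    # sub-network r > 0.5, top 5% hubs/bottlenecks, 2x3 module minima,
    # univariate screening p < 0.05)
    pair_fdr: float = pairs.DEFAULT_FDR_THRESHOLD
    tail: str = "at_least"
    min_shared: int = 1
    coexpr_fdr: float = coexpression.DEFAULT_FDR_THRESHOLD
    require_positive: bool = True
    r_min_sub: float = coexpression.SUB_NETWORK_R_MIN
    top_fraction: float = network.DEFAULT_TOP_FRACTION
    min_lnc: int = bicliques.DEFAULT_MIN_LNC
    min_mrna: int = bicliques.DEFAULT_MIN_MRNA
    screen_p: float = survival.DEFAULT_SCREEN_P
    split_fraction: float = 0.5
    n_gene_clusters: int = association.DEFAULT_N_GENE_CLUSTERS
    n_sample_groups: int = association.DEFAULT_N_SAMPLE_GROUPS
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("pair_fdr", self.pair_fdr, 0, 1.5),
            ("coexpr_fdr", self.coexpr_fdr, 0, 1.5),
            ("top_fraction", self.top_fraction, 0, 1),
            ("split_fraction", self.split_fraction, 0, 1),
            ("screen_p", self.screen_p, 0, 1),
        ):
            if not lo < value <= hi:
                raise ValueError(f"{name}={value} outside ({lo}, {hi}]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None and "simulate" in self.stages:
            self.simulation = simulate.SimulationConfig(seed=self.seed)


def config_from_yaml(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML mapping (nested ``simulation`` ok)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        for key in ("mirnas_per_lncrna", "mirnas_per_mrna", "risk_log_hazards", "planted_biclique"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        raw["simulation"] = simulate.SimulationConfig(**sim)
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Mutable state of a pipeline execution; see :func:`run_pipeline`."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        params = _jsonable(config)
        params.pop("outdir", None)  # location-independent manifests
        self.manifest: dict = {
            "seed": config.seed,
            "parameters": params,
            "stages": {},
            "files": {},
        }
        self.iset: interactions.InteractionSet | None = None
        self.lnc_expr: pd.DataFrame | None = None
        self.mrna_expr: pd.DataFrame | None = None
        self.clinical: pd.DataFrame | None = None
        self.pair_results: pd.DataFrame | None = None
        self.coexpr: pd.DataFrame | None = None
        self.lmcn = None
        self.topology: pd.DataFrame | None = None
        self.modules: list = []
        self.signature: dict | None = None

    # -- helpers ----------------------------------------------------------
    def _emit(self, stage: str, name: str, frame: pd.DataFrame, **counts) -> Path:
        path = self.outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        self.manifest["files"][name] = _sha256(path)
        self.manifest["stages"].setdefault(stage, {}).update(counts)
        return path

    def _done(self, stage: str, **counts) -> None:
        self.manifest["stages"].setdefault(stage, {}).update(counts)

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.simulation
        cohort = simulate.simulate_cohort(cfg)
        paths = simulate.write_cohort(cohort, self.outdir / "cohort")
        for key, p in paths.items():
            self.manifest["files"][str(p.relative_to(self.outdir))] = _sha256(p)
        self.iset = cohort.interactions
        self.lnc_expr = cohort.lnc_expression
        self.mrna_expr = cohort.mrna_expression
        self.clinical = cohort.clinical
        self._done(
            "simulate",
            n_interactions=len(cohort.interactions.table),
            n_samples=cfg.n_samples,
            n_true_pairs=cfg.n_true_pairs,
        )
        if self.config.simulate_external:
            ext_cfg = dataclasses.replace(cfg, seed=self.config.seed + _SEED_EXTERNAL)
            ext = simulate.simulate_cohort(ext_cfg)
            ext_paths = simulate.write_cohort(ext, self.outdir / "external_cohort")
            for p in ext_paths.values():
                self.manifest["files"][str(p.relative_to(self.outdir))] = _sha256(p)

    def _load_inputs(self) -> None:
        c = self.config
        if self.iset is None:
            src = c.interactions_path or self.outdir / "cohort" / "interactions.tsv"
            self.iset = interactions.load_interactions(src)
        if self.lnc_expr is None:
            self.lnc_expr = coexpression.load_expression(
                c.lnc_expression_path or self.outdir / "cohort" / "lnc_expression.tsv"
            )
            self.mrna_expr = coexpression.load_expression(
                c.mrna_expression_path or self.outdir / "cohort" / "mrna_expression.tsv"
            )
        if self.clinical is None:
            self.clinical = survival.load_clinical(
                c.clinical_path or self.outdir / "cohort" / "clinical.tsv"
            )

    def stage_interactions(self) -> None:
        self._load_inputs()
        filtered = interactions.filter_supported(self.iset)
        self.iset = filtered
        path = self.outdir / "filtered_interactions.tsv"
        interactions.write_interactions(filtered, path)
        self.manifest["files"][path.name] = _sha256(path)
        self._done(
            "interactions",
            n_interactions=len(filtered.table),
            n_mirnas=filtered.n_mirnas,
        )

    def _ensure_coexpr(self) -> None:
        if self.coexpr is None:
            self.coexpr = pd.read_csv(self.outdir / "coexpression.tsv", sep="\t")

    def _ensure_network(self) -> None:
        if self.lmcn is None:
            self._ensure_coexpr()
            self.lmcn = network.build_network(self.coexpr, "passed_lmcn")
        if self.topology is None:
            self.topology = network.annotate_topology(self.lmcn)

    def stage_pairs(self) -> None:
        c = self.config
        results = pairs.test_all_pairs(self.iset, tail=c.tail, min_shared=c.min_shared)
        selected = pairs.select_candidate_pairs(results, c.pair_fdr)
        self.pair_results = selected
        self._emit("pairs", "pair_tests.tsv", results, n_tested=len(results))
        self._emit("pairs", "candidate_pairs.tsv", selected, n_selected=len(selected))

    def stage_coexpr(self) -> None:
        c = self.config
        if self.pair_results is None:
            self.pair_results = pd.read_csv(self.outdir / "candidate_pairs.tsv", sep="\t")
        self.coexpr = coexpression.filter_coexpressed(
            self.pair_results,
            self.lnc_expr,
            self.mrna_expr,
            fdr_threshold=c.coexpr_fdr,
            require_positive=c.require_positive,
        )
        self._emit(
            "coexpr",
            "coexpression.tsv",
            self.coexpr,
            n_lmcn_edges=int(self.coexpr["passed_lmcn"].sum()),
            n_sub_edges=int(self.coexpr["passed_sub"].sum()),
        )

    def stage_network(self) -> None:
        self._ensure_network()
        hubs = network.select_hub_bottlenecks(
            self.topology, self.config.top_fraction, "lncRNA"
        )
        nodes = self.topology.reset_index().merge(
            hubs.reset_index()[["id", "is_hub", "is_bottleneck"]], on="id", how="left"
        ).fillna({"is_hub": 0, "is_bottleneck": 0}).astype({"is_hub": int, "is_bottleneck": int})
        degrees = {
            "lncRNA": self.topology.loc[self.topology["gene_class"] == "lncRNA", "degree"],
            "mRNA": self.topology.loc[self.topology["gene_class"] == "mRNA", "degree"],
            "all": self.topology["degree"],
        }
        fits = pd.DataFrame(
            [
                (name, f.slope, f.intercept, f.r_squared, f.n_points, int(f.fittable))
                for name, f in ((k, network.fit_power_law(v)) for k, v in degrees.items())
            ],
            columns=["node_set", "slope", "intercept", "r_squared", "n_points", "fittable"],
        )
        network.write_edge_list(self.lmcn, self.outdir / "edges.tsv")
        self.manifest["files"]["edges.tsv"] = _sha256(self.outdir / "edges.tsv")
        self._emit("network", "nodes.tsv", nodes, n_nodes=len(nodes), n_edges=self.lmcn.number_of_edges())
        self._emit("network", "powerlaw.tsv", fits)

    def stage_modules(self) -> None:
        self._ensure_coexpr()
        sub = network.build_network(self.coexpr, "passed_sub")
        mods = bicliques.enumerate_maximal_bicliques(
            sub, self.config.min_lnc, self.config.min_mrna
        )
        self.modules = bicliques.rank_modules(mods, self.coexpr)
        frame = bicliques.modules_to_frame(self.modules)
        self._emit("modules", "modules.tsv", frame, n_modules=len(frame))

    def _signature_genes(self) -> list[str]:
        if not self.modules and (self.outdir / "modules.tsv").exists():
            frame = pd.read_csv(self.outdir / "modules.tsv", sep="\t")
            if len(frame):
                row = frame.iloc[0]
                return sorted(row["lncrna_ids"].split(",")) + sorted(row["mrna_ids"].split(","))
        if self.modules:
            top = self.modules[0]
            return sorted(top.lncrnas) + sorted(top.mrnas)
        self._ensure_network()
        hubs = network.select_hub_bottlenecks(self.topology, self.config.top_fraction, "lncRNA")
        both = hubs[(hubs["is_hub"] == 1) & (hubs["is_bottleneck"] == 1)]
        return sorted(both.index)

    def stage_survival(self) -> None:
        genes = self._signature_genes()
        expr = pd.concat([self.lnc_expr, self.mrna_expr])
        external = None
        ext_dir = self.outdir / "external_cohort"
        if ext_dir.exists():
            ext = simulate.read_cohort(ext_dir)
            ext_expr = pd.concat([ext.lnc_expression, ext.mrna_expression])
            external = (ext_expr, ext.clinical)
        self.signature = survival.evaluate_signature(
            genes,
            expr,
            self.clinical,
            split_fraction=self.config.split_fraction,
            seed=self.config.seed + _SEED_SPLIT,
            external=external,
            screen_p=self.config.screen_p,
        )
        self._emit(
            "survival",
            "cox_screen.tsv",
            self.signature["fits"],
            n_signature_genes=len(self.signature["model"].genes),
        )
        self._emit("survival", "survival_report.tsv", self.signature["report"])
        curve_rows = []
        for cohort, groups in self.signature["curves"].items():
            for grp, curve in groups.items():
                for t, s, ar in curve.itertuples(index=False):
                    curve_rows.append((cohort, grp, t, s, ar))
        self._emit(
            "survival",
            "km_curves.tsv",
            pd.DataFrame(curve_rows, columns=["cohort", "group", "time", "survival", "at_risk"]),
        )

    def stage_associate(self) -> None:
        self._ensure_network()
        lnc_topo = self.topology[self.topology["gene_class"] == "lncRNA"]
        focal = lnc_topo.sort_values(["degree", "betweenness"], ascending=False).index[0]
        neigh = association.neighbors_of(self.lmcn, focal)
        mrna_neigh = [g for g in neigh if g in self.mrna_expr.index]
        if len(mrna_neigh) < 2:
            logger.warning("focal lncRNA %s has <2 mRNA neighbors; skipping association", focal)
            self._done("associate", focal=str(focal), n_neighbors=len(mrna_neigh))
            return
        sub = self.mrna_expr.loc[mrna_neigh]
        clusters = association.hierarchical_cluster(
            sub,
            min(self.config.n_gene_clusters, len(mrna_neigh)),
            min(self.config.n_sample_groups, sub.shape[1]),
        )
        gene_frame = clusters.gene_labels.rename("cluster").rename_axis("gene_id").reset_index()
        sample_frame = clusters.sample_labels.rename("group").rename_axis("sample_id").reset_index()
        self._emit("associate", "gene_clusters.tsv", gene_frame, focal=str(focal), n_neighbors=len(mrna_neigh))
        self._emit("associate", "sample_groups.tsv", sample_frame)
        if self.config.gmt_path:
            collection = association.load_gmt(self.config.gmt_path)
            background = list(self.mrna_expr.index)
            frames = []
            for label, grp in gene_frame.groupby("cluster"):
                enr = association.geneset_enrichment(grp["gene_id"], background, collection)
                enr.insert(0, "cluster", label)
                frames.append(enr)
            self._emit("associate", "enrichment.tsv", pd.concat(frames, ignore_index=True))

    STAGE_METHODS = {
        "simulate": stage_simulate,
        "interactions": stage_interactions,
        "pairs": stage_pairs,
        "coexpr": stage_coexpr,
        "network": stage_network,
        "modules": stage_modules,
        "survival": stage_survival,
        "associate": stage_associate,
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    A stage failure halts the run, naming the stage and cause; downstream
    stages are not attempted.  The manifest is written on success and on
    failure (with the stages completed so far).
    """
    run = PipelineRun(config)
    needs_inputs = set(STAGES[1:])
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            if stage in needs_inputs:
                run._load_inputs()
            logger.info("--- stage %s ---", stage)
            try:
                PipelineRun.STAGE_METHODS[stage](run)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        manifest_path = run.outdir / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(run.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return run.outdir
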