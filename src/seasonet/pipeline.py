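"""End-to-end orchestration: preprocess -> correlate -> network -> communities -> traits.

One run analyzes a single seed state.  Every stage writes its artifacts
(CSV, GraphML, SIF, JSON) into the output directory and contributes a
summary block to the JSON run report; identical config and seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables as tbl
from .correlate import (correlation_matrix, normality_screen,
                        p_threshold_for_q, write_correlations_csv)
from .community import community_significance, walktrap
from .network import build_network, network_properties, robustness_scan, \
    write_graphml, write_sif
from .preprocess import arcsin_transform, drop_sparse_metabolites, \
    mean_normalize, pareto_scale
from .simulate import SimulationConfig, simulate_dataset, write_fixture
from .traits import sign_summary, trait_subgraph

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either point ``abundance_path`` / ``traits_path`` at existing CSVs or
    set ``simulate=True`` to generate a synthetic dataset first.
    """

    output_dir: str = "seasonet_out"
    state: str = "dehydrated"
    q_target: float = 0.05
    #: "auto" runs the robustness scan; a float fixes the threshold
    r_threshold: str | float = "auto"
    r_fallback: float = 0.5
    walk_length: int = 4
    min_community_size: int = 9
    alpha_normality: float = 0.05
    seed: int = 0
    simulate: bool = False
    sim_config: SimulationConfig | None = None
    abundance_path: str | None = None
    traits_path: str | None = None
    metabolite_meta_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q_target < 1:
            raise ValueError("q_target must lie in (0, 1)")
        if self.state not in tbl.SEED_STATES:
            raise ValueError(f"state must be one of {tbl.SEED_STATES}")
        if self.r_threshold != "auto":
            r = float(self.r_threshold)
            if not 0 < r < 1:
                raise ValueError("fixed r_threshold must lie in (0, 1)")
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if not self.simulate and (self.abundance_path is None or self.traits_path is None):
            raise ValueError("provide input paths or set simulate=True")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim_config", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim_config = SimulationConfig(**sim)
        return cfg


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "stages": self.stages,
                           "warnings": self.warnings},
                          indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def preprocess_for_correlation(table: tbl.AbundanceTable,
                               traits: tbl.TraitSeries,
                               state: str) -> pd.DataFrame:
    """Assemble the months x (metabolites + traits) matrix fed to correlation.

    Metabolite replicate profiles of the selected state are averaged per
    month, mean-normalized and pareto-scaled; trait percentages are
    averaged per month, arcsine-square-root transformed and pareto-scaled.
    The two trait columns are appended after the metabolites.
    """
    monthly = table.for_state(state).monthly_means()
    monthly = drop_sparse_metabolites(monthly)
    metab = pareto_scale(mean_normalize(monthly))

    trait_monthly = traits.monthly_percentages()
    trait_monthly = trait_monthly.loc[[m for m in metab.index
                                       if m in trait_monthly.index]]
    if list(trait_monthly.index) != list(metab.index):
        raise ValueError("trait months do not cover the abundance months")
    trait_t = pareto_scale(pd.DataFrame(
        {t: arcsin_transform(trait_monthly[t].to_numpy())
         for t in trait_monthly.columns}, index=trait_monthly.index))
    combined = pd.concat([metab, trait_t], axis=1)
    return combined


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis for one seed state and write all artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: _jsonable(v) if not isinstance(
        v, (int, float, str, bool, type(None))) else v
        for k, v in asdict(cfg).items()})
    stage = "inputs"
    try:
        if cfg.simulate:
            sim_cfg = cfg.sim_config or SimulationConfig(rng_seed=cfg.seed)
            if cfg.sim_config is None:
                sim_cfg = SimulationConfig(rng_seed=cfg.seed)
            dataset = simulate_dataset(sim_cfg)
            write_fixture(dataset, out / "simulated")
            table, traits, _truth = dataset
            report.stages["simulate"] = {
                "n_metabolites": sim_cfg.n_metabolites,
                "n_months": sim_cfg.n_months,
                "n_replicates": sim_cfg.n_replicates,
                "seed": sim_cfg.rng_seed,
            }
        else:
            table = tbl.read_abundance_csv(cfg.abundance_path,
                                           cfg.metabolite_meta_path)
            traits = tbl.read_traits_csv(cfg.traits_path)

        stage = "preprocess"
        combined = preprocess_for_correlation(table, traits, cfg.state)
        combined.to_csv(out / "preprocessed.csv")
        report.stages["preprocess"] = {
            "n_months": combined.shape[0],
            "n_variables": combined.shape[1],
        }

        stage = "normality"
        norm = normality_screen(combined, alpha=cfg.alpha_normality)
        (out / "normality.json").write_text(json.dumps(norm.to_dict(), indent=2))
        report.stages["normality"] = {
            "violation_fraction": norm.violation_fraction,
            "recommended_method": norm.recommended_method,
        }

        stage = "correlation"
        cstats = correlation_matrix(combined, method="spearman")
        write_correlations_csv(cstats, out / "correlations.csv")
        pvals = cstats.upper_triangle_pvalues()
        p_thresh = p_threshold_for_q(pvals, cfg.q_target)
        report.stages["correlation"] = {
            "method": cstats.method,
            "n_pairs": int(len(pvals)),
            "p_threshold": p_thresh,
            "q_target": cfg.q_target,
        }

        stage = "network"
        kinds = {name: ("trait" if name in tbl.TRAITS else "metabolite")
                 for name in cstats.labels}
        classes = {name: (str(table.metabolite_meta.loc[name, "compound_class"])
                          if name in table.metabolite_meta.index else "other")
                   for name in cstats.labels}
        if cfg.r_threshold == "auto":
            scan = robustness_scan(cstats)
            scan.to_frame().to_csv(out / "scan.csv", index=False)
            chosen_r = scan.chosen_r if scan.converged else cfg.r_fallback
            report.stages["threshold_scan"] = {
                "chosen_r": chosen_r, "converged": scan.converged,
            }
            if not scan.converged:
                report.warnings.append(
                    "robustness scan did not converge; using fallback r")
        else:
            chosen_r = float(cfg.r_threshold)
        net = build_network(cstats, chosen_r, p_thresh, kinds, classes)
        write_graphml(net, out / "network.graphml")
        write_sif(net, out / "network.sif",
                  edge_attr_path=out / "edge_attributes.csv",
                  node_attr_path=out / "node_attributes.csv")
        props = network_properties(net)
        report.stages["network"] = {
            "r_threshold": chosen_r, "p_threshold": p_thresh,
            "n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges(),
            **props,
        }

        stage = "communities"
        partition = walktrap(net, t=cfg.walk_length)
        comm_df = pd.DataFrame(
            sorted(partition.assignment.items()), columns=["node", "community"])
        tests = community_significance(net, partition.assignment,
                                       min_size=cfg.min_community_size)
        tested_ids = {t.community for t in tests if t.tested}
        comm_df["tested"] = comm_df["community"].isin(tested_ids)
        comm_df.to_csv(out / "communities.csv", index=False)
        (out / "community_tests.json").write_text(
            json.dumps([t.to_dict() for t in tests], indent=2))
        (out / "dendrogram.nwk").write_text(partition.newick + "\n")
        sizes = {c: len(v) for c, v in partition.communities.items()}
        report.stages["communities"] = {
            "n_communities": len(sizes),
            "sizes": {str(k): v for k, v in sorted(sizes.items())},
            "modularity": partition.best_modularity,
            "n_tested": len(tested_ids),
            "p_values": {str(t.community): t.p_value for t in tests if t.tested},
        }

        stage = "traits"
        trait_summary = {}
        for trait in tbl.TRAITS:
            if trait not in net:
                continue
            sub = trait_subgraph(net, trait)
            write_graphml(sub.graph, out / f"subgraph_{trait}.graphml")
            summary = sign_summary(sub, by_class=True)
            summary.to_csv(out / f"sign_summary_{trait}.csv", index=False)
            trait_summary[trait] = {
                "degree": len(sub.neighbors),
                "n_positive": int(summary["n_positive"].sum()),
                "n_negative": int(summary["n_negative"].sum()),
            }
        report.stages["traits"] = trait_summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(report.to_json())
    return report
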