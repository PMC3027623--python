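"""End-to-end orchestration of the full parsimony protocol.

One call runs: replicated heuristic search -> rule-1 collapse and
deduplication -> strict and reduced consensus -> rogue-taxon analysis ->
Bremer + bootstrap + jackknife support (absolute and GC) -> each named
alternative-placement hypothesis (constrained search: extra steps and a
Templeton test) -> trait mappings.  The result is a JSON-serialisable
report plus Newick/TSV artifacts, all reproducible from one master seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

from .matrix import CharacterMatrix, read_matrix
from .parsimony import tree_length
from .search import SearchConfig, constrained_search, replicated_search
from .support import (
    bremer_supports,
    identify_unstable_taxa,
    reduced_consensus,
    resampling_support,
    strict_consensus,
)
from .topology_tests import templeton_test
from .traits import (
    ContinuousTrait,
    DiscreteTrait,
    map_discrete_trait,
    reconstruct_continuous,
)
from .tree import Constraint, write_newick

__all__ = ["AnalysisConfig", "PipelineStageError", "run_full_analysis"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name, artifacts so far retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Everything one full analysis needs."""

    matrix: CharacterMatrix
    outgroup: Optional[str] = None
    search: SearchConfig = field(default_factory=SearchConfig)
    prune_for_reduced: Optional[List[str]] = None  # None = use rogue analysis
    hypotheses: Dict[str, Constraint] = field(default_factory=dict)
    bremer: bool = True
    bremer_search: Optional[SearchConfig] = None
    resampling_reps: int = 0
    resampling_search: Optional[SearchConfig] = None
    jackknife_p_del: float = 0.36
    discrete_traits: List[DiscreteTrait] = field(default_factory=list)
    continuous_traits: List[ContinuousTrait] = field(default_factory=list)
    out_dir: Optional[str] = None
    seed: int = 0
    max_mpts_for_tests: int = 20

    @classmethod
    def from_matrix_path(cls, path: str, **kwargs) -> "AnalysisConfig":
        return cls(matrix=read_matrix(path), **kwargs)


def _write(out_dir, name, text):
    if out_dir:
        with open(os.path.join(out_dir, name), "w") as fh:
            fh.write(text)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole protocol; returns the machine-readable report."""
    report: dict = {"seed": config.seed}
    out_dir = config.out_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    matrix = config.matrix

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # pragma: no cover - error path
                _write(out_dir, "report.json", json.dumps(report, indent=2))
                raise PipelineStageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("search")
    def _search():
        cfg = replace(config.search, seed=config.seed)
        res = replicated_search(matrix, cfg)
        state["result"] = res
        state["mpts"] = res.trees
        rep0 = tree_length(res.trees[0], matrix)
        report["best_length"] = rep0.length
        report["ci"] = round(rep0.ci, 4)
        report["ri"] = round(rep0.ri, 4)
        report["ci_informative_only"] = round(rep0.ci_informative, 4)
        report["ri_informative_only"] = round(rep0.ri_informative, 4)
        report["n_mpts"] = res.n_trees
        report["replicate_hits"] = res.replicate_hits
        report["n_replicates"] = res.n_replicates
        _write(out_dir, "mpts.nwk",
               "\n".join(write_newick(t, config.outgroup) for t in res.trees) + "\n")

    @stage("consensus")
    def _consensus():
        cons = strict_consensus(state["mpts"])
        state["consensus"] = cons
        report["strict_consensus_splits"] = len(cons.splits())
        report["strict_consensus"] = write_newick(cons, config.outgroup)
        _write(out_dir, "strict_consensus.nwk", report["strict_consensus"] + "\n")

    @stage("instability")
    def _instability():
        if len(state["mpts"]) < 2:
            state["rogues"] = []
            report["instability"] = []
            return
        rep = identify_unstable_taxa(state["mpts"], matrix)
        state["rogues"] = rep.taxa
        report["instability"] = [
            {
                "taxon": e.taxon,
                "n_positions": len(e.alternatives),
                "cause": e.cause,
                "resolution_gain": e.resolution_gain,
            }
            for e in rep.pruned
        ]

    @stage("reduced_consensus")
    def _reduced():
        prune = (config.prune_for_reduced
                 if config.prune_for_reduced is not None else state["rogues"])
        prune = [p for p in prune if p != config.outgroup]
        report["pruned_for_reduced"] = prune
        if prune:
            red = reduced_consensus(state["mpts"], prune)
            report["reduced_consensus_splits"] = len(red.splits())
            report["reduced_consensus"] = write_newick(red, config.outgroup)
            _write(out_dir, "reduced_consensus.nwk",
                   report["reduced_consensus"] + "\n")

    @stage("support")
    def _support():
        table = None
        if config.bremer and len(state["consensus"].splits()) > 0:
            cfg = config.bremer_search or SearchConfig(
                n_replicates=3, hold_per_replicate=3, seed=config.seed + 1
            )
            table = bremer_supports(matrix, state["mpts"], cfg)
        if config.resampling_reps > 0:
            cfg = config.resampling_search or SearchConfig(
                n_replicates=2, hold_per_replicate=2
            )
            ref = state["consensus"].splits()
            for scheme in ("bootstrap", "jackknife"):
                sub = resampling_support(
                    matrix, cfg, scheme=scheme, n_reps=config.resampling_reps,
                    p_del=config.jackknife_p_del, seed=config.seed + 2,
                    reference_splits=ref,
                )
                table = sub if table is None else table.merge(sub)
        if table is not None:
            df = table.to_dataframe()
            report["support"] = df.to_dict(orient="records")
            _write(out_dir, "support.tsv", df.to_csv(sep="\t", index=False))

    @stage("hypotheses")
    def _hypotheses():
        if not config.hypotheses:
            return
        best = report["best_length"]
        out = {}
        for name, constraint in config.hypotheses.items():
            cfg = replace(
                config.search,
                n_replicates=max(2, config.search.n_replicates // 5),
                seed=config.seed + 3,
            )
            res = constrained_search(matrix, constraint, cfg)
            alt = res.trees[0]
            tests = [
                templeton_test(matrix, mpt, alt)
                for mpt in state["mpts"][: config.max_mpts_for_tests]
            ]
            closest = min(tests, key=lambda r: r.n)
            out[name] = {
                "extra_steps": float(res.best_length - best),
                "templeton_p": closest.p,
                "templeton_n": closest.n,
                "p_range_across_mpts": [
                    min(t.p for t in tests), max(t.p for t in tests)
                ],
            }
        report["hypotheses"] = out

    @stage("traits")
    def _traits():
        if not (config.discrete_traits or config.continuous_traits):
            return
        tree = state["mpts"][0]
        traits_rep = {}
        for trait in config.discrete_traits:
            rec = map_discrete_trait(tree, trait)
            traits_rep[trait.name] = {
                "cost": rec.cost,
                "n_changes": len(rec.changes),
                "n_unambiguous": len(
                    [c for c in rec.changes if c.flag != "ambiguous"]
                ),
                "n_autapomorphies": len(rec.changes_with_flag("autapomorphy")),
            }
        for trait in config.continuous_traits:
            rec = reconstruct_continuous(tree, trait)
            traits_rep[trait.name] = {
                "cost": rec.cost,
                "n_nodes_with_intervals": len(rec.node_intervals),
            }
        report["traits"] = traits_rep

    _write(out_dir, "report.json", json.dumps(report, indent=2))
    return report
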