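"""Full-study orchestration: prune -> average -> calibrate -> signal ->
shift detection -> model table -> phenograms, with machine-readable reports.

The configuration is a flat key/value mapping (or a file of ``key = value``
lines); every tunable that affects results (seeds, grid sizes, shift caps) is
recorded in the report's provenance block, which together with the inputs is
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .oushift import (ALPHA_GRID_SIZE, ALPHA_T_RANGE, LAMBDA_PATH_EPS,
                      LAMBDA_PATH_SIZE, ModelComparison, ShiftModelFit,
                      compare_models)
from .phenogram import heatmap_matrix, phenogram_segments
from .phylosignal import categorical_signal_test, continuous_signal_test
from .treeio import (CATEGORICAL_COLUMN, Phylogeny, anchor_calibrate,
                     average_strain_replicates, prune_to_taxa, read_newick,
                     read_trait_table)

logger = logging.getLogger("phyloshift")

__all__ = ["AnalysisReport", "run_full_analysis", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "n_rand": 1000,
    "n_perm": 1000,
    "max_shifts": 3,
    "categorical": CATEGORICAL_COLUMN,
    "wgd_clade": "",          # comma-separated tip labels; empty = infer below
    "anchor_clade": "",       # comma-separated tip labels ("root" allowed)
    "anchor_age": 0.0,        # MY; 0 disables calibration
    "rename": "",             # comma-separated old=new tip renames
}


def load_config(path) -> dict:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    cfg = dict(DEFAULT_CONFIG)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        default = DEFAULT_CONFIG[key]
        cfg[key] = type(default)(value) if not isinstance(default, str) else value
    return cfg


@dataclass(frozen=True)
class AnalysisReport:
    """Serializable results of one full run."""

    traits: dict          # per continuous trait: signal, model table, params
    categorical: dict     # transition-count randomization test
    heatmap: dict         # z-scored matrix (species x trait), tree tip order
    provenance: dict      # config hash, seed, version, parameters used

    def to_dict(self) -> dict:
        return {"traits": self.traits, "categorical": self.categorical,
                "heatmap": self.heatmap, "provenance": self.provenance}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(traits=d["traits"], categorical=d["categorical"],
                   heatmap=d["heatmap"], provenance=d["provenance"])


def _config_hash(cfg: Mapping) -> str:
    blob = json.dumps({k: cfg[k] for k in sorted(cfg)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _split_labels(value: str) -> list:
    return [s.strip() for s in value.split(",") if s.strip()]


def _fit_block(fit: ShiftModelFit, tree: Phylogeny) -> dict:
    p = fit.params
    return {
        "model": fit.model,
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "bic": fit.bic,
        "alpha": p.alpha,
        "sigma2": p.sigma2,
        "theta0": p.theta0,
        "stationary_variance": p.stationary_variance,
        "n_shifts": len(fit.shift_branches),
        "shifts": [{"branch": int(b), "delta_theta": d,
                    "clade": sorted(tree.labels[t] for t in tree.clade_tips(int(b)))}
                   for b, d in p.shifts],
    }


def _comparison_block(cmp: ModelComparison, tree: Phylogeny) -> dict:
    return {
        "best": cmp.best,
        "models": {name: {"bic": cmp.bic[name], "bicw": cmp.bicw[name],
                          "n_shifts": len(cmp.fits[name].shift_branches)}
                   for name in cmp.bic},
        "best_fit": _fit_block(cmp.fits[cmp.best], tree),
        "variable_fit": _fit_block(cmp.fits["OU_variable"], tree),
    }


def run_full_analysis(tree_file, traits_file, config: Mapping | None = None,
                      out_dir=None, strain_map=None) -> AnalysisReport:
    """Run the complete comparative analysis and (optionally) write reports.

    Parameters
    ----------
    tree_file, traits_file:
        Newick tree and species x trait CSV/TSV (header
        ``species,DW,Gly,RQ,EthY,crabtree``; strain-level tables need
        ``strain_map``).
    config:
        Flat mapping overriding :data:`DEFAULT_CONFIG`.
    out_dir:
        If given, writes ``report.json``, ``model_table.tsv``,
        ``params_table.tsv``, ``signal.tsv``, ``heatmap.tsv`` and
        ``phenogram_<trait>.tsv`` there.
    strain_map:
        Optional mapping (or CSV path with columns ``strain,species``) to
        average strain replicates before analysis.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = sorted(set(config) - set(DEFAULT_CONFIG))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        cfg.update(config)
    seed = int(cfg["seed"])

    tree = read_newick(Path(tree_file).read_text())
    traits = read_trait_table(traits_file)

    rename = dict(pair.split("=", 1) for pair in _split_labels(cfg["rename"]))
    if rename:
        labels = tuple(rename.get(l, l) if l is not None else None
                       for l in tree.labels)
        tree = Phylogeny(tree.parent.copy(), tree.lengths.copy(), labels)

    if strain_map is not None:
        if not isinstance(strain_map, Mapping):
            sm = pd.read_csv(strain_map)
            strain_map = dict(zip(sm["strain"], sm["species"]))
        traits = average_strain_replicates(traits.reset_index()
                                           .rename(columns={"species": "strain"}),
                                           strain_map)

    absent = sorted(set(traits.index) - set(tree.tip_labels))
    if absent:
        raise ValueError(f"species absent from the tree: {absent}")
    if len(traits.index) < tree.n_tips:
        tree = prune_to_taxa(tree, traits.index)
        logger.info("pruned tree to %d trait-bearing species", tree.n_tips)

    if cfg["anchor_age"] and cfg["anchor_clade"]:
        anchor = cfg["anchor_clade"]
        node = "root" if anchor == "root" else _split_labels(anchor)
        tree = anchor_calibrate(tree, node, float(cfg["anchor_age"]))
        logger.info("calibrated anchor %r to %s MY", anchor, cfg["anchor_age"])

    categorical_col = cfg["categorical"]
    wgd_labels = _split_labels(cfg["wgd_clade"])
    if not wgd_labels and categorical_col in traits.columns:
        # default to the largest fully 'positive' clade (independent positive
        # lineages outside it would otherwise drag the MRCA to the root)
        pos = set(traits.index[traits[categorical_col].astype(str) == "positive"])
        best = None
        for nd in range(tree.n_nodes):
            if tree.parent[nd] < 0 or not tree.children[nd]:
                continue
            clade = {tree.labels[t] for t in tree.clade_tips(nd)}
            if clade <= pos and (best is None or len(clade) > len(best)):
                best = clade
        if best:
            wgd_labels = sorted(best)
            logger.info("wgd_clade not set; using largest all-positive clade "
                        "(%d species)", len(wgd_labels))
    if not wgd_labels:
        raise ValueError("config must set wgd_clade (or provide a categorical column)")

    logger.info("parameters: seed=%d n_rand=%d n_perm=%d max_shifts=%d "
                "alpha_grid=%d points alpha*T in %s lambda_path=%d eps=%g",
                seed, cfg["n_rand"], cfg["n_perm"], cfg["max_shifts"],
                ALPHA_GRID_SIZE, ALPHA_T_RANGE, LAMBDA_PATH_SIZE, LAMBDA_PATH_EPS)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    continuous = [c for c in traits.columns
                  if c != categorical_col and pd.api.types.is_numeric_dtype(traits[c])]
    trait_blocks: dict = {}
    model_rows, param_rows, signal_rows = [], [], []
    for name in continuous:
        col = pd.to_numeric(traits[name], errors="coerce").dropna()
        sub = prune_to_taxa(tree, col.index) if len(col) < tree.n_tips else tree
        x = {sp: float(v) for sp, v in col.items()}
        logger.info("trait %s: n=%d species", name, len(col))

        sig = continuous_signal_test(sub, x, n_perm=int(cfg["n_perm"]), seed=seed)
        wgd_here = [l for l in wgd_labels if l in col.index]
        cmp = compare_models(sub, x, wgd_here, max_shifts=int(cfg["max_shifts"]))
        pheno = phenogram_segments(sub, x, groups=wgd_here)

        trait_blocks[name] = {
            "n": int(len(col)),
            "signal": {"K": sig.K, "p_value": sig.p_value, "n_perm": sig.n_perm},
            "comparison": _comparison_block(cmp, sub),
        }
        signal_rows.append({"trait": name, "statistic": "K", "value": sig.K,
                            "p_value": sig.p_value, "n": len(col)})
        for model in cmp.bic:
            model_rows.append({"trait": name, "model": model,
                               "bic": cmp.bic[model], "bicw": cmp.bicw[model]})
        vf = cmp.fits["OU_variable"]
        param_rows.append({"trait": name,
                           "n_shifts": len(vf.shift_branches),
                           "alpha": vf.params.alpha,
                           "sigma2": vf.params.sigma2,
                           "stationary_variance": vf.params.stationary_variance})
        if out is not None:
            pheno.segments.to_csv(out / f"phenogram_{name}.tsv", sep="\t",
                                  index=False)
            trait_blocks[name]["phenogram"] = f"phenogram_{name}.tsv"

    categorical_block: dict = {}
    if categorical_col in traits.columns:
        states = traits[categorical_col].dropna().astype(str)
        sub = prune_to_taxa(tree, states.index) if len(states) < tree.n_tips else tree
        res = categorical_signal_test(sub, dict(states), n_rand=int(cfg["n_rand"]),
                                      seed=seed)
        categorical_block = {
            "trait": categorical_col,
            "observed_transitions": int(res.observed_transitions),
            "null_median": res.null_median,
            "p_value": res.p_value,
            "n_rand": int(cfg["n_rand"]),
            "n": int(len(states)),
        }
        signal_rows.append({"trait": categorical_col, "statistic": "transitions",
                            "value": res.observed_transitions,
                            "p_value": res.p_value, "n": len(states)})

    hm = heatmap_matrix(traits[continuous], tree)
    report = AnalysisReport(
        traits=trait_blocks,
        categorical=categorical_block,
        heatmap={"species": list(hm.index),
                 "traits": list(hm.columns),
                 "z": [[None if pd.isna(v) else float(v) for v in row]
                       for row in hm.to_numpy()]},
        provenance={
            "version": __version__,
            "seed": seed,
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "alpha_grid": {"size": ALPHA_GRID_SIZE, "alpha_T_range": list(ALPHA_T_RANGE)},
            "lambda_path": {"size": LAMBDA_PATH_SIZE, "eps": LAMBDA_PATH_EPS},
            "n_tips": int(tree.n_tips),
        },
    )

    if out is not None:
        (out / "report.json").write_text(report.to_json())
        pd.DataFrame(model_rows).to_csv(out / "model_table.tsv", sep="\t", index=False)
        pd.DataFrame(param_rows).to_csv(out / "params_table.tsv", sep="\t", index=False)
        pd.DataFrame(signal_rows).to_csv(out / "signal.tsv", sep="\t", index=False)
        hm.to_csv(out / "heatmap.tsv", sep="\t", index_label="species")
    return report
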