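"""End-to-end orchestration: simulate/ingest -> filter -> saturation ->
concatenate -> signal dissection -> concordance -> report.

Every stage writes plain-text artifacts (CSV, Newick, FASTA) into the
configured output directory, plus a manifest with a content hash per file
and a human-readable summary. A run is fully determined by its
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import matrixops, saturation, seqio, signal, synthdata
from .likelihood import optimize_branch_lengths
from .models import build_model

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Free parameters of a pipeline run.

    Exactly one of ``simulation`` (a :class:`synthdata.SimulationConfig`
    block) or ``paths`` (locus directory, two hypothesis trees, clade map)
    must be provided.
    """

    output_dir: str = "phylodissect_out"
    seed: int = 0
    simulation: synthdata.SimulationConfig | None = None
    paths: dict[str, str] | None = None
    required_clades: list[str] | None = None
    slope_min: float = saturation.DEFAULT_SLOPE_MIN
    r2_min: float = saturation.DEFAULT_R2_MIN
    model_name: str = "lg"
    model_frequencies: str = "model"
    gamma_shape: float | None = 0.8
    gamma_categories: int = 4
    signal_mode: str = "reoptimize"
    tie_eps: float = 0.0
    n_quartets: int = 100
    recoded_rerun: bool = False
    make_plots: bool = True
    opt_tol: float = 1e-3
    opt_xatol: float = 1e-6
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.simulation is None) == (self.paths is None):
            raise ConfigurationError(
                "exactly one of 'simulation' or 'paths' must be configured"
            )
        if not 0 <= self.tie_eps:
            raise ConfigurationError("tie_eps must be >= 0")
        if self.signal_mode not in ("reoptimize", "fixed"):
            raise ConfigurationError("signal_mode must be reoptimize or fixed")
        if self.model_frequencies not in ("model", "uniform"):
            raise ConfigurationError(
                "model_frequencies must be 'model' or 'uniform' for pipeline runs"
            )
        if self.paths is not None:
            for key in ("loci_dir", "t1", "t2", "clade_map"):
                if key not in self.paths:
                    raise ConfigurationError(f"paths block is missing {key!r}")

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "seed" not in sim:
                sim["seed"] = raw.get("seed", 0)
            sim["locus_length_range"] = tuple(
                sim.get("locus_length_range", (100, 500))
            )
            sim["noise_length_range"] = tuple(sim.get("noise_length_range", (60, 150)))
            sim = synthdata.SimulationConfig(**sim)
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(simulation=sim, extra=extra, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("configuration must be a mapping")
        return cls.from_mapping(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        study = synthdata.simulate_study(config.simulation)
        return (
            study.loci,
            study.t1,
            study.t2,
            study.clade_map,
            study.gene_trees,
            study,
        )
    paths = config.paths
    loci = seqio.read_locus_set(paths["loci_dir"])
    t1 = seqio.read_tree_file(paths["t1"])
    t2 = seqio.read_tree_file(paths["t2"])
    clade_map = seqio.read_clade_map(paths["clade_map"])
    gene_trees = {}
    if "gene_trees_dir" in paths:
        for p in sorted(Path(paths["gene_trees_dir"]).glob("*.nwk")):
            gene_trees[p.stem] = seqio.read_tree_file(p)
    return loci, t1, t2, clade_map, gene_trees, None


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle.

    Returns a dictionary of the headline numbers (locus counts through the
    filters, support-class proportions for genes and sites, per-class
    entropy medians) that the summary file also records.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    loci, t1, t2, clade_map, gene_trees, study = _load_inputs(config)
    n_input = len(loci)
    logger.info("stage ingest: %d loci, %d taxa", n_input, len(loci.all_taxa))

    seqio.write_clade_map(clade_map, out / "clade_map.tsv")
    (out / "t1.nwk").write_text(seqio.write_tree(t1) + "\n")
    (out / "t2.nwk").write_text(seqio.write_tree(t2) + "\n")
    outputs += [out / "clade_map.tsv", out / "t1.nwk", out / "t2.nwk"]

    # ---- decisiveness filter -------------------------------------------
    required = config.required_clades or sorted(set(clade_map.values()))
    filtered = matrixops.decisiveness_filter(loci, clade_map, required)
    logger.info(
        "stage decisiveness: %d -> %d loci (required clades: %s)",
        n_input, len(filtered), ",".join(required),
    )

    # ---- model ----------------------------------------------------------
    model = build_model(
        config.model_name,
        frequencies=config.model_frequencies,
        alpha=config.gamma_shape,
        k=config.gamma_categories,
    )

    # ---- saturation ------------------------------------------------------
    sat_stats = []
    locus_trees = {}
    for name, aln in filtered:
        if name in gene_trees:
            ltree = gene_trees[name]
        else:
            try:
                restricted = signal._restrict(t1, aln.taxa)
                ltree, _ = optimize_branch_lengths(
                    aln, restricted, model,
                    tol=config.opt_tol, xatol=config.opt_xatol,
                )
            except Exception:
                continue
        locus_trees[name] = ltree
        try:
            sat_stats.append(saturation.locus_saturation(aln, ltree, name=name))
        except Exception as exc:
            logger.warning("saturation skipped for %s: %s", name, exc)
    sat_df = pd.DataFrame(
        [
            {"locus": s.name, "slope": s.slope, "r2": s.r2, "n_pairs": s.n_pairs}
            for s in sat_stats
        ]
    )
    sat_df.to_csv(out / "saturation.csv", index=False)
    outputs.append(out / "saturation.csv")
    slow = saturation.select_slow_loci(sat_stats, config.slope_min, config.r2_min)
    logger.info(
        "stage saturation: %d of %d loci pass slope>=%.2f, r2>=%.2f",
        len(slow), len(filtered), config.slope_min, config.r2_min,
    )

    # ---- concatenation ---------------------------------------------------
    supermatrix, ranges = matrixops.concatenate(filtered)
    seqio.write_alignment(supermatrix, out / "supermatrix.fasta")
    (out / "partitions.txt").write_text(
        seqio.write_partitions(ranges, model=config.model_name.upper())
    )
    outputs += [out / "supermatrix.fasta", out / "partitions.txt"]

    # ---- gene-wise signal -----------------------------------------------
    opt_options = {"tol": config.opt_tol, "xatol": config.opt_xatol}
    table = signal.build_signal_table(
        filtered, t1, t2, model, mode=config.signal_mode, tie_eps=config.tie_eps,
        **opt_options,
    )
    table["slow"] = table["locus"].isin(slow)
    table.to_csv(out / "signal_table.csv", index=False)
    outputs.append(out / "signal_table.csv")
    p1, p2, ptie = signal.classify_support(
        table["dgls"].to_numpy(), config.tie_eps
    )

    comparison = signal.compare_gene_properties(table)
    comparison.to_csv(out / "property_comparison.csv", index=False)
    outputs.append(out / "property_comparison.csv")

    # ---- site-wise signal -----------------------------------------------
    dsls = signal.delta_sls(supermatrix, t1, t2, model, **opt_options)
    entropy = matrixops.site_entropy(supermatrix)
    informative = matrixops.informative_mask(supermatrix)
    site_df = pd.DataFrame(
        {
            "site": np.arange(1, supermatrix.n_columns + 1),
            "dsls": dsls,
            "support": [signal.support_class(v, config.tie_eps) for v in dsls],
            "entropy": entropy,
            "informative": informative,
        }
    )
    site_df.to_csv(out / "site_scores.csv", index=False)
    outputs.append(out / "site_scores.csv")
    s1, s2, stie = signal.classify_support(dsls, config.tie_eps)
    # entropy contrast over informative columns only: constant and
    # near-constant sites carry no topology signal but would otherwise
    # dominate the class medians
    inf_df = site_df[site_df["informative"]]
    inf_support = {}
    if len(inf_df):
        i1, i2, itie = signal.classify_support(
            inf_df["dsls"].to_numpy(), config.tie_eps
        )
        inf_support = {"T1": i1, "T2": i2, "tie": itie}
    ent_by_class = {
        cls: float(inf_df.loc[inf_df["support"] == cls, "entropy"].median())
        for cls in ("T1", "T2")
        if (inf_df["support"] == cls).any()
    }

    # ---- concordance -----------------------------------------------------
    gtrees = [gene_trees[n] for n in filtered.names if n in gene_trees]
    conc_frames = []
    for label, ref in (("t1", t1), ("t2", t2)):
        if gtrees:
            g = signal.gene_concordance_factor(gtrees, ref)
            g.insert(0, "reference", label)
            conc_frames.append(("gene", g))
        s = signal.site_concordance_factor(
            supermatrix, ref, n_quartets=config.n_quartets, seed=config.seed
        )
        s.insert(0, "reference", label)
        conc_frames.append(("site", s))
    gene_cf = pd.concat(
        [f for k, f in conc_frames if k == "gene"], ignore_index=True
    ) if any(k == "gene" for k, _ in conc_frames) else pd.DataFrame()
    site_cf = pd.concat(
        [f for k, f in conc_frames if k == "site"], ignore_index=True
    )
    if not gene_cf.empty:
        gene_cf.to_csv(out / "concordance_gene.csv", index=False)
        outputs.append(out / "concordance_gene.csv")
    site_cf.to_csv(out / "concordance_site.csv", index=False)
    outputs.append(out / "concordance_site.csv")

    # ---- optional SR4 recoded re-run ------------------------------------
    recoded_props = None
    if config.recoded_rerun:
        recoded = matrixops.recode_sr4(supermatrix)
        rec_model = build_model(
            "poisson",
            frequencies="empirical",
            alpha=config.gamma_shape,
            k=config.gamma_categories,
            alignment=recoded,
            alphabet=matrixops.SR4_ALPHABET,
        )
        rec_dsls = signal.delta_sls(recoded, t1, t2, rec_model, **opt_options)
        rec_df = pd.DataFrame(
            {
                "site": np.arange(1, recoded.n_columns + 1),
                "dsls": rec_dsls,
                "support": [
                    signal.support_class(v, config.tie_eps) for v in rec_dsls
                ],
            }
        )
        rec_df.to_csv(out / "site_scores_sr4.csv", index=False)
        outputs.append(out / "site_scores_sr4.csv")
        recoded_props = signal.classify_support(rec_dsls, config.tie_eps)

    # ---- plots -----------------------------------------------------------
    if config.make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(table["dgls"], bins=30, color="#4878a8")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("dGLS (lnL T1 - lnL T2)")
        ax.set_ylabel("loci")
        fig.tight_layout()
        fig.savefig(out / "dgls_hist.png", dpi=120)
        plt.close(fig)
        outputs.append(out / "dgls_hist.png")

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(dsls, bins=60, color="#a86048")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("dSLS per site")
        ax.set_ylabel("sites")
        fig.tight_layout()
        fig.savefig(out / "dsls_hist.png", dpi=120)
        plt.close(fig)
        outputs.append(out / "dsls_hist.png")

    # ---- summary, manifest ----------------------------------------------
    results = {
        "n_loci_input": n_input,
        "n_loci_decisive": len(filtered),
        "n_loci_slow": len(slow),
        "gene_support": {"T1": p1, "T2": p2, "tie": ptie},
        "site_support": {"T1": s1, "T2": s2, "tie": stie},
        "site_support_informative": inf_support,
        "median_site_entropy_by_class": ent_by_class,
    }
    if study is not None:
        results["noise_loci"] = len(study.noise_loci)
    if recoded_props is not None:
        results["site_support_sr4"] = {
            "T1": recoded_props[0], "T2": recoded_props[1], "tie": recoded_props[2]
        }
    (out / "results.json").write_text(json.dumps(results, indent=2) + "\n")
    outputs.append(out / "results.json")

    lines = [
        "phylodissect run summary",
        "========================",
        f"loci: {n_input} input -> {len(filtered)} decisive -> {len(slow)} slow",
        f"gene support: T1 {p1:.3f}  T2 {p2:.3f}  tie {ptie:.3f}",
        f"site support: T1 {s1:.3f}  T2 {s2:.3f}  tie {stie:.3f}",
    ]
    for cls, val in ent_by_class.items():
        lines.append(f"median site entropy [{cls}]: {val:.4f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    outputs.append(out / "summary.txt")

    manifest = [f"{_sha256(p)}  {p.name}" for p in outputs]
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return results
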