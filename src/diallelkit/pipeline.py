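"""End-to-end orchestration: simulate -> analyse -> write a report bundle.

:func:`run_pipeline` executes the full analysis on synthetic data generated
from a :class:`~diallelkit.config.PipelineConfig`: plot-level phenotypes for
every trait, the Griffing combining-ability analysis per trait, mid-parent
heterosis, the trait correlation matrix and path analysis, parent SNP
simulation, identity-by-state distances, the two UPGMA dendrograms (SNP- and
trait-based) and their entanglement, and the genetic-distance/hybrid-
performance correlations.  The same configuration always produces an
identical bundle; the manifest records the seed and a configuration hash.

Estimate tables carry both full-precision values and 2-decimal display
columns with significance stars (0.05/0.01/0.001), so published-style tables
can be compared at printed precision without losing machine precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import correlation_matrix, gd_trait_correlations, path_analysis, significance_stars
from .config import PipelineConfig
from .gdist import entanglement, ibs_distance, trait_distance, upgma
from .griffing import (combining_ability_analysis, entry_means, group_summary)
from .heterosis import heterosis_summary, mid_parent_heterosis
from .io import write_distance_matrix, write_plot_table, write_snp_matrix
from .simulate import simulate_diallel, simulate_parent_snps


def _display(value: float, p: float) -> str:
    return f"{value:.2f}{significance_stars(p)}"


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full pipeline; optionally write the report bundle to ``outdir``.

    Returns a dict of in-memory results keyed by table name.  Any stage
    failure propagates with the stage name prepended.
    """
    design = config.design
    results: dict = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("simulate"):
        plots = pd.concat(
            [simulate_diallel(design, config.truth_for(t), trait=t,
                              seed=config.trait_seed(t))
             for t in config.traits],
            ignore_index=True)
        results["plots"] = plots

    with stage("griffing"):
        anova_rows, gca_rows, sca_rows = [], [], []
        summaries = []
        means = {}
        ca_results = {}
        for t in config.traits:
            anova, res, extras = combining_ability_analysis(plots, t, design)
            ca_results[t] = (anova, res, extras)
            x = entry_means(plots, t, design)
            means[t] = x
            for stratum, row in anova.iterrows():
                anova_rows.append((t, stratum, row["df"], row["ss"], row["ms"],
                                   row["F"], row["p"]))
            anova_rows.append((t, "baker", np.nan, np.nan, extras["baker"],
                               np.nan, np.nan))
            anova_rows.append((t, "h2_narrow", np.nan, np.nan,
                               extras["h2_narrow"], np.nan, np.nan))
            anova_rows.append((t, "h2_broad", np.nan, np.nan,
                               extras["h2_broad"], np.nan, np.nan))
            for parent in res.parents:
                gca_rows.append((t, parent, res.gca[parent], res.gca_se[parent],
                                 res.gca_p[parent],
                                 _display(res.gca[parent], res.gca_p[parent])))
            rel = extras["relative_sca"]
            for i, a in enumerate(res.parents):
                for b in res.parents[i + 1:]:
                    sca_rows.append((t, a, b, res.sca.loc[a, b],
                                     res.sca_se.loc[a, b], res.sca_p.loc[a, b],
                                     _display(res.sca.loc[a, b], res.sca_p.loc[a, b]),
                                     np.nan if rel is None else rel.loc[a, b]))
            gs = group_summary(plots, t, design)
            summaries.append(gs.assign(trait=t, group=gs.index,
                                       t_p=gs.attrs["t_p"]))
        results["anova"] = pd.DataFrame(
            anova_rows, columns=["trait", "stratum", "df", "ss", "ms", "F", "p"])
        results["gca"] = pd.DataFrame(
            gca_rows, columns=["trait", "parent", "estimate", "se", "p", "display"])
        results["sca"] = pd.DataFrame(
            sca_rows, columns=["trait", "parent_a", "parent_b", "estimate",
                               "se", "p", "display", "relative_pct"])
        results["group_summary"] = pd.concat(summaries, ignore_index=True)

    with stage("heterosis"):
        het_frames, het_sums = [], []
        for t in config.traits:
            anova, _, _ = ca_results[t]
            het = mid_parent_heterosis(means[t], anova.loc["error", "ms"],
                                       int(anova.loc["error", "df"]))
            het["trait"] = t
            het_frames.append(het)
            het_sums.append(heterosis_summary(het).rename(t))
        results["heterosis"] = pd.concat(het_frames, ignore_index=True)
        results["heterosis_summary"] = pd.DataFrame(het_sums)

    with stage("assoc"):
        entry_labels = [f"{a}x{b}" if a != b else a for a, b in design.entries]
        table = pd.DataFrame(index=entry_labels, columns=config.traits, dtype=float)
        for t in config.traits:
            x = means[t]
            for a, b in design.entries:
                lab = f"{a}x{b}" if a != b else a
                table.loc[lab, t] = x.x[design.index_of(a), design.index_of(b)]
        results["entry_means"] = table
        corr = correlation_matrix(table)
        results["correlations"] = corr
        path = path_analysis(corr, config.dependent_trait)
        results["path"] = path

    with stage("gdist"):
        snps = simulate_parent_snps(config.parents, config.n_markers,
                                    config.divergence_matrix(),
                                    missing_rate=config.missing_rate,
                                    seed=config.snp_seed())
        results["snps"] = snps
        gd = ibs_distance(snps, mode=config.ibs_mode)
        results["gd"] = gd
        parent_means = table.loc[list(config.parents)]
        tdist = trait_distance(parent_means)
        tree_snp = upgma(gd)
        tree_traits = upgma(tdist)
        results["tree_snp"] = tree_snp
        results["tree_traits"] = tree_traits
        results["entanglement"] = entanglement(tree_snp, tree_traits,
                                               L=config.entanglement_L)

        hyb_rows = []
        for t in config.traits:
            _, res, _ = ca_results[t]
            x = means[t]
            het = results["heterosis"]
            het_t = het[het["trait"] == t].set_index(["parent_a", "parent_b"])
            for a, b in design.hybrid_entries:
                hyb_rows.append((a, b, t,
                                 x.x[design.index_of(a), design.index_of(b)],
                                 het_t.loc[(a, b), "het_pct"],
                                 res.sca.loc[a, b]))
        hybrid_table = pd.DataFrame(
            hyb_rows, columns=["parent_a", "parent_b", "trait",
                               "hybrid_mean", "het_pct", "sca"])
        gd_corr_all = gd_trait_correlations(gd.d, hybrid_table)
        gd_corr_all["subset"] = "all"
        frames = [gd_corr_all]
        if config.wild_parent is not None:
            gd_corr_cult = gd_trait_correlations(
                gd.d, hybrid_table, exclude_parent=config.wild_parent)
            gd_corr_cult["subset"] = "cultivated"
            frames.append(gd_corr_cult)
        results["gd_correlations"] = pd.concat(frames, ignore_index=True)

    if outdir is not None:
        _write_bundle(config, results, Path(outdir))
    return results


def _write_bundle(config: PipelineConfig, results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    write_plot_table(results["plots"], outdir / "plots.csv")
    for name in ("anova", "gca", "sca", "group_summary", "heterosis",
                 "heterosis_summary", "gd_correlations"):
        df = results[name]
        df.to_csv(outdir / f"{name}.csv",
                  index=name == "heterosis_summary")
    results["entry_means"].to_csv(outdir / "entry_means.csv")
    corr = results["correlations"]
    corr.r.to_csv(outdir / "correlations.csv")
    corr.p.to_csv(outdir / "correlations_p.csv")
    disp = corr.r.round(2).astype(str) + corr.stars()
    disp.to_csv(outdir / "correlations_display.csv")
    path = results["path"]
    pd.DataFrame({"direct": path.direct, "r_xy": path.r_xy}).to_csv(
        outdir / "path_direct.csv")
    path.indirect.to_csv(outdir / "path_indirect.csv")
    write_snp_matrix(results["snps"], outdir / "snps.csv")
    write_distance_matrix(results["gd"], outdir / "gd.csv")
    (outdir / "tree_snp.nwk").write_text(results["tree_snp"].newick() + "\n")
    (outdir / "tree_traits.nwk").write_text(results["tree_traits"].newick() + "\n")
    tangle = {
        "entanglement": results["entanglement"],
        "L": config.entanglement_L,
        "leaf_order_snp": results["tree_snp"].leaves(),
        "leaf_order_traits": results["tree_traits"].leaves(),
    }
    (outdir / "tanglegram.json").write_text(json.dumps(tangle, indent=2) + "\n")
    manifest = {
        "package": "diallelkit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "path_residual": results["path"].residual,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
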