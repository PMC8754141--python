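"""End-to-end orchestration: simulate-or-load -> rarefy -> alpha -> beta ->
distance decay -> assembly processes, with a machine-readable results bundle.

Every stage writes tab-delimited artifacts into the output directory and the
bundle manifest records provenance (version, config echo, master seed). All
randomness flows from the single master seed through named child streams, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, alpha as alpha_mod, assembly, beta as beta_mod, decay as decay_mod
from .io import (align_inputs, env_columns, read_metadata, read_otu_table, read_tree,
                 write_distance_matrix, write_metadata, write_otu_table, write_tree)
from .simulate import scenario_preset
from .types import DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

@dataclass
class PipelineConfig:
    out_dir: str
    seed: int
    # either a preset name or explicit input paths
    preset: str | None = None
    preset_n_taxa: int = 300
    preset_sites_per_region: int = 10
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    table_orientation: str = "samples_as_columns"
    group_column: str = "region"
    rarefaction_depth: int | None = None  # None: min sample total
    n_rand_nti: int = 999
    n_rand_bnti: int = 999
    n_rand_rc: int = 999
    n_perm_anosim: int = 9999
    n_perm_mantel: int = 999
    n_perm_protest: int = 999
    n_perm_decay: int = 999
    n_perm_diffslope: int = 999
    procrustes_axes: int = 2
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("config must supply a master seed")
        for name in ("n_rand_nti", "n_rand_bnti", "n_rand_rc", "n_perm_anosim",
                     "n_perm_mantel", "n_perm_protest", "n_perm_decay",
                     "n_perm_diffslope"):
            if getattr(self, name) < 99:
                raise ValidationError(f"{name} must be >= 99")
        if self.preset is None and not (self.table_path and self.metadata_path):
            raise ValidationError("config needs either a preset or input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValidationError("config must supply a master seed")
        return cls(**data)


@dataclass
class ResultsBundle:
    out_dir: Path
    manifest: dict
    alpha: pd.DataFrame
    bray: DistanceMatrix
    pcoa: "object"
    tests: pd.DataFrame
    decay_fits: pd.DataFrame
    fractions: pd.DataFrame
    pairs: pd.DataFrame


def _child_seed(master: int, name: str) -> int:
    # deterministic across processes (crc32, not randomized str hash); < 2**31
    h = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(h.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times: dict[str, float] = {}
    seeds = {name: _child_seed(config.seed, name)
             for name in ("simulate", "rarefy", "nti", "bnti", "rc", "anosim",
                          "mantel", "protest", "decay", "diffslope")}

    def tick(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.1fs", stage, stage_times[stage])

    # ---- inputs -----------------------------------------------------------
    if config.preset is not None:
        ds = scenario_preset(config.preset, seed=seeds["simulate"],
                             n_taxa=config.preset_n_taxa,
                             n_sites_per_region=(config.preset_sites_per_region,
                                                 config.preset_sites_per_region))
        table, tree, meta = ds.table, ds.tree, ds.metadata
    else:
        table = read_otu_table(config.table_path, orientation=config.table_orientation)
        tree = read_tree(config.tree_path) if config.tree_path else None
        meta = read_metadata(config.metadata_path)
    table, tree, meta, align_report = align_inputs(table, tree, meta)
    if str(align_report) and (align_report.dropped_samples or align_report.dropped_otus):
        logger.info("alignment: %s", align_report)
    write_otu_table(table, out / "otu_table.tsv", seed=config.seed)
    write_metadata(meta, out / "metadata.tsv", seed=config.seed)
    if tree is not None:
        write_tree(tree, out / "tree.nwk")
    tick("inputs")

    # ---- rarefaction ------------------------------------------------------
    depth = config.rarefaction_depth or int(table.sample_totals().min())
    table = alpha_mod.rarefy(table, depth, seed=seeds["rarefy"])
    write_otu_table(table, out / "otu_table_rarefied.tsv", seed=config.seed,
                    params={"depth": depth})
    tick("rarefy")

    # ---- alpha diversity --------------------------------------------------
    alpha_df = alpha_mod.alpha_table(table, tree, n_rand=config.n_rand_nti,
                                     seed=seeds["nti"])
    alpha_df = alpha_df.join(meta[[config.group_column]])
    alpha_df.to_csv(out / "alpha.tsv", sep="\t")
    tick("alpha")

    # ---- beta structure ---------------------------------------------------
    groups = meta[config.group_column]
    bray = beta_mod.bray_curtis(table)
    write_distance_matrix(bray, out / "bray_curtis.tsv", seed=config.seed)
    ordination = beta_mod.pcoa(bray)
    ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    test_rows = []
    if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
        res = beta_mod.anosim(bray, groups, n_perm=config.n_perm_anosim,
                              seed=seeds["anosim"])
        test_rows.append(("anosim_region", res.statistic_name, res.statistic,
                          res.p_value, res.n_permutations))
    geo = decay_mod.haversine_matrix(meta)
    res = beta_mod.mantel(bray, geo, n_perm=config.n_perm_mantel, seed=seeds["mantel"])
    test_rows.append(("mantel_geo", res.statistic_name, res.statistic,
                      res.p_value, res.n_permutations))
    envs = env_columns(meta)
    if envs:
        env = meta[envs].to_numpy(dtype=float)
        zenv = (env - env.mean(0)) / np.where(env.std(0) > 0, env.std(0), 1.0)
        envdist = DistanceMatrix(
            np.sqrt(((zenv[:, None, :] - zenv[None, :, :]) ** 2).sum(-1)),
            list(meta.index))
        res = beta_mod.mantel(bray, envdist, n_perm=config.n_perm_mantel,
                              seed=seeds["mantel"] + 1)
        test_rows.append(("mantel_env", res.statistic_name, res.statistic,
                          res.p_value, res.n_permutations))
        try:
            env_ord = beta_mod.env_pca(meta[envs])
            env_ord.coordinates.to_csv(out / "env_pca.tsv", sep="\t")
        except ValidationError as exc:
            logger.warning("env PCA skipped: %s", exc)
        # Procrustes between community PCoA and environment PCA
        k = config.procrustes_axes
        try:
            res = beta_mod.procrustes_protest(
                ordination.coordinates.iloc[:, :k], env_ord.coordinates.iloc[:, :k],
                n_perm=config.n_perm_protest, seed=seeds["protest"])
            test_rows.append(("protest_env", res.statistic_name, res.statistic,
                              res.p_value, res.n_permutations))
        except (ValidationError, IndexError) as exc:
            logger.warning("PROTEST skipped: %s", exc)
    tests = pd.DataFrame(test_rows, columns=["test", "statistic_name", "statistic",
                                             "p_value", "n_permutations"])
    tick("beta")

    # ---- distance decay ---------------------------------------------------
    decay_rows = []
    fit = decay_mod.fit_distance_decay(bray, geo, n_perm=config.n_perm_decay,
                                       seed=seeds["decay"])
    decay_rows.append(("all", fit.slope, fit.intercept, fit.r2_adj, fit.p_value,
                       fit.n_pairs))
    region_pairs = {}
    for g in sorted(groups.unique()):
        ids = list(meta.index[groups == g])
        if len(ids) < 3:
            continue
        sub_b, sub_g = bray.reorder(ids), geo.reorder(ids)
        fit_g = decay_mod.fit_distance_decay(sub_b, sub_g, n_perm=config.n_perm_decay,
                                             seed=seeds["decay"] + 1)
        decay_rows.append((str(g), fit_g.slope, fit_g.intercept, fit_g.r2_adj,
                           fit_g.p_value, fit_g.n_pairs))
        region_pairs[g] = decay_mod.decay_pairs(sub_b, sub_g)
    decay_fits = pd.DataFrame(decay_rows, columns=["group", "slope", "intercept",
                                                   "r2_adj", "p_value", "n_pairs"])
    if len(region_pairs) == 2:
        (ga, pa), (gb, pb) = sorted(region_pairs.items())
        res = decay_mod.diff_slope_test(pa, pb, n_perm=config.n_perm_diffslope,
                                        seed=seeds["diffslope"])
        tests.loc[len(tests)] = [f"diffslope_{ga}_vs_{gb}", res.statistic_name,
                                 res.statistic, res.p_value, res.n_permutations]
    decay_fits.to_csv(out / "decay.tsv", sep="\t", index=False)
    tick("decay")

    # ---- assembly processes ----------------------------------------------
    if tree is not None:
        bnti = assembly.beta_nti(table, tree, n_rand=config.n_rand_bnti,
                                 seed=seeds["bnti"])
        rc = assembly.rc_bray(table, n_rand=config.n_rand_rc, seed=seeds["rc"])
        bnti.to_csv(out / "bnti.tsv", sep="\t")
        rc.to_csv(out / "rcbray.tsv", sep="\t")
        pairs = assembly.classify_pairs(bnti, rc)
        fractions = assembly.summarize_fractions(pairs, groups=groups)
        pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        fractions.to_csv(out / "fractions.tsv", sep="\t")
    else:
        pairs = pd.DataFrame(columns=["sample_i", "sample_j", "beta_nti",
                                      "rc_bray", "process"])
        fractions = pd.DataFrame()
    tests.to_csv(out / "tests.tsv", sep="\t", index=False)
    tick("assembly")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "child_seeds": seeds,
        "config": {k: v for k, v in asdict(config).items()},
        "rarefaction_depth": depth,
        "stage_seconds": stage_times,
        "files": sorted(p.name for p in out.glob("*.tsv"))
                 + sorted(p.name for p in out.glob("*.nwk")),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    bundle = ResultsBundle(out_dir=out, manifest=manifest, alpha=alpha_df,
                           bray=bray, pcoa=ordination, tests=tests,
                           decay_fits=decay_fits, fractions=fractions, pairs=pairs)
    if config.make_figures:
        _make_figures(bundle)
    tick("report")
    return bundle


def report(bundle: ResultsBundle) -> str:
    """Human-readable summary of a completed bundle."""
    required = ["alpha.tsv", "bray_curtis.tsv", "tests.tsv", "decay.tsv"]
    missing = [f for f in required if not (bundle.out_dir / f).exists()]
    if missing:
        raise ValidationError(f"bundle incomplete; missing {missing}")
    lines = [
        f"microbiogeo v{bundle.manifest['version']} — seed {bundle.manifest['seed']}",
        f"samples: {len(bundle.alpha)}, rarefaction depth: "
        f"{bundle.manifest['rarefaction_depth']}",
        "",
        "alpha diversity (mean per group):",
    ]
    group_col = bundle.manifest["config"]["group_column"]
    num = bundle.alpha.select_dtypes("number")
    means = num.join(bundle.alpha[group_col]).groupby(group_col).mean(numeric_only=True)
    lines.append(means.round(3).to_string())
    lines.append("")
    lines.append("hypothesis tests:")
    lines.append(bundle.tests.round(4).to_string(index=False))
    lines.append("")
    lines.append("distance-decay fits (similarity per km):")
    lines.append(bundle.decay_fits.round(6).to_string(index=False))
    if len(bundle.fractions):
        lines.append("")
        lines.append("assembly process fractions:")
        lines.append(bundle.fractions.round(3).to_string())
        modal = bundle.fractions.loc["all"].drop("n_pairs").astype(float).idxmax()
        lines.append(f"modal process over all pairs: {modal}")
    text = "\n".join(lines) + "\n"
    with open(bundle.out_dir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(text)
    return text


def _make_figures(bundle: ResultsBundle) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group_col = bundle.manifest["config"]["group_column"]
    groups = bundle.alpha[group_col]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, metric in zip(axes, ["richness", "shannon", "pd"]):
        if metric not in bundle.alpha:
            continue
        data = [bundle.alpha.loc[groups == g, metric].dropna() for g in sorted(groups.unique())]
        ax.boxplot(data, tick_labels=sorted(groups.unique()))
        ax.set_title(metric)
    fig.tight_layout()
    fig.savefig(bundle.out_dir / "fig_alpha.png", dpi=120)
    plt.close(fig)

    coords = bundle.pcoa.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted(groups.unique()):
        sub = coords.loc[groups[groups == g].index]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g))
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(bundle.out_dir / "fig_pcoa.png", dpi=120)
    plt.close(fig)

    if len(bundle.fractions):
        fig, ax = plt.subplots(figsize=(6, 4))
        frac = bundle.fractions.drop(columns="n_pairs")
        bottom = np.zeros(len(frac))
        for proc in frac.columns:
            ax.bar(frac.index, frac[proc], bottom=bottom, label=proc)
            bottom += frac[proc].to_numpy()
        ax.set_ylabel("fraction of pairs")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(bundle.out_dir / "fig_fractions.png", dpi=120)
        plt.close(fig)
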