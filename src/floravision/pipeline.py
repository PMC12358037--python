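"""End-to-end study orchestration: process -> vision -> markers -> statistics.

:func:`run_full_analysis` reproduces the structure of the emulated study on
any input (by default the synthetic study set): per-spectrum colour loci and
contrasts under both pollinator models, sector/quadrant tallies,
below-threshold counts per colour class, marker points with binned
frequencies and MAD/minAD fit metrics, phylogenetic ANOVAs with Holm-adjusted
post hoc tables, and a PCA check of the colour-class grouping.

All output tables are plain delimited text with a commented provenance
header (package version, config hash, seed), so a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .markers import BEE_OPTIMA, DiscriminationOptima, MarkerSettings
from . import markers as mk
from . import phylostats as ps
from . import spectra as sp
from . import synthdata as sd
from . import vision as vis

__all__ = ["AnalysisConfig", "StudyReport", "run_full_analysis", "validate_grouping_pca"]

logger = logging.getLogger(__name__)

#: Colour classes whose marker-point metrics enter the fit-metric ANOVA
#: (the study compares green, green-yellow and the bee-preferred blue-violet).
MARKER_METRIC_CLASSES = ("green", "green_yellow", "blue_violet")


@dataclass
class AnalysisConfig:
    """Configuration of a full study run.

    Paths may be None, in which case the synthetic study set and a Yule tree
    are generated from ``seed``.  All stages derive their random streams from
    ``seed``, so a run is fully reproducible.
    """

    spectra_path: str | None = None
    spectra_dialect: str = "wide"
    groups_path: str | None = None
    tree_path: str | None = None
    background_path: str | None = None
    preset_path: str | None = None
    class_counts: dict[str, int] | None = None
    models: tuple[str, ...] = ("hexagon", "fly_categorical")
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(vis.DEFAULT_THRESHOLDS)
    )
    smooth_span: float = 0.20
    marker_settings: MarkerSettings = field(default_factory=MarkerSettings)
    optima: tuple[float, ...] = (400.0, 500.0)
    n_sim: int = 10000
    seed: int = 1
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "marker_settings" in raw:
            raw["marker_settings"] = MarkerSettings(**raw["marker_settings"])
        for key in ("models", "optima"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """All tables produced by one full run."""

    contrasts: pd.DataFrame
    sector_tallies: pd.DataFrame
    threshold_counts: pd.DataFrame
    marker_points: pd.DataFrame
    marker_bins: pd.DataFrame
    fit_metrics: pd.DataFrame
    excluded_no_markers: list[str]
    phylanova: pd.DataFrame
    posthoc: pd.DataFrame
    pca_scores: pd.DataFrame
    config: AnalysisConfig


def validate_grouping_pca(ss: sp.SpectrumSet, n_components: int = 2) -> pd.DataFrame:
    """PCA of the reflectance matrix to check the colour-class grouping.

    Rows are spectra, features are wavelengths (centred).  Returns a score
    table with columns ``label, group, PC1, PC2`` and the explained-variance
    fractions in ``df.attrs["explained_variance_ratio"]``.  A degenerate set
    (identical spectra, zero total variance) is flagged via
    ``df.attrs["degenerate"]``.
    """
    if len(ss) < 3:
        raise ValueError("PCA grouping check needs at least 3 spectra")
    X = np.vstack([s.reflectance for s in ss])
    total_var = float(np.var(X - X.mean(axis=0)))
    n_components = min(n_components, len(ss) - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):  # zero-variance input is flagged below
        scores = pca.fit_transform(X)
    df = pd.DataFrame(
        {
            "label": ss.labels,
            "group": [ss.group_of(lab) for lab in ss.labels],
            **{f"PC{i + 1}": scores[:, i] for i in range(n_components)},
        }
    )
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    df.attrs["components"] = pca.components_
    df.attrs["degenerate"] = total_var < 1e-12
    if df.attrs["degenerate"]:
        logger.warning("PCA grouping check: spectra are identical; variance is zero")
    return df


def _load_inputs(cfg: AnalysisConfig, rng_seeds: list[int]):
    presets = sd.load_presets(cfg.preset_path) if cfg.preset_path else None
    if cfg.spectra_path is None:
        ss = sd.make_study_set(cfg.class_counts, seed=rng_seeds[0], presets=presets)
    else:
        ss = sp.read_spectra(cfg.spectra_path, dialect=cfg.spectra_dialect)
        if cfg.groups_path:
            gdf = pd.read_csv(cfg.groups_path, sep=None, engine="python", comment="#")
            ss = sp.SpectrumSet(
                ss.spectra, dict(zip(gdf["label"].astype(str), gdf["group"].astype(str)))
            )
    if cfg.tree_path is None:
        tree = sd.make_yule_tree(labels=ss.labels, seed=rng_seeds[1])
    else:
        tree = ps.PhyloTree.from_newick(cfg.tree_path)
    background = None
    if cfg.background_path:
        background = sp.read_spectra(cfg.background_path).spectra[0]
    return ss, tree, background


def _phylanova_stack(
    tree: ps.PhyloTree,
    trait_frames: dict[str, pd.DataFrame],
    n_sim: int,
    seeds: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one phylANOVA per named trait table; stack omnibus and post hoc rows."""
    omni, post = [], []
    for name, traits in trait_frames.items():
        sub = tree
        if set(traits["label"]) != set(tree.tip_labels):
            sub = tree.prune_to(list(traits["label"]))
        res = ps.phylanova(sub, traits, n_sim=n_sim, seed=seeds[name])
        k = traits["group"].nunique()
        n = len(traits)
        omni.append(
            {
                "comparison": name,
                "F": res.f_observed,
                "df_between": k - 1,
                "df_within": n - k,
                "p_phylo": res.p_phylo,
                "n_sim": res.n_sim,
                "seed": res.seed,
            }
        )
        if res.posthoc is not None:
            ph = res.posthoc.copy()
            ph.insert(0, "comparison", name)
            post.append(ph)
    return (
        pd.DataFrame(omni),
        pd.concat(post, ignore_index=True) if post else pd.DataFrame(),
    )


def _provenance_header(cfg: AnalysisConfig, stage: str) -> str:
    return (
        f"# floravision {__version__} | stage={stage} | "
        f"config_hash={cfg.config_hash()} | seed={cfg.seed}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, cfg: AnalysisConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg, stage))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_full_analysis(cfg: AnalysisConfig) -> StudyReport:
    """Run the complete study workflow and (optionally) write its tables.

    Deterministic given ``cfg.seed``.  Any stage failure aborts with a
    stage-tagged error after removing partial outputs.
    """
    seq = np.random.SeedSequence(cfg.seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(12)]

    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    written: list[Path] = []
    stage = "setup"
    try:
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)

        stage = "load"
        ss_raw, tree, background = _load_inputs(cfg, child)
        logger.info("stage=load n_spectra=%d n_tips=%d", len(ss_raw), len(tree))

        stage = "process"
        ss = ss_raw.map(
            lambda s: sp.fix_negative(sp.smooth_spectrum(s, span=cfg.smooth_span))
        )
        ss = sp.aggregate_spectra(ss)
        logger.info("stage=process n_spectra=%d", len(ss))

        stage = "vision"
        contexts = []
        for model in cfg.models:
            maker = vis.bee_context if model == "hexagon" else vis.fly_context
            contexts.append(maker(grid=ss.grid, background=background))
        contrasts = vis.analyse_set(ss, contexts, thresholds=cfg.thresholds)
        sector_tallies = (
            contrasts.groupby(["model", "group", "sector"], dropna=False)
            .size()
            .reset_index(name="n")
        )
        threshold_counts = (
            contrasts.assign(below=~contrasts["above_threshold"])
            .groupby(["model", "group"], dropna=False)
            .agg(n=("label", "size"), n_below_threshold=("below", "sum"))
            .reset_index()
        )
        logger.info("stage=vision rows=%d", len(contrasts))

        stage = "markers"
        marker_sets = [mk.detect_marker_points(s, cfg.marker_settings) for s in ss]
        marker_points = pd.DataFrame(
            {
                "label": [m.label for m in marker_sets],
                "group": [ss.group_of(m.label) for m in marker_sets],
                "marker_points": [
                    ";".join(f"{p:.10g}" for p in m.points) for m in marker_sets
                ],
            }
        )
        bins = []
        for cls, subset in ss.by_group().items():
            members = set(subset.labels)
            b = mk.bin_marker_points([m for m in marker_sets if m.label in members])
            b.insert(0, "group", cls)
            bins.append(b)
        marker_bins = pd.concat(bins, ignore_index=True) if bins else pd.DataFrame()

        stage = "metrics"
        optima = DiscriminationOptima(tuple(cfg.optima), taxon=BEE_OPTIMA.taxon)
        metric_members = {
            lab
            for lab, cls in ss.group_labels.items()
            if cls in MARKER_METRIC_CLASSES
        }
        fit_metrics, excluded = mk.metrics_table(
            [m for m in marker_sets if m.label in metric_members], optima
        )
        if not fit_metrics.empty:
            fit_metrics.insert(1, "group", fit_metrics["label"].map(ss.group_labels))
        logger.info(
            "stage=metrics rows=%d excluded=%d", len(fit_metrics), len(excluded)
        )

        stage = "phylanova"
        chrom = {}
        hex_rows = contrasts[contrasts.model == "hexagon"]
        for model in cfg.models:
            rows = contrasts[contrasts.model == model]
            labelled = rows.dropna(subset=["group"])
            chrom[f"chromatic_{model}_all_classes"] = pd.DataFrame(
                {
                    "label": labelled["label"],
                    "value": labelled["chromatic_EU"],
                    "group": labelled["group"],
                }
            )
            gg = labelled[labelled.group.isin(["green", "green_yellow"])]
            if gg["group"].nunique() == 2:
                chrom[f"chromatic_{model}_green_vs_green_yellow"] = pd.DataFrame(
                    {"label": gg["label"], "value": gg["chromatic_EU"], "group": gg["group"]}
                )
        if "hexagon" in cfg.models:
            labelled = hex_rows.dropna(subset=["group"])
            chrom["achromatic_hexagon_all_classes"] = pd.DataFrame(
                {
                    "label": labelled["label"],
                    "value": labelled["achromatic_EU"],
                    "group": labelled["group"],
                }
            )
            gg = labelled[labelled.group.isin(["green", "green_yellow"])]
            if gg["group"].nunique() == 2:
                chrom["achromatic_hexagon_green_vs_green_yellow"] = pd.DataFrame(
                    {"label": gg["label"], "value": gg["achromatic_EU"], "group": gg["group"]}
                )
        if not fit_metrics.empty:
            # drop classes reduced below 2 members by no-marker exclusions
            sizes = fit_metrics.groupby("group")["label"].size()
            fm = fit_metrics[fit_metrics["group"].isin(sizes[sizes >= 2].index)]
            if fm["group"].nunique() >= 2:
                for col in fm.columns:
                    if col in ("label", "group", "n_points"):
                        continue
                    chrom[f"fit_{col}"] = pd.DataFrame(
                        {"label": fm["label"], "value": fm[col], "group": fm["group"]}
                    )
        seeds = {
            name: int((child[2] + i) % (2**31)) for i, name in enumerate(chrom)
        }
        phyl_df, post_df = _phylanova_stack(tree, chrom, cfg.n_sim, seeds)
        logger.info("stage=phylanova comparisons=%d", len(phyl_df))

        stage = "pca"
        pca_scores = validate_grouping_pca(ss)

        stage = "write"
        report = StudyReport(
            contrasts,
            sector_tallies,
            threshold_counts,
            marker_points,
            marker_bins,
            fit_metrics,
            excluded,
            phyl_df,
            post_df,
            pca_scores,
            cfg,
        )
        if out_dir is not None:
            tables = {
                "contrasts.tsv": contrasts,
                "sector_tallies.tsv": sector_tallies,
                "threshold_counts.tsv": threshold_counts,
                "marker_points.tsv": marker_points,
                "marker_bins.tsv": marker_bins,
                "fit_metrics.tsv": fit_metrics,
                "phylanova.tsv": phyl_df,
                "posthoc.tsv": post_df,
                "pca_scores.tsv": pca_scores,
                "excluded_no_markers.tsv": pd.DataFrame(
                    {"label": excluded, "reason": ["no marker points"] * len(excluded)}
                ),
            }
            for fname, df in tables.items():
                path = out_dir / fname
                _write_table(df, path, cfg, fname.removesuffix(".tsv"))
                written.append(path)
            sp.write_spectra(ss, out_dir / "processed_spectra.tsv")
            written.append(out_dir / "processed_spectra.tsv")
            tree.write_newick(out_dir / "tree.nwk")
            written.append(out_dir / "tree.nwk")
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
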