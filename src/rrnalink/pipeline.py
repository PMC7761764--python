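"""End-to-end orchestration: screen → classify → features → stats.

Consumes a directory of ``<genome>.fna`` / ``<genome>.gff`` pairs and
writes diff-stable TSV reports.  Genomes excluded by concordance screening
appear in ``screening.tsv`` only; every default and decision flag is echoed
to the run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import annotation_io, comparative_stats, concordance, genomic_features
from .annotation_io import Topology
from .insilico_pcr import DEFAULT_PRIMER_PAIRS
from .operon_classifier import ClassifierConfig, call_genome, units_to_frame

log = logging.getLogger(__name__)

STAGES = ("screen", "classify", "features", "stats")

PCA_FEATURES = ["genome_size", "genome_at", "n16S", "mean_16S_len", "mean_23S_len"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    input_dir: Union[str, Path]
    output_dir: Union[str, Path]
    labels_path: Optional[Union[str, Path]] = None
    its_threshold: int = 1500
    mismatch_budgets: tuple[int, ...] = (2, 4)
    topology_override: Optional[dict[str, str]] = None
    # optional functional-comparison inputs
    cog_linked_path: Optional[Union[str, Path]] = None
    cog_unlinked_path: Optional[Union[str, Path]] = None
    rnase_counts_path: Optional[Union[str, Path]] = None
    tree_path: Optional[Union[str, Path]] = None
    pgls_predictor_path: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if list(self.mismatch_budgets) != sorted(set(self.mismatch_budgets)):
            raise ValueError("mismatch budgets must be strictly increasing")
        if self.its_threshold <= 0:
            raise ValueError("its_threshold must be positive")


@dataclass
class PipelineResult:
    output_dir: Path
    screening: pd.DataFrame
    units: Optional[pd.DataFrame] = None
    calls: Optional[pd.DataFrame] = None
    features: Optional[pd.DataFrame] = None


def _discover_genomes(input_dir: Path) -> list[tuple[str, Path, Path]]:
    genomes = []
    for fna in sorted(input_dir.glob("*.fna")):
        gff = fna.with_suffix(".gff")
        if not gff.exists():
            raise PipelineError(f"no GFF companion for {fna.name}")
        genomes.append((fna.stem, fna, gff))
    if not genomes:
        raise PipelineError(f"no .fna genomes found in {input_dir}")
    return genomes


def run_pipeline(config: PipelineConfig, upto: str = "stats") -> PipelineResult:
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; expected one of {STAGES}")
    upto_idx = STAGES.index(upto)
    input_dir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("rrnalink")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("its_threshold=%d", config.its_threshold)
        log.info("mismatch_budgets=%s", list(config.mismatch_budgets))
        log.info("singles_policy=unlinked")
        log.info("mismatch_semantics=absolute_per_primer")
        for t, p in DEFAULT_PRIMER_PAIRS.items():
            log.info(
                "primer_pair %s: %s/%s window (%d, %d)",
                t.value, p.forward.iupac_seq, p.reverse.iupac_seq,
                p.min_product_len, p.max_product_len,
            )
        return _run(config, input_dir, outdir, upto_idx)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, input_dir: Path, outdir: Path, upto_idx: int) -> PipelineResult:
    cfg = ClassifierConfig(its_threshold=config.its_threshold)

    # ---- screen ----
    screening_results = []
    parsed = {}
    for gid, fna, gff in _discover_genomes(input_dir):
        try:
            topo = annotation_io.detect_topology(gff, override=config.topology_override)
            records = annotation_io.read_genome(fna, topology=topo)
            feats = annotation_io.read_rrna_features(gff)
            ann = concordance.profile_counts(feats)
            res = concordance.screen_genome(
                gid, records, ann, DEFAULT_PRIMER_PAIRS, config.mismatch_budgets
            )
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage screen failed for genome {gid!r}: {err}") from err
        screening_results.append(res)
        parsed[gid] = (records, feats)
        log.info("screened %s: %s", gid, res.verdict)
    screening = concordance.screening_to_frame(screening_results)
    screening.to_csv(outdir / "screening.tsv", sep="\t", index=False)
    result = PipelineResult(output_dir=outdir, screening=screening)
    if upto_idx < 1:
        return result

    # ---- classify ----
    passing = [r.genome_id for r in screening_results if r.passed]
    unit_frames, call_rows = [], []
    units_by_genome, calls_by_genome = {}, {}
    for gid in passing:
        records, feats = parsed[gid]
        try:
            chrom_map = {r.id: (r.length, r.topology) for r in records}
            units, call = call_genome(gid, feats, chrom_map, cfg)
        except Exception as err:
            raise PipelineError(f"stage classify failed for genome {gid!r}: {err}") from err
        units_by_genome[gid] = units
        calls_by_genome[gid] = call
        unit_frames.append(units_to_frame(gid, units))
        call_rows.append(
            {
                "genome": gid,
                "status": call.status.value,
                "n_linked": call.n_linked_units,
                "n_unlinked": call.n_unlinked_units,
                "n_singles": call.n_singles,
            }
        )
    units_df = (
        pd.concat(unit_frames, ignore_index=True)
        if unit_frames
        else units_to_frame("", [])
    )
    calls_df = pd.DataFrame(
        call_rows, columns=["genome", "status", "n_linked", "n_unlinked", "n_singles"]
    )
    units_df.to_csv(outdir / "units.tsv", sep="\t", index=False)
    with open(outdir / "genome_calls.tsv", "w") as fh:
        fh.write("# singles_policy=unlinked\n")
        calls_df.to_csv(fh, sep="\t", index=False)
    result.units = units_df
    result.calls = calls_df
    if upto_idx < 2:
        return result

    # ---- features ----
    labels = (
        genomic_features.read_symbiont_labels(config.labels_path)
        if config.labels_path
        else None
    )
    try:
        rows = genomic_features.build_feature_table(
            {gid: parsed[gid][0] for gid in passing},
            units_by_genome,
            calls_by_genome,
            labels,
        )
    except Exception as err:
        raise PipelineError(f"stage features failed: {err}") from err
    features_df = genomic_features.feature_frame(rows)
    features_df.to_csv(outdir / "features.tsv", sep="\t", index=False)
    result.features = features_df
    if upto_idx < 3:
        return result

    # ---- stats ----
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    try:
        _run_stats(config, features_df, stats_dir)
    except Exception as err:
        raise PipelineError(f"stage stats failed: {err}") from err
    return result


def _run_stats(config: PipelineConfig, features: pd.DataFrame, stats_dir: Path) -> None:
    numeric = [c for c in PCA_FEATURES + ["mean_16S_at"] if c in features.columns]
    by_status = features[features["status"] != "undetermined"]
    status_counts = by_status["status"].value_counts()
    usable = status_counts[status_counts >= 2].index.tolist()

    kw_rows, dunn_frames, welch_rows = [], [], []
    sub = by_status[by_status["status"].isin(usable)]
    for col in numeric:
        clean = sub.dropna(subset=[col])
        counts = clean["status"].value_counts()
        groups = counts[counts >= 2].index.tolist()
        data = clean[clean["status"].isin(groups)]
        if data[col].nunique() <= 1:
            log.info("skipping status comparison for %s: constant values", col)
            continue
        if len(groups) >= 3:
            res = comparative_stats.kruskal_dunn(data[col].to_numpy(), data["status"].to_numpy())
            kw_rows.append({"feature": col, "H": res.h_statistic, "p": res.p_value})
            d = res.dunn.copy()
            d.insert(0, "feature", col)
            dunn_frames.append(d)
        elif len(groups) == 2:
            a, b = groups
            res = comparative_stats.welch_t(
                data.loc[data["status"] == a, col],
                data.loc[data["status"] == b, col],
            )
            welch_rows.append(
                {"feature": col, "group_a": a, "group_b": b,
                 "t": res.t, "df": res.df, "p": res.p}
            )
        else:
            log.info("skipping status comparison for %s: fewer than 2 usable groups", col)
    if kw_rows:
        pd.DataFrame(kw_rows).to_csv(stats_dir / "kruskal_dunn.tsv", sep="\t", index=False)
        pd.concat(dunn_frames, ignore_index=True).to_csv(
            stats_dir / "dunn_pairs.tsv", sep="\t", index=False
        )
    if welch_rows:
        pd.DataFrame(welch_rows).to_csv(stats_dir / "welch_status.tsv", sep="\t", index=False)

    # symbiont vs nonsymbiont contrasts among unlinked genomes
    unl = features[(features["status"] == "unlinked") & (features["symbiont"] != "unknown")]
    sym_rows = []
    for col in numeric:
        clean = unl.dropna(subset=[col])
        yes = clean.loc[clean["symbiont"] == "yes", col]
        no = clean.loc[clean["symbiont"] == "no", col]
        if len(yes) >= 2 and len(no) >= 2:
            res = comparative_stats.welch_t(yes, no)
            sym_rows.append(
                {"feature": col, "mean_symbiont": yes.mean(), "mean_nonsymbiont": no.mean(),
                 "t": res.t, "df": res.df, "p": res.p}
            )
    if sym_rows:
        pd.DataFrame(sym_rows).to_csv(stats_dir / "welch_symbiont.tsv", sep="\t", index=False)

    # ordination of the five genomic features
    mat = features.set_index("genome_id")[[c for c in PCA_FEATURES if c in features.columns]]
    mat = mat.dropna()
    if mat.shape[0] >= 2 and mat.shape[1] >= 2:
        res = comparative_stats.pca(mat)
        res.scores.to_csv(stats_dir / "pca_scores.tsv", sep="\t")
        res.loadings.to_csv(stats_dir / "pca_loadings.tsv", sep="\t")
        pd.DataFrame(
            {
                "component": res.scores.columns,
                "explained_variance": res.explained_variance,
                "explained_variance_ratio": res.explained_variance_ratio,
            }
        ).to_csv(stats_dir / "pca_variance.tsv", sep="\t", index=False)
    else:
        log.info("skipping PCA: not enough complete rows")

    # optional: COG paired t across phyla
    if config.cog_linked_path and config.cog_unlinked_path:
        linked = pd.read_csv(config.cog_linked_path, sep="\t", index_col=0)
        unlinked = pd.read_csv(config.cog_unlinked_path, sep="\t", index_col=0)
        comparative_stats.paired_t_by_category(linked, unlinked).to_csv(
            stats_dir / "cog_paired_t.tsv", sep="\t", index=False
        )

    # optional: PGLS of RNase counts on linkage status
    if config.rnase_counts_path and config.tree_path and config.pgls_predictor_path:
        counts = pd.read_csv(config.rnase_counts_path, sep="\t", index_col=0)
        pred = pd.read_csv(config.pgls_predictor_path, sep="\t", index_col=0).iloc[:, 0]
        rows = []
        for fam in counts.columns:
            fit = comparative_stats.pgls_brownian(
                str(config.tree_path), counts[fam], pred
            )
            rows.append(
                {"family": fam, "slope": fit.slope, "se": fit.slope_se,
                 "t": fit.t_stat, "p": fit.p_value}
            )
        pd.DataFrame(rows).to_csv(stats_dir / "pgls_rnase.tsv", sep="\t", index=False)
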