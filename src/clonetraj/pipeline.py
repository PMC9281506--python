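"""End-to-end orchestration: QC -> normalize -> cluster -> typing -> CNV ->
subclones -> trajectory -> composition -> survival -> crosstalk.

Each stage reads the previous stage's in-memory results, logs its
parameters, and writes plain TSV outputs into the output directory.
Re-running with an identical config and seed reproduces identical files.
A single global seed is fanned out to per-stage seeds by fixed offsets so
stages stay independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import crosstalk as crosstalk_mod
from . import io_qc, signatures as sig_mod, stats as stats_mod
from . import trajectory as traj_mod
from .containers import CellMeta

log = logging.getLogger("clonetraj")

# fixed seed offsets per stage
_SEED_CLUSTER = 11
_SEED_SCORE = 23
_SEED_REFERENCE = 37
_SEED_CROSSTALK = 53


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    signature_file: str
    lr_pairs_file: str | None = None
    survival_file: str | None = None
    gene_annotation_file: str | None = None  # default: genes.tsv in input_dir
    min_genes: int = 1500
    max_mito_frac: float = 0.12
    min_cells_per_gene: int = 10
    n_hvg: int = 5000
    n_pcs: int = 50
    cluster_resolution: float = 1.0
    reference_type: str = "Mic"
    reference_n: int = 300
    cnv_window: int = 101
    cnv_expr_cutoff: float = 0.1
    cnv_min_cells_per_gene: int = 5
    n_subclones: int | None = None
    n_perm: int = 1000
    rng_seed: int = 0

    def validate(self) -> None:
        for label, path in [
            ("input_dir", self.input_dir),
            ("signature_file", self.signature_file),
            ("lr_pairs_file", self.lr_pairs_file),
            ("survival_file", self.survival_file),
            ("gene_annotation_file", self.gene_annotation_file),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _write(df: pd.DataFrame, out: Path, name: str, **kwargs) -> None:
    df.to_csv(out / name, sep="\t", index=kwargs.pop("index", False),
              float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory results keyed by stage."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    stage = "setup"
    try:
        config.to_yaml(out / "run_config.yaml")

        stage = "qc"
        log.info("stage qc: reading %s", config.input_dir)
        counts = io_qc.read_counts_mtx(config.input_dir)
        ann_path = config.gene_annotation_file or str(Path(config.input_dir) / "genes.tsv")
        gene_ann = io_qc.read_gene_annotation(ann_path)
        meta_path = Path(config.input_dir) / "cell_meta.tsv"
        meta = CellMeta(pd.read_csv(meta_path, sep="\t"))
        counts, report = io_qc.qc_filter(
            counts, config.min_genes, config.max_mito_frac, config.min_cells_per_gene
        )
        meta = CellMeta(meta.aligned(counts.cell_ids))
        _write(pd.DataFrame([report.__dict__]), out, "qc_report.tsv")
        results["qc_report"] = report
        log.info("stage qc: kept %d/%d cells, %d/%d genes",
                 report.n_cells_kept, report.n_cells_in,
                 report.n_genes_kept, report.n_genes_in)

        stage = "normalize"
        e = io_qc.normalize_e(counts)
        er = io_qc.relative_er(e)
        results["E"] = e
        results["Er"] = er

        stage = "cluster"
        clusters = io_qc.preprocess_cluster(
            e, config.n_hvg, config.n_pcs,
            rng_seed=config.rng_seed + _SEED_CLUSTER,
            resolution=config.cluster_resolution,
        )
        meta.table["cluster"] = clusters.reindex(meta.table["cell_id"]).to_numpy()
        log.info("stage cluster: %d clusters", clusters.nunique())

        stage = "annotate"
        sigs = sig_mod.read_signatures(config.signature_file)
        params = sig_mod.ModuleScoreParams(rng_seed=config.rng_seed + _SEED_SCORE)
        assignment, score_table = sig_mod.se_classify(e, clusters.to_numpy(), sigs, params)
        meta.table["cell_type"] = meta.table["cluster"].map(assignment)
        _write(score_table.reset_index(), out, "se_scores.tsv")
        _write(meta.table[["cell_id", "cluster", "cell_type"]], out, "cell_types.tsv")
        results["cell_types"] = assignment
        log.info("stage annotate: %s", assignment)

        stage = "cnv"
        ref_ids = cnv_mod.sample_reference(
            meta, config.reference_type, n=config.reference_n,
            rng_seed=config.rng_seed + _SEED_REFERENCE,
        )
        cnv = cnv_mod.infer_cnv(
            e, gene_ann, ref_ids,
            window=config.cnv_window,
            expr_cutoff=config.cnv_expr_cutoff,
            min_cells_per_gene=config.cnv_min_cells_per_gene,
            counts=counts,
        )
        levels = cnv_mod.cnv_level(cnv, counts=counts)
        results["cnv"] = cnv
        results["cnv_level"] = levels
        _write(levels.reset_index(), out, "cnv_level.tsv")

        stage = "subclones"
        non_ref = [c for c in cnv.cell_ids if c not in set(ref_ids)]
        sub = cnv_mod.call_subclones(cnv, cells=non_ref, k=config.n_subclones)
        cluster_series = pd.Series(
            meta.table["cluster"].to_numpy(), index=meta.table["cell_id"]
        ).reindex(levels.index)
        malignant = cnv_mod.classify_malignancy(levels, cluster_series, ref_ids)
        meta.table["malignant"] = malignant.reindex(meta.table["cell_id"]).to_numpy()
        sub_labels = sub.labels.map(lambda k: f"subclone{k}")
        meta.table["subclone"] = (
            sub_labels.reindex(meta.table["cell_id"])
            .where(meta.table["malignant"].fillna(False).astype(bool).to_numpy(), pd.NA)
            .to_numpy()
        )
        results["subclones"] = sub
        results["malignant"] = malignant
        _write(meta.table, out, "cell_meta_final.tsv")
        _write(pd.DataFrame({"gene_id": cnv.gene_ids}), out,
               "cnv_gene_order.tsv")
        _write(pd.DataFrame({"reference_cell_id": cnv.reference_cell_ids}),
               out, "cnv_reference_cells.tsv")
        if sub.linkage.size:
            _write(pd.DataFrame(sub.linkage,
                                columns=["child_a", "child_b",
                                         "merge_height", "n_members"]),
                   out, "subclone_linkage.tsv")
        log.info("stage subclones: k=%d silhouette=%.3f", sub.k, sub.silhouette)

        stage = "trajectory"
        traj_markers = derive_trajectory_markers(e, meta)
        traj = traj_mod.trajectory_score(
            e, traj_markers["undiff"], traj_markers["diff"], params
        )
        per_sample = traj_mod.summarize_by_sample(traj, meta)
        results["trajectory"] = traj
        results["per_sample"] = per_sample
        _write(traj.reset_index(), out, "trajectory_scores.tsv")
        _write(per_sample, out, "trajectory_by_sample.tsv")

        stage = "composition"
        comp_tables = {}
        mal_meta = CellMeta(meta.table[meta.table["malignant"].fillna(False).astype(bool)])
        if mal_meta.table["subclone"].nunique() == 2:
            comp_tables["subclone"] = stats_mod.composition_contrast(
                mal_meta, unit="subclone"
            )
            _write(comp_tables["subclone"], out, "composition_subclone.tsv")
        if meta.table["condition"].nunique() == 2:
            comp_tables["condition"] = stats_mod.composition_contrast(
                meta, unit="condition"
            )
            _write(comp_tables["condition"], out, "composition_condition.tsv")
        results["composition"] = comp_tables

        stage = "survival"
        if config.survival_file is not None:
            surv = pd.read_csv(config.survival_file, sep="\t")
            groups = per_sample.set_index("sample_id")["group"]
            surv["group"] = surv["sample_id"].map(groups)
            surv = surv.dropna(subset=["group"])
            if surv["group"].nunique() == 2:
                km = traj_mod.km_logrank(surv)
                results["survival"] = km
                curve_rows = [
                    c.assign(group=g) for g, c in km["curves"].items()
                ]
                _write(pd.concat(curve_rows), out, "km_curves.tsv")
                _write(
                    pd.DataFrame([{"chi_square": km["chi_square"],
                                   "p_value": km["p_value"],
                                   "events": km["events"]}]),
                    out, "logrank.tsv",
                )
                log.info("stage survival: logrank p=%s", km["p_value"])

        stage = "crosstalk"
        if config.lr_pairs_file is not None:
            pairs = crosstalk_mod.read_lr_pairs(config.lr_pairs_file)
        else:
            pairs = crosstalk_mod.bundled_lr_pairs()
        typed = meta.table.dropna(subset=["cell_type"])
        e_typed = e.subset(cells=list(typed["cell_id"]))
        interactions = crosstalk_mod.lr_score(
            e_typed, typed["cell_type"].to_numpy(), pairs,
            n_perm=config.n_perm, rng_seed=config.rng_seed + _SEED_CROSSTALK,
        )
        _write(interactions, out, "lr_interactions.tsv")
        results["lr_interactions"] = interactions
        if typed["condition"].nunique() == 2:
            diff = crosstalk_mod.lr_condition_differential(
                e_typed, typed["cell_type"].to_numpy(),
                typed["condition"].to_numpy(), pairs,
            )
            _write(diff, out, "lr_condition_differential.tsv")
            results["lr_condition_differential"] = diff

        results["cell_meta"] = meta
        log.info("pipeline complete")
        return results
    except Exception:
        log.error("pipeline halted at stage %r", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def derive_trajectory_markers(e, meta, max_markers: int = 100) -> dict:
    """Derive the undifferentiated / differentiated trajectory marker sets.

    Undifferentiated markers are the genes overexpressed by NSC-like cells
    of the stem-dominant subclone against all other malignant cells;
    differentiated markers come from EpC-like cells of the other subclone.
    Falls back to plain NSC-like vs EpC-like markers when subclone labels
    are unavailable.
    """
    table = meta.table if hasattr(meta, "table") else meta
    mal = table[table["malignant"].fillna(False).astype(bool)].dropna(
        subset=["cell_type"]
    )
    if mal.empty:
        raise ValueError("no malignant cells to derive trajectory markers from")
    has_sub = mal["subclone"].notna().any() and mal["subclone"].nunique() >= 2

    def pick_subclone(cell_type: str, prefer_high: bool) -> str | None:
        if not has_sub:
            return None
        frac = (
            mal.assign(is_t=mal["cell_type"] == cell_type)
            .groupby("subclone")["is_t"].mean()
        )
        return frac.idxmax() if prefer_high else frac.idxmin()

    e_mal = e.subset(cells=list(mal["cell_id"]))

    def markers_of(cell_type: str, subclone) -> sig_mod.SignatureSet:
        sel = mal["cell_type"] == cell_type
        if subclone is not None:
            sel &= mal["subclone"] == subclone
        if sel.sum() < 3:
            sel = mal["cell_type"] == cell_type  # subclone split too small
        labels = np.where(sel.to_numpy(), "target", "rest")
        mk = sig_mod.find_markers(e_mal, labels)
        mk = mk[(mk["group"] == "target") & mk["is_marker"]]
        mk = mk.sort_values("log_fold_change", ascending=False).head(max_markers)
        if mk.empty:
            raise ValueError(f"no markers found for {cell_type} / {subclone}")
        return sig_mod.SignatureSet(f"{cell_type}:{subclone or 'all'}",
                                    list(mk["gene_id"]))

    nsc_sub = pick_subclone("NSC-like", prefer_high=True)
    epc_sub = pick_subclone("EpC-like", prefer_high=True)
    if has_sub and nsc_sub == epc_sub:
        epc_sub = pick_subclone("EpC-like", prefer_high=False)
    return {
        "undiff": markers_of("NSC-like", nsc_sub),
        "diff": markers_of("EpC-like", epc_sub),
    }


def prepare_demo(directory, seed: int = 0, sim_config=None):
    """Write the bundled synthetic demo inputs under ``directory`` and
    return a ready-to-run :class:`PipelineConfig` plus the cohort truth.

    QC thresholds are scaled to the synthetic gene universe (~2,000 genes,
    so the distinct-gene cutoff is 300 rather than the 1,500 used on real
    transcriptomes).
    """
    from .simulate import SimConfig, generate_cohort, write_10x_mtx

    directory = Path(directory)
    input_dir = directory / "input"
    if sim_config is None:
        sim_config = SimConfig(rng_seed=seed)
    cohort = generate_cohort(sim_config)
    write_10x_mtx(cohort.counts, cohort.genes, cohort.cell_meta, input_dir)
    cohort.truth.to_csv(input_dir / "truth.tsv", sep="\t", index=False)

    sigs = [
        sig_mod.SignatureSet(name.split(":", 1)[1], genes)
        for name, genes in cohort.programs.items()
        if name.startswith("markers:")
    ]
    sig_path = input_dir / "signatures.tsv"
    sig_mod.write_signatures(sigs, sig_path)

    relapse = cohort.programs["relapse_program"]
    other = [g for g in cohort.counts.gene_ids
             if g not in set(relapse)][: len(relapse)]
    pairs = pd.DataFrame(
        [(relapse[0], relapse[1], "planted_axis_1"),
         (relapse[2], relapse[3], "planted_axis_2"),
         (other[0], other[1], "null_axis_1"),
         (other[2], other[3], "null_axis_2")],
        columns=["ligand", "receptor", "pathway"],
    )
    lr_path = input_dir / "lr_pairs.tsv"
    pairs.to_csv(lr_path, sep="\t", header=False, index=False)

    surv_path = input_dir / "survival.tsv"
    cohort.samples[["sample_id", "survival_time", "event"]].rename(
        columns={"survival_time": "time"}
    ).to_csv(surv_path, sep="\t", index=False)

    config = PipelineConfig(
        input_dir=str(input_dir),
        output_dir=str(directory / "output"),
        signature_file=str(sig_path),
        lr_pairs_file=str(lr_path),
        survival_file=str(surv_path),
        min_genes=300,
        n_perm=200,
        rng_seed=seed,
    )
    return config, cohort
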