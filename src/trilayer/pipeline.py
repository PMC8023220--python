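"""End-to-end orchestration: quantify -> differential -> heterosis |
allelic -> integrate, with a machine-readable run report.

Every threshold flows from one :class:`~trilayer.config.RunConfig`; every
count in the report is re-derivable from the stage output files written
next to it.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from . import allelic as allelic_mod
from . import differential as diff
from . import heterosis as het
from . import integrate as integ
from . import quantify as qt
from .io import (
    ExpressionMatrix,
    read_allele_counts,
    read_counts,
    read_gene_models,
    read_parental_counts,
    read_peaks,
    read_sample_sheet,
)

logger = logging.getLogger("trilayer")

GENOTYPES = ("P1", "P2", "F1")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _complete_m6a_frame(res: pd.DataFrame, genes: pd.Index) -> pd.DataFrame:
    """Reindex a threshold-rule result onto the m6A-layer gene set so every
    gene counts as tested (absence of a level is evidence, not missingness)."""
    out = res.reindex(genes)
    out["tested"] = True
    out["significant"] = out["significant"].notna() & out["significant"].eq(True)
    out["log2fc"] = out["log2fc"].fillna(0.0)
    out.attrs["contrast"] = res.attrs.get("contrast")
    return out


def run_all(
    config: RunConfig,
    input_dir: str | Path,
    output_dir: str | Path,
    annotation: dict[str, set[str]] | None = None,
) -> dict:
    """Run the full pipeline on a fixture directory; returns the run report.

    Expects ``counts.tsv``, ``samples.tsv``, ``genes.gff3``,
    ``peaks_{P1,P2,F1}_rep{1,2}.bed``, ``alleles.tsv`` and
    ``parental_snp_counts.tsv`` under ``input_dir``.
    """
    input_dir = Path(input_dir)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, object] = {
        "version": __version__,
        "seed": config.rng_seed,
        "fc_threshold": config.fc_threshold,
        "alpha": config.alpha,
        "fpkm_min": config.fpkm_min,
        "window_nt": config.window_nt,
        "k_clusters": config.k_clusters,
        "multiple_testing": config.multiple_testing,
    }

    # ---- load -------------------------------------------------------------
    stage = "load"
    try:
        samples = read_sample_sheet(input_dir / "samples.tsv")
        matrix = read_counts(input_dir / "counts.tsv", samples)
        for geno in GENOTYPES:
            for assay in ("mrna_input", "polysome", "m6a_ip"):
                found = [s for s in matrix.samples if s.genotype == geno and s.assay == assay]
                if not found:
                    raise ValueError(f"missing assay {assay!r} for genotype {geno!r}")
        models = read_gene_models(input_dir / "genes.gff3")
        model_by_id = {m.gene_id: m for m in models}
        peak_files = {
            (geno, rep): input_dir / f"peaks_{geno}_rep{rep}.bed"
            for geno in GENOTYPES
            for rep in (1, 2)
        }
        peaks_raw = {
            key: read_peaks(path, replicate=key[1]) for key, path in peak_files.items()
        }
        alleles = read_allele_counts(input_dir / "alleles.tsv")
        parental = read_parental_counts(input_dir / "parental_snp_counts.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- quantify ----------------------------------------------------------
    stage = "quantify"
    try:
        fpkm = qt.compute_fpkm(matrix, model_by_id)
        expressed = qt.expressed_filter(fpkm, matrix, config.fpkm_min)
        te_table = qt.compute_te(fpkm, matrix, expressed)
        consensus: dict[str, list[qt.ConsensusPeak]] = {}
        levels: dict[str, pd.Series] = {}
        for geno in GENOTYPES:
            cons = qt.consensus_peaks(peaks_raw[(geno, 1)], peaks_raw[(geno, 2)])
            cons = qt.annotate_peaks(cons, models, config.window_nt)
            consensus[geno] = cons
            levels[geno] = qt.gene_m6a_level(cons)
            qt.write_consensus_peaks(cons, outdir / f"consensus_peaks_{geno}.tsv")
            report[f"peaks_raw_{geno}"] = len(peaks_raw[(geno, 1)]) + len(peaks_raw[(geno, 2)])
            report[f"peaks_consensus_{geno}"] = len(cons)
            report[f"m6a_genes_{geno}"] = int(levels[geno].size)
        seg_dist = qt.segment_distribution(consensus["F1"])
        for seg, frac in seg_dist.items():
            report[f"segment_frac_F1_{seg}"] = round(frac, 4)
        fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
        te_table.to_csv(outdir / "te.tsv", sep="\t", na_rep="NA")
        pd.DataFrame(levels).to_csv(outdir / "m6a_level.tsv", sep="\t", na_rep="NA")
        for geno in GENOTYPES:
            for assay in ("mrna_input", "polysome"):
                report[f"expressed_{geno}_{assay}"] = len(expressed[(geno, assay)])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- differential: mRNA ------------------------------------------------
    stage = "differential"
    try:
        mrna = matrix.select(assay="mrna_input")
        poly = matrix.select(assay="polysome")
        contrasts = [("F1", "P1"), ("F1", "P2"), ("P1", "P2")]
        mrna_res = {c: diff.nb_test(mrna, c, config) for c in contrasts}
        mrna_res[("F1", "MPV")] = diff.mpv_contrast(mrna, config)
        te_res = {c: diff.te_test(poly, mrna, c, config, expressed) for c in contrasts}
        te_res[("F1", "MPV")] = diff.te_mpv_contrast(poly, mrna, config, expressed)
        mpv_levels = _m6a_mpv_levels(levels["P1"], levels["P2"])
        m6a_res = {
            ("F1", "P1"): diff.m6a_diff(levels["F1"], levels["P1"], config, ("F1", "P1")),
            ("F1", "P2"): diff.m6a_diff(levels["F1"], levels["P2"], config, ("F1", "P2")),
            ("P1", "P2"): diff.m6a_diff(levels["P1"], levels["P2"], config, ("P1", "P2")),
            ("F1", "MPV"): diff.m6a_diff(levels["F1"], mpv_levels, config, ("F1", "MPV")),
        }
        for layer, res in (("mrna", mrna_res), ("te", te_res), ("m6a", m6a_res)):
            for (a, b), r in res.items():
                diff.write_results(r, outdir / f"diff_{layer}_{a}_vs_{b}.tsv")
                report[f"diff_{layer}_{a}_vs_{b}"] = int(r["significant"].sum())
                report[f"tested_{layer}_{a}_vs_{b}"] = int(r["tested"].sum())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- heterosis ----------------------------------------------------------
    stage = "heterosis"
    try:
        norm = diff.normalized_counts(mrna)
        geno_cols = {
            g: [s.sample_id for s in mrna.samples if s.genotype == g] for g in GENOTYPES
        }
        mrna_values = pd.DataFrame(
            {g: norm[cols].mean(axis=1) for g, cols in geno_cols.items()}
        )
        expressed_any = (
            expressed[("P1", "mrna_input")]
            | expressed[("P2", "mrna_input")]
            | expressed[("F1", "mrna_input")]
        )
        mrna_values = mrna_values.loc[mrna_values.index.isin(expressed_any)]
        calls = {}
        calls["mrna"] = het.classify_heterosis(
            mrna_res[("F1", "MPV")], mrna_res[("F1", "P1")], mrna_res[("F1", "P2")],
            mrna_res[("P1", "P2")], mrna_values, layer="mrna",
        )
        te_values = te_table.reindex(columns=["P1", "P2", "F1"])
        calls["te"] = het.classify_heterosis(
            te_res[("F1", "MPV")], te_res[("F1", "P1")], te_res[("F1", "P2")],
            te_res[("P1", "P2")], te_values, layer="te",
        )
        m6a_genes = levels["F1"].index  # the hybrid's m6A-modified gene set
        m6a_values = pd.DataFrame(
            {g: levels[g].reindex(m6a_genes).fillna(0.0) for g in GENOTYPES}
        )
        calls["m6a"] = het.classify_heterosis(
            _complete_m6a_frame(m6a_res[("F1", "MPV")], m6a_genes),
            _complete_m6a_frame(m6a_res[("F1", "P1")], m6a_genes),
            _complete_m6a_frame(m6a_res[("F1", "P2")], m6a_genes),
            _complete_m6a_frame(m6a_res[("P1", "P2")], m6a_genes),
            m6a_values, layer="m6a",
        )
        summaries = {}
        for layer in ("mrna", "m6a", "te"):
            het.write_calls(calls[layer], outdir / f"heterosis_{layer}.tsv")
            summary = het.summarize_layer(calls[layer])
            p1p2 = {"mrna": mrna_res, "te": te_res, "m6a": m6a_res}[layer][("P1", "P2")]
            if layer == "m6a":
                p1p2 = _complete_m6a_frame(p1p2, m6a_genes)
            contrib = het.parental_contribution(calls[layer], p1p2)
            summaries[layer] = summary
            for pat, n in summary["counts"].items():
                report[f"heterosis_{layer}_{pat}"] = n
            report[f"heterosis_{layer}_non_additive"] = summary["non_additive"]
            report[f"heterosis_{layer}_up"] = summary["up"]
            report[f"heterosis_{layer}_down"] = summary["down"]
            if summary["up_pct"] is not None:
                report[f"heterosis_{layer}_up_pct"] = summary["up_pct"]
                report[f"heterosis_{layer}_down_pct"] = summary["down_pct"]
            report[f"parental_contribution_{layer}_n"] = contrib["parental_divergent"]
            if contrib["percent"] is not None:
                report[f"parental_contribution_{layer}_pct"] = contrib["percent"]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- allelic ------------------------------------------------------------
    stage = "allelic"
    try:
        bias = allelic_mod.allelic_bias_test(alleles, config.alpha)
        bias.to_csv(outdir / "allelic_bias.tsv", sep="\t", na_rep="NA")
        btab = allelic_mod.bias_table(bias)
        btab.to_csv(outdir / "allelic_bias_table.tsv", sep="\t")
        for assay, row in btab.iterrows():
            report[f"allelic_biased_{assay}"] = int(row["total"])
            report[f"allelic_biased_{assay}_a1"] = int(row["a1_higher"])
            report[f"allelic_biased_{assay}_a2"] = int(row["a2_higher"])
        for assay in ("mrna_input", "m6a_ip", "polysome"):
            ct = allelic_mod.classify_cis_trans(parental, alleles, config.alpha, assay=assay)
            ct.to_csv(outdir / f"cis_trans_{assay}.tsv", sep="\t", na_rep="NA")
            tab = allelic_mod.cis_trans_table(ct)
            tab.to_csv(outdir / f"cis_trans_table_{assay}.tsv", sep="\t")
            for cat, row in tab.iterrows():
                report[f"cis_trans_{assay}_{cat}"] = int(row["n"])
                report[f"cis_trans_{assay}_{cat}_pct"] = float(row["percent"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- integrate -----------------------------------------------------------
    stage = "integrate"
    try:
        nonadd_union = pd.Index([])
        for layer in ("mrna", "m6a", "te"):
            c = calls[layer]
            nonadd_union = nonadd_union.union(
                c.index[c["pattern"].isin(["AHP", "HP", "LP", "BLP"])]
            )
        report["non_additive_union"] = int(len(nonadd_union))
        if len(nonadd_union) >= config.k_clusters:
            f1_mrna = mrna_values["F1"] if "F1" in mrna_values else pd.Series(dtype=float)
            triplets = integ.percentile_triplets(
                f1_mrna,
                levels["F1"],
                te_table["F1"] if "F1" in te_table else pd.Series(dtype=float),
                list(nonadd_union),
            )
            labels, centers = integ.kmeans_cluster(
                triplets, config.k_clusters, config.rng_seed
            )
            out = triplets.copy()
            out["cluster"] = labels
            out.to_csv(outdir / "clusters.tsv", sep="\t")
            for c in range(1, config.k_clusters + 1):
                report[f"cluster_{c}_size"] = int((labels == c).sum())
            if annotation:
                universe = set(
                    expressed[("F1", "mrna_input")]
                    | expressed[("P1", "mrna_input")]
                    | expressed[("P2", "mrna_input")]
                )
                enr_frames = []
                for c in range(1, config.k_clusters + 1):
                    cluster_genes = set(labels.index[labels == c]) & universe
                    if not cluster_genes:
                        continue
                    e = integ.set_enrichment(
                        cluster_genes, annotation, universe,
                        n_perm=1000, seed=config.rng_seed + c,
                    )
                    e.insert(0, "cluster", c)
                    enr_frames.append(e)
                if enr_frames:
                    enr = pd.concat(enr_frames)
                    enr.to_csv(outdir / "enrichment.tsv", sep="\t")
                    report["enriched_sets"] = int(enr["significant"].sum())
        else:
            logger.warning("too few non-additive genes for clustering; skipped")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    _write_report(report, outdir)
    return report


def _m6a_mpv_levels(p1: pd.Series, p2: pd.Series) -> pd.Series:
    """Mid-parent m6A level: mean of parental levels with an unmodified
    parent contributing 0; genes unmodified in both parents are absent."""
    genes = p1.index.union(p2.index)
    mpv = (p1.reindex(genes).fillna(0.0) + p2.reindex(genes).fillna(0.0)) / 2.0
    return mpv[mpv > 0]


def _write_report(report: dict, outdir: Path) -> None:
    flat = pd.DataFrame(
        {"key": list(report.keys()), "value": [report[k] for k in report]}
    )
    flat.to_csv(outdir / "report.tsv", sep="\t", index=False)
    with open(outdir / "report.txt", "w") as fh:
        fh.write("trilayer run report\n===================\n")
        for k, v in report.items():
            fh.write(f"{k:42s} {v}\n")
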