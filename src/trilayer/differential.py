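"""Count-based differential testing for genotype contrasts on all layers.

Three engines share one decision contract (effect size + p + BH-FDR +
fold-change threshold):

* :func:`nb_test` — negative-binomial Wald test on gene counts for any
  genotype pair, with median-of-ratios normalization and method-of-moments
  dispersions shrunk toward a mean-dispersion trend.
* :func:`mpv_contrast` — the hybrid-vs-mid-parent test realized by pairing
  parental replicates into in-silico mid-parent pseudo-samples and running
  the same NB machinery.
* :func:`te_test` / :func:`te_mpv_contrast` — translational-efficiency
  contrasts via Welch tests on per-replicate log2 polysome/input ratios
  with a variance floor.

The m6A layer has no replicate variance after the replicate-consensus step,
so :func:`m6a_diff` is a threshold rule on consensus levels (presence
change, or level ratio >= the fold-change threshold) with no p-value.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import ExpressionMatrix

logger = logging.getLogger("trilayer")

RESULT_COLUMNS = ["log2fc", "p", "p_adj", "significant", "tested"]

# prior degrees of freedom credited to the genome-wide dispersion trend
# that the gene-wise estimates are shrunk toward; 12 keeps the null
# rejection rate closest to nominal across the calibration simulations
NB_PRIOR_DF = 12


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The reference is the per-gene geometric mean over samples, computed on
    genes with nonzero counts in every sample. If no such gene exists the
    factors fall back to total-count scaling (logged).
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        logger.warning("size_factors: no gene nonzero in all samples; using total-count scaling")
        sf = counts.sum(axis=0)
        if (sf == 0).any():
            raise ValueError("sample with zero total counts")
    else:
        sub = counts[all_pos]
        log_ref = np.log(sub).mean(axis=1)
        sf = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=m.counts.columns)


def normalized_counts(m: ExpressionMatrix) -> pd.DataFrame:
    sf = size_factors(m)
    return m.counts / sf


def _bh(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _decide(log2fc: np.ndarray, p: np.ndarray, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    p_adj = _bh(p)
    crit = p_adj if cfg.multiple_testing == "bh_fdr" else p
    with np.errstate(invalid="ignore"):
        sig = (crit < cfg.alpha) & (np.abs(log2fc) >= np.log2(cfg.fc_threshold))
    return p_adj, np.where(np.isfinite(crit), sig, False).astype(bool)


# ---------------------------------------------------------------------------
# NB Wald engine
# ---------------------------------------------------------------------------

def _dispersion(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion: pooled method-of-moments estimate shrunk
    50/50 toward a 1/mean trend fitted across genes."""
    num = np.zeros(groups[0].shape[0])
    den = np.zeros_like(num)
    mu_all = np.zeros_like(num)
    n_all = 0
    for g in groups:
        n = g.shape[1]
        mu = g.mean(axis=1)
        mu_all += mu * n
        n_all += n
        if n < 2:
            continue
        var = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (var - mu) / np.square(mu)
        d = np.where(mu > 0, d, np.nan)
        w = n - 1
        num += np.nan_to_num(d) * w * np.isfinite(d)
        den += w * np.isfinite(d)
    mu_all /= max(n_all, 1)
    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    raw = np.clip(raw, 1e-8, 10.0)
    # trend: disp ~ a0 + a1/mean, least squares on genes with a raw estimate
    ok = np.isfinite(raw) & (mu_all > 0)
    if ok.sum() >= 10:
        x = 1.0 / mu_all[ok]
        y = raw[ok]
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = 0.1, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu_all, 1e-8)
    shrunk = 0.5 * np.where(np.isfinite(raw), raw, trend) + 0.5 * trend
    return np.clip(shrunk, 1e-8, 10.0)


def _nb_wald(
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    gene_ids: Sequence[str],
    cfg: RunConfig,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Wald test on normalized counts: group a vs group b, log2fc = log2(a/b)."""
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("nb test requires >= 2 replicates per side")
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    tested = (mean_a > 0) | (mean_b > 0)
    disp = _dispersion([norm_a, norm_b])
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    # delta method on log of a NB group mean: var(log mu_hat) ~ (1/mu + disp)/n
    var_log = (1.0 / (mean_a + 0.5) + disp) / n_a + (1.0 / (mean_b + 0.5) + disp) / n_b
    se_log2 = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / se_log2
    # moderated df: residual df plus prior df contributed by the
    # genome-wide dispersion trend (quasi-likelihood-style moderation)
    df = (n_a + n_b - 2) + NB_PRIOR_DF
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(tested, p, np.nan)
    log2fc = np.where(tested, log2fc, np.nan)
    p_adj, sig = _decide(log2fc, p, cfg)
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p_adj, "significant": sig, "tested": tested},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    out.attrs["contrast"] = contrast
    return out


def nb_test(m: ExpressionMatrix, contrast: tuple[str, str], cfg: RunConfig) -> pd.DataFrame:
    """NB Wald test of ``contrast[0]`` vs ``contrast[1]`` within one assay.

    ``m`` must contain samples of exactly one assay. Size factors are
    computed across the two groups jointly. Genes all-zero in both groups
    are reported untested (NA).
    """
    assays = {s.assay for s in m.samples}
    if len(assays) != 1:
        raise ValueError(f"nb_test expects a single-assay matrix, got {sorted(assays)}")
    geno_a, geno_b = contrast
    sub_samples = [s for s in m.samples if s.genotype in (geno_a, geno_b)]
    sub = ExpressionMatrix(m.counts[[s.sample_id for s in sub_samples]], sub_samples)
    norm = normalized_counts(sub)
    a_cols = [s.sample_id for s in sub_samples if s.genotype == geno_a]
    b_cols = [s.sample_id for s in sub_samples if s.genotype == geno_b]
    return _nb_wald(
        norm[a_cols].to_numpy(), norm[b_cols].to_numpy(), m.gene_ids, cfg, contrast
    )


def mpv_pseudo_counts(m: ExpressionMatrix) -> np.ndarray:
    """In-silico mid-parent pseudo-samples for one assay.

    P1 and P2 replicates (normalized jointly with F1) are paired in
    replicate order, up to the smaller replicate number; each pair yields
    ``(P1_norm + P2_norm) / 2``. Returns genes x pairs (real-valued).
    """
    norm = normalized_counts(m)
    p1 = sorted((s for s in m.samples if s.genotype == "P1"), key=lambda s: s.replicate)
    p2 = sorted((s for s in m.samples if s.genotype == "P2"), key=lambda s: s.replicate)
    n = min(len(p1), len(p2))
    if len(p1) != len(p2):
        logger.warning(
            "mpv: unequal parental replicates (%d vs %d); pairing first %d",
            len(p1), len(p2), n,
        )
    cols = []
    for a, b in zip(p1[:n], p2[:n]):
        cols.append((norm[a.sample_id].to_numpy() + norm[b.sample_id].to_numpy()) / 2.0)
    return np.column_stack(cols)


def mpv_contrast(m: ExpressionMatrix, cfg: RunConfig) -> pd.DataFrame:
    """Hybrid vs mid-parent-value test for one assay.

    MPV pseudo-counts are rounded to the nearest integer for the count
    model; F1 replicates enter as their (jointly) normalized counts. The NB
    engine then runs with unit size factors.
    """
    for geno in ("P1", "P2", "F1"):
        reps = [s for s in m.samples if s.genotype == geno]
        if len(reps) < 2:
            raise ValueError(f"mpv_contrast: genotype {geno} needs >= 2 replicates")
    mpv = np.round(mpv_pseudo_counts(m))
    norm = normalized_counts(m)
    f1_cols = [s.sample_id for s in m.samples if s.genotype == "F1"]
    f1 = np.round(norm[f1_cols].to_numpy())
    return _nb_wald(f1, mpv, m.gene_ids, cfg, ("F1", "MPV"))


# ---------------------------------------------------------------------------
# translational efficiency engine
# ---------------------------------------------------------------------------

def _replicate_log2_te(
    poly: ExpressionMatrix, inp: ExpressionMatrix
) -> dict[str, np.ndarray]:
    """Per-genotype genes x replicates matrix of log2((poly+0.5)/(input+0.5)).

    Each assay is normalized by its own size factors across all its
    samples; replicates are paired across assays by replicate number.
    """
    if poly.gene_ids != inp.gene_ids:
        raise ValueError("polysome and input matrices must share gene order")
    poly_norm = normalized_counts(poly)
    inp_norm = normalized_counts(inp)
    out: dict[str, np.ndarray] = {}
    by_geno_poly: dict[str, dict[int, str]] = {}
    by_geno_inp: dict[str, dict[int, str]] = {}
    for s in poly.samples:
        by_geno_poly.setdefault(s.genotype, {})[s.replicate] = s.sample_id
    for s in inp.samples:
        by_geno_inp.setdefault(s.genotype, {})[s.replicate] = s.sample_id
    for geno, reps in by_geno_poly.items():
        common = sorted(set(reps) & set(by_geno_inp.get(geno, {})))
        if not common:
            continue
        cols = []
        for r in common:
            p = poly_norm[reps[r]].to_numpy()
            i = inp_norm[by_geno_inp[geno][r]].to_numpy()
            cols.append(np.log2((p + 0.5) / (i + 0.5)))
        out[geno] = np.column_stack(cols)
    return out


def _welch_floor(
    te_a: np.ndarray,
    te_b: np.ndarray,
    gene_ids: Sequence[str],
    valid: np.ndarray,
    cfg: RunConfig,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Moderated Welch test on per-replicate log2 TE.

    Gene-wise variances are shrunk toward the genome-wide mean variance of
    their group with ``NB_PRIOR_DF`` prior degrees of freedom (empirical
    Bayes, as in limma), then floored at the 10th percentile of the
    moderated variance distribution; the Welch-Satterthwaite df uses the
    moderated per-group df.
    """
    n_a, n_b = te_a.shape[1], te_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("te test requires >= 2 replicates per side")
    d0 = NB_PRIOR_DF
    var_a = te_a.var(axis=1, ddof=1)
    var_b = te_b.var(axis=1, ddof=1)
    s0_a = float(var_a[valid].mean()) if valid.any() else float(var_a.mean())
    s0_b = float(var_b[valid].mean()) if valid.any() else float(var_b.mean())
    var_a = (d0 * s0_a + (n_a - 1) * var_a) / (d0 + n_a - 1)
    var_b = (d0 * s0_b + (n_b - 1) * var_b) / (d0 + n_b - 1)
    pooled = np.concatenate([var_a[valid], var_b[valid]])
    floor = np.percentile(pooled, 10) if pooled.size else 0.0
    floor = max(floor, 1e-8)
    var_a = np.maximum(var_a, floor)
    var_b = np.maximum(var_b, floor)
    effect = te_a.mean(axis=1) - te_b.mean(axis=1)
    se2_a, se2_b = var_a / n_a, var_b / n_b
    se = np.sqrt(se2_a + se2_b)
    tstat = effect / se
    df = np.square(se2_a + se2_b) / (
        np.square(se2_a) / (d0 + n_a - 1) + np.square(se2_b) / (d0 + n_b - 1)
    )
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(valid, p, np.nan)
    effect = np.where(valid, effect, np.nan)
    p_adj, sig = _decide(effect, p, cfg)
    out = pd.DataFrame(
        {"log2fc": effect, "p": p, "p_adj": p_adj, "significant": sig, "tested": valid},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    out.attrs["contrast"] = contrast
    return out


def te_test(
    poly: ExpressionMatrix,
    inp: ExpressionMatrix,
    contrast: tuple[str, str],
    cfg: RunConfig,
    expressed: Mapping[tuple[str, str], set[str]] | None = None,
) -> pd.DataFrame:
    """Differential translational efficiency between two genotypes.

    Genes failing the expression floor in the input assay of either
    genotype are reported untested.
    """
    te = _replicate_log2_te(poly, inp)
    geno_a, geno_b = contrast
    for g in contrast:
        if g not in te:
            raise ValueError(f"te_test: genotype {g!r} missing matched replicates")
    gene_ids = poly.gene_ids
    valid = np.ones(len(gene_ids), dtype=bool)
    if expressed is not None:
        idx = pd.Index(gene_ids)
        for g in contrast:
            valid &= idx.isin(expressed.get((g, "mrna_input"), set()))
    return _welch_floor(te[geno_a], te[geno_b], gene_ids, valid, cfg, contrast)


def te_mpv_contrast(
    poly: ExpressionMatrix,
    inp: ExpressionMatrix,
    cfg: RunConfig,
    expressed: Mapping[tuple[str, str], set[str]] | None = None,
) -> pd.DataFrame:
    """F1 vs mid-parent translational efficiency.

    Mid-parent pseudo-replicates are built per assay by averaging paired,
    normalized parental replicates; log2 TE then pairs the pseudo-replicates
    across assays.
    """
    te = _replicate_log2_te(poly, inp)
    if "F1" not in te:
        raise ValueError("te_mpv_contrast: F1 replicates missing")
    mpv_poly = mpv_pseudo_counts(poly)
    mpv_inp = mpv_pseudo_counts(inp)
    n = min(mpv_poly.shape[1], mpv_inp.shape[1])
    te_mpv = np.log2((mpv_poly[:, :n] + 0.5) / (mpv_inp[:, :n] + 0.5))
    gene_ids = poly.gene_ids
    valid = np.ones(len(gene_ids), dtype=bool)
    if expressed is not None:
        idx = pd.Index(gene_ids)
        for g in ("F1", "P1", "P2"):
            valid &= idx.isin(expressed.get((g, "mrna_input"), set()))
    return _welch_floor(te["F1"], te_mpv, gene_ids, valid, cfg, ("F1", "MPV"))


# ---------------------------------------------------------------------------
# m6A threshold rule
# ---------------------------------------------------------------------------

def m6a_diff(
    levels_a: pd.Series,
    levels_b: pd.Series,
    cfg: RunConfig,
    contrast: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Differential m6A modification between two genotypes.

    A gene is differential when modified in exactly one genotype (gain /
    loss relative to side a) or modified in both with a level ratio >= the
    fold-change threshold. Consensus levels carry no replicate variance, so
    no p-value is produced; ``log2fc`` uses a 0.5 offset with unmodified
    genes entering at level 0.
    """
    genes = levels_a.index.union(levels_b.index).sort_values()
    a = levels_a.reindex(genes)
    b = levels_b.reindex(genes)
    a_mod, b_mod = a.notna(), b.notna()
    av = a.fillna(0.0).to_numpy()
    bv = b.fillna(0.0).to_numpy()
    ratio = np.where(bv > 0, av / np.where(bv > 0, bv, 1.0), np.inf)
    both = (a_mod & b_mod).to_numpy()
    ratio_hit = both & (
        (np.maximum(ratio, np.divide(1.0, ratio, out=np.full_like(ratio, np.inf), where=ratio > 0)))
        >= cfg.fc_threshold
    )
    presence = (a_mod ^ b_mod).to_numpy()
    differential = presence | ratio_hit
    log2fc = np.log2((av + 0.5) / (bv + 0.5))
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": np.nan,
            "p_adj": np.nan,
            "significant": differential,
            "tested": (a_mod | b_mod).to_numpy(),
            "direction": np.where(
                differential, np.where(log2fc > 0, "gain", "loss"), "none"
            ),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    out.attrs["contrast"] = contrast
    return out


def write_results(res: pd.DataFrame, path) -> None:
    out = res.copy()
    a, b = out.attrs.get("contrast", ("a", "b"))
    out.insert(0, "contrast", f"{a}_vs_{b}")
    if "direction" not in out.columns:
        out["direction"] = np.where(
            out["significant"], np.where(out["log2fc"] > 0, "up", "down"), "none"
        )
    out.to_csv(path, sep="\t", na_rep="NA")
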