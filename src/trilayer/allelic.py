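"""Allele-specific expression in the hybrid and cis/trans divergence.

With *A* the parental expression divergence and *B* the F1 allelic
divergence, each tested per gene (A: exact binomial on library-normalized
parental SNP-covered counts; B: exact binomial on F1 allele counts; A vs B:
Fisher exact on the 2x2 table), genes fall into:

* cis only            — A != 0, B != 0, A = B
* trans only          — A != 0, B = 0,  A != B
* cis and trans       — A != 0, B != 0, A != B (enhancing when cis and
  trans effects share a sign, compensating otherwise), together with the
  fully compensatory case A = 0, B != 0, A != B
* conserved           — no divergence anywhere

The cis effect is estimated by B (allelic log2 ratio), the trans effect by
A - B. Boolean combinations outside the table (e.g. A = B significant with
neither A nor B) are counted as conserved, never dropped.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("cis_only", "trans_only", "cis_and_trans", "conserved")
SUBTYPES = ("enhancing", "compensating", "fully_compensatory", "none")

MIN_DEPTH = 10  # minimum informative reads per gene per test


def binom_two_sided(k: np.ndarray, n: np.ndarray, p0: float | np.ndarray = 0.5) -> np.ndarray:
    """Two-sided exact binomial p-value as twice the smaller tail, capped at 1.

    At p0 = 0.5 this equals the symmetric exact test (e.g. 30 successes in
    30 trials gives 2 * 0.5^30).
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lo = stats.binom.cdf(k, n, p0)
    hi = stats.binom.sf(k - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def allelic_bias_test(table: pd.DataFrame, alpha: float, assay: str | None = None) -> pd.DataFrame:
    """Exact binomial test of allelic balance per gene.

    ``table`` is indexed by (gene_id, assay) with columns ``a1_count``,
    ``a2_count`` (a1 = P1-origin reads). Genes with total depth below
    ``MIN_DEPTH`` are reported untested (p = NA).
    """
    df = table.reset_index()
    if assay is not None:
        df = df[df["assay"] == assay]
    a1 = df["a1_count"].to_numpy(np.int64)
    a2 = df["a2_count"].to_numpy(np.int64)
    total = a1 + a2
    tested = total >= MIN_DEPTH
    p = np.full(len(df), np.nan)
    p[tested] = binom_two_sided(a1[tested], total[tested])
    ratio = np.log2((a1 + 0.5) / (a2 + 0.5))
    with np.errstate(invalid="ignore"):
        biased = np.where(tested, p < alpha, False).astype(bool)
    direction = np.where(
        biased, np.where(a1 > a2, "a1_higher", "a2_higher"), "none"
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "assay": df["assay"].to_numpy(),
            "a1_count": a1,
            "a2_count": a2,
            "ratio_log2": ratio,
            "p": p,
            "tested": tested,
            "biased": biased,
            "direction": direction,
        }
    )
    return out.set_index(["gene_id", "assay"]).sort_index()


def bias_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-assay counts of biased genes split by direction."""
    rows = []
    for assay, sub in results.groupby(level="assay"):
        b = sub[sub["biased"]]
        rows.append(
            {
                "assay": assay,
                "total": int(len(b)),
                "a1_higher": int((b["direction"] == "a1_higher").sum()),
                "a2_higher": int((b["direction"] == "a2_higher").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("assay")


def classify_cis_trans(
    parental: pd.DataFrame,
    f1_alleles: pd.DataFrame,
    alpha: float,
    assay: str | None = None,
) -> pd.DataFrame:
    """Cis/trans regulatory classification per gene.

    Parameters
    ----------
    parental:
        Per-gene SNP-covered read totals for each parent; columns
        ``p1_count``, ``p2_count`` (index gene_id, or (gene_id, assay) with
        ``assay`` given).
    f1_alleles:
        F1 allele count table indexed by (gene_id, assay) with columns
        ``a1_count``, ``a2_count``.
    alpha:
        Per-gene significance level for all three tests (unadjusted).

    Parental counts are normalized between parents by their SNP-covered
    library sizes before testing, so that A and B sit on the same scale for
    the Fisher comparison. Genes below ``MIN_DEPTH`` on either side are
    unclassified.
    """
    par = parental.reset_index()
    f1 = f1_alleles.reset_index()
    if assay is not None:
        if "assay" in par.columns:
            par = par[par["assay"] == assay]
        f1 = f1[f1["assay"] == assay]
    par = par.set_index("gene_id")
    f1 = f1.set_index("gene_id")
    genes = par.index.intersection(f1.index)
    par = par.loc[genes]
    f1 = f1.loc[genes]

    p1 = par["p1_count"].to_numpy(np.int64)
    p2 = par["p2_count"].to_numpy(np.int64)
    a1 = f1["a1_count"].to_numpy(np.int64)
    a2 = f1["a2_count"].to_numpy(np.int64)

    lib1, lib2 = p1.sum(), p2.sum()
    scale = np.exp((np.log(max(lib1, 1)) + np.log(max(lib2, 1))) / 2)
    p1n = p1 * scale / max(lib1, 1)
    p2n = p2 * scale / max(lib2, 1)
    p1r = np.round(p1n).astype(np.int64)
    p2r = np.round(p2n).astype(np.int64)

    testable = ((p1 + p2) >= MIN_DEPTH) & ((a1 + a2) >= MIN_DEPTH)

    # A: parental divergence — binomial on raw counts against the
    # library-ratio expectation (equivalent to testing normalized counts
    # against 1:1)
    p0 = lib1 / (lib1 + lib2) if (lib1 + lib2) > 0 else 0.5
    pA = binom_two_sided(p1, p1 + p2, p0)
    # B: F1 allelic divergence
    pB = binom_two_sided(a1, a1 + a2)
    # A vs B: Fisher exact on normalized parental vs allelic counts
    pAB = np.ones(len(genes))
    for i in range(len(genes)):
        if testable[i]:
            pAB[i] = stats.fisher_exact([[p1r[i], p2r[i]], [a1[i], a2[i]]])[1]

    sigA = pA < alpha
    sigB = pB < alpha
    sigAB = pAB < alpha

    A_log2 = np.log2((p1n + 0.5) / (p2n + 0.5))
    B_log2 = np.log2((a1 + 0.5) / (a2 + 0.5))
    cis_eff = B_log2
    trans_eff = A_log2 - B_log2

    category = np.full(len(genes), "conserved", dtype=object)
    subtype = np.full(len(genes), "none", dtype=object)

    cis_only = sigA & sigB & ~sigAB
    trans_only = sigA & ~sigB & sigAB
    both = sigA & sigB & sigAB
    fully = ~sigA & sigB & sigAB

    category[cis_only] = "cis_only"
    category[trans_only] = "trans_only"
    category[both | fully] = "cis_and_trans"
    subtype[both & (np.sign(cis_eff) == np.sign(trans_eff))] = "enhancing"
    subtype[both & (np.sign(cis_eff) != np.sign(trans_eff))] = "compensating"
    subtype[fully] = "fully_compensatory"
    # remaining combinations (incl. A=B significant with neither A nor B)
    # stay "conserved" — counted, never dropped

    out = pd.DataFrame(
        {
            "A_log2": A_log2,
            "B_log2": B_log2,
            "pA": pA,
            "pB": pB,
            "pAB": pAB,
            "category": np.where(testable, category, "NA"),
            "subtype": np.where(testable, subtype, "none"),
            "tested": testable,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return out


def cis_trans_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Category counts and percentages of the classified total."""
    from .heterosis import percent_round

    classified = calls[calls["category"] != "NA"]
    if classified.empty:
        raise ValueError("no classified genes")
    total = len(classified)
    rows = []
    for cat in CATEGORIES:
        n = int((classified["category"] == cat).sum())
        rows.append({"category": cat, "n": n, "percent": percent_round(n, total)})
    return pd.DataFrame(rows).set_index("category")
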