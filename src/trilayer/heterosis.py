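"""Heterotic pattern classification and layer summaries.

A gene is *additive* when the hybrid does not differ significantly from
the mid-parent value (MPV). Non-additive genes are binned by where the
hybrid sits relative to the two parents:

* ``AHP`` — above higher parent: significantly above the higher parent.
* ``HP``  — high parent: above MPV and not significantly different from
  the higher parent.
* ``LP``  — low parent: below MPV and not significantly different from
  the lower parent.
* ``BLP`` — below lower parent: significantly below the lower parent.

Genes significant against MPV and both parents yet lying between the
parents are binned to the nearer parent on the log scale (the scheme has
no fifth bin). ``AHP+HP`` are the up-regulated direction, ``LP+BLP`` the
down-regulated one.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

PATTERNS = ("additive", "AHP", "HP", "LP", "BLP")
LAYERS = ("mrna", "m6a", "te")


def percent_round(part: int, whole: int) -> float:
    """``100 * part / whole`` rounded half away from zero to one decimal."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if not 0 <= part <= whole:
        raise ValueError("need 0 <= part <= whole")
    x = 1000.0 * part / whole
    return math.floor(x + 0.5) / 10.0


def classify_heterosis(
    mpv_res: pd.DataFrame,
    f1_vs_p1: pd.DataFrame,
    f1_vs_p2: pd.DataFrame,
    p1_vs_p2: pd.DataFrame,
    values: pd.DataFrame,
    layer: str = "mrna",
) -> pd.DataFrame:
    """Per-gene heterosis pattern for one regulatory layer.

    Parameters
    ----------
    mpv_res, f1_vs_p1, f1_vs_p2, p1_vs_p2:
        Differential results (all with F1/P1 listed first in their
        contrast, i.e. positive log2fc = first group higher).
    values:
        Per-genotype gene summaries with columns ``P1``, ``P2``, ``F1``
        (mean normalized expression, m6A level, or TE). The higher/lower
        parent is decided per gene from these values.
    layer:
        Label recorded in the output (``mrna``/``m6a``/``te``).

    Returns a DataFrame indexed by gene with ``pattern``, ``direction``
    and the underlying values; genes missing any contrast are ``NA``.
    """
    genes = values.index
    pats = pd.Series("NA", index=genes, dtype=object)
    dirs = pd.Series("none", index=genes, dtype=object)

    frames = {"mpv": mpv_res, "fp1": f1_vs_p1, "fp2": f1_vs_p2, "pp": p1_vs_p2}
    aligned = {k: v.reindex(genes) for k, v in frames.items()}

    complete = pd.Series(True, index=genes)
    for v in aligned.values():
        complete &= v["tested"].fillna(False).astype(bool)
    complete &= values[["P1", "P2", "F1"]].notna().all(axis=1)

    p1v = values["P1"].to_numpy(dtype=float)
    p2v = values["P2"].to_numpy(dtype=float)
    f1v = values["F1"].to_numpy(dtype=float)
    mpv = (p1v + p2v) / 2.0

    p1_is_high = p1v >= p2v
    hp_val = np.where(p1_is_high, p1v, p2v)
    lp_val = np.where(p1_is_high, p2v, p1v)

    mpv_sig = aligned["mpv"]["significant"].fillna(False).to_numpy(dtype=bool)
    mpv_fc = aligned["mpv"]["log2fc"].to_numpy(dtype=float)
    fp1_sig = aligned["fp1"]["significant"].fillna(False).to_numpy(dtype=bool)
    fp1_fc = aligned["fp1"]["log2fc"].to_numpy(dtype=float)
    fp2_sig = aligned["fp2"]["significant"].fillna(False).to_numpy(dtype=bool)
    fp2_fc = aligned["fp2"]["log2fc"].to_numpy(dtype=float)

    # per-gene contrast against the higher / lower parent
    hi_sig = np.where(p1_is_high, fp1_sig, fp2_sig)
    hi_fc = np.where(p1_is_high, fp1_fc, fp2_fc)
    lo_sig = np.where(p1_is_high, fp2_sig, fp1_sig)
    lo_fc = np.where(p1_is_high, fp2_fc, fp1_fc)

    comp = complete.to_numpy()
    nonadd = comp & mpv_sig
    above_mpv = np.where(np.isfinite(mpv_fc), mpv_fc > 0, f1v > mpv)

    ahp = nonadd & hi_sig & (hi_fc > 0)
    blp = nonadd & lo_sig & (lo_fc < 0)
    hp = nonadd & ~ahp & ~blp & above_mpv & ~hi_sig
    lp = nonadd & ~ahp & ~blp & ~above_mpv & ~lo_sig
    # residual: significant vs both parents but between them -> nearer parent
    residual = nonadd & ~ahp & ~blp & ~hp & ~lp
    eps = 1e-12
    d_hi = np.abs(np.log(f1v + eps) - np.log(hp_val + eps))
    d_lo = np.abs(np.log(f1v + eps) - np.log(lp_val + eps))
    res_hp = residual & (d_hi <= d_lo)
    res_lp = residual & (d_hi > d_lo)

    pats[comp & ~mpv_sig] = "additive"
    pats[ahp] = "AHP"
    pats[hp | res_hp] = "HP"
    pats[lp | res_lp] = "LP"
    pats[blp] = "BLP"
    dirs[pats.isin(["AHP", "HP"]).to_numpy()] = "up"
    dirs[pats.isin(["LP", "BLP"]).to_numpy()] = "down"

    out = pd.DataFrame(
        {
            "layer": layer,
            "pattern": pats,
            "direction": dirs,
            "P1": p1v,
            "P2": p2v,
            "F1": f1v,
        },
        index=genes,
    )
    out.index.name = "gene_id"
    n_na = int((pats == "NA").sum())
    if n_na:
        import logging

        logging.getLogger("trilayer").info(
            "classify_heterosis[%s]: %d genes unclassified (incomplete contrasts)", layer, n_na
        )
    return out


def summarize_layer(calls: pd.DataFrame) -> dict:
    """Counts per pattern plus up/down splits with percentages of the
    non-additive total."""
    classified = calls[calls["pattern"] != "NA"]
    if classified.empty:
        raise ValueError("no classified genes")
    counts = {p: int((classified["pattern"] == p).sum()) for p in PATTERNS}
    nonadd = sum(counts[p] for p in ("AHP", "HP", "LP", "BLP"))
    up = counts["AHP"] + counts["HP"]
    down = counts["LP"] + counts["BLP"]
    out = {
        "classified": int(len(classified)),
        "counts": counts,
        "non_additive": nonadd,
        "up": up,
        "down": down,
    }
    if nonadd > 0:
        out["pct"] = {p: percent_round(counts[p], nonadd) for p in ("AHP", "HP", "LP", "BLP")}
        out["up_pct"] = percent_round(up, nonadd)
        out["down_pct"] = percent_round(down, nonadd)
        out["non_additive_pct"] = percent_round(nonadd, len(classified))
    else:
        out["pct"] = {p: None for p in ("AHP", "HP", "LP", "BLP")}
        out["up_pct"] = out["down_pct"] = out["non_additive_pct"] = None
    return out


def parental_contribution(calls: pd.DataFrame, p1_vs_p2: pd.DataFrame) -> dict:
    """How much hybrid non-additivity is explained by parental divergence.

    Counts non-additive genes that are also significantly different between
    the two parents, with the percentage of the non-additive total.
    """
    nonadd = calls.index[calls["pattern"].isin(["AHP", "HP", "LP", "BLP"])]
    par_sig = p1_vs_p2["significant"].reindex(nonadd).fillna(False).astype(bool)
    overlap = int(par_sig.sum())
    total = int(len(nonadd))
    return {
        "non_additive": total,
        "parental_divergent": overlap,
        "percent": percent_round(overlap, total) if total > 0 else None,
    }


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", na_rep="NA")
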