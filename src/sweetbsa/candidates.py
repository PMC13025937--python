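"""Candidate-gene screening within consensus regions.

The funnel mirrors a standard BSA-seq follow-up: (1) keep genes expressed in
the tissues where the trait acts (FPKM strictly above a cutoff in seed or
endosperm by default), (2) flag genes whose functional annotation text
matches sugar-metabolism keywords (a purely mechanical string match over a
user-supplied annotation table — no biological inference), and (3) order
candidates by those flags and by the descriptive qPCR expression contrast
between low- and high-degradation lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotype import relative_expression

DEFAULT_TISSUES = ("seed", "endosperm")
DEFAULT_KEYWORDS = ("sugar", "sucrose", "carbohydrate", "kinase",
                    "glycosyl", "amylase", "invertase", "fggy")


def expression_screen(gene_ids: list[str], fpkm: pd.DataFrame,
                      tissues: tuple[str, ...] = DEFAULT_TISSUES,
                      cutoff: float = 1.0) -> pd.DataFrame:
    """Flag genes with FPKM strictly above ``cutoff`` in any screened tissue.

    ``fpkm`` is indexed by gene_id with one column per tissue.  Genes absent
    from the matrix fail the screen (no detectable expression).  Raising the
    cutoff never adds genes.
    """
    present = [t for t in tissues if t in fpkm.columns]
    rows = []
    for gid in gene_ids:
        if gid in fpkm.index and present:
            max_fpkm = float(fpkm.loc[gid, present].max())
        else:
            max_fpkm = 0.0
        rows.append({"gene_id": gid, "max_fpkm": max_fpkm,
                     "passes_expression_screen": max_fpkm > cutoff})
    return pd.DataFrame(rows, columns=["gene_id", "max_fpkm",
                                       "passes_expression_screen"])


def keyword_screen(gene_ids: list[str], annotations: pd.DataFrame,
                   keywords: tuple[str, ...] = DEFAULT_KEYWORDS) -> pd.DataFrame:
    """Case-insensitive keyword match on functional annotation text.

    ``annotations`` needs columns gene_id and description.  Genes without an
    annotation row, or with an empty keyword set, are not flagged.
    """
    desc = annotations.set_index("gene_id")["description"].astype(str).str.lower()
    kw = [k.lower() for k in keywords]
    rows = []
    for gid in gene_ids:
        text = desc.get(gid, "")
        rows.append({"gene_id": gid,
                     "sugar_metabolism_flag": any(k in text for k in kw)})
    return pd.DataFrame(rows, columns=["gene_id", "sugar_metabolism_flag"])


def qpcr_contrast(ct: pd.DataFrame, low_samples: list[str],
                  high_samples: list[str]) -> pd.Series:
    """Descriptive per-gene |low - high| contrast of mean 2^-dCT expression.

    ``ct`` needs columns sample, gene, ct_target, ct_reference.  Genes
    without measurements in both groups get contrast 0.
    """
    ct = ct.copy()
    ct["expr"] = relative_expression(ct["ct_target"], ct["ct_reference"])
    low = ct.loc[ct["sample"].isin(low_samples)].groupby("gene")["expr"].mean()
    high = ct.loc[ct["sample"].isin(high_samples)].groupby("gene")["expr"].mean()
    return (low - high).abs().dropna()


def rank_candidates(report: pd.DataFrame,
                    contrast: pd.Series | None = None) -> pd.DataFrame:
    """Deterministic candidate ordering.

    Sorts (stably, so ties preserve input order) by sugar_metabolism_flag,
    then passes_expression_screen, then the absolute qPCR expression
    contrast, all descending.  The contrast is descriptive only — no
    hypothesis test is performed.
    """
    out = report.copy()
    if contrast is not None:
        out["expression_contrast"] = (
            out["gene_id"].map(contrast).fillna(0.0).to_numpy())
    else:
        out["expression_contrast"] = 0.0
    out = out.sort_values(
        ["sugar_metabolism_flag", "passes_expression_screen",
         "expression_contrast"],
        ascending=False, kind="stable").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
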