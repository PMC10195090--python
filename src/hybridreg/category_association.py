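"""Associations between expression categories, the cis index and molecular
divergence.

The association table has one row per transcript x sex x cross actually
analyzed (the FO cross contributes females only), carrying the inheritance
and regulatory categories, |log2FC| expression divergence, I_cis and the
Ka/Ks estimates.  Category effects are fitted by ordinary least squares on
square-root-transformed responses with factors category, sex and cross plus
the category x sex interaction; because one cell of the sex x cross design
is empty the model deliberately omits the sex x cross and three-way terms
(sex contrasts are informed by the OF cross only, cross contrasts by
females only).  Contrasts are reported against the conserved category.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

RESPONSES = ("n_transcripts", "abs_ed", "I_cis", "Ka", "Ks", "ka_ks")

TABLE_COLUMNS = [
    "transcript_id", "sex", "cross", "inheritance_category",
    "regulatory_category", "abs_ed", "ed_significant", "ai_significant",
    "I_cis", "Ka", "Ks", "ka_ks",
]


def build_association_table(classifications: pd.DataFrame,
                            divergence: pd.DataFrame | None = None,
                            ed_results: pd.DataFrame | None = None
                            ) -> pd.DataFrame:
    """Assemble the comparative matrix.

    classifications: tidy frame with transcript_id, sex, cross,
        inheritance_category, regulatory_category and (optionally) I_cis /
        abs_ed / significance flags per row.
    divergence: per-transcript Ka/Ks/d_xy frame (no sex/cross); left-joined,
        so transcripts lacking divergence estimates carry missing values.
    ed_results: optional tidy frame (transcript_id, sex, cross, abs_ed,
        ed_significant); inner-joined when given.
    """
    t = classifications.copy()
    if "transcript_id" not in t.columns:
        t = t.reset_index()
    key = ["transcript_id", "sex", "cross"]
    if t.duplicated(key).any():
        dups = t.loc[t.duplicated(key), key].head().values.tolist()
        raise ValueError(f"duplicate transcript x sex x cross rows: {dups}")
    if ((t["cross"] == "FO") & (t["sex"] == "M")).any():
        raise ValueError("FO-male rows are not possible in this design")
    if ed_results is not None:
        e = ed_results.copy()
        if "transcript_id" not in e.columns:
            e = e.reset_index()
        t = t.merge(e, on=[k for k in key if k in e.columns], how="inner")
        if t.empty:
            warnings.warn("classification and ED tables share no transcripts")
    if divergence is not None:
        d = divergence.copy()
        if "transcript_id" not in d.columns:
            d = d.reset_index()
        t = t.merge(d, on="transcript_id", how="left")
    for col in TABLE_COLUMNS:
        if col not in t.columns:
            t[col] = np.nan
    return t[TABLE_COLUMNS + [c for c in t.columns if c not in TABLE_COLUMNS]]


def normalized_category_counts(table: pd.DataFrame,
                               category_col: str = "inheritance_category",
                               n_contigs: dict | int | None = None
                               ) -> pd.DataFrame:
    """Category counts per sex x cross, normalized to the number of
    assembled contigs per library (defaults to the profile's transcript
    count, so the normalized tally sums to 1)."""
    rows = []
    for (sex, cross), g in table.groupby(["sex", "cross"]):
        if isinstance(n_contigs, dict):
            total = n_contigs[(sex, cross)]
        elif n_contigs is not None:
            total = int(n_contigs)
        else:
            total = len(g)
        counts = g[category_col].value_counts()
        for cat, n in counts.items():
            rows.append({"sex": sex, "cross": cross, "category": cat,
                         "n": int(n), "normalized": n / total})
    return pd.DataFrame(rows)


def _check_full_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns via QR pivoting
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [model.exog_names[i] for i in range(len(diag))
                   if diag[i] < 1e-8 * diag.max()]
        raise ValueError(
            f"design matrix is rank deficient beyond the incomplete-design "
            f"aliasing; aliased terms: {aliased}")


def fit_category_glm(table: pd.DataFrame, response: str,
                     category_col: str = "inheritance_category",
                     reference: str = "conserved") -> pd.DataFrame:
    """Category effects on a sqrt-transformed response, vs ``reference``.

    response: one of n_transcripts / abs_ed / I_cis / Ka / Ks / ka_ks.
    For n_transcripts the table is first aggregated to normalized counts
    per category x sex x cross; other responses are fitted at transcript
    level.  Undefined values are dropped listwise.  Categories with fewer
    than two observations are excluded.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    if response == "n_transcripts":
        data = normalized_category_counts(table, category_col)
        data = data.rename(columns={"category": category_col,
                                    "normalized": "_resp"})
    else:
        data = table[[category_col, "sex", "cross", response]].rename(
            columns={response: "_resp"})
    data = data.dropna(subset=["_resp", category_col, "sex", "cross"])
    if (data["_resp"] < 0).any():
        raise ValueError(f"response {response} has negative values; "
                         "sqrt transform undefined")
    keep = data[category_col].value_counts()
    data = data[data[category_col].isin(keep[keep >= 2].index)]
    if reference not in set(data[category_col]):
        raise ValueError(f"reference category {reference!r} absent")
    data = data.assign(_sqrt=np.sqrt(data["_resp"]))

    terms = [f"C({category_col}, Treatment('{reference}'))"]
    if data["sex"].nunique() > 1:
        terms.append("C(sex)")
    if data["cross"].nunique() > 1:
        terms.append("C(cross)")
    if data["sex"].nunique() > 1 and data[category_col].nunique() > 1:
        terms.append(f"C({category_col}, Treatment('{reference}')):C(sex)")
    # no sex x cross or three-way terms: that cell of the design is empty
    formula = "_sqrt ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    _check_full_rank(model)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError(
            f"model for {response} is saturated "
            f"({model.exog.shape[0]} rows, {model.exog.shape[1]} terms)")
    res = model.fit()
    rows = []
    for term, est, se, p in zip(res.params.index, res.params, res.bse,
                                res.pvalues):
        comparison = ""
        if category_col in term and "T." in term and ":" not in term:
            level = term.split("T.")[-1].rstrip("]")
            comparison = f"category {level} vs {reference}"
        rows.append({"term": term, "estimate": float(est),
                     "std_error": float(se), "p": float(p),
                     "comparison": comparison, "response": response})
    return pd.DataFrame(rows)


def compare_ed_ai_divergence(table: pd.DataFrame,
                             responses=("Ka", "Ks", "ka_ks")) -> pd.DataFrame:
    """Two-group contrasts of molecular divergence for significant vs
    non-significant ED and AI transcripts, per sex, on the sqrt scale."""
    rows = []
    for flag_col, label in (("ed_significant", "ED"),
                            ("ai_significant", "AI")):
        if flag_col not in table.columns:
            continue
        for sex, g in table.groupby("sex"):
            g = g.dropna(subset=[flag_col])
            for resp in responses:
                sub = g.dropna(subset=[resp])
                sig = sub[sub[flag_col].astype(bool)]
                non = sub[~sub[flag_col].astype(bool)]
                if len(sig) < 2 or len(non) < 2:
                    warnings.warn(
                        f"{label}/{sex}/{resp}: a group is (nearly) empty; "
                        "contrast skipped")
                    continue
                d = sub.assign(_sqrt=np.sqrt(sub[resp]),
                               _flag=sub[flag_col].astype(int))
                res = smf.ols("_sqrt ~ _flag", data=d).fit()
                rows.append({"contrast": label, "sex": sex, "response": resp,
                             "estimate": float(res.params["_flag"]),
                             "std_error": float(res.bse["_flag"]),
                             "p": float(res.pvalues["_flag"]),
                             "n_significant": len(sig),
                             "n_nonsignificant": len(non),
                             "comparison": f"{label} significant vs not"})
    return pd.DataFrame(rows)
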