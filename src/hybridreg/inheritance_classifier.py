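"""Inheritance-mode classification of hybrid gene expression.

Each transcript is placed in one of seven categories from the three
total-expression contrasts — parents vs each other (ED), hybrid vs parent 1
(fraterculus) and hybrid vs parent 2 (obliqua) — together with the position
of the hybrid normalized mean relative to the parental means:

* conserved       — no contrast significant
* dominant_frat   — ED significant, hybrid matches fraterculus
* dominant_obliq  — ED significant, hybrid matches obliqua
* additive        — all three significant, hybrid strictly between parents
* overdominant    — hybrid differs from both parents, above both
* underdominant   — hybrid differs from both parents, below both
* ambiguous       — any other pattern (including exact ties)

By default the transgressive calls do not require parental ED (a hybrid
outside the parental range with both hybrid-parent contrasts significant
suffices); ``require_ed_for_transgressive=True`` restricts them to
transcripts with significant ED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INHERITANCE_CATEGORIES = (
    "conserved", "additive", "dominant_frat", "dominant_obliq",
    "overdominant", "underdominant", "ambiguous",
)

_POSITIONS = ("below", "between", "above")


@dataclass(frozen=True)
class InheritanceRecord:
    transcript_id: str
    category: str
    ed_log2fc: float
    hybrid_position: str  # below | between | above | tie


def hybrid_position(hybrid_mean: float, p1_mean: float, p2_mean: float) -> str:
    """Position of the hybrid mean relative to the parental range.

    Exact equality with either parent is a tie (classified ambiguous).
    """
    lo, hi = min(p1_mean, p2_mean), max(p1_mean, p2_mean)
    if hybrid_mean == lo or hybrid_mean == hi:
        return "tie"
    if hybrid_mean < lo:
        return "below"
    if hybrid_mean > hi:
        return "above"
    return "between"


def _categorize(ed_sig: bool, hp1_sig: bool, hp2_sig: bool, position: str,
                require_ed_for_transgressive: bool) -> str:
    if not (ed_sig or hp1_sig or hp2_sig):
        return "conserved"
    if ed_sig and not hp1_sig and hp2_sig:
        return "dominant_frat"
    if ed_sig and hp1_sig and not hp2_sig:
        return "dominant_obliq"
    if hp1_sig and hp2_sig:
        if position == "between":
            return "additive" if ed_sig else "ambiguous"
        if position in ("above", "below") and (ed_sig or not require_ed_for_transgressive):
            return "overdominant" if position == "above" else "underdominant"
    return "ambiguous"


def classify_inheritance(ed: pd.Series, h_vs_p1: pd.Series, h_vs_p2: pd.Series,
                         means: dict, *,
                         require_ed_for_transgressive: bool = False) -> InheritanceRecord:
    """Classify a single transcript.

    ed / h_vs_p1 / h_vs_p2: rows of the respective contrast tables (need
    'significant' and, for ed, 'log2fc').
    means: {'hybrid': float, 'p1': float, 'p2': float} normalized means on
    the same TMM scale the tests used.
    """
    for name, row in (("ED", ed), ("H_vs_P1", h_vs_p1), ("H_vs_P2", h_vs_p2)):
        if row is None or "significant" not in row:
            raise ValueError(f"missing contrast result: {name}")
    pos = hybrid_position(means["hybrid"], means["p1"], means["p2"])
    cat = _categorize(bool(ed["significant"]), bool(h_vs_p1["significant"]),
                      bool(h_vs_p2["significant"]), pos,
                      require_ed_for_transgressive)
    return InheritanceRecord(str(ed.name), cat, float(ed["log2fc"]), pos)


def classify_inheritance_table(ed: pd.DataFrame, h_vs_p1: pd.DataFrame,
                               h_vs_p2: pd.DataFrame,
                               means: pd.DataFrame, *,
                               require_ed_for_transgressive: bool = False
                               ) -> tuple[pd.DataFrame, pd.Series]:
    """Vectorized classification of a full transcript set.

    means: DataFrame indexed by transcript with columns hybrid, p1, p2.
    Returns (records, tally); the tally always sums to the transcript count.
    """
    idx = ed.index
    for other in (h_vs_p1, h_vs_p2, means):
        if not idx.equals(other.index):
            raise ValueError("contrast tables must share the transcript index")
    if len(idx) == 0:
        records = pd.DataFrame(
            columns=["category", "ed_log2fc", "hybrid_position"],
            index=pd.Index([], name="transcript_id"))
        tally = pd.Series(0, index=list(INHERITANCE_CATEGORIES), dtype=int)
        return records, tally

    e = ed["significant"].to_numpy(bool)
    s1 = h_vs_p1["significant"].to_numpy(bool)
    s2 = h_vs_p2["significant"].to_numpy(bool)
    h = means["hybrid"].to_numpy(float)
    lo = np.minimum(means["p1"].to_numpy(float), means["p2"].to_numpy(float))
    hi = np.maximum(means["p1"].to_numpy(float), means["p2"].to_numpy(float))
    tie = (h == lo) | (h == hi)
    above = h > hi
    below = h < lo
    between = ~tie & ~above & ~below

    cat = np.full(len(idx), "ambiguous", dtype=object)
    trans_ok = e if require_ed_for_transgressive else np.ones_like(e)
    both = s1 & s2
    cat[both & above & trans_ok.astype(bool)] = "overdominant"
    cat[both & below & trans_ok.astype(bool)] = "underdominant"
    cat[e & both & between] = "additive"
    cat[e & ~s1 & s2] = "dominant_frat"
    cat[e & s1 & ~s2] = "dominant_obliq"
    cat[~e & ~s1 & ~s2] = "conserved"

    pos = np.full(len(idx), "between", dtype=object)
    pos[tie] = "tie"
    pos[above] = "above"
    pos[below] = "below"

    records = pd.DataFrame(
        {"category": cat, "ed_log2fc": ed["log2fc"].to_numpy(float),
         "hybrid_position": pos}, index=idx)
    records.index.name = "transcript_id"
    tally = (records["category"].value_counts()
             .reindex(INHERITANCE_CATEGORIES, fill_value=0).astype(int))
    return records, tally
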