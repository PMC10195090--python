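"""Cis/trans regulatory-divergence classification and the cis index.

Because both alleles in an F1 hybrid share one trans-acting environment,
the hybrid allele ratio Rh = log2(A1/A2) isolates cis-regulatory
divergence, while the parental ratio Rp = log2(P1/P2) carries both
components; their difference T = Rp - Rh is the trans component, and
I_cis = |Rh| / (|Rh| + |T|) the relative cis contribution.

The seven-way classification combines three significance flags — parental
expression divergence (ED), allelic imbalance in hybrids (AI) and the
hybrid-vs-parent ratio test (RATIO) — with the signs of Rh and Rp:

* conserved      — (ns, ns, ns)
* cis_only       — (sig, sig, ns): the parental difference is retained by
                   the alleles, ratios do not differ
* trans_only     — (sig, ns, sig)
* cis_plus_trans — (sig, sig, sig) with sign(Rh) == sign(Rp)
* cis_x_trans    — (sig, sig, sig) with opposing signs
* compensatory   — (ns, sig, sig): cis and trans cancel, no net ED
* ambiguous      — every other pattern
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

REGULATORY_CATEGORIES = (
    "conserved", "cis_only", "trans_only", "cis_plus_trans",
    "cis_x_trans", "compensatory", "ambiguous",
)

_SIGN_EPS = 1e-9  # |Rh| or |Rp| below this is treated as zero sign


@dataclass(frozen=True)
class RegulatoryRecord:
    transcript_id: str
    Rh: float
    Rp: float
    T: float
    I_cis: float | None
    category: str
    x_linked_flag: bool = False


def compute_ratios(a1: float, a2: float, p1: float, p2: float) -> tuple[float, float, float]:
    """(Rh, Rp, T) from normalized group means; requires positive means."""
    if min(a1, a2, p1, p2) <= 0:
        raise ValueError("group means must be positive (run zero adjustment)")
    rh = float(np.log2(a1 / a2))
    rp = float(np.log2(p1 / p2))
    return rh, rp, rp - rh


def cis_index(rh: float, t: float) -> float | None:
    """I_cis = |Rh| / (|Rh| + |T|); None when both components are zero."""
    denom = abs(rh) + abs(t)
    if denom == 0:
        return None
    return abs(rh) / denom


def _category(ed: bool, ai: bool, ratio: bool, rh: float, rp: float) -> str:
    if not ed and not ai and not ratio:
        return "conserved"
    if ed and ai and not ratio:
        return "cis_only"
    if ed and not ai and ratio:
        return "trans_only"
    if ed and ai and ratio:
        if abs(rh) < _SIGN_EPS or abs(rp) < _SIGN_EPS:
            return "ambiguous"
        return "cis_plus_trans" if np.sign(rh) == np.sign(rp) else "cis_x_trans"
    if not ed and ai and ratio:
        return "compensatory"
    return "ambiguous"


def classify_regulatory(ed: pd.Series, ai: pd.Series, ratio: pd.Series,
                        rh: float, rp: float) -> RegulatoryRecord:
    """Classify a single transcript from its three contrast rows and ratios."""
    for name, row in (("ED", ed), ("AI", ai), ("RATIO", ratio)):
        if row is None or "significant" not in row:
            raise ValueError(f"missing contrast result: {name}")
    t = rp - rh
    cat = _category(bool(ed["significant"]), bool(ai["significant"]),
                    bool(ratio["significant"]), rh, rp)
    return RegulatoryRecord(str(ed.name), rh, rp, t, cis_index(rh, t), cat)


def classify_regulatory_table(ed: pd.DataFrame, ai: pd.DataFrame,
                              ratio: pd.DataFrame,
                              ratios: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification.

    ratios: DataFrame indexed by transcript with columns Rh and Rp.
    Returns a frame with Rh, Rp, T, I_cis (NaN when undefined) and category.
    """
    idx = ed.index
    for other in (ai, ratio, ratios):
        if not idx.equals(other.index):
            raise ValueError("contrast tables must share the transcript index")
    e = ed["significant"].to_numpy(bool)
    a = ai["significant"].to_numpy(bool)
    r = ratio["significant"].to_numpy(bool)
    rh = ratios["Rh"].to_numpy(float)
    rp = ratios["Rp"].to_numpy(float)
    t = rp - rh

    cat = np.full(len(idx), "ambiguous", dtype=object)
    cat[~e & ~a & ~r] = "conserved"
    cat[e & a & ~r] = "cis_only"
    cat[e & ~a & r] = "trans_only"
    cat[~e & a & r] = "compensatory"
    all_sig = e & a & r
    sign_ok = (np.abs(rh) >= _SIGN_EPS) & (np.abs(rp) >= _SIGN_EPS)
    same = np.sign(rh) == np.sign(rp)
    cat[all_sig & sign_ok & same] = "cis_plus_trans"
    cat[all_sig & sign_ok & ~same] = "cis_x_trans"

    denom = np.abs(rh) + np.abs(t)
    with np.errstate(invalid="ignore", divide="ignore"):
        icis = np.where(denom > 0, np.abs(rh) / np.where(denom > 0, denom, 1.0), np.nan)
    out = pd.DataFrame({"Rh": rh, "Rp": rp, "T": t, "I_cis": icis,
                        "category": cat}, index=idx)
    out.index.name = "transcript_id"
    return out


def flag_x_linked(ai_results: pd.DataFrame, raw_counts, sheet) -> pd.Series:
    """Flag transcripts whose ASE pattern is consistent with X linkage.

    A transcript is flagged when its allelic imbalance is significant AND
    every raw (pre-zero-adjust) fraterculus-allele count in hybrid males is
    zero — in this cross design the X of hybrid males comes from the
    obliqua mother, so X-linked transcripts show hemizygous obliqua
    expression.  Returns a boolean Series over ai_results' transcripts.
    """
    df = getattr(raw_counts, "df", raw_counts)
    male_frat_cols: list[str] = []
    for line in ("OF", "FO"):
        male_frat_cols += sheet.columns_for(line, "M", "frat")
    if not male_frat_cols:
        warnings.warn("no male hybrid samples; X-linkage scan is empty")
        return pd.Series(False, index=ai_results.index, name="x_linked_flag")
    sub = df.reindex(ai_results.index)[male_frat_cols]
    absent = (sub == 0).all(axis=1)
    flags = ai_results["significant"].astype(bool) & absent
    flags.name = "x_linked_flag"
    return flags
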