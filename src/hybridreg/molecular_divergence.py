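"""Molecular divergence between the parental species.

Three per-transcript quantities:

* d      — per-SNP differentiation, the absolute allele-frequency
           difference between species (a fixed difference has d = 1);
* d_xy   — fraction of a transcript's SNPs that are fixed differences;
* Ka/Ks  — nonsynonymous and synonymous substitution rates from an aligned
           coding-sequence pair, by the Nei–Gojobori (1986) counting method
           with Jukes–Cantor multiple-hit correction.

NG86 counting: each codon position contributes fractional synonymous site
counts according to how many of its three possible point mutations preserve
the amino acid (mutations to stop codons count as nonsynonymous), so
S + N = 3 per codon exactly.  Codon pairs differing at several positions
average the synonymous/nonsynonymous tallies over all orderings of the
minimal mutational path, excluding orderings that pass through a stop
codon.  pS = Sd / S and pN = Nd / N use site counts averaged between the
two sequences; K = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
import math
import warnings

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = "TCAG"

# standard genetic code, '*' = stop
_CODON_TABLE = {
    a + b + c: aa
    for (a, b, c), aa in zip(
        ((a, b, c) for a in BASES for b in BASES for c in BASES),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper().replace("U", "T")]


@dataclass(frozen=True)
class SnpRecord:
    transcript_id: str
    position: int
    freq_frat: float
    freq_obliq: float

    @property
    def d(self) -> float:
        return snp_d(self.freq_frat, self.freq_obliq)

    @property
    def fixed(self) -> bool:
        return self.d == 1.0


@dataclass(frozen=True)
class DivergenceRecord:
    transcript_id: str
    Ka: float | None = None
    Ks: float | None = None
    ka_ks: float | None = None
    d_xy: float | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# SNP-level divergence
# ---------------------------------------------------------------------------

def snp_d(freq_frat: float, freq_obliq: float) -> float:
    """Absolute allele-frequency difference |frat - obliq| for one SNP."""
    if not (0.0 <= freq_frat <= 1.0 and 0.0 <= freq_obliq <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return abs(freq_frat - freq_obliq)


def dxy(snps) -> float | None:
    """Fixed-SNP fraction for one transcript; None for an empty SNP list."""
    ds = [s.d if isinstance(s, SnpRecord) else float(s) for s in snps]
    if not ds:
        return None
    return sum(1 for d in ds if d == 1.0) / len(ds)


def read_snp_table(path) -> pd.DataFrame:
    """TSV with columns transcript_id, position, freq_frat, freq_obliq."""
    df = pd.read_csv(path, sep="\t")
    need = {"transcript_id", "position", "freq_frat", "freq_obliq"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    for col in ("freq_frat", "freq_obliq"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    df["d"] = (df["freq_frat"] - df["freq_obliq"]).abs()
    df["fixed"] = df["d"] == 1.0
    return df


def dxy_table(snp_table: pd.DataFrame, maf: float = 0.02) -> pd.Series:
    """Per-transcript d_xy.  SNPs whose minor allele frequency is below
    ``maf`` in both species are excluded before counting."""
    t = snp_table.copy()
    minor_f = np.minimum(t["freq_frat"], 1 - t["freq_frat"])
    minor_o = np.minimum(t["freq_obliq"], 1 - t["freq_obliq"])
    same_major = (t["freq_frat"] - 0.5) * (t["freq_obliq"] - 0.5) > 0
    # near-monomorphic for the same allele in both species: likely noise
    noise = (minor_f < maf) & (minor_o < maf) & same_major
    t = t[~noise]
    out = t.groupby("transcript_id").apply(
        lambda g: (g["d"] == 1.0).mean(), include_groups=False)
    out.name = "d_xy"
    return out


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon."""
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if translate_codon(mutant) == aa:
                syn += 1.0
    # each position has 3 possible mutations; 9 per codon -> 3 sites
    return syn / 3.0, 3.0 - syn / 3.0


def _check_cds(seq: str, label: str, final_stop_ok: bool = True) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: CDS length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if any(b not in BASES for b in c):
            continue  # ambiguous codons are skipped by the callers
        if translate_codon(c) == "*" and not (final_stop_ok and i == len(codons) - 1):
            raise ValueError(f"{label}: internal stop codon at codon {i + 1}")
    return codons


def ng86_sites(cds: str, label: str = "cds") -> tuple[float, float]:
    """Total (S, N) NG86 site counts for one coding sequence.

    Codons containing ambiguous bases are skipped with a warning; a single
    terminal stop codon is tolerated and excluded from the counts.
    S + N equals 3 x (number of counted codons) exactly.
    """
    codons = _check_cds(cds, label)
    s_total = n_total = 0.0
    for i, c in enumerate(codons):
        if any(b not in BASES for b in c):
            warnings.warn(f"{label}: skipping ambiguous codon {i + 1} ({c})")
            continue
        if translate_codon(c) == "*":
            continue  # terminal stop
        s, n = _codon_sites(c)
        s_total += s
        n_total += n
    return s_total, n_total


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two codons
    over all orderings of the minimal mutational path, excluding paths that
    pass through a stop codon.  None if every path is blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_counts, nonsyn_counts = [], []
    for order in permutations(diff):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate_codon(nxt) == "*":
                blocked = True
                break
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            syn_counts.append(syn)
            nonsyn_counts.append(nonsyn)
    if not syn_counts:
        return None
    return float(np.mean(syn_counts)), float(np.mean(nonsyn_counts))


def jukes_cantor(p: float) -> float | None:
    """JC69 distance -(3/4) ln(1 - 4p/3); None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(cds1: str, cds2: str,
              transcript_id: str = "") -> DivergenceRecord:
    """Ka and Ks between an aligned coding-sequence pair (NG86 + JC69).

    Site counts are averaged between the two sequences; codons with
    ambiguous bases in either sequence, terminal stops, and codon pairs
    whose every minimal path crosses a stop are skipped.
    """
    if len(cds1) != len(cds2):
        raise ValueError(
            f"{transcript_id}: aligned CDS lengths differ "
            f"({len(cds1)} vs {len(cds2)})")
    codons1 = _check_cds(cds1, f"{transcript_id}/seq1")
    codons2 = _check_cds(cds2, f"{transcript_id}/seq2")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for i, (c1, c2) in enumerate(zip(codons1, codons2)):
        if any(b not in BASES for b in c1 + c2):
            warnings.warn(f"{transcript_id}: skipping ambiguous codon {i + 1}")
            continue
        if translate_codon(c1) == "*" or translate_codon(c2) == "*":
            continue  # terminal stop
        counts = _codon_path_counts(c1, c2)
        if counts is None:
            warnings.warn(
                f"{transcript_id}: codon {i + 1} has no stop-free minimal "
                "path; skipped")
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd += counts[0]
        nd += counts[1]
    if s_sites == 0 and n_sites == 0:
        return DivergenceRecord(transcript_id, note="no countable codons")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    note = ""
    if ks is None:
        note = "pS >= 3/4: Ks undefined"
    if ka is None:
        note = (note + "; " if note else "") + "pN >= 3/4: Ka undefined"
    ka_ks = None
    if ka is not None and ks is not None and ks > 0:
        ka_ks = ka / ks
    elif ks == 0 and not note:
        note = "Ks = 0: Ka/Ks undefined"
    return DivergenceRecord(transcript_id, Ka=ka, Ks=ks, ka_ks=ka_ks, note=note)


# ---------------------------------------------------------------------------
# FASTA plumbing
# ---------------------------------------------------------------------------

def read_cds_pairs(path) -> dict[str, tuple[str, str]]:
    """Aligned CDS pairs from FASTA: two records per transcript, ids
    ``<transcript>_frat`` and ``<transcript>_obliq``."""
    seqs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        for suffix in ("_frat", "_obliq"):
            if rec.id.endswith(suffix):
                tid = rec.id[: -len(suffix)]
                seqs.setdefault(tid, {})[suffix[1:]] = str(rec.seq)
                break
        else:
            raise ValueError(f"FASTA id {rec.id!r} lacks _frat/_obliq suffix")
    out = {}
    for tid, pair in seqs.items():
        if set(pair) != {"frat", "obliq"}:
            raise ValueError(f"transcript {tid}: missing one species' CDS")
        out[tid] = (pair["frat"], pair["obliq"])
    return out


def divergence_table(cds_pairs: dict[str, tuple[str, str]],
                     snp_table: pd.DataFrame | None = None,
                     maf: float = 0.02) -> pd.DataFrame:
    """Per-transcript DivergenceRecord table (Ka, Ks, Ka/Ks, d_xy)."""
    rows = []
    for tid, (c1, c2) in cds_pairs.items():
        rec = kaks_ng86(c1, c2, tid)
        rows.append({"transcript_id": tid, "Ka": rec.Ka, "Ks": rec.Ks,
                     "ka_ks": rec.ka_ks, "note": rec.note})
    out = pd.DataFrame(rows).set_index("transcript_id") if rows else \
        pd.DataFrame(columns=["Ka", "Ks", "ka_ks", "note"],
                     index=pd.Index([], name="transcript_id"))
    if snp_table is not None and len(snp_table):
        out = out.join(dxy_table(snp_table, maf=maf), how="outer")
    else:
        out["d_xy"] = np.nan
    return out
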