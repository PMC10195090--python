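"""Count-matrix data model, readers/writers, and count-level preprocessing.

The analysis starts from a transcript x sample matrix of reads overlapping
fixed inter-specific SNPs.  Parental samples contribute one total-expression
column each; every hybrid biological replicate contributes two
allele-specific columns (A1 = fraterculus-derived, A2 = obliqua-derived).
Preprocessing follows the standard ASE recipe: round to integers, filter on
a counts-per-million floor within every comparable replicate group, then
replace remaining zeros with ones so downstream binomial ratio tests are
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

LINES = ("frat", "obliq", "OF", "FO")
PARENTAL_LINES = ("frat", "obliq")
HYBRID_LINES = ("OF", "FO")
SEXES = ("M", "F")
ALLELES = ("frat", "obliq", "none")

SHEET_COLUMNS = ("sample_id", "line", "sex", "replicate", "allele")


class DataValidationError(ValueError):
    """Raised when an input file or table violates the data model."""


@dataclass(frozen=True)
class FilterConfig:
    """Low-expression filter settings.

    min_cpm: counts-per-million floor (default 3).
    min_replicates: number of replicates per group that must reach the
        floor for a transcript to be kept (default 2, i.e. 2-of-3).
    zero_adjust: whether remaining zeros are bumped to one after filtering.
    """

    min_cpm: float = 3.0
    min_replicates: int = 2
    zero_adjust: bool = True

    def __post_init__(self) -> None:
        if self.min_cpm < 0:
            raise DataValidationError("min_cpm must be >= 0")
        if self.min_replicates < 1:
            raise DataValidationError("min_replicates must be >= 1")


class CountMatrix:
    """Rectangular transcript x sample matrix of non-negative integer counts.

    Thin wrapper over a pandas DataFrame (index = transcript ids, columns =
    sample ids) that enforces the invariants once at construction:
    no duplicate ids, no negative values, integer dtype.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate transcript ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dups[:5]}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataValidationError("counts must be numeric")
        if values.size and (values < 0).any():
            raise DataValidationError("negative counts are not allowed")
        self.df = counts.round().astype(np.int64)
        self.df.index.name = "transcript_id"

    # -- accessors -------------------------------------------------------
    @property
    def transcript_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.df.equals(other.df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.df.shape[0]} transcripts x {self.df.shape[1]} samples)"

    def subset(self, transcript_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.df.loc[list(transcript_ids)])


class SampleSheet:
    """Sample metadata: line, sex, replicate and (for hybrids) allele of origin.

    The design mirrors an interspecific cross scheme in which one direction
    (FO) yields only female progeny, so FO-male rows are rejected outright.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SHEET_COLUMNS if c not in table.columns]
        if missing:
            raise DataValidationError(f"sample sheet missing columns: {missing}")
        table = table.loc[:, list(SHEET_COLUMNS)].copy()
        if table.empty:
            raise DataValidationError("sample sheet is empty")
        table["sample_id"] = table["sample_id"].astype(str)
        if table["sample_id"].duplicated().any():
            raise DataValidationError("duplicate sample_id in sheet")
        bad = set(table["line"]) - set(LINES)
        if bad:
            raise DataValidationError(f"unknown line token(s): {sorted(bad)}")
        bad = set(table["sex"]) - set(SEXES)
        if bad:
            raise DataValidationError(f"unknown sex token(s): {sorted(bad)}")
        table["allele"] = table["allele"].fillna("none")
        bad = set(table["allele"]) - set(ALLELES)
        if bad:
            raise DataValidationError(f"unknown allele token(s): {sorted(bad)}")
        table["replicate"] = table["replicate"].astype(int)
        if (table["replicate"] < 1).any():
            raise DataValidationError("replicate numbers must be positive")
        fo_male = (table["line"] == "FO") & (table["sex"] == "M")
        if fo_male.any():
            raise DataValidationError(
                "FO male samples are not possible: the FO cross "
                "only produces female progeny"
            )
        parental = table["line"].isin(PARENTAL_LINES)
        if (parental & (table["allele"] != "none")).any():
            raise DataValidationError("parental columns must have allele = none")
        if ((~parental) & (table["allele"] == "none")).any():
            raise DataValidationError("hybrid columns must carry an allele of origin")
        # each hybrid biological replicate contributes exactly two allele columns
        hyb = table[~parental]
        per_rep = hyb.groupby(["line", "sex", "replicate"])["allele"].agg(
            lambda a: tuple(sorted(a))
        )
        bad_reps = per_rep[per_rep != ("frat", "obliq")]
        if len(bad_reps):
            raise DataValidationError(
                f"hybrid replicates without exactly one column per allele: "
                f"{bad_reps.index.tolist()}"
            )
        self.df = table.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    def select(self, line=None, sex=None, allele=None) -> pd.DataFrame:
        """Rows matching the given line/sex/allele, sorted by replicate."""
        out = self.df
        if line is not None:
            out = out[out["line"] == line]
        if sex is not None:
            out = out[out["sex"] == sex]
        if allele is not None:
            out = out[out["allele"] == allele]
        return out.sort_values("replicate")

    def columns_for(self, line, sex, allele=None) -> list[str]:
        return self.select(line, sex, allele)["sample_id"].tolist()

    def groups(self) -> dict[tuple, list[str]]:
        """Comparable replicate groups for the low-expression filter.

        Parental line x sex, and each hybrid allele class (cross x sex x
        allele); every group is a set of columns that are biological
        replicates of the same expression quantity.
        """
        out: dict[tuple, list[str]] = {}
        for line in PARENTAL_LINES:
            for sex in SEXES:
                cols = self.columns_for(line, sex)
                if cols:
                    out[(line, sex, "none")] = cols
        for line in HYBRID_LINES:
            for sex in SEXES:
                for allele in PARENTAL_LINES:
                    cols = self.columns_for(line, sex, allele)
                    if cols:
                        out[(line, sex, allele)] = cols
        return out

    def validate_against(self, m: CountMatrix) -> None:
        sheet_ids = set(self.df["sample_id"])
        matrix_ids = set(map(str, m.sample_ids))
        if sheet_ids != matrix_ids:
            raise DataValidationError(
                f"sheet/matrix sample mismatch: only in sheet "
                f"{sorted(sheet_ids - matrix_ids)[:5]}, only in matrix "
                f"{sorted(matrix_ids - sheet_ids)[:5]}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated count table (header = sample ids, first column =
    transcript ids).  Values are rounded to the nearest integer; negative
    values, ragged rows and duplicate ids are rejected."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataValidationError(f"{path}: empty file")
        fields = header.rstrip("\n").split("\t")
        n_fields = len(fields)
        sample_fields = fields[1:]
        if len(set(sample_fields)) != len(sample_fields):
            raise DataValidationError(f"{path}: duplicate sample ids in header")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
                raise DataValidationError(
                    f"{path}:{lineno}: expected {n_fields} fields"
                )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.df.to_csv(path, sep="\t", index_label="transcript_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab- or comma-separated sample sheet and validate it."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise DataValidationError(f"{path}: empty file")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise DataValidationError(f"{path}: no sample rows")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: cell * 1e6 / column total.  Errors on an all-zero
    column, naming the offending sample."""
    totals = m.df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DataValidationError(
            f"zero library size for sample(s): {zero.index.tolist()}"
        )
    return m.df * 1e6 / totals


def filter_min_cpm(
    m: CountMatrix, sheet: SampleSheet, cfg: FilterConfig | None = None
) -> CountMatrix:
    """Keep transcripts reaching ``min_cpm`` in at least ``min_replicates``
    replicates within EVERY comparable group.

    Comparable groups are each parental line x sex, and each hybrid cross x
    sex evaluated on per-replicate total expression (the two allele columns
    summed).  Filtering hybrids at the total level — not per allele — keeps
    hemizygous transcripts (e.g. X-linked loci expressed from one parental
    allele only) in the dataset; their residual allele zeros are what the
    downstream zero adjustment exists for.
    """
    cfg = cfg or FilterConfig()
    sheet.validate_against(m)
    totals = m.df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DataValidationError(
            f"zero library size for sample(s): {zero.index.tolist()}"
        )
    keep = pd.Series(True, index=m.transcript_ids)

    def apply_group(key, rate_frame):
        nonlocal keep
        if rate_frame.shape[1] < cfg.min_replicates:
            raise DataValidationError(
                f"group {key} has {rate_frame.shape[1]} replicates < "
                f"min_replicates={cfg.min_replicates}"
            )
        keep &= (rate_frame >= cfg.min_cpm).sum(axis=1) >= cfg.min_replicates

    for line in PARENTAL_LINES:
        for sex in SEXES:
            cols = sheet.columns_for(line, sex)
            if cols:
                apply_group((line, sex), m.df[cols] * 1e6 / totals[cols])
    for line in HYBRID_LINES:
        for sex in SEXES:
            a1 = sheet.select(line, sex, "frat")
            a2 = sheet.select(line, sex, "obliq")
            if a1.empty:
                continue
            rep_rates = {}
            for r in sorted(a1["replicate"]):
                c1 = a1[a1["replicate"] == r]["sample_id"].iloc[0]
                c2 = a2[a2["replicate"] == r]["sample_id"].iloc[0]
                rep_rates[r] = ((m.df[c1] + m.df[c2]) * 1e6
                                / (totals[c1] + totals[c2]))
            apply_group((line, sex), pd.DataFrame(rep_rates))
    return CountMatrix(m.df.loc[keep])


def adjust_zeros(m: CountMatrix) -> CountMatrix:
    """Replace every remaining zero with one (applied after filtering, so
    the binomial ratio tests see strictly positive integers)."""
    df = m.df.copy()
    df[df == 0] = 1
    return CountMatrix(df)


def hybrid_totals(m: CountMatrix, sheet: SampleSheet) -> dict[tuple, pd.DataFrame]:
    """Per-replicate hybrid total expression (A1 + A2), derived on demand.

    Returns {(cross, sex): DataFrame} with one column per replicate,
    columns named '<cross>_<sex>_r<replicate>'.
    """
    out: dict[tuple, pd.DataFrame] = {}
    for line in HYBRID_LINES:
        for sex in SEXES:
            a1 = sheet.select(line, sex, "frat")
            a2 = sheet.select(line, sex, "obliq")
            if a1.empty:
                continue
            reps = sorted(a1["replicate"])
            cols = {}
            for r in reps:
                c1 = a1[a1["replicate"] == r]["sample_id"].iloc[0]
                c2 = a2[a2["replicate"] == r]["sample_id"].iloc[0]
                cols[f"{line}_{sex}_r{r}"] = m.df[c1] + m.df[c2]
            out[(line, sex)] = pd.DataFrame(cols, index=m.transcript_ids)
    return out
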