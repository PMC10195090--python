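"""Ground-truth generator for allele-resolved hybrid count data.

The generator emulates the study design the pipeline targets: two parental
lines (frat, obliq) with male and female samples, reciprocal F1 hybrids OF
and FO where the FO cross yields females only, three biological replicates
per cross, and hybrid libraries split into two allele-specific columns.
Counts are negative binomial with a common dispersion and per-library size
factors.

Per transcript the architecture is a (cis, trans) pair of log2 effects c
and t on top of a baseline mean mu for the obliqua background:

* obliqua parent mean        mu
* fraterculus parent mean    mu * 2^(c+t)
* hybrid obliqua allele      (mu/2) * 2^(t/2)
* hybrid fraterculus allele  (mu/2) * 2^(c + t/2)

Both hybrid alleles share the mid-parent trans environment (each receives
t/2), so in expectation Rh = c, Rp = c + t and T = t.  An optional
inheritance override rescales the hybrid total mean (preserving the allele
ratio) to a dominant / additive / transgressive target, and x-linked
transcripts draw zero fraterculus-allele counts in hybrid males.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data_io import CountMatrix, SampleSheet
from . import diffexpr_stats as ds

INHERITANCE_OVERRIDES = (
    "additive", "dominant_frat", "dominant_obliq", "overdominant",
    "underdominant",
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Generating regulatory architecture for one transcript."""

    transcript_id: str
    cis: float = 0.0
    trans: float = 0.0
    base_mean: float = 500.0
    inheritance_override: str | None = None
    x_linked: bool = False

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if (self.inheritance_override is not None
                and self.inheritance_override not in INHERITANCE_OVERRIDES):
            raise ValueError(
                f"unknown inheritance_override {self.inheritance_override!r}")

    @property
    def regulatory_class(self) -> str:
        """The class the architecture encodes (expected Rh = c, Rp = c + t)."""
        c, t = self.cis, self.trans
        if c == 0 and t == 0:
            return "conserved"
        if t == 0:
            return "cis_only"
        if c == 0:
            return "trans_only"
        if c + t == 0:
            return "compensatory"
        return "cis_plus_trans" if np.sign(c) == np.sign(c + t) else "cis_x_trans"


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; a fixed seed gives byte-identical output."""

    n_replicates: int = 3
    dispersion: float = 0.05
    seed: int = 0
    lib_size_sigma: float = 0.15  # sd of log-normal library-size factors
    library_sizes: dict | None = None  # explicit per-sample factors
    include_fo: bool = True
    sexes: tuple = ("M", "F")

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def architecture_mix(n_transcripts: int, fractions: dict[str, float],
                     effect: float = 3.0, base_mean: float = 500.0,
                     x_linked_fraction: float = 0.0,
                     seed: int = 0) -> list[ArchitectureSpec]:
    """Build a transcript set with the given class fractions.

    fractions: {class: fraction} over conserved / cis_only / trans_only /
    cis_plus_trans / cis_x_trans / compensatory; must sum to ~1.  Effects
    have magnitude ``effect`` with random sign.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-6:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = list(fractions)
    counts = np.floor(np.array([fractions[c] for c in classes]) * n_transcripts).astype(int)
    counts[0] += n_transcripts - counts.sum()
    specs = []
    i = 0
    for cls, k in zip(classes, counts):
        for _ in range(k):
            sign = rng.choice([-1.0, 1.0])
            if cls == "conserved":
                c, t = 0.0, 0.0
            elif cls == "cis_only":
                c, t = sign * effect, 0.0
            elif cls == "trans_only":
                c, t = 0.0, sign * effect
            elif cls == "compensatory":
                c, t = sign * effect, -sign * effect
            elif cls == "cis_plus_trans":
                c, t = sign * effect, sign * effect / 2
            elif cls == "cis_x_trans":
                c, t = sign * effect, -sign * 2 * effect
            else:
                raise ValueError(f"unknown architecture class {cls!r}")
            xl = bool(rng.random() < x_linked_fraction)
            specs.append(ArchitectureSpec(f"tr{i:05d}", c, t, base_mean,
                                          x_linked=xl))
            i += 1
    return specs


def _design_columns(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for line in ("frat", "obliq"):
        for sex in cfg.sexes:
            for r in range(1, cfg.n_replicates + 1):
                rows.append((f"{line}_{sex}_r{r}", line, sex, r, "none"))
    crosses = ["OF"] + (["FO"] if cfg.include_fo else [])
    for line in crosses:
        for sex in cfg.sexes:
            if line == "FO" and sex == "M":
                continue  # this cross direction yields only females
            for r in range(1, cfg.n_replicates + 1):
                for allele in ("frat", "obliq"):
                    rows.append((f"{line}_{sex}_r{r}_{allele}", line, sex, r, allele))
    return pd.DataFrame(rows, columns=["sample_id", "line", "sex",
                                       "replicate", "allele"])


def expected_means(spec: ArchitectureSpec) -> dict[str, float]:
    """Noise-free group means implied by one architecture."""
    mu = spec.base_mean
    c, t = spec.cis, spec.trans
    p_frat = mu * 2.0 ** (c + t)
    p_obliq = mu
    a_frat = (mu / 2.0) * 2.0 ** (c + t / 2.0)
    a_obliq = (mu / 2.0) * 2.0 ** (t / 2.0)
    if spec.inheritance_override is not None:
        hi, lo = max(p_frat, p_obliq), min(p_frat, p_obliq)
        target = {
            # log-scale midpoint: additivity of the log2 effects, which is
            # the scale the fold-change thresholds operate on
            "additive": float(np.sqrt(p_frat * p_obliq)),
            "dominant_frat": p_frat,
            "dominant_obliq": p_obliq,
            "overdominant": hi * 2.0 ** 1.5,
            "underdominant": lo / 2.0 ** 1.5,
        }[spec.inheritance_override]
        scale = target / (a_frat + a_obliq)
        a_frat, a_obliq = a_frat * scale, a_obliq * scale
    return {"p_frat": p_frat, "p_obliq": p_obliq,
            "a_frat": a_frat, "a_obliq": a_obliq}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, np.maximum(mean, 0.0) * phi)
    return rng.poisson(lam)


def simulate_counts(specs: list[ArchitectureSpec], cfg: SimConfig
                    ) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Draw a full allele-resolved count matrix plus its ground truth.

    Returns (CountMatrix, SampleSheet, truth) where truth records, per
    transcript, the generating cis/trans effects, the implied Rh / Rp / T,
    the regulatory class, any inheritance override and the X-linkage flag.
    """
    if not specs:
        raise ValueError("no architectures given")
    design = _design_columns(cfg)
    rng = np.random.default_rng(cfg.seed)
    if cfg.library_sizes is not None:
        factors = np.array([cfg.library_sizes[s] for s in design["sample_id"]])
    elif cfg.lib_size_sigma > 0:
        factors = np.exp(rng.normal(0.0, cfg.lib_size_sigma, len(design)))
    else:
        factors = np.ones(len(design))

    mean_rows = np.empty((len(specs), len(design)))
    for i, spec in enumerate(specs):
        m = expected_means(spec)
        for j, row in enumerate(design.itertuples(index=False)):
            if row.line == "frat":
                mu = m["p_frat"]
            elif row.line == "obliq":
                mu = m["p_obliq"]
            elif row.allele == "frat":
                mu = 0.0 if (spec.x_linked and row.sex == "M") else m["a_frat"]
            else:
                mu = m["a_obliq"]
            mean_rows[i, j] = mu * factors[j]
    counts = _nb_draw(rng, mean_rows, cfg.dispersion)

    cm = CountMatrix(pd.DataFrame(
        counts, index=pd.Index([s.transcript_id for s in specs],
                               name="transcript_id"),
        columns=design["sample_id"].tolist()))
    sheet = SampleSheet(design)
    truth = pd.DataFrame(
        {"cis": [s.cis for s in specs],
         "trans": [s.trans for s in specs],
         "base_mean": [s.base_mean for s in specs],
         "Rh": [s.cis for s in specs],
         "Rp": [s.cis + s.trans for s in specs],
         "T": [s.trans for s in specs],
         "regulatory_class": [s.regulatory_class for s in specs],
         "inheritance_override": [s.inheritance_override for s in specs],
         "x_linked": [s.x_linked for s in specs]},
        index=cm.transcript_ids)
    return cm, sheet, truth


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def power_analysis(cfg: SimConfig, effect_grid, n_sims: int = 20,
                   n_transcripts: int = 2000, de_fraction: float = 0.1,
                   fc_thresholds=(0.0, 0.5, 1.0, 1.25, 1.5),
                   base_mean: float = 100.0, alpha: float = 0.05
                   ) -> pd.DataFrame:
    """Power of the two-group NB test across fold-change thresholds.

    For each true effect size in ``effect_grid`` (log2 units; 0 = all-null)
    and each |log2FC| call threshold, simulates ``n_sims`` two-group
    datasets (``de_fraction`` of transcripts differentially expressed with
    random sign), runs the NB test + BH-FDR at ``alpha`` and reports the
    mean fraction of truly-DE transcripts called (power) and the realized
    false-discovery proportion.
    """
    effect_grid = list(effect_grid)
    if not effect_grid:
        raise ValueError("effect_grid must be non-empty")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for effect in effect_grid:
        power = {th: [] for th in fc_thresholds}
        fdp = {th: [] for th in fc_thresholds}
        for _ in range(n_sims):
            de = np.zeros(n_transcripts, dtype=bool)
            if effect != 0:
                de[: int(round(de_fraction * n_transcripts))] = True
            signs = rng.choice([-1.0, 1.0], n_transcripts)
            lfc = np.where(de, signs * effect, 0.0)
            mu = base_mean * np.exp(rng.normal(0, 1, n_transcripts))
            mean_a = mu * 2.0 ** (lfc / 2.0)
            mean_b = mu * 2.0 ** (-lfc / 2.0)
            r = cfg.n_replicates
            a = _nb_draw(rng, np.repeat(mean_a[:, None], r, 1), cfg.dispersion)
            b = _nb_draw(rng, np.repeat(mean_b[:, None], r, 1), cfg.dispersion)
            res = ds.nb_two_group_test(a, b, phi=cfg.dispersion)
            q = ds.bh_fdr(res["p"].to_numpy())
            for th in fc_thresholds:
                called = (q < alpha) & (res["log2fc"].abs().to_numpy() > th)
                n_called = int(called.sum())
                fp = int((called & ~de).sum())
                fdp[th].append(fp / max(n_called, 1))
                if de.any():
                    power[th].append(float((called & de).sum() / de.sum()))
        for th in fc_thresholds:
            rows.append({
                "effect": effect, "fc_threshold": th,
                "power": float(np.mean(power[th])) if power[th] else np.nan,
                "fdp": float(np.mean(fdp[th])),
                "fdp_se": float(np.std(fdp[th], ddof=1) / np.sqrt(n_sims))
                if n_sims > 1 else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mapping-bias diagnostic
# ---------------------------------------------------------------------------

def mapping_bias_diagnostic(m: CountMatrix, sheet: SampleSheet,
                            conf: float = 0.95) -> pd.DataFrame:
    """Per hybrid library: mean log2(A1/A2) across transcripts with a CI.

    In the absence of reference-mapping bias the allele ratio should sit at
    1:1; a library is flagged when its confidence interval excludes zero.
    Transcripts with a zero count for either allele are left out of that
    library's average.
    """
    df = getattr(m, "df", m)
    rows = []
    for line in ("OF", "FO"):
        for sex in ("M", "F"):
            a1 = sheet.select(line, sex, "frat")
            a2 = sheet.select(line, sex, "obliq")
            for r in sorted(a1["replicate"]):
                c1 = df[a1[a1["replicate"] == r]["sample_id"].iloc[0]]
                c2 = df[a2[a2["replicate"] == r]["sample_id"].iloc[0]]
                ok = (c1 > 0) & (c2 > 0)
                ratios = np.log2(c1[ok] / c2[ok])
                n = len(ratios)
                mean = float(ratios.mean()) if n else np.nan
                if n > 1:
                    half = stats.t.ppf(0.5 + conf / 2, n - 1) * ratios.std(ddof=1) / np.sqrt(n)
                else:
                    half = np.nan
                rows.append({"library": f"{line}_{sex}_r{r}", "line": line,
                             "sex": sex, "replicate": r, "n_transcripts": n,
                             "mean_log2_ratio": mean,
                             "ci_low": mean - half, "ci_high": mean + half,
                             "biased": bool(n > 1 and (mean - half > 0
                                                       or mean + half < 0))})
    if not rows:
        raise ValueError("no hybrid allele columns found")
    return pd.DataFrame(rows).set_index("library")
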