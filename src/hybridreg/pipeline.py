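"""End-to-end orchestration: filter -> normalize -> test -> classify ->
divergence -> association, with a run manifest and a summary report.

The unit of analysis is a profile, i.e. a cross x sex combination; the FO
cross contributes only females.  Within each profile five contrasts are
computed and BH-adjusted as separate families (contrast x sex x cross):
parental ED, hybrid allelic imbalance, the hybrid-vs-parent ratio test and
the two hybrid-vs-parent total-expression tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data_io import (
    CountMatrix, FilterConfig, SampleSheet, adjust_zeros, cpm,
    filter_min_cpm, hybrid_totals, read_counts, read_sample_sheet,
)
from . import diffexpr_stats as ds
from .diffexpr_stats import StatConfig
from .inheritance_classifier import classify_inheritance_table
from .regulatory_classifier import classify_regulatory_table, flag_x_linked
from .molecular_divergence import (
    divergence_table, read_cds_pairs, read_snp_table,
)
from .category_association import (
    build_association_table, compare_ed_ai_divergence, fit_category_glm,
    normalized_category_counts,
)

log = logging.getLogger("hybridreg")

_FLOAT_FMT = "%.6g"  # stable TSV formatting so reruns are byte-identical


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    counts: str
    sample_sheet: str
    out_dir: str = "hybridreg_out"
    cds_fasta: str | None = None
    snp_table: str | None = None
    stat: StatConfig = field(default_factory=StatConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    require_ed_for_transgressive: bool = False
    remove_x_linked: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stat = StatConfig(**raw.pop("stat", {}))
        filt = FilterConfig(**raw.pop("filter", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(stat=stat, filter=filt, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class Bundle:
    """In-memory results of one pipeline run."""

    tests: dict            # (contrast, sex, cross) -> DataFrame
    inheritance: pd.DataFrame
    regulatory: pd.DataFrame
    tallies: pd.DataFrame
    association: pd.DataFrame
    glms: pd.DataFrame
    ed_ai_divergence: pd.DataFrame
    divergence: pd.DataFrame | None
    dispersion: float
    tmm: pd.Series
    n_input: int
    n_filtered: int
    manifest: dict


def _profiles(sheet: SampleSheet):
    for cross in ("OF", "FO"):
        for sex in ("M", "F"):
            if sheet.columns_for(cross, sex, "frat"):
                yield cross, sex


def _group_lambda(df, cols, eff, phi):
    """MLE normalized mean for one replicate group (vector over transcripts)."""
    y = df[cols].to_numpy(float)
    s = eff.loc[cols].to_numpy(float)
    return ds._fit_mean(y, s / eff.mean(), phi)


def analyze(m_raw: CountMatrix, sheet: SampleSheet,
            stat: StatConfig | None = None,
            filt: FilterConfig | None = None,
            require_ed_for_transgressive: bool = False,
            remove_x_linked: bool = False,
            divergence: pd.DataFrame | None = None) -> Bundle:
    """Run the full statistical analysis on in-memory inputs."""
    stat = stat or StatConfig()
    filt = filt or FilterConfig()
    sheet.validate_against(m_raw)
    n_input = len(m_raw.transcript_ids)

    m_filt = filter_min_cpm(m_raw, sheet, filt)
    log.info("filter: %d -> %d transcripts", n_input, len(m_filt.transcript_ids))
    m = adjust_zeros(m_filt) if filt.zero_adjust else m_filt
    if len(m.transcript_ids) == 0:
        raise RuntimeError("stage filter: no transcripts pass the cpm filter")

    factors = ds.tmm_factors(m)
    eff = ds.effective_lib_sizes(m, factors)

    if stat.dispersion is not None:
        phi = stat.dispersion
    else:
        groups = [f"{r.line}_{r.sex}_{r.allele}"
                  for r in sheet.df.itertuples(index=False)]
        order = [groups[list(sheet.sample_ids).index(c)] for c in m.sample_ids]
        phi = ds.estimate_common_dispersion(m, order, lib_sizes=eff.loc[m.sample_ids])
        log.info("estimated common dispersion: %.4f", phi)

    totals = hybrid_totals(m, sheet)
    ids = m.transcript_ids
    df = m.df

    tests: dict = {}
    inh_rows, reg_rows, tally_rows = [], [], []

    # parental ED per sex (shared across crosses)
    ed_by_sex: dict[str, pd.DataFrame] = {}
    means_parent: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sex in ("M", "F"):
        p1c = sheet.columns_for("frat", sex)
        p2c = sheet.columns_for("obliq", sex)
        if not p1c or not p2c:
            continue
        res = ds.nb_two_group_test(
            df[p1c].to_numpy(float), df[p2c].to_numpy(float),
            lib_sizes=(eff.loc[p1c].to_numpy(), eff.loc[p2c].to_numpy()),
            phi=phi, transcript_ids=ids)
        ed_by_sex[sex] = ds.call_significance(res, stat)
        means_parent[sex] = (_group_lambda(df, p1c, eff, phi),
                             _group_lambda(df, p2c, eff, phi))
        tests[("ED", sex, "parental")] = ed_by_sex[sex]

    x_flags_by_sex: dict[str, pd.Series] = {}
    for cross, sex in _profiles(sheet):
        a1c = sheet.columns_for(cross, sex, "frat")
        a2c = sheet.columns_for(cross, sex, "obliq")
        p1c = sheet.columns_for("frat", sex)
        p2c = sheet.columns_for("obliq", sex)
        ed = ed_by_sex[sex]

        ai = ds.nb_two_group_test(
            df[a1c].to_numpy(float), df[a2c].to_numpy(float),
            lib_sizes=(eff.loc[a1c].to_numpy(), eff.loc[a2c].to_numpy()),
            phi=phi, transcript_ids=ids)
        ai = ds.call_significance(ai, stat)
        tests[("AI", sex, cross)] = ai

        # the binomial model compares count ratios, so columns are first
        # equalized to a common effective depth (library-normalized
        # pseudo-counts); otherwise depth imbalance between the parental
        # libraries masquerades as a trans effect
        ref_depth = float(np.exp(np.log(eff).mean()))
        pseudo = lambda cols: (df[cols].to_numpy(float)
                               * (ref_depth / eff.loc[cols].to_numpy()))
        ratio = ds.binomial_ratio_test(
            pseudo(a1c), pseudo(a2c), pseudo(p1c), pseudo(p2c),
            transcript_ids=ids)
        ratio = ds.call_significance(
            ratio, stat, apply_fc_threshold=stat.fc_threshold_on_ratio)
        tests[("RATIO", sex, cross)] = ratio

        tot = totals[(cross, sex)]
        rep_names = list(tot.columns)
        eff_tot = np.array([
            eff.loc[a1c].to_numpy()[i] + eff.loc[a2c].to_numpy()[i]
            for i in range(len(rep_names))])
        hv1 = ds.nb_two_group_test(
            tot.to_numpy(float), df[p1c].to_numpy(float),
            lib_sizes=(eff_tot, eff.loc[p1c].to_numpy()),
            phi=phi, transcript_ids=ids)
        hv1 = ds.call_significance(hv1, stat)
        tests[("H_vs_P1", sex, cross)] = hv1
        hv2 = ds.nb_two_group_test(
            tot.to_numpy(float), df[p2c].to_numpy(float),
            lib_sizes=(eff_tot, eff.loc[p2c].to_numpy()),
            phi=phi, transcript_ids=ids)
        hv2 = ds.call_significance(hv2, stat)
        tests[("H_vs_P2", sex, cross)] = hv2

        # normalized means on a common scale
        lam_p1, lam_p2 = means_parent[sex]
        lam_a1 = _group_lambda(df, a1c, eff, phi)
        lam_a2 = _group_lambda(df, a2c, eff, phi)
        eff_tot_series = pd.Series(eff_tot, index=rep_names)
        lam_h = ds._fit_mean(tot.to_numpy(float),
                             eff_tot_series.to_numpy() / eff.mean(), phi)
        means = pd.DataFrame({"hybrid": lam_h, "p1": lam_p1, "p2": lam_p2},
                             index=ids)

        inh, _ = classify_inheritance_table(
            ed, hv1, hv2, means,
            require_ed_for_transgressive=require_ed_for_transgressive)
        inh = inh.assign(sex=sex, cross=cross)

        ratios = pd.DataFrame(
            {"Rh": np.log2(lam_a1 / lam_a2), "Rp": np.log2(lam_p1 / lam_p2)},
            index=ids)
        reg = classify_regulatory_table(ed, ai, ratio, ratios)
        if sex == "M":
            flags = flag_x_linked(ai, m_filt, sheet)
            x_flags_by_sex[sex] = flags
        else:
            flags = pd.Series(False, index=ids, name="x_linked_flag")
        reg = reg.assign(x_linked_flag=flags, sex=sex, cross=cross)

        if remove_x_linked and flags.any():
            keep = ~flags
            inh, reg = inh[keep], reg[keep]
            log.info("%s/%s: removed %d X-linkage candidates",
                     cross, sex, int(flags.sum()))

        inh_rows.append(inh.reset_index())
        reg_rows.append(reg.reset_index())
        for kind, frame in (("inheritance", inh), ("regulatory", reg)):
            for cat, n in frame["category"].value_counts().items():
                tally_rows.append({"sex": sex, "cross": cross, "kind": kind,
                                   "category": cat, "n": int(n)})

    inheritance = pd.concat(inh_rows, ignore_index=True)
    regulatory = pd.concat(reg_rows, ignore_index=True)
    tallies = pd.DataFrame(tally_rows)

    # association table and GLMs
    cls = inheritance.rename(columns={"category": "inheritance_category"})[
        ["transcript_id", "sex", "cross", "inheritance_category", "ed_log2fc"]]
    regc = regulatory.rename(columns={"category": "regulatory_category"})[
        ["transcript_id", "sex", "cross", "regulatory_category", "I_cis"]]
    cls = cls.merge(regc, on=["transcript_id", "sex", "cross"])
    cls["abs_ed"] = cls["ed_log2fc"].abs()
    ed_flags = pd.concat(
        [res[["significant"]].rename(columns={"significant": "ed_significant"})
         .reset_index().assign(sex=sex)
         for (kind, sex, _), res in tests.items() if kind == "ED"],
        ignore_index=True)
    ai_flags = pd.concat(
        [res[["significant"]].rename(columns={"significant": "ai_significant"})
         .reset_index().assign(sex=sex, cross=cross)
         for (kind, sex, cross), res in tests.items() if kind == "AI"],
        ignore_index=True)
    cls = cls.merge(ed_flags, on=["transcript_id", "sex"], how="left")
    cls = cls.merge(ai_flags, on=["transcript_id", "sex", "cross"], how="left")
    association = build_association_table(cls, divergence)

    glm_frames = []
    for resp, cat_col in (("n_transcripts", "inheritance_category"),
                          ("n_transcripts", "regulatory_category"),
                          ("abs_ed", "inheritance_category"),
                          ("abs_ed", "regulatory_category"),
                          ("I_cis", "inheritance_category"),
                          ("Ka", "regulatory_category"),
                          ("Ks", "regulatory_category"),
                          ("ka_ks", "regulatory_category")):
        if resp in ("Ka", "Ks", "ka_ks") and (
                divergence is None or association[resp].dropna().empty):
            continue
        try:
            g = fit_category_glm(association, resp, category_col=cat_col)
            g["category_kind"] = cat_col
            glm_frames.append(g)
        except ValueError as exc:
            log.warning("GLM %s by %s skipped: %s", resp, cat_col, exc)
    glms = (pd.concat(glm_frames, ignore_index=True)
            if glm_frames else pd.DataFrame())
    ed_ai = (compare_ed_ai_divergence(association)
             if divergence is not None else pd.DataFrame())

    manifest = {
        "package_version": __version__,
        "n_transcripts_input": n_input,
        "n_transcripts_filtered": int(len(m.transcript_ids)),
        "dispersion": float(phi),
        "tmm_factors": {str(k): float(v) for k, v in factors.items()},
    }
    return Bundle(tests=tests, inheritance=inheritance, regulatory=regulatory,
                  tallies=tallies, association=association, glms=glms,
                  ed_ai_divergence=ed_ai, divergence=divergence,
                  dispersion=float(phi), tmm=factors, n_input=n_input,
                  n_filtered=int(len(m.transcript_ids)), manifest=manifest)


def run_pipeline(cfg: RunConfig) -> Bundle:
    """Load inputs per the config, analyze, and write all outputs."""
    for label, path in (("counts", cfg.counts), ("sample_sheet", cfg.sample_sheet),
                        ("cds_fasta", cfg.cds_fasta), ("snp_table", cfg.snp_table)):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"config {label}: no such file {path}")
    m = read_counts(cfg.counts)
    sheet = read_sample_sheet(cfg.sample_sheet)
    div = None
    if cfg.cds_fasta is not None:
        snps = read_snp_table(cfg.snp_table) if cfg.snp_table else None
        div = divergence_table(read_cds_pairs(cfg.cds_fasta), snps)
    bundle = analyze(m, sheet, cfg.stat, cfg.filter,
                     cfg.require_ed_for_transgressive, cfg.remove_x_linked,
                     divergence=div)
    bundle.manifest.update({"config": cfg.to_dict(), "seed": cfg.seed})
    write_outputs(bundle, cfg.out_dir)
    return bundle


def write_outputs(bundle: Bundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (kind, sex, cross), res in bundle.tests.items():
        res.to_csv(out / f"test_{kind}_{sex}_{cross}.tsv", sep="\t",
                   float_format=_FLOAT_FMT)
    bundle.inheritance.to_csv(out / "inheritance.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    bundle.regulatory.to_csv(out / "regulatory.tsv", sep="\t", index=False,
                             float_format=_FLOAT_FMT)
    bundle.tallies.to_csv(out / "category_tallies.tsv", sep="\t", index=False)
    bundle.association.to_csv(out / "association.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    if len(bundle.glms):
        bundle.glms.to_csv(out / "category_glms.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    if len(bundle.ed_ai_divergence):
        bundle.ed_ai_divergence.to_csv(out / "ed_ai_divergence.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)
    if bundle.divergence is not None:
        bundle.divergence.to_csv(out / "divergence.tsv", sep="\t",
                                 float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.md", "w") as fh:
        fh.write(write_report(bundle))


def write_report(bundle: Bundle) -> str:
    """Human-readable summary of a run."""
    lines = ["# hybridreg run summary", ""]
    lines.append(f"Transcripts in: {bundle.n_input}; "
                 f"passing filter: {bundle.n_filtered}; "
                 f"common NB dispersion: {bundle.dispersion:.4f}")
    lines.append("")
    if bundle.n_filtered == 0 or not len(bundle.tallies):
        lines.append("Zero transcripts analyzed.")
        return "\n".join(lines) + "\n"
    for kind in ("inheritance", "regulatory"):
        lines.append(f"## {kind.capitalize()} categories")
        sub = bundle.tallies[bundle.tallies["kind"] == kind]
        for (sex, cross), g in sub.groupby(["sex", "cross"]):
            total = g["n"].sum()
            parts = ", ".join(
                f"{row.category} {row.n} ({100 * row.n / total:.1f}%)"
                for row in g.sort_values("n", ascending=False).itertuples())
            lines.append(f"- {cross} {sex} (n={total}): {parts}")
        lines.append("")
    icis = bundle.association.groupby("inheritance_category")["I_cis"].mean()
    if icis.notna().any():
        lines.append("## Mean cis index by inheritance category")
        for cat, v in icis.dropna().items():
            lines.append(f"- {cat}: {v:.3f}")
        lines.append("")
    if "ka_ks" in bundle.association and bundle.association["ka_ks"].notna().any():
        kk = bundle.association.groupby("regulatory_category")["ka_ks"].mean()
        lines.append("## Mean Ka/Ks by regulatory category")
        for cat, v in kk.dropna().items():
            lines.append(f"- {cat}: {v:.3f}")
        lines.append("")
    return "\n".join(lines) + "\n"
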