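import numpy as np
import pandas as pd
import pytest

import hybridreg as hr


def study_design_sheet(n_replicates: int = 3) -> pd.DataFrame:
    """Sample-sheet rows mirroring the 21-library cross design."""
    rows = []
    for line in ("frat", "obliq"):
        for sex in ("M", "F"):
            for r in range(1, n_replicates + 1):
                rows.append((f"{line}_{sex}_r{r}", line, sex, r, "none"))
    for line, sexes in (("OF", ("M", "F")), ("FO", ("F",))):
        for sex in sexes:
            for r in range(1, n_replicates + 1):
                for allele in ("frat", "obliq"):
                    rows.append((f"{line}_{sex}_r{r}_{allele}", line, sex, r,
                                 allele))
    return pd.DataFrame(rows, columns=["sample_id", "line", "sex",
                                       "replicate", "allele"])


@pytest.fixture
def design_sheet() -> hr.SampleSheet:
    return hr.SampleSheet(study_design_sheet())


@pytest.fixture(scope="session")
def mixed_simulation():
    """A moderate mixed-architecture simulation shared across tests."""
    fractions = {"conserved": 0.25, "cis_only": 0.25, "trans_only": 0.25,
                 "cis_x_trans": 0.125, "compensatory": 0.125}
    specs = hr.architecture_mix(800, fractions, effect=3.0, base_mean=500.0,
                                seed=101)
    cfg = hr.SimConfig(dispersion=0.05, seed=101)
    m, sheet, truth = hr.simulate_counts(specs, cfg)
    return m, sheet, truth


@pytest.fixture(scope="session")
def mixed_bundle(mixed_simulation):
    m, sheet, truth = mixed_simulation
    bundle = hr.analyze(m, sheet, hr.StatConfig(dispersion=0.05))
    return bundle, truth


def uniform_matrix(n_transcripts=50, value=20, sheet_df=None) -> hr.CountMatrix:
    sheet_df = sheet_df if sheet_df is not None else study_design_sheet()
    ids = [f"t{i}" for i in range(n_transcripts)]
    data = np.full((n_transcripts, len(sheet_df)), value, dtype=int)
    return hr.CountMatrix(pd.DataFrame(data, index=ids,
                                       columns=sheet_df["sample_id"]))
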