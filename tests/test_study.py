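"""Synthetic-study generator: error model, censoring, determinism, round-trip."""

import numpy as np
import pandas as pd
import pytest

from permpbpk import GestationalPhysiology, TKDataset, generate_study
from permpbpk.study import CENSOR_STATES, StudyDesign


@pytest.fixture(scope="module")
def gd1_dataset(phys, chem_cis_gd1):
    return generate_study({"cis": chem_cis_gd1}, phys, sigma_log=0.15, seed=11,
                          gestational_days=[1])


class TestDesign:
    def test_matrices_per_gestational_day(self):
        d = StudyDesign()
        assert "feces" in d.matrices_for(1) and "placenta" not in d.matrices_for(1)
        assert "placenta" in d.matrices_for(15) and "feces" in d.matrices_for(15)
        m20 = d.matrices_for(20)
        assert {"placenta", "fetal_blood", "fetal_liver", "fetal_brain"} <= set(m20)
        assert "feces" not in m20

    def test_loq_units(self):
        d = StudyDesign()
        assert d.loq("cis", "blood") == pytest.approx(0.026)  # 26 ng/ml
        assert d.loq("trans", "brain") == pytest.approx(0.020)  # 20 ng/g
        # feces LOQ is an amount threshold over the 24-h collection
        assert d.loq("cis", "feces") == pytest.approx(0.004 * 10 / 1000)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(n_per_group=0)
        with pytest.raises(ValueError):
            StudyDesign(sample_times=(1, 30))


class TestGenerate:
    def test_record_count_per_group(self, gd1_dataset):
        d = StudyDesign()
        df = gd1_dataset.records
        for mat in ("blood", "liver", "fat"):
            sub = df[df["matrix"] == mat]
            assert len(sub) == d.n_per_group * len(d.sample_times)
        assert len(df[df["matrix"] == "feces"]) == 1  # one pooled 24-h collection

    def test_exact_without_noise_or_censoring(self, phys, chem_cis_gd1):
        tiny_loq = {k: 1e-12 for k in StudyDesign().loq_table}
        design = StudyDesign(loq_table=tiny_loq, n_per_group=1)
        ds = generate_study({"cis": chem_cis_gd1}, phys, design=design, sigma_log=0.0,
                            seed=0, gestational_days=[1])
        assert set(ds.records["censor"]) == {"quantified"}
        # replicate-free, noise-free records equal the model prediction: the
        # same seed with noise must differ
        noisy = generate_study({"cis": chem_cis_gd1}, phys, design=design, sigma_log=0.15,
                               seed=0, gestational_days=[1])
        assert not np.allclose(
            ds.records["concentration"], noisy.records["concentration"]
        )

    def test_all_censored_with_infinite_loq(self, phys, chem_cis_gd1):
        big = {k: np.inf for k in StudyDesign().loq_table}
        ds = generate_study({"cis": chem_cis_gd1}, phys,
                            design=StudyDesign(loq_table=big, not_detected_fraction=0.0),
                            sigma_log=0.1, seed=1, gestational_days=[1])
        assert set(ds.records["censor"]) == {"below_loq_detected"}

    def test_seed_determinism(self, phys, chem_cis_gd1, gd1_dataset):
        again = generate_study({"cis": chem_cis_gd1}, phys, sigma_log=0.15, seed=11,
                               gestational_days=[1])
        pd.testing.assert_frame_equal(gd1_dataset.records, again.records)
        other = generate_study({"cis": chem_cis_gd1}, phys, sigma_log=0.15, seed=12,
                               gestational_days=[1])
        assert not other.records["concentration"].equals(gd1_dataset.records["concentration"])

    def test_lognormal_error_sd(self, phys, chem_cis_gd1):
        """10,000 replicates of one sampling point: sd of log-values ~ 0.15."""
        design = StudyDesign(sample_times=(6.0,), n_per_group=10_000,
                             loq_table={k: 1e-12 for k in StudyDesign().loq_table})
        ds = generate_study({"cis": chem_cis_gd1}, phys, design=design, sigma_log=0.15,
                            seed=5, gestational_days=[1])
        blood = ds.records[ds.records["matrix"] == "blood"]["concentration"]
        assert np.log(blood).std(ddof=1) == pytest.approx(0.15, abs=0.005)

    def test_censoring_monotone_in_loq(self, phys, chem_cis_gd1):
        """Raising every LOQ can only censor more records (fixed seed)."""
        base = StudyDesign().loq_table
        counts = []
        for factor in (0.2, 1.0, 5.0, 25.0):
            design = StudyDesign(loq_table={k: v * factor for k, v in base.items()})
            ds = generate_study({"cis": chem_cis_gd1}, phys, design=design,
                                sigma_log=0.15, seed=3, gestational_days=[1])
            counts.append((ds.records["censor"] != "quantified").sum())
        assert counts == sorted(counts)

    def test_below_loq_records_carry_half_loq(self, gd1_dataset):
        sub = gd1_dataset.records.query("censor == 'below_loq_detected'")
        assert len(sub) > 0
        np.testing.assert_allclose(sub["concentration"], sub["loq"] / 2)

    def test_unknown_gestational_day_rejected(self, phys, chem_cis_gd1):
        with pytest.raises(ValueError, match="not part of the design"):
            generate_study({"cis": chem_cis_gd1}, phys, gestational_days=[7])


class TestRoundTrip:
    def test_write_read_identity(self, gd1_dataset, tmp_path):
        p = tmp_path / "study.csv"
        gd1_dataset.write_csv(p)
        back = TKDataset.read_csv(p)
        pd.testing.assert_frame_equal(
            back.records, gd1_dataset.records, check_dtype=False
        )

    def test_empty_dataset_roundtrips(self, tmp_path):
        empty = TKDataset(pd.DataFrame(columns=gd1_columns()))
        p = tmp_path / "empty.csv"
        empty.write_csv(p)
        assert len(TKDataset.read_csv(p)) == 0

    def test_unknown_censor_token_errors_with_line(self, gd1_dataset, tmp_path):
        p = tmp_path / "bad.csv"
        df = gd1_dataset.records.copy()
        df.loc[2, "censor"] = "mystery"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="line 4"):
            TKDataset.read_csv(p)

    def test_quantified_below_loq_rejected(self, gd1_dataset):
        df = gd1_dataset.records.copy()
        row = df[df["censor"] == "quantified"].index[0]
        df.loc[row, "concentration"] = df.loc[row, "loq"] / 10
        with pytest.raises(ValueError, match="LOQ"):
            TKDataset(df)


def gd1_columns():
    from permpbpk.study import _COLUMNS

    return _COLUMNS
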