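"""Kinetics conversion, tolerance consensus, sample quantification, stability QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breathvoc.siftms import (
    CompoundSpec,
    DuplicateRecordError,
    InstrumentParams,
    InvalidInputError,
    IonScanRecord,
    ProductIonChannel,
    SchemaError,
    channel_concentration,
    placeholder_library,
    quantify_sample,
    quantify_table,
    read_library,
    read_scans,
    stability_check,
    tolerance_consensus,
)


def brute_force_consensus(estimates, tolerance=0.20):
    """Independent oracle: filter against the minimum, then average."""
    c_min = min(estimates)
    accepted = [e for e in estimates if e <= c_min * (1 + tolerance)]
    return sum(accepted) / len(accepted), accepted


class TestChannelConcentration:
    def test_zero_signal_gives_zero_ppb(self, instr):
        ch = ProductIonChannel("x", "H3O+", 59, 2.5e-9, 1.0)
        assert channel_concentration(IonScanRecord("s", ch, 0.0, 1e6), instr) == 0.0

    def test_hand_derived_value(self, instr):
        # [A] = 1000 / (1e6 * 2.5e-9 * 5e-3) = 8e7 cm^-3;
        # mole fraction 8e7 / 2.46e19 = 3.2520e-12 -> 3.2520e-3 ppb
        ch = ProductIonChannel("x", "H3O+", 59, 2.5e-9, 1.0)
        c = channel_concentration(IonScanRecord("s", ch, 1000.0, 1e6), instr)
        assert c == pytest.approx(3.2520325e-3, rel=1e-6)

    def test_branching_fraction_scales_k_eff(self, instr):
        full = ProductIonChannel("x", "H3O+", 59, 2.5e-9, 1.0)
        half = ProductIonChannel("x", "H3O+", 59, 2.5e-9, 0.5)
        c_full = channel_concentration(IonScanRecord("s", full, 1000.0, 1e6), instr)
        c_half = channel_concentration(IonScanRecord("s", half, 1000.0, 1e6), instr)
        assert c_half == pytest.approx(2 * c_full)

    @given(
        product=st.floats(1e-3, 1e6),
        precursor=st.floats(1e2, 1e8),
        a=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_homogeneity_in_count_rates(self, product, precursor, a):
        """Degree +1 in product rate, degree -1 in precursor rate."""
        instr = InstrumentParams()
        ch = ProductIonChannel("x", "O2+", 43, 1.8e-9, 0.9)
        base = channel_concentration(IonScanRecord("s", ch, product, precursor), instr)
        up = channel_concentration(IonScanRecord("s", ch, a * product, precursor), instr)
        down = channel_concentration(IonScanRecord("s", ch, product, a * precursor), instr)
        assert up == pytest.approx(a * base, rel=1e-9)
        assert down == pytest.approx(base / a, rel=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(precursor_rate=0.0),
            dict(precursor_rate=-5.0),
            dict(product_rate=-1.0),
        ],
    )
    def test_invalid_scan_fields_rejected(self, bad):
        ch = ProductIonChannel("x", "H3O+", 59, 2.5e-9, 1.0)
        kwargs = dict(sample_id="s", channel=ch, product_rate=10.0, precursor_rate=1e6)
        kwargs.update(bad)
        with pytest.raises(InvalidInputError):
            IonScanRecord(**kwargs)

    def test_invalid_instrument_and_channel_params_rejected(self):
        with pytest.raises(InvalidInputError, match="reaction_time"):
            InstrumentParams(reaction_time=0.0)
        with pytest.raises(InvalidInputError, match="rate_coefficient"):
            ProductIonChannel("x", "H3O+", 59, 0.0, 1.0)
        with pytest.raises(InvalidInputError, match="branching_fraction"):
            ProductIonChannel("x", "H3O+", 59, 1e-9, 1.5)


class TestToleranceConsensus:
    @pytest.mark.parametrize(
        "estimates, expected_consensus, expected_accepted",
        [
            ([100, 115, 130], 107.5, [100, 115]),
            ([42], 42.0, [42]),
            ([10, 10, 10], 10.0, [10, 10, 10]),
            ([100, 121], 100.0, [100]),          # 121 > 120 excluded
            ([100, 120], 110.0, [100, 120]),     # boundary inclusive
        ],
    )
    def test_worked_examples(self, estimates, expected_consensus, expected_accepted):
        consensus, accepted = tolerance_consensus(estimates)
        assert consensus == pytest.approx(expected_consensus)
        assert accepted == expected_accepted

    def test_empty_estimates_rejected(self):
        with pytest.raises(InvalidInputError):
            tolerance_consensus([])

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(2000):
            n = rng.integers(1, 9)
            est = rng.uniform(0, 1e3, size=n).tolist()
            got, got_acc = tolerance_consensus(est)
            want, want_acc = brute_force_consensus(est)
            assert got == pytest.approx(want, rel=1e-12)
            assert sorted(got_acc) == pytest.approx(sorted(want_acc))

    @given(
        est=st.lists(st.floats(0.001, 1e3), min_size=1, max_size=8),
        scale=st.floats(0.01, 100),
    )
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariant_and_scale_equivariant(self, est, scale):
        consensus, _ = tolerance_consensus(est)
        perm, _ = tolerance_consensus(list(reversed(est)))
        scaled, _ = tolerance_consensus([scale * e for e in est])
        assert perm == pytest.approx(consensus, rel=1e-12)
        assert scaled == pytest.approx(scale * consensus, rel=1e-9)
        c_min = min(est)
        assert c_min * (1 - 1e-12) <= consensus <= c_min * 1.2 * (1 + 1e-12)


class TestQuantifySample:
    def test_all_zero_rates_give_row_of_zeros(self, two_compound_library, instr):
        scans = [
            IonScanRecord("s1", spec.channels[0], 0.0, 1e6)
            for spec in two_compound_library
        ]
        row, _ = quantify_sample(scans, two_compound_library, instr)
        assert row == {"voc_a": 0.0, "voc_b": 0.0}

    def test_multi_channel_composes_kinetics_and_consensus(self, instr):
        # forge product rates whose channel estimates are exactly [100, 115, 130]
        channels = tuple(
            ProductIonChannel("c", "H3O+", 50 + i, 2.0e-9, 1.0) for i in range(3)
        )
        lib = [CompoundSpec("c", "c", "others", channels)]
        targets = [100.0, 115.0, 130.0]
        scans = []
        for ch, target in zip(channels, targets):
            base = channel_concentration(IonScanRecord("s", ch, 1.0, 1e6), instr)
            scans.append(IonScanRecord("s", ch, target / base, 1e6))
        row, details = quantify_sample(scans, lib, instr)
        assert row["c"] == pytest.approx(107.5, rel=1e-9)
        assert len(details["c"].accepted_channels) == 2

    def test_missing_compound_reported_as_nan_not_zero(self, two_compound_library, instr):
        scans = [IonScanRecord("s1", two_compound_library[0].channels[0], 500.0, 1e6)]
        row, _ = quantify_sample(scans, two_compound_library, instr)
        assert row["voc_a"] > 0
        assert np.isnan(row["voc_b"])

    def test_single_channel_reduces_to_channel_concentration(self, two_compound_library, instr):
        scan = IonScanRecord("s1", two_compound_library[0].channels[0], 777.0, 2e6)
        row, _ = quantify_sample([scan], two_compound_library[:1], instr)
        assert row["voc_a"] == pytest.approx(channel_concentration(scan, instr), rel=1e-12)

    def test_unknown_channel_and_duplicates_rejected(self, two_compound_library, instr):
        alien = ProductIonChannel("ghost", "O2+", 99, 1e-9, 1.0)
        with pytest.raises(SchemaError):
            quantify_sample([IonScanRecord("s", alien, 1.0, 1e6)], two_compound_library, instr)
        ch = two_compound_library[0].channels[0]
        dup = [IonScanRecord("s", ch, 1.0, 1e6), IonScanRecord("s", ch, 2.0, 1e6)]
        with pytest.raises(DuplicateRecordError):
            quantify_sample(dup, two_compound_library, instr)


class TestStabilityCheck:
    def test_constant_replicates_are_stable_with_zero_cv(self):
        out = stability_check({"voc": [5, 5, 5, 5]}, cv_threshold=0.1)
        assert out.loc["voc", "cv"] == 0.0
        assert bool(out.loc["voc", "stable"])

    def test_cv_uses_sample_standard_deviation(self):
        # sd([10, 20], ddof=1) / mean = 7.0711 / 15 = 0.4714
        out = stability_check({"voc": [10, 20]}, cv_threshold=0.5)
        assert out.loc["voc", "cv"] == pytest.approx(np.sqrt(50) / 15, rel=1e-9)

    def test_zero_threshold_flags_any_variation_unstable(self):
        out = stability_check({"voc": [10, 10.01]}, cv_threshold=0.0)
        assert not bool(out.loc["voc", "stable"])

    def test_single_replicate_rejected(self):
        with pytest.raises(InvalidInputError):
            stability_check({"voc": [5]})


class TestIo:
    def test_library_and_scans_round_trip_through_csv(self, tmp_path, instr, rng):
        lib = placeholder_library(n_compounds=4, seed=3)
        rows = ["compound_id,name,category,reagent,product_mz,rate_coefficient,branching_fraction,scale"]
        for spec in lib:
            for ch in spec.channels:
                rows.append(f"{spec.compound_id},{spec.name},{spec.category},{ch.reagent},"
                            f"{ch.product_mz},{ch.rate_coefficient},{ch.branching_fraction},{spec.scale}")
        lib_path = tmp_path / "library.csv"
        lib_path.write_text("\n".join(rows))
        lib2 = read_library(lib_path)
        assert [s.compound_id for s in lib2] == [s.compound_id for s in lib]

        scan_rows = ["sample_id,reagent,product_mz,product_rate,precursor_rate"]
        for spec in lib2:
            for ch in spec.channels:
                scan_rows.append(f"s1,{ch.reagent},{ch.product_mz},{rng.uniform(10, 1000):.3f},1e6")
        scan_path = tmp_path / "scans.csv"
        scan_path.write_text("\n".join(scan_rows))
        records = read_scans(scan_path, lib2)
        table, sidecar = quantify_table(records, lib2, instr)
        assert list(table.index) == ["s1"]
        assert set(table.columns) == {s.compound_id for s in lib2}
        assert (table.loc["s1"] >= 0).all()
        assert set(sidecar["s1"]) <= set(table.columns)
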