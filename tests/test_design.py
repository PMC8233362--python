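"""Scaling-law calibration, inverse design, tissue matching."""

import numpy as np
import pandas as pd
import pytest

import brushmech as bm
from brushmech.design import ReferenceTable


def synthetic_table(C=4500.0):
    """Rows constructed exactly on the scaling line through the origin."""
    rows = []
    for n_sc, beta, n_x in [(14, 0.10, 100), (14, 0.20, 50), (70, 0.30, 50)]:
        E = C * beta / (1 + n_sc) ** 1.5
        p = bm.MaterialParams(E, beta)
        rows.append(
            dict(
                chemistry="SYN",
                ratio="1:1",
                n_sc=n_sc,
                n_bb=900,
                n_x=n_x,
                E_kPa=E,
                beta=beta,
                E0_kPa=p.E0,
                lambda_max_exp=beta**-0.5,
                lambda_max_calc=beta**-0.5,
            )
        )
    return ReferenceTable(pd.DataFrame(rows))


class TestCalibrateScaling:
    def test_exact_line_recovers_slope(self):
        cal = bm.calibrate_scaling(synthetic_table(C=4500.0))
        assert cal.constants.C == pytest.approx(4500.0, abs=1e-9)
        assert np.allclose(cal.residuals, 0.0, atol=1e-9)

    def test_reference_rows_correlate(self, reference_table):
        cal = bm.calibrate_scaling(reference_table, chemistry="NCO:OH")
        assert cal.n == 6
        assert cal.pearson_r >= 0.9

    def test_scale_equivariance(self, reference_table):
        cal = bm.calibrate_scaling(reference_table)
        doubled = ReferenceTable(reference_table.df.assign(E_kPa=2 * reference_table.df["E_kPa"]))
        cal2 = bm.calibrate_scaling(doubled)
        assert cal2.constants.C == pytest.approx(2 * cal.constants.C, rel=1e-12)

    def test_degenerate_predictor_rejected(self):
        t = synthetic_table()
        df = t.df.copy()
        df["beta"] = 0.1
        df["n_sc"] = 14
        with pytest.raises(bm.TableError):
            bm.calibrate_scaling(ReferenceTable(df))

    def test_too_few_rows_rejected(self, reference_table):
        with pytest.raises(bm.TableError):
            bm.calibrate_scaling(reference_table, chemistry="PCMA")


class TestProposeArchitectures:
    @pytest.fixture()
    def ncooh_setup(self, reference_table):
        anchors = reference_table.subset("NCO:OH")
        cal = bm.calibrate_scaling(reference_table, chemistry="NCO:OH")
        return anchors, cal.constants

    def test_self_retrieval_of_reference_row(self, ncooh_setup):
        anchors, constants = ncooh_setup
        # NCO:OH 1:4 row: [n_x, n_sc] = [200, 14], E0 = 5.1 kPa, beta = 0.10
        target = bm.DesignTarget(E0_target=5.1, beta_target=0.10)
        cands, _ = bm.propose_architectures(target, constants, [14, 70], [50, 100, 200, 400], anchors=anchors)
        assert cands, "expected at least one candidate"
        assert (cands[0].n_x, cands[0].n_sc) == (200, 14)

    def test_infeasible_target_returns_empty_with_diagnostics(self, ncooh_setup):
        anchors, constants = ncooh_setup
        target = bm.DesignTarget(E0_target=0.1, beta_target=0.9, E0_band=1.0, beta_band=1.0)
        cands, diags = bm.propose_architectures(target, constants, [14, 70], [50, 100, 200, 400], anchors=anchors)
        assert cands == []
        assert len(diags) == 8
        assert all("status" in d for d in diags)

    def test_widening_bands_never_shrinks_candidates(self, ncooh_setup):
        anchors, constants = ncooh_setup
        keys = set()
        for band in (0.05, 0.15, 0.5, 1.0):
            target = bm.DesignTarget(E0_target=5.1, beta_target=0.10, E0_band=band, beta_band=band)
            cands, _ = bm.propose_architectures(target, constants, [14, 70], [50, 100, 200, 400], anchors=anchors)
            new_keys = {(c.n_x, c.n_sc) for c in cands}
            assert keys <= new_keys
            keys = new_keys

    def test_deterministic(self, ncooh_setup):
        anchors, constants = ncooh_setup
        target = bm.DesignTarget(E0_target=5.0, beta_target=0.12, E0_band=0.5, beta_band=0.5)
        a = bm.propose_architectures(target, constants, [14], [50, 100, 200], anchors=anchors)
        b = bm.propose_architectures(target, constants, [14], [50, 100, 200], anchors=anchors)
        assert [c.to_dict() for c in a[0]] == [c.to_dict() for c in b[0]]

    def test_empty_grid_rejected(self, ncooh_setup):
        anchors, constants = ncooh_setup
        with pytest.raises(bm.DesignError):
            bm.propose_architectures(bm.DesignTarget(5.0, 0.1), constants, [], [100], anchors=anchors)


class TestRequiredBeta:
    def test_fixed_point_solves_the_coupling(self):
        k = bm.ScalingConstants(prefactor_mode="calibrated", C=4500.0)
        beta = bm.required_beta(5.0, 14, k)
        assert beta is not None
        E = bm.structural_modulus_predicted(beta, 14, k)
        assert bm.young_modulus(bm.MaterialParams(E, beta)) == pytest.approx(5.0, abs=1e-8)

    def test_infeasible_target_returns_none(self):
        k = bm.ScalingConstants(prefactor_mode="calibrated", C=10.0)
        # C is far too small to reach 100 kPa at n_sc = 70
        assert bm.required_beta(100.0, 70, k) is None


class TestMatchTissue:
    def test_self_match_ranks_first_with_zero_distance(self):
        tissue, _ = bm.gen_tissue_curve(E0=5.0, beta=0.12)
        true_E = 3.0 * 5.0 / (1 + 2 / (1 - 0.12) ** 2)
        cands = [
            bm.MaterialParams(true_E, 0.12),
            bm.MaterialParams(2 * true_E, 0.12),
            bm.MaterialParams(true_E, 0.25),
        ]
        matches = bm.match_tissue(tissue, cands)
        assert matches[0].params.beta == 0.12
        assert matches[0].params.E_struct == pytest.approx(true_E)
        assert matches[0].distance < 1e-9

    def test_doubled_modulus_ranks_behind_exact(self):
        tissue, _ = bm.gen_tissue_curve(E0=5.0, beta=0.12)
        true_E = 3.0 * 5.0 / (1 + 2 / (1 - 0.12) ** 2)
        matches = bm.match_tissue(tissue, [bm.MaterialParams(2 * true_E, 0.12), bm.MaterialParams(true_E, 0.12)])
        assert matches[0].params.E_struct == pytest.approx(true_E)

    def test_ranking_invariant_to_candidate_order(self):
        tissue, _ = bm.gen_tissue_curve(E0=3.0, beta=0.2)
        cands = [bm.MaterialParams(e, b) for e, b in [(1.0, 0.1), (2.0, 0.2), (3.0, 0.3)]]
        a = bm.match_tissue(tissue, cands)
        b = bm.match_tissue(tissue, cands[::-1])
        assert [m.params for m in a] == [m.params for m in b]

    def test_no_overlap_is_input_error(self):
        c = bm.StressStrainCurve(lam=[1.0], sigma=[0.0])
        with pytest.raises(bm.DesignError):
            bm.match_tissue(c, [bm.MaterialParams(1.0, 0.1)])


class TestDerivedColumns:
    def test_recomputation_flags_per_row(self, reference_table):
        df = bm.recompute_derived_columns(reference_table)
        assert len(df) == 11
        # every row agrees within the printed-input rounding slack
        assert (df["E0_abs_diff"] <= 0.3).all()
        # the exactly-reproducing rows
        exact = df[df["E0_match_1dp"]]
        assert {("F:M", "1:1"), ("F:M", "2:1"), ("F:M", "4:1"), ("PCMA", "1.5"), ("PCMA", "3")} <= set(
            zip(exact["chemistry"], exact["ratio"])
        )


class TestReferenceTableInvariants:
    def test_packaged_table_has_eleven_valid_rows(self, reference_table):
        assert len(reference_table) == 11
        assert (reference_table.df["beta"] < 1).all()

    def test_missing_column_rejected(self, reference_table):
        with pytest.raises(bm.TableError):
            ReferenceTable(reference_table.df.drop(columns=["beta"]))

    def test_nonpositive_cell_rejected(self, reference_table):
        df = reference_table.df.copy()
        df.loc[0, "E_kPa"] = -1.0
        with pytest.raises(bm.TableError):
            ReferenceTable(df)
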