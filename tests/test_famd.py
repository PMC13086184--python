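import numpy as np
import pandas as pd
import pytest

from cdexposure import build_daily_exposure, patient_metrics
from cdexposure.famd import (
    MixedTable,
    build_mixed_table,
    contrib_frame,
    eigen_frame,
    famd_fit,
    top_contributors,
)
from cdexposure.records_io import ValidationError


def reference_famd_eigenvalues(quant, qual):
    """Independent oracle: eigendecomposition of the weighted Gram matrix.

    Built with pandas.get_dummies + numpy.linalg.eigh, a separate route from
    the package's SVD pipeline.
    """
    n = len(quant)
    blocks = []
    if quant.shape[1]:
        blocks.append(((quant - quant.mean()) / quant.std(ddof=0)).to_numpy())
    for col in qual.columns:
        D = pd.get_dummies(qual[col], dtype=float).to_numpy()
        p = D.mean(axis=0)
        blocks.append((D - p) / np.sqrt(p))
    Z = np.hstack(blocks)
    return np.sort(np.linalg.eigvalsh(Z.T @ Z / n))[::-1]


def random_mixed_table(rng, n=30, p_quant=3):
    quant = pd.DataFrame(
        rng.normal(size=(n, p_quant)), columns=[f"x{i}" for i in range(p_quant)]
    )
    qual = pd.DataFrame(
        {
            "g2": rng.choice(["a", "b"], size=n),
            "g3": rng.choice(["u", "v", "w"], size=n),
        }
    )
    # guarantee every level observed
    qual.iloc[:2, 0] = ["a", "b"]
    qual.iloc[:3, 1] = ["u", "v", "w"]
    return MixedTable(quant, qual)


class TestBuildMixedTable:
    def _metrics(self, cohort, toy_tables, n=40):
        kb, pims = toy_tables
        out = []
        for stay in cohort.stays[:n]:
            recs = [r for r in cohort.administrations if r.patient_id == stay.patient_id]
            out.extend(patient_metrics(build_daily_exposure(recs, stay, kb=kb, pim_list=pims)))
        return out

    def test_pim_variables_never_enter(self, cohort200, toy_tables):
        metrics = self._metrics(cohort200, toy_tables)
        table = build_mixed_table(metrics, mode="cde")
        assert not any("pim" in v.lower() for v in table.variables)

    def test_modes_share_the_qualitative_block(self, cohort200, toy_tables):
        metrics = self._metrics(cohort200, toy_tables)
        a = build_mixed_table(metrics, mode="cde")
        b = build_mixed_table(metrics, mode="cded")
        pd.testing.assert_frame_equal(a.qualitative, b.qualitative)
        assert "cde_pp" in a.quantitative.columns and "cded_pp" in b.quantitative.columns

    def test_single_level_qualitative_column_dropped(self, cohort200, toy_tables, caplog):
        metrics = self._metrics(cohort200, toy_tables)
        # at default generator settings no patient reaches 10 distinct drugs
        # on the admission day, so presence of HPP at admission is constant
        with caplog.at_level("WARNING", logger="cdexposure"):
            table = build_mixed_table(metrics, mode="cde")
        assert "hpp_admission" not in table.qualitative.columns
        assert any("single-level" in r.message for r in caplog.records)


class TestFAMDFit:
    def test_all_quantitative_reduces_to_standardized_pca(self):
        rng = np.random.default_rng(1)
        quant = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        table = MixedTable(quant, pd.DataFrame(index=quant.index))
        res = famd_fit(table, n_components=4)
        pca_eigs = np.sort(np.linalg.eigvalsh(np.corrcoef(quant.to_numpy().T)))[::-1]
        assert np.allclose(res.eigenvalues, pca_eigs, atol=1e-8)

    def test_total_inertia_identity(self):
        rng = np.random.default_rng(2)
        table = random_mixed_table(rng, n=40, p_quant=4)
        res = famd_fit(table, n_components=9)
        # p_quant + (total categories - p_qual) = 4 + (5 - 2)
        assert res.total_inertia == pytest.approx(7.0, abs=1e-8)
        assert res.eigenvalues.sum() == pytest.approx(7.0, abs=1e-8)

    def test_binary_qualitative_inertia(self):
        rng = np.random.default_rng(3)
        quant = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        qual = pd.DataFrame({"g": rng.choice(["x", "y"], size=30)})
        res = famd_fit(MixedTable(quant, qual), n_components=4)
        assert res.eigenvalues.sum() == pytest.approx(4.0, abs=1e-8)

    def test_contributions_sum_to_100_per_dimension(self):
        rng = np.random.default_rng(4)
        res = famd_fit(random_mixed_table(rng), n_components=4)
        sums = res.variable_contributions_pct.sum(axis=0)
        assert np.allclose(sums.to_numpy(), 100.0, atol=1e-8)

    def test_agreement_with_independent_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            table = random_mixed_table(rng, n=int(rng.integers(15, 40)))
            res = famd_fit(table, n_components=5)
            ref = reference_famd_eigenvalues(table.quantitative, table.qualitative)
            assert np.allclose(res.eigenvalues, ref[: res.n_components], atol=1e-6)

    def test_row_coordinates_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(6)
        res = famd_fit(random_mixed_table(rng), n_components=3)
        var = res.row_coordinates.to_numpy().var(axis=0, ddof=0)
        assert np.allclose(var, res.eigenvalues, atol=1e-8)

    def test_duplicating_rows_leaves_eigenvalues_unchanged(self):
        rng = np.random.default_rng(7)
        table = random_mixed_table(rng)
        doubled = MixedTable(
            pd.concat([table.quantitative] * 2, ignore_index=True),
            pd.concat([table.qualitative] * 2, ignore_index=True),
        )
        a = famd_fit(table, 3)
        b = famd_fit(doubled, 3)
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-8)

    def test_cos2_bounded(self):
        rng = np.random.default_rng(8)
        res = famd_fit(random_mixed_table(rng), n_components=7)
        cos2 = res.variable_cos2.to_numpy()
        assert ((cos2 >= -1e-12) & (cos2 <= 1 + 1e-12)).all()
        assert (res.variable_cos2.sum(axis=1) <= 1 + 1e-8).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        table = random_mixed_table(rng)
        a = famd_fit(table, 3)
        b = famd_fit(table, 3)
        pd.testing.assert_frame_equal(a.row_coordinates, b.row_coordinates)
        for j in range(a.n_components):
            col = a.column_coordinates.iloc[:, j]
            assert col.iloc[int(np.argmax(np.abs(col.to_numpy())))] > 0

    def test_rank_deficiency_returns_fewer_components(self, caplog):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(20, 1))
        quant = pd.DataFrame(
            np.hstack([base, 2 * base, -base]), columns=list("abc")
        )
        table = MixedTable(quant, pd.DataFrame(index=quant.index))
        with caplog.at_level("WARNING", logger="cdexposure"):
            res = famd_fit(table, n_components=3)
        assert res.n_components == 1
        assert any("rank" in r.message for r in caplog.records)


class TestTopContributors:
    def test_dominant_variable_ranks_first_and_is_flagged(self):
        rng = np.random.default_rng(11)
        n = 50
        strong = rng.normal(size=n)
        quant = pd.DataFrame(
            {
                "strong_a": strong,
                "strong_b": strong + rng.normal(scale=0.01, size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
                "noise3": rng.normal(size=n),
            }
        )
        res = famd_fit(MixedTable(quant, pd.DataFrame(index=quant.index)), 2)
        ranked = top_contributors(res, 1)
        assert ranked.loc[0, "variable"].startswith("strong")
        assert bool(ranked.loc[0, "above_threshold"])

    def test_flags_consistent_with_threshold(self):
        rng = np.random.default_rng(12)
        res = famd_fit(random_mixed_table(rng), 3)
        ranked = top_contributors(res, 2)
        for rec in ranked.itertuples(index=False):
            assert rec.above_threshold == (
                rec.contribution_pct > res.expected_contribution_threshold_pct
            )

    def test_dimension_out_of_range(self):
        rng = np.random.default_rng(13)
        res = famd_fit(random_mixed_table(rng), 2)
        with pytest.raises(ValidationError):
            top_contributors(res, 3)

    def test_output_frames_shape(self):
        rng = np.random.default_rng(14)
        res = famd_fit(random_mixed_table(rng), 3)
        eig = eigen_frame(res)
        assert list(eig.columns) == ["dimension", "eigenvalue", "explained_pct", "cumulative_pct"]
        contrib = contrib_frame(res)
        assert len(contrib) == 3 * len(res.variable_contributions_pct)
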