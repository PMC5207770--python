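"""beta/M transforms, probe and genotype QC, HWE exact test against a
brute-force enumeration oracle, and constrained cell-type deconvolution."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methadmix.data import (
    CellReference,
    GenotypeMatrix,
    MethylationMatrix,
    beta_to_m,
    estimate_cell_proportions,
    filter_probes,
    hwe_exact_p,
    m_to_beta,
    qc_genotypes,
)


class TestBetaM:
    @pytest.mark.parametrize(
        "beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0), (4 / 5, 2.0)]
    )
    def test_known_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, rel=1e-9)

    @given(
        st.lists(
            st.floats(min_value=1e-4, max_value=1 - 1e-4),
            min_size=2,
            max_size=20,
            unique_by=lambda x: round(x, 6),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, betas):
        b = np.unique(np.round(betas, 6))
        assert np.all(np.diff(beta_to_m(b)) > 0)

    def test_m_maps_reals_into_open_unit_interval(self):
        # |m| up to ~50 — the float64-representable range of the inverse
        m = np.array([-50.0, -10.0, 0.0, 10.0, 50.0])
        b = m_to_beta(m)
        assert np.all((b > 0) & (b < 1))

    def test_boundary_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = beta_to_m(np.array([0.0, 0.5, 1.0]))
        assert np.isfinite(out).all()


def _meth(values, det=None):
    values = pd.DataFrame(values)
    values.columns = [f"cg{j}" for j in values.columns]
    det = None if det is None else pd.DataFrame(np.asarray(det), index=values.index, columns=values.columns)
    return MethylationMatrix(values.clip(0.01, 0.99), scale="beta", detection_p=det)


class TestFilterProbes:
    def test_all_pass_unchanged(self, rng):
        m = _meth(rng.uniform(0.2, 0.8, (4, 6)), np.zeros((4, 6)))
        out = filter_probes(m)
        assert list(out.probes) == list(m.probes)

    def test_single_fully_failed_probe_removed(self, rng):
        det = np.zeros((4, 6))
        det[:, 2] = 0.9
        out = filter_probes(_meth(rng.uniform(0.2, 0.8, (4, 6)), det))
        assert "cg2" not in out.probes and len(out.probes) == 5

    def test_enumerated_toy_matrix_matches_brute_force(self, rng):
        det = np.array(
            [
                [0.0, 0.02, 0.0, 0.5],
                [0.0, 0.0, 0.0, 0.5],
                [0.005, 0.0, 0.02, 0.0],
                [0.0, 0.0, 0.02, 0.0],
                [0.0, 0.011, 0.0, 0.0],
            ]
        ).T  # 4 samples x 5 probes
        p_cut, frac = 0.01, 0.3
        expected = [
            j for j in range(5) if (det[:, j] > p_cut).mean() <= frac
        ]
        out = filter_probes(_meth(rng.uniform(0.2, 0.8, (4, 5)), det), p_cut, frac)
        assert list(out.probes) == [f"cg{j}" for j in expected]

    def test_idempotent(self, rng):
        det = rng.uniform(0, 0.02, (6, 10))
        m = _meth(rng.uniform(0.2, 0.8, (6, 10)), det)
        once = filter_probes(m, 0.01, 0.5)
        twice = filter_probes(once, 0.01, 0.5)
        assert 0 < len(once.probes) < 10
        assert list(once.probes) == list(twice.probes)

    def test_all_removed_raises(self, rng):
        with pytest.raises(ValueError, match="all probes removed"):
            filter_probes(_meth(rng.uniform(0.2, 0.8, (3, 4)), np.full((3, 4), 0.9)))


def _hwe_brute_force(n_aa, n_ab, n_bb):
    """Independent oracle: exact conditional probabilities via Fractions."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    rare = min(na, 2 * n - na)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        probs[h] = Fraction(2**h * math.factorial(n), math.factorial(h) * math.factorial(hr) * math.factorial(hc))
    total = sum(probs.values())
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs) / total)


class TestHWE:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (10, 5, 10), (0, 20, 0), (7, 13, 29), (1, 0, 40), (3, 3, 3)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(_hwe_brute_force(*counts), rel=1e-9)

    def test_equilibrium_counts_keep_p_high(self):
        assert hwe_exact_p(25, 50, 25) > 0.9

    def test_monomorphic_returns_one(self):
        assert hwe_exact_p(30, 0, 0) == 1.0


def _geno(dosages, positions=None):
    dos = pd.DataFrame(np.asarray(dosages, dtype=float))
    dos.columns = [f"snp{j}" for j in dos.columns]
    dos.index = [f"S{i}" for i in range(len(dos))]
    pos = pd.Series(
        positions if positions is not None else np.arange(1, dos.shape[1] + 1) * 100,
        index=dos.columns,
    )
    return GenotypeMatrix(dos, pos)


class TestGenotypeQC:
    def test_missingness_filter(self, rng):
        dos = rng.integers(0, 3, (50, 3)).astype(float)
        dos[:3, 0] = np.nan  # 6% missing
        geno = _geno(dos)
        groups = pd.Series(["g1"] * 50, index=geno.samples)
        kept, log = qc_genotypes(geno, groups, miss_cut=0.05, hwe_cut=0.0)
        assert "snp0" not in kept.snps
        assert (log["reason"] == "missingness").sum() == 1

    def test_hwe_violation_removed_within_group(self, rng):
        # one group in perfect HWE, the other all-heterozygote (gross excess)
        hw = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        bad = np.ones(100)
        dos = np.column_stack([np.concatenate([hw, hw]), np.concatenate([hw, bad])])
        geno = _geno(dos)
        groups = pd.Series(["a"] * 100 + ["b"] * 100, index=geno.samples)
        kept, log = qc_genotypes(geno, groups, hwe_cut=1e-6)
        assert "snp0" in kept.snps and "snp1" not in kept.snps
        assert log.iloc[0]["reason"] == "hwe:b"

    def test_small_group_skipped_with_warning(self, rng):
        dos = rng.integers(0, 3, (10, 2)).astype(float)
        geno = _geno(dos)
        groups = pd.Series(["big"] * 7 + ["tiny"] * 3, index=geno.samples)
        with pytest.warns(UserWarning, match="tiny"):
            qc_genotypes(geno, groups)

    def test_qc_idempotent(self, rng):
        dos = rng.integers(0, 3, (60, 8)).astype(float)
        dos[:5, 1] = np.nan
        geno = _geno(dos)
        groups = pd.Series(["g"] * 60, index=geno.samples)
        once, _ = qc_genotypes(geno, groups)
        twice, log2 = qc_genotypes(once, groups)
        assert list(once.snps) == list(twice.snps) and len(log2) == 0


class TestDeconvolution:
    def _ref(self, rng, cells=3, probes=200):
        W = rng.normal(0, 2, (cells, probes))
        return CellReference(
            pd.DataFrame(W, index=[f"c{k}" for k in range(cells)], columns=[f"p{j}" for j in range(probes)])
        )

    def _as_meth(self, X, ref):
        return MethylationMatrix(
            pd.DataFrame(np.atleast_2d(X), columns=ref.profiles.columns), scale="m"
        )

    def test_pure_profile_returns_indicator(self, rng):
        ref = self._ref(rng)
        props, resid = estimate_cell_proportions(self._as_meth(ref.profiles.iloc[1].to_numpy(), ref), ref)
        np.testing.assert_allclose(props.iloc[0].to_numpy(), [0, 1, 0], atol=1e-9)
        assert resid.iloc[0] == pytest.approx(0, abs=1e-9)

    def test_even_mixture_exact(self, rng):
        ref = self._ref(rng)
        x = 0.5 * ref.profiles.iloc[0] + 0.5 * ref.profiles.iloc[2]
        props, _ = estimate_cell_proportions(self._as_meth(x.to_numpy(), ref), ref)
        np.testing.assert_allclose(props.iloc[0].to_numpy(), [0.5, 0, 0.5], atol=1e-9)

    def test_noisy_mixture_recovery(self, rng):
        ref = self._ref(rng)
        P = rng.dirichlet(np.ones(3) * 4, size=40)
        X = P @ ref.profiles.to_numpy() + rng.normal(0, 0.05, (40, 200))
        props, _ = estimate_cell_proportions(self._as_meth(X, ref), ref)
        assert np.abs(props.to_numpy() - P).mean() < 0.02

    def test_invariant_to_probe_reordering(self, rng):
        ref = self._ref(rng, probes=50)
        x = 0.3 * ref.profiles.iloc[0] + 0.6 * ref.profiles.iloc[1]
        meth = self._as_meth(x.to_numpy(), ref)
        perm = rng.permutation(50)
        meth2 = MethylationMatrix(meth.values.iloc[:, perm], scale="m")
        p1, _ = estimate_cell_proportions(meth, ref)
        p2, _ = estimate_cell_proportions(meth2, ref)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-9)

    def test_rank_deficient_reference_names_collinear_types(self, rng):
        W = rng.normal(0, 2, (3, 100))
        W[2] = W[0]
        ref = CellReference(
            pd.DataFrame(W, index=["gran", "lymph", "gran_copy"], columns=[f"p{j}" for j in range(100)])
        )
        with pytest.raises(ValueError, match="gran"):
            estimate_cell_proportions(self._as_meth(W[0], ref), ref)


class TestIO:
    def test_beta_tsv_round_trip(self, small_study, tmp_path):
        from methadmix import io as mio

        mio.write_beta_tsv(small_study.meth, tmp_path / "b.tsv", tmp_path / "d.tsv")
        back = mio.read_beta_tsv(tmp_path / "b.tsv", detection_path=tmp_path / "d.tsv")
        np.testing.assert_allclose(
            back.values.to_numpy(), small_study.meth.values.to_numpy(), rtol=1e-4
        )
        assert list(back.probes) == list(small_study.meth.probes)

    def test_vcf_round_trip_through_pysam(self, small_study, tmp_path):
        from methadmix import io as mio

        path = tmp_path / "g.vcf"
        mio.write_vcf(small_study.genotypes, path)
        back = mio.read_vcf(path)
        pd.testing.assert_frame_equal(back.dosages, small_study.genotypes.dosages)
        np.testing.assert_array_equal(
            back.positions_bp.to_numpy(), small_study.genotypes.positions_bp.to_numpy()
        )

    def test_dosage_tsv_round_trip(self, small_study, tmp_path):
        from methadmix import io as mio

        mio.write_dosage_tsv(small_study.genotypes, tmp_path / "d.tsv")
        back = mio.read_dosage_tsv(tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(back.dosages, small_study.genotypes.dosages)

    def test_tracts_bed_round_trip_preserves_dosage(self, small_study, tmp_path):
        from methadmix import io as mio
        from methadmix.ancestry import global_from_local

        path = tmp_path / "t.bed"
        mio.write_tracts_bed(small_study.local, path)
        back = mio.read_tracts_bed(path, small_study.local.labels)
        np.testing.assert_allclose(
            global_from_local(back).to_numpy(),
            global_from_local(small_study.local).to_numpy(),
            atol=1e-6,
        )

    def test_sample_sheet_round_trip(self, small_study, tmp_path):
        from methadmix import io as mio

        mio.write_sample_sheet(small_study.samples, tmp_path / "s.csv")
        back = mio.read_sample_sheet(tmp_path / "s.csv")
        pd.testing.assert_frame_equal(back, small_study.samples)
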