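import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sgnb.nb_inference import (
    NormalizationResult,
    cml_loglik,
    estimate_theta_em,
    fit_dispersion,
    quantile_adjust,
    tmm_normalize,
)
from sgnb.read_typing import CountTable, DesignInfo
from sgnb.simulate import simulate_counts_model


def make_table(counts, lib_sizes=None):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    idx = pd.MultiIndex.from_tuples([("g", str(i)) for i in range(counts.shape[0])],
                                    names=["gene_id", "read_type"])
    df = pd.DataFrame(counts, index=idx, columns=samples)
    lib = pd.Series(dict(zip(samples, lib_sizes if lib_sizes is not None
                             else counts.sum(axis=0).astype(float))))
    return CountTable(df, lib)


def flat_norm(lib_sizes, samples=None):
    """Normalization with unit factors, for unit tests of the estimators."""
    lib = np.asarray(lib_sizes, dtype=float)
    samples = samples or [f"s{i}" for i in range(lib.size)]
    return NormalizationResult(list(samples), samples[0], np.ones(lib.size), lib, lib)


def design_for(j0, j1):
    return DesignInfo({f"s{i}": (0 if i < j0 else 1) for i in range(j0 + j1)})


class TestTMM:
    def test_identical_samples_unit_factors(self, rng):
        col = rng.poisson(40, 300)
        table = make_table(np.column_stack([col, col]))
        norm = tmm_normalize(table)
        assert np.allclose(norm.factors, 1.0)

    def test_doubled_sample_equalized(self, rng):
        a = rng.poisson(40, 300) + 1
        table = make_table(np.column_stack([a, 2 * a]))
        norm = tmm_normalize(table)
        # effective sizes compensate the doubling: expression a/N*_0 == 2a/N*_1
        ratio = norm.effective_sizes[1] / norm.effective_sizes[0]
        assert abs(ratio - 2.0) < 1e-6

    def test_matches_independent_reimplementation(self, rng):
        counts = rng.negative_binomial(2, 0.05, size=(400, 5))
        counts = counts[counts.sum(axis=1) > 0]
        lib = counts.sum(axis=0) * rng.uniform(1.5, 3.0, 5)
        table = make_table(counts, lib)
        norm = tmm_normalize(table)
        oracle = _tmm_oracle(counts.astype(float), lib.astype(float))
        assert np.allclose(norm.factors, oracle, rtol=1e-10)

    def test_matches_edger(self, rng, tmp_path):
        import subprocess

        counts = rng.negative_binomial(2, 0.05, size=(400, 5))
        counts = counts[counts.sum(axis=1) > 0]
        lib = counts.sum(axis=0) * rng.uniform(1.5, 3.0, 5)
        np.savetxt(tmp_path / "c.tsv", counts, fmt="%d", delimiter="\t")
        np.savetxt(tmp_path / "l.tsv", lib, delimiter="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'cnt <- as.matrix(read.delim("{tmp_path}/c.tsv", header=FALSE));'
            f'lib <- scan("{tmp_path}/l.tsv", quiet=TRUE);'
            'cat(calcNormFactors(cnt, lib.size=lib, method="TMM"), sep=",")'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        edger = np.array([float(v) for v in res.stdout.split(",")])
        norm = tmm_normalize(make_table(counts, lib))
        # rank ties at the trim boundary may resolve differently in R
        assert np.allclose(norm.factors, edger, rtol=2e-3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            tmm_normalize(make_table(np.array([[3], [4]])))


def _tmm_oracle(counts, lib, logratio_trim=0.3, sum_trim=0.05):
    """Straightforward reimplementation of the weighted trimmed mean of M values."""
    f75 = np.quantile(counts / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        obs, r = counts[:, j], counts[:, ref]
        keep = (obs > 0) & (r > 0)
        obs, r = obs[keep], r[keep]
        m = np.log2((obs / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((obs / lib[j]) * (r / lib[ref]))
        w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref] - r) / (lib[ref] * r)
        n = len(m)
        keep_idx = np.ones(n, bool)
        for v, trim in ((m, logratio_trim), (a, sum_trim)):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(n)
            ranks[order] = np.arange(1, n + 1)
            # average ranks for ties, as midranks
            ser = pd.Series(v).rank()
            keep_idx &= (ser.to_numpy() >= np.floor(n * trim) + 1) & (
                ser.to_numpy() <= n - np.floor(n * trim))
        factors.append(2 ** (np.sum(m[keep_idx] / w[keep_idx]) / np.sum(1 / w[keep_idx])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestCmlLoglik:
    def test_single_sample_is_zero(self):
        for x, phi in [(0, 0.5), (7, 0.01), (123, 3.0)]:
            assert cml_loglik([x], phi) == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariant(self, rng):
        x = rng.integers(0, 50, 6)
        assert cml_loglik(x, 0.3) == pytest.approx(cml_loglik(x[::-1], 0.3))

    def test_matches_arbitrary_precision_evaluation(self, rng):
        import mpmath

        mpmath.mp.dps = 50

        def oracle(x, phi):
            r = mpmath.mpf(1) / mpmath.mpf(phi)
            j = len(x)
            z = sum(x)
            val = sum(mpmath.loggamma(xi + r) for xi in x)
            val += mpmath.loggamma(j * r) - mpmath.loggamma(z + j * r) - j * mpmath.loggamma(r)
            return float(val)

        assert cml_loglik([3, 5], 0.5) == pytest.approx(oracle([3, 5], 0.5), rel=1e-12)
        for _ in range(20):
            x = rng.integers(0, 200, rng.integers(2, 8)).tolist()
            phi = float(rng.uniform(0.001, 5.0))
            assert cml_loglik(x, phi) == pytest.approx(oracle(x, phi), rel=1e-10, abs=1e-10)

    def test_phi_zero_continuity(self):
        x = [3, 9, 4]
        lim = cml_loglik(x, 0.0)
        assert cml_loglik(x, 1e-9) == pytest.approx(lim, rel=1e-4)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cml_loglik([-1, 2], 0.5)


class TestQuantileAdjust:
    def test_identity_for_equal_sizes(self, rng):
        x = rng.integers(0, 80, 10).astype(float)
        out = quantile_adjust(x, np.full(10, 5e4), 5e4, theta=1e-3, phi=0.2)
        assert np.array_equal(out, x)

    def test_zero_maps_to_zero(self):
        out = quantile_adjust([0.0], [1e5], 2e4, theta=1e-3, phi=0.4)
        assert out[0] == 0.0

    def test_theta_zero_with_positive_count_rejected(self):
        with pytest.raises(ValueError):
            quantile_adjust([3.0], [1e4], 1e4, theta=0.0, phi=0.1)

    def test_monotone_in_count(self):
        x = np.arange(0, 60, dtype=float)
        out = quantile_adjust(x, np.full(60, 3e4), 1e4, theta=1e-3, phi=0.3)
        d = np.diff(out)
        assert np.all(d >= 0)
        assert np.all(d[out[1:] > 1e-12] > 0)  # strict once above the clamp at zero

    def test_matches_cdf_summation_oracle(self):
        # independent route: accumulate pmf terms directly and invert by scan
        x, nj, nstar, theta, phi = 10.0, 2.0e4, 1.0e4, 0.001, 0.1

        def pmf(k, mean):
            r = 1 / phi
            return math.exp(
                math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
                + r * math.log(r / (r + mean)) + k * math.log(mean / (r + mean))
            )

        u = sum(pmf(k, nj * theta) for k in range(int(x))) + 0.5 * pmf(x, nj * theta)
        acc, k = 0.0, 0
        grid = []
        while True:
            p = pmf(k, nstar * theta)
            grid.append(acc + 0.5 * p)
            acc += p
            if grid[-1] > u and len(grid) > 2:
                break
            k += 1
        idx = max(i for i, g in enumerate(grid) if g <= u)
        expected = idx + (u - grid[idx]) / (grid[idx + 1] - grid[idx])
        got = quantile_adjust([x], [nj], nstar, theta, phi)[0]
        assert got == pytest.approx(expected, rel=1e-8)


class TestThetaEM:
    def test_equal_offsets_closed_form(self):
        x = np.array([4.0, 9.0, 2.0, 5.0])
        n = np.full(4, 1e4)
        assert estimate_theta_em(x, n, 0.4) == pytest.approx(x.mean() / 1e4, rel=1e-7)

    def test_all_zero_counts(self):
        assert estimate_theta_em([0, 0, 0], [1e4, 2e4, 3e4], 0.3) == 0.0

    def test_phi_zero_pooled_ratio(self):
        assert estimate_theta_em([2, 9], [1e3, 3e3], 0.0) == pytest.approx(11 / 4e3)

    def test_matches_grid_search_mle(self):
        x = np.array([2.0, 9.0])
        n = np.array([1000.0, 3000.0])
        phi = 0.2

        def nb_loglik(theta):
            r = 1 / phi
            mu = n * theta
            return float(np.sum(stats.nbinom.logpmf(x, r, r / (r + mu))))

        coarse = np.linspace(1e-5, 2e-2, 1001)
        best = coarse[np.argmax([nb_loglik(t) for t in coarse])]
        fine = np.linspace(best - 5e-4, best + 5e-4, 200001)
        theta_star = fine[np.argmax([nb_loglik(t) for t in fine])]
        got = estimate_theta_em(x, n, phi)
        assert got == pytest.approx(theta_star, rel=1e-5)

    def test_em_ascends_marginal_likelihood(self, rng):
        x = rng.negative_binomial(5, 0.3, 8).astype(float)
        n = rng.uniform(5e3, 2e4, 8)
        phi = 0.25
        _, state = estimate_theta_em(x, n, phi, return_state=True)

        def nb_loglik(theta):
            if theta == 0:
                return -np.inf
            r = 1 / phi
            mu = n * theta
            return float(np.sum(stats.nbinom.logpmf(x, r, r / (r + mu))))

        lls = [nb_loglik(t) for t in state.theta_trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


class TestFitDispersion:
    def test_equal_lib_sizes_pseudo_equals_raw(self, rng):
        x = rng.negative_binomial(5, 0.3, 10).astype(float)
        x[0] += 1  # ensure nonzero
        norm = flat_norm(np.full(10, 1e4))
        fit = fit_dispersion(x, design_for(5, 5), norm)
        assert np.allclose(fit.pseudo, x)
        assert fit.z0 == int(np.floor(x[:5].sum() + 0.5))

    def test_all_zero_group_skipped(self):
        norm = flat_norm(np.full(6, 1e4))
        assert fit_dispersion(np.zeros(6), design_for(3, 3), norm) is None

    def test_recovers_dispersion_from_nb_data(self):
        # NB(theta=5e-4, phi=0.2), J=50 per condition, 50 replicates
        rng = np.random.default_rng(2024)
        lib = rng.uniform(1.5e4, 2.5e4, 100)
        norm = flat_norm(lib)
        design = design_for(50, 50)
        phis = []
        for _ in range(50):
            x = simulate_counts_model([5e-4], 0.2, lib, rng)[0].astype(float)
            fit = fit_dispersion(x, design, norm)
            phis.append(fit.phi)
        assert abs(np.median(phis) - 0.2) / 0.2 < 0.25

    def test_poisson_data_hits_lower_boundary(self):
        rng = np.random.default_rng(7)
        lib = np.full(100, 1e5)  # mean count 50: dispersion sd well below 0.01
        norm = flat_norm(lib)
        design = design_for(50, 50)
        small = [fit_dispersion(rng.poisson(5e-4 * lib).astype(float), design, norm).phi < 0.01
                 for _ in range(50)]
        assert np.mean(small) >= 0.9

    def test_rmse_shrinks_with_sample_size(self):
        rng = np.random.default_rng(11)
        theta, phi = 5e-4, 0.2
        rmses_phi, rmses_theta = [], []
        for j in (10, 30, 100):
            lib = rng.uniform(1.5e4, 2.5e4, 2 * j)
            norm = flat_norm(lib)
            design = design_for(j, j)
            est = []
            for _ in range(40):
                x = simulate_counts_model([theta], phi, lib, rng)[0].astype(float)
                fit = fit_dispersion(x, design, norm)
                est.append((fit.phi, fit.theta_pooled))
            est = np.array(est)
            rmses_phi.append(np.sqrt(np.mean((est[:, 0] - phi) ** 2)))
            rmses_theta.append(np.sqrt(np.mean((est[:, 1] - theta) ** 2)))
        assert rmses_phi[0] > rmses_phi[2]
        assert rmses_theta[0] > rmses_theta[2]
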