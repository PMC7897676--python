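"""IR preprocessing, QMF scoring, library ranking, co-addition and LOI."""

import numpy as np
import pytest

from isoformid.errors import DomainError
from isoformid.ir import (DepositionSimConfig, IRLibrary, IRSpectrum, coadd,
                          default_grid, limit_of_identification,
                          median_qmf_ladder, preprocess, qmf, rank_library,
                          NOT_REACHED)
from isoformid.simulate import IRSimConfig, simulate_ir_library

GRID = default_grid()


def _bands(centers, widths, amps, grid=GRID):
    out = np.zeros_like(grid)
    for c, w, a in zip(centers, widths, amps):
        out += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return out


@pytest.fixture(scope="module")
def benchmark():
    """Fixed-seed isomer-family library with noisy queries."""
    return simulate_ir_library(IRSimConfig(seed=0))


@pytest.fixture(scope="module")
def spectrum():
    return IRSpectrum(GRID, _bands([800, 1200, 1700, 2900],
                                   [5, 8, 10, 20], [1.0, 0.6, 0.4, 0.8]),
                      name="probe")


class TestPreprocess:
    def test_on_grid_spectrum_only_normalized(self, spectrum):
        out = preprocess(spectrum, GRID)
        assert np.allclose(out.wavenumbers, GRID)
        assert out.absorbance.min() == 0.0
        assert out.absorbance.max() == 1.0

    def test_constant_spectrum_flags_degenerate(self):
        flat = IRSpectrum(GRID, np.full(len(GRID), 0.7), name="flat")
        out = preprocess(flat, GRID)
        assert out.degenerate
        assert np.all(out.absorbance == 0.0)

    def test_finer_input_decimated_onto_target_grid(self, spectrum):
        fine_grid = np.arange(650.0, 4000.1, 2.0)
        fine = IRSpectrum(fine_grid, np.interp(fine_grid, GRID,
                                               spectrum.absorbance))
        out = preprocess(fine, GRID)
        assert len(out) == len(GRID)

    def test_insufficient_overlap_rejected(self, spectrum):
        narrow = IRSpectrum(GRID[:300], spectrum.absorbance[:300])
        with pytest.raises(DomainError):
            preprocess(narrow, GRID)


class TestQmf:
    def test_self_match_is_100(self, spectrum):
        s = preprocess(spectrum, GRID)
        assert qmf(s, s) == pytest.approx(100.0, abs=1e-9)

    def test_negation_clamped_to_zero(self, spectrum):
        s = preprocess(spectrum, GRID)
        neg = IRSpectrum(GRID, -s.absorbance)
        assert qmf(neg, s) == 0.0

    def test_symmetry(self, benchmark):
        library, queries = benchmark
        a = preprocess(library["fam1-iso1"], GRID)
        b = preprocess(library["fam1-iso2"], GRID)
        assert qmf(a, b) == pytest.approx(qmf(b, a), abs=1e-12)

    def test_affine_rescaling_invariance(self, spectrum):
        s = preprocess(spectrum, GRID)
        scaled = IRSpectrum(GRID, 3.7 * spectrum.absorbance + 0.25)
        assert qmf(preprocess(scaled, GRID), s) == pytest.approx(
            100.0, abs=1e-9)

    def test_zero_variance_gives_zero(self, spectrum):
        s = preprocess(spectrum, GRID)
        flat = preprocess(IRSpectrum(GRID, np.ones(len(GRID))), GRID)
        assert qmf(flat, s) == 0.0

    def test_grid_mismatch_rejected(self, spectrum):
        with pytest.raises(DomainError):
            qmf(spectrum, IRSpectrum(GRID[:-1], spectrum.absorbance[:-1]))


class TestRankLibrary:
    def test_self_query_is_hit_one_at_100(self, benchmark):
        library, _ = benchmark
        hits = rank_library(library["decoy01"], library)
        assert hits[0].name == "decoy01"
        assert hits[0].qmf == pytest.approx(100.0, abs=1e-9)

    def test_hitlist_sorted_with_contiguous_ranks(self, benchmark):
        library, queries = benchmark
        hits = rank_library(queries[0][0], library)
        assert [h.rank for h in hits] == list(range(1, len(library) + 1))
        qmfs = [h.qmf for h in hits]
        assert qmfs == sorted(qmfs, reverse=True)

    def test_noisy_isomer_queries_rank_true_compound_first(self, benchmark):
        """Positional-isomer discrimination: the true isomer ranks #1 and
        the best wrong family member trails by a wide margin."""
        library, queries = benchmark
        for query, true_name in queries:
            hits = rank_library(query, library)
            assert hits[0].name == true_name
            family = true_name.split("-")[0]
            best_wrong = max(h.qmf for h in hits
                             if h.name.startswith(family)
                             and h.name != true_name)
            assert hits[0].qmf - best_wrong > 30.0

    def test_degenerate_query_scores_zero_alphabetical(self, benchmark):
        library, _ = benchmark
        flat = IRSpectrum(GRID, np.zeros(len(GRID)), name="flat")
        hits = rank_library(flat, library)
        assert all(h.qmf == 0.0 for h in hits)
        assert [h.name for h in hits] == library.names


class TestCoadd:
    def test_single_deposition_is_identity(self, spectrum):
        out = coadd([spectrum])
        assert np.array_equal(out.absorbance, spectrum.absorbance)
        assert out.n_depositions == 1

    def test_pure_signal_scales_n_fold(self, spectrum):
        out = coadd([spectrum] * 5)
        assert np.allclose(out.absorbance, 5 * spectrum.absorbance)
        assert out.n_depositions == 5

    def test_grid_mismatch_rejected(self, spectrum):
        other = IRSpectrum(GRID + 2.0, spectrum.absorbance)
        with pytest.raises(DomainError):
            coadd([spectrum, other])

    def test_median_qmf_non_decreasing_in_depositions(self, spectrum):
        """Co-adding noisy deposits of a weak analyte monotonically
        improves the median match against the clean reference."""
        ref = preprocess(spectrum, GRID)
        medians = []
        for n in (1, 2, 4, 8):
            scores = []
            for rep in range(100):
                rng = np.random.default_rng([7, n, rep])
                deposits = [
                    IRSpectrum(GRID, 0.02 * spectrum.absorbance
                               + rng.normal(0, 0.02, len(GRID)))
                    for _ in range(n)]
                scores.append(qmf(preprocess(coadd(deposits), GRID), ref))
            medians.append(np.median(scores))
        assert all(b >= a for a, b in zip(medians, medians[1:]))


class TestNoiseMonotonicity:
    def test_increasing_noise_never_helps(self, spectrum):
        ref = preprocess(spectrum, GRID)
        medians = []
        for sigma in (0.0, 0.02, 0.05, 0.1, 0.3):
            scores = []
            for rep in range(30):
                rng = np.random.default_rng([11, int(sigma * 1000), rep])
                noisy = IRSpectrum(GRID, spectrum.absorbance
                                   + rng.normal(0, sigma, len(GRID)))
                scores.append(qmf(preprocess(noisy, GRID), ref))
            medians.append(np.median(scores))
        assert all(b <= a + 1e-9 for a, b in zip(medians, medians[1:]))


class TestLimitOfIdentification:
    def test_noiseless_query_identified_at_first_deposition(self, spectrum):
        config = DepositionSimConfig(reference=spectrum, noise_sigma=0.0,
                                     baseline_drift=0.0, n_replicates=3,
                                     max_depositions=3, seed=0)
        assert limit_of_identification(config, 99.0) == 1

    def test_threshold_100_with_noise_not_reached(self, spectrum):
        config = DepositionSimConfig(reference=spectrum, noise_sigma=0.05,
                                     n_replicates=5, max_depositions=4,
                                     seed=0)
        assert limit_of_identification(config, 100.0) == NOT_REACHED

    def test_deposition_ladder_reproduces_weak_analyte_trajectory(self):
        """A weak deposit starts unsearchable (QMF < 20) and becomes
        identifiable within a handful of consecutive depositions."""
        library, _ = simulate_ir_library(IRSimConfig(seed=0))
        config = DepositionSimConfig(reference=library["fam1-iso1"], seed=3)
        ladder = median_qmf_ladder(config)
        assert ladder[0] < 20.0
        assert all(b >= a - 2.0 for a, b in zip(ladder, ladder[1:]))
        loi80 = limit_of_identification(config, 80.0)
        loi90 = limit_of_identification(config, 90.0)
        assert loi80 != NOT_REACHED and loi80 <= 9
        assert loi90 != NOT_REACHED and loi80 <= loi90 <= 12

    def test_bad_threshold_rejected(self, spectrum):
        config = DepositionSimConfig(reference=spectrum)
        with pytest.raises(DomainError):
            limit_of_identification(config, 0.0)


class TestLibraryContainer:
    def test_duplicate_names_rejected(self, spectrum):
        library = IRLibrary()
        library.add(IRSpectrum(GRID, spectrum.absorbance, name="x"))
        with pytest.raises(DomainError):
            library.add(IRSpectrum(GRID, spectrum.absorbance, name="x"))

    def test_empty_library_cannot_be_searched(self, spectrum):
        with pytest.raises(DomainError):
            rank_library(spectrum, IRLibrary())
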