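"""Fragment matching, MP/AMP and dot-product scoring, and candidate ranking."""

import itertools
import math

import numpy as np
import pytest

from aglycon import (
    CompoundEntry,
    FragmentPeak,
    SpectralLibrary,
    Spectrum,
    amp,
    dot_product,
    match_fragments,
    match_probability,
    search,
)
from aglycon.search import head_to_tail_table


def spectrum(mzs, intensities=None, precursor=500.0, source_id="s"):
    if intensities is None:
        intensities = [100.0] * len(mzs)
    return Spectrum(
        precursor_mz=precursor,
        peaks=tuple(FragmentPeak(m, i) for m, i in zip(mzs, intensities)),
        source_id=source_id,
    )


def random_spectrum(rng, n=None, precursor=None, spacing=1.0):
    n = n or int(rng.integers(2, 10))
    precursor = precursor or float(rng.uniform(300, 900))
    mzs = np.sort(rng.choice(np.arange(80, precursor, spacing), size=n, replace=False))
    ints = rng.uniform(1, 100, size=n)
    return spectrum(mzs.tolist(), ints.tolist(), precursor=precursor)


def brute_force_assignment(sample, reference, tol):
    """Exhaustive max-cardinality, minimum-total-|error| one-to-one assignment."""
    pairs = [
        (i, j, abs(sp.mz - rp.mz))
        for i, sp in enumerate(sample.peaks)
        for j, rp in enumerate(reference.peaks)
        if abs(sp.mz - rp.mz) <= tol
    ]
    best = (0, 0.0, frozenset())
    n = len(pairs)
    for r in range(len(pairs), -1, -1):
        for combo in itertools.combinations(pairs, r):
            if len({i for i, _, _ in combo}) < len(combo):
                continue
            if len({j for _, j, _ in combo}) < len(combo):
                continue
            total = sum(err for _, _, err in combo)
            cardinality = len(combo)
            if (cardinality, -total) > (best[0], -best[1]):
                best = (cardinality, total, frozenset((i, j) for i, j, _ in combo))
        if best[0] == r:  # cannot do better with fewer pairs
            break
    return best


class TestMatchFragments:
    def test_identical_spectra_match_fully(self):
        s = spectrum([100.0, 150.0, 200.0, 250.0, 300.0])
        matches = match_fragments(s, s)
        assert len(matches) == 5
        assert all(m.mz_error == 0.0 for m in matches)

    def test_disjoint_spectra_no_match(self):
        a = spectrum([100.0, 150.0])
        b = spectrum([100.5, 151.0])
        assert match_fragments(a, b, tol=0.01) == []

    def test_smallest_error_wins_one_to_two(self):
        # sample 100.005 against references 100.000 (err 0.005) and
        # 100.009 (err 0.004): the smaller-error partner is chosen
        sample = spectrum([100.005])
        reference = spectrum([100.000, 100.009])
        matches = match_fragments(sample, reference, tol=0.01)
        assert len(matches) == 1
        assert matches[0].reference_mz == pytest.approx(100.009)

    def test_one_to_one_no_double_use(self):
        sample = spectrum([100.000, 100.004])
        reference = spectrum([100.002])
        matches = match_fragments(sample, reference, tol=0.01)
        assert len(matches) == 1

    def test_greedy_agrees_with_exhaustive_assignment(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n_s, n_r = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            sample = spectrum(
                np.sort(rng.uniform(100, 110, size=n_s)).tolist(),
                rng.uniform(1, 100, size=n_s).tolist(),
            )
            reference = spectrum(
                np.sort(rng.uniform(100, 110, size=n_r)).tolist(),
                rng.uniform(1, 100, size=n_r).tolist(),
            )
            greedy = match_fragments(sample, reference, tol=0.01)
            cardinality, total, _ = brute_force_assignment(sample, reference, 0.01)
            assert len(greedy) == cardinality
            assert sum(abs(m.mz_error) for m in greedy) == pytest.approx(total, abs=1e-9)


class TestMatchProbability:
    def test_self_match_is_100(self):
        s = spectrum([100.0, 150.0, 200.0], [10.0, 50.0, 100.0])
        assert match_probability(s, s) == pytest.approx(100.0)

    def test_no_match_is_zero(self):
        assert match_probability(spectrum([100.0]), spectrum([200.0])) == 0.0

    def test_missing_one_of_four_equal_peaks(self):
        # MP = 100 * (2*3/7) * sqrt(1 * 3/4) = 74.23
        reference = spectrum([100.0, 150.0, 200.0, 250.0], [50.0] * 4)
        sample = spectrum([100.0, 150.0, 200.0], [50.0] * 3)
        assert match_probability(sample, reference) == pytest.approx(74.23, abs=0.01)

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            match_probability(spectrum([100.0]), spectrum([]))

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a, b = random_spectrum(rng), random_spectrum(rng)
            mp_ab = match_probability(a, b)
            mp_ba = match_probability(b, a)
            assert mp_ab == pytest.approx(mp_ba, abs=1e-9)
            scaled = spectrum(
                [p.mz for p in a.peaks],
                [p.intensity * 37.5 for p in a.peaks],
                precursor=a.precursor_mz,
            )
            assert match_probability(scaled, b) == pytest.approx(mp_ab, abs=1e-9)


class TestAmp:
    def test_amp_is_mean_of_mps(self):
        rng = np.random.default_rng(29)
        sample = random_spectrum(rng)
        refs = [random_spectrum(rng, precursor=sample.precursor_mz) for _ in range(3)]
        entry = CompoundEntry("c", sample.precursor_mz, refs)
        mps = [match_probability(sample, r) for r in refs]
        assert amp(sample, entry) == pytest.approx(sum(mps) / 3, abs=1e-12)

    def test_amp_extremes(self):
        s = spectrum([100.0, 150.0], [50.0, 100.0], precursor=300.0)
        identical = CompoundEntry("same", 300.0, [s, s])
        assert amp(s, identical) == pytest.approx(100.0)
        other = spectrum([210.0, 260.0], precursor=300.0)
        disjoint = CompoundEntry("other", 300.0, [other, other, other])
        assert amp(s, disjoint) == 0.0


class TestDotProduct:
    def test_identical_is_one(self):
        s = spectrum([100.0, 150.0, 200.0], [10.0, 50.0, 100.0])
        assert dot_product(s, s) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert dot_product(spectrum([100.0]), spectrum([200.0])) == 0.0

    def test_unmatched_sample_peak_penalised(self):
        # cos = 100*100 / (sqrt(100^2 + 50^2) * 100) = 0.894
        sample = spectrum([100.0, 150.0], [100.0, 50.0])
        reference = spectrum([100.0], [100.0])
        assert dot_product(sample, reference) == pytest.approx(2 / math.sqrt(5), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            a, b = random_spectrum(rng), random_spectrum(rng)
            assert dot_product(a, b) == pytest.approx(dot_product(b, a), abs=1e-12)

    def test_self_match_maximality(self, noiseless_library):
        entry = noiseless_library.entries[0]
        s = entry.spectra[0]
        scores = [
            dot_product(s, other.spectra[0]) for other in noiseless_library
        ]
        assert dot_product(s, s) == pytest.approx(1.0)
        assert max(scores) == pytest.approx(1.0)

    def test_interference_peaks_never_increase_score(self):
        """Fragments absent from the reference (deviating fragmentation of the
        conjugate) can only lower the spectral similarity."""
        rng = np.random.default_rng(37)
        for _ in range(100):
            sample = random_spectrum(rng)
            reference = random_spectrum(rng)
            base_score = dot_product(sample, reference)
            # peak guaranteed > tol away from every reference peak
            ref_mzs = np.array([p.mz for p in reference.peaks])
            while True:
                extra = float(rng.uniform(80, 1000))
                if np.min(np.abs(ref_mzs - extra)) > 0.05:
                    break
            augmented = spectrum(
                [p.mz for p in sample.peaks] + [extra],
                [p.intensity for p in sample.peaks] + [float(rng.uniform(10, 100))],
                precursor=sample.precursor_mz,
            )
            assert dot_product(augmented, reference) <= base_score + 1e-12

    def test_agrees_with_matchms_cosine(self):
        from matchms import Spectrum as MatchmsSpectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(41)
        shared = np.sort(rng.choice(np.arange(100, 400), size=8, replace=False)).astype(float)
        sample = spectrum(shared[:6].tolist(), rng.uniform(5, 100, size=6).tolist())
        reference = spectrum(shared[2:].tolist(), rng.uniform(5, 100, size=6).tolist())

        def to_matchms(s):
            return MatchmsSpectrum(
                mz=np.array([p.mz for p in s.peaks]),
                intensities=np.array([p.intensity for p in s.peaks]),
                metadata={"precursor_mz": s.precursor_mz},
                metadata_harmonization=False,
            )

        expected = CosineGreedy(tolerance=0.01).pair(to_matchms(sample), to_matchms(reference))
        assert dot_product(sample, reference) == pytest.approx(
            float(expected["score"]), abs=1e-9
        )


class TestSearch:
    def test_precursor_window_excludes_distant_entries(self):
        entry = CompoundEntry("far", 286.1400, [spectrum([100.0], precursor=286.1400)])
        library = SpectralLibrary(entries=[entry])
        sample = spectrum([100.0], precursor=286.1180)
        assert search(sample, library) == []

    def test_amp_threshold_controls_acceptance(self, noiseless_library, noiseless_dataset):
        from aglycon import GLUCA_NL, GLUC_NL, deconjugate_spectrum, screen_dataset

        spectra, _ = noiseless_dataset
        hit = screen_dataset(spectra, [GLUC_NL, GLUCA_NL])[0]
        deconv = deconjugate_spectrum(hit.spectrum, hit.loss, secondary_loss=GLUCA_NL)
        accepted = search(deconv, noiseless_library)
        assert accepted[0].accepted
        rejected = search(deconv, noiseless_library, amp_threshold=101.0)
        assert not any(r.accepted for r in rejected)

    def test_ranking_is_deterministic(self, noiseless_library, noiseless_dataset):
        from aglycon import GLUCA_NL, GLUC_NL, deconjugate_spectrum, screen_dataset

        spectra, _ = noiseless_dataset
        hit = screen_dataset(spectra, [GLUC_NL, GLUCA_NL])[0]
        deconv = deconjugate_spectrum(hit.spectrum, hit.loss, secondary_loss=GLUCA_NL)
        first = search(deconv, noiseless_library)
        second = search(deconv, noiseless_library)
        assert [r.compound.name for r in first] == [r.compound.name for r in second]
        amps = [r.amp for r in first]
        assert amps == sorted(amps, reverse=True)


class TestHeadToTail:
    def test_paired_table_covers_all_peaks(self):
        sample = spectrum([100.0, 150.0, 200.0], [100.0, 50.0, 25.0])
        reference = spectrum([100.0, 180.0], [80.0, 40.0])
        table = head_to_tail_table(sample, reference)
        assert table.matched.sum() == 1
        assert len(table) == 4  # 1 match + 2 unmatched sample + 1 unmatched ref
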