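"""Modified cosine, analog search, duplicate removal and FG reranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mchem import specsearch as ss


def make_spectrum(sid, precursor, peaks, structure=None):
    return ss.Spectrum(id=sid, precursor_mz=precursor, peaks=peaks, structure=structure)


def random_spectrum(rng, sid, n_peaks, precursor=None):
    mzs = np.sort(rng.uniform(50, 500, n_peaks))
    while np.any(np.diff(mzs) < 1e-5):
        mzs = np.sort(rng.uniform(50, 500, n_peaks))
    intens = rng.uniform(1, 100, n_peaks)
    prec = precursor if precursor is not None else float(rng.uniform(200, 800))
    return make_spectrum(sid, prec, [(float(m), float(i)) for m, i in zip(mzs, intens)])


def oracle_modified_cosine(a, b, tol, sqrt_intensity=True):
    """Exhaustive enumeration over all one-to-one peak pairings, maximizing
    (score, n_matched) lexicographically."""
    wa = np.sqrt(a.intensity_array) if sqrt_intensity else a.intensity_array.astype(float)
    wb = np.sqrt(b.intensity_array) if sqrt_intensity else b.intensity_array.astype(float)
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    shift = b.precursor_mz - a.precursor_mz
    mza, mzb = a.mz_array, b.mz_array
    allowed = [
        (i, j)
        for i in range(len(mza))
        for j in range(len(mzb))
        if abs(mza[i] - mzb[j]) <= tol or abs(mza[i] - mzb[j] + shift) <= tol
    ]

    best = (0.0, 0)

    def recurse(k, used_b, score, count):
        nonlocal best
        if (round(score, 12), count) > (round(best[0], 12), best[1]):
            best = (score, count)
        if k == len(allowed):
            return
        recurse(k + 1, used_b, score, count)  # skip this pair
        i, j = allowed[k]
        if i not in used_b[0] and j not in used_b[1]:
            recurse(
                k + 1,
                (used_b[0] | {i}, used_b[1] | {j}),
                score + wa[i] * wb[j],
                count + 1,
            )

    recurse(0, (frozenset(), frozenset()), 0.0, 0)
    return min(best[0], 1.0), best[1]


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, "S", 8)
        score, n = ss.modified_cosine(s, s, 0.5)
        assert score == pytest.approx(1.0)
        assert n == 8

    def test_no_pairs_within_tolerance(self):
        a = make_spectrum("A", 500.0, [(100.0, 10.0), (200.0, 5.0)])
        b = make_spectrum("B", 500.0, [(150.0, 10.0), (250.0, 5.0)])
        assert ss.modified_cosine(a, b, 0.5) == (0.0, 0)

    def test_shifted_peak_pairs_through_precursor_delta(self):
        # product spectrum: one fragment keeps its m/z, one carries the +50 shift
        a = make_spectrum("A", 300.0, [(100.0, 10.0), (200.0, 10.0)])
        b = make_spectrum("B", 350.0, [(100.0, 10.0), (250.0, 10.0)])
        score, n = ss.modified_cosine(a, b, 0.01)
        assert n == 2
        assert score == pytest.approx(1.0)

    def test_empty_peak_list_raises(self):
        a = make_spectrum("A", 300.0, [(100.0, 1.0)])
        empty = ss.Spectrum(id="E", precursor_mz=300.0, peaks=[])
        with pytest.raises(ss.SpectrumError, match="non-empty"):
            ss.modified_cosine(a, empty, 0.5)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_small_spectra(self, seed):
        rng = np.random.default_rng(seed)
        a = random_spectrum(rng, "A", int(rng.integers(2, 7)))
        b = random_spectrum(
            rng, "B", int(rng.integers(2, 7)), precursor=a.precursor_mz + float(rng.uniform(-30, 30))
        )
        tol = 5.0  # generous so shifted/direct pairs actually occur
        score, n = ss.modified_cosine(a, b, tol)
        exp_score, exp_n = oracle_modified_cosine(a, b, tol)
        assert score == pytest.approx(exp_score, abs=1e-9)
        assert n == exp_n

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_matchms_on_separated_peaks(self, seed):
        """Independent cross-check against the molecular-networking ecosystem's
        implementation, on spectra whose peaks admit unique pairings."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(seed)
        # peaks spaced > 2*tol so greedy and exact pairing coincide
        mza = np.sort(rng.choice(np.arange(100, 500, 10), 6, replace=False)).astype(float)
        ia = rng.uniform(10, 100, 6)
        offset = 35.0  # off the 10 Da grid, so shifted peaks cannot collide
        a = make_spectrum("A", 400.0, list(zip(mza, ia)))
        b_peaks = [(mz + (offset if k % 2 else 0.0), float(rng.uniform(10, 100))) for k, mz in enumerate(mza)]
        b = make_spectrum("B", 400.0 + offset, sorted(b_peaks))
        score, n = ss.modified_cosine(a, b, 0.1, sqrt_intensity=False)
        sa = matchms.Spectrum(mz=a.mz_array, intensities=a.intensity_array, metadata={"precursor_mz": a.precursor_mz})
        sb = matchms.Spectrum(mz=b.mz_array, intensities=b.intensity_array, metadata={"precursor_mz": b.precursor_mz})
        res = ModifiedCosine(tolerance=0.1).pair(sa, sb)
        assert score == pytest.approx(float(res["score"]), abs=1e-6)
        assert n == int(res["matches"])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = random_spectrum(rng, "A", int(rng.integers(2, 8)))
        b = random_spectrum(rng, "B", int(rng.integers(2, 8)))
        s_ab, n_ab = ss.modified_cosine(a, b, 1.0)
        s_ba, n_ba = ss.modified_cosine(b, a, 1.0)
        assert s_ab == pytest.approx(s_ba, abs=1e-9)
        assert n_ab == n_ba
        assert 0.0 <= s_ab <= 1.0 + 1e-9

    def test_reduces_to_plain_cosine_at_equal_precursors(self):
        rng = np.random.default_rng(3)
        a = random_spectrum(rng, "A", 6, precursor=400.0)
        b = random_spectrum(rng, "B", 6, precursor=400.0)
        # with equal precursors the shifted criterion duplicates the direct one
        wa = np.sqrt(a.intensity_array); wa /= np.linalg.norm(wa)
        wb = np.sqrt(b.intensity_array); wb /= np.linalg.norm(wb)
        direct = [
            (i, j)
            for i in range(6)
            for j in range(6)
            if abs(a.mz_array[i] - b.mz_array[j]) <= 1.0
        ]
        score, _ = ss.modified_cosine(a, b, 1.0)
        assert score <= 1.0
        if not direct:
            assert score == 0.0

    def test_greedy_never_beats_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = random_spectrum(rng, "A", 6)
            b = random_spectrum(rng, "B", 6, precursor=a.precursor_mz + 20.0)
            exact, _ = ss.modified_cosine(a, b, 5.0, method="exact")
            greedy, _ = ss.modified_cosine(a, b, 5.0, method="greedy")
            assert greedy <= exact + 1e-12


class TestAnalogSearch:
    def _library(self, rng, query, n):
        lib = []
        for k in range(n):
            lib.append(
                ss.Spectrum(
                    id=f"L{k:03d}",
                    precursor_mz=query.precursor_mz + float(rng.uniform(-50, 50)),
                    peaks=[
                        (mz + float(rng.uniform(-0.2, 0.2)), i * float(rng.uniform(0.5, 1.5)))
                        for mz, i in query.peaks
                    ],
                    structure="CCO",
                )
            )
        return lib

    def test_query_in_library_ranks_first(self):
        rng = np.random.default_rng(1)
        query = random_spectrum(rng, "Q", 8)
        lib = self._library(rng, query, 10)
        lib.append(ss.Spectrum(id="EXACT", precursor_mz=query.precursor_mz, peaks=query.peaks, structure="CCO"))
        matches = ss.analog_search(query, lib, ss.SearchParams(min_cosine=0.0))
        assert matches[0].library_id == "EXACT"
        assert matches[0].score == pytest.approx(1.0)

    def test_below_min_cosine_is_empty(self):
        rng = np.random.default_rng(2)
        query = random_spectrum(rng, "Q", 6)
        junk = [random_spectrum(rng, f"L{k}", 6) for k in range(5)]
        for s in junk:
            s.structure = "CCO"
        assert ss.analog_search(query, junk, ss.SearchParams(min_cosine=0.99)) == []

    def test_truncates_to_max_analogs(self):
        rng = np.random.default_rng(3)
        query = random_spectrum(rng, "Q", 8)
        lib = self._library(rng, query, 40)
        params = ss.SearchParams(min_cosine=0.0, min_matched_peaks=1, max_analogs=30)
        matches = ss.analog_search(query, lib, params)
        assert len(matches) == 30
        scores = [m.score for m in matches]
        assert scores == sorted(scores, reverse=True)

    def test_empty_library_is_empty_result(self):
        rng = np.random.default_rng(4)
        assert ss.analog_search(random_spectrum(rng, "Q", 5), []) == []


class TestRemoveExactAndDuplicates:
    def _match(self, lid, structure, score):
        return ss.AnalogMatch("Q", lid, structure, score, 5, 0.0)

    def test_exact_canonical_match_removed(self):
        matches = [self._match("L1", "OCC", 0.9), self._match("L2", "CCN", 0.8)]
        out = ss.remove_exact_and_duplicates(matches, "CCO")
        assert [m.library_id for m in out] == ["L2"]

    def test_duplicates_keep_best_scoring(self):
        matches = [self._match("L1", "CCN", 0.9), self._match("L2", "NCC", 0.7)]
        out = ss.remove_exact_and_duplicates(matches, "CCO")
        assert [(m.library_id, m.score) for m in out] == [("L1", 0.9)]

    def test_no_removals_is_identity(self):
        matches = [self._match("L1", "CCN", 0.9), self._match("L2", "CCCl", 0.7)]
        assert ss.remove_exact_and_duplicates(matches, "CCO") == matches

    def test_refills_to_max_after_removal(self):
        matches = [self._match(f"L{k}", "OCC" if k < 2 else f"{'C' * (k + 1)}N", 1.0 - 0.01 * k) for k in range(6)]
        out = ss.remove_exact_and_duplicates(matches, "CCO", max_analogs=3)
        assert len(out) == 3
        assert all(m.structure != "OCC" for m in out)

    def test_unparseable_structure_warns_and_is_kept(self):
        matches = [self._match("L1", "not_a_smiles(", 0.9)]
        with pytest.warns(UserWarning, match="unparseable"):
            out = ss.remove_exact_and_duplicates(matches, "CCO")
        assert len(out) == 1


STRUCTURE_POOL = ["CC(=O)CC", "CCCCO", "c1ccccc1O", "CCN", "CCCC", "O=CCC"]


class TestRerankByFg:
    def _matches(self, specs):
        return [
            ss.AnalogMatch("Q", f"L{k}", smiles, score, 5, 0.0)
            for k, (smiles, score) in enumerate(specs)
        ]

    def test_fg_bearing_match_moves_ahead(self, registry):
        matches = self._matches([("CCCC", 0.9), ("CC(=O)CC", 0.6)])
        out = ss.rerank_by_fg(matches, {"C"}, registry)
        assert [m.library_id for m in out] == ["L1", "L0"]
        assert [m.fg_consistent for m in out] == [True, False]

    def test_empty_observed_is_identity(self, registry):
        matches = self._matches([("CCCC", 0.9), ("CC(=O)CC", 0.6)])
        out = ss.rerank_by_fg(matches, set(), registry)
        assert [m.library_id for m in out] == ["L0", "L1"]

    def test_all_consistent_is_identity(self, registry):
        matches = self._matches([("CC(=O)CC", 0.9), ("O=CCC", 0.6)])
        out = ss.rerank_by_fg(matches, {"C"}, registry)
        assert [m.library_id for m in out] == ["L0", "L1"]

    def test_all_mode_requires_every_observed_reaction(self, registry):
        # phenol has B but not C; the ketone-phenol carries both
        matches = self._matches([("c1ccccc1O", 0.9), ("CC(=O)Cc1ccc(O)cc1", 0.5)])
        out_all = ss.rerank_by_fg(matches, {"B", "C"}, registry, mode="all")
        assert [m.library_id for m in out_all] == ["L1", "L0"]
        out_any = ss.rerank_by_fg(matches, {"B", "C"}, registry, mode="any")
        assert [m.library_id for m in out_any] == ["L0", "L1"]

    def test_unknown_reaction_id_raises(self, registry):
        with pytest.raises(ss.SpectrumError, match="unknown"):
            ss.rerank_by_fg(self._matches([("CCO", 0.5)]), {"Z"}, registry)

    @given(
        st.lists(
            st.tuples(st.sampled_from(STRUCTURE_POOL), st.floats(0, 1)),
            max_size=8,
        ),
        st.sets(st.sampled_from(["A", "B", "C"])),
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_permutation_and_idempotence(self, specs, observed):
        from mchem.reactions import default_registry

        registry = default_registry()
        matches = self._matches(sorted(specs, key=lambda t: -t[1]))
        out = ss.rerank_by_fg(matches, observed, registry)
        assert sorted(m.library_id for m in out) == sorted(m.library_id for m in matches)
        again = ss.rerank_by_fg(out, observed, registry)
        assert [m.library_id for m in again] == [m.library_id for m in out]
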