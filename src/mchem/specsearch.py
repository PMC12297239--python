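"""Modified-cosine spectral similarity, analog search, and FG-first reranking.

The modified cosine allows fragment peaks to pair either at equal m/z or
offset by the precursor mass difference, so structural analogs that differ
by one modification still score highly (open-modification semantics).  Peak
pairing here is the exact maximum-weight one-to-one assignment over the
bipartite graph of eligible pairs, solved with the Hungarian algorithm; a
greedy variant is available for comparison.

Reranking moves library matches whose structures carry the functional groups
evidenced by the observed derivatization reactions ahead of those that do
not, as a stable partition that preserves the incoming (cosine) order inside
each block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chemcore import StructureError, canonical_smiles, match_substructure
from .reactions import Reaction, registry_by_id

__all__ = [
    "Spectrum",
    "SearchParams",
    "AnalogMatch",
    "SpectrumError",
    "modified_cosine",
    "analog_search",
    "remove_exact_and_duplicates",
    "rerank_by_fg",
    "fg_consistent",
]


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum:
    """An MS/MS spectrum: precursor, charge, peak list, optional structure."""

    id: str
    precursor_mz: float
    peaks: list[tuple[float, float]]
    charge: int = 1
    structure: str | None = None
    rt: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise SpectrumError(f"spectrum {self.id}: precursor_mz must be positive")
        mzs = [mz for mz, _ in self.peaks]
        if any(i < 0 for _, i in self.peaks):
            raise SpectrumError(f"spectrum {self.id}: negative intensity")
        if mzs != sorted(mzs):
            self.peaks = sorted(self.peaks)
            mzs = sorted(mzs)
        if any(b - a < 1e-6 for a, b in zip(mzs, mzs[1:])):
            raise SpectrumError(f"spectrum {self.id}: peaks closer than 1e-6 Da")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class SearchParams:
    """Analog-search thresholds (deliberately looser than exact-match search)."""

    min_cosine: float = 0.5
    min_matched_peaks: int = 4
    fragment_tol: float = 0.5
    precursor_tol: float = 2.0
    max_analogs: int = 30
    sqrt_intensity: bool = True

    def __post_init__(self) -> None:
        if min(self.min_cosine, self.fragment_tol, self.precursor_tol) < 0:
            raise SpectrumError("search thresholds must be non-negative")
        if self.max_analogs < 1 or self.min_matched_peaks < 0:
            raise SpectrumError("max_analogs must be >= 1")


@dataclass(frozen=True)
class AnalogMatch:
    query_id: str
    library_id: str
    structure: str | None
    score: float
    n_matched: int
    precursor_delta: float
    fg_consistent: bool | None = None

    def __post_init__(self) -> None:
        if not -1e-9 <= self.score <= 1 + 1e-9:
            raise SpectrumError("score outside [0, 1]")
        if self.n_matched < 0:
            raise SpectrumError("n_matched must be non-negative")


def _weights(spec: Spectrum, sqrt_intensity: bool) -> np.ndarray:
    w = spec.intensity_array.astype(float)
    if sqrt_intensity:
        w = np.sqrt(w)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol: float = 0.5,
    sqrt_intensity: bool = True,
    method: str = "exact",
) -> tuple[float, int]:
    """Modified cosine score and matched-peak count of two spectra.

    Peaks pair directly (|mz_a - mz_b| <= tol) or shifted by the precursor
    difference (|mz_a - mz_b + (prec_b - prec_a)| <= tol); a pair eligible
    both ways counts once.  Each peak is used at most once, and the pairing
    maximizes the sum of products of sqrt-scaled, L2-normalized intensities
    (ties resolved toward more matched pairs).  ``method='greedy'`` pairs in
    descending weight order instead of solving the exact assignment.
    """
    if not a.peaks or not b.peaks:
        raise SpectrumError("modified cosine requires non-empty peak lists")
    wa, wb = _weights(a, sqrt_intensity), _weights(b, sqrt_intensity)
    mza, mzb = a.mz_array, b.mz_array
    shift = b.precursor_mz - a.precursor_mz
    diff = mza[:, None] - mzb[None, :]
    allowed = (np.abs(diff) <= fragment_tol) | (np.abs(diff + shift) <= fragment_tol)
    if not allowed.any():
        return 0.0, 0
    pairs = wa[:, None] * wb[None, :]

    if method == "greedy":
        score, n = _greedy_assignment(allowed, pairs)
    elif method == "exact":
        # epsilon makes the assignment prefer more matched pairs among
        # score-equal solutions (relevant only with zero intensities)
        eps = 1e-9 / max(allowed.sum(), 1)
        cost = np.where(allowed, -(pairs + eps), 0.0)
        rows, cols = linear_sum_assignment(cost)
        used = allowed[rows, cols]
        score = float(pairs[rows[used], cols[used]].sum())
        n = int(used.sum())
    else:
        raise SpectrumError(f"unknown pairing method: {method!r}")
    return float(min(max(score, 0.0), 1.0)), n


def _greedy_assignment(allowed: np.ndarray, pairs: np.ndarray) -> tuple[float, int]:
    idx = np.argwhere(allowed)
    order = sorted(range(len(idx)), key=lambda k: -pairs[idx[k][0], idx[k][1]])
    used_a: set[int] = set()
    used_b: set[int] = set()
    score, n = 0.0, 0
    for k in order:
        i, j = map(int, idx[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(pairs[i, j])
        n += 1
    return score, n


def analog_search(
    query: Spectrum,
    library: list[Spectrum],
    params: SearchParams | None = None,
    keep_all: bool = False,
) -> list[AnalogMatch]:
    """Score a query against a library and return the ranked analogs.

    Candidates must reach ``min_cosine`` and ``min_matched_peaks``; survivors
    are sorted by score descending (ties by library id) and truncated to
    ``max_analogs`` unless ``keep_all`` is set (used by the exact-match /
    duplicate removal step, which refills from below the cut).  No precursor
    window is applied: analogs at any mass offset are eligible.
    """
    params = params or SearchParams()
    matches = []
    for entry in library:
        score, n = modified_cosine(
            query, entry, params.fragment_tol, params.sqrt_intensity
        )
        if score >= params.min_cosine and n >= params.min_matched_peaks:
            matches.append(
                AnalogMatch(
                    query_id=query.id,
                    library_id=entry.id,
                    structure=entry.structure,
                    score=score,
                    n_matched=n,
                    precursor_delta=entry.precursor_mz - query.precursor_mz,
                )
            )
    matches.sort(key=lambda m: (-m.score, m.library_id))
    return matches if keep_all else matches[: params.max_analogs]


def remove_exact_and_duplicates(
    matches: list[AnalogMatch],
    query_structure: str,
    max_analogs: int | None = None,
) -> list[AnalogMatch]:
    """Drop exact structure matches and keep one (best) match per structure.

    ``matches`` should be the full ranked candidate list so the result can be
    refilled up to ``max_analogs`` after removal.  Equality is canonical-form
    SMILES equality; matches whose structure fails to parse are skipped from
    the removal logic (kept, warned about).
    """
    try:
        query_canon = canonical_smiles(query_structure)
    except StructureError:
        raise
    seen: set[str] = set()
    out = []
    for m in matches:
        if m.structure is None:
            warnings.warn(f"match {m.library_id} carries no structure; kept as unique")
            out.append(m)
            continue
        try:
            canon = canonical_smiles(m.structure)
        except StructureError:
            warnings.warn(f"unparseable structure on match {m.library_id}; kept as unique")
            out.append(m)
            continue
        if canon == query_canon or canon in seen:
            continue
        seen.add(canon)
        out.append(m)
    return out[:max_analogs] if max_analogs is not None else out


def fg_consistent(
    structure: str,
    observed: set[str],
    registry: list[Reaction],
    mode: str = "all",
) -> bool:
    """Does a structure carry the groups evidenced by the observed reactions?

    ``mode='all'`` (default) requires at least one SMARTS hit for *every*
    observed reaction; ``'any'`` accepts a hit for any one of them.  An empty
    observed set is vacuously consistent.
    """
    if mode not in ("all", "any"):
        raise SpectrumError(f"unknown fg mode: {mode!r}")
    by_id = registry_by_id(registry)
    unknown = observed - by_id.keys()
    if unknown:
        raise SpectrumError(f"unknown reaction ids: {sorted(unknown)}")
    if not observed:
        return True
    hits = (
        any(match_substructure(structure, s) > 0 for s in by_id[rid].smarts())
        for rid in sorted(observed)
    )
    return all(hits) if mode == "all" else any(hits)


def rerank_by_fg(
    matches: list[AnalogMatch],
    observed: set[str],
    registry: list[Reaction],
    mode: str = "all",
) -> list[AnalogMatch]:
    """Stable FG-first partition of a scored match list.

    Matches consistent with every observed derivatization move ahead of the
    rest; within each block the incoming order (normally cosine-descending)
    is preserved, so the result is a permutation of the input and reranking
    is idempotent.  With no observed reactions the list is returned unchanged
    apart from the ``fg_consistent`` flags.
    """
    flagged = [
        replace(
            m,
            fg_consistent=(
                m.structure is not None
                and fg_consistent(m.structure, observed, registry, mode)
            )
            if observed
            else True,
        )
        for m in matches
    ]
    return [m for m in flagged if m.fg_consistent] + [
        m for m in flagged if not m.fg_consistent
    ]
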