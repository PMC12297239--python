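"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the data shapes the workflow consumes — paired
with/without-reagent LC-MS runs containing educt features at [M+H]+ and
derivatized products offset by the reaction delta m/z, plus toy MS/MS
spectra and analog libraries with graded structural similarity — together
with the ground truth needed to score recovery.  They deliberately do NOT
model isotope envelopes, adduct ladders, chromatographic peak shapes or
physical fragmentation: the point is to exercise the linking, search and
reranking machinery against a known answer, not to simulate a mass
spectrometer.

All randomness flows through a single ``numpy.random.Generator`` derived
from the config seed; a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import Descriptors

from .chemcore import ELECTRON_MASS, _mol
from .linking import Condition, Feature, LinkingParams
from .reactions import Reaction, default_registry, simulate_reactivity
from .specsearch import Spectrum

__all__ = [
    "FixtureConfig",
    "PlantedEdge",
    "GroundTruth",
    "FixtureError",
    "default_structure_pool",
    "make_feature_table",
    "make_spectra",
    "make_analog_benchmark",
]

PROTON_MASS = 1.00782503207 - ELECTRON_MASS


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 3 derivatized + 3 underivatized replicate samples; true
    conversion yields uniform in [10, 95]% (a titration-like spread that
    straddles the 5% reaction-A cut without hugging it); RT jitter sd 0.01
    min, well inside the 0.05 min co-elution tolerance; product mass error
    sd 0.0003 Da clipped at +/-0.001 Da, below half the 0.002 Da tolerance
    floor; 2 decoy features per structure.
    """

    seed: int = 0
    n_samples_per_condition: int = 3
    yield_range: tuple[float, float] = (10.0, 95.0)
    rt_jitter_sd: float = 0.01
    mass_error_sd: float = 0.0003
    mass_error_max: float = 0.001
    n_decoys_per_structure: int = 2
    rt_span: tuple[float, float] = (1.0, 14.0)
    base_area: float = 1e6
    # spectra / benchmark
    n_fragments: int = 12
    fragment_mz_range: tuple[float, float] = (50.0, 500.0)
    n_queries: int = 50
    n_decoy_analogs: int = 3
    analog_shared_fraction: float = 0.6
    decoy_shared_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.rt_jitter_sd < 0 or self.mass_error_sd < 0:
            raise FixtureError("noise standard deviations must be >= 0")
        lo, hi = self.yield_range
        if not 0 <= lo <= hi <= 100:
            raise FixtureError("yield_range must lie within [0, 100]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedEdge:
    precursor_id: str
    product_id: str
    reaction_id: str
    true_yield_pct: float


@dataclass
class GroundTruth:
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    structure_reactions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    feature_structures: dict[str, str] = field(default_factory=dict)
    query_truth: dict[str, str] = field(default_factory=dict)
    query_observed: dict[str, tuple[str, ...]] = field(default_factory=dict)
    query_best_analog: dict[str, str] = field(default_factory=dict)


def default_structure_pool() -> list[str]:
    """A small diverse pool covering all three reaction chemistries.

    Ketones/aldehydes (reaction C), amines and phenols (B), Michael
    acceptors, a beta-lactone and a terminal alkene (A), plus unreactive
    hydrocarbons/ethers that should never link.
    """
    return [
        "CC(=O)CCCC",          # hexan-2-one: C
        "O=CCCCCC",            # hexanal: C
        "CCCCCN",              # pentylamine: B
        "c1ccccc1O",           # phenol: B
        "CC(=O)C=C",           # methyl vinyl ketone: A (enone) + C
        "O=C1OCC1",            # beta-propiolactone: A
        "C=CCCCC",             # hex-1-ene: A (terminal alkene)
        "CCCCCC",              # hexane: unreactive
        "CCOCC",               # diethyl ether: unreactive
        "CCCCCCO",             # hexan-1-ol: unreactive toward all three
    ]


def _neutral_mass(smiles: str) -> float:
    return Descriptors.ExactMolWt(_mol(smiles))


def make_feature_table(
    structures: list[str],
    registry: list[Reaction] | None = None,
    config: FixtureConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Feature], GroundTruth]:
    """Generate a paired with/without-reagent feature table with ground truth.

    Per structure: one educt feature at [M+H]+ present in both conditions;
    for every reaction the structure is predicted to undergo, one product
    feature at educt m/z + delta (+ clipped Gaussian mass error), RT jittered
    within the co-elution tolerance, present only in derivatized samples and
    with areas realizing a drawn true yield.  Decoy features are placed at
    random m/z guaranteed not to sit one reaction delta away from any real
    feature.
    """
    registry = registry if registry is not None else default_registry()
    config = config or FixtureConfig()
    rng = rng if rng is not None else config.rng()
    n = config.n_samples_per_condition
    samples_u = [f"ctrl_{i + 1}" for i in range(n)]
    samples_d = [f"rx_{i + 1}" for i in range(n)]
    conditions = {
        **{s: Condition.UNDERIVATIZED for s in samples_u},
        **{s: Condition.DERIVATIZED for s in samples_d},
    }

    features: list[Feature] = []
    truth = GroundTruth()
    for k, smiles in enumerate(structures):
        educt_id = f"F{len(features) + 1:04d}"
        mz = _neutral_mass(smiles) + PROTON_MASS
        rt = float(rng.uniform(*config.rt_span))
        base = float(config.base_area * rng.uniform(0.5, 2.0))
        predictions = simulate_reactivity(smiles, registry, structure_id=educt_id)
        reacted = [p.reaction_id for p in predictions]
        truth.structure_reactions[smiles] = tuple(reacted)
        truth.feature_structures[educt_id] = smiles

        # per-reaction conversion; the upper bound is divided by the number
        # of reactions so the educt never converts past 100% in total, and
        # the resulting per-edge yields stay inside yield_range
        lo, hi = config.yield_range
        yields = {
            rid: float(rng.uniform(lo, hi / max(len(reacted), 1)))
            for rid in reacted
        }
        educt_fraction = 1.0 - sum(yields.values()) / 100.0
        educt_areas = {s: base * float(rng.uniform(0.9, 1.1)) for s in samples_u}
        deriv_base = {s: base * float(rng.uniform(0.9, 1.1)) for s in samples_d}
        educt_areas.update(
            {s: deriv_base[s] * educt_fraction for s in samples_d}
        )
        features.append(
            Feature(
                id=educt_id,
                mz=mz,
                rt=rt,
                areas=educt_areas,
                conditions=dict(conditions),
                ms2_ref=f"MS2_{educt_id}",
            )
        )
        by_id = {r.id: r for r in registry}
        for rid in reacted:
            product_id = f"F{len(features) + 1:04d}"
            err = _clipped_normal(rng, config.mass_error_sd, config.mass_error_max)
            jitter = float(
                np.clip(rng.normal(0.0, config.rt_jitter_sd), -0.04, 0.04)
            ) if config.rt_jitter_sd > 0 else 0.0
            # per-sample product areas realize the same yield fraction in
            # every sample, so both yield modes recover the planted value
            y = yields[rid]
            product_areas = {s: deriv_base[s] * (y / 100.0) for s in samples_d}
            features.append(
                Feature(
                    id=product_id,
                    mz=mz + by_id[rid].delta_mass + err,
                    rt=rt + jitter,
                    areas=product_areas,
                    conditions={s: Condition.DERIVATIZED for s in samples_d},
                )
            )
            # planted yield as the linker computes it: product/(product+educt)
            # over derivatized areas
            planted = 100.0 * (y / 100.0) / (educt_fraction + y / 100.0)
            truth.planted_edges.append(PlantedEdge(educt_id, product_id, rid, planted))

    _add_decoys(features, registry, config, rng)
    return features, truth


def _clipped_normal(rng: np.random.Generator, sd: float, bound: float) -> float:
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -bound, bound))


def _add_decoys(
    features: list[Feature],
    registry: list[Reaction],
    config: FixtureConfig,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> None:
    """Append decoy features whose m/z collides with no reaction delta."""
    n_decoys = config.n_decoys_per_structure * max(len(features) // 2, 1)
    deltas = [r.delta_mass for r in registry]
    # keep decoys comfortably outside any plausible pairing tolerance
    margin = max(3 * config.mass_error_sd, 2 * LinkingParams().mz_tol_floor_da, 0.05)
    samples = list(features[0].conditions) if features else ["ctrl_1", "rx_1"]
    conditions = dict(features[0].conditions) if features else {}
    for _ in range(n_decoys):
        for attempt in range(max_tries):
            mz = float(rng.uniform(100.0, 1000.0))
            existing = [f.mz for f in features]
            ok = all(
                abs(abs(mz - other) - d) > margin
                for other in existing
                for d in deltas
            )
            if ok:
                break
        else:
            raise FixtureError("could not place a collision-free decoy")
        features.append(
            Feature(
                id=f"D{len(features) + 1:04d}",
                mz=mz,
                rt=float(rng.uniform(*config.rt_span)),
                areas={s: float(rng.uniform(1e4, 1e6)) for s in samples},
                conditions=conditions,
            )
        )


# ---------------------------------------------------------------------------
# Toy spectra and the analog benchmark
# ---------------------------------------------------------------------------


def _template_peaks(
    rng: np.random.Generator, config: FixtureConfig
) -> list[tuple[float, float]]:
    mzs = np.sort(rng.uniform(*config.fragment_mz_range, size=config.n_fragments))
    # enforce the 1e-6 Da uniqueness invariant
    while np.any(np.diff(mzs) < 1e-5):
        mzs = np.sort(rng.uniform(*config.fragment_mz_range, size=config.n_fragments))
    intens = rng.uniform(10.0, 100.0, size=config.n_fragments)
    return [(float(m), float(i)) for m, i in zip(mzs, intens)]


def _derived_peaks(
    template: list[tuple[float, float]],
    shared_fraction: float,
    precursor_offset: float,
    rng: np.random.Generator,
    config: FixtureConfig,
) -> list[tuple[float, float]]:
    """Analog spectrum: keeps a fraction of fragments, shifts some by the offset."""
    n = len(template)
    n_shared = int(round(shared_fraction * n))
    idx = rng.permutation(n)
    peaks: list[tuple[float, float]] = []
    for rank, k in enumerate(idx):
        mz, inten = template[k]
        if rank < n_shared:
            # half the shared fragments carry the modification (shifted)
            if precursor_offset != 0.0 and rank % 2 == 0:
                peaks.append((mz + precursor_offset, inten * float(rng.uniform(0.8, 1.2))))
            else:
                peaks.append((mz, inten * float(rng.uniform(0.8, 1.2))))
        else:
            peaks.append(
                (float(rng.uniform(*config.fragment_mz_range)), inten)
            )
    uniq: dict[float, float] = {}
    for mz, inten in sorted(peaks):
        if uniq and min(abs(mz - u) for u in uniq) < 1e-5:
            mz += 1e-4
        uniq[mz] = inten
    return sorted(uniq.items())


def make_spectra(
    structures: list[str],
    config: FixtureConfig | None = None,
    rng: np.random.Generator | None = None,
    plant_exact: bool = False,
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Template-based toy query spectra plus an analog library.

    Each structure gets a random fragment template; its library analog shares
    ``analog_shared_fraction`` of the fragments and carries a precursor
    offset.  With ``plant_exact`` the query's own spectrum/structure is also
    inserted into the library (for exact-match-removal tests).
    """
    config = config or FixtureConfig()
    rng = rng if rng is not None else config.rng()
    queries, library = [], []
    for k, smiles in enumerate(structures):
        prec = _neutral_mass(smiles) + PROTON_MASS
        template = _template_peaks(rng, config)
        queries.append(Spectrum(id=f"Q{k + 1:03d}", precursor_mz=prec, peaks=template))
        offset = float(rng.uniform(10.0, 60.0))
        library.append(
            Spectrum(
                id=f"L{k + 1:03d}",
                precursor_mz=prec + offset,
                peaks=_derived_peaks(
                    template, config.analog_shared_fraction, offset, rng, config
                ),
                structure=smiles,
            )
        )
        if plant_exact:
            library.append(
                Spectrum(
                    id=f"L{k + 1:03d}x",
                    precursor_mz=prec,
                    peaks=template,
                    structure=smiles,
                )
            )
    return queries, library


# benchmark structure families: (truth, high-Tanimoto FG analog, FG-free decoy base)
def _benchmark_family(i: int) -> tuple[str, str, str]:
    tail = "C" * (3 + i % 5)
    truth = f"CC(=O){tail}CC"          # ketone -> reaction C observed
    analog = f"CC(=O){tail}CCC"        # homolog, keeps the ketone
    decoy = f"CC(O){tail}CC"           # alcohol: same skeleton, no ketone
    return truth, analog, decoy


def make_analog_benchmark(
    config: FixtureConfig | None = None,
    registry: list[Reaction] | None = None,
) -> tuple[list[Spectrum], list[Spectrum], GroundTruth]:
    """Seeded benchmark where FG-aware reranking is exercised non-trivially.

    Each query's true structure is a ketone (observed reaction C).  The
    library holds one high-Tanimoto analog that keeps the ketone but shares
    fewer fragments (lower cosine) and several low-Tanimoto alcohol decoys
    that share more fragments (higher cosine) but lack the group, so cosine
    ranking alone puts the wrong structures first and the FG partition must
    repair the ordering.
    """
    config = config or FixtureConfig()
    registry = registry if registry is not None else default_registry()
    rng = config.rng()
    queries, library = [], []
    truth = GroundTruth()
    for i in range(config.n_queries):
        t_smiles, a_smiles, d_base = _benchmark_family(i)
        prec = _neutral_mass(t_smiles) + PROTON_MASS
        template = _template_peaks(rng, config)
        qid = f"Q{i + 1:03d}"
        observed = tuple(
            p.reaction_id for p in simulate_reactivity(t_smiles, registry)
        )
        queries.append(
            Spectrum(
                id=qid,
                precursor_mz=prec,
                peaks=template,
                metadata={"observed_reactions": set(observed)} if observed else {},
            )
        )
        truth.query_truth[qid] = t_smiles
        truth.query_observed[qid] = observed
        aid = f"L{i + 1:03d}_fg"
        offset = float(rng.uniform(10.0, 40.0))
        library.append(
            Spectrum(
                id=aid,
                precursor_mz=prec + offset,
                peaks=_derived_peaks(
                    template, config.analog_shared_fraction, offset, rng, config
                ),
                structure=a_smiles,
            )
        )
        truth.query_best_analog[qid] = aid
        for j in range(config.n_decoy_analogs):
            d_offset = float(rng.uniform(-5.0, 5.0))
            library.append(
                Spectrum(
                    id=f"L{i + 1:03d}_d{j + 1}",
                    precursor_mz=prec + d_offset,
                    peaks=_derived_peaks(
                        template, config.decoy_shared_fraction, d_offset, rng, config
                    ),
                    structure=d_base + "C" * j,
                )
            )
    return queries, library, truth
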