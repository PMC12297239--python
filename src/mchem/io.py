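"""Readers and writers for the formats the pipeline touches.

Feature tables and edge/match/evaluation tables are plain delimited text
(pandas); spectra travel as MGF via pyteomics, with two reactivity keys —
``MCHEM_REACTIONS`` (comma-joined reaction ids) and ``MCHEM_SMARTS``
(semicolon-joined patterns) — carrying derivatization evidence alongside
each spectrum.  Retention time is stored in minutes internally and converted
to/from MGF's RTINSECONDS exactly once at the boundary.  The reaction
registry round-trips through YAML so users can substitute their own SMARTS
sets.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .chemcore import parse_formula
from .linking import Condition, Feature, ReactivityEdge, build_network
from .reactions import Reaction
from .specsearch import AnalogMatch, Spectrum

__all__ = [
    "IOError_",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "write_edges",
    "read_edges",
    "write_matches",
    "read_matches",
    "load_registry",
    "save_registry",
    "write_graphml",
    "write_provenance",
]

REACTIONS_KEY = "mchem_reactions"
SMARTS_KEY = "mchem_smarts"

FEATURE_COLUMNS = ["id", "mz", "rt", "sample", "condition", "area"]
EDGE_COLUMNS = [
    "precursor_id",
    "product_id",
    "reaction",
    "delta_observed",
    "mass_error",
    "rt_delta",
    "yield_pct",
    "correlation",
]
MATCH_COLUMNS = [
    "query_id",
    "library_id",
    "structure",
    "rank",
    "score",
    "n_matched",
    "fg_consistent",
    "precursor_delta",
]


class IOError_(ValueError):
    """Raised on malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(
    path: str | Path,
    reactions_key: str = REACTIONS_KEY,
    smarts_key: str = SMARTS_KEY,
) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.

    Unrecognized header keys are preserved verbatim in ``metadata``;
    RTINSECONDS is converted to minutes; ``MCHEM_REACTIONS=A,C`` style keys
    populate ``metadata['observed_reactions']`` as a set.
    """
    spectra = []
    try:
        entries = list(_mgf.read(str(path), use_index=False, convert_arrays=1))
    except Exception as exc:  # pyteomics raises assorted parse errors
        raise IOError_(f"malformed MGF file {path}: {exc}") from exc
    for i, entry in enumerate(entries):
        params = dict(entry["params"])
        if "pepmass" not in params:
            raise IOError_(f"{path}: spectrum block {i + 1} missing PEPMASS")
        pepmass = params.pop("pepmass")
        precursor_mz = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
        charge = 1
        if "charge" in params:
            raw = params.pop("charge")
            charge = int(raw[0]) if isinstance(raw, (list, tuple)) else int(raw)
        rt = None
        if "rtinseconds" in params:
            rt = float(params.pop("rtinseconds")) / 60.0
        sid = str(params.pop("title", f"spectrum_{i + 1}"))
        structure = params.pop("smiles", None)
        metadata = {k: v for k, v in params.items()}
        if reactions_key in metadata:
            raw = str(metadata.pop(reactions_key))
            metadata["observed_reactions"] = (
                {r for r in raw.split(",") if r} if raw else set()
            )
        if smarts_key in metadata:
            metadata["annotation_smarts"] = tuple(
                s for s in str(metadata.pop(smarts_key)).split(";") if s
            )
        peaks = [
            (float(mz), float(inten))
            for mz, inten in zip(entry["m/z array"], entry["intensity array"])
        ]
        spectra.append(
            Spectrum(
                id=sid,
                precursor_mz=precursor_mz,
                peaks=peaks,
                charge=charge,
                structure=structure,
                rt=rt,
                metadata=metadata,
            )
        )
    return spectra


def write_mgf(
    spectra: list[Spectrum],
    path: str | Path,
    reactions_key: str = REACTIONS_KEY,
    smarts_key: str = SMARTS_KEY,
) -> None:
    """Write spectra (with any reactivity annotations) as MGF."""
    records = []
    for s in spectra:
        params: dict = {"title": s.id, "pepmass": s.precursor_mz, "charge": s.charge}
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        if s.structure is not None:
            params["smiles"] = s.structure
        meta = dict(s.metadata)
        observed = meta.pop("observed_reactions", None)
        if observed:
            params[reactions_key] = ",".join(sorted(observed))
        smarts = meta.pop("annotation_smarts", None)
        if smarts:
            params[smarts_key] = ";".join(smarts)
        params.update(meta)
        records.append(
            {
                "m/z array": np.array([mz for mz, _ in s.peaks]),
                "intensity array": np.array([i for _, i in s.peaks]),
                "params": params,
            }
        )
    _mgf.write(records, str(path), file_mode="w")


def spectra_from_features(features: list[Feature]) -> list[Spectrum]:
    """Annotated placeholder spectra for features (single precursor peak).

    Used to export reactivity evidence for features that carry no MS2 scan
    of their own; downstream tools only consume the header annotations.
    """
    out = []
    for f in features:
        meta: dict = {}
        if f.observed_reactions:
            meta["observed_reactions"] = set(f.observed_reactions)
        if f.annotation_smarts:
            meta["annotation_smarts"] = tuple(f.annotation_smarts)
        out.append(
            Spectrum(
                id=f.ms2_ref or f.id,
                precursor_mz=f.mz,
                peaks=[(f.mz, 100.0)],
                rt=f.rt,
                metadata=meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Feature / edge / match tables
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path) -> list[Feature]:
    """Read a long-form feature table: id,mz,rt,sample,condition,area."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    neg = df.index[df["area"] < 0]
    if len(neg):
        raise IOError_(f"{path}: negative area at row {int(neg[0]) + 2}")
    dup = df.duplicated(subset=["id", "sample"])
    if dup.any():
        raise IOError_(f"{path}: duplicated (id, sample) rows")
    features = []
    for fid, grp in df.groupby("id", sort=True):
        if grp["mz"].nunique() > 1 or grp["rt"].nunique() > 1:
            raise IOError_(f"{path}: inconsistent mz/rt for feature {fid}")
        features.append(
            Feature(
                id=str(fid),
                mz=float(grp["mz"].iloc[0]),
                rt=float(grp["rt"].iloc[0]),
                areas={str(r["sample"]): float(r["area"]) for _, r in grp.iterrows()},
                conditions={
                    str(r["sample"]): Condition(r["condition"])
                    for _, r in grp.iterrows()
                },
            )
        )
    return features


def write_feature_table(features: list[Feature], path: str | Path) -> None:
    rows = [
        {
            "id": f.id,
            "mz": f.mz,
            "rt": f.rt,
            "sample": s,
            "condition": f.conditions[s].value,
            "area": f.areas.get(s, 0.0),
        }
        for f in features
        for s in sorted(f.conditions)
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def write_edges(edges: list[ReactivityEdge], path: str | Path) -> None:
    rows = [
        {
            "precursor_id": e.precursor_id,
            "product_id": e.product_id,
            "reaction": e.reaction_id,
            "delta_observed": round(e.delta_observed, 6),
            "mass_error": round(e.mass_error, 6),
            "rt_delta": round(e.rt_delta, 4),
            "yield_pct": round(e.yield_pct, 4) if e.yield_pct is not None else "",
            "correlation": round(e.correlation, 4) if e.correlation is not None else "",
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, index=False)


def read_edges(path: str | Path) -> list[ReactivityEdge]:
    df = pd.read_csv(path)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    return [
        ReactivityEdge(
            precursor_id=str(r["precursor_id"]),
            product_id=str(r["product_id"]),
            reaction_id=str(r["reaction"]),
            delta_observed=float(r["delta_observed"]),
            mass_error=float(r["mass_error"]),
            rt_delta=float(r["rt_delta"]),
            yield_pct=None if pd.isna(r["yield_pct"]) else float(r["yield_pct"]),
            correlation=None if pd.isna(r["correlation"]) else float(r["correlation"]),
        )
        for _, r in df.iterrows()
    ]


def write_matches(matches: list[AnalogMatch], path: str | Path) -> None:
    rows = [
        {
            "query_id": m.query_id,
            "library_id": m.library_id,
            "structure": m.structure or "",
            "rank": rank,
            "score": round(m.score, 6),
            "n_matched": m.n_matched,
            "fg_consistent": "" if m.fg_consistent is None else m.fg_consistent,
            "precursor_delta": round(m.precursor_delta, 4),
        }
        for rank, m in enumerate(matches, start=1)
    ]
    pd.DataFrame(rows, columns=MATCH_COLUMNS).to_csv(path, index=False)


def read_matches(path: str | Path) -> list[AnalogMatch]:
    df = pd.read_csv(path)
    missing = [c for c in MATCH_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    df = df.sort_values(["query_id", "rank"], kind="stable")
    return [
        AnalogMatch(
            query_id=str(r["query_id"]),
            library_id=str(r["library_id"]),
            structure=None if pd.isna(r["structure"]) or r["structure"] == "" else str(r["structure"]),
            score=float(r["score"]),
            n_matched=int(r["n_matched"]),
            precursor_delta=float(r["precursor_delta"]),
            fg_consistent=None if pd.isna(r["fg_consistent"]) else bool(r["fg_consistent"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Registry config, network, provenance
# ---------------------------------------------------------------------------


def save_registry(registry: list[Reaction], path: str | Path) -> None:
    doc = [
        {
            "id": r.id,
            "reagent": r.reagent,
            "net_change": r.net_change.to_string(),
            "min_yield_pct": r.min_yield_pct,
            "patterns": [{"label": lab, "smarts": s} for lab, s in r.patterns],
        }
        for r in registry
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_registry(path: str | Path) -> list[Reaction]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise IOError_(f"{path}: registry config must be a list of reactions")
    return [
        Reaction(
            id=str(entry["id"]),
            reagent=str(entry.get("reagent", "")),
            net_change=parse_formula(str(entry["net_change"])),
            patterns=tuple(
                (str(p["label"]), str(p["smarts"])) for p in entry["patterns"]
            ),
            min_yield_pct=float(entry.get("min_yield_pct", 0.0)),
        )
        for entry in doc
    ]


def write_graphml(
    edges: list[ReactivityEdge], features: list[Feature], path: str | Path
) -> None:
    nx.write_graphml(build_network(edges, features), str(path))


def write_provenance(path: str | Path, **entries) -> None:
    """Record inputs, parameters and versions alongside an output directory."""
    from . import __version__

    doc = {
        "mchem_version": __version__,
        "python": sys.version.split()[0],
        **entries,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
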